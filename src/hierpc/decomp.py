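"""PARAFAC decomposition, core consistency, model fitting and comparison.

The pooled contrast tensor (Channel x Time-Frequency x Contrast) is
factorized as a sum of rank-1 components ``sum_r a_r o b_r o c_r`` by
alternating least squares (CP/PARAFAC).  Two uses:

* *model-free*: all three modes free; the core consistency diagnostic
  (CORCONDIA) selects the number of latent components;
* *model-driven*: the Contrast mode is fixed to the signal profiles a
  candidate model predicts, and only the spatial and spectro-temporal
  loadings are estimated.  A grid search over the model's scaling factors
  minimizes the residual sum of squares subject to a consistency floor, and
  candidate models are compared by BIC.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pcmodel import (
    MODEL_1LEVEL_SP,
    MODEL_1LEVEL_TP,
    MODEL_2LEVEL,
    MODEL_ADAPTATION,
    MODEL_FREE,
    ModelSpec,
    ScalingFactors,
    profile_for,
)

__all__ = [
    "FactorModel",
    "FitResult",
    "ModelComparisonRow",
    "parafac",
    "corcondia",
    "fit_fixed_contrast",
    "grid_search",
    "bic",
    "compare_models",
    "congruence",
    "default_grids",
]

DEFAULT_TOL = 1e-6
DEFAULT_CONSISTENCY_FLOOR = 80.0


@dataclass
class FactorModel:
    """CP loadings and fit diagnostics.

    ``a`` (channels x k), ``b`` (time-frequency x k), ``c`` (contrasts x k).
    When ``fixed_c`` is True, ``c`` is exactly the matrix that was supplied.
    Scale is carried by ``b``; free modes have unit-norm columns with the
    largest-magnitude entry of each ``a`` (and free ``c``) column positive.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    k: int
    rss: float
    n_iter: int
    converged: bool
    fixed_c: bool = False
    tol: float = DEFAULT_TOL
    init: str = "svd"
    seed: int = 0
    rss_history: list = field(default_factory=list, repr=False)

    def reconstruct(self) -> np.ndarray:
        return np.einsum("ir,jr,kr->ijk", self.a, self.b, self.c)


def _mttkrp(x, f1, f2, mode):
    """Matricized tensor times Khatri-Rao product for one mode."""
    if mode == 0:
        return np.einsum("ijk,jr,kr->ir", x, f1, f2, optimize=True)
    if mode == 1:
        return np.einsum("ijk,ir,kr->jr", x, f1, f2, optimize=True)
    return np.einsum("ijk,ir,jr->kr", x, f1, f2, optimize=True)


def _solve_gram(gram, rhs):
    try:
        return np.linalg.solve(gram, rhs.T).T
    except np.linalg.LinAlgError:
        return rhs @ np.linalg.pinv(gram)


def _svd_init(x, k, rng):
    factors = []
    for mode in range(3):
        unf = np.moveaxis(x, mode, 0).reshape(x.shape[mode], -1)
        n = unf.shape[0]
        try:
            if n <= unf.shape[1]:
                u, _, _ = np.linalg.svd(unf @ unf.T, hermitian=True)
            else:
                u, _, _ = np.linalg.svd(unf, full_matrices=False)
        except np.linalg.LinAlgError:
            u = rng.standard_normal((n, max(k, 1)))
        if u.shape[1] < k:
            u = np.hstack([u, rng.standard_normal((n, k - u.shape[1]))])
        factors.append(u[:, :k].copy())
    return factors


def _dtld_init(x, k, rng):
    """Direct-trilinear-decomposition initialization (GRAM).

    Compresses the tensor to a k x k x 2 core, solves the generalized
    eigenproblem of the two core slabs for the first-mode loadings, and
    fills the remaining modes by one least-squares pass.  Requires
    ``k <= min(I, J)`` and ``K >= 2``.
    """
    i_dim, j_dim, k_dim = x.shape
    if k > min(i_dim, j_dim) or k_dim < 2:
        raise np.linalg.LinAlgError("tensor too small for DTLD")
    u1, u2, u3 = (f[:, :d] for f, d in zip(_svd_init(x, max(k, 2), rng), (k, k, 2)))
    core = np.einsum("ip,jq,kr,ijk->pqr", u1, u2, u3, x, optimize=True)
    s1, s2 = core[:, :, 0], core[:, :, 1]
    m = s1 @ np.linalg.pinv(s2)
    vals, vecs = np.linalg.eig(m)
    order = np.argsort(-np.abs(vals))
    a = np.real(u1 @ vecs[:, order[:k]])
    if not np.all(np.isfinite(a)) or np.linalg.matrix_rank(a) < k:
        raise np.linalg.LinAlgError("degenerate DTLD eigenvectors")
    # one LS pass for the other modes given a
    b = rng.standard_normal((j_dim, k))
    c = rng.standard_normal((k_dim, k))
    gram = (a.T @ a) * (c.T @ c)
    b = _solve_gram(gram, _mttkrp(x, a, c, 1))
    gram = (a.T @ a) * (b.T @ b)
    c = _solve_gram(gram, _mttkrp(x, a, b, 2))
    return [a, b, c]


def _normalize(fm: FactorModel) -> FactorModel:
    """Unit-norm/sign convention: scale into b, dominant entries positive."""
    for mat, is_free in ((fm.a, True), (fm.c, not fm.fixed_c)):
        if not is_free:
            continue
        norms = np.linalg.norm(mat, axis=0)
        norms[norms == 0] = 1.0
        signs = np.array([np.sign(col[np.argmax(np.abs(col))]) or 1.0 for col in (mat / norms).T])
        mat /= norms * signs
        fm.b *= norms * signs
    return fm


def parafac(
    tensor,
    k: int,
    init: str = "svd",
    tol: float = DEFAULT_TOL,
    max_iter: int = 500,
    seed: int = 0,
    fixed_c=None,
) -> FactorModel:
    """CP decomposition by alternating least squares.

    Parameters
    ----------
    tensor : ndarray or ContrastTensor
        3-way array (channels x time-frequency x contrasts).
    k : int
        Number of rank-1 components.
    init : {"svd", "dtld", "random"}
        Initialization; DTLD falls back to SVD (with a warning) when the
        eigen construction is infeasible.
    tol : float
        Relative change in fit at which iteration stops.
    fixed_c : ndarray, optional
        (contrasts x k) matrix to hold the third mode fixed at (model-driven
        factorization).  The returned ``c`` is this matrix, bit-identical.
    """
    x = np.asarray(getattr(tensor, "values", tensor), dtype=float)
    if x.ndim != 3:
        raise ValueError("tensor must be 3-way")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    if fixed_c is not None:
        fixed_c = np.asarray(fixed_c, dtype=float)
        if fixed_c.shape != (x.shape[2], k):
            raise ValueError(
                f"fixed_c must be (n_contrasts, k) = {(x.shape[2], k)}, got {fixed_c.shape}"
            )
    if init == "random":
        factors = [rng.standard_normal((d, k)) for d in x.shape]
    elif init == "svd":
        factors = _svd_init(x, k, rng)
    elif init == "dtld":
        try:
            factors = _dtld_init(x, k, rng)
        except np.linalg.LinAlgError as err:
            warnings.warn(f"DTLD initialization failed ({err}); falling back to SVD")
            factors = _svd_init(x, k, rng)
    else:
        raise ValueError(f"unknown init {init!r}")
    if fixed_c is not None:
        factors[2] = fixed_c.copy()
    norm_x2 = float(np.sum(x * x))
    modes = (0, 1) if fixed_c is not None else (0, 1, 2)
    rss_prev = np.inf
    rss = norm_x2
    history = []
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        for mode in modes:
            others = [factors[m] for m in range(3) if m != mode]
            gram = (others[0].T @ others[0]) * (others[1].T @ others[1])
            mtt = _mttkrp(x, others[0], others[1], mode)
            factors[mode] = _solve_gram(gram, mtt)
        # RSS from the last-updated mode: ||X||^2 - 2<X, Xhat> + ||Xhat||^2
        last = factors[modes[-1]]
        inner = float(np.sum(last * mtt))
        grams = [f.T @ f for f in factors]
        norm_hat2 = float(np.sum(grams[0] * grams[1] * grams[2]))
        rss = max(norm_x2 - 2.0 * inner + norm_hat2, 0.0)
        history.append(rss)
        denom = max(norm_x2, np.finfo(float).tiny)
        last_change = abs(rss_prev - rss) / denom
        if last_change < tol:
            converged = True
            break
        rss_prev = rss
    if not converged:
        warnings.warn(
            f"PARAFAC did not converge in {max_iter} iterations "
            f"(last relative fit change {last_change:.2e})"
        )
    fm = FactorModel(
        a=factors[0],
        b=factors[1],
        c=fixed_c if fixed_c is not None else factors[2],
        k=k,
        rss=rss,
        n_iter=n_iter,
        converged=converged,
        fixed_c=fixed_c is not None,
        tol=tol,
        init=init,
        seed=seed,
        rss_history=history,
    )
    return _normalize(fm)


def corcondia(tensor, fm: FactorModel) -> float:
    """Core consistency diagnostic, in percent (can be negative).

    Computes the least-squares Tucker core for the fitted CP loadings and
    measures its distance from the superidentity:
    ``100 * (1 - ||G - T||^2 / ||T||^2)``.
    """
    x = np.asarray(getattr(tensor, "values", tensor), dtype=float)
    pinvs = []
    for mat in (fm.a, fm.b, fm.c):
        if np.linalg.matrix_rank(mat) < mat.shape[1]:
            warnings.warn("singular loading matrix in CORCONDIA; using pseudo-inverse")
        pinvs.append(np.linalg.pinv(mat))
    g = np.einsum("pi,qj,rk,ijk->pqr", pinvs[0], pinvs[1], pinvs[2], x, optimize=True)
    t = np.zeros((fm.k,) * 3)
    for r in range(fm.k):
        t[r, r, r] = 1.0
    return float(100.0 * (1.0 - np.sum((g - t) ** 2) / fm.k))


def fit_fixed_contrast(tensor, c_profiles, tol: float = DEFAULT_TOL, max_iter: int = 500, seed: int = 0, init: str = "svd") -> FactorModel:
    """Model-driven factorization: Contrast mode fixed to ``c_profiles``.

    ``c_profiles`` is (n_contrasts x k) — one column per model component.
    Raises if the columns are collinear (the model's profiles cannot be
    distinguished by the fit).
    """
    c = np.asarray(c_profiles, dtype=float)
    if c.ndim != 2:
        raise ValueError("c_profiles must be 2-D (n_contrasts x k)")
    if np.linalg.matrix_rank(c) < c.shape[1]:
        bad = []
        norms = np.linalg.norm(c, axis=0)
        for p, q in itertools.combinations(range(c.shape[1]), 2):
            if norms[p] == 0 or norms[q] == 0:
                bad.append((p, q))
            elif abs(c[:, p] @ c[:, q]) / (norms[p] * norms[q]) > 1 - 1e-10:
                bad.append((p, q))
        raise ValueError(f"rank-deficient contrast profiles; collinear column pairs: {bad}")
    return parafac(tensor, k=c.shape[1], init=init, tol=tol, max_iter=max_iter, seed=seed, fixed_c=c)


@dataclass
class FitResult:
    """Grid-search outcome: per-point diagnostics and the best feasible fit."""

    grid: pd.DataFrame
    best_params: dict
    best_model: FactorModel
    best_rss: float
    best_consistency: float
    consistency_floor: float
    feasible: bool


def default_grids(model_id: str, scope: str) -> dict:
    """Default scaling-factor grids (steps 0.1 for s0/a/tau0, 0.2 for s1/s2)."""
    grids = {"s0": np.round(np.arange(0.0, 1.001, 0.1), 10)}
    if model_id in (MODEL_2LEVEL, MODEL_1LEVEL_TP, MODEL_1LEVEL_SP):
        grids["s1"] = np.round(np.arange(0.0, 2.001, 0.2), 10)
    if model_id == MODEL_2LEVEL:
        grids["s2"] = np.round(np.arange(0.0, 2.001, 0.2), 10)
        if scope == "across":
            grids["a"] = np.round(np.arange(0.0, 1.001, 0.1), 10)
    if model_id == MODEL_ADAPTATION:
        grids["tau0"] = np.round(np.arange(0.1, 2.001, 0.1), 10)
    return grids


def grid_search(
    tensor,
    designs,
    model_id: str = MODEL_2LEVEL,
    scope: str = "within",
    grids: dict = None,
    error_mode: str = "both",
    contrast_defs=None,
    consistency_floor: float = DEFAULT_CONSISTENCY_FLOOR,
    tol: float = DEFAULT_TOL,
    max_iter: int = 200,
    seed: int = 0,
    adaptation_seed: int = 0,
) -> FitResult:
    """Fit a candidate model over a grid of scaling factors.

    For every grid point the model's contrast profiles are generated, the
    tensor is factorized with the Contrast mode fixed to them, and RSS plus
    core consistency are recorded.  The best point minimizes RSS among
    points whose consistency exceeds ``consistency_floor`` (percent).
    """
    x = np.asarray(getattr(tensor, "values", tensor), dtype=float)
    if grids is None:
        grids = default_grids(model_id, scope)
    names = list(grids)
    records = []
    best = None
    for values in itertools.product(*(grids[n] for n in names)):
        params = dict(zip(names, values))
        try:
            factors = ScalingFactors(
                s0=params.get("s0", 1.0),
                s1=params.get("s1", 1.0),
                s2=params.get("s2", 1.0),
                tau0=params.get("tau0"),
                a=params.get("a"),
            )
            spec = ModelSpec(model_id, factors, error_mode)
            profile = profile_for(spec, designs, scope, contrast_defs=contrast_defs, seed=adaptation_seed)
            fm = fit_fixed_contrast(x, profile.values.T, tol=tol, max_iter=max_iter, seed=seed)
            cc = corcondia(x, fm)
            records.append({**params, "rss": fm.rss, "consistency": cc, "feasible": cc > consistency_floor})
            if cc > consistency_floor and (best is None or fm.rss < best[1].rss):
                best = (params, fm, cc)
        except (ValueError, np.linalg.LinAlgError) as err:
            records.append({**params, "rss": np.nan, "consistency": np.nan, "feasible": False, "error": str(err)})
    grid_df = pd.DataFrame.from_records(records)
    if best is None:
        return FitResult(grid_df, {}, None, np.nan, np.nan, consistency_floor, feasible=False)
    return FitResult(grid_df, best[0], best[1], best[1].rss, best[2], consistency_floor, feasible=True)


def bic(u: float, w: float, rss: float) -> float:
    """Bayesian information criterion ``u*ln(RSS/u) + w*ln(u)`` (natural log).

    ``u`` is the number of data points (the tensor size), ``w`` the number
    of estimated elements (sum of free-mode dimensions times the number of
    components).
    """
    if u <= 0 or rss <= 0:
        raise ValueError("u and rss must be positive")
    if w < 0:
        raise ValueError("w must be non-negative")
    return float(u * np.log(rss / u) + w * np.log(u))


@dataclass
class ModelComparisonRow:
    """One row of the model-comparison table."""

    model_id: str
    params: dict
    u: int
    w: int
    rss: float
    consistency: float
    bic: float
    k: int


def _model_free_k(scope: str) -> int:
    return 2 if scope == "within" else 3


def _fixed_model_k(model_id: str, scope: str) -> int:
    if model_id == MODEL_2LEVEL:
        return 2 if scope == "within" else 3
    if model_id in (MODEL_1LEVEL_TP, MODEL_1LEVEL_SP):
        return 1 if scope == "within" else 2
    if model_id == MODEL_ADAPTATION:
        return 1
    raise ValueError(f"no fixed-profile k for {model_id!r}")


def compare_models(
    tensor,
    designs,
    scope: str,
    model_ids=(MODEL_FREE, MODEL_2LEVEL, MODEL_1LEVEL_TP, MODEL_1LEVEL_SP, MODEL_ADAPTATION),
    grids: dict = None,
    error_mode: str = "both",
    contrast_defs=None,
    consistency_floor: float = DEFAULT_CONSISTENCY_FLOOR,
    tol: float = DEFAULT_TOL,
    max_iter: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit a set of candidate models and tabulate (u, w, RSS, BIC).

    ``grids`` optionally maps model_id -> parameter grids (see
    :func:`grid_search`); the number of data points is the tensor size and
    the number of estimated elements is (sum of free-mode dimensions) x k.
    """
    x = np.asarray(getattr(tensor, "values", tensor), dtype=float)
    i_dim, j_dim, k_dim = x.shape
    u = i_dim * j_dim * k_dim
    rows = []
    for model_id in model_ids:
        if model_id == MODEL_FREE:
            k = _model_free_k(scope)
            fm = parafac(x, k=k, init="svd", tol=tol, max_iter=max_iter, seed=seed)
            cc = corcondia(x, fm)
            w = (i_dim + j_dim + k_dim) * k
            b = bic(u, w, fm.rss) if fm.rss > 0 else -np.inf  # exact fit
            rows.append(ModelComparisonRow(model_id, {}, u, w, fm.rss, cc, b, k))
            continue
        k = _fixed_model_k(model_id, scope)
        fit = grid_search(
            x,
            designs,
            model_id=model_id,
            scope=scope,
            grids=None if grids is None else grids.get(model_id),
            error_mode=error_mode,
            contrast_defs=contrast_defs,
            consistency_floor=consistency_floor,
            tol=tol,
            max_iter=max_iter,
            seed=seed,
        )
        if not fit.feasible:
            rows.append(ModelComparisonRow(model_id, {}, u, (i_dim + j_dim) * k, np.nan, np.nan, np.nan, k))
            continue
        w = (i_dim + j_dim) * k
        b = bic(u, w, fit.best_rss) if fit.best_rss > 0 else -np.inf
        rows.append(
            ModelComparisonRow(model_id, fit.best_params, u, w, fit.best_rss, fit.best_consistency, b, k)
        )
    return pd.DataFrame(
        [
            {
                "model": r.model_id,
                "params": r.params,
                "u": r.u,
                "w": r.w,
                "k": r.k,
                "rss": r.rss,
                "consistency": r.consistency,
                "bic": r.bic,
            }
            for r in rows
        ]
    )


def congruence(u, v) -> float:
    """Tucker congruence |<u, v>| / (||u|| ||v||) between two loading vectors."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    return float(np.abs(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v)))
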