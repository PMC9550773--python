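"""Contrast enumeration, bootstrap significance testing and tensor assembly.

The analysis compares event-related spectral perturbations (ERSPs) between
trial types of the same block ("within-block") or between the same trial
type of two blocks with equal sequence length ("across-block"), keeping only
a linearly independent subset of all possible comparisons.  Significant
contrast values (subject-level bootstrap with FDR correction) are pooled
into a 3-way tensor *Channel x Time-Frequency x Contrast* for the
decomposition stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .paradigm import TRIAL_TYPES

__all__ = [
    "ContrastDefinition",
    "SignificanceMask",
    "ContrastTensor",
    "enumerate_contrasts",
    "bootstrap_significance",
    "assemble_tensor",
]


@dataclass(frozen=True)
class ContrastDefinition:
    """One contrast: ``minuend - subtrahend``, each a (block_id, trial_type)."""

    scope: str
    minuend: tuple
    subtrahend: tuple
    index: int

    def __post_init__(self):
        if self.scope not in ("within", "across"):
            raise ValueError(f"scope must be 'within' or 'across', got {self.scope!r}")
        if self.scope == "within":
            if self.minuend[0] != self.subtrahend[0] or self.minuend[1] == self.subtrahend[1]:
                raise ValueError("within contrast must compare two types of one block")
        else:
            if self.minuend[0] == self.subtrahend[0] or self.minuend[1] != self.subtrahend[1]:
                raise ValueError("across contrast must compare one type of two blocks")

    @property
    def label(self) -> str:
        if self.scope == "within":
            return f"{self.minuend[0]}:{self.minuend[1]}-{self.subtrahend[1]}"
        return f"{self.minuend[0]}-{self.subtrahend[0]}:{self.minuend[1]}"


def enumerate_contrasts(designs, scope: str):
    """The non-redundant contrast set over an 8-block design.

    Within each block only ``xy - xx`` and ``xo - xx`` are kept
    (``xy - xo`` is their difference), giving 16 contrasts.  Across blocks,
    each sequence-length group of 4 blocks is compared along the 4 edges of
    the cycle ``b1 - b2, b2 - b4, b4 - b3, b3 - b1`` (blocks in listed
    order; the 2 chords of the cycle are linear combinations of the edges),
    per trial type, giving 24 contrasts.
    """
    designs = list(designs)
    if scope == "within":
        defs = []
        for d in designs:
            for t in ("xy", "xo"):
                defs.append(
                    ContrastDefinition("within", (d.block_id, t), (d.block_id, "xx"), len(defs) + 1)
                )
        return defs
    if scope != "across":
        raise ValueError(f"scope must be 'within' or 'across', got {scope!r}")
    defs = []
    for n in (2, 3):
        group = [d for d in designs if d.n_tones == n]
        if len(group) != 4:
            raise ValueError(f"across contrasts need 4 blocks with n_tones={n}, got {len(group)}")
        b = [d.block_id for d in group]
        edges = [(b[0], b[1]), (b[1], b[3]), (b[3], b[2]), (b[2], b[0])]
        for t in TRIAL_TYPES:
            for m, s in edges:
                defs.append(ContrastDefinition("across", (m, t), (s, t), len(defs) + 1))
    return defs


@dataclass(frozen=True)
class SignificanceMask:
    """Boolean significance of a contrast map plus the test's provenance."""

    mask: np.ndarray
    alpha: float
    n_boot: int
    correction: str
    rule: str
    seed: int


def _bootstrap_means(x, n_boot, rng, chunk: int = 50):
    """Bootstrap distribution of the subject mean; shape (n_boot, ...).

    Resamples in chunks to bound peak memory at ``chunk * x.size`` floats.
    """
    n = x.shape[0]
    out = np.empty((n_boot,) + x.shape[1:])
    for start in range(0, n_boot, chunk):
        stop = min(start + chunk, n_boot)
        idx = rng.integers(0, n, size=(stop - start, n))
        out[start:stop] = x[idx].mean(axis=1)
    return out


def bootstrap_significance(
    ersp_a,
    ersp_b,
    n_boot: int = 1000,
    alpha: float = 0.05,
    rule: str = "disjoint",
    fdr_scope: str = "per_channel",
    seed: int = 0,
):
    """Significance-masked contrast response between two conditions.

    Parameters
    ----------
    ersp_a, ersp_b : ndarray, shape (n_subjects, n_channels, ...)
        Per-subject ERSP maps of the two conditions (paired: equal subject
        count required).
    rule : {"disjoint", "diff"}
        ``disjoint`` declares a pixel significant when the two conditions'
        bootstrap confidence intervals do not overlap (per-pixel p = the
        smallest level at which they separate).  ``diff`` uses the two-sided
        bootstrap p-value of the mean difference.
    fdr_scope : {"per_channel", "joint"}
        Family for the Benjamini-Hochberg correction.

    Returns
    -------
    contrast : ndarray
        ``mean(ersp_a) - mean(ersp_b)`` with nonsignificant pixels set to 0.
    sig : SignificanceMask
    """
    ersp_a = np.asarray(ersp_a, dtype=float)
    ersp_b = np.asarray(ersp_b, dtype=float)
    if ersp_a.shape[0] != ersp_b.shape[0]:
        raise ValueError(
            f"subject-count mismatch: {ersp_a.shape[0]} vs {ersp_b.shape[0]}"
        )
    if ersp_a.shape[1:] != ersp_b.shape[1:]:
        raise ValueError("condition maps must share their grid")
    if rule not in ("disjoint", "diff"):
        raise ValueError(f"unknown rule {rule!r}")
    rng = np.random.default_rng(seed)
    shape = ersp_a.shape[1:]
    flat_a = ersp_a.reshape(ersp_a.shape[0], -1)
    flat_b = ersp_b.reshape(ersp_b.shape[0], -1)
    boot_a = _bootstrap_means(flat_a, n_boot, rng)
    boot_b = _bootstrap_means(flat_b, n_boot, rng)
    if rule == "diff":
        diff = boot_a - boot_b  # bootstrap of the mean difference
        p_hi = (diff <= 0).mean(axis=0)
        p_lo = (diff >= 0).mean(axis=0)
        pvals = np.minimum(2 * np.minimum(p_hi, p_lo), 1.0)
        pvals = np.maximum(pvals, 1.0 / n_boot)
    else:
        boot_a = np.sort(boot_a, axis=0)
        boot_b = np.sort(boot_b, axis=0)
        # Smallest CI level at which the per-condition intervals separate:
        # the (m, n_boot-1-m) order statistics bound the two-sided CI at
        # level alpha = 2*(m+1)/(n_boot+1).  Separation is monotone in m
        # (wider CIs separate less easily), so the first separating m while
        # scanning from the widest CI upward gives the per-pixel p-value.
        pvals = np.ones(flat_a.shape[1])
        undecided = np.ones(flat_a.shape[1], dtype=bool)
        m_max = (n_boot - 1) // 2
        for m in range(0, m_max + 1):
            sep = (boot_a[m] > boot_b[n_boot - 1 - m]) | (boot_b[m] > boot_a[n_boot - 1 - m])
            newly = sep & undecided
            if newly.any():
                pvals[newly] = min(2.0 * (m + 1) / (n_boot + 1), 1.0)
                undecided &= ~newly
                if not undecided.any():
                    break
    if fdr_scope == "joint":
        reject = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    elif fdr_scope == "per_channel":
        n_ch = shape[0]
        per_ch = pvals.reshape(n_ch, -1)
        reject = np.stack(
            [multipletests(p, alpha=alpha, method="fdr_bh")[0] for p in per_ch]
        ).reshape(-1)
    else:
        raise ValueError(f"unknown fdr_scope {fdr_scope!r}")
    mask = reject.reshape(shape)
    contrast = (flat_a.mean(axis=0) - flat_b.mean(axis=0)).reshape(shape)
    contrast = np.where(mask, contrast, 0.0)
    sig = SignificanceMask(mask=mask, alpha=alpha, n_boot=n_boot, correction=f"fdr_bh/{fdr_scope}", rule=rule, seed=seed)
    return contrast, sig


@dataclass(frozen=True)
class ContrastTensor:
    """Channel x Time-Frequency x Contrast array of masked contrast values.

    The time-frequency axis is flattened frequency-major: the value at
    (frequency f, time t) sits at flat index ``f * n_times + t``.
    """

    values: np.ndarray
    contrasts: tuple
    n_freqs: int
    n_times: int
    masks: tuple = None

    def __post_init__(self):
        if self.values.ndim != 3:
            raise ValueError("tensor must be 3-way")
        if self.values.shape[1] != self.n_freqs * self.n_times:
            raise ValueError("time-frequency axis does not match n_freqs * n_times")
        if self.values.shape[2] != len(self.contrasts):
            raise ValueError("contrast axis does not match the contrast list")

    @property
    def shape(self):
        return self.values.shape

    def unflatten(self, contrast_idx: int) -> np.ndarray:
        """Time-frequency maps (channels, freqs, times) of one contrast."""
        return self.values[:, :, contrast_idx].reshape(
            self.values.shape[0], self.n_freqs, self.n_times
        )


def assemble_tensor(maps, contrast_defs, masks=None) -> ContrastTensor:
    """Stack masked contrast maps (channels, freqs, times) into a tensor.

    The third-mode order equals the order of ``contrast_defs``; flattening
    of the (frequency, time) plane is frequency-major.
    """
    maps = [np.asarray(m, dtype=float) for m in maps]
    if len(maps) != len(contrast_defs):
        raise ValueError("one map per contrast required")
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ValueError("all contrast maps must share their grid")
    if len(shape) != 3:
        raise ValueError("maps must be (channels, freqs, times)")
    n_ch, n_f, n_t = shape
    values = np.stack([m.reshape(n_ch, n_f * n_t) for m in maps], axis=2)
    return ContrastTensor(values=values, contrasts=tuple(contrast_defs), n_freqs=n_f, n_times=n_t, masks=tuple(masks) if masks else None)
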