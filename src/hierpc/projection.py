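"""Single-trial projections onto component structures and their coupling.

Each extracted component defines a spatial vector S (over channels) and a
spectro-temporal matrix F/T (frequencies x times).  Projecting a single
trial's ERSP onto these — the bilinear form ``S @ ERSP @ (F/T)`` summed over
frequency — yields one scalar per trial per component.  Correlations between
the per-trial series of two components are adjusted by subtracting the mean
correlation obtained after randomly permuting each trial's ERSP values
(which preserves the value distribution but destroys the spatio-spectro-
temporal structure), controlling for overlap between the templates and for
global per-trial amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ComponentStructure",
    "ProjectionSeries",
    "CorrelationResult",
    "refine_structure",
    "project_trials",
    "adjusted_correlations",
    "group_test",
]


@dataclass(frozen=True)
class ComponentStructure:
    """Spatial + spectro-temporal template of one component."""

    label: str
    spatial: np.ndarray
    spectro_temporal: np.ndarray
    refined: bool = False

    def __post_init__(self):
        if np.asarray(self.spatial).ndim != 1 or np.asarray(self.spectro_temporal).ndim != 2:
            raise ValueError("spatial must be 1-D and spectro_temporal 2-D")


def _median_threshold(v: np.ndarray) -> np.ndarray:
    """Zero entries whose magnitude is strictly below the median magnitude."""
    v = np.array(v, dtype=float)
    med = np.median(np.abs(v))
    v[np.abs(v) < med] = 0.0
    return v


def refine_structure(spatial, spectro_temporal, label: str = "") -> ComponentStructure:
    """Median-threshold a component template.

    In each of the spatial and spectro-temporal parts, absolute values
    strictly below that part's median absolute value are set to zero (ties
    are kept); signs of surviving entries are preserved.
    """
    spatial = np.asarray(spatial, dtype=float)
    spectro_temporal = np.asarray(spectro_temporal, dtype=float)
    if not spatial.any() or not spectro_temporal.any():
        raise ValueError("cannot refine an all-zero structure")
    return ComponentStructure(
        label, _median_threshold(spatial), _median_threshold(spectro_temporal), refined=True
    )


@dataclass
class ProjectionSeries:
    """Per-trial scalar activations of one component in one block run."""

    label: str
    values: np.ndarray
    trial_info: object = None
    block_id: str = None

    def __len__(self):
        return len(self.values)


def project_trials(trial_ersps, structure: ComponentStructure, trial_info=None, block_id=None) -> ProjectionSeries:
    """Bilinear projection ``S @ ERSP @ F/T`` of every trial.

    ``trial_ersps`` is (n_trials, n_channels, n_freqs, n_times) or
    (n_trials, n_channels, n_freqs * n_times) with frequency-major
    flattening matching the structure's spectro-temporal shape.
    """
    x = np.asarray(trial_ersps, dtype=float)
    ft = structure.spectro_temporal
    if x.ndim == 3:
        x = x.reshape(x.shape[0], x.shape[1], *ft.shape)
    if x.shape[1] != len(structure.spatial) or x.shape[2:] != ft.shape:
        raise ValueError(
            f"trial ERSPs {x.shape[1:]} do not match structure "
            f"({len(structure.spatial)}, {ft.shape})"
        )
    vals = np.einsum("c,icft,ft->i", structure.spatial, x, ft, optimize=True)
    return ProjectionSeries(structure.label, vals, trial_info, block_id)


@dataclass
class CorrelationResult:
    """Raw, shuffle-expected and adjusted correlation for one component pair."""

    pair: tuple
    r: float
    r_shuffle: float
    adjusted: float
    n_shuffles: int
    n_trials: int
    seed: int


def _pearson(a, b):
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def adjusted_correlations(
    trial_ersps,
    structures,
    pairs=None,
    n_shuffles: int = 500,
    seed: int = 0,
    shuffle_mode: str = "joint",
) -> dict:
    """Shuffle-adjusted Pearson correlations between component activations.

    For every pair of structures the raw correlation ``r`` between the
    per-trial projection series is compared with ``r_shuffle`` — the mean
    correlation over ``n_shuffles`` re-projections in which each trial's
    ERSP values are randomly permuted (jointly over channels, frequencies
    and times by default; ``shuffle_mode='per_axis'`` permutes each axis
    independently instead).  The adjusted correlation is ``r - r_shuffle``.

    Returns ``{pair_label: CorrelationResult}``.
    """
    x = np.asarray(trial_ersps, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 trials")
    if shuffle_mode not in ("joint", "per_axis"):
        raise ValueError(f"unknown shuffle_mode {shuffle_mode!r}")
    structures = list(structures)
    labels = [s.label for s in structures]
    if pairs is None:
        pairs = [(labels[i], labels[j]) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    proj = {s.label: project_trials(x, s).values for s in structures}
    raw = {p: _pearson(proj[p[0]], proj[p[1]]) for p in pairs}
    rng = np.random.default_rng(seed)
    ntr = x.shape[0]
    flat = x.reshape(ntr, -1)
    acc = {p: 0.0 for p in pairs}
    n_used = {p: 0 for p in pairs}
    for _ in range(n_shuffles):
        if shuffle_mode == "joint":
            xs = rng.permuted(flat, axis=1).reshape(x.shape)
        else:
            xs = x
            for ax in range(1, x.ndim):
                idx = rng.permutation(x.shape[ax])
                xs = np.take(xs, idx, axis=ax)
        proj_s = {s.label: project_trials(xs, s).values for s in structures}
        for p in pairs:
            r = _pearson(proj_s[p[0]], proj_s[p[1]])
            if np.isfinite(r):
                acc[p] += r
                n_used[p] += 1
    out = {}
    for p in pairs:
        r_sh = acc[p] / n_used[p] if n_used[p] else np.nan
        out[p] = CorrelationResult(
            pair=p,
            r=raw[p],
            r_shuffle=r_sh,
            adjusted=raw[p] - r_sh if np.isfinite(raw[p]) else np.nan,
            n_shuffles=n_shuffles,
            n_trials=ntr,
            seed=seed,
        )
    return out


def group_test(adjusted_values) -> float:
    """Two-sided Wilcoxon signed-rank test of the adjusted correlations
    against a zero median, pooled over blocks x subjects."""
    vals = np.asarray(adjusted_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) < 5:
        raise ValueError("need at least 5 values")
    if np.all(vals == 0):
        raise ValueError("all-zero differences: signed-rank test undefined")
    return float(stats.wilcoxon(vals, alternative="two-sided").pvalue)
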