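"""Characterization of extracted components and of learning effects.

A fitted component lives in three tensor modes: a spatial loading over
channels, a flattened time-frequency loading, and a contrast profile.  This
module unflattens and normalizes the time-frequency loading (per-frequency
standardization, which equalizes the visual weight of frequencies whose raw
power scales differ), extracts spectral profiles, band-averaged time
courses, peak markers and baseline-referenced significance, builds
occurrence maps of significance masks, and summarizes early-vs-late learning
changes with a PCA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "BAND_DEFS",
    "ComponentProfile",
    "LearningMap",
    "profile_component",
    "occurrence_map",
    "learning_pca",
    "normalize_per_frequency",
]

#: canonical EEG frequency bands (Hz, inclusive edges)
BAND_DEFS = {"theta": (4, 7), "alpha": (8, 12), "beta": (13, 30), "gamma": (31, 100)}

DEFAULT_PROFILE_BASELINE = (-0.7, -0.4)


def normalize_per_frequency(tf_map: np.ndarray) -> np.ndarray:
    """Divide each frequency row by its standard deviation over time.

    Idempotent up to scale: constant-over-time rows (SD 0) are left as-is.
    """
    tf_map = np.asarray(tf_map, dtype=float)
    sd = tf_map.std(axis=-1, keepdims=True)
    return np.where(sd > 0, tf_map / np.where(sd > 0, sd, 1.0), tf_map)


@dataclass
class ComponentProfile:
    """Spatial, spectral and temporal summary of one fitted component."""

    label: str
    spatial: np.ndarray
    tf_map: np.ndarray
    tf_map_normalized: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    spectral_profile: np.ndarray
    band_traces: dict
    band_significance: dict
    peak_freq: float
    peak_latency: dict
    baseline: tuple


def profile_component(
    factor_model,
    component: int,
    freqs,
    times,
    label: str = None,
    band_defs: dict = None,
    baseline=DEFAULT_PROFILE_BASELINE,
    sd_factor: float = 3.0,
) -> ComponentProfile:
    """Profile one component of a fitted factor model.

    The flattened time-frequency loading is unfolded (frequency-major),
    normalized per frequency, and summarized as (i) a spectral profile — the
    maximum over time at each frequency — with its peak frequency, (ii)
    band-averaged time courses with per-band peak latencies, and (iii) a
    significance trace per band: samples exceeding ``sd_factor`` times the
    standard deviation of the trace in the ``baseline`` window.
    """
    freqs = np.asarray(freqs, dtype=float)
    times = np.asarray(times, dtype=float)
    band_defs = BAND_DEFS if band_defs is None else band_defs
    if component >= factor_model.k:
        raise ValueError(f"component {component} not in a k={factor_model.k} model")
    bmask = (times >= baseline[0] - 1e-9) & (times <= baseline[1] + 1e-9)
    if not bmask.any():
        raise ValueError(f"baseline {baseline} is outside the analysis window")
    spatial = factor_model.a[:, component]
    tf_map = factor_model.b[:, component].reshape(len(freqs), len(times))
    tf_norm = normalize_per_frequency(tf_map)
    spectral = tf_norm.max(axis=1)
    peak_freq = float(freqs[np.argmax(spectral)])
    traces, sig, peak_lat = {}, {}, {}
    for band, (lo, hi) in band_defs.items():
        rows = (freqs >= lo) & (freqs <= hi)
        if not rows.any():
            continue
        trace = tf_norm[rows].mean(axis=0)
        thresh = sd_factor * trace[bmask].std()
        traces[band] = trace
        sig[band] = trace > thresh
        peak_lat[band] = float(times[np.argmax(trace)])
    return ComponentProfile(
        label=label or f"component {component}",
        spatial=spatial,
        tf_map=tf_map,
        tf_map_normalized=tf_norm,
        freqs=freqs,
        times=times,
        spectral_profile=spectral,
        band_traces=traces,
        band_significance=sig,
        peak_freq=peak_freq,
        peak_latency=peak_lat,
        baseline=tuple(baseline),
    )


def occurrence_map(masks, times, baseline=DEFAULT_PROFILE_BASELINE, display_floor: float = 5.0):
    """Overall occurrence of significance across channels and contrasts.

    ``masks`` is an iterable of boolean (channels, freqs, times) arrays (one
    per contrast).  Returns the mean significance per time-frequency pixel,
    with values below ``display_floor`` times the per-frequency baseline
    standard deviation zeroed for display, alongside the raw mean.
    """
    masks = [np.asarray(m, dtype=float) for m in masks]
    mean_map = np.mean([m.mean(axis=0) for m in masks], axis=0)
    times = np.asarray(times, dtype=float)
    bmask = (times >= baseline[0] - 1e-9) & (times <= baseline[1] + 1e-9)
    if not bmask.any():
        raise ValueError(f"baseline {baseline} is outside the analysis window")
    sd = mean_map[:, bmask].std(axis=1, keepdims=True)
    display = np.where(mean_map > display_floor * sd, mean_map, 0.0)
    return display, mean_map


@dataclass
class LearningMap:
    """Late-minus-early change in significant contrast responses."""

    diff: np.ndarray
    pc1_map: np.ndarray
    channel_weights: np.ndarray
    explained_variance_ratio: float
    degenerate: bool


def learning_pca(masks_early, masks_late) -> LearningMap:
    """First principal component of the late-minus-early significance change.

    Inputs are boolean (channels, freqs, times) masks, one per phase.  The
    difference per channel takes values in {-1, 0, 1}; rows (channels) are
    mean-centered and the
    first principal component of the channels x time-frequency matrix is
    returned with its channel weights, sign-fixed so the dominant channel
    weight is positive.  An all-zero difference yields a degenerate result.
    """
    early = np.asarray(masks_early)
    late = np.asarray(masks_late)
    if early.shape != late.shape:
        raise ValueError("early and late masks must share their shape")
    diff = late.astype(int) - early.astype(int)
    n_ch = diff.shape[0]
    flat = diff.reshape(n_ch, -1).astype(float)
    if not np.any(diff):
        return LearningMap(diff, None, None, 0.0, degenerate=True)
    centered = flat - flat.mean(axis=1, keepdims=True)
    if np.allclose(centered, 0):
        return LearningMap(diff, None, None, 0.0, degenerate=True)
    pca = PCA(n_components=1)
    scores = pca.fit_transform(centered)[:, 0]
    pc1 = pca.components_[0]
    sign = np.sign(scores[np.argmax(np.abs(scores))]) or 1.0
    shape = diff.shape[1:]
    return LearningMap(
        diff,
        (pc1 * sign).reshape(shape),
        scores * sign,
        float(pca.explained_variance_ratio_[0]),
        degenerate=False,
    )
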