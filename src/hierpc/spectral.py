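"""Time-frequency power and event-related spectral perturbation (ERSP).

Per-trial time-frequency representations are obtained by Morlet wavelet
convolution (7-cycle wavelets at integer center frequencies, 1-100 Hz by
default) and converted to decibels against a pre-stimulus baseline.  The
contrast analysis then works on a fixed window around the onset of the last
tone of each sequence (375 samples at 500 Hz by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from mne.time_frequency import tfr_array_morlet

__all__ = [
    "EpochSet",
    "TimeFrequencyMap",
    "EdgeArtifactError",
    "default_freqs",
    "morlet_tfr",
    "ersp",
    "analysis_window",
    "DEFAULT_ANALYSIS_WINDOW",
]

DEFAULT_BASELINE = (-0.2, 0.0)
#: analysis window (seconds) relative to the last-tone onset; 0.75 s at
#: 500 Hz = 375 samples
DEFAULT_ANALYSIS_WINDOW = (-0.25, 0.50)


class EdgeArtifactError(ValueError):
    """Raised when the epoch is too short for the requested wavelets."""


def default_freqs() -> np.ndarray:
    """Integer center frequencies 1..100 Hz."""
    return np.arange(1.0, 101.0)


@dataclass
class EpochSet:
    """Epoched multichannel signals with per-trial labels.

    ``data`` is (n_trials, n_channels, n_times); ``tmin`` is the time of the
    first sample relative to the first-tone onset.  ``trial_info`` is a
    DataFrame with (at least) columns ``block``, ``trial_type``, ``run`` and
    ``trial_index``; ``last_tone`` is the onset time of the final stimulus
    slot relative to the first tone (0.2 s for 2-tone, 0.4 s for 3-tone
    sequences).
    """

    data: np.ndarray
    sfreq: float
    ch_names: list
    tmin: float
    trial_info: pd.DataFrame
    last_tone: float = 0.2
    montage: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, times)")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.ch_names) != self.data.shape[1]:
            raise ValueError("one channel name per channel required")
        if len(self.trial_info) != self.data.shape[0]:
            raise ValueError("one trial_info row per trial required")

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[2]) / self.sfreq

    def select(self, **criteria) -> "EpochSet":
        """Subset trials by trial_info column values (e.g. trial_type='xy')."""
        keep = np.ones(len(self.trial_info), dtype=bool)
        for col, val in criteria.items():
            vals = self.trial_info[col].to_numpy()
            keep &= np.isin(vals, val) if isinstance(val, (list, tuple, set)) else vals == val
        return EpochSet(
            self.data[keep],
            self.sfreq,
            self.ch_names,
            self.tmin,
            self.trial_info[keep].reset_index(drop=True),
            self.last_tone,
            self.montage,
        )


@dataclass
class TimeFrequencyMap:
    """Power or dB values on a channels x frequencies x times grid."""

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    units: str = "power"
    alignment: str = "first_tone"

    def crop(self, tmin: float, tmax: float) -> "TimeFrequencyMap":
        keep = (self.times >= tmin - 1e-9) & (self.times < tmax - 1e-9)
        return TimeFrequencyMap(self.values[..., keep], self.freqs, self.times[keep], self.units, self.alignment)


def morlet_tfr(
    epochs: EpochSet,
    freqs=None,
    n_cycles: float = 7.0,
    pad: bool = False,
    decim: int = 1,
) -> TimeFrequencyMap:
    """Per-trial Morlet wavelet power.

    A wavelet at frequency ``f`` spans ``n_cycles / f`` seconds; if the
    epoch is shorter than the longest wavelet an :class:`EdgeArtifactError`
    is raised unless ``pad`` is set, in which case the signal is zero-padded
    symmetrically and the result cropped back (edge values carry incomplete
    support and are attenuated accordingly).

    Returns a map with values (n_trials, n_channels, n_freqs, n_times).
    """
    freqs = default_freqs() if freqs is None else np.asarray(freqs, dtype=float)
    data = epochs.data
    n_times = data.shape[2]
    # Morlet wavelet support: +-5 Gaussian SDs, sigma_t = n_cycles / (2 pi f)
    support = int(np.ceil(10.0 * n_cycles / (2 * np.pi * freqs.min()) * epochs.sfreq)) + 1
    if support > n_times:
        if not pad:
            raise EdgeArtifactError(
                f"epoch of {n_times} samples is shorter than the "
                f"{support}-sample wavelet at {freqs.min():g} Hz; enable pad="
                "True or raise the lowest frequency"
            )
        lpad = (support - n_times) // 2 + 1
        data = np.pad(data, ((0, 0), (0, 0), (lpad, lpad)))
    power = tfr_array_morlet(
        data, sfreq=epochs.sfreq, freqs=freqs, n_cycles=n_cycles, output="power", decim=decim
    )
    if data.shape[2] != n_times:
        start = (data.shape[2] - n_times) // 2 if decim == 1 else 0
        if decim != 1:
            raise ValueError("pad and decim cannot be combined")
        power = power[..., lpad : lpad + n_times]
    times = epochs.times[::decim]
    return TimeFrequencyMap(power, freqs, times[: power.shape[-1]], units="power")


def ersp(
    tfr: TimeFrequencyMap,
    baseline=DEFAULT_BASELINE,
    average: bool = True,
    eps_scale: float = 1e-12,
) -> TimeFrequencyMap:
    """Baseline-normalized power in decibels.

    With ``average=True`` (the condition-level ERSP) the power is first
    averaged over trials, then divided by its mean baseline per channel and
    frequency and log-scaled: ``10*log10(P / mean_baseline(P))`` — so the
    baseline window averages to 0 dB up to the within-window power trend.
    With ``average=False`` each trial is normalized by its own baseline
    (single-trial dB maps for the projection analysis).  Zero baseline power
    is floored at ``eps_scale`` times the map's mean power.
    """
    if tfr.units != "power":
        raise ValueError("ersp expects a power map")
    bmask = (tfr.times >= baseline[0] - 1e-9) & (tfr.times <= baseline[1] + 1e-9)
    if not bmask.any():
        raise ValueError(f"baseline {baseline} is outside the epoch")
    power = tfr.values
    if average and power.ndim == 4:
        power = power.mean(axis=0)
    base = power[..., bmask].mean(axis=-1, keepdims=True)
    floor = eps_scale * max(power.mean(), np.finfo(float).tiny)
    if (base <= 0).any():
        import warnings

        warnings.warn("zero baseline power in some channel x frequency cells; flooring")
    base = np.maximum(base, floor)
    db = 10.0 * np.log10(np.maximum(power, floor) / base)
    return TimeFrequencyMap(db, tfr.freqs, tfr.times, units="dB", alignment=tfr.alignment)


def analysis_window(
    tf_map: TimeFrequencyMap,
    last_tone: float,
    window=DEFAULT_ANALYSIS_WINDOW,
    n_samples: int = None,
) -> TimeFrequencyMap:
    """Crop a map to the contrast-analysis window around the last tone.

    The window is expressed relative to the last-tone onset; the returned
    times are re-aligned so 0 is the last-tone onset.  If ``n_samples`` is
    given the crop is trimmed/validated to exactly that many samples.
    """
    cropped = tf_map.crop(last_tone + window[0], last_tone + window[1])
    values, times = cropped.values, cropped.times - last_tone
    if n_samples is not None:
        if values.shape[-1] < n_samples:
            raise ValueError(
                f"window yields {values.shape[-1]} samples; {n_samples} requested"
            )
        values = values[..., :n_samples]
        times = times[:n_samples]
    return TimeFrequencyMap(values, tf_map.freqs, times, cropped.units, alignment="last_tone")
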