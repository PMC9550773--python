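"""Ground-truth synthetic datasets for every stage of the pipeline.

The generators invert the analysis' forward model: four components (P1, P2,
PE1, PE2) with known spatial and spectro-temporal signatures are scaled by
the predictive-coding model's signal strengths per block and trial type and
summed into ERSP-level maps (plus subject effects and pixel noise), or
rendered as oscillatory bursts in raw epochs.  Because prediction signals
are identical across trial types, within-block contrast tensors built from
these maps are exactly rank 2 in expectation (PE1, PE2) and across-block
tensors exactly rank 3 (P1, P2, mixed PE).

Component signatures follow the reported physiology: prediction signals are
pre-stimulus beta oscillations (P1 high-beta ~23 Hz, central; P2 low-beta
~15 Hz, frontal) and prediction errors are post-stimulus gamma bursts (PE1
~156 ms, centrolateral; PE2 ~192 ms, central midline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .paradigm import TRIAL_TYPES, BlockDesign, default_designs, generate_trial_order
from .pcmodel import (
    ScalingFactors,
    adaptation_trial_responses,
    signal_strengths,
    single_trial_amplitudes,
)
from .projection import ComponentStructure
from .spectral import EpochSet

__all__ = [
    "GroundTruth",
    "SynthConfig",
    "COMPONENT_SIGNATURES",
    "default_montage",
    "make_ground_truth",
    "simulate_ersp_dataset",
    "simulate_contrast_maps",
    "model_contrast_tensor",
    "random_rank_tensor",
    "simulate_epochs",
    "simulate_single_trial_ersps",
    "simulate_adaptation_only",
]

#: (peak frequency Hz, sigma_f Hz, peak time s rel. last tone, sigma_t s,
#:  spatial centers in montage coordinates, spatial sigma)
COMPONENT_SIGNATURES = {
    "P1": dict(freq=23.0, sigma_f=3.0, time=-0.10, sigma_t=0.06, centers=((0.0, 0.0),), sigma_s=0.35),
    "P2": dict(freq=15.0, sigma_f=2.5, time=-0.12, sigma_t=0.07, centers=((0.0, 0.75),), sigma_s=0.35),
    "PE1": dict(freq=62.0, sigma_f=6.0, time=0.156, sigma_t=0.035, centers=((-0.55, 0.1), (0.55, 0.1)), sigma_s=0.25),
    "PE2": dict(freq=40.0, sigma_f=6.0, time=0.192, sigma_t=0.045, centers=((0.0, 0.15),), sigma_s=0.25),
}


def default_montage(n_channels: int = 60) -> np.ndarray:
    """Planar (x, y) scalp coordinates on concentric rings, unit head radius."""
    rings = [1, 6, 12, 18, 23]
    radii = [0.0, 0.25, 0.5, 0.75, 0.95]
    pts = []
    ring = 0
    while len(pts) < n_channels:
        n_on, r = (rings[ring], radii[ring]) if ring < len(rings) else (24, 1.05)
        for i in range(n_on):
            if len(pts) >= n_channels:
                break
            th = 2 * np.pi * i / n_on + (0.5 * np.pi)
            pts.append((r * np.cos(th), r * np.sin(th)))
        ring += 1
    return np.array(pts[:n_channels])


@dataclass
class GroundTruth:
    """Known component structures plus the generating model conditions."""

    structures: dict
    factors: ScalingFactors
    error_mode: str
    freqs: np.ndarray
    times: np.ndarray
    montage: np.ndarray
    noise_sd: float
    subject_sd: float
    gain_sd: float
    seed: int

    def structure(self, label) -> ComponentStructure:
        return self.structures[label]


@dataclass
class SynthConfig:
    """Study conditions for the synthetic experiment.

    Defaults match the reference study: 30 subjects, the 8-block grid with
    144 sequences per block, ERSP-level generation.
    """

    designs: list = field(default_factory=default_designs)
    n_subjects: int = 30
    level: str = "ersp"
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.level not in ("ersp", "epochs"):
            raise ValueError("level must be 'ersp' or 'epochs'")


def _gauss2d(xy, centers, sigma):
    v = np.zeros(len(xy))
    for cx, cy in centers:
        v += np.exp(-((xy[:, 0] - cx) ** 2 + (xy[:, 1] - cy) ** 2) / (2 * sigma**2))
    return v


def make_ground_truth(
    n_channels: int = 60,
    freqs=None,
    times=None,
    factors: ScalingFactors = None,
    error_mode: str = "both",
    noise_sd: float = 0.03,
    subject_sd: float = 0.2,
    gain_sd: float = 0.3,
    seed: int = 0,
) -> GroundTruth:
    """Construct the four-component ground truth.

    ``factors`` defaults to the reported best fit (s0=0.3, s1=0.8, s2=1.0,
    a=0.5).  ``noise_sd`` is the pixel noise (dB) added to subject-level
    ERSP maps and ``subject_sd`` the log-SD of per-subject component gains;
    ``gain_sd`` is the log-SD of the trial-to-trial prediction-gain jitter
    used by the single-trial generator.
    """
    if factors is None:
        factors = ScalingFactors(s0=0.3, s1=0.8, s2=1.0, a=0.5)
    freqs = np.arange(1.0, 101.0) if freqs is None else np.asarray(freqs, dtype=float)
    times = (-0.25 + np.arange(375) / 500.0) if times is None else np.asarray(times, dtype=float)
    montage = default_montage(n_channels)
    structures = {}
    for label, sig in COMPONENT_SIGNATURES.items():
        spatial = _gauss2d(montage, sig["centers"], sig["sigma_s"])
        ft = np.exp(
            -((freqs[:, None] - sig["freq"]) ** 2) / (2 * sig["sigma_f"] ** 2)
            - ((times[None, :] - sig["time"]) ** 2) / (2 * sig["sigma_t"] ** 2)
        )
        structures[label] = ComponentStructure(label, spatial, ft)
    gt = GroundTruth(
        structures, factors, error_mode, freqs, times, montage, noise_sd, subject_sd, gain_sd, seed
    )
    labels = list(structures)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            vi = np.outer(structures[labels[i]].spatial, structures[labels[i]].spectro_temporal.ravel()).ravel()
            vj = np.outer(structures[labels[j]].spatial, structures[labels[j]].spectro_temporal.ravel()).ravel()
            cong = abs(vi @ vj) / (np.linalg.norm(vi) * np.linalg.norm(vj))
            if cong >= 0.95:
                raise ValueError(f"ground-truth structures {labels[i]}/{labels[j]} nearly collinear ({cong:.3f})")
    return gt


def _component_amplitudes(design: BlockDesign, gt: GroundTruth) -> dict:
    """Mean component amplitudes per trial type from the generating model."""
    table = signal_strengths(design, gt.factors, gt.error_mode)
    return {
        t: {"P1": table.p1, "P2": table.p2, "PE1": table.pe1(t), "PE2": table.pe2(t)}
        for t in TRIAL_TYPES
    }


def simulate_ersp_dataset(config: SynthConfig, gt: GroundTruth) -> dict:
    """Per-subject, per-condition ERSP maps.

    Returns ``{(subject, block_id, trial_type): map}`` with maps of shape
    (n_channels, n_freqs, n_times).  Each subject scales every component by
    an independent mean-one lognormal gain (log-SD ``gt.subject_sd``) and
    pixel noise of SD ``gt.noise_sd`` (dB) is added — noise at the
    subject-mean level, emulating the residual trial-averaged variability.
    """
    rng = np.random.default_rng(config.seed)
    labels = list(gt.structures)
    outer = {
        lab: np.einsum("c,ft->cft", gt.structures[lab].spatial, gt.structures[lab].spectro_temporal)
        for lab in labels
    }
    mu = -0.5 * gt.subject_sd**2
    out = {}
    for subj in range(config.n_subjects):
        gains = dict(zip(labels, rng.lognormal(mu, gt.subject_sd, size=len(labels))))
        for design in config.designs:
            amps = _component_amplitudes(design, gt)
            for t in TRIAL_TYPES:
                m = sum(gains[lab] * amps[t][lab] * outer[lab] for lab in labels)
                m = m + rng.normal(0.0, gt.noise_sd, m.shape)
                out[(subj, design.block_id, t)] = m
    return out


def simulate_contrast_maps(dataset: dict, contrast_defs, n_subjects: int) -> dict:
    """Per-subject contrast maps ``{(subject, contrast_index): map_a, map_b}``
    arranged for :func:`hierpc.contrasts.bootstrap_significance`: returns
    ``{contrast_index: (stack_a, stack_b)}`` with stacks of shape
    (n_subjects, ...)."""
    out = {}
    for c in contrast_defs:
        a = np.stack([dataset[(s, c.minuend[0], c.minuend[1])] for s in range(n_subjects)])
        b = np.stack([dataset[(s, c.subtrahend[0], c.subtrahend[1])] for s in range(n_subjects)])
        out[c.index] = (a, b)
    return out


def model_contrast_tensor(
    profile_values: np.ndarray,
    n_channels: int = 20,
    n_tf: int = 500,
    noise: float = 0.0,
    seed: int = 0,
    loadings=None,
):
    """Exact trilinear tensor from a model contrast profile plus noise.

    ``profile_values`` is (k, n_contrasts) — each row becomes the fixed
    Contrast-mode loading of one rank-1 component; random (seeded) standard
    normal loadings fill the channel and time-frequency modes unless
    ``loadings`` supplies ``(a, b)``.  ``noise`` is the pixel noise SD
    relative to the signal RMS.  Returns ``(tensor, a, b)``.
    """
    rng = np.random.default_rng(seed)
    prof = np.asarray(profile_values, dtype=float)
    k = prof.shape[0]
    if loadings is None:
        a = rng.standard_normal((n_channels, k))
        b = rng.standard_normal((n_tf, k))
    else:
        a, b = (np.asarray(m, dtype=float) for m in loadings)
    x = np.einsum("ir,jr,kr->ijk", a, b, prof.T)
    if noise > 0:
        rms = np.sqrt(np.mean(x**2))
        x = x + rng.normal(0.0, noise * rms, x.shape)
    return x, a, b


def random_rank_tensor(shape=(60, 37500, 16), k: int = 2, noise: float = 0.0, seed: int = 0, max_congruence: float = 0.95):
    """Random exact rank-``k`` tensor with non-collinear loadings per mode.

    Returns ``(tensor, loadings)`` with ``loadings = [a, b, c]``.
    """
    rng = np.random.default_rng(seed)
    loadings = []
    for dim in shape:
        for _ in range(100):
            m = rng.standard_normal((dim, k))
            mn = m / np.linalg.norm(m, axis=0)
            if k == 1 or np.max(np.abs(np.triu(mn.T @ mn, 1))) < max_congruence:
                break
        loadings.append(m)
    x = np.einsum("ir,jr,kr->ijk", *loadings)
    if noise > 0:
        x = x + rng.normal(0.0, noise * np.sqrt(np.mean(x**2)), x.shape)
    return x, loadings


def simulate_epochs(
    design: BlockDesign,
    gt: GroundTruth,
    sfreq: float = 500.0,
    snr: float = 5.0,
    seed: int = 0,
    run: str = "A",
    n_channels: int = None,
) -> EpochSet:
    """Raw epochs for one block run: oscillatory bursts plus broadband noise.

    Each component contributes a burst whose carrier sits at the component's
    peak frequency and whose Gaussian envelope peaks at the component's
    latency relative to the last tone; burst amplitudes follow the model's
    per-trial-type signal strengths.  ``snr`` is the ratio of the strongest
    burst's envelope peak to the noise SD.  The epoch spans -1.5 s before
    the first tone to 1.9 s after the last tone (2.3 s / 2.5 s total for
    2-/3-tone sequences).
    """
    rng = np.random.default_rng(seed)
    nyq = sfreq / 2.0
    for lab, sig in COMPONENT_SIGNATURES.items():
        if sig["freq"] >= nyq:
            raise ValueError(f"component {lab} carrier {sig['freq']} Hz exceeds Nyquist ({nyq} Hz)")
    last_tone = 0.2 * (design.n_tones - 1)
    tmin, tmax = -1.5, last_tone + 1.9
    times = np.arange(tmin, tmax, 1.0 / sfreq)
    order = generate_trial_order(design, seed)
    amps = _component_amplitudes(design, gt)
    n_ch = n_channels or len(gt.montage)
    spatial = {lab: s.spatial[:n_ch] for lab, s in gt.structures.items()}
    peak_amp = max(max(a.values()) for a in amps.values())
    noise_sd = peak_amp / snr if snr > 0 else 0.0
    data = rng.normal(0.0, noise_sd, (len(order.labels), n_ch, len(times)))
    t_rel = times - last_tone
    for lab, sig in COMPONENT_SIGNATURES.items():
        env = np.exp(-((t_rel - sig["time"]) ** 2) / (2 * sig["sigma_t"] ** 2))
        phase = rng.uniform(0, 2 * np.pi)
        carrier = np.cos(2 * np.pi * sig["freq"] * t_rel + phase)
        burst = env * carrier
        for i, lab_t in enumerate(order.labels):
            data[i] += amps[lab_t][lab] * np.outer(spatial[lab], burst)
    info = pd.DataFrame(
        {
            "block": design.block_id,
            "trial_type": list(order.labels),
            "run": run,
            "trial_index": np.arange(len(order.labels)),
        }
    )
    return EpochSet(
        data=data,
        sfreq=sfreq,
        ch_names=[f"ch{i:02d}" for i in range(n_ch)],
        tmin=tmin,
        trial_info=info,
        last_tone=last_tone,
        montage=gt.montage[:n_ch],
    )


def simulate_single_trial_ersps(
    design: BlockDesign,
    gt: GroundTruth,
    noise_sd: float = 0.2,
    seed: int = 0,
    trials: str = "dominant",
):
    """Single-trial ERSP maps with model-coupled component amplitudes.

    Per-trial amplitudes come from :func:`hierpc.pcmodel.single_trial_amplitudes`
    (prediction-gain jitter, log-SD ``gt.gain_sd``), so the trial-to-trial
    couplings between P and PE amplitudes carry the model's sign structure.
    ``trials='dominant'`` keeps only the block's dominant sequence type —
    the regime for which the model states its correlation signs;
    ``trials='all'`` keeps the full pseudorandom series.

    Returns ``(maps, amplitudes)``: maps (n_trials, n_channels, n_freqs,
    n_times) and the amplitude DataFrame.
    """
    ss = np.random.SeedSequence([seed, gt.seed]).generate_state(2)
    amp = single_trial_amplitudes(design, gt.factors, gain_sd=gt.gain_sd, seed=int(ss[0]), error_mode=gt.error_mode)
    if trials == "dominant":
        dom = max(design.counts, key=design.counts.get)
        amp = amp[amp.trial_type == dom].reset_index(drop=True)
    elif trials != "all":
        raise ValueError("trials must be 'dominant' or 'all'")
    rng = np.random.default_rng(int(ss[1]))
    labels = list(gt.structures)
    outer = {
        lab: np.einsum("c,ft->cft", gt.structures[lab].spatial, gt.structures[lab].spectro_temporal)
        for lab in labels
    }
    maps = sum(amp[lab].to_numpy()[:, None, None, None] * outer[lab][None] for lab in labels)
    maps = maps + rng.normal(0.0, noise_sd, maps.shape)
    return maps, amp


def simulate_adaptation_only(design: BlockDesign, s0: float, tau0: float, seed: int = 0):
    """Trial-by-trial adaptation-only response amplitudes for one block."""
    return adaptation_trial_responses(design, s0, tau0, seed=seed)
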