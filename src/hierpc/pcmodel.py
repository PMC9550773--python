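"""Two-level predictive-coding model of the local-global paradigm.

The model has a sensory level (S), a first level encoding the tone-to-tone
transition structure, and a second level encoding the sequence structure.
Tones *x* and *y* are processed in separate streams.  At steady state each
level's prediction minimizes the mean-squared prediction error it receives:

* level 1 predicts the sensory input: ``P1_x = s0**(n-1) * TP_x`` and
  ``P1_y = TP_y``, where ``s0`` in [0, 1] scales the input to a tone that has
  been repeated ``n-1`` times (sensory adaptation; no adaptation in the
  y stream because *y* never repeats);
* level 2 predicts the magnitude of the first-level error:
  ``P2_x = SP_xx * |s0**(n-1) - P1_x*s1| + (1 - SP_xx) * P1_x*s1`` and
  analogously for the y stream with the input strength 1.

``s1`` and ``s2`` scale the first- and second-level predictions when errors
are computed (1 = optimal, <1 hypo-, >1 hyper-sensitive).  Prediction errors
are encoded as firing rates, i.e. as the absolute value of the signed
difference; the sign is kept alongside so that purely positive or purely
negative error computations (and their trial-to-trial correlation structure)
can be analyzed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .paradigm import (
    TRIAL_TYPES,
    BlockDesign,
    ProbabilitySet,
    generate_trial_order,
    no_ending_transition_probabilities,
    occurrence_probabilities,
    sequence_probabilities,
    transition_probabilities,
)

MODEL_2LEVEL = "2-level PC:TP+SP"
MODEL_1LEVEL_TP = "1-level PC:TP"
MODEL_1LEVEL_SP = "1-level PC:SP"
MODEL_NO_TRANSITION = "No-transition"
MODEL_NO_ENDING = "No-ending"
MODEL_ADAPTATION = "Adaptation-only"
MODEL_FREE = "Model-free"

ERROR_MODES = ("both", "positive_only", "negative_only")

_TWO_LEVEL_IDS = (MODEL_2LEVEL, MODEL_NO_TRANSITION, MODEL_NO_ENDING)
_ONE_LEVEL_IDS = (MODEL_1LEVEL_TP, MODEL_1LEVEL_SP)

__all__ = [
    "MODEL_2LEVEL",
    "MODEL_1LEVEL_TP",
    "MODEL_1LEVEL_SP",
    "MODEL_NO_TRANSITION",
    "MODEL_NO_ENDING",
    "MODEL_ADAPTATION",
    "MODEL_FREE",
    "ERROR_MODES",
    "ScalingFactors",
    "ModelSpec",
    "PredictionState",
    "SignalTable",
    "ContrastProfileMatrix",
    "optimal_predictions",
    "mspe1",
    "mspe2",
    "signal_strengths",
    "within_contrast_profile",
    "across_contrast_profile",
    "alt_model_profile",
    "adaptation_response",
    "adaptation_trial_responses",
    "adaptation_contrast_profile",
    "profile_for",
    "single_trial_amplitudes",
]


@dataclass(frozen=True)
class ScalingFactors:
    """Model tuning parameters.

    ``s0`` in [0, 1]: sensory adaptation floor (1 = none).  ``s1``, ``s2`` in
    [0, 2]: scaling of first/second-level predictions.  ``tau0`` (seconds, in
    [0.1, 2]) is the recovery time constant of the adaptation-only model and
    ``a`` in [0, 1] the PE1/PE2 mixing weight of the across-block fit; both
    are optional.
    """

    s0: float = 1.0
    s1: float = 1.0
    s2: float = 1.0
    tau0: float = None
    a: float = None

    def __post_init__(self):
        if not 0.0 <= self.s0 <= 1.0:
            raise ValueError(f"s0 must be in [0, 1], got {self.s0}")
        for name, v in (("s1", self.s1), ("s2", self.s2)):
            if not 0.0 <= v <= 2.0:
                raise ValueError(f"{name} must be in [0, 2], got {v}")
        if self.tau0 is not None and not 0.1 <= self.tau0 <= 2.0:
            raise ValueError(f"tau0 must be in [0.1, 2] s, got {self.tau0}")
        if self.a is not None and not 0.0 <= self.a <= 1.0:
            raise ValueError(f"a must be in [0, 1], got {self.a}")


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: identity, tuning parameters and error computation."""

    model_id: str
    factors: ScalingFactors = field(default_factory=ScalingFactors)
    error_mode: str = "both"

    def __post_init__(self):
        known = _TWO_LEVEL_IDS + _ONE_LEVEL_IDS + (MODEL_ADAPTATION, MODEL_FREE)
        if self.model_id not in known:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if self.error_mode not in ERROR_MODES:
            raise ValueError(f"unknown error_mode {self.error_mode!r}")
        if self.model_id == MODEL_ADAPTATION and self.factors.tau0 is None:
            raise ValueError("Adaptation-only requires tau0")


@dataclass(frozen=True)
class PredictionState:
    """Steady-state prediction strengths (and the minimized objectives)."""

    p1_x: float
    p1_y: float
    p2_x: float = None
    p2_y: float = None
    mspe1_x: float = None
    mspe1_y: float = None
    mspe2_x: float = None
    mspe2_y: float = None


def mspe1(p1, tp, input_strength):
    """Mean-squared first-level error for a candidate prediction ``p1``.

    With probability ``tp`` the predicted tone arrives (input
    ``input_strength``), otherwise the input in this stream is 0.
    """
    return tp * (input_strength - p1) ** 2 + (1 - tp) * p1**2


def mspe2(p2, sp, input_strength, p1_scaled):
    """Mean-squared second-level error for a candidate prediction ``p2``.

    With probability ``sp`` the first-level error is
    ``|input_strength - p1_scaled|``, otherwise it is ``p1_scaled``.
    """
    return sp * (abs(input_strength - p1_scaled) - p2) ** 2 + (1 - sp) * (p1_scaled - p2) ** 2


def _level1_drive(design: BlockDesign, model_id: str) -> tuple:
    """(drive_x, drive_y, probs) — the probabilities that set level 1."""
    if model_id in (MODEL_2LEVEL, MODEL_1LEVEL_TP):
        probs = transition_probabilities(design)
        return probs.tp_x, probs.tp_y, probs
    if model_id == MODEL_NO_ENDING:
        probs = no_ending_transition_probabilities(design)
        return probs.tp_x, probs.tp_y, probs
    if model_id == MODEL_NO_TRANSITION:
        probs = occurrence_probabilities(design)
        return probs.tp_x, probs.tp_y, probs
    if model_id == MODEL_1LEVEL_SP:
        probs = transition_probabilities(design)
        return probs.sp_xx, probs.sp_xy, probs
    raise ValueError(f"no level-1 drive for model {model_id!r}")


def optimal_predictions(
    probs: ProbabilitySet,
    factors: ScalingFactors,
    n_tones: int,
    drive=None,
) -> PredictionState:
    """Closed-form steady-state predictions.

    ``drive`` overrides the probabilities driving level 1 (defaults to the
    transition probabilities ``(TP_x, TP_y)`` from ``probs``); level 2 is
    always driven by the sequence probabilities.
    """
    s0, s1 = factors.s0, factors.s1
    in_x = s0 ** (n_tones - 1)
    drive_x, drive_y = drive if drive is not None else (probs.tp_x, probs.tp_y)
    p1_x = in_x * drive_x
    p1_y = 1.0 * drive_y
    sp_xx, sp_xy = probs.sp_xx, probs.sp_xy
    p2_x = sp_xx * abs(in_x - p1_x * s1) + (1 - sp_xx) * p1_x * s1
    p2_y = sp_xy * abs(1.0 - p1_y * s1) + (1 - sp_xy) * p1_y * s1
    return PredictionState(
        p1_x=p1_x,
        p1_y=p1_y,
        p2_x=p2_x,
        p2_y=p2_y,
        mspe1_x=mspe1(p1_x, drive_x, in_x),
        mspe1_y=mspe1(p1_y, drive_y, 1.0),
        mspe2_x=mspe2(p2_x, sp_xx, in_x, p1_x * s1),
        mspe2_y=mspe2(p2_y, sp_xy, 1.0, p1_y * s1),
    )


def _rectify(e, mode):
    if e is None:
        return None
    if mode == "both":
        return abs(e)
    if mode == "positive_only":
        return max(e, 0.0)
    if mode == "negative_only":
        return max(-e, 0.0)
    raise ValueError(f"unknown error_mode {mode!r}")


def _stream_inputs(trial_type, in_x):
    """Sensory input strengths (x stream, y stream) during the last tone."""
    return {"xx": (in_x, 0.0), "xy": (0.0, 1.0), "xo": (0.0, 0.0)}[trial_type]


@dataclass(frozen=True)
class SignalTable:
    """Signed and rectified signal strengths of one block.

    ``signed[t]`` maps a trial type to the signed errors ``(e1_x, e1_y,
    e2_x, e2_y)`` during the last tone; second-level entries are ``None``
    for single-level models.  ``p1``/``p2`` are the stream-summed,
    ``s``-scaled prediction strengths (identical across trial types — the
    predictions are in place before the last tone arrives).
    """

    block_id: str
    model_id: str
    factors: ScalingFactors
    error_mode: str
    p1: float
    p2: float
    signed: dict
    predictions: PredictionState

    def _strength(self, trial_type, level):
        ex, ey = {1: self.signed[trial_type][:2], 2: self.signed[trial_type][2:]}[level]
        if ex is None:
            return None
        return _rectify(ex, self.error_mode) + _rectify(ey, self.error_mode)

    def pe1(self, trial_type):
        return self._strength(trial_type, 1)

    def pe2(self, trial_type):
        return self._strength(trial_type, 2)


def signal_strengths(
    design: BlockDesign,
    factors: ScalingFactors,
    error_mode: str = "both",
    model_id: str = MODEL_2LEVEL,
) -> SignalTable:
    """Signed errors and signal strengths for every trial type of a block.

    The last-tone sensory inputs are ``s0**(n-1)`` in the x stream for
    ``xx`` (the tone was repeated), 1 in the y stream for ``xy``, and 0
    elsewhere.  The first-level signed error is input minus ``s1``-scaled
    prediction; the second-level signed error is the *magnitude* of the
    first-level error minus the ``s2``-scaled second-level prediction.
    """
    if error_mode not in ERROR_MODES:
        raise ValueError(f"unknown error_mode {error_mode!r}")
    drive_x, drive_y, probs = _level1_drive(design, model_id)
    pred = optimal_predictions(probs, factors, design.n_tones, drive=(drive_x, drive_y))
    one_level = model_id in _ONE_LEVEL_IDS
    s1, s2 = factors.s1, factors.s2
    in_x = factors.s0 ** (design.n_tones - 1)
    signed = {}
    for t in TRIAL_TYPES:
        ix, iy = _stream_inputs(t, in_x)
        e1x = ix - pred.p1_x * s1
        e1y = iy - pred.p1_y * s1
        if one_level:
            signed[t] = (e1x, e1y, None, None)
        else:
            e2x = abs(e1x) - pred.p2_x * s2
            e2y = abs(e1y) - pred.p2_y * s2
            signed[t] = (e1x, e1y, e2x, e2y)
    return SignalTable(
        block_id=design.block_id,
        model_id=model_id,
        factors=factors,
        error_mode=error_mode,
        p1=s1 * (pred.p1_x + pred.p1_y),
        p2=None if one_level else s2 * (pred.p2_x + pred.p2_y),
        signed=signed,
        predictions=pred,
    )


@dataclass(frozen=True)
class ContrastProfileMatrix:
    """Model-predicted remainders of each signal component per contrast.

    ``values`` has one row per component (``row_names``) and one column per
    contrast, in the order of ``contrasts``.
    """

    row_names: tuple
    values: np.ndarray
    contrasts: tuple
    model_id: str
    factors: ScalingFactors
    error_mode: str = "both"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=list(self.row_names),
            columns=[c.index for c in self.contrasts],
        )

    def row(self, name) -> np.ndarray:
        return self.values[self.row_names.index(name)]


def _tables_by_block(designs, factors, error_mode, model_id):
    return {d.block_id: signal_strengths(d, factors, error_mode, model_id) for d in designs}


def within_contrast_profile(
    designs,
    factors: ScalingFactors,
    error_mode: str = "both",
    model_id: str = MODEL_2LEVEL,
    contrast_defs=None,
) -> ContrastProfileMatrix:
    """Predicted prediction-error remainders in the within-block contrasts.

    Prediction signals are identical across trial types of a block and
    cancel exactly, so only PE rows are emitted (one for single-level
    models).
    """
    from .contrasts import enumerate_contrasts

    if contrast_defs is None:
        contrast_defs = enumerate_contrasts(designs, "within")
    if any(c.scope != "within" for c in contrast_defs):
        raise ValueError("within_contrast_profile requires within-block contrasts")
    tables = _tables_by_block(designs, factors, error_mode, model_id)
    one_level = model_id in _ONE_LEVEL_IDS
    rows = ("PE1",) if one_level else ("PE1", "PE2")
    values = np.zeros((len(rows), len(contrast_defs)))
    for j, c in enumerate(contrast_defs):
        ta, tb = tables[c.minuend[0]], tables[c.subtrahend[0]]
        values[0, j] = ta.pe1(c.minuend[1]) - tb.pe1(c.subtrahend[1])
        if not one_level:
            values[1, j] = ta.pe2(c.minuend[1]) - tb.pe2(c.subtrahend[1])
    return ContrastProfileMatrix(rows, values, tuple(contrast_defs), model_id, factors, error_mode)


def across_contrast_profile(
    designs,
    factors: ScalingFactors,
    error_mode: str = "both",
    a: float = 0.5,
    model_id: str = MODEL_2LEVEL,
    contrast_defs=None,
) -> ContrastProfileMatrix:
    """Predicted remainders in the across-block contrasts.

    Both predictions and errors survive a between-block contrast of the same
    trial type.  The two-level model emits rows ``P1``, ``P2`` and the mixed
    error ``a*PE1 + (1-a)*PE2``; single-level models emit ``P1`` and ``PE1``.
    """
    from .contrasts import enumerate_contrasts

    if not 0.0 <= a <= 1.0:
        raise ValueError(f"a must be in [0, 1], got {a}")
    if contrast_defs is None:
        contrast_defs = enumerate_contrasts(designs, "across")
    if any(c.scope != "across" for c in contrast_defs):
        raise ValueError("across_contrast_profile requires across-block contrasts")
    tables = _tables_by_block(designs, factors, error_mode, model_id)
    one_level = model_id in _ONE_LEVEL_IDS
    rows = ("P1", "PE1") if one_level else ("P1", "P2", "PE")
    values = np.zeros((len(rows), len(contrast_defs)))
    for j, c in enumerate(contrast_defs):
        ta, tb = tables[c.minuend[0]], tables[c.subtrahend[0]]
        t = c.minuend[1]
        values[0, j] = ta.p1 - tb.p1
        d_pe1 = ta.pe1(t) - tb.pe1(t)
        if one_level:
            values[1, j] = d_pe1
        else:
            values[1, j] = ta.p2 - tb.p2
            values[2, j] = a * d_pe1 + (1 - a) * (ta.pe2(t) - tb.pe2(t))
    return ContrastProfileMatrix(rows, values, tuple(contrast_defs), model_id, factors, error_mode)


def alt_model_profile(model_spec: ModelSpec, designs, scope: str, contrast_defs=None, a: float = 0.5) -> ContrastProfileMatrix:
    """Contrast profile of an alternative (non-proposed) predictive model."""
    if model_spec.model_id not in _ONE_LEVEL_IDS + (MODEL_NO_TRANSITION, MODEL_NO_ENDING):
        raise ValueError(f"alt_model_profile does not handle {model_spec.model_id!r}")
    fn = within_contrast_profile if scope == "within" else across_contrast_profile
    kwargs = {} if scope == "within" else {"a": model_spec.factors.a if model_spec.factors.a is not None else a}
    return fn(
        designs,
        model_spec.factors,
        error_mode=model_spec.error_mode,
        model_id=model_spec.model_id,
        contrast_defs=contrast_defs,
        **kwargs,
    )


def adaptation_response(onsets, s0: float, tau0: float) -> np.ndarray:
    """Per-stimulus response amplitudes under exponential-recovery adaptation.

    The response to a stimulus delivered ``dt`` seconds after the previous
    one is ``1 - (1 - s0) * exp(-dt / tau0)``: immediately after a stimulus
    the evocable response drops to ``s0`` and recovers toward 1 with time
    constant ``tau0``.  The first stimulus of a block evokes a full
    response.
    """
    onsets = np.asarray(onsets, dtype=float)
    if onsets.ndim != 1:
        raise ValueError("onsets must be a 1-D array")
    if (np.diff(onsets) <= 0).any():
        raise ValueError("onsets must be strictly increasing")
    if not 0.0 <= s0 <= 1.0 or not 0.1 <= tau0 <= 2.0:
        raise ValueError("s0 must be in [0, 1] and tau0 in [0.1, 2] s")
    amps = np.ones_like(onsets)
    if len(onsets) > 1:
        dt = np.diff(onsets)
        amps[1:] = 1.0 - (1.0 - s0) * np.exp(-dt / tau0)
    return amps


def adaptation_trial_responses(
    design: BlockDesign,
    s0: float,
    tau0: float,
    seed: int = 0,
    tone_soa: float = 0.2,
    tone_duration: float = 0.1,
):
    """Adaptation-only response to the last stimulus slot of every trial.

    Builds the block's pseudorandom stimulus timeline (tones ``tone_soa``
    apart within a sequence, inter-sequence intervals from the trial order)
    and evaluates :func:`adaptation_response` at every delivered tone.
    Omitted last tones evoke no response (amplitude 0) and do not reset
    adaptation.

    Returns ``(per_trial, per_type)``: amplitudes per trial and their means
    per trial type.
    """
    order = generate_trial_order(design, seed)
    n = design.n_tones
    onsets, owner = [], []
    t = 0.0
    for i, (label, isi) in enumerate(zip(order.labels, order.isis)):
        n_delivered = {"xx": n, "xy": n, "xo": n - 1}[label]
        for k in range(n_delivered):
            onsets.append(t + k * tone_soa)
        owner.append((i, label, n_delivered))
        # next sequence starts isi seconds after the offset of the last slot
        t += (n - 1) * tone_soa + tone_duration + isi
    amps = adaptation_response(np.array(onsets), s0, tau0)
    per_trial = np.zeros(len(order.labels))
    pos = 0
    for i, label, n_delivered in owner:
        pos += n_delivered
        per_trial[i] = amps[pos - 1] if label != "xo" else 0.0
    labels = np.array(order.labels)
    per_type = {tt: float(per_trial[labels == tt].mean()) for tt in TRIAL_TYPES if (labels == tt).any()}
    return per_trial, per_type


def adaptation_contrast_profile(
    designs,
    s0: float,
    tau0: float,
    scope: str,
    contrast_defs=None,
    seed: int = 0,
) -> ContrastProfileMatrix:
    """Single-row contrast profile of the adaptation-only model."""
    from .contrasts import enumerate_contrasts

    if contrast_defs is None:
        contrast_defs = enumerate_contrasts(designs, scope)
    per_type = {d.block_id: adaptation_trial_responses(d, s0, tau0, seed=seed)[1] for d in designs}
    values = np.array(
        [[per_type[c.minuend[0]][c.minuend[1]] - per_type[c.subtrahend[0]][c.subtrahend[1]] for c in contrast_defs]]
    )
    factors = ScalingFactors(s0=s0, tau0=tau0)
    return ContrastProfileMatrix(("SSA",), values, tuple(contrast_defs), MODEL_ADAPTATION, factors)


def profile_for(model_spec: ModelSpec, designs, scope: str, contrast_defs=None, a: float = 0.5, seed: int = 0) -> ContrastProfileMatrix:
    """Contrast profile of any candidate model (dispatch helper)."""
    if model_spec.model_id == MODEL_2LEVEL:
        if scope == "within":
            return within_contrast_profile(
                designs, model_spec.factors, model_spec.error_mode, contrast_defs=contrast_defs
            )
        a_eff = model_spec.factors.a if model_spec.factors.a is not None else a
        return across_contrast_profile(
            designs, model_spec.factors, model_spec.error_mode, a=a_eff, contrast_defs=contrast_defs
        )
    if model_spec.model_id == MODEL_ADAPTATION:
        return adaptation_contrast_profile(
            designs, model_spec.factors.s0, model_spec.factors.tau0, scope, contrast_defs, seed=seed
        )
    return alt_model_profile(model_spec, designs, scope, contrast_defs, a=a)


def single_trial_amplitudes(
    design: BlockDesign,
    factors: ScalingFactors,
    gain_sd: float = 0.3,
    seed: int = 0,
    error_mode: str = "both",
    trial_labels=None,
) -> pd.DataFrame:
    """Trial-by-trial component amplitudes under prediction-gain jitter.

    Each trial multiplies every prediction by an independent mean-one
    lognormal gain (one per stream and level) and the prediction errors are
    recomputed from the jittered predictions.  This realizes the model's
    interaction structure at the single-trial level: in the dominant
    sequence the second-level error sits in the regime where prediction
    fluctuations drive it directly, so P2 and PE2 co-fluctuate positively
    and PE1 and PE2 negatively in xx-dominant blocks (and with flipped
    signs in xy-dominant blocks, where the errors change sign).

    Returns a DataFrame with columns ``trial_type, P1, P2, PE1, PE2``.
    """
    rng = np.random.default_rng(seed)
    if trial_labels is None:
        trial_labels = generate_trial_order(design, int(rng.integers(2**31 - 1))).labels
    drive_x, drive_y, probs = _level1_drive(design, MODEL_2LEVEL)
    pred = optimal_predictions(probs, factors, design.n_tones, drive=(drive_x, drive_y))
    s1, s2 = factors.s1, factors.s2
    in_x = factors.s0 ** (design.n_tones - 1)
    ntr = len(trial_labels)
    mu = -0.5 * gain_sd**2  # mean-one lognormal gains
    g1x, g1y, g2x, g2y = rng.lognormal(mu, gain_sd, size=(4, ntr))
    ins = np.array([_stream_inputs(t, in_x) for t in trial_labels])
    e1x = ins[:, 0] - g1x * pred.p1_x * s1
    e1y = ins[:, 1] - g1y * pred.p1_y * s1
    e2x = np.abs(e1x) - g2x * pred.p2_x * s2
    e2y = np.abs(e1y) - g2y * pred.p2_y * s2

    def rect(e):
        if error_mode == "both":
            return np.abs(e)
        if error_mode == "positive_only":
            return np.maximum(e, 0.0)
        return np.maximum(-e, 0.0)

    return pd.DataFrame(
        {
            "trial_type": list(trial_labels),
            "P1": s1 * (g1x * pred.p1_x + g1y * pred.p1_y),
            "P2": s2 * (g2x * pred.p2_x + g2y * pred.p2_y),
            "PE1": rect(e1x) + rect(e1y),
            "PE2": rect(e2x) + rect(e2y),
        }
    )
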