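"""Local-global auditory paradigm: block designs and learned regularities.

A *block* delivers short tone sequences of a fixed length ``n_tones`` (2 or
3).  Each sequence is one of three types: ``xx`` (the last tone repeats the
preceding standard tone *x*), ``xy`` (the last tone is the deviant *y*) and
``xo`` (the last tone is omitted).  Listeners implicitly learn two
regularities from a block:

* a *local* regularity — the transition probabilities ``TP_x / TP_y / TP_o``
  of what follows a tone *x* (another *x*, a *y*, or nothing), and
* a *global* regularity — the sequence probabilities ``SP_xx / SP_xy /
  SP_xo`` of the three sequence types.

Transitions from the final *x* of an ``xx`` sequence into the silent
inter-sequence gap count as x-to-o transitions: the local level predicts
what follows an *x* without knowing whether the sequence is over.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRIAL_TYPES = ("xx", "xy", "xo")

__all__ = [
    "TRIAL_TYPES",
    "BlockDesign",
    "ProbabilitySet",
    "TrialOrder",
    "build_design",
    "sequence_probabilities",
    "transition_probabilities",
    "no_ending_transition_probabilities",
    "occurrence_probabilities",
    "generate_trial_order",
    "default_designs",
    "designs_to_table",
    "designs_from_table",
]


class PhaseStratificationError(ValueError):
    """Raised when trial counts cannot be split evenly across phases."""


@dataclass(frozen=True)
class BlockDesign:
    """Configuration of one sequence block.

    Parameters
    ----------
    block_id : str
        Label of the block (e.g. ``"B1"``).
    n_tones : int
        Number of stimulus items per sequence, 2 or 3.
    counts : dict
        Number of sequences per trial type, keys ``xx``, ``xy``, ``xo``.
    n_phases : int
        Number of equal-ratio phases the block is divided into.
    tone_roles : tuple
        The two run configurations (which physical tone plays *x*).
    """

    block_id: str
    n_tones: int
    counts: dict
    n_phases: int = 4
    tone_roles: tuple = ("A", "B")

    def __post_init__(self):
        if self.n_tones not in (2, 3):
            raise ValueError(f"n_tones must be 2 or 3, got {self.n_tones}")
        if set(self.counts) != set(TRIAL_TYPES):
            raise ValueError(f"counts must have keys {TRIAL_TYPES}")
        if any(c < 0 or int(c) != c for c in self.counts.values()):
            raise ValueError("counts must be non-negative integers")
        if self.total == 0:
            raise ValueError(f"block {self.block_id}: empty design")
        if self.n_phases < 1:
            raise ValueError("n_phases must be >= 1")
        for t, c in self.counts.items():
            if c % self.n_phases:
                raise PhaseStratificationError(
                    f"block {self.block_id}: count for {t} ({c}) is not "
                    f"divisible by n_phases ({self.n_phases})"
                )

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def per_phase(self) -> dict:
        return {t: c // self.n_phases for t, c in self.counts.items()}


@dataclass(frozen=True)
class ProbabilitySet:
    """Sequence probabilities, expected transition counts and transition
    probabilities of one block.

    ``sp``, ``tn`` and ``tp`` are each ordered ``(x, y, o)`` — for ``sp``
    that means ``(SP_xx, SP_xy, SP_xo)``.  ``tn`` holds the expected number
    of transitions out of a tone *x* per sequence; ``tp`` the normalized
    transition probabilities.
    """

    sp: tuple
    tn: tuple = None
    tp: tuple = None

    def __post_init__(self):
        for name, triple, normalized in (("SP", self.sp, True), ("TN", self.tn, False), ("TP", self.tp, True)):
            if triple is None:
                continue
            arr = np.asarray(triple, dtype=float)
            if arr.shape != (3,):
                raise ValueError(f"{name} must be a triple")
            if (arr < -1e-12).any():
                raise ValueError(f"{name} entries must be non-negative")
            if normalized and abs(arr.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} must sum to 1, got {arr.sum()!r}")

    @property
    def sp_xx(self):
        return self.sp[0]

    @property
    def sp_xy(self):
        return self.sp[1]

    @property
    def sp_xo(self):
        return self.sp[2]

    @property
    def tp_x(self):
        return self.tp[0]

    @property
    def tp_y(self):
        return self.tp[1]

    @property
    def tp_o(self):
        return self.tp[2]


@dataclass(frozen=True)
class TrialOrder:
    """A phase-stratified pseudorandom ordering of one block's sequences."""

    labels: tuple
    phase_bounds: tuple
    isis: tuple
    seed: int

    def __len__(self):
        return len(self.labels)


def build_design(block_id, n_tones, counts, n_phases=4, tone_roles=("A", "B")) -> BlockDesign:
    """Validate and construct a :class:`BlockDesign`."""
    return BlockDesign(block_id, n_tones, dict(counts), n_phases, tone_roles)


def sequence_probabilities(design: BlockDesign) -> ProbabilitySet:
    """Sequence probabilities ``SP_t = counts[t] / total``."""
    total = design.total
    sp = tuple(design.counts[t] / total for t in TRIAL_TYPES)
    return ProbabilitySet(sp=sp)


def _tp_from_tn(sp, tn):
    # TN_x + TN_y + TN_o = TN_x + 1 whenever TN_o = 1 - SP_xy, so the
    # denominator below equals the full transition count either way.
    denom = sum(tn)
    tp = tuple(v / denom for v in tn)
    return ProbabilitySet(sp=sp, tn=tuple(tn), tp=tp)


def transition_probabilities(design: BlockDesign) -> ProbabilitySet:
    """Expected transition counts and probabilities out of tone *x*.

    An ``n``-tone sequence contains ``n-1`` x-to-x transitions if it is
    ``xx`` and ``n-2`` otherwise; exactly one x-to-y transition if it is
    ``xy``; and one x-to-o transition if it is ``xo`` *or* ``xx`` (the
    sequence-final *x* is followed by silence).
    """
    n = design.n_tones
    sp = sequence_probabilities(design).sp
    sp_xx, sp_xy, sp_xo = sp
    tn_x = (n - 1) * sp_xx + (n - 2) * sp_xy + (n - 2) * sp_xo
    tn_y = sp_xy
    tn_o = 1.0 - sp_xy
    return _tp_from_tn(sp, (tn_x, tn_y, tn_o))


def no_ending_transition_probabilities(design: BlockDesign) -> ProbabilitySet:
    """Transition probabilities of the *No-ending* model variant.

    Neglects the x-to-o transition at the end of ``xx`` sequences, so
    ``TN_o = SP_xo`` and the probabilities are renormalized over the reduced
    transition count.
    """
    n = design.n_tones
    sp = sequence_probabilities(design).sp
    sp_xx, sp_xy, sp_xo = sp
    tn_x = (n - 1) * sp_xx + (n - 2) * sp_xy + (n - 2) * sp_xo
    tn_y = sp_xy
    tn_o = sp_xo
    return _tp_from_tn(sp, (tn_x, tn_y, tn_o))


def occurrence_probabilities(design: BlockDesign) -> ProbabilitySet:
    """Stimulus-occurrence frequencies of the *No-transition* model variant.

    Ignores sequential structure entirely: each sequence is treated as a bag
    of ``n_tones`` stimulus slots and the relative frequency of *x*, *y* and
    omitted slots is returned in place of transition probabilities.
    """
    n = design.n_tones
    sp = sequence_probabilities(design).sp
    sp_xx, sp_xy, sp_xo = sp
    occ_x = n * sp_xx + (n - 1) * (sp_xy + sp_xo)
    occ_y = sp_xy
    occ_o = sp_xo
    tot = occ_x + occ_y + occ_o  # = n
    return ProbabilitySet(sp=sp, tn=(occ_x, occ_y, occ_o), tp=(occ_x / tot, occ_y / tot, occ_o / tot))


def generate_trial_order(design: BlockDesign, seed: int, isi_range=(1.0, 1.4)) -> TrialOrder:
    """Phase-stratified pseudorandom sequence order for one block run.

    Each phase contains the block's global trial-type proportions exactly;
    within a phase the order is uniformly random (consecutive rare sequences
    are allowed).  Inter-sequence intervals (offset of the last tone to the
    onset of the next first tone) are drawn uniformly from ``isi_range``.
    """
    rng = np.random.default_rng(seed)
    labels = []
    bounds = [0]
    phase = [t for t in TRIAL_TYPES for _ in range(design.per_phase[t])]
    for _ in range(design.n_phases):
        order = list(rng.permutation(phase))
        labels.extend(order)
        bounds.append(len(labels))
    isis = rng.uniform(isi_range[0], isi_range[1], size=len(labels))
    return TrialOrder(tuple(labels), tuple(bounds), tuple(isis), seed)


def default_designs() -> list:
    """The canonical 8-block grid used throughout the synthetic experiments.

    Block 1 (2-tone, 96/24/24) follows the published configuration.  The
    remaining seven blocks are a documented fixture, not ground truth: the
    grid crosses {2-tone, 3-tone} x {strong, weak dominance} x {xx-dominant,
    xy-dominant}, with Blocks 1-4 xx-dominant and Blocks 5-8 xy-dominant and
    the 2-tone blocks being {1, 2, 5, 6}.
    """
    spec = [
        ("B1", 2, {"xx": 96, "xy": 24, "xo": 24}),
        ("B2", 2, {"xx": 72, "xy": 36, "xo": 36}),
        ("B3", 3, {"xx": 96, "xy": 24, "xo": 24}),
        ("B4", 3, {"xx": 72, "xy": 36, "xo": 36}),
        ("B5", 2, {"xx": 24, "xy": 96, "xo": 24}),
        ("B6", 2, {"xx": 36, "xy": 72, "xo": 36}),
        ("B7", 3, {"xx": 24, "xy": 96, "xo": 24}),
        ("B8", 3, {"xx": 36, "xy": 72, "xo": 36}),
    ]
    return [build_design(b, n, c) for b, n, c in spec]


def designs_to_table(designs) -> pd.DataFrame:
    """Tabular (TSV-friendly) representation of a design list."""
    return pd.DataFrame(
        [
            {
                "block_id": d.block_id,
                "n_tones": d.n_tones,
                "count_xx": d.counts["xx"],
                "count_xy": d.counts["xy"],
                "count_xo": d.counts["xo"],
                "n_phases": d.n_phases,
            }
            for d in designs
        ]
    )


def designs_from_table(table) -> list:
    """Inverse of :func:`designs_to_table`; accepts a DataFrame or TSV text."""
    if isinstance(table, str):
        table = pd.read_csv(io.StringIO(table), sep="\t")
    return [
        build_design(
            str(r.block_id),
            int(r.n_tones),
            {"xx": int(r.count_xx), "xy": int(r.count_xy), "xo": int(r.count_xo)},
            int(getattr(r, "n_phases", 4)),
        )
        for r in table.itertuples(index=False)
    ]
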