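"""Seeded generator of sequences with controllable planted stem-loops.

The generator emulates the positive-class design of the recognition
experiments: a uniform i.i.d. ACGT background with, at a configurable
probability, one hairpin embedded entirely inside a terminal window (the
last or first 50 nt by default).  Stem composition (via a dinucleotide
bias), loop motif/length, mismatch count, and bulge sizes are all
controllable, and ground-truth coordinates are returned for every plant.

The uniform background keeps the null clean: chance hairpins occur at a
rate that is estimable by Monte-Carlo, and shuffling a generated sequence
yields a matched negative.  Two guards make round-trips against the
detector well-posed: short guard zones flanking the planted hairpin are
drawn from {A, C} on both sides (two bases from {A, C} can never form a
Watson-Crick pair, so the stem cannot be extended outward, even via a
bulge), and random loops are resampled so their terminal bases do not pair
with each other (which would extend the stem inward).  For strict
round-trip experiments ``loop_alphabet="AC"`` additionally rules out any
base-pairing within the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Optional

import numpy as np

from .hairpin import FIVE_PRIME, THREE_PRIME, HairpinAnnotation, HairpinParams
from .records import SequenceRecord, reverse_complement

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SyntheticSpecError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic cohort."""

    n_sequences: int
    seq_length: int = 300
    plant_probability: float = 1.0
    stem_length_range: tuple[int, int] = (10, 20)
    loop_length_range: tuple[int, int] = (5, 10)
    loop_motif: Optional[str] = None
    n_mismatches: int = 0
    bulge_sizes: tuple[int, int] = (0, 0)
    stem_dinuc_bias: Optional[dict[str, float]] = None
    plant_window: str = THREE_PRIME
    terminal_window: int = 50
    loop_alphabet: str = "ACGT"
    bulge_alphabet: str = "ACGT"
    gc_clamp: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plant_window not in (THREE_PRIME, FIVE_PRIME):
            raise SyntheticSpecError("plant_window must be three_prime/five_prime")
        if not (0.0 <= self.plant_probability <= 1.0):
            raise SyntheticSpecError("plant_probability must be in [0, 1]")
        if self.stem_length_range[0] > self.stem_length_range[1]:
            raise SyntheticSpecError("bad stem_length_range")
        if self.loop_length_range[0] > self.loop_length_range[1]:
            raise SyntheticSpecError("bad loop_length_range")
        if max(self.bulge_sizes) > 3 or min(self.bulge_sizes) < 0:
            raise SyntheticSpecError("bulge sizes must be within 0..3")
        if self.n_mismatches < 0:
            raise SyntheticSpecError("n_mismatches must be >= 0")
        if self.stem_dinuc_bias is not None:
            if any(w < 0 for w in self.stem_dinuc_bias.values()):
                raise SyntheticSpecError("bias weights must be nonnegative")
        max_span = (
            2 * self.stem_length_range[1]
            + sum(self.bulge_sizes)
            + (len(self.loop_motif) if self.loop_motif else self.loop_length_range[1])
        )
        if max_span > min(self.seq_length, self.terminal_window):
            raise SyntheticSpecError(
                f"hairpin span up to {max_span} nt cannot fit inside the "
                f"{min(self.seq_length, self.terminal_window)} nt plant window"
            )
        stem_for_mm = self.stem_length_range[0]
        if self.n_mismatches > max(0, min(8, stem_for_mm - 2)):
            raise SyntheticSpecError(
                "too many mismatches for the loop-proximal core of the shortest stem"
            )


def _bias_matrices(bias: Optional[dict[str, float]]) -> np.ndarray:
    """Row-normalized 4x4 transition weights from a dinucleotide bias map."""
    W = np.ones((4, 4))
    if bias:
        for (x, y) in product("ACGT", repeat=2):
            W["ACGT".index(x), "ACGT".index(y)] = bias.get(x + y, 1.0)
    return W


def _sample_arm(length: int, W: np.ndarray, rng: np.random.Generator) -> str:
    marginal = W.sum(axis=1)
    out = [int(rng.choice(4, p=marginal / marginal.sum()))]
    for _ in range(length - 1):
        row = W[out[-1]]
        out.append(int(rng.choice(4, p=row / row.sum())))
    return "".join(_BASES[out])


def generate(spec: SyntheticSpec) -> tuple[list[SequenceRecord], dict[str, Optional[HairpinAnnotation]]]:
    """Generate records plus per-record ground truth (None when no plant).

    Byte-identical outputs for identical specs (seeded numpy Generator).
    """
    rng = np.random.default_rng(spec.seed % (2**31))
    records: list[SequenceRecord] = []
    truths: dict[str, Optional[HairpinAnnotation]] = {}
    W = _bias_matrices(spec.stem_dinuc_bias)

    for i in range(spec.n_sequences):
        seq_id = f"syn{i}"
        background = rng.choice(_BASES, size=spec.seq_length)
        truth: Optional[HairpinAnnotation] = None
        if rng.random() < spec.plant_probability:
            seq, truth = _plant(seq_id, background, spec, W, rng)
        else:
            seq = "".join(background)
        records.append(SequenceRecord(id=seq_id, sequence=seq))
        truths[seq_id] = truth
    return records, truths


def _sample_loop(spec: SyntheticSpec, rng: np.random.Generator) -> str:
    if spec.loop_motif:
        return spec.loop_motif.upper().replace("U", "T")
    length = int(rng.integers(spec.loop_length_range[0], spec.loop_length_range[1] + 1))
    alphabet = np.array(list(spec.loop_alphabet))
    while True:
        loop = "".join(rng.choice(alphabet, size=length))
        if _COMP[loop[0]] != loop[-1]:  # loop ends must not pair (inward extension)
            return loop


def _plant(
    seq_id: str,
    background: np.ndarray,
    spec: SyntheticSpec,
    W: np.ndarray,
    rng: np.random.Generator,
) -> tuple[str, HairpinAnnotation]:
    n = len(background)
    stem = int(rng.integers(spec.stem_length_range[0], spec.stem_length_range[1] + 1))
    loop = _sample_loop(spec, rng)
    left_paired = _sample_arm(stem, W, rng)
    if spec.gc_clamp:
        # close the stem on a strong C.G pair; with a non-pairing loop this
        # pins the loop/stem boundary exactly (no inward-shifted alternative)
        left_paired = left_paired[:-1] + str(rng.choice(np.array(["C", "G"])))
    right_paired = reverse_complement(left_paired)

    # substitutional mismatches at interior, loop-proximal stem steps
    # (t = 0 is loop-adjacent; boundary steps stay paired, and steps beyond
    # t = 8 stay paired so a detector with stem_min = 10 cannot trim a
    # mismatch away by shortening the stem)
    mm_steps: tuple[int, ...] = ()
    if spec.n_mismatches:
        candidates = np.arange(1, min(9, stem - 1))
        chosen = rng.choice(candidates, size=spec.n_mismatches, replace=False)
        mm_steps = tuple(sorted(int(t) for t in chosen))
        right_list = list(right_paired)
        for t in mm_steps:
            # step t pairs left_paired[-1-t] with right_paired[t]
            partner = left_paired[-1 - t]
            options = [b for b in "ACGT" if b != _COMP[partner]]
            right_list[t] = options[int(rng.integers(3))]
        right_paired = "".join(right_list)

    # bulges go in the loop-proximal core (paired steps loop-side < 9) so the
    # loop-side sub-stem alone cannot satisfy stem_min = 10 and the detector
    # cannot trim the bulge away
    bl, br = spec.bulge_sizes
    if bl:
        pl = int(rng.integers(1, min(9, stem)))  # paired steps loop-side of the bulge
        bulge_left = "".join(rng.choice(np.array(list(spec.bulge_alphabet)), size=bl))
        left_arm = left_paired[: stem - pl] + bulge_left + left_paired[stem - pl :]
    else:
        pl, bulge_left, left_arm = 0, "", left_paired
    if br:
        pr = int(rng.integers(1, min(9, stem)))
        bulge_right = "".join(rng.choice(np.array(list(spec.bulge_alphabet)), size=br))
        right_arm = right_paired[:pr] + bulge_right + right_paired[pr:]
    else:
        pr, bulge_right, right_arm = 0, "", right_paired

    hairpin = left_arm + loop + right_arm
    span = len(hairpin)
    window = min(spec.terminal_window, n)
    if spec.plant_window == THREE_PRIME:
        lo, hi = n - window, n - span
    else:
        lo, hi = 0, window - span
    start = int(rng.integers(lo, hi + 1))
    seq = list("".join(background))
    seq[start : start + span] = hairpin

    # flank guards: {A,C} x {A,C} can never pair, so no outward extension of
    # the planted stem is possible, with or without a bulge (reach <= 4 nt)
    guard = np.array(["A", "C"])
    for p in range(max(0, start - 4), start):
        seq[p] = str(rng.choice(guard))
    for p in range(start + span, min(n, start + span + 4)):
        seq[p] = str(rng.choice(guard))

    j = start + len(left_arm)
    k = j + len(loop)
    truth = HairpinAnnotation(
        seq_id=seq_id,
        left_arm=(start, j),
        loop=(j, k),
        right_arm=(k, start + span),
        stem_length=stem,
        mismatch_count=spec.n_mismatches,
        mismatch_steps=mm_steps,
        left_bulge=(j - pl - bl, j - pl) if bl else None,
        right_bulge=(k + pr, k + pr + br) if br else None,
        paired_left_string=left_paired,
        paired_right_string=right_paired,
        loop_string=loop,
        bulge_left_string=bulge_left,
        bulge_right_string=bulge_right,
    )
    return "".join(seq), truth


def detection_params_for(spec: SyntheticSpec) -> HairpinParams:
    """Detector constraints consistent with a generator spec (used by the
    round-trip tests and the pipeline)."""
    return HairpinParams(
        loop_min=min(spec.loop_length_range[0], 3),
        loop_max=max(spec.loop_length_range[1], 10),
    )
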