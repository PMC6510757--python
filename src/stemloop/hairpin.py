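"""Approximate stem-loop (inverted repeat) detection.

A hairpin is modelled as a 5' arm, an unpaired loop, and a 3' arm, where the
two arms base-pair into a stem.  The stem may contain substitutional
mismatches and at most one contiguous bulge (a run of unpaired nucleotides)
per arm.  Detection enumerates, for every admissible loop interval, all stem
configurations (stem length, bulge length and placement on either arm),
scores each by its mismatch count, and reports one canonical configuration
per loop.  Canonicalization rules:

* the innermost (loop-adjacent) and outermost stem positions must be
  Watson-Crick matches - stems are bounded by base pairs, so a terminal
  mismatch is read as loop/exterior, not stem;
* bulges are strictly interior to their arm (flanked by paired positions);
* per loop interval the best configuration is chosen by (fewest total
  defects, i.e. mismatches plus bulged nucleotides; then longest stem, then
  smallest total bulge, then lexicographically earliest bulge placement),
  a total order, so detection is deterministic.  Counting bulged
  nucleotides together with mismatches resolves the ambiguity between a
  mismatch and a 1x1 internal loop (a bulge on each arm): both cost the
  same, and the longer-stem mismatch description is preferred;
* an annotation whose base-pair set is a strict subset of another reported
  annotation's pair set is suppressed (it is the same physical stem, trimmed).

The scan is vectorized: for each loop the complementarity matrix between the
two flanking regions is reduced to cumulative sums along its 16 shifted
diagonals (shifts 0-3 on each side), after which every stem configuration is
scored with O(1) gathers.  This reproduces a banded alignment of the left arm
against the reverse complement of the downstream region with one gap run of
up to ``max_bulge_per_arm`` nucleotides per arm.

Coordinates are 0-based, half-open.  N never pairs; inside a stem it counts
as a mismatch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np

from .records import SequenceRecord

logger = logging.getLogger(__name__)

_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

THREE_PRIME = "three_prime"
FIVE_PRIME = "five_prime"


@dataclass(frozen=True)
class HairpinParams:
    """Constraints of the stem-loop search.

    Defaults follow the annotation settings used for retrotransposon 3' ends:
    stems of 10-20 bp, loops of at most 10 nt, and up to 5 mismatches in the
    stem.  ``loop_min`` (not constrained by those settings) defaults to 3,
    the smallest sterically sensible hairpin loop.  At most one contiguous
    bulge of up to ``max_bulge_per_arm`` nt is allowed per arm; bulge
    nucleotides are unpaired and do not consume the mismatch budget.
    """

    stem_min: int = 10
    stem_max: int = 20
    loop_min: int = 3
    loop_max: int = 10
    max_mismatches: int = 5
    max_bulge_per_arm: int = 3
    allow_wobble: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.stem_min <= self.stem_max):
            raise ValueError("require 1 <= stem_min <= stem_max")
        if not (1 <= self.loop_min <= self.loop_max):
            raise ValueError("require 1 <= loop_min <= loop_max")
        if self.max_mismatches < 0 or self.max_bulge_per_arm < 0:
            raise ValueError("mismatch/bulge budgets must be >= 0")

    @property
    def min_span(self) -> int:
        return 2 * self.stem_min + self.loop_min


@dataclass(frozen=True)
class HairpinAnnotation:
    """One stem-loop call on a sequence.

    ``mismatch_steps`` holds the 0-based stem positions (0 = loop-adjacent)
    that are not Watson-Crick paired.  Bulge intervals are ``None`` when the
    corresponding arm has no bulge.  Paired strings exclude bulge
    nucleotides; ``paired_left_string`` reverse-complements
    ``paired_right_string`` at all positions except the mismatch steps.
    """

    seq_id: str
    left_arm: tuple[int, int]
    loop: tuple[int, int]
    right_arm: tuple[int, int]
    stem_length: int
    mismatch_count: int
    mismatch_steps: tuple[int, ...]
    left_bulge: Optional[tuple[int, int]]
    right_bulge: Optional[tuple[int, int]]
    paired_left_string: str
    paired_right_string: str
    loop_string: str
    bulge_left_string: str = ""
    bulge_right_string: str = ""

    @property
    def span(self) -> tuple[int, int]:
        return (self.left_arm[0], self.right_arm[1])

    @property
    def loop_length(self) -> int:
        return self.loop[1] - self.loop[0]

    def pair_positions(self) -> frozenset[tuple[int, int]]:
        """Genomic (left, right) coordinates of every paired stem position."""
        j = self.loop[0]
        k = self.loop[1]
        bl = 0 if self.left_bulge is None else self.left_bulge[1] - self.left_bulge[0]
        pl = 0 if self.left_bulge is None else j - self.left_bulge[1]
        br = 0 if self.right_bulge is None else self.right_bulge[1] - self.right_bulge[0]
        pr = 0 if self.right_bulge is None else self.right_bulge[0] - k
        pairs = []
        for t in range(self.stem_length):
            a = bl if (bl and t >= pl) else 0
            b = br if (br and t >= pr) else 0
            pairs.append((j - 1 - t - a, k + t + b))
        return frozenset(pairs)

    def key(self) -> tuple:
        """Canonical identity tuple (used by tests and round-trip checks)."""
        return (
            self.left_arm,
            self.loop,
            self.right_arm,
            self.left_bulge,
            self.right_bulge,
            self.stem_length,
            self.mismatch_count,
        )


def _pair_table(allow_wobble: bool) -> np.ndarray:
    comp = np.zeros((5, 5), dtype=bool)
    for x, y in (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")):
        comp[_CODES[x], _CODES[y]] = True
    if allow_wobble:
        comp[_CODES["G"], _CODES["T"]] = True
        comp[_CODES["T"], _CODES["G"]] = True
    return comp


def _encode(sequence: str) -> np.ndarray:
    return np.frombuffer(
        sequence.encode("ascii")
        .translate(bytes.maketrans(b"ACGTN", bytes(range(5)))),
        dtype=np.uint8,
    )


@lru_cache(maxsize=8)
def _config_table(stem_min: int, stem_max: int, max_bulge: int):
    """Flat table of all stem configurations (stem, bl, pL, br, pR).

    For each configuration the mismatch count of a candidate is
    ``stem - matched`` where ``matched`` is assembled from cumulative sums of
    the 16 shifted diagonals of the local complementarity matrix:

        matched = C[0,0][m1] + C[mid][m2] - C[mid][m1]
                + C[bl,br][stem] - C[bl,br][m2]

    with m1/m2 the ordered bulge onset positions.  Index arrays into the flat
    (16, W+1) cumulative-sum block are precomputed here; only the gathers
    happen per loop.
    """
    W = stem_max + max_bulge  # local window width per arm
    rows = []
    for stem in range(stem_min, stem_max + 1):
        left_opts = [(0, 0)] + [
            (bl, pl) for bl in range(1, max_bulge + 1) for pl in range(1, stem)
        ]
        right_opts = [(0, 0)] + [
            (br, pr) for br in range(1, max_bulge + 1) for pr in range(1, stem)
        ]
        for bl, pl in left_opts:
            for br, pr in right_opts:
                rows.append((stem, bl, pl, br, pr))
    arr = np.asarray(rows, dtype=np.int64)
    stem, bl, pl, br, pr = (arr[:, i] for i in range(5))

    pl_eff = np.where(bl > 0, pl, stem)
    pr_eff = np.where(br > 0, pr, stem)
    m1 = np.minimum(pl_eff, pr_eff)
    m2 = np.maximum(pl_eff, pr_eff)
    a_mid = np.where(pl_eff < pr_eff, bl, 0)
    b_mid = np.where(pr_eff < pl_eff, br, 0)

    stride = W + 1
    n_shift = max_bulge + 1
    ch_mid = (a_mid * n_shift + b_mid) * stride
    ch_end = (bl * n_shift + br) * stride
    idx_m1_00 = m1  # channel (0,0) is offset 0
    idx_m1_mid = ch_mid + m1
    idx_m2_mid = ch_mid + m2
    idx_m2_end = ch_end + m2
    idx_stem_end = ch_end + stem
    idx_outer_end = ch_end + stem - 1  # outer boundary pair check

    # Partial ranking key: mismatches are prepended at scan time.
    # (shorter stem worse) then (total bulge, bl, pL, br, pR) ascending.
    P = stem_max + 1  # radix for bulge onset positions (pl, pr < stem <= stem_max)
    B = 2 * max_bulge + 2  # radix for bulge lengths and their sum
    base_key = (((((stem_max - stem) * B + (bl + br)) * B + bl) * P + pl) * B + br) * P + pr
    if int(base_key.max(initial=0)) >= 2**32:
        raise ValueError("stem/bulge ranges too large for ranking-key packing")

    return {
        "W": W,
        "stem": stem,
        "bl": bl,
        "pl": pl,
        "br": br,
        "pr": pr,
        "idx_m1_00": idx_m1_00,
        "idx_m1_mid": idx_m1_mid,
        "idx_m2_mid": idx_m2_mid,
        "idx_m2_end": idx_m2_end,
        "idx_stem_end": idx_stem_end,
        "idx_outer_end": idx_outer_end,
        "base_key": base_key,
    }


_SENTINEL = np.int64(2**62)


def _diag_cumsums(M: np.ndarray, max_shift: int, W: int) -> np.ndarray:
    """Cumulative sums C[a*4+b, m] = sum_{t<m} M[t+a, t+b] for shifts 0..3."""
    n_shift = max_shift + 1
    C = np.zeros((n_shift * n_shift, W + 1), dtype=np.int64)
    for a in range(n_shift):
        for b in range(n_shift):
            d = np.diagonal(M, offset=b - a)
            start = a if b >= a else b
            vals = d[start:]
            row = C[a * n_shift + b]
            np.cumsum(vals, out=row[1 : 1 + len(vals)])
            if 1 + len(vals) <= W:
                row[1 + len(vals) :] = row[len(vals)]
    return C


def find_stem_loops(
    record: SequenceRecord,
    params: HairpinParams = HairpinParams(),
    prune_nested: bool = True,
) -> list[HairpinAnnotation]:
    """Enumerate canonical stem-loop annotations of ``record``.

    Returns annotations sorted by loop start (then loop end).  An empty
    sequence, or one too short to host a hairpin, yields an empty list.
    ``prune_nested=False`` keeps annotations whose pair set is contained in
    another annotation's (one candidate per loop interval regardless).
    """
    s = record.sequence
    n = len(s)
    if n < params.min_span:
        return []
    codes = _encode(s)
    comp = _pair_table(params.allow_wobble)
    cfg = _config_table(params.stem_min, params.stem_max, params.max_bulge_per_arm)
    W = cfg["W"]
    stride = W + 1

    cand: list[HairpinAnnotation] = []
    max_mm = params.max_mismatches

    for j in range(params.stem_min, n - params.stem_min - params.loop_min + 1):
        k_hi = min(j + params.loop_max, n - params.stem_min)
        for k in range(j + params.loop_min, k_hi + 1):
            if not comp[codes[j - 1], codes[k]]:
                continue  # innermost stem position must pair
            nl = min(j, W)
            nr = min(n - k, W)
            lw = np.full(W, 4, dtype=np.uint8)
            lw[:nl] = codes[j - 1 : j - 1 - nl : -1] if j - 1 - nl >= 0 else codes[j - 1 :: -1]
            rw = np.full(W, 4, dtype=np.uint8)
            rw[:nr] = codes[k : k + nr]
            M = comp[lw[:, None], rw[None, :]]
            C = _diag_cumsums(M, params.max_bulge_per_arm, W).ravel()

            matched = (
                C[cfg["idx_m1_00"]]
                + C[cfg["idx_m2_mid"]]
                - C[cfg["idx_m1_mid"]]
                + C[cfg["idx_stem_end"]]
                - C[cfg["idx_m2_end"]]
            )
            mm = cfg["stem"] - matched
            outer_ok = (C[cfg["idx_stem_end"]] - C[cfg["idx_outer_end"]]) == 1
            fit = (cfg["stem"] + cfg["bl"] <= nl) & (cfg["stem"] + cfg["br"] <= nr)
            valid = fit & outer_ok & (mm <= max_mm)
            if not valid.any():
                continue
            defects = mm + cfg["bl"] + cfg["br"]
            keys = np.where(valid, defects * (2**32) + cfg["base_key"], _SENTINEL)
            best = int(np.argmin(keys))
            cand.append(
                _build_annotation(
                    record,
                    j,
                    k,
                    int(cfg["stem"][best]),
                    int(cfg["bl"][best]),
                    int(cfg["pl"][best]),
                    int(cfg["br"][best]),
                    int(cfg["pr"][best]),
                    comp,
                    codes,
                )
            )

    if prune_nested:
        return _dominance_filter(cand)
    cand.sort(key=lambda a: (a.loop[0], a.loop[1]))
    return cand


def _build_annotation(
    record: SequenceRecord,
    j: int,
    k: int,
    stem: int,
    bl: int,
    pl: int,
    br: int,
    pr: int,
    comp: np.ndarray,
    codes: np.ndarray,
) -> HairpinAnnotation:
    s = record.sequence
    left_start = j - stem - bl
    right_end = k + stem + br
    left_bulge = (j - pl - bl, j - pl) if bl else None
    right_bulge = (k + pr, k + pr + br) if br else None

    mismatch_steps = []
    for t in range(stem):
        a = bl if (bl and t >= pl) else 0
        b = br if (br and t >= pr) else 0
        if not comp[codes[j - 1 - t - a], codes[k + t + b]]:
            mismatch_steps.append(t)

    if left_bulge:
        paired_left = s[left_start : left_bulge[0]] + s[left_bulge[1] : j]
        bulge_left = s[left_bulge[0] : left_bulge[1]]
    else:
        paired_left = s[left_start:j]
        bulge_left = ""
    if right_bulge:
        paired_right = s[k : right_bulge[0]] + s[right_bulge[1] : right_end]
        bulge_right = s[right_bulge[0] : right_bulge[1]]
    else:
        paired_right = s[k:right_end]
        bulge_right = ""

    return HairpinAnnotation(
        seq_id=record.id,
        left_arm=(left_start, j),
        loop=(j, k),
        right_arm=(k, right_end),
        stem_length=stem,
        mismatch_count=len(mismatch_steps),
        mismatch_steps=tuple(mismatch_steps),
        left_bulge=left_bulge,
        right_bulge=right_bulge,
        paired_left_string=paired_left,
        paired_right_string=paired_right,
        loop_string=s[j:k],
        bulge_left_string=bulge_left,
        bulge_right_string=bulge_right,
    )


def _dominance_filter(annotations: list[HairpinAnnotation]) -> list[HairpinAnnotation]:
    """Drop annotations whose pair set is a strict subset of another's."""
    with_sets = [(ann, ann.pair_positions()) for ann in annotations]
    with_sets.sort(key=lambda x: -len(x[1]))
    kept: list[tuple[HairpinAnnotation, frozenset]] = []
    for ann, pairs in with_sets:
        if any(pairs < kp for _, kp in kept):
            continue
        kept.append((ann, pairs))
    out = [ann for ann, _ in kept]
    out.sort(key=lambda a: (a.loop[0], a.loop[1]))
    return out


def select_terminal_stemloops(
    record: SequenceRecord,
    annotations: list[HairpinAnnotation],
    end: str = THREE_PRIME,
    window: int = 50,
) -> Optional[HairpinAnnotation]:
    """Pick the single best hairpin fully contained in a terminal window.

    Ranking: longer stem, then fewer mismatches, then closer to the selected
    terminus (ties broken on loop coordinates for determinism).  Returns
    ``None`` when no annotation qualifies.
    """
    if end not in (THREE_PRIME, FIVE_PRIME):
        raise ValueError(f"end must be {THREE_PRIME!r} or {FIVE_PRIME!r}")
    n = len(record)
    if window < 2 * 1 + 1:
        logger.warning("window %d cannot host any hairpin", window)
        return None
    if end == THREE_PRIME:
        lo, hi = max(0, n - window), n
    else:
        lo, hi = 0, min(window, n)

    def proximity(a: HairpinAnnotation) -> int:
        return n - a.span[1] if end == THREE_PRIME else a.span[0]

    qualifying = [
        a
        for a in annotations
        if a.seq_id == record.id and a.span[0] >= lo and a.span[1] <= hi
    ]
    if not qualifying:
        return None
    qualifying.sort(
        key=lambda a: (-a.stem_length, a.mismatch_count, proximity(a), a.loop)
    )
    return qualifying[0]


def extract_terminal_window(
    record: SequenceRecord, end: str = THREE_PRIME, window: int = 50
) -> SequenceRecord:
    """Return the first/last ``min(window, length)`` nt as a new record."""
    if end not in (THREE_PRIME, FIVE_PRIME):
        raise ValueError(f"end must be {THREE_PRIME!r} or {FIVE_PRIME!r}")
    n = len(record)
    w = min(window, n)
    if end == THREE_PRIME:
        seq = record.sequence[n - w :]
        tag = f"3prime_last{w}"
    else:
        seq = record.sequence[:w]
        tag = f"5prime_first{w}"
    return SequenceRecord(id=f"{record.id}|{tag}", sequence=seq)
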