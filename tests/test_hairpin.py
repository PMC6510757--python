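"""Detection of approximate stem-loops and terminal selection.

Expected annotation sets for the worked fixtures were computed with the
brute-force partition enumerator in ``_oracles.py`` and frozen here; each
annotation is the canonical identity tuple
(left_arm, loop, right_arm, left_bulge, right_bulge, stem, mismatches).
"""

import numpy as np
import pytest

from _oracles import brute_force_stem_loops
from stemloop.hairpin import (
    FIVE_PRIME,
    THREE_PRIME,
    HairpinParams,
    extract_terminal_window,
    find_stem_loops,
    select_terminal_stemloops,
)
from stemloop.records import SequenceRecord, reverse_complement

ARM = "ATTGCACCGGCC"  # 12-bp arm; hairpin = ARM + AAAAA + revcomp(ARM)
PERFECT = ARM + "AAAAA" + reverse_complement(ARM)


def keys(annotations):
    return [a.key() for a in annotations]


def test_poly_a_has_no_hairpins():
    assert find_stem_loops(SequenceRecord("a", "A" * 60)) == []


def test_perfect_stem_without_bulges_is_the_single_call():
    # with bulges disabled only the planted 12-bp stem explains the repeat
    anns = find_stem_loops(
        SequenceRecord("p", PERFECT), HairpinParams(max_bulge_per_arm=0)
    )
    assert keys(anns) == [((0, 12), (12, 17), (17, 29), None, None, 12, 0)]
    a = anns[0]
    assert a.loop_string == "AAAAA"
    assert a.paired_left_string == ARM
    assert reverse_complement(a.paired_right_string) == a.paired_left_string


def test_perfect_stem_default_params_matches_frozen_oracle_set():
    # bulges allow two register-shifted redescriptions of the same repeat;
    # the frozen set is the oracle's canonical output
    anns = find_stem_loops(SequenceRecord("p", PERFECT))
    assert keys(anns) == [
        ((0, 11), (11, 17), (17, 29), None, (18, 19), 11, 0),
        ((0, 12), (12, 17), (17, 29), None, None, 12, 0),
        ((0, 12), (12, 18), (18, 29), (10, 11), None, 11, 0),
    ]


def test_two_substitutions_in_right_arm_give_mismatch_count_2():
    rc = list(reverse_complement(ARM))
    rc[2] = "T"  # step 2 from the loop, was pairing ARM[-3]='G' via 'C'
    rc[5] = "A"  # step 5, was pairing ARM[-6]='A' via 'T'
    seq = ARM + "AAAAA" + "".join(rc)
    anns = find_stem_loops(SequenceRecord("m", seq), HairpinParams(max_bulge_per_arm=0))
    best = select_terminal_stemloops(
        SequenceRecord("m", seq), anns, end=THREE_PRIME, window=len(seq)
    )
    assert best.stem_length == 12
    assert best.mismatch_count == 2
    assert best.mismatch_steps == (2, 5)


def test_nine_bp_arms_are_below_the_stem_range():
    arm9 = "TTGCACCGC"
    seq = arm9 + "AAAAA" + reverse_complement(arm9)
    assert find_stem_loops(SequenceRecord("s", seq)) == []


def test_wobble_pair_counts_as_mismatch_only_when_disabled():
    rc = list(reverse_complement(ARM))
    rc[3] = "T"  # creates G.T apposition at step 3
    seq = ARM + "AAAAA" + "".join(rc)
    strict = HairpinParams(max_bulge_per_arm=0)
    wobbly = HairpinParams(max_bulge_per_arm=0, allow_wobble=True)
    rec = SequenceRecord("w", seq)
    assert keys(find_stem_loops(rec, strict)) == [
        ((0, 12), (12, 17), (17, 29), None, None, 12, 1)
    ]
    assert keys(find_stem_loops(rec, wobbly)) == [
        ((0, 12), (12, 17), (17, 29), None, None, 12, 0)
    ]


def test_annotation_invariants_hold_on_random_sequences(rng):
    params = HairpinParams()
    for _ in range(40):
        n = int(rng.integers(30, 80))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        for a in find_stem_loops(SequenceRecord("r", seq), params):
            assert a.left_arm[1] <= a.loop[0] <= a.loop[1] <= a.right_arm[0]
            assert params.stem_min <= a.stem_length <= params.stem_max
            assert params.loop_min <= a.loop_length <= params.loop_max
            assert a.mismatch_count <= params.max_mismatches
            # paired strings reverse-complement except at mismatch steps
            left, right = a.paired_left_string, a.paired_right_string
            bad = [
                t
                for t in range(a.stem_length)
                if reverse_complement(left[-1 - t]) != right[t]
            ]
            assert tuple(sorted(bad)) == a.mismatch_steps
            for bulge, arm in ((a.left_bulge, a.left_arm), (a.right_bulge, a.right_arm)):
                if bulge is not None:
                    assert arm[0] < bulge[0] < bulge[1] < arm[1]
                    assert bulge[1] - bulge[0] <= params.max_bulge_per_arm


def test_reverse_complement_symmetry(rng):
    """Hairpins of a sequence map, coordinate-reflected, onto hairpins of
    its reverse complement.  Compared on the reflection-invariant projection
    (loop, stem length, mismatches, total bulge): the canonical left/right
    bulge placement tie-break is deliberately not mirror-symmetric."""
    params = HairpinParams()
    for _ in range(15):
        n = int(rng.integers(29, 60))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        fwd = find_stem_loops(SequenceRecord("f", seq), params, prune_nested=False)
        rev = find_stem_loops(
            SequenceRecord("r", reverse_complement(seq)), params, prune_nested=False
        )

        def total_bulge(a):
            return len(a.bulge_left_string) + len(a.bulge_right_string)

        reflected = sorted(
            ((n - a.loop[1], n - a.loop[0]), a.stem_length, a.mismatch_count, total_bulge(a))
            for a in rev
        )
        assert (
            sorted((a.loop, a.stem_length, a.mismatch_count, total_bulge(a)) for a in fwd)
            == reflected
        )


def test_relaxing_budgets_never_removes_hairpin_loops(rng):
    """Monotonicity at the candidate level: widening the stem range or the
    mismatch budget can only add loop intervals with a reported hairpin
    (nested-structure pruning, which reranks across loops, is disabled)."""
    tight = HairpinParams(stem_min=11, stem_max=16, max_mismatches=2)
    loose = HairpinParams(stem_min=10, stem_max=20, max_mismatches=5)
    for _ in range(15):
        n = int(rng.integers(30, 60))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        rec = SequenceRecord("m", seq)
        loops_tight = {a.loop for a in find_stem_loops(rec, tight, prune_nested=False)}
        loops_loose = {a.loop for a in find_stem_loops(rec, loose, prune_nested=False)}
        assert loops_tight <= loops_loose


def test_agreement_with_brute_force_on_structured_input():
    seq = "GGCACGTGCC" * 3 + "ATATAT"
    params = HairpinParams()
    assert keys(find_stem_loops(SequenceRecord("x", seq), params)) == (
        brute_force_stem_loops(seq, params)
    )


def test_select_terminal_prefers_longer_stem():
    # two planted hairpins in the last 50 nt: stem 14 and stem 11
    arm14, arm11 = "GATTGCACGACGCC", "TGCACGACGCC"[:11]
    h1 = arm14 + "AAAAA" + reverse_complement(arm14)
    h2 = arm11 + "AACAA" + reverse_complement(arm11)
    seq = h1 + "TT" + h2
    rec = SequenceRecord("s", seq)
    anns = find_stem_loops(rec, HairpinParams(max_bulge_per_arm=0))
    stems = {a.stem_length for a in anns}
    assert {14, 11} <= stems
    best = select_terminal_stemloops(rec, anns, end=THREE_PRIME, window=len(seq))
    assert best.stem_length == max(stems)


def test_select_terminal_requires_full_containment():
    arm = "ATTGCACGACGC"
    hairpin = arm + "AAAAA" + reverse_complement(arm)
    # hairpin at the 5' end of a 100-mer: outside the last-50 window
    seq = hairpin + "C" * 71
    rec = SequenceRecord("s", seq)
    anns = find_stem_loops(rec, HairpinParams(max_bulge_per_arm=0))
    assert anns
    assert select_terminal_stemloops(rec, anns, end=THREE_PRIME, window=50) is None
    assert select_terminal_stemloops(rec, anns, end=FIVE_PRIME, window=50) is not None


def test_extract_terminal_window_clamps_and_tags():
    rec = SequenceRecord("x", "ACGT" * 50)
    last = extract_terminal_window(rec, THREE_PRIME, 50)
    assert last.sequence == rec.sequence[-50:] and "3prime" in last.id
    first = extract_terminal_window(rec, FIVE_PRIME, 50)
    assert first.sequence == rec.sequence[:50]
    short = extract_terminal_window(SequenceRecord("y", "ACGTAC"), THREE_PRIME, 50)
    assert short.sequence == "ACGTAC"


def test_empty_and_invalid_inputs():
    assert find_stem_loops(SequenceRecord("e", "")) == []
    with pytest.raises(ValueError):
        HairpinParams(stem_min=0)
    with pytest.raises(ValueError):
        HairpinParams(loop_min=7, loop_max=3)
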