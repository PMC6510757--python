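"""Feature encodings: k-mer frequencies and the 134-entry structural layout."""

import numpy as np
import pytest

from stemloop.encode import (
    BASES,
    EncodingError,
    SCHEME_KMER,
    SCHEME_STRUCTURE,
    DinucPropertyTable,
    FeatureVector,
    encode_bulge,
    encode_loop,
    encode_stem,
    encode_structure,
    eligible_for_structure,
    kmer_feature_names,
    kmer_frequencies,
    structure_feature_names,
)
from stemloop.hairpin import HairpinParams, find_stem_loops, select_terminal_stemloops
from stemloop.records import SequenceRecord, reverse_complement


def test_property_table_is_complete_and_finite(table):
    assert len(table.values) == 16
    assert len(table.properties) == 10
    assert table.properties[0] == "shift" and table.properties[-1] == "hydrophilicity"
    for vec in table.values.values():
        assert np.all(np.isfinite(vec))
    # thermodynamic values are symmetric under reverse complementation
    comp = {"A": "U", "U": "A", "C": "G", "G": "C"}
    for dinuc in table.values:
        rc = "".join(comp[b] for b in reversed(dinuc))
        for prop in ("enthalpy", "entropy", "free_energy"):
            i = table.properties.index(prop)
            assert table.values[dinuc][i] == table.values[rc][i]


def test_table_provenance_notes_present(table):
    assert set(table.provenance) == set(table.properties)


def idx(names, name):
    return list(names).index(name)


def test_kmer_poly_a():
    fv = kmer_frequencies(SequenceRecord("a", "AAAA"))
    assert fv.scheme == SCHEME_KMER and len(fv.values) == 80
    assert fv.values[idx(fv.names, "AA")] == 1.0
    assert fv.values[idx(fv.names, "AAA")] == 1.0
    assert fv.values.sum() == 2.0


def test_kmer_acgt():
    fv = kmer_frequencies(SequenceRecord("a", "ACGT"))
    for k2 in ("AC", "CG", "GT"):
        assert fv.values[idx(fv.names, k2)] == pytest.approx(1 / 3)
    for k3 in ("ACG", "CGT"):
        assert fv.values[idx(fv.names, k3)] == pytest.approx(1 / 2)
    assert np.count_nonzero(fv.values) == 5


def test_kmer_frequencies_normalize_per_width(rng):
    seq = "".join(rng.choice(list("ACGT"), size=50))
    fv = kmer_frequencies(SequenceRecord("x", seq))
    assert fv.values[:16].sum() == pytest.approx(1.0)
    assert fv.values[16:].sum() == pytest.approx(1.0)


def test_kmer_windows_with_n_are_skipped_in_numerator_only():
    fv = kmer_frequencies(SequenceRecord("n", "AANAA"))
    # 4 dinucleotide windows, 2 contain N
    assert fv.values[idx(fv.names, "AA")] == pytest.approx(2 / 4)
    assert fv.values[:16].sum() == pytest.approx(2 / 4)


def test_kmer_shorter_than_widest_window_gives_zero_vector():
    for seq in ("AC", "A"):
        fv = kmer_frequencies(SequenceRecord("s", seq), ks=(2, 3))
        assert not fv.values.any()


def test_loop_one_hot_layout():
    block = encode_loop("GGATA")  # DNA spelling of the GGAUA loop motif
    assert len(block) == 20
    expected = np.zeros(20)
    for pos, base in enumerate("GGATA"):
        expected[4 * pos + BASES.index(base)] = 1.0
    assert np.array_equal(block, expected)


def test_loop_uses_only_first_five_positions():
    assert np.array_equal(encode_loop("AAAAAAA"), encode_loop("AAAAA"))
    assert encode_loop("ACGTAGG").sum() == 5


def test_loop_n_position_is_all_zero_and_short_loop_errors():
    block = encode_loop("ANGTA")
    assert block.sum() == 4 and not block[4:8].any()
    with pytest.raises(EncodingError):
        encode_loop("ACGT")


def test_bulge_layout_and_zero_fill():
    assert not encode_bulge("", "").any()
    block = encode_bulge("AG", "")
    # left bulge filled loop-proximal first: LB0 = 3'-most left-bulge base
    assert block[0:4].tolist() == [0, 0, 1, 0]  # LB0 = G
    assert block[4:8].tolist() == [1, 0, 0, 0]  # LB1 = A
    assert not block[8:].any()
    assert encode_bulge("ACT", "GGG").sum() == 6
    with pytest.raises(EncodingError):
        encode_bulge("ACTG", "")


def test_stem_block_constant_arm(table):
    block = encode_stem("G" * 10, table)
    assert len(block) == 90
    gg = table.lookup("GG")
    assert np.array_equal(block.reshape(9, 10), np.tile(gg, (9, 1)))


def test_stem_block_alternating_arm_reads_steps_from_the_loop(table):
    # arm 5'->3' "GCGCGCGCGC": loop-adjacent step LS0 = positions 9,8 read
    # 5'->3' = "GC"; steps then alternate CG/GC outward
    block = encode_stem("GCGCGCGCGC", table).reshape(9, 10)
    for step in range(9):
        expected = table.lookup("GC" if step % 2 == 0 else "CG")
        assert np.array_equal(block[step], expected)


def test_stem_takes_ten_loop_proximal_nucleotides(table):
    long_arm = "AAAAA" + "GCGCGCGCGC"
    assert np.array_equal(encode_stem(long_arm, table), encode_stem("GCGCGCGCGC", table))
    with pytest.raises(EncodingError):
        encode_stem("GCGCGCGADA"[:9], table)


def test_stem_step_with_n_is_zero_filled(table):
    block = encode_stem("GCGCNCGCGC", table).reshape(9, 10)
    assert not block[4].any() and not block[5].any()
    assert block[0].any()


def test_structure_vector_is_134_with_documented_names(table):
    names = structure_feature_names(table)
    assert len(names) == 134
    assert names[0] == "LS0:shift" and names[89] == "LS8:hydrophilicity"
    assert names[90] == "LP0:A" and names[109] == "LP4:T"
    assert names[110] == "LB0:A" and names[133] == "RB2:T"


def _detected_hairpin(seq):
    rec = SequenceRecord("h", seq)
    anns = find_stem_loops(rec, HairpinParams(loop_min=5))
    return select_terminal_stemloops(rec, anns, window=len(seq))


def test_structure_encoding_of_a_clean_hairpin(table):
    arm = "ATTGCACGACGC"
    ann = _detected_hairpin(arm + "AAAAA" + reverse_complement(arm))
    fv = encode_structure(ann, table)
    assert fv.scheme == SCHEME_STRUCTURE and len(fv.values) == 134
    # stem block: LS0 is the loop-adjacent step of the 5' arm ("GC")
    assert np.array_equal(fv.values[0:10], table.lookup("GC"))
    # loop block sums to 5 (one-hot completeness), bulge block all zero
    assert fv.values[90:110].sum() == 5.0
    assert not fv.values[110:].any()


def test_structure_encoding_determinism(table):
    arm = "ATTGCACGACGC"
    ann = _detected_hairpin(arm + "AAAAA" + reverse_complement(arm))
    a = encode_structure(ann, table)
    b = encode_structure(ann, table)
    assert np.array_equal(a.values, b.values) and a.names == b.names


def test_eligibility_filter(table):
    arm = "ATTGCACGACGC"
    ann = _detected_hairpin(arm + "AAAAA" + reverse_complement(arm))
    assert eligible_for_structure(ann)
    short_loop = _detected_hairpin(arm + "AAAAA" + reverse_complement(arm))
    assert short_loop.loop_length >= 5


def test_feature_vector_contracts():
    with pytest.raises(ValueError):
        FeatureVector(names=("a", "a"), values=np.zeros(2), scheme=SCHEME_KMER)
    with pytest.raises(ValueError):
        FeatureVector(names=("a",), values=np.zeros(1), scheme=SCHEME_STRUCTURE)
    assert len(kmer_feature_names()) == 80


def test_encoding_never_fails_for_acgt_stems(table, rng):
    for _ in range(50):
        arm = "".join(rng.choice(list("ACGT"), size=10))
        assert len(encode_stem(arm, table)) == 90
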