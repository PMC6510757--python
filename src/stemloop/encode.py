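"""Feature encodings for the two model families.

Sequence-based scheme (``sequence_kmer``): overlapping di- and trinucleotide
frequencies of a window, 16 + 64 = 80 features, each k-mer count divided by
the number of width-k windows so clipped inputs remain comparable.

Structure-based scheme (``structure_sl``): 134 features per stem-loop,
concatenated as

* 90 stem features - the 10 loop-proximal nucleotides of the 5' arm give 9
  overlapping dinucleotide steps (LS0 adjacent to the loop ... LS8 toward
  the stem base), each mapped to 10 physico-chemical/helical properties of
  the bundled RNA dinucleotide table;
* 20 loop features - one-hot (A, C, G, T) for the first five loop positions
  LP0-LP4 read 5'->3';
* 24 bulge features - one-hot slots LB0-LB2 (left-arm bulge) and RB0-RB2
  (right-arm bulge), filled loop-proximal first, zero-padded when a bulge is
  shorter than 3 nt or absent.

Feature names are globally unique ``position:property`` labels
(``LS0:shift``, ``LP2:G``, ``RB1:T``) with a stable documented order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from pathlib import Path
from typing import Iterable

import logging

import numpy as np

from .hairpin import HairpinAnnotation
from .records import SequenceRecord

logger = logging.getLogger(__name__)

PROPERTY_NAMES = (
    "shift",
    "slide",
    "rise",
    "tilt",
    "roll",
    "twist",
    "enthalpy",
    "entropy",
    "free_energy",
    "hydrophilicity",
)

BASES = ("A", "C", "G", "T")

SCHEME_KMER = "sequence_kmer"
SCHEME_STRUCTURE = "structure_sl"

MIN_STEM_FOR_ENCODING = 10
MIN_LOOP_FOR_ENCODING = 5
MAX_BULGE_FOR_ENCODING = 3


class EncodingError(ValueError):
    """Raised when an instance cannot be encoded under the fixed layout."""


@dataclass(frozen=True)
class DinucPropertyTable:
    """16 RNA dinucleotides x 10 named properties, with provenance strings."""

    properties: tuple[str, ...]
    values: dict[str, np.ndarray]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.values) != 16:
            raise ValueError(f"expected 16 dinucleotides, got {len(self.values)}")
        for dinuc, vec in self.values.items():
            if len(vec) != len(self.properties) or not np.all(np.isfinite(vec)):
                raise ValueError(f"bad property vector for {dinuc!r}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DinucPropertyTable":
        provenance: dict[str, str] = {}
        header: list[str] | None = None
        values: dict[str, np.ndarray] = {}
        for line in Path(path).read_text().splitlines():
            if line.startswith("#!"):
                name, _, note = line[2:].strip().partition("\t")
                provenance[name.strip()] = note.strip()
                continue
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields[1:]]
                continue
            values[fields[0].strip()] = np.asarray(fields[1:], dtype=float)
        if header is None:
            raise ValueError(f"no header row in property table {path}")
        return cls(properties=tuple(header), values=values, provenance=provenance)

    @classmethod
    def load_default(cls) -> "DinucPropertyTable":
        path = resources.files("stemloop.data") / "dinucleotide_properties.tsv"
        return cls.from_tsv(str(path))

    def lookup(self, dinucleotide_rna: str) -> np.ndarray:
        return self.values[dinucleotide_rna]


@dataclass(frozen=True)
class FeatureVector:
    """Named, ordered numeric features for one instance."""

    names: tuple[str, ...]
    values: np.ndarray
    scheme: str

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if self.scheme == SCHEME_STRUCTURE and len(self.values) != 134:
            raise ValueError("structure_sl vectors must have exactly 134 entries")


def kmer_feature_names(ks: Iterable[int] = (2, 3)) -> tuple[str, ...]:
    names: list[str] = []
    for k in sorted(ks):
        names.extend("".join(p) for p in product(BASES, repeat=k))
    return tuple(names)


def kmer_frequencies(record: SequenceRecord, ks: Iterable[int] = (2, 3)) -> FeatureVector:
    """Overlapping k-mer frequencies (counts / number of width-k windows).

    Windows containing N are skipped in the numerator but still counted in
    the denominator.  A record shorter than max(ks) yields all zeros.
    """
    ks = tuple(sorted(ks))
    seq = record.sequence
    names = kmer_feature_names(ks)
    index = {name: i for i, name in enumerate(names)}
    values = np.zeros(len(names))
    if len(seq) < max(ks):
        logger.warning(
            "record %s shorter than max k-mer width; all-zero features", record.id
        )
        return FeatureVector(names=names, values=values, scheme=SCHEME_KMER)
    for k in ks:
        n_windows = len(seq) - k + 1
        if n_windows <= 0:
            continue
        for i in range(n_windows):
            kmer = seq[i : i + k]
            if kmer in index:  # windows containing N are skipped
                values[index[kmer]] += 1
        lo = names.index("".join(BASES[0] * k))
        values[lo : lo + 4**k] /= n_windows
    return FeatureVector(names=names, values=values, scheme=SCHEME_KMER)


def _one_hot(base: str) -> np.ndarray:
    vec = np.zeros(4)
    if base in BASES:
        vec[BASES.index(base)] = 1.0
    return vec  # N (or padding) stays all-zero


def encode_loop(loop_string: str) -> np.ndarray:
    """20 binary features for loop positions LP0-LP4 (first five, 5'->3')."""
    if len(loop_string) < MIN_LOOP_FOR_ENCODING:
        raise EncodingError(
            f"loop {loop_string!r} shorter than {MIN_LOOP_FOR_ENCODING} nt"
        )
    return np.concatenate([_one_hot(b) for b in loop_string[:5]])


def encode_bulge(bulge_left: str, bulge_right: str) -> np.ndarray:
    """24 binary features for bulge slots LB0-LB2 then RB0-RB2.

    Slots are filled loop-proximal first: the left-arm bulge string (given
    5'->3') is read from its 3' end toward 5', the right-arm bulge from its
    5' end toward 3'.  Missing positions are all-zero.
    """
    if len(bulge_left) > 3 or len(bulge_right) > 3:
        raise EncodingError("bulge longer than 3 nt cannot be encoded")
    blocks = []
    ordered_left = bulge_left[::-1]
    for slot in range(3):
        blocks.append(_one_hot(ordered_left[slot]) if slot < len(ordered_left) else np.zeros(4))
    for slot in range(3):
        blocks.append(_one_hot(bulge_right[slot]) if slot < len(bulge_right) else np.zeros(4))
    return np.concatenate(blocks)


def encode_stem(paired_left_string: str, table: DinucPropertyTable) -> np.ndarray:
    """90 numeric features from the 10 loop-proximal nt of the 5' arm.

    The arm is given 5'->3' with the loop at its 3' end.  Steps LS0
    (loop-adjacent) .. LS8 are the 9 overlapping dinucleotides of that
    10-mer, each read 5'->3', mapped T->U and looked up in the property
    table; layout is step-major.  A step containing N contributes zeros.
    """
    if len(paired_left_string) < MIN_STEM_FOR_ENCODING:
        raise EncodingError(
            f"paired stem length {len(paired_left_string)} < {MIN_STEM_FOR_ENCODING}"
        )
    proximal = paired_left_string[-10:].replace("T", "U")
    blocks = []
    for step in range(9):  # LS0 = loop-adjacent dinucleotide step
        dinuc = proximal[8 - step : 10 - step]
        if "N" in dinuc:
            logger.warning("stem step LS%d contains N; zero-filled", step)
            blocks.append(np.zeros(len(table.properties)))
        else:
            blocks.append(table.lookup(dinuc))
    return np.concatenate(blocks)


def structure_feature_names(table: DinucPropertyTable) -> tuple[str, ...]:
    names = [f"LS{i}:{p}" for i in range(9) for p in table.properties]
    names += [f"LP{i}:{b}" for i in range(5) for b in BASES]
    names += [f"LB{i}:{b}" for i in range(3) for b in BASES]
    names += [f"RB{i}:{b}" for i in range(3) for b in BASES]
    return tuple(names)


def eligible_for_structure(hairpin: HairpinAnnotation) -> bool:
    """Whether a hairpin fits the fixed 134-feature layout."""
    return (
        hairpin.stem_length >= MIN_STEM_FOR_ENCODING
        and hairpin.loop_length >= MIN_LOOP_FOR_ENCODING
        and len(hairpin.bulge_left_string) <= MAX_BULGE_FOR_ENCODING
        and len(hairpin.bulge_right_string) <= MAX_BULGE_FOR_ENCODING
    )


def encode_structure(
    hairpin: HairpinAnnotation, table: DinucPropertyTable
) -> FeatureVector:
    """Concatenate [stem 90 | loop 20 | bulge 24] into one 134-entry vector."""
    values = np.concatenate(
        [
            encode_stem(hairpin.paired_left_string, table),
            encode_loop(hairpin.loop_string),
            encode_bulge(hairpin.bulge_left_string, hairpin.bulge_right_string),
        ]
    )
    return FeatureVector(
        names=structure_feature_names(table), values=values, scheme=SCHEME_STRUCTURE
    )
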