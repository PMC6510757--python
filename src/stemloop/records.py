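"""Sequence records and alphabet handling.

All sequences are kept in a normalized DNA convention: uppercase over
{A, C, G, T, N}, with RNA input (U) mapped to T on the way in.  Coordinates
everywhere in the package are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AlphabetError(ValueError):
    """Raised when a sequence contains a symbol outside {A,C,G,T,U,N}."""


def normalize_sequence(sequence: str) -> str:
    """Uppercase, map U->T and validate against the DNA alphabet.

    Raises :class:`AlphabetError` naming the first offending symbol.
    """
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - ALPHABET
    if bad:
        offender = sorted(bad)[0]
        raise AlphabetError(
            f"sequence contains non-nucleotide symbol {offender!r} "
            f"(allowed: A, C, G, T, U, N)"
        )
    return seq


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """An identified nucleotide sequence (normalized DNA alphabet)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: non-normalized symbol {sorted(bad)[0]!r}; "
                "use SequenceRecord.from_raw() for un-normalized input"
            )

    @classmethod
    def from_raw(cls, id: str, sequence: str) -> "SequenceRecord":
        return cls(id=id, sequence=normalize_sequence(sequence))

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(
            id=f"{self.id}|rc", sequence=reverse_complement(self.sequence)
        )
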