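"""Dinucleotide-preserving sequence shuffling (Altschul-Erikson).

Shuffled sequences form the negative class of the classification
experiments: they keep the exact multiset of overlapping dinucleotides of
the input (hence also mononucleotide counts, and the first and last
nucleotide), so a classifier cannot separate the classes on low-order
composition alone.

The sampler builds the dinucleotide multigraph (a directed edge per
overlapping dinucleotide), draws a uniform-random arborescence toward the
terminal symbol to fix each vertex's last outgoing edge, permutes the
remaining out-edges, and emits the resulting Eulerian walk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import SequenceRecord


@dataclass(frozen=True)
class ShuffleConfig:
    seed: int = 0
    n_shuffles_per_sequence: int = 1

    def __post_init__(self) -> None:
        if self.n_shuffles_per_sequence < 1:
            raise ValueError("n_shuffles_per_sequence must be >= 1")


def shuffle_string(seq: str, rng: np.random.Generator) -> str:
    """One Altschul-Erikson shuffle of ``seq`` (any alphabet, length >= 2)."""
    if len(seq) < 2:
        raise ValueError("dinucleotide shuffle requires length >= 2")
    vertices = sorted(set(seq))
    if len(vertices) == 1:
        return seq
    edges: dict[str, list[str]] = {v: [] for v in vertices}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]

    # Sample last out-edges forming an arborescence toward `last`
    # (rejection sampling over uniform random choices -> uniform Eulerian walk).
    others = [v for v in vertices if v != last and edges[v]]
    while True:
        last_edge = {v: edges[v][int(rng.integers(len(edges[v])))] for v in others}
        if _reaches_all(last_edge, last):
            break

    walk_edges: dict[str, list[str]] = {}
    for v in vertices:
        pool = list(edges[v])
        if v in last_edge:
            pool.remove(last_edge[v])
        order = rng.permutation(len(pool))
        shuffled = [pool[i] for i in order]
        if v in last_edge:
            shuffled.append(last_edge[v])
        walk_edges[v] = shuffled

    out = [seq[0]]
    ptr = {v: 0 for v in vertices}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = walk_edges[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def _reaches_all(last_edge: dict[str, str], sink: str) -> bool:
    for v in last_edge:
        seen = set()
        cur = v
        while cur != sink:
            if cur in seen or cur not in last_edge:
                return False
            seen.add(cur)
            cur = last_edge[cur]
    return True


def dinucleotide_shuffle(
    record: SequenceRecord, config: ShuffleConfig, index: int = 0
) -> list[SequenceRecord]:
    """Produce ``n_shuffles_per_sequence`` shuffles of one record.

    Deterministic given (sequence, config.seed, index); ids are suffixed
    ``|shuf<k>``.  ``index`` decorrelates the random streams of records
    shuffled as part of one batch.
    """
    out = []
    for k in range(config.n_shuffles_per_sequence):
        rng = np.random.default_rng([config.seed % (2**31), index, k])
        out.append(
            SequenceRecord(
                id=f"{record.id}|shuf{k + 1}",
                sequence=shuffle_string(record.sequence, rng),
            )
        )
    return out


def shuffle_records(
    records: list[SequenceRecord], config: ShuffleConfig
) -> list[SequenceRecord]:
    """Shuffle a batch of records; order follows the input, shuffles grouped
    per source record."""
    out: list[SequenceRecord] = []
    for i, rec in enumerate(records):
        out.extend(dinucleotide_shuffle(rec, config, index=i))
    return out
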