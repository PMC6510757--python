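"""Independent brute-force oracles used by the test suite.

These deliberately avoid the vectorized machinery of the package: the
hairpin oracle enumerates explicit genomic-interval partitions
(left arm, left bulge, loop, right bulge, right arm) with plain string
operations, and the shuffle oracle enumerates Eulerian paths of the
dinucleotide multigraph by exhaustive recursion.
"""

from __future__ import annotations

from collections import Counter

WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
WOBBLE = {("G", "T"), ("T", "G")}


def pairs(x: str, y: str, allow_wobble: bool = False) -> bool:
    return (x, y) in WC or (allow_wobble and (x, y) in WOBBLE)


def brute_force_stem_loops(seq, params):
    """Enumerate all valid hairpin candidates partition-by-partition and apply
    the canonical reporting rules (best per loop, then dominance filter).

    Returns a list of canonical identity tuples
    (left_arm, loop, right_arm, left_bulge, right_bulge, stem, mismatches)
    sorted by loop coordinates, matching HairpinAnnotation.key().
    """
    n = len(seq)
    per_loop_best = {}
    for j in range(1, n):
        for k in range(j + params.loop_min, min(j + params.loop_max, n - 1) + 1):
            if not pairs(seq[j - 1], seq[k], params.allow_wobble):
                continue  # innermost stem position must pair
            best = None
            # left arm [i, j) with optional interior bulge [u, v)
            for i in range(max(0, j - params.stem_max - params.max_bulge_per_arm), j):
                left_opts = [(None, seq[i:j])]
                for u in range(i + 1, j):
                    for blen in range(1, params.max_bulge_per_arm + 1):
                        v = u + blen
                        if v >= j:
                            break
                        left_opts.append(((u, v), seq[i:u] + seq[v:j]))
                for lbulge, pleft in left_opts:
                    stem = len(pleft)
                    if not (params.stem_min <= stem <= params.stem_max):
                        continue
                    # right arm [k, l) with optional interior bulge [w, x)
                    for l in range(k + 1, min(n, k + params.stem_max + params.max_bulge_per_arm) + 1):
                        right_opts = [(None, seq[k:l])]
                        for w in range(k + 1, l):
                            for blen in range(1, params.max_bulge_per_arm + 1):
                                x = w + blen
                                if x >= l:
                                    break
                                right_opts.append(((w, x), seq[k:w] + seq[x:l]))
                        for rbulge, pright in right_opts:
                            if len(pright) != stem:
                                continue
                            mm_steps = [
                                t
                                for t in range(stem)
                                if not pairs(pleft[-1 - t], pright[t], params.allow_wobble)
                            ]
                            if len(mm_steps) > params.max_mismatches:
                                continue
                            if 0 in mm_steps or (stem - 1) in mm_steps:
                                continue  # stems are bounded by pairs
                            bl = 0 if lbulge is None else lbulge[1] - lbulge[0]
                            pl = 0 if lbulge is None else j - lbulge[1]
                            br = 0 if rbulge is None else rbulge[1] - rbulge[0]
                            pr = 0 if rbulge is None else rbulge[0] - k
                            rank = (
                                len(mm_steps) + bl + br,  # total defects
                                -stem,
                                bl + br,
                                bl,
                                pl,
                                br,
                                pr,
                            )
                            entry = (
                                rank,
                                ((i, j), (j, k), (k, l), lbulge, rbulge, stem, len(mm_steps)),
                            )
                            if best is None or entry[0] < best[0]:
                                best = entry
            if best is not None:
                per_loop_best[(j, k)] = best[1]

    # dominance filter on base-pair sets
    def pair_set(tup):
        (i, j), (jj, k), (kk, l), lbulge, rbulge, stem, _ = tup
        bl = 0 if lbulge is None else lbulge[1] - lbulge[0]
        pl = 0 if lbulge is None else j - lbulge[1]
        br = 0 if rbulge is None else rbulge[1] - rbulge[0]
        pr = 0 if rbulge is None else rbulge[0] - k
        out = set()
        for t in range(stem):
            a = bl if (bl and t >= pl) else 0
            b = br if (br and t >= pr) else 0
            out.add((j - 1 - t - a, k + t + b))
        return frozenset(out)

    entries = [(tup, pair_set(tup)) for tup in per_loop_best.values()]
    entries.sort(key=lambda e: -len(e[1]))
    kept = []
    for tup, ps in entries:
        if any(ps < kp for _, kp in kept):
            continue
        kept.append((tup, ps))
    result = [tup for tup, _ in kept]
    result.sort(key=lambda t: t[1])
    return result


def enumerate_eulerian_sequences(seq: str) -> set[str]:
    """All sequences with the same overlapping-dinucleotide multiset, the same
    first and last symbol (exhaustive walk enumeration; tiny inputs only)."""
    edges = Counter(seq[i : i + 2] for i in range(len(seq) - 1))
    out: set[str] = set()

    def walk(cur: str, remaining: Counter, acc: list[str]) -> None:
        if not +remaining:
            if cur == seq[-1]:
                out.add("".join(acc))
            return
        for edge, cnt in list(remaining.items()):
            if cnt and edge[0] == cur:
                remaining[edge] -= 1
                acc.append(edge[1])
                walk(edge[1], remaining, acc)
                acc.pop()
                remaining[edge] += 1

    walk(seq[0], edges, [seq[0]])
    return out
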