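"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive expected results by exhaustive enumeration,
staying structurally independent of the package's implementations.
"""

from __future__ import annotations

from Bio.Seq import Seq


def oracle_codon(seq: str, pos: int, circular: bool) -> str | None:
    n = len(seq)
    if circular:
        return (seq + seq)[pos % n:pos % n + 3]
    if pos < 0 or pos + 3 > n:
        return None
    return seq[pos:pos + 3]


def oracle_boundary_scan(
    reading: str,
    anchor: int,
    wanted: frozenset[str],
    blocking: frozenset[str],
    window: int,
    circular: bool,
    extend_sign: int,
) -> tuple[int, bool]:
    """Enumerate all offsets in [-window, +window], apply the opposite-set
    restriction, pick the minimal-|offset| hit (ties: extending direction)."""
    c0 = oracle_codon(reading, anchor, circular)
    if c0 is not None and c0 in wanted:
        return anchor, True
    blockers = [
        d for d in range(-window, window + 1)
        if (c := oracle_codon(reading, anchor + d, circular)) is not None and c in blocking
    ]
    barrier = max(blockers) if blockers else None
    candidates = [
        d for d in range(-window, window + 1)
        if d != 0
        and (barrier is None or d > barrier)
        and (c := oracle_codon(reading, anchor + d, circular)) is not None
        and c in wanted
    ]
    if not candidates:
        return anchor, False
    best = min(candidates, key=lambda d: (abs(d), 0 if d * extend_sign > 0 else 1))
    return anchor + best, True


def oracle_lca(parents: dict[int, int], root: int, query: list[int]) -> int:
    """Ancestor-set intersection; deepest shared ancestor wins."""

    def ancestors(t: int) -> list[int]:
        out = [t]
        while t != root:
            t = parents[t]
            out.append(t)
        return out

    common = set(ancestors(query[0]))
    for q in query[1:]:
        common &= set(ancestors(q))
    # deepest = largest depth (path length from root)
    def depth(t: int) -> int:
        return len(ancestors(t)) - 1

    return max(common, key=depth)


def oracle_revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def oracle_kmer_occurrences(sequence: str, label: str, edge_len: int, circular: bool):
    """Naive substring scan: canonical kmer -> sorted (genome, pos, forward)."""
    n = len(sequence)
    doubled = sequence + sequence[: edge_len - 1]
    out: dict[str, list[tuple[str, int, bool]]] = {}
    limit = n if circular else n - edge_len + 1
    for pos in range(max(limit, 0)):
        kmer = doubled[pos:pos + edge_len]
        if set(kmer) - set("ACGT"):
            continue
        rc = oracle_revcomp(kmer)
        canon, fwd = (kmer, True) if kmer <= rc else (rc, False)
        out.setdefault(canon, []).append((label, pos, fwd))
    return out


def oracle_average_linkage_clusters(dist: list[list[float]], cut: float) -> list[set[int]]:
    """Naive agglomerative average-linkage clustering, merging while the
    closest pair of clusters is within `cut`."""
    clusters: list[set[int]] = [{i} for i in range(len(dist))]
    while len(clusters) > 1:
        best = None
        best_d = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = sum(dist[a][b] for a in clusters[i] for b in clusters[j]) / (
                    len(clusters[i]) * len(clusters[j])
                )
                if best_d is None or d < best_d - 1e-12:
                    best_d, best = d, (i, j)
        if best_d is None or best_d > cut:
            break
        i, j = best
        clusters[i] |= clusters[j]
        del clusters[j]
    return clusters
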