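"""End-to-end annotation: map, bridge, filter, cluster, emit predictions.

The input genome's (k+1)-mers are looked up in the reference index. A
(k+1)-mer is admitted to the match profile only if its edge weight — the
number of distinct reference genomes containing it — reaches the
``edge_weight`` threshold. Admitted occurrences transfer their gene labels
position-exactly onto the covered input positions (orientation-aware, so a
reference match on the opposite strand flips the vote's strand).

Per (reference genome, gene, strand), maximal runs of labelled input
positions become interval predictions; runs separated by an unmatched gap of
at most ``gap_bridge`` nt are merged, standing in for the graph bridging of
unmatched regions. Genes predicted by fewer than ``prediction_count``
distinct reference genomes are dropped. The surviving predictions of each
gene are clustered (average linkage on 1 − positional Jaccard overlap, cut
at ``cluster_cut``); a cluster is selected when its relative frequency
reaches ``alpha`` times the highest relative frequency, and contributes one
consensus prediction (member-wise median endpoints, majority strand).

If a genetic code is supplied, the selected predictions finally pass through
boundary correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .boundary import DEFAULT_WINDOW, GenePrediction, correct_boundaries
from .genetic_code import GeneticCode
from .refdb import (
    DEFAULT_K,
    INTERGENIC,
    KmerIndex,
    enumerate_kmers,
    kmer_is_usable,
    restrict_index,
)
from .taxonomy import EmptyReferenceSetError, TaxonomyTree, resolve_filter

__all__ = [
    "Parameters",
    "MatchProfile",
    "IntervalPrediction",
    "PredictionCluster",
    "AnnotationError",
    "map_input",
    "derive_interval_predictions",
    "filter_by_prediction_count",
    "cluster_and_select",
    "annotate",
]

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    """Invalid parameters or inconsistent inputs to the pipeline."""


@dataclass(frozen=True)
class Parameters:
    """Runtime parameters of the annotation pipeline.

    edge_weight
        Minimum number of reference genomes that must contain a (k+1)-mer of
        the input for it to enter the match profile.
    prediction_count
        Minimum number of reference genomes that must predict a gene for it
        to be considered.
    alpha
        Fraction of the highest relative frequency a prediction cluster must
        reach to be selected (0 selects every cluster, 1 only the maximal
        ones).
    gap_bridge
        Maximum unmatched gap (nt) bridged between two runs of the same
        (genome, gene, strand); defaults to 2k.
    cluster_cut
        Distance threshold at which the per-gene dendrogram is cut.
    """

    k: int = DEFAULT_K
    edge_weight: int = 2
    prediction_count: int = 2
    alpha: float = 0.5
    gap_bridge: int | None = None
    cluster_cut: float = 0.5
    circular: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise AnnotationError(f"k must be >= 1, got {self.k}")
        if self.edge_weight < 1:
            raise AnnotationError(f"edge weight must be >= 1, got {self.edge_weight}")
        if self.prediction_count < 1:
            raise AnnotationError(
                f"prediction count must be >= 1, got {self.prediction_count}"
            )
        if not 0.0 <= self.alpha <= 1.0:
            raise AnnotationError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.gap_bridge is not None and self.gap_bridge < 0:
            raise AnnotationError(f"gap bridge must be >= 0, got {self.gap_bridge}")
        if not 0.0 < self.cluster_cut <= 1.0:
            raise AnnotationError(
                f"cluster cut must be in (0, 1], got {self.cluster_cut}"
            )

    @property
    def effective_gap_bridge(self) -> int:
        return 2 * self.k if self.gap_bridge is None else self.gap_bridge


VoteKey = tuple[str, str, str, str]  # genome_label, gene_name, kind, strand


@dataclass
class MatchProfile:
    """Per-position votes from surviving (k+1)-mer occurrences.

    ``coverage`` maps a (genome, gene, kind, strand) vote key to a boolean
    mask over input positions; only (k+1)-mers whose edge weight reaches the
    edge-weight threshold contribute.
    """

    length: int
    circular: bool
    coverage: dict[VoteKey, np.ndarray] = field(default_factory=dict)

    def votes_at(self, position: int) -> set[VoteKey]:
        p = position % self.length if self.circular else position
        return {key for key, mask in self.coverage.items() if mask[p]}

    @property
    def n_votes(self) -> int:
        return int(sum(int(m.sum()) for m in self.coverage.values()))


@dataclass(frozen=True)
class IntervalPrediction:
    """One reference genome's prediction of one gene on the input."""

    gene_name: str
    genome_label: str
    start: int
    end: int
    strand: str
    kind: str = "protein"


@dataclass(frozen=True)
class PredictionCluster:
    gene_name: str
    members: tuple[IntervalPrediction, ...]
    rel_freq: float
    consensus: tuple[int, int, str]
    kind: str = "protein"


def map_input(sequence: str, index: KmerIndex, params: Parameters) -> MatchProfile:
    """Build the match profile of the input against the reference index."""
    if params.k != index.k:
        raise AnnotationError(
            f"parameter k={params.k} does not match index k={index.k}"
        )
    n = len(sequence)
    edge_len = index.edge_length
    profile = MatchProfile(length=n, circular=params.circular)
    support_cache: dict[str, int] = {}
    for pos, kmer in enumerate_kmers(sequence, edge_len, params.circular):
        if not kmer_is_usable(kmer):
            continue
        canon, input_fwd, occs = index.lookup(kmer)
        if not occs:
            continue
        support = support_cache.get(canon)
        if support is None:
            support = len({o.genome_label for o in occs})
            support_cache[canon] = support
        if support < params.edge_weight:
            continue
        for occ in occs:
            same = occ.forward == input_fwd
            for lab in occ.labels:
                strand = lab.strand if same else ("-" if lab.strand == "+" else "+")
                lo, hi = (lab.lo, lab.hi) if same else (edge_len - lab.hi, edge_len - lab.lo)
                key = (occ.genome_label, lab.gene_name, lab.kind, strand)
                mask = profile.coverage.get(key)
                if mask is None:
                    mask = np.zeros(n, dtype=bool)
                    profile.coverage[key] = mask
                a, b = pos + lo, pos + hi
                if b <= n:
                    mask[a:b] = True
                else:  # wraps the origin (circular input)
                    mask[a:] = True
                    mask[: b - n] = True
    return profile


def _runs(mask: np.ndarray, circular: bool) -> list[tuple[int, int]]:
    """Maximal half-open runs of True; a circular wrap run has end > len."""
    n = len(mask)
    if not mask.any():
        return []
    if mask.all():
        return [(0, n)]
    padded = np.diff(mask.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    runs = list(zip(starts.tolist(), ends.tolist()))
    if circular and len(runs) > 1 and runs[0][0] == 0 and runs[-1][1] == n:
        first = runs.pop(0)
        last = runs.pop()
        runs.append((last[0], n + first[1]))
    return runs


def _bridge(runs: list[tuple[int, int]], gap: int, n: int, circular: bool) -> list[tuple[int, int]]:
    """Merge runs separated by an unmatched gap of at most `gap` nt."""
    if not runs:
        return []
    runs = sorted(runs)
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if s - pe <= gap:
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    if circular and len(merged) > 1:
        # gap across the origin between the last run's end and the first's start
        fs, fe = merged[0]
        ls, le = merged[-1]
        if fs + n - le <= gap:
            merged = merged[1:-1] + [(ls, n + fe)]
    if circular and len(merged) == 1 and merged[0][1] - merged[0][0] > n:
        merged = [(merged[0][0] % n, merged[0][0] % n + n)]
    return merged


def derive_interval_predictions(
    profile: MatchProfile, params: Parameters
) -> list[IntervalPrediction]:
    """Turn the match profile into per-reference interval predictions.

    For each (genome, gene, strand) vote key, maximal runs of covered
    positions are emitted; runs separated by a gap of at most ``gap_bridge``
    nt are bridged. Intergenic votes are never emitted.
    """
    gap = params.effective_gap_bridge
    out: list[IntervalPrediction] = []
    for (genome, gene, kind, strand), mask in sorted(
        profile.coverage.items(), key=lambda kv: kv[0]
    ):
        if gene == INTERGENIC:
            continue
        for s, e in _bridge(_runs(mask, profile.circular), gap, profile.length, profile.circular):
            out.append(IntervalPrediction(gene, genome, s, e, strand, kind))
    return out


def filter_by_prediction_count(
    preds: Sequence[IntervalPrediction], prediction_count: int
) -> list[IntervalPrediction]:
    """Drop genes predicted by fewer than `prediction_count` distinct genomes."""
    genomes_per_gene: dict[str, set[str]] = {}
    for p in preds:
        genomes_per_gene.setdefault(p.gene_name, set()).add(p.genome_label)
    return [
        p for p in preds if len(genomes_per_gene[p.gene_name]) >= prediction_count
    ]


def _positions(p: IntervalPrediction, n: int) -> frozenset[int]:
    return frozenset(q % n for q in range(p.start, p.end))


def _jaccard_distance(a: frozenset[int], b: frozenset[int]) -> float:
    union = len(a | b)
    return 1.0 - (len(a & b) / union if union else 0.0)


def _lower_median(values: Sequence[int]) -> int:
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def cluster_and_select(
    preds: Sequence[IntervalPrediction],
    params: Parameters,
    length: int,
) -> list[PredictionCluster]:
    """Cluster each gene's predictions and select by relative frequency.

    Average-linkage agglomerative clustering on d(a, b) = 1 − positional
    Jaccard overlap; the dendrogram is cut at ``cluster_cut``. A cluster is
    selected when its relative frequency (members / total predictions of the
    gene) is at least alpha × the gene's maximum relative frequency. The
    consensus interval is the member-wise lower-median start and end; strand
    by majority, ties to '+'.
    """
    by_gene: dict[str, list[IntervalPrediction]] = {}
    for p in preds:
        by_gene.setdefault(p.gene_name, []).append(p)

    selected: list[PredictionCluster] = []
    for gene in sorted(by_gene):
        members = sorted(
            by_gene[gene], key=lambda p: (p.start, p.end, p.strand, p.genome_label)
        )
        total = len(members)
        if total == 1:
            assignment = [1]
        else:
            possets = [_positions(p, length) for p in members]
            dm = np.zeros((total, total))
            for i in range(total):
                for j in range(i + 1, total):
                    dm[i, j] = dm[j, i] = _jaccard_distance(possets[i], possets[j])
            link = linkage(squareform(dm, checks=False), method="average")
            assignment = fcluster(link, t=params.cluster_cut, criterion="distance")
        groups: dict[int, list[IntervalPrediction]] = {}
        for p, cid in zip(members, assignment):
            groups.setdefault(int(cid), []).append(p)
        max_size = max(len(g) for g in groups.values())
        for cid in sorted(groups):
            grp = groups[cid]
            if len(grp) + 1e-9 < params.alpha * max_size:
                continue
            starts = [p.start for p in grp]
            ends = [p.end for p in grp]
            plus = sum(1 for p in grp if p.strand == "+")
            strand = "+" if plus * 2 >= len(grp) else "-"
            kinds = sorted({p.kind for p in grp})
            kind = max(kinds, key=lambda k: sum(1 for p in grp if p.kind == k))
            selected.append(
                PredictionCluster(
                    gene_name=gene,
                    members=tuple(grp),
                    rel_freq=len(grp) / total,
                    consensus=(_lower_median(starts), _lower_median(ends), strand),
                    kind=kind,
                )
            )
    return selected


def annotate(
    sequence: str,
    index: KmerIndex,
    params: Parameters | None = None,
    taxonomy: TaxonomyTree | None = None,
    taxa_filter: tuple[Iterable, str] | None = None,
    code: GeneticCode | None = None,
    sequence_id: str = "input",
    window: int = DEFAULT_WINDOW,
) -> list[GenePrediction]:
    """Run the full annotation pipeline on one input sequence.

    Optional taxonomic filtering restricts the reference index before
    mapping; optional genetic code enables boundary correction afterwards.
    Output is sorted by start coordinate and deterministic for fixed inputs.
    """
    params = params or Parameters()
    if taxa_filter is not None:
        if taxonomy is None:
            raise AnnotationError("a taxonomic filter requires a taxonomy tree")
        taxa, mode = taxa_filter
        all_genomes = index.genomes
        kept = resolve_filter(taxonomy, taxa, mode, all_genomes)
        if not kept:
            raise EmptyReferenceSetError(
                "empty reference set after filtering: annotation cannot proceed"
            )
        index = restrict_index(index, kept)

    profile = map_input(sequence, index, params)
    interval_preds = derive_interval_predictions(profile, params)
    interval_preds = filter_by_prediction_count(interval_preds, params.prediction_count)
    clusters = cluster_and_select(interval_preds, params, len(sequence))

    preds = [
        GenePrediction(
            gene_name=c.gene_name,
            start=c.consensus[0],
            end=c.consensus[1],
            strand=c.consensus[2],
            kind=c.kind,
            support=len(c.members),
        )
        for c in clusters
    ]
    if not preds:
        logger.warning("%s: no gene predictions survived filtering", sequence_id)
        return []
    if code is not None:
        reports = correct_boundaries(
            sequence, preds, code, window=window, circular=params.circular
        )
        preds = [r.corrected for r in reports]
    return sorted(preds, key=lambda p: (p.start, p.end, p.gene_name))
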