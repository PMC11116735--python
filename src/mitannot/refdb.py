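"""Reference database: a (k+1)-mer occurrence index over annotated mitogenomes.

The annotation pipeline maps the input against a de Bruijn graph of annotated
reference mitogenomes; edges of that graph are (k+1)-mers. This module keeps
the functional equivalent of the graph: for every canonical (k+1)-mer (the
lexicographic minimum of the string and its reverse complement) the list of
its occurrences across the reference genomes, each occurrence carrying the
gene annotations overlapping its footprint. The number of distinct genomes
containing a (k+1)-mer is its edge weight (``genome_support``), which the
user thresholds at mapping time.

Defaults: k = 24, so edges are 25-mers — effectively unique within a ~16.5 kb
mitogenome yet shared across related species. Occurrences whose footprint
contains an ambiguous base (N) are excluded. With odd-length (k+1)-mers a
string can never equal its own reverse complement, so orientation is
unambiguous; for even lengths a self-complementary (k+1)-mer is recorded as
forward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from ._seq import revcomp

__all__ = [
    "ReferenceGenome",
    "GeneAnnotation",
    "Occurrence",
    "GeneLabel",
    "KmerIndex",
    "RefDBError",
    "DEFAULT_K",
    "INTERGENIC",
    "enumerate_kmers",
    "kmer_is_usable",
    "canonical",
    "build_index",
    "restrict_index",
    "save_index",
    "load_index",
]

logger = logging.getLogger(__name__)

DEFAULT_K = 24
INTERGENIC = "intergenic"
_STRICT = frozenset("ACGT")


class RefDBError(ValueError):
    """Invalid reference data or index operation."""


@dataclass(frozen=True)
class ReferenceGenome:
    label: str
    sequence: str
    circular: bool = True
    tax_id: int = 0

    def __post_init__(self) -> None:
        if not self.label:
            raise RefDBError("reference genome needs a non-empty label")
        if not self.sequence:
            raise RefDBError(f"{self.label}: empty sequence")
        bad = set(self.sequence) - frozenset("ACGTN")
        if bad:
            raise RefDBError(f"{self.label}: invalid characters {sorted(bad)}")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval on a reference genome, 0-based half-open.

    On circular genomes an origin-crossing gene has ``end > genome length``.
    """

    genome_label: str
    gene_name: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "protein"

    def __post_init__(self) -> None:
        if not self.gene_name:
            raise RefDBError(f"annotation on {self.genome_label}: empty gene name")
        if self.start < 0 or self.start >= self.end:
            raise RefDBError(
                f"{self.genome_label}/{self.gene_name}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise RefDBError(f"{self.genome_label}/{self.gene_name}: bad strand")


@dataclass(frozen=True)
class GeneLabel:
    """A gene annotation attached to one (k+1)-mer occurrence.

    ``lo``/``hi`` delimit (half-open, in footprint-relative offsets 0..k+1)
    the part of the occurrence's footprint the annotation actually covers, so
    mapping can transfer labels position-exactly onto the input.
    """

    gene_name: str
    kind: str
    strand: str
    lo: int
    hi: int


@dataclass(frozen=True)
class Occurrence:
    """One placement of a canonical (k+1)-mer in a reference genome.

    ``position`` is the forward-strand start of the footprint; ``forward`` is
    True when the genome's forward-strand (k+1)-mer equals the canonical
    form, False when it equals its reverse complement.
    """

    genome_label: str
    position: int
    forward: bool
    labels: tuple[GeneLabel, ...]


def kmer_is_usable(kmer: str) -> bool:
    """A k-mer is usable iff free of ambiguity codes."""
    return set(kmer) <= _STRICT


def canonical(kmer: str) -> tuple[str, bool]:
    """Canonical form (lexicographic min of kmer and revcomp) + forward flag."""
    rc = revcomp(kmer)
    return (kmer, True) if kmer <= rc else (rc, False)


def enumerate_kmers(sequence: str, length: int, circular: bool) -> list[tuple[int, str]]:
    """All (position, k-mer) pairs of a sequence.

    A circular sequence of length L yields exactly L occurrences (start
    positions 0..L-1, wrapping past the origin); a linear one yields
    L-length+1, or none when shorter than `length`. K-mers containing
    ambiguity codes are emitted too; filter with :func:`kmer_is_usable`.
    """
    if length < 1:
        raise RefDBError(f"k-mer length must be >= 1, got {length}")
    n = len(sequence)
    if circular:
        ext = sequence + sequence[: length - 1]
        return [(i, ext[i:i + length]) for i in range(n)]
    return [(i, sequence[i:i + length]) for i in range(n - length + 1)]


def _coverage_mask(a: GeneAnnotation, n: int, circular: bool) -> bytearray:
    """Byte mask over genome positions covered by the annotation (mod n)."""
    mask = bytearray(n)
    for p in range(a.start, a.end):
        if circular:
            mask[p % n] = 1
        elif 0 <= p < n:
            mask[p] = 1
    return mask


@dataclass
class KmerIndex:
    """Map from canonical (k+1)-mer to its reference occurrences."""

    k: int
    entries: dict[str, list[Occurrence]] = field(default_factory=dict)

    @property
    def edge_length(self) -> int:
        return self.k + 1

    def genome_support(self, kmer: str) -> int:
        """Edge weight: distinct genomes with >= 1 occurrence of the kmer."""
        occs = self.entries.get(kmer, ())
        return len({o.genome_label for o in occs})

    @property
    def genomes(self) -> set[str]:
        return {o.genome_label for occs in self.entries.values() for o in occs}

    @property
    def n_occurrences(self) -> int:
        return sum(len(v) for v in self.entries.values())

    def lookup(self, kmer: str) -> tuple[str, bool, list[Occurrence]]:
        """Canonicalize `kmer` and return (canonical, forward, occurrences)."""
        canon, fwd = canonical(kmer)
        return canon, fwd, self.entries.get(canon, [])


def _labels_for(
    masked: Sequence[tuple[GeneAnnotation, bytearray]],
    pos: int,
    edge_len: int,
    n: int,
    circular: bool,
) -> tuple[GeneLabel, ...]:
    """Annotations overlapping the footprint [pos, pos+edge_len), with the
    overlapping sub-range in footprint offsets."""
    labels: list[GeneLabel] = []
    for a, mask in masked:
        if circular:
            offs = [i for i in range(edge_len) if mask[(pos + i) % n]]
        else:
            offs = [i for i in range(edge_len) if pos + i < n and mask[pos + i]]
        if offs:
            labels.append(
                GeneLabel(a.gene_name, a.kind, a.strand, min(offs), max(offs) + 1)
            )
    if not labels:
        labels.append(GeneLabel(INTERGENIC, "other", "+", 0, edge_len))
    return tuple(sorted(labels, key=lambda l: (l.gene_name, l.lo)))


def build_index(
    genomes: Sequence[ReferenceGenome],
    annotations: Sequence[GeneAnnotation],
    k: int = DEFAULT_K,
) -> KmerIndex:
    """Index every usable (k+1)-mer occurrence of every reference genome.

    Both strands are served by canonical-form indexing with the occurrence's
    orientation recorded. Each occurrence carries the gene annotations whose
    interval overlaps its (k+1)-nt footprint (any overlap >= 1 nt assigns the
    label); footprints overlapping no annotation carry the reserved
    "intergenic" label. Occurrences spanning an N are skipped.
    """
    if k < 1:
        raise RefDBError(f"k must be >= 1, got {k}")
    labels_seen = [g.label for g in genomes]
    if len(set(labels_seen)) != len(labels_seen):
        dupes = sorted({l for l in labels_seen if labels_seen.count(l) > 1})
        raise RefDBError(f"duplicate genome labels: {dupes}")
    by_genome: dict[str, list[GeneAnnotation]] = {g.label: [] for g in genomes}
    for a in annotations:
        if a.genome_label not in by_genome:
            raise RefDBError(
                f"annotation {a.gene_name!r} references unknown genome "
                f"{a.genome_label!r}"
            )
        by_genome[a.genome_label].append(a)

    edge_len = k + 1
    index = KmerIndex(k=k)
    for g in genomes:
        n = len(g.sequence)
        if not g.circular and n < edge_len:
            logger.warning(
                "genome %s (length %d) shorter than %d-mers; contributes nothing",
                g.label, n, edge_len,
            )
            continue
        masked = [
            (a, _coverage_mask(a, n, g.circular)) for a in by_genome[g.label]
        ]
        for pos, kmer in enumerate_kmers(g.sequence, edge_len, g.circular):
            if not kmer_is_usable(kmer):
                continue
            canon, fwd = canonical(kmer)
            occ = Occurrence(
                genome_label=g.label,
                position=pos,
                forward=fwd,
                labels=_labels_for(masked, pos, edge_len, n, g.circular),
            )
            index.entries.setdefault(canon, []).append(occ)
    return index


def restrict_index(index: KmerIndex, genome_set: Iterable[str]) -> KmerIndex:
    """Keep only occurrences from `genome_set`; drop emptied (k+1)-mers."""
    keep = set(genome_set)
    if not keep:
        raise RefDBError("cannot restrict index to an empty genome set")
    out = KmerIndex(k=index.k)
    for kmer, occs in index.entries.items():
        kept = [o for o in occs if o.genome_label in keep]
        if kept:
            out.entries[kmer] = kept
    return out


# -- persistence: sorted, versioned TSV for bit-exact diffing ---------------

_FORMAT = "mitannot-kmer-index"
_VERSION = 1


def save_index(index: KmerIndex, path: str | Path) -> None:
    """Write the index as a sorted TSV: kmer, genome, position, strand, labels."""
    lines = [f"#{_FORMAT}\tv{_VERSION}\tk={index.k}"]
    rows = []
    for kmer, occs in index.entries.items():
        for o in occs:
            lab = ";".join(
                f"{l.gene_name}:{l.kind}:{l.strand}:{l.lo}:{l.hi}" for l in o.labels
            )
            rows.append((kmer, o.genome_label, o.position, "+" if o.forward else "-", lab))
    rows.sort()
    lines += ["\t".join(map(str, r)) for r in rows]
    Path(path).write_text("\n".join(lines) + "\n")


def load_index(path: str | Path) -> KmerIndex:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith(f"#{_FORMAT}"):
        raise RefDBError(f"{path}: not a {_FORMAT} file")
    header = lines[0].split("\t")
    k = int(header[2].removeprefix("k="))
    index = KmerIndex(k=k)
    for line in lines[1:]:
        if not line.strip():
            continue
        kmer, genome, pos, strand, lab = line.split("\t")
        labels = tuple(
            GeneLabel(p[0], p[1], p[2], int(p[3]), int(p[4]))
            for p in (item.split(":") for item in lab.split(";"))
        )
        index.entries.setdefault(kmer, []).append(
            Occurrence(genome, int(pos), strand == "+", labels)
        )
    return index
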