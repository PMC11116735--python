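"""Synthetic data: taxonomies, annotated mitogenome families, perturbations.

Everything the pipeline consumes can be generated here, reproducibly from a
seed: a random rooted taxonomy with names and synonyms, a family of
annotated circular mitogenome-like sequences diverged from one ancestor by
point substitutions along the tree's branches, and boundary-perturbed
annotations whose true shifts are recorded as a test oracle.

The substitution-only model keeps annotation coordinates exact ground truth
(no indels), which the identity and recall checks rely on. The ancestor's
protein genes begin with a start codon and end with a stop codon of the
chosen translation table, so codon precision is exactly 1.0 at substitution
rate 0. Genome length defaults to 16,500 nt, the average length of a
complete metazoan mitogenome; the default gene complement mirrors the 13
protein-coding genes plus rRNAs/tRNAs of a typical animal mitogenome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._seq import revcomp
from .boundary import DEFAULT_WINDOW
from .genetic_code import GeneticCode, get_genetic_code
from .refdb import GeneAnnotation, ReferenceGenome
from .taxonomy import TaxonNode, TaxonomyTree

__all__ = [
    "SimulationSpec",
    "SimulationError",
    "simulate_taxonomy",
    "simulate_genome_family",
    "perturb_boundaries",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# Canonical metazoan mitochondrial protein gene names, used in order.
_PROTEIN_NAMES = [
    "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
    "cox1", "cox2", "cox3", "atp6", "atp8", "cob",
]
_SYLLABLES = [
    "ba", "ce", "di", "fo", "ga", "hy", "ka", "lo", "mi", "nu",
    "pe", "ra", "so", "tu", "ve", "xa", "zo",
]


class SimulationError(ValueError):
    """Impossible simulation specification."""


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions for one synthetic data set.

    ``substitution_rate`` is the per-site substitution probability along each
    tree edge (and one private round per genome). ``perturbation_max`` bounds
    boundary shifts and must not exceed the correction window.
    """

    seed: int = 0
    n_taxa: int = 15
    n_genomes: int = 8
    genome_length: int = 16_500
    n_protein_genes: int = 13
    n_rna_genes: int = 2
    substitution_rate: float = 0.01
    perturbation_max: int = 6
    table_id: int = 2

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise SimulationError("need at least 2 taxa")
        if min(self.n_genomes, self.genome_length, self.n_protein_genes) < 1:
            raise SimulationError("counts and lengths must be positive")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise SimulationError("substitution rate must be in [0, 1)")
        if not 0 <= self.perturbation_max <= DEFAULT_WINDOW:
            raise SimulationError(
                f"perturbation max must be in [0, {DEFAULT_WINDOW}]"
            )


def _rng(spec: SimulationSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def _random_name(rng: np.random.Generator, taken: set[str]) -> str:
    while True:
        genus = "".join(rng.choice(_SYLLABLES, size=3)).capitalize()
        species = "".join(rng.choice(_SYLLABLES, size=3))
        name = f"{genus} {species}"
        if name not in taken:
            taken.add(name)
            return name


def simulate_taxonomy(spec: SimulationSpec) -> TaxonomyTree:
    """Random rooted taxonomy with unique names, synonyms and common names.

    Node ids are 1..n_taxa with 1 the root; every non-root node's parent is
    drawn uniformly among earlier ids, so ids increase with depth.
    """
    rng = _rng(spec, 0)
    taken: set[str] = set()
    nodes: dict[int, TaxonNode] = {}
    for tid in range(1, spec.n_taxa + 1):
        parent = 1 if tid == 1 else int(rng.integers(1, tid))
        node = TaxonNode(
            tax_id=tid,
            parent_id=parent,
            rank="no rank" if tid == 1 else "clade",
            scientific_name=_random_name(rng, taken),
        )
        if tid % 3 == 0:
            node.synonyms.append(_random_name(rng, taken))
        if tid % 4 == 0:
            node.common_name = _random_name(rng, taken)
        nodes[tid] = node
    return TaxonomyTree(nodes=nodes, root_id=1)


def _gene_plan(spec: SimulationSpec, rng: np.random.Generator):
    """Names, lengths, strands and kinds of the ancestral gene complement."""
    names, lengths, kinds = [], [], []
    for i in range(spec.n_protein_genes):
        name = _PROTEIN_NAMES[i] if i < len(_PROTEIN_NAMES) else f"orf{i + 1}"
        names.append(name)
        # multiples of 3 in [300, 900]: long enough that the two boundary
        # windows of one gene can never interact
        lengths.append(int(rng.integers(100, 301)) * 3)
        kinds.append("protein")
    for j in range(spec.n_rna_genes):
        if j == 0:
            names.append("rrnS")
            lengths.append(int(rng.integers(700, 1001)))
            kinds.append("rrna")
        else:
            names.append(f"trn{chr(ord('A') + j - 1)}")
            lengths.append(int(rng.integers(65, 76)))
            kinds.append("trna")
    strands = ["+" if rng.random() < 0.7 else "-" for _ in names]
    return names, lengths, strands, kinds


def _mutate(seq_arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0.0:
        return seq_arr.copy()
    out = seq_arr.copy()
    hits = np.flatnonzero(rng.random(len(out)) < rate)
    for p in hits:
        choices = _BASES[_BASES != out[p]]
        out[p] = rng.choice(choices)
    return out


def simulate_genome_family(
    spec: SimulationSpec, tree: TaxonomyTree
) -> tuple[list[ReferenceGenome], list[GeneAnnotation], list[GeneAnnotation]]:
    """Evolve a family of annotated circular genomes along the taxonomy.

    One ancestral genome with non-overlapping genes is placed at the root;
    every taxon's sequence evolves from its parent's by point substitutions
    at the branch rate, and each genome (assigned to a random leaf, labels
    attached to the tree) receives one further private round. Annotation
    coordinates are identical across the family. Returns
    ``(genomes, annotations, truth)`` where `truth` records every gene's
    true interval per genome.
    """
    rng = _rng(spec, 1)
    code = get_genetic_code(spec.table_id)
    names, lengths, strands, kinds = _gene_plan(spec, rng)

    min_gap = 20
    needed = sum(lengths) + min_gap * (len(names) + 1)
    if needed > spec.genome_length:
        raise SimulationError(
            f"genes need {needed} nt but genome length is {spec.genome_length}"
        )

    # ancestral sequence
    anc = rng.choice(_BASES, size=spec.genome_length)

    # place genes left to right with random gaps
    slack = spec.genome_length - sum(lengths) - min_gap * (len(names) + 1)
    extra = rng.multinomial(slack, np.full(len(names) + 1, 1 / (len(names) + 1)))
    gene_templates: list[GeneAnnotation] = []
    pos = 0
    for i, (name, glen, strand, kind) in enumerate(zip(names, lengths, strands, kinds)):
        pos += min_gap + int(extra[i])
        start, end = pos, pos + glen
        gene_templates.append(GeneAnnotation("", name, start, end, strand, kind))
        pos = end

    def _write_codon(arr: np.ndarray, at: int, codon: str, strand: str) -> None:
        c = codon if strand == "+" else revcomp(codon)
        arr[at:at + 3] = np.frombuffer(c.encode(), dtype="S1")

    start_codons = sorted(code.start_codons)
    stop_codons = sorted(code.stop_codons)
    for g in gene_templates:
        if g.kind != "protein":
            continue
        start_codon = start_codons[int(rng.integers(len(start_codons)))]
        stop_codon = stop_codons[int(rng.integers(len(stop_codons)))]
        if g.strand == "+":
            _write_codon(anc, g.start, start_codon, "+")
            _write_codon(anc, g.end - 3, stop_codon, "+")
        else:
            _write_codon(anc, g.end - 3, start_codon, "-")
            _write_codon(anc, g.start, stop_codon, "-")

    # evolve one sequence per taxon, parent before child (ids increase with depth)
    taxon_seq: dict[int, np.ndarray] = {tree.root_id: anc}
    for tid in sorted(tree.nodes):
        if tid == tree.root_id:
            continue
        parent_seq = taxon_seq[tree.nodes[tid].parent_id]
        taxon_seq[tid] = _mutate(parent_seq, spec.substitution_rate, rng)

    leaves = sorted(t for t, kids in tree.children.items() if not kids)
    genomes: list[ReferenceGenome] = []
    annotations: list[GeneAnnotation] = []
    truth: list[GeneAnnotation] = []
    for i in range(spec.n_genomes):
        label = f"MG{i + 1:06d}"
        tid = int(rng.choice(leaves))
        seq = _mutate(taxon_seq[tid], spec.substitution_rate, rng)
        genomes.append(
            ReferenceGenome(
                label=label, sequence=seq.tobytes().decode(), circular=True, tax_id=tid
            )
        )
        tree.nodes[tid].genome_labels.append(label)
        for g in gene_templates:
            row = GeneAnnotation(label, g.gene_name, g.start, g.end, g.strand, g.kind)
            annotations.append(row)
            truth.append(row)
    return genomes, annotations, truth


# -- boundary perturbation --------------------------------------------------

def _codon(seq: str, pos: int) -> str:
    n = len(seq)
    pos %= n
    return seq[pos:pos + 3] if pos + 3 <= n else seq[pos:] + seq[: pos + 3 - n]


def _recoverable(
    reading: str,
    anchor: int,
    shift: int,
    wanted: frozenset[str],
    blocking: frozenset[str],
    window: int,
) -> bool:
    """Would the window search from ``anchor + shift`` land back on ``anchor``?

    Conservative, independent check of the correction rules: the original
    codon must be valid; no other valid codon may lie at an offset of equal
    or smaller magnitude from the perturbed position; and no opposite-set
    codon may sit at an offset >= the original's (which would bar it).
    """
    if _codon(reading, anchor) not in wanted:
        return False
    back = -shift  # offset of the original anchor, seen from the perturbed one
    perturbed = anchor + shift
    for d in range(-window, window + 1):
        c = _codon(reading, perturbed + d)
        if d != back and abs(d) <= abs(back) and c in wanted:
            return False
        if d >= back and c in blocking:
            return False
    return True


def perturb_boundaries(
    annotations: Sequence[GeneAnnotation],
    genomes: Sequence[ReferenceGenome],
    spec: SimulationSpec,
) -> tuple[list[GeneAnnotation], list[dict]]:
    """Shift protein-gene boundaries by recoverable random offsets.

    Each protein boundary is moved by a uniform signed offset of magnitude
    1..perturbation_max, skipping offsets that would leave an ambiguous
    window (another valid codon at least as close, or an opposite-set codon
    barring the original). The returned shift records (reading-direction
    offsets, one dict per annotation) are the oracle: correction must undo
    them exactly. With perturbation_max = 0 this is the identity.
    """
    rng = _rng(spec, 2)
    code = get_genetic_code(spec.table_id)
    seq_of = {g.label: g.sequence for g in genomes}
    window = DEFAULT_WINDOW

    perturbed: list[GeneAnnotation] = []
    records: list[dict] = []
    for a in annotations:
        if a.kind != "protein":
            perturbed.append(a)
            records.append({"genome": a.genome_label, "gene": a.gene_name,
                            "start_shift": 0, "stop_shift": 0})
            continue
        seq = seq_of[a.genome_label]
        n = len(seq)
        reading = seq if a.strand == "+" else revcomp(seq)
        length = a.end - a.start
        r_start = a.start if a.strand == "+" else (n - a.end) % n
        r_end = r_start + length

        def _draw(anchor: int, wanted, blocking) -> int:
            offsets = [d for m in range(1, spec.perturbation_max + 1) for d in (m, -m)]
            order = rng.permutation(len(offsets))
            for idx in order:
                d = offsets[int(idx)]
                if _recoverable(reading, anchor, d, wanted, blocking, window):
                    return d
            return 0

        ds = _draw(r_start, code.start_codons, code.stop_codons) if spec.perturbation_max else 0
        de = _draw(r_end - 3, code.stop_codons, code.start_codons) if spec.perturbation_max else 0

        new_r_start, new_r_end = r_start + ds, r_end + de
        if a.strand == "+":
            f_start, f_end = new_r_start, new_r_end
        else:
            f_start = (n - new_r_end) % n
            f_end = f_start + (new_r_end - new_r_start)
        perturbed.append(
            GeneAnnotation(a.genome_label, a.gene_name, f_start, f_end, a.strand, a.kind)
        )
        records.append({"genome": a.genome_label, "gene": a.gene_name,
                        "start_shift": ds, "stop_shift": de})
    return perturbed, records
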