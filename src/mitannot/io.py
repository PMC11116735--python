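"""Readers and writers: FASTA, GFF3, BED, correction reports, taxdump.

All writers are deterministic — identical inputs give byte-identical files —
and everything written here can be re-read losslessly by the matching reader.
GFF3 is the primary output (1-based inclusive coordinates); BED (0-based
half-open) is the secondary twin. A gene crossing the origin of a circular
genome is written as two parts sharing an ID (GFF3) or name (BED).
"""

from __future__ import annotations

import io as _io
import zipfile
from pathlib import Path
from typing import Sequence

from Bio import SeqIO

from .boundary import CorrectionReport, GenePrediction
from .refdb import GeneAnnotation
from .taxonomy import TaxonomyTree

__all__ = [
    "FastaError",
    "read_fasta",
    "write_fasta",
    "write_gff",
    "read_gff",
    "write_bed",
    "read_bed",
    "write_report",
    "read_report",
    "write_taxdump",
    "write_genome_map",
    "annotations_to_predictions",
    "predictions_to_annotations",
    "zip_directory",
]

_IUPAC = frozenset("ACGTUNRYSWKMBDHV")
_SOURCE = "mitannot"


class FastaError(ValueError):
    """Malformed FASTA / sequence text."""


def _clean_sequence(raw: str, first_line_no: int) -> str:
    out: list[str] = []
    for off, line in enumerate(raw.splitlines()):
        stripped = "".join(line.split())
        bad = set(stripped.upper()) - _IUPAC
        if bad:
            raise FastaError(
                f"line {first_line_no + off}: invalid nucleotide characters "
                f"{''.join(sorted(bad))!r}"
            )
        out.append(stripped.upper().replace("U", "T"))
    return "".join(out)


def read_fasta(source: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records, or bare pasted sequence text, as (id, sequence).

    Accepts a path to a FASTA file or the text itself. Text without a ``>``
    header — the paste-box case — yields a single record with a generated
    id. Sequences are uppercased with U replaced by T; characters outside
    the IUPAC nucleotide alphabet raise with the offending line number.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).is_file()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    if not text.strip():
        raise FastaError("empty input: no sequence found")

    if not text.lstrip().startswith(">"):
        return [("pasted_sequence", _clean_sequence(text, 1))]

    # Use Biopython for record structure (ids); validate characters from the
    # raw text ourselves so errors can carry true line numbers.
    records = list(SeqIO.parse(_io.StringIO(text), "fasta"))
    if not records:
        raise FastaError("no FASTA records found")
    sequences: list[str] = []
    for no, line in enumerate(text.splitlines(), start=1):
        if line.lstrip().startswith(">"):
            sequences.append("")
        elif sequences:
            sequences[-1] += _clean_sequence(line, no)
    out = []
    for rec, seq in zip(records, sequences):
        if not seq:
            raise FastaError(f"record {rec.id!r}: empty sequence")
        out.append((rec.id, seq))
    return out


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    lines = []
    for rid, seq in records:
        lines.append(f">{rid}")
        lines.extend(seq[i:i + width] for i in range(0, len(seq), width))
    Path(path).write_text("\n".join(lines) + "\n")


# -- GFF3 -------------------------------------------------------------------

_KIND_TO_TYPE = {"protein": "gene", "trna": "tRNA", "rrna": "rRNA", "other": "region"}
_TYPE_TO_KIND = {v: k for k, v in _KIND_TO_TYPE.items()}


def write_gff(
    preds: Sequence[GenePrediction],
    sequence_id: str,
    length: int,
    circular: bool,
    path: str | Path,
) -> None:
    """Write predictions as GFF3 (1-based inclusive coordinates).

    Origin-crossing genes on a circular sequence (end > length) are split
    into two feature lines sharing an ID.
    """
    lines = ["##gff-version 3", f"##sequence-region {sequence_id} 1 {length}"]
    circ = "true" if circular else "false"
    lines.append(
        f"{sequence_id}\t{_SOURCE}\tregion\t1\t{length}\t.\t+\t.\t"
        f"ID=region:{sequence_id};Is_circular={circ}"
    )
    for i, p in enumerate(preds):
        ftype = _KIND_TO_TYPE[p.kind]
        attrs = f"ID=gene{i}:{p.gene_name};Name={p.gene_name};gene_kind={p.kind};support={p.support}"
        if p.end <= length:
            parts = [(p.start + 1, p.end)]
        else:
            parts = [(p.start + 1, length), (1, p.end - length)]
        for a, b in parts:
            lines.append(
                f"{sequence_id}\t{_SOURCE}\t{ftype}\t{a}\t{b}\t.\t{p.strand}\t.\t{attrs}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff(path: str | Path) -> tuple[str, int, bool, list[GenePrediction]]:
    """Read back a GFF3 file written by :func:`write_gff`."""
    sequence_id, length, circular = "", 0, False
    rows: dict[str, dict] = {}
    order: list[str] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            if line.startswith("##sequence-region"):
                _, sequence_id, _, length_s = line.split()
                length = int(length_s)
            continue
        seqid, _src, ftype, a, b, _score, strand, _frame, attr_s = line.split("\t")
        attrs = dict(kv.split("=", 1) for kv in attr_s.split(";"))
        if ftype == "region" and attrs.get("ID", "").startswith("region:"):
            circular = attrs.get("Is_circular") == "true"
            continue
        fid = attrs["ID"]
        row = rows.get(fid)
        if row is None:
            rows[fid] = {
                "name": attrs["Name"],
                "kind": attrs.get("gene_kind", _TYPE_TO_KIND.get(ftype, "other")),
                "support": int(attrs.get("support", 0)),
                "strand": strand,
                "parts": [],
            }
            order.append(fid)
        rows[fid]["parts"].append((int(a) - 1, int(b)))
    preds = []
    for fid in order:
        row = rows[fid]
        parts = row["parts"]
        if len(parts) == 1:
            start, end = parts[0]
        else:  # wrapped gene: head part runs to the sequence end
            head = next(p for p in parts if p[1] == length)
            tail = next(p for p in parts if p[0] == 0)
            start, end = head[0], length + tail[1]
        preds.append(
            GenePrediction(
                gene_name=row["name"], start=start, end=end,
                strand=row["strand"], kind=row["kind"], support=row["support"],
            )
        )
    return sequence_id, length, circular, preds


# -- BED --------------------------------------------------------------------

def write_bed(
    preds: Sequence[GenePrediction],
    sequence_id: str,
    length: int,
    path: str | Path,
) -> None:
    """BED6+1 twin of the GFF3 output (0-based half-open; col 7 = kind)."""
    lines = []
    for p in preds:
        if p.end <= length:
            parts = [(p.start, p.end)]
        else:
            parts = [(p.start, length), (0, p.end - length)]
        for a, b in parts:
            lines.append(
                f"{sequence_id}\t{a}\t{b}\t{p.gene_name}\t{p.support}\t{p.strand}\t{p.kind}"
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bed(
    path: str | Path, length: int | None = None, circular: bool = False
) -> list[GenePrediction]:
    """Read a BED file written by :func:`write_bed` (or plain BED4/6).

    With ``circular`` and ``length`` given, a pair of lines sharing a name
    where one ends at `length` and the other starts at 0 is reassembled into
    a single wrapped prediction.
    """
    raw: list[dict] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        raw.append(
            {
                "start": int(f[1]), "end": int(f[2]),
                "name": f[3] if len(f) > 3 else "feature",
                "support": int(f[4]) if len(f) > 4 and f[4] != "." else 0,
                "strand": f[5] if len(f) > 5 else "+",
                "kind": f[6] if len(f) > 6 else "other",
            }
        )
    if circular and length is not None:
        merged: list[dict] = []
        used = [False] * len(raw)
        for i, head in enumerate(raw):
            if used[i] or head["end"] != length:
                continue
            for j, tail in enumerate(raw):
                if j == i or used[j]:
                    continue
                if (
                    tail["start"] == 0
                    and tail["name"] == head["name"]
                    and tail["strand"] == head["strand"]
                ):
                    head = dict(head, end=length + tail["end"])
                    used[i] = used[j] = True
                    merged.append(head)
                    break
        raw = [r for i, r in enumerate(raw) if not used[i]] + merged
    return [
        GenePrediction(
            gene_name=r["name"], start=r["start"], end=r["end"],
            strand=r["strand"], kind=r["kind"], support=r["support"],
        )
        for r in raw
    ]


# -- reference annotation files (multi-genome BED / GFF3) -------------------

def read_annotation_file(path: str | Path) -> list[GeneAnnotation]:
    """Read reference gene annotations from BED (0-based half-open) or GFF3.

    The first column (BED) / seqid (GFF3) names the reference genome. GFF3
    coordinates are converted to 0-based half-open; the feature type maps to
    the gene kind and the Name attribute (or ID) to the gene name.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        out = []
        for line in path.read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            seqid, _src, ftype, a, b, _score, strand, _frame, attr_s = line.split("\t")
            if ftype == "region":
                continue
            attrs = dict(kv.split("=", 1) for kv in attr_s.split(";") if "=" in kv)
            name = attrs.get("Name") or attrs.get("ID") or ftype
            kind = attrs.get("gene_kind", _TYPE_TO_KIND.get(ftype, "other"))
            out.append(GeneAnnotation(seqid, name, int(a) - 1, int(b), strand, kind))
        return out
    out = []
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        out.append(
            GeneAnnotation(
                genome_label=f[0],
                gene_name=f[3] if len(f) > 3 else "feature",
                start=int(f[1]),
                end=int(f[2]),
                strand=f[5] if len(f) > 5 else "+",
                kind=f[6] if len(f) > 6 else "other",
            )
        )
    return out


def write_annotation_bed(annos: Sequence[GeneAnnotation], path: str | Path) -> None:
    """Write reference annotations as BED6+1 (col 7 = kind)."""
    lines = [
        f"{a.genome_label}\t{a.start}\t{a.end}\t{a.gene_name}\t0\t{a.strand}\t{a.kind}"
        for a in annos
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# -- correction report ------------------------------------------------------

_REPORT_HEADER = (
    "gene_name\tkind\tstrand\toriginal_start\toriginal_end\t"
    "corrected_start\tcorrected_end\tstart_shift\tstop_shift\tstart_hit\tstop_hit"
)


def write_report(reports: Sequence[CorrectionReport], path: str | Path) -> None:
    lines = [_REPORT_HEADER]
    for r in reports:
        p, c = r.original, r.corrected
        lines.append(
            f"{p.gene_name}\t{p.kind}\t{p.strand}\t{p.start}\t{p.end}\t"
            f"{c.start}\t{c.end}\t{r.start_shift}\t{r.stop_shift}\t"
            f"{int(r.start_hit)}\t{int(r.stop_hit)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_report(path: str | Path) -> list[CorrectionReport]:
    lines = Path(path).read_text().splitlines()
    out = []
    for line in lines[1:]:
        (name, kind, strand, os_, oe, cs, ce, sshift, eshift, shit, ehit) = line.split("\t")
        orig = GenePrediction(name, int(os_), int(oe), strand, kind)
        corr = GenePrediction(name, int(cs), int(ce), strand, kind)
        out.append(
            CorrectionReport(orig, corr, int(sshift), int(eshift), bool(int(shit)), bool(int(ehit)))
        )
    return out


# -- taxonomy dumps ---------------------------------------------------------

def write_taxdump(tree: TaxonomyTree, nodes_path: str | Path, names_path: str | Path) -> None:
    """Write the tree in the NCBI taxdump dialect (nodes.dmp / names.dmp)."""
    nodes_lines = []
    names_lines = []
    for tid in sorted(tree.nodes):
        n = tree.nodes[tid]
        nodes_lines.append(f"{tid}\t|\t{n.parent_id}\t|\t{n.rank}\t|")
        names_lines.append(f"{tid}\t|\t{n.scientific_name}\t|\t\t|\tscientific name\t|")
        for syn in n.synonyms:
            names_lines.append(f"{tid}\t|\t{syn}\t|\t\t|\tsynonym\t|")
        if n.common_name:
            names_lines.append(f"{tid}\t|\t{n.common_name}\t|\t\t|\tcommon name\t|")
    Path(nodes_path).write_text("\n".join(nodes_lines) + "\n")
    Path(names_path).write_text("\n".join(names_lines) + "\n")


def write_genome_map(tree: TaxonomyTree, path: str | Path) -> None:
    """2-column TSV: genome label, tax_id."""
    rows = []
    for tid in sorted(tree.nodes):
        for label in tree.nodes[tid].genome_labels:
            rows.append(f"{label}\t{tid}")
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


# -- annotation <-> prediction adapters ------------------------------------

def annotations_to_predictions(annos: Sequence[GeneAnnotation]) -> list[GenePrediction]:
    return [
        GenePrediction(a.gene_name, a.start, a.end, a.strand, a.kind, 0) for a in annos
    ]


def predictions_to_annotations(
    preds: Sequence[GenePrediction], genome_label: str
) -> list[GeneAnnotation]:
    return [
        GeneAnnotation(genome_label, p.gene_name, p.start, p.end, p.strand, p.kind)
        for p in preds
    ]


def zip_directory(directory: str | Path, zip_path: str | Path) -> None:
    """Package an output directory as a zip archive."""
    directory = Path(directory)
    with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_DEFLATED) as zf:
        for p in sorted(directory.rglob("*")):
            if p.is_file():
                zf.write(p, p.relative_to(directory))
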