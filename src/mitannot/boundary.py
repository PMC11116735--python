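"""Gene-boundary correction against a genetic code.

Protein-gene predictions derived from reference mapping are often a few
nucleotides off at their ends: the first codon of the predicted interval is
not an initiation codon, or the last codon is not a termination codon. Given
the input genome's translation table, each boundary is re-examined within a
window of at most 6 nt in each direction and moved to the nearest position
whose codon belongs to the appropriate codon set.

The search rules, in the gene's reading direction:

* If the boundary codon is already valid, the boundary is kept (hit).
* Otherwise candidate positions at signed offsets 1..window in both
  directions are examined; the candidate with the smallest |offset| whose
  codon is valid wins. At equal distance the offset that extends the gene
  wins (upstream for a start, downstream for a stop); this tie-break is
  configurable.
* If a codon of the *opposite* set occurs anywhere in the examined region —
  a stop codon while searching for a start, a start codon while searching
  for a stop — the search is restricted to the region strictly downstream
  of the most downstream such codon. Extending a gene's start upstream past
  a stop codon would place a terminator inside the reading frame.

Candidates are read at every nucleotide offset, not frame-locked, because a
mis-predicted boundary may itself be out of frame. Start and stop move
independently; the corrected length need not stay a multiple of three.

Coordinates are 0-based half-open on the forward strand. On circular
sequences the window may cross the origin and intervals may wrap (end >
sequence length); positions are reduced modulo the length on access.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

from .genetic_code import GeneticCode
from ._seq import revcomp

__all__ = [
    "GenePrediction",
    "CorrectionReport",
    "BoundaryError",
    "correct_start",
    "correct_stop",
    "correct_boundaries",
    "codon_precision",
    "DEFAULT_WINDOW",
]

DEFAULT_WINDOW = 6

Kind = Literal["protein", "trna", "rrna", "other"]
Tie = Literal["extend", "shrink"]


class BoundaryError(ValueError):
    """Validation failure in boundary correction."""


@dataclass(frozen=True)
class GenePrediction:
    """A predicted gene interval on the input sequence.

    ``start``/``end`` are 0-based half-open forward-strand coordinates. On a
    circular sequence an origin-crossing gene is represented with
    ``end > sequence length``.
    """

    gene_name: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "protein"
    support: int = 0

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise BoundaryError(
                f"{self.gene_name}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise BoundaryError(f"{self.gene_name}: invalid strand {self.strand!r}")
        if self.kind not in ("protein", "trna", "rrna", "other"):
            raise BoundaryError(f"{self.gene_name}: invalid kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CorrectionReport:
    """Outcome of correcting one prediction.

    Shifts are signed nucleotide offsets in the gene's reading direction
    (positive = downstream). ``start_hit``/``stop_hit`` record whether the
    respective boundary codon is valid after correction.
    """

    original: GenePrediction
    corrected: GenePrediction
    start_shift: int
    stop_shift: int
    start_hit: bool
    stop_hit: bool


def _codon_at(seq: str, pos: int, circular: bool) -> str | None:
    """Codon starting at `pos` of `seq`; None if out of bounds (linear)."""
    n = len(seq)
    if circular:
        pos %= n
        if pos + 3 <= n:
            return seq[pos:pos + 3]
        return seq[pos:] + seq[: pos + 3 - n]
    if pos < 0 or pos + 3 > n:
        return None
    return seq[pos:pos + 3]


def _candidate_offsets(window: int, tie: Tie, extend_sign: int) -> list[int]:
    """Offsets 1..window in both directions, ordered by |offset|; at equal
    distance the extending direction first (or shrinking, per `tie`)."""
    first = extend_sign if tie == "extend" else -extend_sign
    out: list[int] = []
    for d in range(1, window + 1):
        out.append(first * d)
        out.append(-first * d)
    return out


def _scan(
    reading_seq: str,
    anchor: int,
    wanted: frozenset[str],
    blocking: frozenset[str],
    window: int,
    circular: bool,
    tie: Tie,
    extend_sign: int,
) -> tuple[int, bool]:
    """Shared boundary scan in reading coordinates.

    `anchor` is the position of the codon under test (its first base). Returns
    (new codon position, hit flag). Implements the minimal-|offset| search
    with the opposite-set restriction described in the module docstring.
    """
    codon = _codon_at(reading_seq, anchor, circular)
    if codon is not None and codon in wanted:
        return anchor, True

    # Most downstream opposite-set codon in the examined region restricts the
    # search to offsets strictly downstream of it.
    barrier: int | None = None
    for d in range(-window, window + 1):
        c = _codon_at(reading_seq, anchor + d, circular)
        if c is not None and c in blocking:
            barrier = d
    for d in _candidate_offsets(window, tie, extend_sign):
        if barrier is not None and d <= barrier:
            continue
        c = _codon_at(reading_seq, anchor + d, circular)
        if c is not None and c in wanted:
            return anchor + d, True
    return anchor, False


def _reading_interval(pred: GenePrediction, n: int) -> tuple[int, int]:
    """Map the forward-strand interval into reading-strand coordinates.

    For '+' this is the interval itself; for '-' the gene read on the
    reverse complement occupies [n - end, n - start) (taken modulo n for
    wrapped intervals, preserving length).
    """
    if pred.strand == "+":
        return pred.start, pred.end
    length = pred.end - pred.start
    start = (n - pred.end) % n
    return start, start + length


def _to_forward(pred: GenePrediction, r_start: int, r_end: int, n: int) -> tuple[int, int]:
    """Inverse of `_reading_interval`; normalizes so 0 <= start < n <= end or end <= n."""
    length = r_end - r_start
    if pred.strand == "+":
        f_start = r_start % n
    else:
        f_start = (n - r_end) % n
    return f_start, f_start + length


def _validate(sequence: str, pred: GenePrediction, window: int) -> None:
    if len(sequence) < 3:
        raise BoundaryError(f"{pred.gene_name}: sequence shorter than one codon")
    if window < 0:
        raise BoundaryError(f"{pred.gene_name}: negative window {window}")
    if pred.length < 3:
        raise BoundaryError(
            f"{pred.gene_name}: protein prediction shorter than one codon"
        )


def correct_start(
    sequence: str,
    pred: GenePrediction,
    code: GeneticCode,
    window: int = DEFAULT_WINDOW,
    circular: bool = True,
    tie: Tie = "extend",
) -> tuple[int, bool]:
    """Re-examine the 5' boundary of a protein prediction.

    Returns ``(boundary, hit)`` where `boundary` is the corrected interval
    edge in forward-strand coordinates: the new ``start`` for a plus-strand
    gene, the new ``end`` for a minus-strand gene (whose translational start
    sits at the interval's right edge). `hit` is True when the returned
    boundary's codon is an initiation codon of `code`.
    """
    _validate(sequence, pred, window)
    n = len(sequence)
    reading = sequence if pred.strand == "+" else revcomp(sequence)
    r_start, r_end = _reading_interval(pred, n)
    new_r, hit = _scan(
        reading, r_start, code.start_codons, code.stop_codons,
        window, circular, tie, extend_sign=-1,
    )
    f_start, f_end = _to_forward(pred, new_r, r_end, n)
    return (f_start, hit) if pred.strand == "+" else (f_end, hit)


def correct_stop(
    sequence: str,
    pred: GenePrediction,
    code: GeneticCode,
    window: int = DEFAULT_WINDOW,
    circular: bool = True,
    tie: Tie = "extend",
) -> tuple[int, bool]:
    """Re-examine the 3' boundary; mirror of :func:`correct_start`.

    Returns the new ``end`` for a plus-strand gene, the new ``start`` for a
    minus-strand gene. The codon under test is the final codon of the
    interval in reading direction; start codons found in the window restrict
    the search downstream.
    """
    _validate(sequence, pred, window)
    n = len(sequence)
    reading = sequence if pred.strand == "+" else revcomp(sequence)
    r_start, r_end = _reading_interval(pred, n)
    anchor = r_end - 3
    new_anchor, hit = _scan(
        reading, anchor, code.stop_codons, code.start_codons,
        window, circular, tie, extend_sign=+1,
    )
    new_r_end = new_anchor + 3
    f_start, f_end = _to_forward(pred, r_start, new_r_end, n)
    return (f_end, hit) if pred.strand == "+" else (f_start, hit)


def _correct_one(
    sequence: str,
    pred: GenePrediction,
    code: GeneticCode,
    window: int,
    circular: bool,
    tie: Tie,
) -> CorrectionReport:
    if pred.kind != "protein":
        return CorrectionReport(pred, pred, 0, 0, False, False)
    n = len(sequence)
    reading = sequence if pred.strand == "+" else revcomp(sequence)
    r_start, r_end = _reading_interval(pred, n)
    new_r_start, start_hit = _scan(
        reading, r_start, code.start_codons, code.stop_codons,
        window, circular, tie, extend_sign=-1,
    )
    new_anchor, stop_hit = _scan(
        reading, r_end - 3, code.stop_codons, code.start_codons,
        window, circular, tie, extend_sign=+1,
    )
    new_r_end = new_anchor + 3
    start_shift = new_r_start - r_start
    stop_shift = new_r_end - r_end
    if new_r_end - new_r_start < 3:  # degenerate: shifts collapsed the gene
        return CorrectionReport(pred, pred, 0, 0, False, False)
    f_start, f_end = _to_forward(pred, new_r_start, new_r_end, n)
    corrected = replace(pred, start=f_start, end=f_end)
    return CorrectionReport(pred, corrected, start_shift, stop_shift, start_hit, stop_hit)


def correct_boundaries(
    sequence: str,
    preds: Sequence[GenePrediction],
    code: GeneticCode,
    window: int = DEFAULT_WINDOW,
    circular: bool = True,
    tie: Tie = "extend",
) -> list[CorrectionReport]:
    """Correct both boundaries of every protein prediction.

    Non-protein predictions pass through unchanged with zero shifts.
    Minus-strand genes are corrected on the reverse complement with
    coordinates mapped back. Validation errors carry the offending gene name.
    """
    reports = []
    for pred in preds:
        try:
            reports.append(_correct_one(sequence, pred, code, window, circular, tie))
        except BoundaryError:
            raise
        except ValueError as exc:  # pragma: no cover - defensive
            raise BoundaryError(f"{pred.gene_name}: {exc}") from exc
    return reports


def codon_precision(
    sequence: str,
    preds: Sequence[GenePrediction],
    code: GeneticCode,
    circular: bool = True,
) -> tuple[float, float]:
    """Proportion of protein predictions with valid boundary codons.

    Returns ``(start_precision, stop_precision)``: the fraction of protein
    predictions whose first codon (reading direction) is an initiation codon,
    and whose final codon is a termination codon. This is the evaluation
    metric used to quantify the effect of boundary correction.
    """
    proteins = [p for p in preds if p.kind == "protein"]
    if not proteins:
        raise BoundaryError("no protein predictions: codon precision undefined")
    n = len(sequence)
    start_ok = stop_ok = 0
    for p in proteins:
        reading = sequence if p.strand == "+" else revcomp(sequence)
        r_start, r_end = _reading_interval(p, n)
        first = _codon_at(reading, r_start, circular)
        last = _codon_at(reading, r_end - 3, circular)
        if first is not None and first in code.start_codons:
            start_ok += 1
        if last is not None and last in code.stop_codons:
            stop_ok += 1
    return start_ok / len(proteins), stop_ok / len(proteins)
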