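"""NCBI translation tables: start/stop codon membership.

Gene-boundary correction needs to know, for a given NCBI-numbered genetic
code, which trinucleotides act as initiation codons and which as termination
codons. The mitochondrially relevant tables (2, 3, 4, 5, 9, 13, 14) plus the
standard code (1) are shipped as static data transcribed from the NCBI
genetic-code standard; nothing is fetched at runtime.

Sequences are handled in the DNA alphabet (T, not U).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

__all__ = [
    "Codon",
    "GeneticCode",
    "UnknownTranslationTableError",
    "InvalidCodonError",
    "get_genetic_code",
    "supported_tables",
    "classify_codon",
]

# Strict codon alphabet; IUPAC ambiguity codes are tolerated by classify_codon
# (they classify as "neither") but never appear inside a codon set.
_STRICT = frozenset("ACGT")
_IUPAC = frozenset("ACGTUNRYSWKMBDHV")


class UnknownTranslationTableError(KeyError):
    """Raised for a table_id with no NCBI translation table behind it."""


class InvalidCodonError(ValueError):
    """Raised for a codon that is not 3 IUPAC nucleotide letters."""


@dataclass(frozen=True)
class Codon:
    """A trinucleotide over {A,C,G,T}, uppercase, no ambiguity codes."""

    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) != 3 or not set(self.seq) <= _STRICT:
            raise InvalidCodonError(
                f"not a valid codon: {self.seq!r} (need 3 characters over A/C/G/T)"
            )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.seq


@dataclass(frozen=True)
class GeneticCode:
    """One NCBI translation table, reduced to its start/stop codon sets."""

    table_id: int
    name: str
    start_codons: frozenset[str] = field(repr=False)
    stop_codons: frozenset[str] = field(repr=False)

    def __post_init__(self) -> None:
        if not self.start_codons or not self.stop_codons:
            raise ValueError(f"table {self.table_id}: empty codon set")
        for c in self.start_codons | self.stop_codons:
            Codon(c)  # validates

    def is_start(self, codon: str) -> bool:
        return codon in self.start_codons

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons


def _normalize(codon) -> str:
    seq = codon.seq if isinstance(codon, Codon) else str(codon)
    seq = seq.upper().replace("U", "T")
    if len(seq) != 3 or not set(seq) <= _IUPAC:
        raise InvalidCodonError(
            f"malformed codon {seq!r}: need 3 IUPAC nucleotide letters"
        )
    return seq


@lru_cache(maxsize=1)
def _load_tables() -> dict[int, GeneticCode]:
    tables: dict[int, GeneticCode] = {}
    text = resources.files("mitannot.data").joinpath("codon_tables.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tid_s, name, starts, stops = re.split(r"\t", line)
        tid = int(tid_s)
        tables[tid] = GeneticCode(
            table_id=tid,
            name=name,
            start_codons=frozenset(starts.split(",")),
            stop_codons=frozenset(stops.split(",")),
        )
    return tables


def supported_tables() -> tuple[int, ...]:
    """NCBI table numbers this package ships."""
    return tuple(sorted(_load_tables()))


def get_genetic_code(table_id: int) -> GeneticCode:
    """Look up an NCBI translation table by number.

    Raises
    ------
    UnknownTranslationTableError
        If `table_id` is not among the shipped tables.
    """
    try:
        return _load_tables()[int(table_id)]
    except (KeyError, ValueError, TypeError):
        raise UnknownTranslationTableError(
            f"unknown translation table: {table_id!r} "
            f"(supported: {', '.join(map(str, supported_tables()))})"
        ) from None


def classify_codon(code: GeneticCode, codon) -> str:
    """Classify a codon as ``start``, ``stop``, ``both`` or ``neither``.

    Ambiguity codes (N, R, ...) make a codon classify as ``neither``: a codon
    with unknown bases must never trigger a boundary shift. Malformed input
    (wrong length, non-IUPAC letters) raises :class:`InvalidCodonError`.
    """
    seq = _normalize(codon)
    if not set(seq) <= _STRICT:
        return "neither"
    is_start = seq in code.start_codons
    is_stop = seq in code.stop_codons
    if is_start and is_stop:
        return "both"
    if is_start:
        return "start"
    if is_stop:
        return "stop"
    return "neither"
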