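"""Small nucleotide-string helpers shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
                            "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb")


def revcomp(seq: str) -> str:
    """Reverse complement in the DNA alphabet (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def circular_slice(seq: str, start: int, length: int) -> str:
    """Substring of a circular sequence, wrapping past the origin.

    `start` may be any integer; it is reduced modulo len(seq).
    """
    n = len(seq)
    start %= n
    end = start + length
    if end <= n:
        return seq[start:end]
    return seq[start:] + seq[: end - n] if length <= n else (seq * (end // n + 1))[start:start + length]
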