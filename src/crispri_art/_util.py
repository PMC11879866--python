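"""Small shared sequence helpers."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = set("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str, limit: int | None = None) -> int:
    """Hamming distance between equal-length strings.

    With ``limit`` set, returns ``limit + 1`` as soon as the distance
    exceeds it (early exit for scanning loops).
    """
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if limit is not None and d > limit:
                return d
    return d


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return sum(1 for c in seq if c in "GCgc") / len(seq)
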