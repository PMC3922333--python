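"""Small DNA helpers shared across the pipeline.

Sequences are plain upper-case strings over {A, C, G, T, N}; all coordinates
are 0-based, half-open.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DNA_ALPHABET = frozenset("ACGTN")
UNAMBIGUOUS = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of an {A,C,G,T,N} string."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str, allow_n: bool = True) -> bool:
    alphabet = DNA_ALPHABET if allow_n else UNAMBIGUOUS
    return all(c in alphabet for c in seq)


def hamming(a: str, b: str, limit: int | None = None) -> int:
    """Hamming distance between equal-length strings.

    With ``limit`` set, counting stops once the distance exceeds it and
    ``limit + 1`` is returned (early exit for index verification).
    """
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    d = 0
    if limit is None:
        for x, y in zip(a, b):
            if x != y:
                d += 1
        return d
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


def mismatch_positions(a: str, b: str) -> list[int]:
    return [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
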