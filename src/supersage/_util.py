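"""Small shared helpers: sequence alphabet checks, reverse complement, rounding."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DNA_ALPHABET = frozenset("ACGT")
DNA_ALPHABET_N = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, allow_n: bool = True) -> str:
    """Uppercase-normalize *seq* and reject characters outside the DNA alphabet.

    Raises ValueError naming the first offending position.
    """
    seq = seq.upper()
    alphabet = DNA_ALPHABET_N if allow_n else DNA_ALPHABET
    for i, base in enumerate(seq):
        if base not in alphabet:
            raise ValueError(f"invalid base {base!r} at position {i}")
    return seq


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (e.g. 18.05 -> 18.1), unlike banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
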