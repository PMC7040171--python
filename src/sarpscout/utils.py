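"""Small shared helpers (rounding, DNA alphabet, reverse complement)."""

from __future__ import annotations

import math

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero for positive x.

    All user-facing percentages go through this so that printed census and
    cluster-similarity values are reproducible to the integer.
    """
    return int(math.floor(x + 0.5))


def percent(numerator: float, denominator: float) -> int:
    """Integer percentage numerator/denominator, round-half-up."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator)


def normalize_dna(seq: str, ambiguity: str = "normalize") -> str:
    """Upper-case a DNA string; handle non-ACGTN ambiguity codes.

    ambiguity="normalize" replaces any IUPAC ambiguity code other than N
    (and any other letter) with N; ambiguity="strict" raises ValueError.
    Soft-masked (lower-case) bases are upper-cased either way.
    """
    seq = seq.upper()
    if set(seq) <= DNA_ALPHABET:
        return seq
    if ambiguity == "strict":
        bad = sorted(set(seq) - DNA_ALPHABET)
        raise ValueError(f"non-ACGTN characters in sequence: {bad}")
    return "".join(c if c in DNA_ALPHABET else "N" for c in seq)
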