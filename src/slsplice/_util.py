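"""Shared helpers: reverse complement, IUPAC codes, report rounding."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC ambiguity codes for non-empty subsets of {A, C, G, T}.
IUPAC_CODES = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AC"): "M",
    frozenset("AG"): "R",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
    frozenset("ACG"): "V",
    frozenset("ACT"): "H",
    frozenset("AGT"): "D",
    frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N, case kept)."""
    return seq.translate(_COMP)[::-1]


def iupac_code(bases) -> str:
    """IUPAC one-letter code for a set of bases; 'N' for empty input."""
    key = frozenset(b.upper() for b in bases)
    if not key:
        return "N"
    return IUPAC_CODES[key]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero, as printed reports do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(num: float, den: float, ndigits: int = 2) -> float:
    """Percentage num/den*100, half-up rounded; NaN when den == 0."""
    if den == 0:
        return float("nan")
    return round_half_up(100.0 * num / den, ndigits)
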