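"""Nucleotide alphabet primitives: IUPAC ambiguity codes and strand operations.

The consensus machinery represents every alignment column as a set of bases; the
IUPAC single-letter codes are the canonical bijection between the 15 non-empty
subsets of {A, C, G, T} and one-character symbols.  Strict homology compares
symbols for identity; non-strict homology asks whether two symbols' base sets
intersect (a concrete T "under" a W = {A, T} site counts as homologous).
"""

from __future__ import annotations

BASES: tuple[str, ...] = ("A", "C", "G", "T")
GAP = "-"

IUPAC_TO_SET: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

SET_TO_IUPAC: dict[frozenset[str], str] = {s: c for c, s in IUPAC_TO_SET.items()}

IUPAC_ALPHABET: frozenset[str] = frozenset(IUPAC_TO_SET)

# 4-bit masks (A=1, C=2, G=4, T=8) for fast set-intersection tests.
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
IUPAC_MASK: dict[str, int] = {
    sym: sum(_BASE_BIT[b] for b in bases) for sym, bases in IUPAC_TO_SET.items()
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRWSMKVHDBN-")


def iupac_code(bases) -> str:
    """Return the IUPAC symbol for a non-empty subset of {A, C, G, T}."""
    key = frozenset(bases)
    if not key:
        raise ValueError("cannot encode an empty base set")
    try:
        return SET_TO_IUPAC[key]
    except KeyError:
        bad = sorted(key - frozenset(BASES))
        raise ValueError(f"not a subset of ACGT: {bad}") from None


def iupac_set(symbol: str) -> frozenset[str]:
    """Return the base set of an IUPAC symbol."""
    try:
        return IUPAC_TO_SET[symbol]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide symbol: {symbol!r}") from None


def symbols_compatible(x: str, y: str) -> bool:
    """True iff the base sets of two IUPAC symbols intersect.

    A gap is compatible with nothing (including another gap).
    """
    if x == GAP or y == GAP:
        return False
    try:
        return (IUPAC_MASK[x] & IUPAC_MASK[y]) != 0
    except KeyError:
        bad = x if x not in IUPAC_MASK else y
        raise ValueError(f"not an IUPAC nucleotide symbol: {bad!r}") from None


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string (IUPAC symbols and gaps allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]
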