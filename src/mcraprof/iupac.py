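"""IUPAC nucleotide codes: degenerate-base matching, complements, normalization.

Degenerate primers (e.g. ``TAYGAYCARATHTGGYT``) use single-letter ambiguity
codes, each standing for a set of bases. Matching a primer against a read
means testing set membership position by position.
"""

from __future__ import annotations

# 15-letter IUPAC nucleotide alphabet (T==U after normalization).
IUPAC_SETS: dict[str, frozenset[str]] = {
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

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# 4-bit masks (A=1, C=2, G=4, T=8); two codes are compatible iff masks intersect.
IUPAC_MASKS: dict[str, int] = {
    code: sum({"A": 1, "C": 2, "G": 4, "T": 8}[b] for b in bases)
    for code, bases in IUPAC_SETS.items()
}


def normalize(seq: str) -> str:
    """Uppercase and map RNA U to T. Raises on characters outside IUPAC DNA."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - set(IUPAC_SETS)
    if bad:
        raise ValueError(f"non-IUPAC nucleotide character(s): {sorted(bad)!r}")
    return s


def iupac_match(pattern_base: str, base: str) -> bool:
    """True iff ``base`` is in the allowed set of the IUPAC code ``pattern_base``."""
    try:
        allowed = IUPAC_SETS[pattern_base.upper()]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide code: {pattern_base!r}") from None
    b = base.upper()
    if b not in IUPAC_SETS:
        raise ValueError(f"not an IUPAC nucleotide code: {base!r}")
    return b in allowed


def revcomp(seq: str) -> str:
    """Reverse complement, preserving ambiguity codes (R<->Y, M<->K, ...)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]
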