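"""IUPAC nucleotide alphabet utilities shared across the package.

Each IUPAC code is represented internally as a 4-bit mask over {A, C, G, T},
so that "two codes can pair a common base" is a single bitwise AND. The gap
character ``-`` carries an empty mask and never matches anything.
"""

from __future__ import annotations

import numpy as np

#: base -> bitmask (A=1, C=2, G=4, T=8)
_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}

#: every accepted IUPAC DNA code, mapped to the set of bases it denotes
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_MASK: dict[str, int] = {
    code: sum(_BASE_BITS[b] for b in bases) for code, bases in IUPAC_SETS.items()
}
IUPAC_MASK["-"] = 0

ALPHABET = frozenset(IUPAC_MASK)
UNAMBIGUOUS = frozenset("ACGT")
GAP = "-"

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")

#: 256-entry lookup: byte value of a residue -> its IUPAC mask (0 if invalid)
MASK_TABLE = np.zeros(256, dtype=np.uint8)
for _code, _mask in IUPAC_MASK.items():
    MASK_TABLE[ord(_code)] = _mask


def normalize(seq: str) -> str:
    """Upper-case a sequence and convert legacy ``.`` gaps to ``-``."""
    return seq.upper().replace(".", GAP)


def validate(seq: str, *, allow_gaps: bool = True, context: str = "sequence") -> None:
    """Raise :class:`AlphabetError` at the first character outside the alphabet."""
    allowed = ALPHABET if allow_gaps else ALPHABET - {GAP}
    for i, ch in enumerate(seq):
        if ch not in allowed:
            raise AlphabetError(
                f"{context}: invalid character {ch!r} at position {i + 1}"
            )


def reverse_complement(seq: str) -> str:
    """Reverse complement honouring IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def complements(a: str, b: str) -> bool:
    """True iff codes *a* and *b* can form a Watson-Crick pair.

    Strict Watson-Crick: G.T wobbles never count. Ambiguity codes pair if
    any base in one set complements any base in the other, i.e. the mask of
    *a* intersects the complemented mask of *b*.
    """
    return bool(IUPAC_MASK[a] & IUPAC_MASK[b.translate(_COMPLEMENT)])


def matches(a: str, b: str, *, iupac: bool = True) -> bool:
    """True iff code *a* is compatible with code *b* on the same strand.

    With ``iupac`` on, compatibility is non-empty base-set intersection;
    with it off, only identical unambiguous bases match.
    """
    if iupac:
        return bool(IUPAC_MASK[a] & IUPAC_MASK[b])
    return a == b and a in UNAMBIGUOUS


class AlphabetError(ValueError):
    """A sequence contains a character outside the IUPAC DNA alphabet."""
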