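"""Shared nucleotide-sequence primitives: IUPAC alphabet, normalization, reverse complement.

All sequences in this package are plain upper-case Python strings over the IUPAC
nucleotide alphabet, held in the forward orientation of whatever record they came
from. ``U`` is normalized to ``T`` on ingest.
"""

from __future__ import annotations

# IUPAC nucleotide codes mapped to the set of unambiguous bases they stand for.
IUPAC_BASES: dict[str, frozenset[str]] = {
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

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)


class AlphabetError(ValueError):
    """A sequence contains a character outside the IUPAC nucleotide alphabet."""


def normalize(sequence: str, *, name: str | None = None) -> str:
    """Upper-case a sequence, map U->T, strip gaps/whitespace, validate the alphabet.

    Raises :class:`AlphabetError` naming the offending character (and record,
    when ``name`` is given).
    """
    seq = sequence.upper().replace("U", "T")
    seq = "".join(seq.split()).replace("-", "").replace(".", "")
    for ch in seq:
        if ch not in IUPAC_BASES:
            where = f" in record {name!r}" if name else ""
            raise AlphabetError(f"non-IUPAC nucleotide character {ch!r}{where}")
    return seq


def revcomp(sequence: str) -> str:
    """IUPAC-aware reverse complement. Involution: ``revcomp(revcomp(x)) == x``."""
    for ch in sequence:
        if ch.upper() not in IUPAC_BASES:
            raise AlphabetError(f"non-IUPAC nucleotide character {ch!r}")
    return sequence.upper().translate(_COMPLEMENT)[::-1]


def iupac_match(a: str, b: str) -> bool:
    """Whether two IUPAC codes are compatible (their base sets intersect)."""
    return not IUPAC_BASES[a].isdisjoint(IUPAC_BASES[b])
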