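"""In-silico PCR: primer binding-site search and predicted amplicon extraction.

Binding sites are found by sliding the primer along both strands with
IUPAC-aware base matching: a position matches when the primer code's base set
intersects the template code's base set. Products are formed for every
inward-facing forward/reverse site combination on opposite strands, up to a
maximum product length. Coordinates are 0-based half-open on the template's
forward strand throughout; the product length convention includes both primer
footprints.

The two primer pairs used for *L. helveticus* strain typing are provided as
constants: LHSLP_PAIR targets the *slpH* locus (1,116 bp on the CNRZ32
reference) and PHES_PAIR the *L. gallinarum* pheS species assay (180 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .seqs import IUPAC_BASES, iupac_match, normalize, revcomp

__all__ = [
    "Primer",
    "PrimerPair",
    "BindingSite",
    "Amplicon",
    "AmpliconLengthRange",
    "find_binding_sites",
    "simulate_pcr",
    "amplicon_length_range",
    "specificity_screen",
    "LHSLP_PAIR",
    "PHES_PAIR",
]

MIN_PRIMER_LEN = 10


@dataclass(frozen=True)
class Primer:
    """A PCR primer, written 5'->3'; IUPAC ambiguity codes allowed."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize(self.sequence, name=self.name))
        if len(self.sequence) < MIN_PRIMER_LEN:
            raise ValueError(f"primer {self.name!r} shorter than {MIN_PRIMER_LEN} nt")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse primer pair with product and matching constraints.

    ``three_prime_exact`` bases at each primer's 3' end must match with zero
    mismatches even when ``max_mismatches`` > 0 (extension-blocking rule).
    """

    forward: Primer
    reverse: Primer
    max_product_len: int = 3000
    max_mismatches: int = 0
    three_prime_exact: int = 3

    def __post_init__(self) -> None:
        if self.max_product_len <= len(self.forward) + len(self.reverse):
            raise ValueError("max_product_len must exceed the combined primer lengths")


@dataclass(frozen=True)
class BindingSite:
    """A primer binding site on the template's forward-strand coordinates."""

    start: int
    end: int
    strand: str  # '+' : primer anneals to the minus strand, extends rightwards
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product.

    ``sequence`` is oriented to begin with the forward primer's footprint;
    ``orientation`` is '+' when the forward primer sits on the template's
    forward strand, '-' when the product comes off the reverse strand.
    """

    template_id: str
    start: int
    end: int
    orientation: str
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


def _mismatches_at(template: str, primer: str, offset: int, limit: int,
                   tp_exact_idx: Sequence[int]) -> int | None:
    """Mismatch count of `primer` laid on `template[offset:]`, or None if rejected."""
    n = 0
    for k, pch in enumerate(primer):
        tch = template[offset + k]
        if tch not in IUPAC_BASES or not iupac_match(pch, tch):
            if k in tp_exact_idx:
                return None
            n += 1
            if n > limit:
                return None
    return n


def find_binding_sites(template: str, primer: Primer | str,
                       max_mismatches: int = 0,
                       three_prime_exact: int = 3) -> list[BindingSite]:
    """All binding sites of a primer on both strands of a template.

    A site on '+' means the primer sequence (5'->3') matches the forward
    strand left-to-right and would extend rightwards; on '-' the primer
    matches the reverse strand and would extend leftwards. The 3'-terminal
    ``three_prime_exact`` bases must match exactly.
    """
    template = normalize(template)
    pseq = primer.sequence if isinstance(primer, Primer) else normalize(primer)
    L = len(pseq)
    if L > len(template):
        return []
    sites: list[BindingSite] = []
    # '+' strand: primer as written; 3' end is the last bases.
    tp_plus = set(range(L - three_prime_exact, L))
    # '-' strand: search with revcomp(primer); primer 3' end maps to the first bases.
    rc = revcomp(pseq)
    tp_minus = set(range(three_prime_exact))
    for offset in range(len(template) - L + 1):
        m = _mismatches_at(template, pseq, offset, max_mismatches, tp_plus)
        if m is not None:
            sites.append(BindingSite(offset, offset + L, "+", m))
        m = _mismatches_at(template, rc, offset, max_mismatches, tp_minus)
        if m is not None:
            sites.append(BindingSite(offset, offset + L, "-", m))
    return sites


def simulate_pcr(template: str, pair: PrimerPair,
                 template_id: str = "template") -> list[Amplicon]:
    """Predict all PCR products of a primer pair on one template.

    A product arises from a forward-primer site and a reverse-primer site on
    opposite strands, facing inwards, with length (including both primer
    footprints) at most ``pair.max_product_len``. No products is an empty
    list, not an error.
    """
    template = normalize(template)
    fwd = find_binding_sites(template, pair.forward, pair.max_mismatches,
                             pair.three_prime_exact)
    rev = find_binding_sites(template, pair.reverse, pair.max_mismatches,
                             pair.three_prime_exact)
    out: list[Amplicon] = []
    # forward primer on '+', reverse primer on '-', reverse site to the right
    for f in (s for s in fwd if s.strand == "+"):
        for r in (s for s in rev if s.strand == "-"):
            if r.start >= f.start and r.end - f.start <= pair.max_product_len:
                out.append(Amplicon(template_id, f.start, r.end, "+",
                                    template[f.start:r.end]))
    # mirrored: forward primer on '-', reverse primer on '+', product off the
    # reverse strand; oriented sequence starts with the forward footprint
    for f in (s for s in fwd if s.strand == "-"):
        for r in (s for s in rev if s.strand == "+"):
            if f.end >= r.end and f.end - r.start <= pair.max_product_len:
                out.append(Amplicon(template_id, r.start, f.end, "-",
                                    revcomp(template[r.start:f.end])))
    out.sort(key=lambda a: (a.start, a.end, a.orientation))
    return out


@dataclass
class AmpliconLengthRange:
    """Product-length range over templates yielding exactly one product."""

    min_length: int | None
    max_length: int | None
    single_product: dict[str, int] = field(default_factory=dict)
    no_product: list[str] = field(default_factory=list)
    multi_product: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return self.min_length is None


def amplicon_length_range(templates: Iterable[tuple[str, str]],
                          pair: PrimerPair) -> AmpliconLengthRange:
    """(min, max) product length over all templates with exactly one product.

    Templates yielding zero or multiple products are listed separately; if no
    template yields a single product the range is explicitly empty.
    """
    single: dict[str, int] = {}
    none_: list[str] = []
    multi: list[str] = []
    for name, seq in templates:
        prods = simulate_pcr(seq, pair, template_id=name)
        if not prods:
            none_.append(name)
        elif len(prods) == 1:
            single[name] = prods[0].length
        else:
            multi.append(name)
    if not single:
        return AmpliconLengthRange(None, None, {}, none_, multi)
    lengths = single.values()
    return AmpliconLengthRange(min(lengths), max(lengths), single, none_, multi)


def specificity_screen(panel: Iterable[tuple[str, str]],
                       pair: PrimerPair) -> pd.DataFrame:
    """Presence/absence table of predicted products over a labeled template panel.

    Mirrors a wet-lab specificity table: a template is '+' iff it yields at
    least one product within the pair's length cap. Columns: template_id,
    amplified ('+'/'-'), n_products, product_lengths (comma-joined, '.' if none).
    """
    rows = []
    for name, seq in panel:
        prods = simulate_pcr(seq, pair, template_id=name)
        rows.append({
            "template_id": name,
            "amplified": "+" if prods else "-",
            "n_products": len(prods),
            "product_lengths": ",".join(str(p.length) for p in prods) or ".",
        })
    if not rows:
        raise ValueError("specificity_screen needs a non-empty panel")
    return pd.DataFrame(rows)


# Published primer pairs -----------------------------------------------------

#: slpH typing pair; amplifies 1,116 bp on the L. helveticus CNRZ32 reference.
LHSLP_PAIR = PrimerPair(
    forward=Primer("LHslpF", "CAAGGAGGAAAGACCACATGA"),
    reverse=Primer("LHslpR", "TGTACTTGCCAGTTGCCTTG"),
)

#: L. gallinarum pheS species assay; amplifies a 180-bp fragment.
PHES_PAIR = PrimerPair(
    forward=Primer("LgallpheSF", "TCAGGACCTTGTACTACCTTGTAA"),
    reverse=Primer("LgallpheSR", "TGCTACTAAGGCTGAAATCGT"),
)
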