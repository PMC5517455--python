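"""Group-specific identifying subsequences ("markers") and read classification.

A marker is a short k-mer that occurs (in forward orientation) in every member
of one *slpH* group's reference alleles and occurs — in either orientation —
in no member of any other group. Because sequencing reads come off both
strands, a marker set is kept closed under reverse complement: every marker is
stored with its reverse-complement mate, and which of the two forms hits a
read tells the read's orientation as well as its group.

The twelve published markers (four strings per group: two forward forms and
their reverse complements) are available via :func:`published_markers`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .seqs import normalize, revcomp

__all__ = [
    "MarkerSet",
    "ScanResult",
    "published_markers",
    "discover_markers",
    "scan_read",
    "MarkerDiscoveryError",
]


class MarkerDiscoveryError(ValueError):
    """No discriminative k-mer exists for a group within the allowed k range."""


@dataclass(frozen=True)
class ScanResult:
    """Classification of one read: group + orientation, ambiguous, or unclassified."""

    status: str  # 'classified' | 'ambiguous' | 'unclassified'
    group: str | None = None
    orientation: str | None = None  # 'forward' | 'reverse'
    position: int | None = None  # 0-based offset of the leftmost marker hit


class MarkerSet:
    """Per-group marker strings, closed under reverse complement.

    ``pairs`` maps group label -> tuple of (forward_form, reverse_form)
    marker pairs. Construction verifies closure by building the reverse
    forms itself and rejects any marker that occurs (in either orientation)
    in another group's set.
    """

    def __init__(self, forward_markers: Mapping[str, Iterable[str]]):
        self.pairs: dict[str, tuple[tuple[str, str], ...]] = {}
        for group, fwd_list in forward_markers.items():
            pairs = tuple((normalize(m), revcomp(normalize(m))) for m in fwd_list)
            if not pairs:
                raise ValueError(f"group {group!r} has no markers")
            self.pairs[group] = pairs
        self._check_exclusive()

    def _check_exclusive(self) -> None:
        seen: dict[str, str] = {}
        for group, pairs in self.pairs.items():
            for f, r in pairs:
                for form in (f, r):
                    owner = seen.get(form)
                    if owner is not None and owner != group:
                        raise ValueError(
                            f"marker {form!r} occurs in groups {owner!r} and {group!r}")
                    seen[form] = group

    @property
    def groups(self) -> list[str]:
        return sorted(self.pairs)

    def all_strings(self, group: str) -> tuple[str, ...]:
        """Both orientations of every marker of one group (the 4-string sets)."""
        out: list[str] = []
        for f, r in self.pairs[group]:
            out.append(f)
            if r != f:  # palindromic markers contribute one string
                out.append(r)
        return tuple(out)

    def verify_closure(self) -> bool:
        """Closure under reverse complement holds by construction; re-check anyway."""
        for group in self.pairs:
            strings = set(self.all_strings(group))
            if any(revcomp(s) not in strings for s in strings):
                return False
        return True

    def verify_against_db(self, db) -> None:
        """Check the discriminative property on a reference database.

        Every group's forward markers must occur in all of that group's
        member sequences, and neither orientation may occur in any member of
        a different group. Raises ValueError on the first violation.
        """
        for group, pairs in self.pairs.items():
            members = db.group_members(group)
            if not members:
                raise ValueError(f"database has no members of group {group!r}")
            for f, _ in pairs:
                for rec in members:
                    if f not in rec.sequence:
                        raise ValueError(
                            f"marker {f!r} absent from {rec.st_id} of its own group {group!r}")
            for rec in db.records:
                if rec.group_id == group:
                    continue
                for f, r in pairs:
                    if f in rec.sequence or r in rec.sequence:
                        raise ValueError(
                            f"marker {f!r}/{r!r} of group {group!r} occurs in "
                            f"{rec.st_id} (group {rec.group_id!r})")

    # -- serialization: TSV with columns group, marker, orientation_tag -----

    def to_tsv(self) -> str:
        lines = ["group\tmarker\torientation_tag"]
        for group in self.groups:
            for f, r in self.pairs[group]:
                lines.append(f"{group}\t{f}\tforward")
                lines.append(f"{group}\t{r}\treverse")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "MarkerSet":
        fwd: dict[str, list[str]] = {}
        lines = [ln for ln in text.splitlines() if ln.strip()]
        header = lines[0].split("\t")
        if header[:2] != ["group", "marker"]:
            raise ValueError("marker TSV must have columns group, marker, orientation_tag")
        for ln in lines[1:]:
            group, marker, tag = ln.split("\t")
            if tag == "forward":
                fwd.setdefault(group, []).append(marker)
        return cls(fwd)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_tsv())

    @classmethod
    def load(cls, path: str | Path) -> "MarkerSet":
        return cls.from_tsv(Path(path).read_text())


def published_markers() -> MarkerSet:
    """The twelve published *slpH* group markers (four strings per group)."""
    return MarkerSet({
        "group1": ["GGCTACACT", "GATCAATTAA"],
        "group2": ["CCTTAATGTA", "CTGACGATGT"],
        "group3": ["ATTGGTTCAG", "GGTGTTGCTA"],
    })


def discover_markers(db, k_min: int = 8, k_max: int = 12) -> MarkerSet:
    """Find one discriminative k-mer per group by exhaustive screening.

    For each group, the smallest k in [k_min, k_max] admitting at least one
    k-mer that occurs (forward orientation) in every member of the group and
    whose forward and reverse-complement forms occur in no member of any
    other group is used. Tie-break: the lexicographically smallest such
    k-mer. Raises :class:`MarkerDiscoveryError` naming the group when no k
    works.
    """
    groups = db.group_labels()
    if len(groups) < 2:
        raise MarkerDiscoveryError("marker discovery needs at least 2 groups")
    chosen: dict[str, list[str]] = {}
    for group in groups:
        members = [r.sequence for r in db.group_members(group)]
        others = [r.sequence for r in db.records if r.group_id != group]
        marker = None
        for k in range(k_min, k_max + 1):
            shared: set[str] | None = None
            for seq in members:
                kmers = {seq[i:i + k] for i in range(len(seq) - k + 1)}
                shared = kmers if shared is None else shared & kmers
                if not shared:
                    break
            if not shared:
                continue
            def exclusive(m: str) -> bool:
                rc = revcomp(m)
                return not any(m in o or rc in o for o in others)
            candidates = sorted(m for m in shared if exclusive(m))
            if candidates:
                marker = candidates[0]
                break
        if marker is None:
            raise MarkerDiscoveryError(
                f"no discriminative k-mer for group {group!r} with k in "
                f"[{k_min}, {k_max}]")
        chosen[group] = [marker]
    return MarkerSet(chosen)


def scan_read(sequence: str, markers: MarkerSet) -> ScanResult:
    """Classify a read by its leftmost marker hit.

    A forward-form hit gives (group, 'forward'); a reverse-form hit gives
    (group, 'reverse'). Hits in two or more distinct groups make the read
    ambiguous; no hit leaves it unclassified. Orientation follows the
    leftmost hit.
    """
    seq = sequence.upper()
    hits: list[tuple[int, str, str]] = []  # (position, group, orientation)
    for group, pairs in markers.pairs.items():
        for f, r in pairs:
            pos = seq.find(f)
            if pos >= 0:
                hits.append((pos, group, "forward"))
            if r != f:
                pos = seq.find(r)
                if pos >= 0:
                    hits.append((pos, group, "reverse"))
    if not hits:
        return ScanResult("unclassified")
    groups_hit = {g for _, g, _ in hits}
    if len(groups_hit) > 1:
        return ScanResult("ambiguous")
    pos, group, orientation = min(hits)
    return ScanResult("classified", group, orientation, pos)
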