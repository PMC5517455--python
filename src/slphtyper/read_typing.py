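"""Culture-independent typing of amplicon reads.

Pipeline stages, mirroring the wet-lab workflow for sheared ~400-bp amplicon
libraries sequenced on a semiconductor instrument:

1. quality-trim each read with a 5'->3' sliding window (default 4 bases,
   mean phred < 20 cuts; reads shorter than 101 bases after trimming are
   dropped);
2. classify the trimmed read into a *slpH* group via the identifying
   subsequences and orient it to the reference strand;
3. dereplicate the oriented fragments at 100% sequence identity;
4. map each distinct fragment against the reference ST alleles by exact
   substring containment;
5. report an ST only when it attracts at least 3% of its group's reads
   (the true-positive rule); fragment clusters matching no reference that
   pass the same rule are nominated as new STs.

Exact matching plus the 3% rule is the noise control: a sequencing error
makes a read its own singleton cluster, which the abundance filter then
suppresses.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .database import AlignmentParams, STDatabase, pairwise_identity, st_sort_key
from .markers import MarkerSet, scan_read
from .seqs import revcomp

__all__ = [
    "SequencingRead",
    "TypingConfig",
    "TypingProfile",
    "STCall",
    "NewSTCluster",
    "StageTallies",
    "sliding_window_trim",
    "canonicalize",
    "dereplicate",
    "map_cluster",
    "build_profile",
    "type_fastq",
    "type_reads",
    "read_fastq",
    "write_fastq",
    "FastqFormatError",
]


class FastqFormatError(ValueError):
    """Malformed FASTQ input or an unsupported quality encoding."""


@dataclass(frozen=True)
class SequencingRead:
    """A read with per-base phred qualities (same length as the bases)."""

    read_id: str
    bases: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError(f"read {self.read_id!r}: bases/qualities length mismatch")
        if any(q < 0 for q in self.qualities):
            raise ValueError(f"read {self.read_id!r}: negative phred quality")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class TypingConfig:
    """Tunable thresholds of the typing pipeline.

    Defaults follow the published protocol: SLIDINGWINDOW:4:20, MINLEN:101,
    and the 3%-of-group-reads true-positive rule. ``threshold_denominator``
    picks what "all reads within a group" means for the 3% rule:
    ``"mapped"`` (reads in clusters that matched a known ST uniquely) or
    ``"classified"`` (all length-eligible classified reads of the group).
    ``abundance_denominator`` picks the base of the reported percentages:
    ``"reported"`` (sum over reported STs; percentages then total 100) or
    ``"group"`` (the group's threshold denominator).
    """

    trim_window: int = 4
    trim_mean_q: float = 20.0
    min_len: int = 101
    st_call_threshold: float = 3.0
    min_fragment_len: int = 101
    new_st_threshold: float | None = None  # None -> st_call_threshold
    threshold_denominator: str = "mapped"
    abundance_denominator: str = "reported"

    def __post_init__(self) -> None:
        if not 0 < self.st_call_threshold <= 100:
            raise ValueError("st_call_threshold must lie in (0, 100]")
        if self.new_st_threshold is not None and not 0 < self.new_st_threshold <= 100:
            raise ValueError("new_st_threshold must lie in (0, 100]")
        if self.trim_window < 1:
            raise ValueError("trim_window must be >= 1")
        if self.min_len < self.trim_window:
            raise ValueError("min_len must be >= trim_window")
        if self.threshold_denominator not in ("mapped", "classified"):
            raise ValueError("threshold_denominator must be 'mapped' or 'classified'")
        if self.abundance_denominator not in ("reported", "group"):
            raise ValueError("abundance_denominator must be 'reported' or 'group'")

    @property
    def effective_new_st_threshold(self) -> float:
        return self.new_st_threshold if self.new_st_threshold is not None \
            else self.st_call_threshold


# -- FASTQ I/O ---------------------------------------------------------------

_MAX_SANE_PHRED = 60  # phred+33 qualities above this indicate a +64-encoded file


def read_fastq(path: str | Path) -> list[SequencingRead]:
    """Read a phred+33 FASTQ file; loud failure on malformed records or +64 encoding."""
    reads: list[SequencingRead] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4 != 0:
        raise FastqFormatError(
            f"{path}: truncated FASTQ (line count {len(lines)} not a multiple of 4)")
    for rec_no, i in enumerate(range(0, len(lines), 4), start=1):
        head, bases, plus, qual = lines[i:i + 4]
        if not head.startswith("@") or not plus.startswith("+"):
            raise FastqFormatError(f"{path}: malformed FASTQ record {rec_no}")
        if len(bases) != len(qual):
            raise FastqFormatError(
                f"{path}: record {rec_no}: sequence/quality length mismatch")
        quals = tuple(ord(c) - 33 for c in qual)
        if any(q < 0 for q in quals):
            raise FastqFormatError(
                f"{path}: record {rec_no}: quality character below '!' "
                "(not phred+33)")
        if quals and min(quals) > _MAX_SANE_PHRED - 29 and max(quals) > _MAX_SANE_PHRED:
            raise FastqFormatError(
                f"{path}: record {rec_no}: qualities look phred+64-encoded; "
                "only phred+33 is supported")
        reads.append(SequencingRead(head[1:].split()[0], bases.upper(), quals))
    return reads


def write_fastq(reads: Iterable[SequencingRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(min(q, 93) + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{qual}\n")


# -- stages ------------------------------------------------------------------


def sliding_window_trim(read: SequencingRead,
                        config: TypingConfig | None = None) -> SequencingRead | None:
    """5'->3' sliding-window quality trim; returns None when the read is dropped.

    Windows of ``trim_window`` bases advance in steps of one; the read is cut
    at the start index of the first window whose mean quality falls below
    ``trim_mean_q`` (no trailing-base rescue). Reads whose kept prefix is
    shorter than ``min_len`` are dropped.
    """
    config = config or TypingConfig()
    w = config.trim_window
    q = np.asarray(read.qualities, dtype=float)
    cut = len(read)
    if len(read) >= w:
        means = np.convolve(q, np.ones(w) / w, mode="valid")
        failing = np.nonzero(means < config.trim_mean_q)[0]
        if failing.size:
            cut = int(failing[0])
    if cut < config.min_len:
        return None
    if cut == len(read):
        return read
    return SequencingRead(read.read_id, read.bases[:cut], read.qualities[:cut])


def canonicalize(read: SequencingRead | str, markers: MarkerSet):
    """Classify a trimmed read and orient it to the reference strand.

    Returns ``(group, oriented_fragment)`` for classified reads (the fragment
    is the whole trimmed read, reverse-complemented when the hit was a
    reverse-form marker), or the string ``"unclassified"`` / ``"ambiguous"``.
    """
    bases = read if isinstance(read, str) else read.bases
    res = scan_read(bases, markers)
    if res.status != "classified":
        return res.status
    frag = bases if res.orientation == "forward" else revcomp(bases)
    return res.group, frag


def dereplicate(fragments: Iterable[tuple[str, str]]) -> Counter:
    """Collapse (group, fragment) pairs at 100% identity into counted clusters."""
    return Counter(fragments)


def map_cluster(fragment: str, db: STDatabase) -> set[str]:
    """STs whose reference allele contains the fragment as an exact substring."""
    return {rec.st_id for rec in db.records if fragment in rec.sequence}


@dataclass
class STCall:
    """One reported ST (known or new) with its read support and abundance."""

    st_id: str
    group: str
    reads: int
    abundance_pct: float
    is_new: bool = False
    representative: str | None = None
    nearest_st: str | None = None
    identity_to_nearest: float | None = None


@dataclass
class NewSTCluster:
    """A fragment cluster matching no known ST that passed the abundance rule."""

    representative: str
    count: int
    group: str
    nearest_st: str | None
    identity_to_nearest: float | None


@dataclass
class StageTallies:
    """Read-count bookkeeping; every input read lands in exactly one bucket."""

    n_input: int = 0
    n_dropped_trim: int = 0
    n_unclassified: int = 0
    n_ambiguous: int = 0
    n_too_short: int = 0
    n_mapped_unique: int = 0
    n_mapped_shared: int = 0
    n_unmapped: int = 0

    def conserved(self) -> bool:
        return self.n_input == (self.n_dropped_trim + self.n_unclassified
                                + self.n_ambiguous + self.n_too_short
                                + self.n_mapped_unique + self.n_mapped_shared
                                + self.n_unmapped)


@dataclass
class TypingProfile:
    """Per-group, per-ST abundance profile with new-ST clusters and tallies."""

    calls: list[STCall] = field(default_factory=list)
    new_st_clusters: list[NewSTCluster] = field(default_factory=list)
    group_classified: dict[str, int] = field(default_factory=dict)
    group_mapped: dict[str, int] = field(default_factory=dict)
    suppressed_known: dict[str, int] = field(default_factory=dict)
    suppressed_new_reads: int = 0
    shared_reads: int = 0
    tallies: StageTallies = field(default_factory=StageTallies)
    config: TypingConfig = field(default_factory=TypingConfig)

    @property
    def reported_sts(self) -> list[str]:
        return [c.st_id for c in self.calls]

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "group": c.group, "st_id": c.st_id, "reads": c.reads,
            "abundance_pct": round(c.abundance_pct, 2), "is_new": c.is_new,
            "nearest_st": c.nearest_st if c.is_new else ".",
        } for c in self.calls]
        cols = ["group", "st_id", "reads", "abundance_pct", "is_new", "nearest_st"]
        return pd.DataFrame(rows, columns=cols)


def _per_read_frame(rows: list[dict]) -> pd.DataFrame:
    cols = ["read_id", "outcome", "group", "st_id"]
    return pd.DataFrame(rows, columns=cols)


def build_profile(mapped_clusters: Sequence[tuple[str, str, int, set[str]]],
                  db: STDatabase,
                  config: TypingConfig | None = None,
                  tallies: StageTallies | None = None) -> TypingProfile:
    """Apply the abundance filter and assemble the profile.

    ``mapped_clusters`` holds ``(group, fragment, count, matching_st_ids)``
    tuples (empty set = new-ST candidate, >1 = shared). An ST is reported iff
    its uniquely-mapping read count reaches ``st_call_threshold`` percent of
    its group's denominator; new-ST clusters are held to the same rule and
    numbered above the database maximum.
    """
    config = config or TypingConfig()
    profile = TypingProfile(config=config, tallies=tallies or StageTallies())

    st_counts: dict[str, Counter] = {}      # group -> Counter(st_id)
    candidates: dict[str, list] = {}        # group -> [(fragment, count)]
    classified_total: Counter = Counter()
    mapped_total: Counter = Counter()
    for group, fragment, count, matches in mapped_clusters:
        classified_total[group] += count
        if len(matches) == 1:
            st_counts.setdefault(group, Counter())[next(iter(matches))] += count
            mapped_total[group] += count
        elif len(matches) > 1:
            profile.shared_reads += count
        else:
            candidates.setdefault(group, []).append((fragment, count))

    profile.group_classified = dict(classified_total)
    profile.group_mapped = dict(mapped_total)

    def denominator(group: str) -> int:
        if config.threshold_denominator == "classified":
            return classified_total[group]
        return mapped_total[group]

    calls: list[STCall] = []
    for group in sorted(st_counts):
        denom = denominator(group)
        cut = config.st_call_threshold / 100.0 * denom
        for st_id, count in st_counts[group].items():
            if denom > 0 and count >= cut:
                calls.append(STCall(st_id, group, count, 0.0))
            else:
                profile.suppressed_known[st_id] = count

    next_number = db.max_st_number() + 1
    for group in sorted(candidates):
        denom = denominator(group)
        cut = config.effective_new_st_threshold / 100.0 * denom
        # deterministic order: biggest cluster first, then sequence
        for fragment, count in sorted(candidates[group], key=lambda t: (-t[1], t[0])):
            if denom > 0 and count >= cut:
                nearest, pid = None, None
                if len(fragment) >= config.min_fragment_len:
                    # a fragment is a window of a full allele: terminal gaps
                    # are structural, so score identity without them
                    frag_params = AlignmentParams(end_gaps="exclude")
                    best = max(db.records,
                               key=lambda r: pairwise_identity(fragment, r.sequence,
                                                               frag_params))
                    nearest = best.st_id
                    pid = pairwise_identity(fragment, best.sequence, frag_params)
                st_id = f"ST{next_number}"
                next_number += 1
                calls.append(STCall(st_id, group, count, 0.0, is_new=True,
                                    representative=fragment, nearest_st=nearest,
                                    identity_to_nearest=pid))
                profile.new_st_clusters.append(
                    NewSTCluster(fragment, count, group, nearest, pid))
            else:
                profile.suppressed_new_reads += count

    total_reported = sum(c.reads for c in calls)
    for c in calls:
        if config.abundance_denominator == "reported":
            c.abundance_pct = 100.0 * c.reads / total_reported if total_reported else 0.0
        else:
            denom = denominator(c.group)
            c.abundance_pct = 100.0 * c.reads / denom if denom else 0.0
    calls.sort(key=lambda c: (c.group, st_sort_key(c.st_id)))
    profile.calls = calls
    return profile


def type_reads(reads: Sequence[SequencingRead], db: STDatabase,
               markers: MarkerSet,
               config: TypingConfig | None = None,
               ) -> tuple[TypingProfile, pd.DataFrame]:
    """Run the full pipeline on in-memory reads.

    Returns the profile plus a per-read outcome table (read_id, outcome,
    group, st_id) used for stage accounting and simulation scoring. Read
    counts are conserved across stages.
    """
    config = config or TypingConfig()
    tallies = StageTallies(n_input=len(reads))
    per_read: list[dict] = []
    frag_of_read: list[tuple[str, str, str]] = []  # (read_id, group, fragment)
    for read in reads:
        trimmed = sliding_window_trim(read, config)
        if trimmed is None:
            tallies.n_dropped_trim += 1
            per_read.append({"read_id": read.read_id, "outcome": "dropped_trim",
                             "group": ".", "st_id": "."})
            continue
        result = canonicalize(trimmed, markers)
        if result == "unclassified":
            tallies.n_unclassified += 1
            per_read.append({"read_id": read.read_id, "outcome": "unclassified",
                             "group": ".", "st_id": "."})
            continue
        if result == "ambiguous":
            tallies.n_ambiguous += 1
            per_read.append({"read_id": read.read_id, "outcome": "ambiguous",
                             "group": ".", "st_id": "."})
            continue
        group, fragment = result
        if len(fragment) < config.min_fragment_len:
            tallies.n_too_short += 1
            per_read.append({"read_id": read.read_id, "outcome": "too_short",
                             "group": group, "st_id": "."})
            continue
        frag_of_read.append((read.read_id, group, fragment))

    clusters = dereplicate((g, f) for _, g, f in frag_of_read)
    match_of: dict[tuple[str, str], set[str]] = {
        key: map_cluster(key[1], db) for key in clusters
    }
    mapped_clusters = [(g, f, n, match_of[(g, f)]) for (g, f), n in clusters.items()]

    for read_id, group, fragment in frag_of_read:
        matches = match_of[(group, fragment)]
        if len(matches) == 1:
            tallies.n_mapped_unique += 1
            per_read.append({"read_id": read_id, "outcome": "mapped",
                             "group": group, "st_id": next(iter(matches))})
        elif len(matches) > 1:
            tallies.n_mapped_shared += 1
            per_read.append({"read_id": read_id, "outcome": "shared",
                             "group": group, "st_id": "."})
        else:
            tallies.n_unmapped += 1
            per_read.append({"read_id": read_id, "outcome": "unmapped",
                             "group": group, "st_id": "."})

    profile = build_profile(mapped_clusters, db, config, tallies)
    return profile, _per_read_frame(per_read)


def type_fastq(path: str | Path, db: STDatabase, markers: MarkerSet,
               config: TypingConfig | None = None,
               ) -> tuple[TypingProfile, pd.DataFrame]:
    """Pipeline entry point for a phred+33 FASTQ file (see :func:`type_reads`)."""
    return type_reads(read_fastq(path), db, markers, config)
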