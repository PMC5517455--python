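"""Reference database of *slpH* sequence types (STs).

An ST is defined by a unique allele sequence of the typing locus (here the
*slpH* amplicon region, forward orientation). The database stores one record
per ST together with a group label: *slpH* alleles fall into deeply diverged
sequence clusters (~91% identity within a group, ~57% between), and the group
structure is what makes short-read typing possible downstream.

Grouping is computed by single-linkage clustering of global pairwise percent
identity at a configurable link threshold (default 75%, the midpoint of the
within/between identity gap).
"""

from __future__ import annotations

import json
import re
import statistics
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import Align, SeqIO
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .seqs import normalize

SCHEMA_VERSION = 1
DEFAULT_LINK_THRESHOLD = 75.0

__all__ = [
    "AlignmentParams",
    "STRecord",
    "STDatabase",
    "IdentityMatrix",
    "Assignment",
    "GroupIdentitySummary",
    "read_fasta",
    "write_fasta",
    "pairwise_identity",
    "identity_matrix",
    "group_partition",
    "group_identity_summary",
    "build_database",
    "assign_full_sequence",
    "assign_isolates",
    "allele_count",
    "st_sort_key",
]


class DatabaseError(ValueError):
    """Validation failure while building or loading an ST database."""


class UntypableQueryError(ValueError):
    """Query sequence rejected before assignment (e.g. too short)."""


@dataclass(frozen=True)
class AlignmentParams:
    """Global-alignment scoring and the identity convention.

    A gap of length k is penalized ``gap_open + (k - 1) * gap_extend``
    (penalties as magnitudes). ``end_gaps`` selects the identity convention:
    ``"include"`` counts terminal gap columns in the denominator,
    ``"exclude"`` trims them first. Identity is matches / alignment columns,
    as percent; identical ambiguity letters count as matches, any differing
    letters (including ambiguity codes) as mismatches.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = 5.0
    gap_extend: float = 1.0
    end_gaps: str = "include"

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties are magnitudes and must be >= 0")
        if self.end_gaps not in ("include", "exclude"):
            raise ValueError("end_gaps must be 'include' or 'exclude'")

    def aligner(self) -> Align.PairwiseAligner:
        return Align.PairwiseAligner(
            mode="global",
            match_score=self.match,
            mismatch_score=self.mismatch,
            open_gap_score=-self.gap_open,
            extend_gap_score=-self.gap_extend,
        )


@dataclass(frozen=True)
class STRecord:
    """One sequence type: id, group label (or None), allele sequence, provenance."""

    st_id: str
    sequence: str
    group_id: str | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DatabaseError(f"record {self.st_id!r} has an empty sequence")
        object.__setattr__(self, "sequence", normalize(self.sequence, name=self.st_id))


def st_sort_key(st_id: str):
    """Natural sort: ST2 before ST10; non-conforming ids sort after, lexically."""
    m = re.fullmatch(r"ST(\d+)", st_id)
    return (0, int(m.group(1)), "") if m else (1, 0, st_id)


@dataclass
class IdentityMatrix:
    """Symmetric percent-identity matrix over ST labels (diagonal 100)."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("identity matrix must be symmetric")
        if not np.allclose(np.diag(v), 100.0):
            raise ValueError("identity matrix diagonal must be 100")
        if v.min() < 0 or v.max() > 100 + 1e-9:
            raise ValueError("identities must lie in [0, 100]")
        self.values = v

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


class STDatabase:
    """Ordered collection of :class:`STRecord` with creation metadata."""

    def __init__(self, records: Sequence[STRecord], metadata: dict | None = None):
        if not records:
            raise DatabaseError("an ST database needs at least one record")
        seen_ids: dict[str, STRecord] = {}
        seen_seqs: dict[str, str] = {}
        for rec in records:
            if rec.st_id in seen_ids:
                raise DatabaseError(f"duplicate st_id {rec.st_id!r}")
            if rec.sequence in seen_seqs:
                raise DatabaseError(
                    "identical sequence under two st_ids: "
                    f"{seen_seqs[rec.sequence]!r} and {rec.st_id!r}"
                )
            seen_ids[rec.st_id] = rec
            seen_seqs[rec.sequence] = rec.st_id
        self.records: list[STRecord] = list(records)
        self.metadata: dict = metadata or {}
        groups = self.group_labels()
        for rec in self.records:
            if rec.group_id is not None and rec.group_id not in groups:
                raise DatabaseError(f"record {rec.st_id!r} has unknown group")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, st_id: str) -> STRecord:
        for rec in self.records:
            if rec.st_id == st_id:
                return rec
        raise KeyError(st_id)

    def group_labels(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.group_id is not None and rec.group_id not in out:
                out.append(rec.group_id)
        return sorted(out)

    def group_members(self, group_id: str) -> list[STRecord]:
        return [r for r in self.records if r.group_id == group_id]

    def max_st_number(self) -> int:
        nums = [st_sort_key(r.st_id)[1] for r in self.records
                if st_sort_key(r.st_id)[0] == 0]
        return max(nums, default=0)

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "schema_version": SCHEMA_VERSION,
            "metadata": self.metadata,
            "records": [
                {"st_id": r.st_id, "group_id": r.group_id,
                 "sequence": r.sequence, "source": r.source}
                for r in self.records
            ],
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "STDatabase":
        doc = json.loads(text)
        if doc.get("schema_version") != SCHEMA_VERSION:
            raise DatabaseError("unsupported database schema version")
        records = [STRecord(st_id=r["st_id"], sequence=r["sequence"],
                            group_id=r.get("group_id"), source=r.get("source", ""))
                   for r in doc["records"]]
        return cls(records, metadata=doc.get("metadata", {}))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "STDatabase":
        return cls.from_json(Path(path).read_text())


# -- FASTA / TSV I/O -------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, normalized-uppercase-sequence), ...]`` in file order."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[tuple[str, str]] = []
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        raise DatabaseError(f"{path}: not FASTA (first record lacks '>' header)")
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, normalize(str(rec.seq), name=rec.id)))
    if not out:
        warnings.warn(f"{path}: empty FASTA, no records read", stacklevel=2)
    return out


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_metadata_tsv(path: str | Path) -> dict[str, dict]:
    """Read a metadata TSV with columns st_id, group_id, source (header required)."""
    import csv

    out: dict[str, dict] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            gid = (row.get("group_id") or "").strip()
            out[row["st_id"].strip()] = {
                "group_id": gid or None,
                "source": (row.get("source") or "").strip(),
            }
    return out


# -- pairwise identity and grouping ----------------------------------------


def pairwise_identity(seq_a: str, seq_b: str,
                      params: AlignmentParams | None = None) -> float:
    """Percent identity of the optimal global alignment of two sequences.

    Symmetric; returns exactly 100.0 iff the sequences are identical.
    """
    if not seq_a or not seq_b:
        raise ValueError("pairwise_identity requires two non-empty sequences")
    a = normalize(seq_a)
    b = normalize(seq_b)
    if a == b:
        return 100.0
    params = params or AlignmentParams()
    aln = params.aligner().align(a, b)[0]
    counts = aln.counts()
    identities = counts.identities
    columns = counts.identities + counts.mismatches + counts.gaps
    if params.end_gaps == "exclude":
        end_gap = (counts.left_insertions + counts.left_deletions
                   + counts.right_insertions + counts.right_deletions)
        columns -= end_gap
    pct = 100.0 * identities / columns
    # a non-identical pair must not round up to the reserved value 100.0
    return min(pct, 100.0 - 1e-9)


def identity_matrix(records: Sequence[STRecord],
                    params: AlignmentParams | None = None) -> IdentityMatrix:
    """All-against-all percent identity over database records (n(n-1)/2 alignments)."""
    labels = [r.st_id for r in records]
    n = len(records)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = pairwise_identity(records[i].sequence, records[j].sequence, params)
            values[i, j] = values[j, i] = pid
    return IdentityMatrix(labels, values)


def group_partition(matrix: IdentityMatrix,
                    link_threshold: float = DEFAULT_LINK_THRESHOLD) -> dict[str, str]:
    """Single-linkage connected components at identity >= threshold.

    Deterministic labels: components are numbered ``group1, group2, ...`` in
    order of their smallest member ST id (natural sort).
    """
    if not 0 <= link_threshold <= 100:
        raise ValueError("link_threshold must lie in [0, 100]")
    adj = csr_matrix(matrix.values >= link_threshold)
    n_comp, comp = connected_components(adj, directed=False)
    members: dict[int, list[str]] = {}
    for label, c in zip(matrix.labels, comp):
        members.setdefault(int(c), []).append(label)
    ordered = sorted(members.values(), key=lambda ms: min(st_sort_key(m) for m in ms))
    out: dict[str, str] = {}
    for gi, ms in enumerate(ordered, start=1):
        for m in ms:
            out[m] = f"group{gi}"
    return out


@dataclass
class GroupIdentitySummary:
    """Mean/SD percent identity over unordered ST pairs, within vs between groups."""

    within_mean: float | None
    within_sd: float | None
    between_mean: float | None
    between_sd: float | None
    n_within_pairs: int
    n_between_pairs: int


def _summary_stats(vals: list[float]) -> tuple[float | None, float | None]:
    if not vals:
        return None, None
    mean = statistics.fmean(vals)
    sd = statistics.stdev(vals) if len(vals) > 1 else 0.0
    return mean, sd


def group_identity_summary(db: STDatabase,
                           params: AlignmentParams | None = None,
                           matrix: IdentityMatrix | None = None) -> GroupIdentitySummary:
    """Within-group and between-group identity statistics of a grouped database.

    With a single group the between-group statistic is undefined (None), not zero.
    """
    if len(db) < 2:
        raise DatabaseError("need at least 2 records for identity statistics")
    matrix = matrix or identity_matrix(db.records, params)
    group_of = {r.st_id: r.group_id for r in db.records}
    within: list[float] = []
    between: list[float] = []
    labels = matrix.labels
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            val = float(matrix.values[i, j])
            if group_of[labels[i]] == group_of[labels[j]]:
                within.append(val)
            else:
                between.append(val)
    wm, ws = _summary_stats(within)
    bm, bs = _summary_stats(between)
    return GroupIdentitySummary(wm, ws, bm, bs, len(within), len(between))


def build_database(records: Sequence[STRecord],
                   grouping: dict[str, str] | None = None,
                   params: AlignmentParams | None = None,
                   link_threshold: float = DEFAULT_LINK_THRESHOLD,
                   metadata: dict | None = None) -> STDatabase:
    """Assemble and validate an ST database, computing groups when not supplied.

    ``grouping`` maps st_id -> group label; when absent, groups come from
    single-linkage clustering of the identity matrix at ``link_threshold``.
    Duplicate sequences under different st_ids are rejected.
    """
    if not records:
        raise DatabaseError("no records supplied")
    params = params or AlignmentParams()
    if grouping is None:
        grouping = group_partition(identity_matrix(records, params), link_threshold)
    relabeled = [STRecord(st_id=r.st_id, sequence=r.sequence,
                          group_id=grouping.get(r.st_id, r.group_id),
                          source=r.source)
                 for r in records]
    meta = dict(metadata or {})
    meta.setdefault("link_threshold", link_threshold)
    meta.setdefault("alignment_params", asdict(params))
    return STDatabase(relabeled, metadata=meta)


# -- full-length (Sanger) assignment ----------------------------------------


@dataclass
class Assignment:
    """Result of typing one full-length query sequence against the database."""

    st_id: str
    is_new: bool
    group_id: str | None
    nearest_st: str | None
    identity_to_nearest: float | None


def assign_full_sequence(query: str, db: STDatabase,
                         min_len: int = 300,
                         params: AlignmentParams | None = None,
                         new_st_number: int | None = None) -> Assignment:
    """Assign a full-length amplicon (e.g. a Sanger read) to a known or new ST.

    An exact sequence match returns that ST; anything else is a new-ST
    designation numbered ``new_st_number`` (default: next unused integer above
    the database maximum), reported with its nearest known ST and the percent
    identity to it. The new ST inherits the group of its nearest ST.
    """
    q = normalize(query)
    if len(q) < min_len:
        raise UntypableQueryError(
            f"query of {len(q)} bases is below the minimum of {min_len}")
    for rec in db.records:
        if q == rec.sequence:
            return Assignment(rec.st_id, False, rec.group_id, rec.st_id, 100.0)
    best_rec, best_pid = None, -1.0
    for rec in db.records:
        pid = pairwise_identity(q, rec.sequence, params)
        if pid > best_pid:
            best_rec, best_pid = rec, pid
    number = new_st_number if new_st_number is not None else db.max_st_number() + 1
    return Assignment(f"ST{number}", True, best_rec.group_id, best_rec.st_id, best_pid)


def assign_isolates(queries: Sequence[tuple[str, str]], db: STDatabase,
                    min_len: int = 300,
                    params: AlignmentParams | None = None):
    """Type a batch of isolate sequences and tabulate per-ST relative abundance.

    Identical novel sequences share one new-ST designation; new numbers are
    assigned in input order, continuing above the database maximum. Returns
    ``(per-isolate DataFrame, per-ST abundance DataFrame)``.
    """
    import pandas as pd

    next_number = db.max_st_number() + 1
    novel: dict[str, Assignment] = {}
    rows = []
    for name, seq in queries:
        q = normalize(seq, name=name)
        exact = next((r for r in db.records if r.sequence == q), None)
        if exact is not None:
            asn = Assignment(exact.st_id, False, exact.group_id, exact.st_id, 100.0)
        elif q in novel:
            asn = novel[q]
        else:
            asn = assign_full_sequence(q, db, min_len=min_len, params=params,
                                       new_st_number=next_number)
            novel[q] = asn
            next_number += 1
        rows.append({"isolate_id": name, "st_id": asn.st_id, "group_id": asn.group_id,
                     "is_new": asn.is_new, "nearest_st": asn.nearest_st,
                     "identity_to_nearest": asn.identity_to_nearest})
    per_isolate = pd.DataFrame(rows)
    counts = per_isolate.groupby("st_id", sort=False).agg(
        n_isolates=("isolate_id", "size"),
        group_id=("group_id", "first"),
        is_new=("is_new", "first"),
    ).reset_index()
    counts["abundance_pct"] = 100.0 * counts["n_isolates"] / counts["n_isolates"].sum()
    counts = counts.sort_values("st_id", key=lambda s: s.map(st_sort_key),
                                ignore_index=True)
    return per_isolate, counts


def allele_count(sequences: Iterable[str]) -> int:
    """Number of distinct sequences after case normalization."""
    return len({s.upper().replace("U", "T") for s in sequences})
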