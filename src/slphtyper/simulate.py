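"""Synthetic reference databases and semiconductor-style amplicon reads.

The generator reproduces the *study conditions* the typing method was built
for, so every pipeline stage can be exercised without external data:

* a reference database whose alleles fall into three deeply diverged groups
  (~91% pairwise identity within a group, ~57% between) with amplicon lengths
  in the observed 1,104–1,230 bp range and one planted identifying
  subsequence per group;
* single-end reads from sheared ~400-bp amplicon fragments of a strain
  mixture, with substitution and homopolymer-biased indel errors and a
  quality profile that decays toward the 3' end, as on an Ion Torrent PGM.

Error positions are drawn in proportion to the phred-implied error
probability of the simulated qualities (scaled so the per-read mean rates
equal the configured rates): errors concentrate where the instrument reports
low confidence, which is exactly what makes sliding-window quality trimming
effective on the real platform.

Everything is deterministic under the configured seeds, down to the bytes of
the FASTQ output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .database import STDatabase, STRecord, build_database
from .markers import MarkerSet
from .pcr import LHSLP_PAIR, PrimerPair, simulate_pcr
from .read_typing import SequencingRead
from .seqs import revcomp

__all__ = [
    "SynthDBSpec",
    "CommunitySpec",
    "ErrorModel",
    "synthetic_reference_db",
    "simulate_reads",
    "confusion_report",
]

_BASES = np.array(list("ACGT"))


def _divergence_for_identity(target: float) -> float:
    """Per-branch substitution probability giving a target pairwise identity.

    Two sequences independently mutated from a common ancestor at per-site
    probability a (uniform choice among the three other bases) match at a
    site with probability (1-a)^2 + a^2/3; solve for a.
    """
    if not 0 < target < 1:
        raise ValueError("target identity must lie in (0, 1)")
    # (4/3) a^2 - 2a + (1 - target) = 0, smaller root
    disc = 4.0 - 16.0 * (1.0 - target) / 3.0
    return (3.0 / 8.0) * (2.0 - math.sqrt(disc))


@dataclass(frozen=True)
class SynthDBSpec:
    """Recipe for a synthetic grouped ST database."""

    n_groups: int = 3
    sts_per_group: int = 10
    within_identity: float = 0.91
    between_identity: float = 0.57
    length_range: tuple[int, int] = (1104, 1230)
    marker_len: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.between_identity < self.within_identity < 1:
            raise ValueError("need 0 < between_identity < within_identity < 1")
        if self.length_range[0] <= 0 or self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid amplicon length range")


@dataclass(frozen=True)
class CommunitySpec:
    """A strain mixture: st_id -> proportion, read depth, RNG seed."""

    mixture: dict[str, float]
    n_reads: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if not self.mixture or any(p <= 0 for p in self.mixture.values()):
            raise ValueError("mixture proportions must be positive")
        if abs(sum(self.mixture.values()) - 1.0) > 1e-9:
            raise ValueError("mixture proportions must sum to 1")

    @classmethod
    def equimolar(cls, st_ids: Sequence[str], n_reads: int, seed: int = 0
                  ) -> "CommunitySpec":
        p = 1.0 / len(st_ids)
        mix = {st: p for st in st_ids}
        # absorb float residue so the sum is exactly 1
        last = st_ids[-1]
        mix[last] = 1.0 - p * (len(st_ids) - 1)
        return cls(mix, n_reads, seed)


@dataclass(frozen=True)
class ErrorModel:
    """Per-base sequencing error rates and the simulated quality profile.

    ``substitution_rate`` and ``indel_rate`` are per-read mean rates;
    positions are weighted by the phred-implied error probability of the
    simulated quality string. Indels at a base extending a homopolymer run
    of >= 3 are boosted by ``homopolymer_multiplier`` (insertions duplicate
    the current base; deletions drop it). Quality at position i is drawn as
    ``mean_quality - three_prime_decay * i + N(0, quality_sd)``, clipped to
    [2, 40].
    """

    substitution_rate: float = 0.005
    indel_rate: float = 0.01
    homopolymer_multiplier: float = 3.0
    mean_quality: float = 28.0
    three_prime_decay: float = 0.05
    quality_sd: float = 3.0

    def __post_init__(self) -> None:
        if not (0 <= self.substitution_rate < 1 and 0 <= self.indel_rate < 1):
            raise ValueError("error rates must lie in [0, 1)")
        if self.homopolymer_multiplier < 1:
            raise ValueError("homopolymer_multiplier must be >= 1")

    @classmethod
    def none(cls) -> "ErrorModel":
        """Error-free reads at flat quality (the no-noise limit)."""
        return cls(substitution_rate=0.0, indel_rate=0.0,
                   homopolymer_multiplier=1.0, mean_quality=28.0,
                   three_prime_decay=0.0, quality_sd=0.0)

    def apply(self, fragment: str, rng: np.random.Generator
              ) -> tuple[str, tuple[int, ...]]:
        """Simulate base calls and qualities for one oriented fragment."""
        n = len(fragment)
        qual = self.mean_quality - self.three_prime_decay * np.arange(n)
        if self.quality_sd > 0:
            qual = qual + rng.normal(0.0, self.quality_sd, n)
        qual = np.clip(np.rint(qual), 2, 40).astype(int)
        if self.substitution_rate == 0 and self.indel_rate == 0:
            return fragment, tuple(int(q) for q in qual)
        perr = np.power(10.0, -qual / 10.0)
        weight = perr / perr.mean()
        p_sub = np.clip(self.substitution_rate * weight, 0.0, 0.9)
        p_ind = self.indel_rate * weight
        frag = np.frombuffer(fragment.encode(), dtype="S1")
        hp = np.zeros(n, dtype=bool)
        if n >= 4:
            runs = (frag[3:] == frag[2:-1]) & (frag[2:-1] == frag[1:-2]) \
                & (frag[1:-2] == frag[:-3])
            hp[3:] = runs
        p_ind = np.clip(np.where(hp, p_ind * self.homopolymer_multiplier, p_ind),
                        0.0, 0.9)
        bases: list[str] = []
        quals: list[int] = []
        u = rng.random((n, 2))
        for i in range(n):
            ch = fragment[i]
            q = int(qual[i])
            if u[i, 0] < p_ind[i]:
                if u[i, 1] < 0.5:
                    continue  # deletion
                bases.append(ch)  # insertion: duplicate the base
                quals.append(q)
                bases.append(ch)
                quals.append(q)
                continue
            if u[i, 1] < p_sub[i]:
                others = [b for b in "ACGT" if b != ch]
                ch = others[int(rng.integers(0, 3))]
            bases.append(ch)
            quals.append(q)
        return "".join(bases), tuple(quals)


# -- synthetic database ------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for i in np.nonzero(hit)[0]:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


def synthetic_reference_db(spec: SynthDBSpec,
                           pair: PrimerPair = LHSLP_PAIR,
                           max_retries: int = 20
                           ) -> tuple[STDatabase, MarkerSet]:
    """Generate a grouped reference database with planted group markers.

    One random ancestor per group is derived from a common root at the
    between-group divergence; each ST is an independently mutated copy of its
    group ancestor at the within-group divergence (substitutions only, so
    identity targets are analytically controlled). Every allele carries the
    real primer footprints at its ends — each record yields exactly one
    product under ``pair`` — and one planted marker k-mer per group,
    overwritten at a fixed mid-gene position in every member and verified
    discriminative post hoc. Deterministic under ``spec.seed``.
    """
    fwd_site = pair.forward.sequence
    rev_site = revcomp(pair.reverse.sequence)
    flank = len(fwd_site) + len(rev_site)
    a_between = _divergence_for_identity(spec.between_identity)
    a_within = _divergence_for_identity(spec.within_identity)

    last_err: Exception | None = None
    for attempt in range(max_retries):
        rng = np.random.default_rng((spec.seed, attempt))
        try:
            core_lens = [int(rng.integers(spec.length_range[0],
                                          spec.length_range[1] + 1)) - flank
                         for _ in range(spec.n_groups)]
            root = _random_seq(rng, max(core_lens))
            records: list[STRecord] = []
            grouping: dict[str, str] = {}
            forward_markers: dict[str, list[str]] = {}
            st_no = 0
            for g in range(spec.n_groups):
                group = f"group{g + 1}"
                core_len = core_lens[g]
                ancestor = _mutate(root[:core_len], a_between, rng)
                # markers sit mid-gene, like the published identifying
                # subsequences; a central, fixed position keeps the chance
                # that a sheared fragment covers the marker comparable
                # across groups
                pos = (core_len - spec.marker_len) // 2
                marker = _random_seq(rng, spec.marker_len)
                forward_markers[group] = [marker]
                for _ in range(spec.sts_per_group):
                    st_no += 1
                    st_id = f"ST{st_no}"
                    core = _mutate(ancestor, a_within, rng)
                    core = core[:pos] + marker + core[pos + spec.marker_len:]
                    seq = fwd_site + core + rev_site
                    records.append(STRecord(st_id=st_id, sequence=seq,
                                            group_id=group,
                                            source=f"synthetic:{spec.seed}"))
                    grouping[st_id] = group
            db = build_database(records, grouping=grouping,
                                metadata={"synthetic": True,
                                          "generator_seed": spec.seed,
                                          "within_identity": spec.within_identity,
                                          "between_identity": spec.between_identity})
            markers = MarkerSet(forward_markers)
            markers.verify_against_db(db)
            for rec in db.records:
                if len(simulate_pcr(rec.sequence, pair, rec.st_id)) != 1:
                    raise ValueError(f"{rec.st_id}: spurious primer site")
            return db, markers
        except ValueError as err:  # marker collision / spurious site: retry
            last_err = err
    raise RuntimeError(
        f"synthetic database generation failed after {max_retries} attempts: "
        f"{last_err}")


# -- read simulation ---------------------------------------------------------


def simulate_reads(db: STDatabase, pair: PrimerPair,
                   community: CommunitySpec, errors: ErrorModel,
                   fragment_len_mean: float = 400.0,
                   fragment_len_sd: float = 40.0,
                   read_len_cap: int = 400,
                   min_fragment_len: int = 30,
                   ) -> tuple[list[SequencingRead], pd.DataFrame]:
    """Simulate sheared single-end amplicon reads from a strain mixture.

    Each read: draw an ST by mixture proportions, amplify its allele with
    ``pair`` (must yield exactly one product), draw a fragment (uniform
    position, Normal(mean, sd) length truncated to the template and
    ``read_len_cap``), a uniform strand, then apply the error model. Returns
    the reads plus a truth table (read_id, st_id, group). Deterministic under
    ``community.seed``.
    """
    templates: dict[str, str] = {}
    group_of: dict[str, str] = {}
    for st_id in community.mixture:
        try:
            rec = db.get(st_id)
        except KeyError:
            raise ValueError(f"mixture references unknown ST {st_id!r}") from None
        prods = simulate_pcr(rec.sequence, pair, st_id)
        if len(prods) != 1:
            raise ValueError(
                f"{st_id}: expected exactly one amplicon, got {len(prods)}")
        templates[st_id] = prods[0].sequence
        group_of[st_id] = rec.group_id

    rng = np.random.default_rng(community.seed)
    st_ids = sorted(community.mixture, key=lambda s: (len(s), s))
    props = np.array([community.mixture[s] for s in st_ids])
    props = props / props.sum()
    picks = rng.choice(len(st_ids), size=community.n_reads, p=props)

    reads: list[SequencingRead] = []
    truth_rows: list[dict] = []
    for i, k in enumerate(picks):
        st_id = st_ids[int(k)]
        template = templates[st_id]
        flen = int(round(rng.normal(fragment_len_mean, fragment_len_sd)))
        flen = max(min_fragment_len, min(flen, len(template), read_len_cap))
        start = int(rng.integers(0, len(template) - flen + 1))
        frag = template[start:start + flen]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        bases, quals = errors.apply(frag, rng)
        read_id = f"read{i + 1:06d}"
        reads.append(SequencingRead(read_id, bases, quals))
        truth_rows.append({"read_id": read_id, "st_id": st_id,
                           "group": group_of[st_id]})
    truth = pd.DataFrame(truth_rows, columns=["read_id", "st_id", "group"])
    return reads, truth


def confusion_report(truth: pd.DataFrame, per_read: pd.DataFrame) -> pd.DataFrame:
    """Per-ST precision/recall of read assignments against the simulation truth.

    Precision counts are taken over uniquely-mapped reads; recall is against
    all truth reads of the ST. Precision with no predicted reads is undefined
    (NaN), not zero. Raises on read-id mismatch.
    """
    if set(per_read["read_id"]) - set(truth["read_id"]):
        raise ValueError("per-read table contains read ids absent from the truth table")
    merged = per_read.merge(truth, on="read_id", how="left",
                            suffixes=("_pred", "_true"))
    mapped = merged[merged["outcome"] == "mapped"]
    rows = []
    for st in sorted(set(truth["st_id"]) | set(mapped["st_id_pred"]),
                     key=lambda s: (len(s), s)):
        tp = int(((mapped["st_id_pred"] == st) & (mapped["st_id_true"] == st)).sum())
        fp = int(((mapped["st_id_pred"] == st) & (mapped["st_id_true"] != st)).sum())
        n_true = int((truth["st_id"] == st).sum())
        precision = tp / (tp + fp) if (tp + fp) else float("nan")
        recall = tp / n_true if n_true else float("nan")
        rows.append({"st_id": st, "true_reads": n_true, "tp": tp, "fp": fp,
                     "fn": n_true - tp, "precision": precision, "recall": recall})
    return pd.DataFrame(rows)
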