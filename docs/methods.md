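# Methods

This note documents the models, conventions and default parameters behind
`slphtyper`, the design choices made where the protocol leaves room, and what
the synthetic-data tests do and do not demonstrate.

## Sequence types and the reference database

An ST is defined by a unique nucleotide sequence of the *slpH* amplicon
region, stored in forward orientation. Ingest normalizes case, maps U to T,
strips gaps and rejects non-IUPAC characters. Two records with identical
sequence under different ST ids are a validation error, never a silent
merge: identity of sequence is what defines the type.

**Pairwise identity** is computed from one optimal global alignment
(Needleman–Wunsch, via Biopython's `PairwiseAligner`): match +1, mismatch
−1, gap open 5, gap extend 1 (a gap of length k costs 5 + (k−1)·1), identity
= matching columns / all alignment columns × 100. Two conventions are
selectable: end-gap columns counted in the denominator (default) or trimmed
first. The default is used for full-length allele comparisons; the
end-gap-excluded variant is used when scoring a short read fragment against
a full allele, where terminal gaps are structural rather than evolutionary.
Identical ambiguity letters count as matches; any differing letters,
including ambiguity codes, as mismatches. 100.0 is reserved for literally
identical sequences. These alignment parameters are a package convention —
the original analysis used interactive alignment tools without stated
parameters — so the identity statistics carry a small
alignment-parameter sensitivity (roughly ±1–2 points on the between-group
mean, where gap placement matters most).

**Grouping** is single-linkage clustering at percent identity ≥ 75, the
midpoint of the observed ~91% within / ~57% between gap, implemented as
connected components of the thresholded identity matrix. Labels are
deterministic: components are numbered `group1, group2, …` by their smallest
member ST id in natural sort order. Single linkage is monotone: raising the
threshold can only split groups, never merge them.

**Full-length assignment** (Sanger isolates): an exact sequence match
returns that ST; anything else is a new ST numbered above the database
maximum (continuing the published numbering convention), reported with the
nearest known ST and identity. Queries below 300 bases are rejected as
untypable rather than force-assigned. In batch isolate typing, identical
novel sequences share one new number, assigned in input order.

## In-silico PCR

Primer sites are found by sliding the primer along both strands; a position
matches when the primer IUPAC code's base set intersects the template
code's. Default mismatch tolerance is 0 (the protocol uses a
high-fidelity polymerase); when mismatches are allowed, the 3'-terminal 3
bases must still match exactly — the standard extension-blocking heuristic.
Products are formed for every inward-facing forward/reverse site combination
up to 3,000 bp, and the product length includes both primer footprints
(which reproduces the 1,116-bp convention of the reference locus with a
21 + 20 nt pair). Coordinates are 0-based half-open on the forward strand.
Absence of a product is an empty result, not an error: a negative is a valid
specificity reading. The typing workflows refuse templates with more than
one product as an ambiguous locus, but all products are always reported.

## Group markers

A marker must occur (forward orientation) in every allele of its group and
occur in no allele of any other group in either orientation; the set is kept
closed under reverse complement so a hit also gives read orientation.
Discovery is exhaustive: for each group the smallest k in [k_min, k_max]
(default 8–12) admitting a candidate is taken, tie-broken by
lexicographically smallest k-mer — deterministic and directly checkable
against a brute-force enumeration oracle, which the test suite does. One
marker hit suffices to classify a read; hits in two or more groups make the
read ambiguous and it is excluded from typing but tallied. Marker matching
is exact: markers are short, and a read whose marker is hit by an error is
simply left unclassified rather than misclassified.

## Read typing pipeline

Stages, with every read landing in exactly one bucket (conservation is
asserted in tests):

1. **Trim**: windows of 4 bases slide from the 5' end in steps of one; the
   read is cut at the start index of the first window whose mean phred falls
   below 20, with no trailing-base rescue. Kept prefixes shorter than 101
   bases drop the read. (The cut-at-window-start rule is stated explicitly
   so tests can be exact.)
2. **Classify and orient**: marker scan; reverse-form hits reverse-complement
   the read so all fragments share the reference orientation. The fragment
   is the whole trimmed, oriented read — no marker-anchored sub-windowing.
3. **Dereplicate** at 100% identity into counted clusters.
4. **Map** each distinct fragment by exact substring containment in the
   reference alleles. No mismatches are tolerated: one error makes a read
   its own cluster, which the abundance filter then suppresses. Fragments
   matching several STs are "shared" and excluded from per-ST counts
   (fractional assignment was rejected for determinism); fragments matching
   none are new-ST candidates.
5. **Filter and report**: an ST is reported iff its uniquely-mapping read
   count reaches 3% of its group's denominator; new-ST candidate clusters
   are held to the same rule and numbered above the database maximum.

Two denominators are defensible for "all reads within a group" and both are
supported: reads in clusters uniquely mapping to known STs (`"mapped"`, the
default) or all length-eligible classified reads (`"classified"`). Reported
relative abundance defaults to the share over reported STs (summing to 100);
the group denominator is available as an option because the published
per-ST abundances do not sum exactly to 100 and the original denominator
cannot be inferred. Note a consequence of any within-group percentage rule:
in a group that received very few reads (e.g. a 5% strain in a small run),
3% of the group can be below one read and singleton error clusters can pass
the filter. That is honest behavior of the rule at low depth, visible in the
three-strain-mixture test.

FASTQ input is fixed to phred+33; files whose qualities decode uniformly
high (the phred+64 signature) are rejected loudly rather than silently
mis-scaled.

## Read simulator

The simulator reproduces the study conditions so the pipeline can be
validated end to end.

**Synthetic databases.** One random root sequence; per group an ancestor
mutated from the root; per ST an allele mutated from its group ancestor.
Substitutions only, so identity targets are analytic: two sequences
independently mutated from a common ancestor at per-site probability *a*
match at a site with probability (1−a)² + a²/3, and *a* is solved from the
target (0.91 within, 0.57 between). Because cross-group ST pairs carry the
within-group divergence on top of the ancestor divergence, their measured
identity lands a few points below the between-group target (~52–53% instead
of 57%); both fall well inside the generator's acceptance bands (85–97% and
45–70%). Amplicon lengths are drawn per group from the observed 1,104–1,230
bp range; every allele carries the real primer footprints at its ends and
one planted 10-mer marker per group, overwritten at the central position of
each member (markers sit mid-gene, like the published identifying
subsequences, and a central fixed position keeps fragment coverage of the
marker comparable across groups) and verified discriminative post hoc, with
bounded reseeded retries on collision.

**Reads.** Per read: ST drawn by mixture proportions; fragment position
uniform on the ST's amplicon with length ~ Normal(400, 40) truncated to the
template and a 400-base cap (emulating shearing plus 400-bp size
selection); strand uniform. Qualities decay linearly from Q28 at the 5' end
(0.05 phred/base, Gaussian noise sd 3, clipped to [2, 40]). Error rates are
per-read means — substitution 0.5%, indel 1%, indels boosted 3× at bases
extending a homopolymer run of ≥ 3 (insertions duplicate the base,
deletions drop it) — distributed across positions in proportion to the
phred-implied error probability of the simulated qualities. This coupling
is the one property of real base callers the pipeline depends on: errors
concentrate where reported confidence is low, which is why sliding-window
trimming recovers exact-matching prefixes. Uncorrelated error placement
would make 100%-identity mapping fail at rates no real platform shows.
Everything is deterministic under the seed, down to FASTQ bytes.

**What the simulator does not model** — and hence what passing tests do not
show about real data: PCR amplification and pooling bias (the dominant
source of the published equimolar-mixture spread), chimera formation,
flow-space signal artifacts, indel divergence between alleles, and
non-uniform fragment coverage. Marker coverage by sheared fragments differs
slightly between groups when amplicon lengths differ, which biases
cross-group abundances exactly as the real extraction step does; the
zero-error abundance calibration is therefore tested on an equal-length
synthetic database, as a multinomial check over three seeds.

## Problem sizes and numerical choices

The test suite and acceptance script use 30-allele databases (~1.1–1.2 kb),
mixtures of 2–10 strains and 300–5,000 reads — sizes at which the in-silico
validation is exact enough to be meaningful while the full suite runs in
well under a minute of alignment time. Identity matrices on n alleles
compute n(n−1)/2 alignments; the 30-allele matrix takes a few seconds.
Floating-point identities are capped strictly below 100 for non-identical
pairs so the "100 iff identical" contract cannot be broken by rounding.
Ties in marker discovery, new-ST ordering (largest cluster first, then
sequence) and group labeling are all broken deterministically.

## Known limitations

- Typing resolution is bounded by the locus: alleles identical over a
  fragment's window are "shared" and contribute to no ST; full-amplicon
  (long-read) typing would remove this ceiling.
- The 3% rule is a per-group relative threshold; at low per-group read
  depth it degenerates (see above), and real new STs below 3% of their
  group are invisible by design.
- The reference identity statistics depend mildly on alignment parameters;
  the defaults are stated above and alternatives are configurable, but no
  attempt is made to reproduce any particular interactive aligner.
- Species specificity of the typing primers is incomplete by construction
  (the closest relative also amplifies); the companion pheS assay screen is
  the control for that, not the typing pipeline itself.
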