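# slphtyper

Culture-independent strain typing of *Lactobacillus helveticus* from amplicon
sequencing of the *slpH* locus.

*L. helveticus* is a dominant lactic acid bacterium of natural whey cultures
(NWCs) and ripened cheeses, and different strains of it behave differently in
fermentation. Classical typing (RAPD, PFGE, MLST) requires isolating
colonies, which skews the observed community toward strains that grow well on
plates. This package implements a typing workflow that skips cultivation: the
single-copy core-genome gene *slpH*, encoding a putative surface-layer
protein, is polymorphic enough that each unique allele of its amplicon region
defines a **sequence type (ST)** — a proxy for a strain. It is written for
microbiologists and bioinformaticians who want to profile *L. helveticus*
strain communities in dairy samples, or to study the method itself on
simulated data.

## The method

*slpH* alleles fall into three deeply diverged **groups**: alleles within a
group share ~91% nucleotide identity while alleles across groups share only
~57%. The workflow exploits that structure end to end:

1. **Reference database.** Known alleles (amplicon region, forward
   orientation) are stored one record per ST. Grouping is computed by
   single-linkage clustering of global pairwise percent identity at a 75%
   link threshold — the midpoint of the within/between identity gap.
2. **In-silico PCR.** The typing primer pair LHslpF/LHslpR
   (`CAAGGAGGAAAGACCACATGA` / `TGTACTTGCCAGTTGCCTTG`) is located on a
   template with IUPAC-aware matching on both strands; inward-facing site
   pairs yield predicted products (1,104–1,230 bp across known alleles).
   A second pair targeting *L. gallinarum* pheS (180 bp) supports species
   specificity screening.
3. **Group markers.** Short "identifying subsequences" — k-mers present in
   every allele of one group and absent, in both orientations, from the
   others — classify a read into a group and reveal its strand. The twelve
   published marker strings ship with the package
   (`slphtyper markers published`), and `discover_markers` derives minimal-k
   markers for any grouped database by exhaustive screening.
4. **Read typing.** Amplicons are sheared to ~400-bp fragments and sequenced
   single-ended on a semiconductor instrument. Reads are quality-trimmed
   (sliding window of 4 bases, mean phred < 20 cuts; minimum length 101),
   classified and oriented by marker, dereplicated at 100% identity, and
   mapped to reference alleles by exact substring containment. An ST is
   reported only if it attracts **at least 3% of its group's reads** — the
   true-positive rule that suppresses sequencing-error clusters. Clusters
   matching no known allele that pass the same rule are nominated as **new
   STs**, numbered above the database maximum.
5. **Isolate typing.** Full-length Sanger amplicons from picked colonies are
   assigned by exact sequence match, with novel alleles reported as new STs
   together with their nearest known ST and identity.

A validation-oriented simulator generates reference databases with the
group-identity structure above and Ion-Torrent-like reads (sheared ~400-bp
fragments, quality decay toward the 3' end, homopolymer-biased indels) from
strain mixtures, so every stage is testable without downloads.

## Worked example

`examples/type_community_reads.py` re-creates the validation experiment in
silico — an equimolar 10-strain mixture, 5,000 reads, default error model:

```
input reads           5000
dropped by trimming   783
no group marker       3583
mapped to known STs   516
error clusters        118 (suppressed by the 3% rule)

 group st_id  reads  abundance_pct  is_new nearest_st
group1   ST1     52          10.08   False          .
group1   ST2     59          11.43   False          .
...
reported STs: 10 of 10 spiked
assignment precision over mapped reads: 1.000
```

Reads without a marker in their trimmed prefix carry no group information
and are discarded, exactly as in the wet-lab protocol; erroneous reads form
singleton clusters that the 3% rule removes. All ten spiked strains — and
nothing else — are reported, each near its true 10% share.
`examples/type_isolates.py` shows the culture-dependent counterpart: an
81-colony batch in a 44/7/28/2 composition types to abundances
54.3/8.6/34.6/2.5%, with the two novel alleles nominated as new STs.

The same workflows are available from the shell:

```sh
slphtyper simulate db --seed 42 --out-db db.json --out-markers markers.tsv
slphtyper simulate reads --db db.json --mixture ST1,ST11,ST21 \
    --n-reads 5000 --seed 1 --out-fastq reads.fastq --out-truth truth.tsv
slphtyper type-reads --fastq reads.fastq --db db.json --markers markers.tsv \
    --out-profile profile.tsv --out-report report.json
```

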