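"""Discover group-identifying subsequences and classify a read with them.

A marker is the smallest k-mer present in every allele of one group and
absent, in both orientations, from all other groups. The published slpH set
(12 strings, 4 per group) follows the same closure convention.
"""

import slphtyper as sl

db, _ = sl.synthetic_reference_db(sl.SynthDBSpec(seed=42))
markers = sl.discover_markers(db, k_min=8, k_max=12)

for group in markers.groups:
    print(f"{group}: {', '.join(markers.all_strings(group))}")

read = db.records[0].sequence[400:700]
res = sl.scan_read(read, markers)
print(f"\na 300-bp read from {db.records[0].st_id} scans as: "
      f"group={res.group} orientation={res.orientation}")

published = sl.published_markers()
print("\npublished slpH marker set (forward + reverse-complement forms):")
for group in published.groups:
    print(f"  {group}: {', '.join(published.all_strings(group))}")
print("Each 4-string set is 2 markers plus their reverse complements, so a")
print("hit also reveals which strand the read came from.")
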