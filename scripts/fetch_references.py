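#!/usr/bin/env python
"""Fetch the published reference allele regions from NCBI GenBank (network).

Downloads every region listed in the allele registry plus the *L. gallinarum*
pheS assay region, then derives the per-ST amplicon sequences by local
in-silico PCR. Writes three plain-text FASTA files under data/:

  reference_loci.fasta       raw fetched regions (plus flanks where the
                             accession has genomic context), named by st_id
  reference_amplicons.fasta  the single in-silico PCR product per ST
  pheS_gallinarum.fasta      the pheS region of L. gallinarum DSM 10532

The reference-data tests under tests/test_acceptance.py pick these files up
automatically once present.

Usage:  python scripts/fetch_references.py [--flank 200]
"""

from __future__ import annotations

import argparse
import re
import sys
import time
import urllib.parse
import urllib.request
from pathlib import Path

import slphtyper as sl
from slphtyper.registry import REGISTRY

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
PHES_REGION = ("pheS_DSM10532", "AZEL01000044", 72250, 73299)
DATA = Path(__file__).resolve().parents[1] / "data"


def efetch(accession: str, start: int | None = None, stop: int | None = None,
           strand: int = 1) -> str:
    params = {"db": "nuccore", "id": accession, "rettype": "fasta",
              "retmode": "text"}
    if start is not None:
        params.update(seq_start=start, seq_stop=stop, strand=strand)
    url = EUTILS + "?" + urllib.parse.urlencode(params)
    with urllib.request.urlopen(url, timeout=60) as resp:
        text = resp.read().decode()
    seq = "".join(text.split("\n")[1:])
    if not seq:
        raise RuntimeError(f"empty efetch response for {accession}")
    time.sleep(0.4)  # NCBI rate limit
    return seq.upper()


def parse_region(acc_field: str) -> tuple[str, int | None, int | None, int]:
    m = re.fullmatch(r"([A-Z0-9_.]+):(\d+)\.\.(\d+)", acc_field)
    if not m:
        return acc_field, None, None, 1
    acc, a, b = m.group(1), int(m.group(2)), int(m.group(3))
    if a <= b:
        return acc, a, b, 1
    return acc, b, a, 2  # reversed coordinates: minus strand


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--flank", type=int, default=200,
                    help="extra genomic context fetched around region-style "
                         "accessions (bases)")
    args = ap.parse_args()
    DATA.mkdir(exist_ok=True)

    loci: list[tuple[str, str]] = []
    for st_id, info in REGISTRY.items():
        acc, start, stop, strand = parse_region(info["accession"])
        if start is not None:
            start = max(1, start - args.flank)
            stop = stop + args.flank
        print(f"fetching {st_id} <- {info['accession']}", file=sys.stderr)
        loci.append((st_id, efetch(acc, start, stop, strand)))
    sl.write_fasta(DATA / "reference_loci.fasta", loci)

    amplicons: list[tuple[str, str]] = []
    for st_id, seq in loci:
        products = sl.simulate_pcr(seq, sl.LHSLP_PAIR, st_id)
        if len(products) != 1:
            raise SystemExit(
                f"{st_id}: expected exactly one slpH product, got "
                f"{len(products)}; inspect reference_loci.fasta")
        amplicons.append((st_id, products[0].sequence))
    sl.write_fasta(DATA / "reference_amplicons.fasta", amplicons)

    name, acc, start, stop = PHES_REGION
    print(f"fetching {name} <- {acc}:{start}..{stop}", file=sys.stderr)
    sl.write_fasta(DATA / "pheS_gallinarum.fasta",
                   [(name, efetch(acc, start, stop))])
    print(f"wrote {DATA}/reference_loci.fasta, reference_amplicons.fasta, "
          "pheS_gallinarum.fasta", file=sys.stderr)


if __name__ == "__main__":
    main()
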