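"""Published registry of *slpH* reference alleles.

Maps each reference strain to its GenBank accession (or accession:region for
alleles embedded in genome assemblies), its assigned sequence type and its
*slpH* group. Sequences themselves are not redistributed here; use
``scripts/fetch_references.py`` to download them into
``data/reference_amplicons.fasta``, after which :func:`load_reference_db`
builds the full reference database.
"""

from __future__ import annotations

from pathlib import Path

from .database import STDatabase, STRecord, read_fasta

__all__ = ["REGISTRY", "registry_rows", "load_reference_db", "REFERENCE_FASTA"]

# strain, accession[:region], st_id, group
_REGISTRY_TSV = """\
CNRZ32\tNC_021744:188864..190276\tST18\tgroup3
DPC4571\tNC_010080:185923..187353\tST16\tgroup1
R0052\tNC_018528:173786..175240\tST7\tgroup2
H9\tNZ_CP002427:158282..159730\tST5\tgroup2
H10\tNC_017467:184227..185654\tST24\tgroup3
KLDS1.8701\tNZ_CP009907:360112..361575\tST4\tgroup2
MB2-1\tNZ_CP011386:169834..171285\tST6\tgroup2
CIRM_BIA_951\tHG530785:24314..25666\tST26\tgroup2
CAUH18\tNZ_CP012381:192832..194253\tST19\tgroup3
D75\tNZ_CP020029:1867932..1866469\tST33\tgroup2
M3\tNZ_JRTS01000020:2926..4227\tST12\tgroup3
LMG_22464\tNZ_JQCJ01000044:7029..8378\tST25\tgroup1
CIRM_BIA_953\tNZ_CBUH010000081:863..2185\tST28\tgroup3
LH12\tLSVI01000069.1:5275..6597\tST29\tgroup3
DSM20075\tNZ_GG700752:369748..371067\tST30\tgroup3
FAM1450\tMF401525\tST20\tgroup3
FAM22287\tMF401526\tST21\tgroup3
FAM1213\tMF401527\tST22\tgroup3
FAM2888\tMF401528\tST23\tgroup3
FAM21790\tMF401529\tST17\tgroup3
FAM22076\tMF401530\tST1\tgroup2
FAM1182\tMF401531\tST2\tgroup2
FAM22077\tMF401532\tST3\tgroup2
FAM13019\tMF401533\tST10\tgroup2
FAM17275\tMF401534\tST9\tgroup2
FAM22156\tMF401535\tST11\tgroup2
FAM20575\tMF401536\tST8\tgroup2
FAM8102\tMF401537\tST13\tgroup1
FAM21339\tMF401538\tST14\tgroup1
FAM21456\tMF401539\tST15\tgroup1
LH32\tMF417547\tST27\tgroup3
"""

#: st_id -> {"strain": ..., "accession": ..., "group_id": ...}
REGISTRY: dict[str, dict[str, str]] = {}
for _line in _REGISTRY_TSV.splitlines():
    _strain, _acc, _st, _grp = _line.split("\t")
    REGISTRY[_st] = {"strain": _strain, "accession": _acc, "group_id": _grp}

#: default location of the fetched reference sequences (repo-root relative)
REFERENCE_FASTA = Path(__file__).resolve().parents[2] / "data" / "reference_amplicons.fasta"


def registry_rows() -> list[dict[str, str]]:
    """The registry as a list of row dicts, in published order."""
    return [{"st_id": st, **info} for st, info in REGISTRY.items()]


def load_reference_db(fasta_path: str | Path | None = None,
                      grouped: bool = True) -> STDatabase:
    """Build the reference ST database from fetched sequences.

    The FASTA must contain one record per registry ST, named by st_id
    (as written by ``scripts/fetch_references.py``). With ``grouped`` the
    published group labels are attached; otherwise records are ungrouped.
    """
    path = Path(fasta_path) if fasta_path is not None else REFERENCE_FASTA
    if not path.exists():
        raise FileNotFoundError(
            f"{path}: reference sequences not present; run "
            "scripts/fetch_references.py (requires network access to NCBI)")
    seqs = dict(read_fasta(path))
    missing = sorted(set(REGISTRY) - set(seqs))
    if missing:
        raise ValueError(f"reference FASTA lacks registry STs: {', '.join(missing)}")
    records = [
        STRecord(st_id=st, sequence=seqs[st],
                 group_id=REGISTRY[st]["group_id"] if grouped else None,
                 source=f"{REGISTRY[st]['strain']}|{REGISTRY[st]['accession']}")
        for st in REGISTRY
    ]
    return STDatabase(records, metadata={"source": "published registry"})
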