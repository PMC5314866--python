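"""Readers and writers for the tabular formats the pipeline exchanges.

The manifest is stored in the 450k manifest dialect (``IlmnID``, ``CHR``,
``MAPINFO``, semicolon-joined ``UCSC_RefGene_Name`` / ``UCSC_RefGene_Group``,
``Relation_to_UCSC_CpG_Island``) so real manifest extracts drop in directly;
internally a plainer column naming is used. Beta matrices are TSV with
probes as rows and samples as columns. Gene sets use the GMT convention
(term, description, tab-separated members).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

_MANIFEST_OUT = {
    "probe_id": "IlmnID",
    "chromosome": "CHR",
    "position": "MAPINFO",
    "gene_names": "UCSC_RefGene_Name",
    "gene_regions": "UCSC_RefGene_Group",
    "cpg_context": "Relation_to_UCSC_CpG_Island",
    "probe_class": "Probe_Class",
    "snp_within_10bp": "SNP_10bp_Flag",
    "multi_mapping": "MultiMap_Flag",
}
_MANIFEST_IN = {v: k for k, v in _MANIFEST_OUT.items()}


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    out = manifest[list(_MANIFEST_OUT)].rename(columns=_MANIFEST_OUT).copy()
    out["SNP_10bp_Flag"] = out["SNP_10bp_Flag"].astype(int)
    out["MultiMap_Flag"] = out["MultiMap_Flag"].astype(int)
    out.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, dtype={"CHR": str},
                      keep_default_na=False, na_values=[])
    missing = set(_MANIFEST_IN) - set(raw.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    man = raw[list(_MANIFEST_IN)].rename(columns=_MANIFEST_IN)
    man["position"] = man["position"].astype(int)
    man["snp_within_10bp"] = man["snp_within_10bp"].astype(int).astype(bool)
    man["multi_mapping"] = man["multi_mapping"].astype(int).astype(bool)
    return man


def write_beta(beta: pd.DataFrame, path: str | Path) -> None:
    beta.to_csv(path, sep="\t", index_label="probe_id")


def read_beta(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path)
    required = {"sample_id", "tissue", "bmi", "gender", "age"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return sheet


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file into term -> member-gene lists."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            term, _desc, *genes = parts
            sets[term] = [g for g in genes if g]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term, genes in gene_sets.items():
            fh.write("\t".join([term, description, *genes]) + "\n")
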