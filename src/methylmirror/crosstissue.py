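"""Cross-tissue signature selection and sample clustering.

The selection cascade distils per-tissue differential CpG calls into a
blood-detectable signature of the adipose methylation state:

1. intersect the adipose and leukocyte DM sets (Venn overlap), dropping
   multi-mapping probes;
2. keep CpGs whose group difference has the same (strictly nonzero) sign
   in both tissues;
3. restrict to promoter CpGs (TSS1500, TSS200, 5'UTR or 1st exon) in CpG
   islands or shores, where methylation is most likely to be regulatory;
4. keep CpGs whose difference magnitude exceeds the threshold in BOTH
   tissues ("similar magnitude"), optionally also requiring the two
   deltas to agree within a tolerance.

Each stage only removes probes, so stage sizes are monotone
non-increasing and every stage is idempotent.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "PROMOTER_REGIONS",
    "SIGNATURE_CONTEXTS",
    "overlap_dmcpgs",
    "direction_consistent",
    "region_filter",
    "signature_select",
    "venn_counts",
    "hierarchical_cluster",
]

PROMOTER_REGIONS = frozenset({"TSS1500", "TSS200", "5'UTR", "1stExon"})
SIGNATURE_CONTEXTS = frozenset({"Island", "N_Shore", "S_Shore"})


def overlap_dmcpgs(dm_adipose, dm_leukocyte,
                   multimap_blacklist=()) -> set[str]:
    """Probes differentially methylated in both tissues, minus
    multi-mapping probes."""
    return (set(dm_adipose) & set(dm_leukocyte)) - set(multimap_blacklist)


def direction_consistent(common, adipose_records: pd.DataFrame,
                         leukocyte_records: pd.DataFrame) -> pd.DataFrame:
    """Candidates whose deltas share a strictly nonzero sign in both tissues.

    Returns a frame with ``probe_id, delta_adipose, delta_leukocyte,
    direction`` (hyper/hypo in the obese group). A zero delta carries no
    direction and is excluded.
    """
    adi = adipose_records.set_index("probe_id")["delta"]
    leu = leukocyte_records.set_index("probe_id")["delta"]
    rows = []
    for probe in sorted(common):
        if probe not in adi.index or probe not in leu.index:
            raise KeyError(f"no DM record for probe {probe} in both tissues")
        da, dl = float(adi[probe]), float(leu[probe])
        if np.sign(da) == np.sign(dl) != 0:
            rows.append({"probe_id": probe, "delta_adipose": da,
                         "delta_leukocyte": dl,
                         "direction": "hyper" if da > 0 else "hypo"})
    return pd.DataFrame(rows, columns=["probe_id", "delta_adipose",
                                       "delta_leukocyte", "direction"])


def region_filter(candidates: pd.DataFrame, manifest: pd.DataFrame,
                  promoter_regions=PROMOTER_REGIONS,
                  contexts=SIGNATURE_CONTEXTS) -> pd.DataFrame:
    """Keep candidates with >=1 promoter-class gene-region annotation AND a
    CpG context among islands/shores (any-hit rule for multi-annotated
    probes)."""
    if candidates.empty:
        return candidates.copy()
    ann = manifest.set_index("probe_id")
    keep = []
    for probe in candidates["probe_id"]:
        if probe not in ann.index:
            raise KeyError(f"probe {probe} missing from manifest")
        regions = {r for r in str(ann.loc[probe, "gene_regions"]).split(";")
                   if r}
        in_promoter = bool(regions & set(promoter_regions))
        keep.append(in_promoter
                    and ann.loc[probe, "cpg_context"] in set(contexts))
    return candidates.loc[keep].reset_index(drop=True)


def signature_select(candidates: pd.DataFrame,
                     min_abs_delta_each: float = 0.05,
                     similarity_tol: float | None = None) -> pd.DataFrame:
    """Final signature: |delta| strictly greater than the threshold in BOTH
    tissues, optionally with |delta_adipose - delta_leukocyte| within
    ``similarity_tol``."""
    if candidates.empty:
        return candidates.copy()
    keep = ((candidates["delta_adipose"].abs() > min_abs_delta_each)
            & (candidates["delta_leukocyte"].abs() > min_abs_delta_each))
    if similarity_tol is not None:
        keep &= (candidates["delta_adipose"]
                 - candidates["delta_leukocyte"]).abs() <= similarity_tol
    return candidates.loc[keep].reset_index(drop=True)


def venn_counts(dm_adipose, dm_leukocyte, same_direction: pd.DataFrame,
                signature: pd.DataFrame | None = None) -> dict:
    """Summary counts of the overlap analysis (Venn diagram plus the
    direction split of the common CpGs)."""
    a, l = set(dm_adipose), set(dm_leukocyte)
    counts = {
        "adipose_only": len(a - l),
        "leukocyte_only": len(l - a),
        "common": len(a & l),
        "same_direction": int(len(same_direction)),
        "hyper": int((same_direction["direction"] == "hyper").sum())
        if len(same_direction) else 0,
        "hypo": int((same_direction["direction"] == "hypo").sum())
        if len(same_direction) else 0,
    }
    if signature is not None:
        counts["signature"] = int(len(signature))
    return counts


def hierarchical_cluster(beta: pd.DataFrame, k: int = 2) -> dict:
    """Agglomerative clustering of samples on a beta submatrix.

    Euclidean distance, complete linkage; samples are pre-sorted by id so
    the result is invariant to input column order (lexicographic
    tie-break). Returns the dendrogram leaf ordering and a k-cluster cut
    (labels relabelled by first appearance in sorted id order). A constant
    matrix yields a single cluster with a warning.
    """
    if beta.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if beta.shape[0] < 1:
        raise ValueError("need at least 1 probe")
    beta = beta[sorted(beta.columns)]
    x = beta.to_numpy(dtype=float).T

    dists = pdist(x, metric="euclidean")
    if np.allclose(dists, 0.0):
        warnings.warn("constant beta matrix: all samples in one cluster",
                      RuntimeWarning, stacklevel=2)
        return {"sample_order": list(beta.columns),
                "labels": pd.Series(1, index=beta.columns, name="cluster")}

    link = linkage(dists, method="complete")
    order = [beta.columns[i] for i in leaves_list(link)]
    raw = fcluster(link, t=k, criterion="maxclust")
    # stable relabelling: cluster 1 is the one containing the first sample
    relabel: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        labels[i] = relabel[lab]
    return {"sample_order": order,
            "labels": pd.Series(labels, index=beta.columns, name="cluster")}
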