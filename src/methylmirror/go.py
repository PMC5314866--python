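"""Gene-set over-representation by the hypergeometric test.

Differentially methylated probes are mapped to their annotated genes
(union over the semicolon-joined manifest entries), and each gene set is
tested for over-representation of those genes against the analysis
universe — by default all genes mapped by the probes that survived
preprocessing — with an upper-tail hypergeometric p-value P(X >= k),
followed by Benjamini-Hochberg adjustment across the tested terms.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .dm import bh_adjust

__all__ = ["map_probes_to_genes", "hypergeom_enrich"]


def map_probes_to_genes(probes, manifest: pd.DataFrame) -> set[str]:
    """Union of gene names annotated to the given probes (case preserved);
    intergenic probes contribute nothing."""
    ann = manifest.set_index("probe_id")
    missing = set(probes) - set(ann.index)
    if missing:
        raise ValueError(f"unannotated probes: {sorted(missing)[:5]}")
    genes: set[str] = set()
    for field in ann.loc[list(probes), "gene_names"]:
        if field:
            genes.update(g for g in str(field).split(";") if g)
    return genes


def hypergeom_enrich(dm_genes, universe_genes, gene_sets: dict,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per gene set.

    With N universe genes, K of them in the term, and n DM genes of which
    k are in the term, p = P(X >= k) for X hypergeometric(N, K, n). Terms
    with no universe member are skipped; adjusted p is BH over the tested
    terms and ``significant`` flags adjusted p < alpha.
    """
    universe = set(universe_genes)
    dm = set(dm_genes)
    outside = dm - universe
    if outside:
        raise ValueError(f"DM genes outside universe: {sorted(outside)[:5]}")
    n_universe = len(universe)
    n_dm = len(dm)

    rows = []
    for term, members in gene_sets.items():
        in_universe = set(members) & universe
        big_k = len(in_universe)
        if big_k == 0:
            continue
        k = len(in_universe & dm)
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n_dm))
        rows.append({"term": term, "k": k, "K": big_k,
                     "n": n_dm, "N": n_universe, "p_value": min(p, 1.0)})
    result = pd.DataFrame(
        rows, columns=["term", "k", "K", "n", "N", "p_value"])
    if len(result):
        result["adjusted_p"] = bh_adjust(result["p_value"].to_numpy())
        result["significant"] = result["adjusted_p"] < alpha
        result = result.sort_values("p_value", kind="stable",
                                    ignore_index=True)
    else:
        result["adjusted_p"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    return result
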