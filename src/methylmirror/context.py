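"""Genomic-context enrichment of differentially methylated CpGs.

Compares the distribution of a DM set against the analyzed background
along three dimensions — gene region (TSS1500, TSS200, 5'UTR, 1stExon,
Body, 3'UTR, intergenic), CpG-island context (island / shore / shelf /
open sea) and chromosome — and tests each category for over- or
under-representation with a 1-df goodness-of-fit chi-square (observed DM
count in the category versus the count expected from the background
proportion). Per-category tests, rather than one omnibus test, give each
category its own over/under call.

A probe annotated to several gene regions (the usual 450k
multi-transcript case) contributes fractionally, 1/k to each of its k
listed regions, so proportions still sum to one.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["category_distribution", "enrichment_test", "enrich_dimension"]

DIMENSIONS = ("gene_region", "cpg_context", "chromosome")


def _region_weights(regions_field: str) -> dict[str, float]:
    regions = [r for r in str(regions_field).split(";") if r] \
        if regions_field else []
    if not regions:
        return {"intergenic": 1.0}
    w = 1.0 / len(regions)
    out: dict[str, float] = {}
    for r in regions:
        out[r] = out.get(r, 0.0) + w
    return out


def category_distribution(probes, manifest: pd.DataFrame,
                          dimension: str,
                          fractional: bool = True) -> pd.DataFrame:
    """Category counts and proportions of a probe set along one dimension.

    ``dimension`` is one of ``gene_region``, ``cpg_context`` or
    ``chromosome``. For ``gene_region`` with ``fractional=True`` (default)
    multi-annotated probes are attributed 1/k per listed region; with
    ``fractional=False`` a probe counts once in every distinct region it
    lists ("any-hit" counting, so proportions may exceed 1 in total).
    """
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}")
    probes = list(probes)
    ann = manifest.set_index("probe_id")
    missing = set(probes) - set(ann.index)
    if missing:
        raise ValueError(f"unannotated probes: {sorted(missing)[:5]}")
    sub = ann.loc[probes]

    if dimension == "chromosome":
        counts = sub["chromosome"].astype(str).value_counts()
    elif dimension == "cpg_context":
        counts = sub["cpg_context"].value_counts()
    else:
        acc: dict[str, float] = {}
        for field in sub["gene_regions"]:
            weights = _region_weights(field)
            if not fractional:
                weights = {r: 1.0 for r in weights}
            for r, w in weights.items():
                acc[r] = acc.get(r, 0.0) + w
        counts = pd.Series(acc)

    total = len(probes)
    out = pd.DataFrame({"count": counts,
                        "proportion": counts / total if total else counts})
    out.index.name = "category"
    return out.sort_index()


def enrichment_test(dm_counts: pd.Series, background_counts: pd.Series,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Per-category over/under-representation chi-square tests.

    For each category the DM set's observed count is compared with the
    count expected under the background proportion via a binary (in
    category vs not) 1-df goodness-of-fit chi-square. Categories with an
    expected count of zero are skipped with a warning. Direction is
    ``over`` / ``under`` when p < alpha, else ``none``.
    """
    n_dm = float(dm_counts.sum())
    n_bg = float(background_counts.sum())
    if n_dm <= 0 or n_bg <= 0:
        raise ValueError("both count vectors must have positive totals")

    rows = []
    for cat in background_counts.index:
        bg_prop = background_counts[cat] / n_bg
        observed = float(dm_counts.get(cat, 0.0))
        expected = bg_prop * n_dm
        if expected <= 0 or expected >= n_dm:
            warnings.warn(f"category {cat!r}: degenerate expected count, "
                          "skipped", RuntimeWarning, stacklevel=2)
            continue
        chi2 = ((observed - expected) ** 2 / expected
                + ((n_dm - observed) - (n_dm - expected)) ** 2
                / (n_dm - expected))
        p = float(stats.chi2.sf(chi2, df=1))
        if p < alpha:
            direction = "over" if observed > expected else "under"
        else:
            direction = "none"
        rows.append({
            "category": cat,
            "observed": observed,
            "dm_proportion": observed / n_dm,
            "background_proportion": bg_prop,
            "chi_square": float(chi2),
            "p_value": p,
            "direction": direction,
        })
    return pd.DataFrame(rows, columns=[
        "category", "observed", "dm_proportion", "background_proportion",
        "chi_square", "p_value", "direction"])


def enrich_dimension(dm_probes, background_probes, manifest: pd.DataFrame,
                     dimension: str, alpha: float = 0.05) -> pd.DataFrame:
    """Distribution + test in one step for a DM set against its background."""
    dm = category_distribution(dm_probes, manifest, dimension)
    bg = category_distribution(background_probes, manifest, dimension)
    out = enrichment_test(dm["count"], bg["count"], alpha=alpha)
    out.insert(0, "dimension", dimension)
    return out
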