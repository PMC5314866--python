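"""Beta computation and the probe quality-control cascade.

Beta is the methylated fraction M / (M + U + offset); the offset (100 by
default, the platform's customary stabiliser) damps ratios at low total
intensity. Probe exclusion applies, in a fixed order, the filters standard
for obesity-style 450k group comparisons: detection failures, sex-chromosome
probes (group sizes and sex composition differ between groups), probes with
a SNP within 10 bp of the 3' end of the probe, rs control and ch (non-CpG)
probes, and multi-mapping probes. Each probe is charged to the first filter
it hits so the removal report is additive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import AUTOSOMES

__all__ = ["FilterReport", "compute_beta", "filter_probes"]

#: fixed first-match-wins filter order
FILTER_ORDER = ("detection", "chrX", "chrY", "snp10bp", "rs", "ch", "multimap")

_VALID_CHROMS = set(AUTOSOMES) | {"X", "Y"}


@dataclass
class FilterReport:
    """Per-category removal counts for one QC pass."""

    input_probes: int = 0
    removed: dict[str, int] = field(
        default_factory=lambda: {cat: 0 for cat in FILTER_ORDER})
    retained: int = 0

    @property
    def total_removed(self) -> int:
        return sum(self.removed.values())

    def to_dict(self) -> dict:
        return {"input_probes": self.input_probes,
                "removed": dict(self.removed), "retained": self.retained}


def compute_beta(methylated, unmethylated, offset: float = 100.0):
    """Methylation fraction beta = M / (M + U + offset), elementwise.

    Accepts scalars, arrays or aligned DataFrames. Negative intensities are
    rejected; an all-zero denominator yields a missing value (NaN) rather
    than an error, matching how failed probes present on the array.
    """
    if offset < 0:
        raise ValueError("offset must be nonnegative")
    m = np.asarray(methylated, dtype=float)
    u = np.asarray(unmethylated, dtype=float)
    if (m < 0).any() or (u < 0).any():
        raise ValueError("intensities must be nonnegative")
    denom = m + u + offset
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(denom > 0, m / np.where(denom > 0, denom, 1.0), np.nan)
    if isinstance(methylated, pd.DataFrame):
        return pd.DataFrame(beta, index=methylated.index,
                            columns=methylated.columns)
    if np.isscalar(methylated) and np.isscalar(unmethylated):
        return float(beta)
    return beta


def filter_probes(beta: pd.DataFrame, manifest: pd.DataFrame,
                  detection_p: pd.DataFrame | None = None,
                  detection_p_max: float = 0.01,
                  per_sample_masking: bool = False,
                  ) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the probe-exclusion cascade and report per-category counts.

    A probe fails detection if any sample's detection p-value exceeds
    ``detection_p_max`` (probe-level removal; with ``per_sample_masking``
    the failing entries are set to NaN instead and the probe is kept unless
    every sample fails). Removal order is ``FILTER_ORDER`` with
    first-match-wins accounting, so counts plus retained equal the input.
    """
    ann = manifest.set_index("probe_id")
    unknown_probes = beta.index.difference(ann.index)
    if len(unknown_probes):
        raise ValueError(
            f"probes missing from manifest: {list(unknown_probes[:5])}")
    ann = ann.loc[beta.index]
    bad_chrom = ~ann["chromosome"].astype(str).isin(_VALID_CHROMS)
    if bad_chrom.any():
        probe = ann.index[bad_chrom][0]
        raise ValueError(
            f"unknown chromosome {ann.loc[probe, 'chromosome']!r} "
            f"for probe {probe}")

    report = FilterReport(input_probes=len(beta))
    beta = beta.copy()

    if detection_p is not None:
        det = detection_p.reindex(index=beta.index, columns=beta.columns)
        fail = det.to_numpy() > detection_p_max
        if per_sample_masking:
            vals = beta.to_numpy(copy=True)
            vals[fail] = np.nan
            beta = pd.DataFrame(vals, index=beta.index, columns=beta.columns)
            detect_fail = pd.Series(fail.all(axis=1), index=beta.index)
        else:
            detect_fail = pd.Series(fail.any(axis=1), index=beta.index)
    else:
        detect_fail = pd.Series(False, index=beta.index)

    criteria = {
        "detection": detect_fail,
        "chrX": ann["chromosome"].astype(str) == "X",
        "chrY": ann["chromosome"].astype(str) == "Y",
        "snp10bp": ann["snp_within_10bp"].astype(bool),
        "rs": ann["probe_class"] == "rs",
        "ch": ann["probe_class"] == "ch",
        "multimap": ann["multi_mapping"].astype(bool),
    }

    remaining = pd.Series(True, index=beta.index)
    for cat in FILTER_ORDER:
        hit = criteria[cat] & remaining
        report.removed[cat] = int(hit.sum())
        remaining &= ~hit

    filtered = beta.loc[remaining]
    report.retained = len(filtered)
    return filtered, report
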