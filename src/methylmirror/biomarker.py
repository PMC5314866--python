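"""Biomarker evaluation of candidate CpGs.

Tools for judging whether a signature CpG's methylation level works as a
blood-accessible marker of the obesity state: ROC/AUC discrimination
with the clinical efficiency bands, rank-based group comparison, Pearson
correlation with BMI, a gender-adjusted linear association, within-subject
cross-tissue correlation, and methylation-expression correlation against
an external expression table.

The AUC is computed through its rank-sum identity, AUC = U / (n1 * n2)
with ties counting one half, and is auto-oriented to >= 0.5 because a
marker discriminates equally well whether the cases are hyper- or
hypomethylated; the raw orientation is retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .dm import wilcoxon_rank_sum

__all__ = [
    "ROCResult",
    "CorrelationResult",
    "AdjustedAssociation",
    "classify_bmi",
    "roc_auc",
    "simulate_marker_auc",
    "mannwhitney_compare",
    "pearson_corr",
    "adjusted_association",
    "cross_tissue_corr",
    "methylation_expression_corr",
]

#: efficiency bands on 100*AUC: (<20 negligible, 20-40 minimal,
#: 41-60 moderate, 61-80 good, >80 excellent); the open gap (40, 41) is
#: assigned to "moderate".
_BANDS = ((20.0, "negligible"), (40.0, "minimal"), (60.0, "moderate"),
          (80.0, "good"), (float("inf"), "excellent"))


def efficiency_band(auc: float) -> str:
    pct = 100.0 * auc
    if pct < 20.0:
        return "negligible"
    if pct <= 40.0:
        return "minimal"
    if pct <= 60.0:
        return "moderate"
    if pct <= 80.0:
        return "good"
    return "excellent"


@dataclass
class ROCResult:
    auc: float          # oriented to >= 0.5
    raw_auc: float      # case-over-control concordance as given
    p_value: float      # from the equivalent two-sided rank-sum test
    efficiency_band: str


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int


@dataclass
class AdjustedAssociation:
    bmi_slope: float
    bmi_p: float
    gender_coef: float
    gender_p: float
    intercept: float


def classify_bmi(bmi: float) -> dict:
    """Study group and WHO category from body-mass index (kg/m^2).

    The study dichotomy pools overweight with obese: obese if BMI > 25,
    non-obese if BMI <= 25. WHO: <25 normal/under-weight, 25-<30
    overweight, >=30 obese.
    """
    if bmi <= 0:
        raise ValueError("BMI must be positive")
    if bmi < 25.0:
        who = "normal/under-weight"
    elif bmi < 30.0:
        who = "overweight"
    else:
        who = "obese"
    return {"group": "obese" if bmi > 25.0 else "non_obese",
            "who_category": who}


def roc_auc(case, control) -> ROCResult:
    """AUC for discriminating cases from controls on a single marker.

    Computed as the Mann-Whitney U statistic over n1*n2 (ties count 1/2),
    auto-oriented to >= 0.5; the p-value is the two-sided rank-sum test's.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("both classes must be present")
    u = stats.mannwhitneyu(case, control, alternative="two-sided").statistic
    raw = float(u) / (case.size * control.size)
    auc = max(raw, 1.0 - raw)
    p = wilcoxon_rank_sum(case, control)
    return ROCResult(auc=auc, raw_auc=raw, p_value=p,
                     efficiency_band=efficiency_band(auc))


def mannwhitney_compare(group_a, group_b) -> float:
    """Two-sided Mann-Whitney U p-value (identical to the rank-sum core)."""
    return wilcoxon_rank_sum(group_a, group_b)


def pearson_corr(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with its two-sided t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic),
                             p_value=float(res.pvalue), n=int(x.size))


def adjusted_association(beta, bmi, gender) -> AdjustedAssociation:
    """OLS of per-sample methylation on BMI adjusted for gender.

    ``gender`` may be 'F'/'M' labels or a 0/1 indicator. Reports the BMI
    slope and the gender coefficient with their p-values; a rank-deficient
    design is rejected.
    """
    beta = np.asarray(beta, dtype=float)
    bmi = np.asarray(bmi, dtype=float)
    g = np.asarray(gender)
    if not (beta.size == bmi.size == g.size):
        raise ValueError("inputs must have equal length")
    if beta.size <= 3:
        raise ValueError("need more than 3 samples")
    if g.dtype.kind in "UO":
        g = (g == g[0]).astype(float)  # indicator of the first-seen level
    else:
        g = g.astype(float)
    design = sm.add_constant(np.column_stack([bmi, g]), has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear design: BMI and gender are confounded")
    fit = sm.OLS(beta, design).fit()
    return AdjustedAssociation(
        bmi_slope=float(fit.params[1]), bmi_p=float(fit.pvalues[1]),
        gender_coef=float(fit.params[2]), gender_p=float(fit.pvalues[2]),
        intercept=float(fit.params[0]))


def simulate_marker_auc(mean_case: float, sd_case: float, n_case: int,
                        mean_control: float, sd_control: float,
                        n_control: int, n_replicates: int = 1000,
                        seed: int = 0) -> float:
    """Mean discrimination AUC of a single-CpG marker under a binormal model.

    Each replicate draws group beta values from normal distributions with
    the given group means and SDs, truncated to [0, 1], and computes the
    rank-based AUC auto-oriented to >= 0.5. The average over replicates
    estimates the marker's expected discrimination at the given group
    sizes, the standard desk check for published group summaries.
    """
    rng = np.random.default_rng(seed)

    def draw(mean, sd, n):
        a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
        return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n,
                                   random_state=rng)

    aucs = np.empty(n_replicates)
    for i in range(n_replicates):
        aucs[i] = roc_auc(draw(mean_case, sd_case, n_case),
                          draw(mean_control, sd_control, n_control)).auc
    return float(aucs.mean())


def cross_tissue_corr(beta_adipose: pd.DataFrame,
                      beta_leukocyte: pd.DataFrame,
                      subject_of_sample: pd.Series,
                      probes) -> dict[str, CorrelationResult]:
    """Per-probe Pearson correlation between tissues across paired subjects.

    ``subject_of_sample`` maps sample id -> subject id; only subjects with
    a sample in both matrices are used. Probes with fewer than 3 pairs are
    skipped with a warning.
    """
    subj_a = {subject_of_sample[s]: s for s in beta_adipose.columns
              if s in subject_of_sample.index}
    subj_l = {subject_of_sample[s]: s for s in beta_leukocyte.columns
              if s in subject_of_sample.index}
    paired = sorted(set(subj_a) & set(subj_l))
    cols_a = [subj_a[s] for s in paired]
    cols_l = [subj_l[s] for s in paired]

    out: dict[str, CorrelationResult] = {}
    for probe in probes:
        if probe not in beta_adipose.index or probe not in beta_leukocyte.index:
            warnings.warn(f"probe {probe} absent from a tissue matrix, "
                          "skipped", RuntimeWarning, stacklevel=2)
            continue
        xa = beta_adipose.loc[probe, cols_a].to_numpy(dtype=float)
        xl = beta_leukocyte.loc[probe, cols_l].to_numpy(dtype=float)
        ok = ~(np.isnan(xa) | np.isnan(xl))
        if ok.sum() < 3:
            warnings.warn(f"probe {probe}: fewer than 3 paired subjects, "
                          "skipped", RuntimeWarning, stacklevel=2)
            continue
        out[probe] = pearson_corr(xa[ok], xl[ok])
    return out


def methylation_expression_corr(methylation: pd.DataFrame,
                                expression: pd.DataFrame
                                ) -> dict[str, CorrelationResult]:
    """Per-gene Pearson correlation between methylation and expression.

    Both inputs are genes x samples (or genes x group summaries); sample
    columns are matched by name, genes by index. Genes absent from either
    table are skipped; an empty intersection is an error.
    """
    genes = methylation.index.intersection(expression.index)
    if len(genes) == 0:
        raise ValueError("no genes shared between methylation and expression")
    samples = methylation.columns.intersection(expression.columns)
    if len(samples) < 3:
        raise ValueError("need at least 3 shared samples/columns")
    out: dict[str, CorrelationResult] = {}
    skipped = 0
    for gene in genes:
        x = methylation.loc[gene, samples].to_numpy(dtype=float)
        y = expression.loc[gene, samples].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
            skipped += 1
            continue
        out[gene] = pearson_corr(x[ok], y[ok])
    if skipped:
        warnings.warn(f"{skipped} genes skipped (too few values or "
                      "constant)", RuntimeWarning, stacklevel=2)
    return out
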