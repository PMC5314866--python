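# Methods

## The analysis problem

Adipose tissue is the biologically relevant tissue for obesity epigenetics
but requires a biopsy; blood is easy to sample. The question the pipeline
answers is whether a set of CpG sites exists whose methylation change with
obesity is concordant between subcutaneous adipose tissue and circulating
leukocytes — a blood-readable mirror of the adipose state. The design is a
two-group comparison (obese vs non-obese, BMI dichotomized at 25 kg/m²,
overweight pooled with obese) run independently in each tissue, followed by
an intersection-and-filtering cascade and biomarker evaluation of the
surviving CpGs.

## Statistical model and procedure

**Beta values.** Methylation at a CpG is the fraction
β = M/(M + U + offset) ∈ [0, 1] of methylated signal. The offset default is
100, the platform's customary stabiliser against noise-dominated ratios at
low total intensity; offset = 0 is supported. An all-zero denominator
yields a missing value rather than an error.

**Probe QC.** Removal order is fixed: detection failure (any sample with
detection p > 0.01; per-sample masking available behind a flag) →
chromosome X → Y → SNP within 10 bp of the probe 3′ end → rs control
probes → ch (non-CpG) probes → multi-mapping probes. First-match-wins
accounting makes the per-category counts additive: retained + Σremoved =
input, and re-filtering a filtered matrix removes nothing.

**Differential testing.** Per CpG, a two-sided Wilcoxon rank-sum test
between groups. Rank tests are used instead of covariate-adjusted linear
models deliberately: with 8–10 controls, model-based per-probe fits are
fragile, while the rank test is exact-able and robust. The exact null
distribution is used when the pooled sample size is ≤ 12 and there are no
ties; otherwise the normal approximation with tie and continuity
correction. P-values are BH-adjusted; a CpG is called differentially
methylated when q < 0.05 AND |Δβ| ≥ the tissue threshold (0.10 adipose,
0.05 leukocyte; both comparisons configurable, the delta gate inclusive).
Δβ is obese minus non-obese, so "hyper" means higher methylation in
obesity.

**Inflation diagnostic.** λ = median(χ²₁(1−p)) / 0.4549, the median-based
genomic inflation factor, with QQ coordinates (−log₁₀ expected vs observed
p quantiles). On confounder-free data λ ≈ 1; cohort analyses of this
design typically show λ ≫ 1 because cell-type composition is not adjusted
— the diagnostic quantifies that, it does not correct it.

**Context enrichment.** For each category of a dimension (gene region,
CpG-island relation, chromosome), the DM set's observed count is tested
against the count expected from the background proportion with a binary
1-df goodness-of-fit chi-square. Per-category tests (not an omnibus test)
give each category its own over/under call. A probe annotated to k gene
regions contributes 1/k to each (fractional attribution), keeping
proportions normalized; any-hit counting is available behind a flag.

**Signature cascade.** (1) intersect per-tissue DM sets and drop
multi-mapping probes; (2) keep strictly same-sign deltas (a zero delta has
no direction and is excluded); (3) keep probes with at least one promoter
annotation (TSS1500, TSS200, 5′UTR, 1stExon — any-hit across the
semicolon-joined transcript list) and island/shore context; (4) keep
probes with |Δβ| strictly > 0.05 in both tissues. A similarity tolerance
|Δβ_adipose − Δβ_leukocyte| ≤ t is available but unset by default: the
magnitude rule alone defines "similar magnitude", because no tolerance
value is canonical and the both-tissue gate already enforces comparability.
Each stage only removes probes, so stage sizes are monotone and each stage
is idempotent.

**Gene-set enrichment.** Probes map to the union of their annotated genes;
the universe defaults to all genes mapped by QC-surviving probes. Each
term is tested with the upper-tail hypergeometric P(X ≥ k), BH-adjusted
across terms; terms with no universe member are skipped.

**Biomarker evaluation.** AUC is computed through the rank-sum identity
U/(n₁n₂) with ties counting ½, auto-oriented to ≥ 0.5 (a marker
discriminates equally well in either direction; the raw orientation is
retained). The efficiency bands are applied to 100·AUC: < 20 negligible,
20–40 minimal, 41–60 moderate, 61–80 good, > 80 excellent; the open gap
(40, 41) falls to "moderate". The AUC p-value is taken from the equivalent
two-sided rank-sum test rather than a bootstrap. BMI association uses
Pearson correlation and, adjusted for gender, OLS of β on BMI + gender
indicator. Cross-tissue correlation is per-probe Pearson across subjects
sampled in both tissues (≥ 3 pairs required).

## The synthetic cohort generator

The generator emulates the statistical structure of the study, not its
biology:

- **Design**: 45 obese subjects with paired adipose and leukocyte samples;
  independent controls (8 adipose, 10 leukocyte); BMI uniform on
  [26.2, 53.1] (obese) and [20.1, 24.3] (controls), ages 20–83 / 23–79,
  genders balanced. These group sizes and ranges are the study conditions,
  not tuning knobs.
- **Baseline methylation**: per-probe means from a trimodal Beta mixture —
  weights 0.35/0.30/0.35 on Beta(2,20), Beta(5,5), Beta(20,2) (modes near
  0.09/0.50/0.91) — the familiar shape of array beta histograms.
- **Per-sample noise**: Beta(μκ, (1−μ)κ) with concentration κ = 50, giving
  within-group SDs ≈ 0.04–0.10 at typical baselines, matching the
  published group SDs (0.02–0.13).
- **Planted effects**: a logit-scale shift applied to case subjects only,
  which keeps β bounded. Shared-effect probes receive the same-signed
  shift in both tissues; tissue-specific probes in one. When no explicit
  shift is given, it is calibrated by bisection so the mean |Δβ| over
  affected probes equals `target_mean_delta` (default 0.15), accounting
  for the asymmetry of up- vs down-shifts via baseline reflection.
  Effects are planted only on QC-clean probes so the filter cascade cannot
  silently consume them.
- **Artifacts**: manifest category proportions are assigned by largest
  remainder (exact to ±1 probe); blacklist prevalences default to the
  per-category rates observed on the real platform (chrX 2.3%, chrY 0.1%,
  rs 0.02%, ch 0.7%, SNP-adjacent 0.24%), multi-mapping 1% and detection
  failure 1% as round defaults; intensities are drawn so that
  β ≈ M/(M+U+100); detection p is < 0.001 for good probes and > 0.01 in at
  least one sample for planted failures — only the 0.01 threshold matters
  downstream.
- **Determinism**: one RNG stream per component, all seeded from
  `SimConfig.seed`; the resolved logit shift is echoed into the cohort's
  config metadata.

**What the generator does not emulate** — and hence what green tests do
not certify about real data: cell-type heterogeneity (the dominant source
of λ inflation in blood), batch/chip-position effects, Infinium I/II
chemistry differences, probe-probe correlation along the genome, age or
sex effects on methylation, and within-subject cross-tissue correlation
of baselines (tissues are drawn independently, so per-probe cross-tissue r
at null probes is ≈ 0 by construction; published within-subject
correlations of 0.68–0.77 for marker CpGs arise from between-group spread
in real cohorts and are not simulation-recoverable).

## Numerical and design choices

- Exact vs asymptotic rank-sum cutover at pooled n = 12: the largest size
  at which exact enumeration is instantaneous and the approximation is
  still noticeably coarse.
- BH is statsmodels' step-up; it is cross-checked in the test suite
  against a from-definition re-implementation, and the exact rank-sum path
  against full enumeration of all group assignments for sizes ≤ 6.
- Zero p-values entering the inflation diagnostic are clamped to the
  smallest positive float with a warning.
- Hierarchical clustering: Euclidean distance, complete linkage; columns
  are pre-sorted by sample id so results are invariant to input order; a
  constant matrix yields one cluster with a warning.
- FDR thresholds are strict (<), delta thresholds inclusive (≥) at the DM
  stage but strict (>) at the signature magnitude stage; boundary cases
  (e.g. a leukocyte delta of exactly 0.05) are therefore excluded from the
  signature, which the published-table regression fixture pins down.
- Degenerate enrichment categories (expected count 0 or equal to the DM
  total) are skipped with a warning rather than returning NaN statistics.

## Problem sizes used in the checks

The test suite and the acceptance script run on synthetic cohorts of
600–10,000 probes. These sizes were chosen so every property being checked
(FDR control, delta recovery within ±0.03, monotone power, cluster/group
agreement) has comfortable statistical resolution while the whole suite
stays fast; the statistics scale to full 485k arrays unchanged because all
per-probe operations are vectorized.

## Known limitations

- Probe-level detection removal discards a probe failing in any sample;
  with many samples this is conservative (per-sample masking is provided
  but not default).
- The chi-square context test treats fractional gene-region counts as
  ordinary counts; with heavy multi-annotation the effective sample size
  is slightly overstated.
- The gender-adjusted model is a two-covariate OLS on beta values, not a
  methylation-specific variance model; it is meant for the handful of
  signature CpGs, not genome-wide use.
- GO enrichment does no ontology graph propagation; terms are tested as
  flat sets from the GMT file.
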