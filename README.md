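# methylmirror

Cross-tissue DNA-methylation analysis for obesity studies: does the
methylation state of circulating leukocytes *mirror* the obesity-associated
methylation changes of subcutaneous adipose tissue well enough to serve as a
blood-accessible biomarker?

`methylmirror` implements the complete analysis as a tested, reusable Python
pipeline for Illumina 450k-style beta-value data:

1. **Probe QC** — beta computation β = M/(M+U+offset) and the standard
   exclusion cascade (detection p > 0.01, sex chromosomes, SNP-within-10bp,
   rs/ch control probes, multi-mapping probes) with additive per-category
   removal accounting.
2. **Differential methylation** — per-CpG two-sided Wilcoxon rank-sum
   between obese and non-obese groups (chosen over linear models because the
   control groups are tiny, n = 8–10), Benjamini–Hochberg FDR, and a
   per-tissue effect-size gate on Δβ = β̄(obese) − β̄(non-obese)
   (|Δβ| ≥ 0.10 adipose, ≥ 0.05 leukocytes), plus QQ/λ inflation
   diagnostics and global-methylation comparison.
3. **Genomic-context enrichment** — per-category 1-df chi-square tests of
   the DM set against the analyzed background over gene regions, CpG-island
   context and chromosomes.
4. **Cross-tissue signature cascade** — Venn overlap of the two DM sets,
   same-direction filtering, restriction to promoter (TSS1500 / TSS200 /
   5′UTR / 1st exon) island-and-shore CpGs, and a both-tissue magnitude rule
   (|Δβ| > 0.05 in each tissue); hierarchical clustering of samples on the
   significant CpGs.
5. **GO-style gene-set enrichment** — upper-tail hypergeometric
   over-representation with BH adjustment, GMT input.
6. **Biomarker evaluation** — ROC/AUC via the rank-sum identity
   AUC = U/(n₁n₂) with clinical efficiency bands (>80% excellent), Pearson
   correlation with BMI, gender-adjusted OLS association, within-subject
   cross-tissue correlation, and methylation–expression correlation.

Because cohort methylation data of this kind are rarely public, the package
ships a first-class **synthetic 450k generator** (`methylmirror.simulate`)
that emulates the study design — trimodal beta baselines, paired tissues
from the same obese subjects (45 obese vs 8/10 controls), planted
logit-scale effects that are shared-direction across tissues or
tissue-specific, detection failures and all blacklist probe classes — and
records every planted effect in a truth ledger so sensitivity, empirical
FDR and direction accuracy of the full pipeline are measurable.

## Worked example

Run the whole pipeline on a synthetic cohort from the shell:

```sh
methylmirror run-all --seed 7 --out results/run7
head -5 results/run7/summary.txt
```

prints (abridged):

```
methylmirror 0.1.0 pipeline report

adipose: 92 DMCpGs of 9464 tested (47 hyper / 45 hypo), lambda = 1.03
leukocyte: 125 DMCpGs of 9464 tested (58 hyper / 67 hypo), lambda = 1.04
overlap: 60 common, 60 same-direction (25 hyper / 35 hypo), 12 promoter island/shore, 12 in signature
```

Read: of ~9.5k probes surviving QC, 92 adipose and 125 leukocyte CpGs pass
FDR < 0.05 plus the delta gate; 60 are shared, all direction-concordant; 12
sit in promoter islands/shores and pass the magnitude rule in both tissues,
forming the signature. λ ≈ 1 confirms no test-statistic inflation on this
confounder-free synthetic cohort. The report continues with per-CpG AUCs
and the recovery of the planted truth (here: adipose sensitivity 0.61,
leukocyte 0.83, empirical FDR ≤ 0.8%).

The same from Python:

```python
from methylmirror.biomarker import simulate_marker_auc

# expected discrimination of the FGFRL1 promoter CpG, simulating group
# betas from the published summaries (obese 0.24 +/- 0.08 at n=45,
# non-obese 0.36 +/- 0.05 at n=8)
auc = simulate_marker_auc(0.24, 0.08, 45, 0.36, 0.05, 8,
                          n_replicates=1000, seed=20)
print(round(auc, 3))   # 0.896 -> "excellent" efficiency band
```

Each stage is also available as a subcommand over plain-text tables
(`methylmirror simulate | preprocess | dmtest | context-enrich |
cross-tissue | go-enrich | biomarker`); see `--help` on any of them.

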