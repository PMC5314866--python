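"""Synthetic 450k-style methylation cohorts with planted ground truth.

The generator emulates the statistical structure of a two-tissue obesity
methylation study: paired subcutaneous adipose tissue and leukocyte samples
from the same obese subjects (n = 45) plus small, unpaired non-obese control
groups (n = 8 adipose, n = 10 leukocyte). Per-probe baseline methylation is
drawn from a trimodal mixture (hypo-, hemi- and hyper-methylated modes, the
familiar shape of array beta-value histograms); planted case effects are
logit-scale shifts, which keep beta bounded in [0, 1]. Every probe's true
status is recorded in a truth ledger so that downstream differential calls
can be scored for sensitivity, empirical FDR and direction accuracy.

The manifest emulates the 450k annotation dialect: CpG-island relation
(Island / N_Shore / S_Shore / N_Shelf / S_Shelf / OpenSea), semicolon-joined
gene names and gene-region annotations (TSS1500, TSS200, 5'UTR, 1stExon,
Body, 3'UTR), probe classes (cg / rs / ch) and the blacklist flags that the
QC cascade consumes (sex chromosomes, SNP within 10 bp of the 3' end,
multi-mapping probes, detection failures).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "SimConfig",
    "Cohort",
    "TissueData",
    "generate_manifest",
    "generate_cohort",
    "generate_gene_sets",
    "evaluate_recovery",
    "calibrate_logit_shift",
]

CPG_CONTEXTS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")
GENE_REGIONS = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR")
AUTOSOMES = tuple(str(c) for c in range(1, 23))

# Approximate 450k marginal frequencies; promoter-dense chromosomes are
# overrepresented relative to genome length, as on the real array.
_DEFAULT_CONTEXT = {
    "Island": 0.31, "N_Shore": 0.12, "S_Shore": 0.11,
    "N_Shelf": 0.05, "S_Shelf": 0.05, "OpenSea": 0.36,
}
_DEFAULT_REGIONS = {
    "TSS1500": 0.14, "TSS200": 0.10, "5'UTR": 0.12, "1stExon": 0.07,
    "Body": 0.31, "3'UTR": 0.04, "intergenic": 0.22,
}
_DEFAULT_CHROM = {
    "1": 0.096, "2": 0.072, "3": 0.052, "4": 0.041, "5": 0.050,
    "6": 0.075, "7": 0.062, "8": 0.043, "9": 0.041, "10": 0.050,
    "11": 0.059, "12": 0.050, "13": 0.025, "14": 0.031, "15": 0.031,
    "16": 0.045, "17": 0.057, "18": 0.027, "19": 0.053, "20": 0.022,
    "21": 0.013, "22": 0.018,
}
# Flag frequencies mirror the rough per-category prevalence on the platform.
_DEFAULT_BLACKLIST = {
    "chrX": 0.023, "chrY": 0.001, "rs": 0.0002, "ch": 0.007,
    "snp10bp": 0.0024, "multimap": 0.01, "detection_fail": 0.01,
}


@dataclass
class SimConfig:
    """Parameters of a synthetic two-tissue methylation cohort.

    ``effect_size_logit`` is the magnitude of the planted log-odds shift; if
    left ``None`` it is calibrated per cohort so that the mean absolute beta
    difference across affected probes equals ``target_mean_delta``.
    ``fraction_shared_effects`` probes get same-sign shifts in both tissues;
    ``fraction_tissue_specific_effects`` are split evenly between
    adipose-only and leukocyte-only effects.
    """

    n_probes: int = 10_000
    n_case_adipose: int = 45
    n_control_adipose: int = 8
    n_case_leukocyte: int = 45
    n_control_leukocyte: int = 10
    fraction_shared_effects: float = 0.01
    fraction_tissue_specific_effects: float = 0.01
    effect_size_logit: float | None = None
    target_mean_delta: float = 0.15
    # per-sample beta concentration: Var = mu(1-mu)/(kappa+1); kappa = 50
    # gives within-group SDs of roughly 0.04-0.10, matching array replicates
    sample_concentration: float = 50.0
    mixture_weights: tuple[float, float, float] = (0.35, 0.30, 0.35)
    blacklist_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BLACKLIST))
    context_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CONTEXT))
    region_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_REGIONS))
    chromosome_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CHROM))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes <= 0:
            raise ValueError("n_probes must be positive")
        for name in ("n_case_adipose", "n_control_adipose",
                     "n_case_leukocyte", "n_control_leukocyte"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("fraction_shared_effects",
                     "fraction_tissue_specific_effects"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        bl = dict(self.blacklist_fractions)
        unknown = set(bl) - set(_DEFAULT_BLACKLIST)
        if unknown:
            raise ValueError(f"unknown blacklist categories: {sorted(unknown)}")
        for cat, v in bl.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"blacklist fraction {cat} must lie in [0, 1]")
        if sum(bl.values()) > 1.0:
            raise ValueError("blacklist fractions must sum to <= 1")
        has_effects = (self.fraction_shared_effects > 0
                       or self.fraction_tissue_specific_effects > 0)
        if self.effect_size_logit == 0 and has_effects:
            raise ValueError(
                "effect_size_logit = 0 is incompatible with nonzero effect "
                "fractions; use zero fractions for a null cohort")


@dataclass
class TissueData:
    """Per-tissue arrays of one simulated cohort."""

    beta: pd.DataFrame              # probes x samples, values in [0, 1]
    detection_p: pd.DataFrame       # probes x samples
    methylated: pd.DataFrame        # M intensities
    unmethylated: pd.DataFrame      # U intensities


@dataclass
class Cohort:
    manifest: pd.DataFrame
    tissues: dict[str, TissueData]
    sample_sheet: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig

    def write(self, outdir: str | Path) -> None:
        """Write all artifacts as headered UTF-8 text tables."""
        from . import io as mio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mio.write_manifest(self.manifest, outdir / "manifest.csv")
        self.sample_sheet.to_csv(outdir / "sample_sheet.csv", index=False)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        for tissue, data in self.tissues.items():
            mio.write_beta(data.beta, outdir / f"beta_{tissue}.tsv")
            data.detection_p.to_csv(
                outdir / f"detection_{tissue}.tsv", sep="\t",
                index_label="probe_id")


def _largest_remainder_counts(proportions: Mapping[str, float],
                              total: int) -> dict[str, int]:
    """Integer allocation matching each proportion within +-1."""
    labels = list(proportions)
    weights = np.asarray([proportions[c] for c in labels], dtype=float)
    weights = weights / weights.sum()
    raw = weights * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    # distribute the remainder to the largest fractional parts
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:short]] += 1
    return dict(zip(labels, counts))


def _assign_categories(rng: np.random.Generator,
                       proportions: Mapping[str, float],
                       n: int) -> np.ndarray:
    counts = _largest_remainder_counts(proportions, n)
    labels = np.repeat(list(counts), list(counts.values()))
    return rng.permutation(labels)


def generate_manifest(config: SimConfig) -> pd.DataFrame:
    """Generate a deterministic 450k-style probe annotation table.

    Columns: ``probe_id, chromosome, position, gene_names, gene_regions,
    cpg_context, probe_class, snp_within_10bp, multi_mapping,
    detection_fail_planted``. Gene names/regions are semicolon-joined,
    parallel lists; intergenic probes have empty strings. Category
    proportions match the configuration within one probe per category.
    """
    n = config.n_probes
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    bl_counts = _largest_remainder_counts(
        {**config.blacklist_fractions,
         "_clean": 1.0 - sum(config.blacklist_fractions.values())}, n)
    bl_counts.pop("_clean")

    probe_class = np.full(n, "cg", dtype=object)
    snp_flag = np.zeros(n, dtype=bool)
    multimap = np.zeros(n, dtype=bool)
    detection_fail = np.zeros(n, dtype=bool)
    forced_chrom = np.full(n, "", dtype=object)

    # blacklist categories are disjoint by construction
    order = rng.permutation(n)
    pos = 0
    for cat in ("chrX", "chrY", "rs", "ch", "snp10bp", "multimap",
                "detection_fail"):
        k = bl_counts.get(cat, 0)
        idx = order[pos:pos + k]
        pos += k
        if cat == "chrX":
            forced_chrom[idx] = "X"
        elif cat == "chrY":
            forced_chrom[idx] = "Y"
        elif cat in ("rs", "ch"):
            probe_class[idx] = cat
        elif cat == "snp10bp":
            snp_flag[idx] = True
        elif cat == "multimap":
            multimap[idx] = True
        elif cat == "detection_fail":
            detection_fail[idx] = True

    chromosome = _assign_categories(rng, config.chromosome_proportions, n)
    sex = forced_chrom != ""
    chromosome[sex] = forced_chrom[sex]

    context = _assign_categories(rng, config.context_proportions, n)
    region = _assign_categories(rng, config.region_proportions, n)

    # unique 1-based positions per chromosome
    position = np.zeros(n, dtype=np.int64)
    for chrom in np.unique(chromosome):
        mask = chromosome == chrom
        k = int(mask.sum())
        position[mask] = np.sort(
            rng.choice(200_000_000, size=k, replace=False) + 1)

    # gene annotations: genic probes list 1-3 transcript hits of the same
    # gene (the common 450k multi-transcript pattern), occasionally a second
    # gene; region annotations are parallel to the names
    n_genes = max(10, n // 8)
    gene_pool = np.array([f"GENE{i:05d}" for i in range(n_genes)])
    gene_of_probe = rng.integers(0, n_genes, size=n)
    n_hits = rng.integers(1, 4, size=n)
    second_gene = rng.random(n) < 0.10
    genic_regions = [r for r in GENE_REGIONS]

    gene_names = np.full(n, "", dtype=object)
    gene_regions = np.full(n, "", dtype=object)
    for i in range(n):
        if region[i] == "intergenic":
            continue
        names = [gene_pool[gene_of_probe[i]]] * int(n_hits[i])
        regs = [region[i]] * int(n_hits[i])
        if second_gene[i]:
            names.append(gene_pool[(gene_of_probe[i] + 1) % n_genes])
            regs.append(genic_regions[rng.integers(0, len(genic_regions))])
        gene_names[i] = ";".join(names)
        gene_regions[i] = ";".join(regs)

    ids = np.empty(n, dtype=object)
    counters = {"cg": 0, "rs": 0, "ch": 0}
    for i in range(n):
        cls = probe_class[i]
        ids[i] = f"{cls}{counters[cls]:08d}"
        counters[cls] += 1

    manifest = pd.DataFrame({
        "probe_id": ids,
        "chromosome": chromosome,
        "position": position,
        "gene_names": gene_names,
        "gene_regions": gene_regions,
        "cpg_context": context,
        "probe_class": probe_class,
        "snp_within_10bp": snp_flag,
        "multi_mapping": multimap,
        "detection_fail_planted": detection_fail,
    })
    return manifest


def _trimodal_baseline(rng: np.random.Generator, n: int,
                       weights: Sequence[float]) -> np.ndarray:
    """Per-probe baseline methylation from a three-mode Beta mixture."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    comp = rng.choice(3, size=n, p=w)
    mu = np.empty(n)
    # low / mid / high modes (means ~0.09, 0.50, 0.91)
    params = [(2.0, 20.0), (5.0, 5.0), (20.0, 2.0)]
    for c, (a, b) in enumerate(params):
        mask = comp == c
        mu[mask] = rng.beta(a, b, size=int(mask.sum()))
    return np.clip(mu, 1e-4, 1.0 - 1e-4)


def calibrate_logit_shift(baselines: np.ndarray,
                          target_mean_delta: float) -> float:
    """Log-odds shift whose mean absolute beta displacement over the given
    baselines equals ``target_mean_delta``.

    Solved by bisection on s -> mean(|expit(logit(mu) + s) - mu|), which is
    continuous and strictly increasing in s.
    """
    mu = np.asarray(baselines, dtype=float)
    if not 0 < target_mean_delta < 1:
        raise ValueError("target_mean_delta must lie in (0, 1)")

    def mean_delta(s: float) -> float:
        return float(np.mean(np.abs(expit(logit(mu) + s) - mu)))

    hi = 1.0
    while mean_delta(hi) < target_mean_delta:
        hi *= 2.0
        if hi > 64:
            raise ValueError("target_mean_delta unreachable for baselines")
    return float(brentq(lambda s: mean_delta(s) - target_mean_delta, 0.0, hi,
                        xtol=1e-10))


def _sample_betas(rng: np.random.Generator, mu: np.ndarray,
                  kappa: float) -> np.ndarray:
    """Draw probes x samples betas around per-probe, per-sample means."""
    a = np.clip(mu * kappa, 1e-3, None)
    b = np.clip((1.0 - mu) * kappa, 1e-3, None)
    return np.clip(rng.beta(a, b), 0.0, 1.0)


def _intensities(rng: np.random.Generator, beta: np.ndarray,
                 offset: float = 100.0) -> tuple[np.ndarray, np.ndarray]:
    """Nonnegative (M, U) pairs with beta ~= M / (M + U + offset)."""
    total = rng.uniform(2_000.0, 10_000.0, size=beta.shape)
    m = np.clip(beta * (total + offset), 0.0, total)
    u = total - m
    return m, u


def generate_cohort(manifest: pd.DataFrame, config: SimConfig) -> Cohort:
    """Simulate paired-tissue beta matrices, intensities, detection p-values,
    a sample sheet and the planted-effect truth ledger.

    Obese subjects contribute paired adipose and leukocyte samples; control
    groups are independent per tissue. Effects are planted only on clean
    probes (autosomal cg, unflagged, detection-passing) so that the QC
    cascade cannot silently remove them.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = len(manifest)
    probe_ids = manifest["probe_id"].to_numpy()

    clean = ((manifest["probe_class"] == "cg")
             & manifest["chromosome"].isin(AUTOSOMES)
             & ~manifest["snp_within_10bp"]
             & ~manifest["multi_mapping"]
             & ~manifest["detection_fail_planted"]).to_numpy()

    n_shared = int(round(config.fraction_shared_effects * n))
    n_specific = int(round(config.fraction_tissue_specific_effects * n))
    n_eff = n_shared + n_specific
    clean_idx = np.flatnonzero(clean)
    if n_eff > len(clean_idx):
        raise ValueError("not enough clean probes to host planted effects")
    chosen = rng.choice(clean_idx, size=n_eff, replace=False)
    shared_idx = chosen[:n_shared]
    adipose_only = chosen[n_shared:n_shared + n_specific // 2]
    leuko_only = chosen[n_shared + n_specific // 2:]

    mu0 = _trimodal_baseline(rng, n, config.mixture_weights)
    sign = rng.choice([-1.0, 1.0], size=n)

    if config.effect_size_logit is not None:
        shift = float(config.effect_size_logit)
    elif n_eff > 0:
        # a downward logit shift displaces |beta| like an upward shift at
        # the reflected baseline 1 - mu, so calibrate on reflected values
        mu_eff = np.where(sign[chosen] > 0, mu0[chosen], 1.0 - mu0[chosen])
        shift = calibrate_logit_shift(mu_eff, config.target_mean_delta)
    else:
        shift = 0.0
    delta = {"adipose": np.zeros(n), "leukocyte": np.zeros(n)}
    for tissue, idx in (("adipose", np.concatenate([shared_idx, adipose_only])),
                        ("leukocyte", np.concatenate([shared_idx, leuko_only]))):
        idx = idx.astype(int)
        mu_case = expit(logit(mu0[idx]) + sign[idx] * shift)
        delta[tissue][idx] = mu_case - mu0[idx]

    groups = {
        "adipose": (config.n_case_adipose, config.n_control_adipose),
        "leukocyte": (config.n_case_leukocyte, config.n_control_leukocyte),
    }
    n_obese = max(config.n_case_adipose, config.n_case_leukocyte)
    obese_subjects = [f"OB{i + 1:03d}" for i in range(n_obese)]

    # subject covariates shared across tissues for paired obese subjects
    obese_bmi = rng.uniform(26.2, 53.1, size=n_obese)
    obese_age = rng.integers(20, 84, size=n_obese)
    obese_gender = rng.permutation(
        ["F"] * (n_obese // 2) + ["M"] * (n_obese - n_obese // 2))

    fail_probes = manifest["detection_fail_planted"].to_numpy()
    tissues: dict[str, TissueData] = {}
    sheets = []
    for tissue, (n_case, n_ctrl) in groups.items():
        prefix = "A" if tissue == "adipose" else "L"
        case_ids = [f"{prefix}_{s}" for s in obese_subjects[:n_case]]
        ctrl_subjects = [f"N{prefix}{i + 1:03d}" for i in range(n_ctrl)]
        ctrl_ids = [f"{prefix}_{s}" for s in ctrl_subjects]
        samples = case_ids + ctrl_ids

        mu_case = mu0[:, None] + delta[tissue][:, None]
        mu_mat = np.concatenate(
            [np.repeat(mu_case, n_case, axis=1),
             np.repeat(mu0[:, None], n_ctrl, axis=1)], axis=1)
        beta = _sample_betas(rng, np.clip(mu_mat, 1e-4, 1 - 1e-4),
                             config.sample_concentration)

        det = rng.uniform(0.0, 0.001, size=beta.shape) + 1e-12
        if fail_probes.any():
            # each planted-failure probe fails in at least one sample
            fail_rows = np.flatnonzero(fail_probes)
            n_bad = rng.integers(1, beta.shape[1] + 1, size=len(fail_rows))
            for row, k in zip(fail_rows, n_bad):
                cols = rng.choice(beta.shape[1], size=int(k), replace=False)
                det[row, cols] = rng.uniform(0.01 + 1e-9, 1.0, size=int(k))

        m_int, u_int = _intensities(rng, beta)
        tissues[tissue] = TissueData(
            beta=pd.DataFrame(beta, index=probe_ids, columns=samples),
            detection_p=pd.DataFrame(det, index=probe_ids, columns=samples),
            methylated=pd.DataFrame(m_int, index=probe_ids, columns=samples),
            unmethylated=pd.DataFrame(u_int, index=probe_ids, columns=samples),
        )

        ctrl_bmi = rng.uniform(20.1, 24.3, size=n_ctrl)
        ctrl_age = rng.integers(23, 80, size=n_ctrl)
        ctrl_gender = rng.permutation(
            ["F"] * (n_ctrl // 2) + ["M"] * (n_ctrl - n_ctrl // 2))
        sheets.append(pd.DataFrame({
            "sample_id": samples,
            "subject_id": obese_subjects[:n_case] + ctrl_subjects,
            "tissue": tissue,
            "group": ["obese"] * n_case + ["non_obese"] * n_ctrl,
            "bmi": np.round(np.concatenate([obese_bmi[:n_case], ctrl_bmi]), 1),
            "gender": np.concatenate([obese_gender[:n_case], ctrl_gender]),
            "age": np.concatenate([obese_age[:n_case], ctrl_age]),
        }))

    affected_mask = np.zeros(n, dtype=bool)
    affected_mask[chosen] = True
    tissue_label = np.full(n, "", dtype=object)
    tissue_label[shared_idx] = "adipose;leukocyte"
    tissue_label[adipose_only] = "adipose"
    tissue_label[leuko_only] = "leukocyte"
    truth = pd.DataFrame({
        "probe_id": probe_ids,
        "affected_tissues": tissue_label,
        "direction": np.where(affected_mask, np.sign(sign).astype(int), 0),
        "true_delta_adipose": delta["adipose"],
        "true_delta_leukocyte": delta["leukocyte"],
        "is_null": ~affected_mask,
    })

    meta = dataclasses.replace(config, effect_size_logit=shift)
    return Cohort(manifest=manifest, tissues=tissues,
                  sample_sheet=pd.concat(sheets, ignore_index=True),
                  truth=truth, config=meta)


def generate_gene_sets(manifest: pd.DataFrame, n_sets: int = 30,
                       set_size: tuple[int, int] = (10, 80),
                       seed: int = 0) -> dict[str, list[str]]:
    """Random gene sets over the manifest's gene universe, GMT-shaped.

    Used to exercise the over-representation machinery when no curated
    ontology is supplied; terms are labelled as synthetic biological
    processes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    genes = sorted({g for names in manifest["gene_names"] if names
                    for g in names.split(";")})
    if not genes:
        return {}
    sets = {}
    for i in range(n_sets):
        k = int(rng.integers(set_size[0], min(set_size[1], len(genes)) + 1))
        members = sorted(rng.choice(genes, size=k, replace=False))
        sets[f"SYNTH_BP_{i:04d}"] = list(members)
    return sets


def evaluate_recovery(calls: pd.DataFrame, truth: pd.DataFrame,
                      tissue: str) -> dict[str, float]:
    """Score differential calls against the planted truth for one tissue.

    ``calls`` must carry ``probe_id``, a boolean ``significant`` column and a
    ``direction`` column ('hyper'/'hypo'). Returns sensitivity (recall over
    planted effects), empirical FDR with the FP / max(1, calls) convention,
    and direction accuracy among recovered true positives.
    """
    if tissue not in ("adipose", "leukocyte"):
        raise ValueError(f"unknown tissue {tissue!r}")
    call_universe = set(calls["probe_id"])
    truth_universe = set(truth["probe_id"])
    if not call_universe <= truth_universe:
        raise ValueError("calls contain probes absent from the truth ledger")

    truth = truth.set_index("probe_id")
    planted = truth[truth["affected_tissues"].str.contains(tissue, na=False)]
    called = calls.loc[calls["significant"], ["probe_id", "direction"]]

    called_set = set(called["probe_id"])
    tp = called_set & set(planted.index)
    fp = called_set - set(planted.index)

    sensitivity = len(tp) / len(planted) if len(planted) else float("nan")
    fdr = len(fp) / max(1, len(called_set))

    if tp:
        dir_map = dict(zip(called["probe_id"], called["direction"]))
        truth_dir = np.sign(planted[f"true_delta_{tissue}"])
        correct = sum(
            (dir_map[p] == "hyper") == (truth_dir[p] > 0) for p in tp)
        direction_accuracy = correct / len(tp)
    else:
        direction_accuracy = float("nan")

    return {"sensitivity": sensitivity, "empirical_fdr": fdr,
            "direction_accuracy": direction_accuracy,
            "n_called": len(called_set), "n_planted": len(planted)}
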