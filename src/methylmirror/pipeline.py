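"""End-to-end orchestration of the cross-tissue methylation workflow.

Stage order follows the analysis narrative: probe QC per tissue ->
per-CpG differential testing (adipose, then leukocytes, each with its own
delta threshold) -> genomic-context enrichment -> cross-tissue overlap
and signature cascade -> gene-set over-representation -> biomarker
evaluation of the signature CpGs. In synthetic mode the inputs come from
the planted-truth simulator, and the report additionally scores recovery
of the planted effects.

All thresholds, seeds and stage counts are echoed verbatim in the
summary so a run is reproducible from its report alone. Progress is
logged to stderr; results never are.
"""

from __future__ import annotations

import contextlib
import dataclasses
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, biomarker, context, crosstissue, dm, go, preprocess
from .simulate import Cohort, SimConfig, evaluate_recovery, generate_cohort, \
    generate_gene_sets, generate_manifest

__all__ = ["PipelineConfig", "run_pipeline", "write_report"]


@dataclass
class TissueThresholds:
    fdr_max: float = 0.05
    min_abs_delta: float = 0.05

    def __post_init__(self) -> None:
        for name in ("fdr_max", "min_abs_delta"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; defaults encode the study thresholds
    (adipose |delta| >= 0.10, leukocyte >= 0.05, FDR < 0.05, detection
    p <= 0.01, beta offset 100, signature magnitude > 0.05)."""

    adipose: TissueThresholds = field(
        default_factory=lambda: TissueThresholds(0.05, 0.10))
    leukocyte: TissueThresholds = field(
        default_factory=lambda: TissueThresholds(0.05, 0.05))
    detection_p_max: float = 0.01
    beta_offset: float = 100.0
    signature_min_delta: float = 0.05
    similarity_tol: float | None = None
    go_alpha: float = 0.05
    seed: int = 0
    sim: SimConfig | None = None
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.detection_p_max <= 1.0:
            raise ValueError("detection_p_max must lie in (0, 1]")


@contextlib.contextmanager
def _stage(name: str, log):
    t0 = time.perf_counter()
    log(f"[{name}] start")
    try:
        yield
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    log(f"[{name}] done in {time.perf_counter() - t0:.2f}s")


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None
    return obj


def run_pipeline(config: PipelineConfig,
                 cohort: Cohort | None = None,
                 gene_sets: dict | None = None,
                 verbose: bool = True) -> dict:
    """Run all stages and return the machine-readable summary.

    With ``cohort=None`` a synthetic cohort is generated from
    ``config.sim`` (seeded from ``config.seed`` when ``sim`` is not
    given). ``gene_sets`` defaults to synthetic sets over the manifest's
    gene universe.
    """
    log = (lambda msg: print(msg, file=sys.stderr)) if verbose \
        else (lambda msg: None)

    with _stage("inputs", log):
        if cohort is None:
            sim = config.sim or SimConfig(seed=config.seed)
            manifest = generate_manifest(sim)
            cohort = generate_cohort(manifest, sim)
        manifest = cohort.manifest
        if gene_sets is None:
            gene_sets = generate_gene_sets(manifest, seed=config.seed)

    thresholds = {"adipose": config.adipose, "leukocyte": config.leukocyte}
    filtered: dict[str, pd.DataFrame] = {}
    reports: dict[str, dict] = {}
    dm_called: dict[str, pd.DataFrame] = {}
    stage_counts: dict[str, dict] = {}

    with _stage("preprocess", log):
        for tissue, data in cohort.tissues.items():
            fb, rep = preprocess.filter_probes(
                data.beta, manifest, data.detection_p,
                detection_p_max=config.detection_p_max)
            filtered[tissue] = fb
            reports[tissue] = rep.to_dict()

    with _stage("dm_test", log):
        for tissue, fb in filtered.items():
            sheet = cohort.sample_sheet
            mine = sheet[sheet["tissue"] == tissue]
            case = mine.loc[mine["group"] == "obese", "sample_id"]
            ctrl = mine.loc[mine["group"] == "non_obese", "sample_id"]
            table = dm.dm_table(fb, case, ctrl)
            th = thresholds[tissue]
            called = dm.call_dmcpgs(table, th.fdr_max, th.min_abs_delta)
            dm_called[tissue] = called
            ok_p = called["p_value"].dropna()
            infl = dm.inflation_lambda(ok_p.to_numpy()) if len(ok_p) else None
            glob = dm.global_methylation_compare(fb, case, ctrl)
            stage_counts[tissue] = {
                "tested": int(called["p_value"].notna().sum()),
                "dmcpgs": int(called["significant"].sum()),
                "hyper": int((called["significant"]
                              & (called["direction"] == "hyper")).sum()),
                "hypo": int((called["significant"]
                             & (called["direction"] == "hypo")).sum()),
                "lambda": infl.lambda_ if infl else None,
                "global_methylation_p": glob["p_value"],
            }

    with _stage("context_enrichment", log):
        enrichment: dict[str, dict] = {}
        for tissue, called in dm_called.items():
            sig = called.loc[called["significant"], "probe_id"]
            background = filtered[tissue].index
            if len(sig) == 0:
                enrichment[tissue] = {}
                continue
            enrichment[tissue] = {
                dim: context.enrich_dimension(
                    sig, background, manifest, dim).to_dict(orient="records")
                for dim in context.DIMENSIONS}

    with _stage("cross_tissue", log):
        sig_probes = {
            t: set(c.loc[c["significant"], "probe_id"])
            for t, c in dm_called.items()}
        multimap = set(
            manifest.loc[manifest["multi_mapping"], "probe_id"])
        common = crosstissue.overlap_dmcpgs(
            sig_probes["adipose"], sig_probes["leukocyte"], multimap)
        consistent = crosstissue.direction_consistent(
            common, dm_called["adipose"], dm_called["leukocyte"])
        promoter = crosstissue.region_filter(consistent, manifest)
        signature = crosstissue.signature_select(
            promoter, config.signature_min_delta, config.similarity_tol)
        venn = crosstissue.venn_counts(
            sig_probes["adipose"], sig_probes["leukocyte"], consistent,
            signature)
        venn["promoter_island_shore"] = int(len(promoter))

        cluster = {}
        for tissue, called in dm_called.items():
            probes = called.loc[called["significant"], "probe_id"]
            if len(probes) >= 1:
                res = crosstissue.hierarchical_cluster(
                    filtered[tissue].loc[probes])
                cluster[tissue] = {
                    "labels": {s: int(v)
                               for s, v in res["labels"].items()}}

    with _stage("go_enrichment", log):
        universe = go.map_probes_to_genes(filtered["adipose"].index, manifest)
        dm_genes = go.map_probes_to_genes(
            sorted(sig_probes["adipose"]), manifest) & universe
        if dm_genes and gene_sets:
            go_table = go.hypergeom_enrich(dm_genes, universe, gene_sets,
                                           alpha=config.go_alpha)
        else:
            go_table = pd.DataFrame()
        signature_genes = go.map_probes_to_genes(
            signature["probe_id"], manifest) if len(signature) else set()

    with _stage("biomarker_eval", log):
        sheet = cohort.sample_sheet
        biomarkers = []
        subj = sheet.set_index("sample_id")["subject_id"]
        xcorr = {}
        if len(signature):
            probes = list(signature["probe_id"])
            xcorr = biomarker.cross_tissue_corr(
                cohort.tissues["adipose"].beta,
                cohort.tissues["leukocyte"].beta, subj, probes)
        for _, row in signature.iterrows():
            probe = row["probe_id"]
            rec: dict = {"probe_id": probe}
            for tissue in ("adipose", "leukocyte"):
                mine = sheet[sheet["tissue"] == tissue]
                case = mine.loc[mine["group"] == "obese", "sample_id"]
                ctrl = mine.loc[mine["group"] == "non_obese", "sample_id"]
                vals = filtered[tissue].loc[probe]
                roc = biomarker.roc_auc(vals[case], vals[ctrl])
                rec[f"auc_{tissue}"] = roc.auc
                rec[f"auc_band_{tissue}"] = roc.efficiency_band
                rec[f"group_p_{tissue}"] = roc.p_value
                corr = biomarker.pearson_corr(
                    vals[mine["sample_id"]].to_numpy(),
                    mine["bmi"].to_numpy())
                rec[f"bmi_r_{tissue}"] = corr.r
                rec[f"bmi_p_{tissue}"] = corr.p_value
                adj = biomarker.adjusted_association(
                    vals[mine["sample_id"]].to_numpy(),
                    mine["bmi"].to_numpy(), mine["gender"].to_numpy())
                rec[f"bmi_slope_adj_{tissue}"] = adj.bmi_slope
                rec[f"bmi_slope_adj_p_{tissue}"] = adj.bmi_p
            if probe in xcorr:
                rec["cross_tissue_r"] = xcorr[probe].r
                rec["cross_tissue_p"] = xcorr[probe].p_value
            biomarkers.append(rec)

    with _stage("recovery", log):
        recovery = {t: evaluate_recovery(dm_called[t], cohort.truth, t)
                    for t in dm_called}

    summary = {
        "software": {"name": "methylmirror", "version": __version__},
        "config": {
            "seed": config.seed,
            "detection_p_max": config.detection_p_max,
            "beta_offset": config.beta_offset,
            "signature_min_delta": config.signature_min_delta,
            "similarity_tol": config.similarity_tol,
            "thresholds": {t: dataclasses.asdict(th)
                           for t, th in thresholds.items()},
            "sim": dataclasses.asdict(cohort.config),
        },
        "filter_reports": reports,
        "dm": stage_counts,
        "enrichment": enrichment,
        "venn": venn,
        "signature": signature.to_dict(orient="records"),
        "signature_genes": sorted(signature_genes),
        "go_top": go_table.head(10).to_dict(orient="records")
        if len(go_table) else [],
        "go_significant": int(go_table["significant"].sum())
        if len(go_table) else 0,
        "cluster": cluster,
        "biomarkers": biomarkers,
        "recovery": recovery,
    }
    summary = _json_safe(summary)

    if config.outdir is not None:
        write_report(summary, Path(config.outdir))
    return summary


def _render_text(summary: dict) -> str:
    lines = [f"methylmirror {summary['software']['version']} pipeline report",
             ""]
    for tissue, counts in summary["dm"].items():
        lam = counts["lambda"]
        lines.append(
            f"{tissue}: {counts['dmcpgs']} DMCpGs of {counts['tested']} "
            f"tested ({counts['hyper']} hyper / {counts['hypo']} hypo), "
            f"lambda = {lam:.2f}" if lam is not None else
            f"{tissue}: {counts['dmcpgs']} DMCpGs of {counts['tested']} tested")
    venn = summary["venn"]
    lines.append(
        f"overlap: {venn['common']} common, {venn['same_direction']} "
        f"same-direction ({venn['hyper']} hyper / {venn['hypo']} hypo), "
        f"{venn['promoter_island_shore']} promoter island/shore, "
        f"{venn.get('signature', 0)} in signature")
    if summary["signature"]:
        lines.append("signature CpGs:")
        for rec in summary["signature"]:
            lines.append(
                f"  {rec['probe_id']}  dA={rec['delta_adipose']:+.3f}  "
                f"dL={rec['delta_leukocyte']:+.3f}  {rec['direction']}")
    else:
        lines.append("signature: empty")
    for rec in summary["biomarkers"]:
        extra = ""
        if "cross_tissue_r" in rec:
            extra = f"  cross-tissue r={rec['cross_tissue_r']:.2f}"
        lines.append(
            f"  {rec['probe_id']}  AUC(adipose)={rec['auc_adipose']:.2f} "
            f"({rec['auc_band_adipose']})  "
            f"AUC(leukocyte)={rec['auc_leukocyte']:.2f} "
            f"({rec['auc_band_leukocyte']}){extra}")
    if summary.get("recovery"):
        for tissue, rec in summary["recovery"].items():
            sens = rec["sensitivity"]
            fdr = rec["empirical_fdr"]
            lines.append(
                f"recovery {tissue}: sensitivity="
                f"{'NA' if sens is None else format(sens, '.3f')}, "
                f"empirical FDR={'NA' if fdr is None else format(fdr, '.3f')}")
    return "\n".join(lines) + "\n"


def write_report(summary: dict, outdir: str | Path) -> None:
    """Write the JSON summary and a human-readable rendering.

    Missing stages are tolerated: the text report marks the gaps instead
    of failing.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)
    try:
        text = _render_text(summary)
    except KeyError as exc:
        text = (f"partial report: stage output {exc} missing\n"
                + json.dumps({k: summary[k] for k in ("software", "config")
                              if k in summary}, indent=2) + "\n")
    with open(outdir / "summary.txt", "w", encoding="utf-8") as fh:
        fh.write(text)
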