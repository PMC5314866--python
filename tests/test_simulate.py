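"""Synthetic-cohort generator: determinism, marginals, planted truth."""

import numpy as np
import pandas as pd
import pytest

from methylmirror.dm import call_dmcpgs, dm_table
from methylmirror.simulate import (
    SimConfig,
    calibrate_logit_shift,
    evaluate_recovery,
    generate_cohort,
    generate_manifest,
)


def _null_config(**kw):
    defaults = dict(n_probes=1000, seed=5, fraction_shared_effects=0.0,
                    fraction_tissue_specific_effects=0.0)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestConfigValidation:
    def test_rejects_zero_probes(self):
        with pytest.raises(ValueError):
            SimConfig(n_probes=0)

    def test_rejects_zero_shift_with_effects(self):
        with pytest.raises(ValueError, match="effect_size_logit"):
            SimConfig(effect_size_logit=0.0, fraction_shared_effects=0.01)

    def test_rejects_blacklist_oversum(self):
        with pytest.raises(ValueError):
            SimConfig(blacklist_fractions={"chrX": 0.6, "chrY": 0.6})


class TestManifest:
    def test_deterministic_for_fixed_seed(self):
        cfg = SimConfig(n_probes=800, seed=7)
        a = generate_manifest(cfg)
        b = generate_manifest(cfg)
        pd.testing.assert_frame_equal(a, b)
        assert a.to_csv() == b.to_csv()

    def test_zero_blacklist_means_all_clean(self):
        cfg = SimConfig(n_probes=500, seed=3, blacklist_fractions={})
        man = generate_manifest(cfg)
        assert (man["probe_class"] == "cg").all()
        assert not man["snp_within_10bp"].any()
        assert not man["multi_mapping"].any()
        assert not man["chromosome"].isin(["X", "Y"]).any()

    def test_category_proportions_within_one_probe(self):
        cfg = SimConfig(n_probes=1000, seed=9,
                        context_proportions={"Island": 0.3, "OpenSea": 0.7})
        man = generate_manifest(cfg)
        islands = (man["cpg_context"] == "Island").sum()
        assert abs(islands - 300) <= 1

    def test_probe_ids_unique_positions_unique_per_chromosome(self, manifest):
        assert manifest["probe_id"].is_unique
        assert (manifest["position"] >= 1).all()
        for _, sub in manifest.groupby("chromosome"):
            assert sub["position"].is_unique

    def test_gene_annotations_parallel(self, manifest):
        genic = manifest[manifest["gene_names"] != ""]
        for names, regions in zip(genic["gene_names"],
                                  genic["gene_regions"]):
            assert len(names.split(";")) == len(regions.split(";"))


class TestCohort:
    def test_same_seed_identical_beta(self, sim_config, manifest):
        a = generate_cohort(manifest, sim_config)
        b = generate_cohort(manifest, sim_config)
        for tissue in ("adipose", "leukocyte"):
            pd.testing.assert_frame_equal(a.tissues[tissue].beta,
                                          b.tissues[tissue].beta)

    def test_betas_bounded_intensities_nonnegative(self, cohort):
        for data in cohort.tissues.values():
            beta = data.beta.to_numpy()
            assert ((beta >= 0) & (beta <= 1)).all()
            assert (data.methylated.to_numpy() >= 0).all()
            assert (data.unmethylated.to_numpy() >= 0).all()

    def test_intensities_reconstruct_beta(self, cohort):
        data = cohort.tissues["adipose"]
        m = data.methylated.to_numpy()
        u = data.unmethylated.to_numpy()
        approx = m / (m + u + 100.0)
        assert np.abs(approx - data.beta.to_numpy()).max() < 0.11

    def test_group_sizes_match_study_design(self, cohort):
        sheet = cohort.sample_sheet
        sizes = sheet.groupby(["tissue", "group"]).size()
        assert sizes[("adipose", "obese")] == 45
        assert sizes[("adipose", "non_obese")] == 8
        assert sizes[("leukocyte", "obese")] == 45
        assert sizes[("leukocyte", "non_obese")] == 10

    def test_obese_subjects_paired_across_tissues(self, cohort):
        sheet = cohort.sample_sheet
        ob = sheet[sheet["group"] == "obese"]
        adi = set(ob.loc[ob["tissue"] == "adipose", "subject_id"])
        leu = set(ob.loc[ob["tissue"] == "leukocyte", "subject_id"])
        assert adi == leu

    def test_detection_failures_planted(self, cohort):
        fail = cohort.manifest.loc[cohort.manifest["detection_fail_planted"],
                                   "probe_id"]
        det = cohort.tissues["adipose"].detection_p
        assert (det.loc[fail].to_numpy() > 0.01).any(axis=1).all()
        clean = det.drop(index=fail)
        assert (clean.to_numpy() <= 0.01).all()

    def test_shared_effects_same_sign_both_tissues(self, cohort):
        truth = cohort.truth
        shared = truth[truth["affected_tissues"] == "adipose;leukocyte"]
        assert len(shared) > 0
        assert (np.sign(shared["true_delta_adipose"])
                == np.sign(shared["true_delta_leukocyte"])).all()
        nonnull = truth[~truth["is_null"]]
        per_tissue = (nonnull[["true_delta_adipose",
                               "true_delta_leukocyte"]].abs().max(axis=1))
        assert (per_tissue > 0).all()

    def test_truth_covers_manifest_once(self, cohort):
        assert sorted(cohort.truth["probe_id"]) == \
            sorted(cohort.manifest["probe_id"])

    def test_planted_delta_recovered_in_observed_means(self):
        """Observed case-control mean differences track the planted deltas
        (mean |observed - true| within 0.03 at n = 45 vs 10)."""
        cfg = SimConfig(n_probes=4000, seed=21,
                        fraction_shared_effects=0.05,
                        fraction_tissue_specific_effects=0.0,
                        target_mean_delta=0.15)
        cohort = generate_cohort(generate_manifest(cfg), cfg)
        sheet = cohort.sample_sheet
        mine = sheet[sheet["tissue"] == "leukocyte"]
        case = mine.loc[mine["group"] == "obese", "sample_id"]
        ctrl = mine.loc[mine["group"] == "non_obese", "sample_id"]
        beta = cohort.tissues["leukocyte"].beta
        observed = (beta[case].mean(axis=1) - beta[ctrl].mean(axis=1))
        truth = cohort.truth.set_index("probe_id")
        affected = truth[~truth["is_null"]]
        err = (observed[affected.index]
               - affected["true_delta_leukocyte"]).abs()
        assert err.mean() < 0.03
        mean_abs = affected["true_delta_leukocyte"].abs().mean()
        assert abs(mean_abs - 0.15) < 1e-6  # calibration is exact on average

    def test_null_cohort_calibrated_at_alpha(self):
        """With no planted effects ~5% of probes reach p < 0.05."""
        cfg = _null_config(n_probes=2000, seed=13)
        cohort = generate_cohort(generate_manifest(cfg), cfg)
        sheet = cohort.sample_sheet
        mine = sheet[sheet["tissue"] == "adipose"]
        case = mine.loc[mine["group"] == "obese", "sample_id"]
        ctrl = mine.loc[mine["group"] == "non_obese", "sample_id"]
        table = dm_table(cohort.tissues["adipose"].beta, case, ctrl)
        frac = (table["p_value"] < 0.05).mean()
        # binomial SD at n=2000 is ~0.005; allow 4 sigma around 0.05
        assert abs(frac - 0.05) < 0.02

    def test_sensitivity_monotone_in_effect_size(self):
        """DM-calling sensitivity is nondecreasing along a 3-point
        effect-size grid at fixed seeds."""
        sens = []
        for shift in (0.2, 0.5, 1.0):
            cfg = SimConfig(n_probes=1500, seed=31,
                            fraction_shared_effects=0.05,
                            fraction_tissue_specific_effects=0.0,
                            effect_size_logit=shift)
            cohort = generate_cohort(generate_manifest(cfg), cfg)
            sheet = cohort.sample_sheet
            mine = sheet[sheet["tissue"] == "leukocyte"]
            case = mine.loc[mine["group"] == "obese", "sample_id"]
            ctrl = mine.loc[mine["group"] == "non_obese", "sample_id"]
            called = call_dmcpgs(
                dm_table(cohort.tissues["leukocyte"].beta, case, ctrl),
                0.05, 0.05)
            rec = evaluate_recovery(called, cohort.truth, "leukocyte")
            sens.append(rec["sensitivity"])
        assert sens[0] <= sens[1] <= sens[2]
        assert sens[2] > 0.5


class TestCalibration:
    def test_calibrated_shift_hits_target(self):
        rng = np.random.default_rng(0)
        mu = rng.uniform(0.05, 0.95, size=500)
        s = calibrate_logit_shift(mu, 0.15)
        from scipy.special import expit, logit
        achieved = np.abs(expit(logit(mu) + s) - mu).mean()
        assert achieved == pytest.approx(0.15, abs=1e-6)

    def test_unreachable_target_rejected(self):
        with pytest.raises(ValueError):
            calibrate_logit_shift(np.array([0.5]), 1.5)


class TestRecovery:
    def _calls(self, probes, significant, direction="hyper"):
        return pd.DataFrame({
            "probe_id": probes,
            "significant": significant,
            "direction": [direction] * len(probes),
        })

    def _truth(self, planted, nulls):
        probes = planted + nulls
        return pd.DataFrame({
            "probe_id": probes,
            "affected_tissues": ["adipose"] * len(planted)
            + [""] * len(nulls),
            "direction": [1] * len(planted) + [0] * len(nulls),
            "true_delta_adipose": [0.1] * len(planted) + [0.0] * len(nulls),
            "true_delta_leukocyte": 0.0,
            "is_null": [False] * len(planted) + [True] * len(nulls),
        })

    def test_perfect_calls(self):
        truth = self._truth(["a", "b"], ["c", "d"])
        calls = self._calls(["a", "b", "c", "d"],
                            [True, True, False, False])
        rec = evaluate_recovery(calls, truth, "adipose")
        assert rec["sensitivity"] == 1.0
        assert rec["empirical_fdr"] == 0.0
        assert rec["direction_accuracy"] == 1.0

    def test_zero_calls_zero_fdr_by_convention(self):
        truth = self._truth(["a"], ["b"])
        calls = self._calls(["a", "b"], [False, False])
        rec = evaluate_recovery(calls, truth, "adipose")
        assert rec["sensitivity"] == 0.0
        assert rec["empirical_fdr"] == 0.0

    def test_fdr_counts_null_calls(self):
        truth = self._truth(["a", "b"], ["c", "d", "e"])
        calls = self._calls(["a", "b", "c", "d"],
                            [True, True, True, True])
        rec = evaluate_recovery(calls, truth, "adipose")
        assert rec["empirical_fdr"] == pytest.approx(2 / 4)

    def test_disjoint_universe_rejected(self):
        truth = self._truth(["a"], ["b"])
        calls = self._calls(["z"], [True])
        with pytest.raises(ValueError):
            evaluate_recovery(calls, truth, "adipose")
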