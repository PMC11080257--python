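"""Group statistics: exact small-sample tests, regressions, voxelwise map."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from csfmotion import (CohortConfig, chi_squared_test, cohort_report,
                       covariate_regression, rank_sum_test,
                       simulate_cohort_table, spearman_corr,
                       voxelwise_group_map)
from csfmotion.errors import CSFMotionError
from oracle_helpers import brute_force_ranksum_p, brute_force_spearman


class TestRankSum:
    def test_identical_samples_give_p_one(self):
        res = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0

    def test_fully_separated_samples(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)  # 2/20 assignments as extreme
        assert "exact" in res.method

    def test_degenerate_constant_samples(self):
        res = rank_sum_test([5.0, 5.0], [5.0, 5.0, 5.0])
        assert res.degenerate and res.p_value == 1.0

    @pytest.mark.parametrize("x,y", [
        ([1, 5, 2], [3, 4]),
        ([1.5, 1.5, 2.0], [1.5, 3.0, 0.5]),     # ties across groups
        ([10, 20, 30, 40], [15, 25, 35, 45]),
        ([0, 0, 1], [0, 1, 1, 2]),
    ])
    def test_exact_path_matches_enumeration(self, x, y):
        res = rank_sum_test(x, y)
        assert res.p_value == pytest.approx(brute_force_ranksum_p(x, y), abs=1e-12)

    def test_large_sample_matches_scipy_asymptotic(self, rng):
        x = rng.normal(0, 1, 20)
        y = rng.normal(0.5, 1, 18)
        res = rank_sum_test(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_large_sample_with_ties_matches_scipy(self, rng):
        x = rng.integers(0, 4, 16).astype(float)
        y = rng.integers(0, 4, 15).astype(float)
        res = rank_sum_test(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)


class TestChiSquared:
    def test_identical_distributions(self):
        res = chi_squared_test([[5, 5], [5, 5]])
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_fully_dependent_table(self):
        res = chi_squared_test([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0)

    def test_zero_margin_flagged(self):
        res = chi_squared_test([[3, 0], [5, 0]])
        assert res.degenerate

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_test([[1.5, 2], [3, 4]])


class TestSpearman:
    def test_monotone_pairs(self):
        up = spearman_corr([1, 2, 3, 4], [10, 20, 30, 40])
        assert up.statistic == pytest.approx(1.0)
        down = spearman_corr([1, 2, 3, 4], [4, 3, 2, 1])
        assert down.statistic == pytest.approx(-1.0)

    def test_small_sample_matches_enumeration(self):
        x, y = (1, 2, 3, 4), (2, 1, 4, 3)
        res = spearman_corr(x, y)
        r_ref, p_ref = brute_force_spearman(x, y)
        assert res.statistic == pytest.approx(r_ref)   # r = 0.6
        assert res.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_zero_variance_flagged(self):
        res = spearman_corr([1.0, 1.0, 1.0], [1, 2, 3])
        assert res.degenerate and np.isnan(res.statistic)

    def test_large_sample_matches_scipy_t_approximation(self, rng):
        x = rng.normal(size=25)
        y = 0.4 * x + rng.normal(size=25)
        res = spearman_corr(x, y)
        ref = sps.spearmanr(x, y)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestCovariateRegression:
    def test_constant_dependent_gives_zero_slopes(self):
        cov = pd.DataFrame({"age": [60, 65, 70, 75, 80.0],
                            "group": ["control", "pd"] * 2 + ["control"]})
        out = covariate_regression([3.0] * 5, cov)
        assert np.allclose(out["coef"], 0.0, atol=1e-12)

    def test_exact_line_recovered(self):
        age = np.array([60, 62, 65, 70, 72, 75.0])
        out = covariate_regression(2.0 * age, pd.DataFrame({"age": age}))
        row = out.iloc[0]
        assert row["coef"] == pytest.approx(2.0)
        assert row["p_value"] < 1e-10

    def test_null_age_effect_calibrated(self, rng):
        rejections = 0
        reps = 400
        for _ in range(reps):
            age = rng.normal(67, 8, 30)
            y = rng.normal(0.006, 0.002, 30)      # independent of age
            out = covariate_regression(y, pd.DataFrame({"age": age}))
            rejections += out.iloc[0]["p_value"] < 0.05
        assert 0.02 <= rejections / reps <= 0.09

    def test_combined_model_and_rank_deficiency(self):
        cov = pd.DataFrame({"age": [60, 62, 65, 70, 72, 75.0, 68, 61],
                            "sex": list("MFMFMFMF")})
        y = np.arange(8, dtype=float)
        out = covariate_regression(y, cov, combined=True)
        assert set(out["model"]) == {"separate:age", "separate:sex", "combined"}
        bad = cov.copy()
        bad["age2"] = bad["age"]
        with pytest.raises(CSFMotionError):
            covariate_regression(y, bad, combined=True)


class TestVoxelwiseGroupMap:
    def _maps(self, rng, n1=10, n2=10, shape=(6, 6, 4), effect=0.0,
              effect_box=None):
        maps = rng.normal(0.006, 0.001, (n1 + n2,) + shape)
        if effect and effect_box is not None:
            sl = tuple(slice(*b) for b in effect_box)
            maps[(slice(n1, None),) + sl] -= effect
        groups = ["control"] * n1 + ["pd"] * n2
        return maps, np.asarray(groups)

    def test_planted_difference_localizes(self, rng):
        box = ((1, 4), (1, 4), (0, 2))
        maps, groups = self._maps(rng, n1=16, n2=16, effect=0.004,
                                  effect_box=box)
        roi = np.ones(maps.shape[1:], bool)
        cmap = voxelwise_group_map(maps, groups, roi, alpha_fdr=0.10)
        assert cmap.n_clusters >= 1
        inside = np.zeros(maps.shape[1:], bool)
        inside[1:4, 1:4, 0:2] = True
        assert ((cmap.label_volume > 0) & ~inside).sum() == 0

    def test_min_extent_filters_small_clusters(self, rng):
        box = ((1, 3), (1, 3), (0, 1))
        maps, groups = self._maps(rng, n1=16, n2=16, effect=0.004,
                                  effect_box=box)
        roi = np.ones(maps.shape[1:], bool)
        cmap = voxelwise_group_map(maps, groups, roi, min_extent=100)
        assert cmap.n_clusters == 0

    def test_null_map_runs_clean(self, rng):
        maps, groups = self._maps(rng)
        cmap = voxelwise_group_map(maps, groups, np.ones(maps.shape[1:], bool))
        assert cmap.label_volume.shape == maps.shape[1:]

    def test_validation(self, rng):
        maps, groups = self._maps(rng)
        with pytest.raises(ValueError):
            voxelwise_group_map(maps, ["a"] * 20, np.ones(maps.shape[1:], bool))
        with pytest.raises(ValueError):
            voxelwise_group_map(maps[:3], ["a", "a", "b"],
                                np.ones(maps.shape[1:], bool))


class TestCohortReport:
    def _measured_table(self, seed=5):
        t = simulate_cohort_table(CohortConfig(seed=seed))
        t = t.rename(columns={"true_perfusion": "perfusion"})
        t["D_suprasellar_csf"] = t["true_D_suprasellar"]
        for cls in ("ventricular_csf", "gray_matter", "white_matter", "optic_nerve"):
            t[f"D_{cls}"] = t[f"true_D_{cls}"]
        return t

    def test_all_measure_rows_present(self):
        report, text = cohort_report(self._measured_table())
        measures = set(report["measure"])
        for m in ("N", "age_years", "sex", "moca", "updrs_pd_only",
                  "decay_rate_ventricular_csf", "decay_rate_gray_matter",
                  "decay_rate_white_matter", "decay_rate_suprasellar_csf",
                  "decay_rate_optic_nerve", "choroid_plexus_perfusion",
                  "spearman_perfusion_vs_D_pooled"):
            assert m in measures
        assert "decay_rate_suprasellar_csf" in text

    def test_group_means_near_generator_truth(self):
        # sampling-theory check: group mean within ~2 SE of the generating mean
        report, _ = cohort_report(self._measured_table(seed=5))
        row = report.set_index("measure").loc["decay_rate_suprasellar_csf"]
        se_c = 0.00213 / np.sqrt(32)
        se_p = 0.00110 / np.sqrt(27)
        assert abs(row["control_mean"] - 0.00673) < 2.5 * se_c
        assert abs(row["pd_mean"] - 0.00517) < 2.5 * se_p

    def test_empty_group_marked(self):
        t = self._measured_table()
        t = t[t["group"] == "pd"].reset_index(drop=True)
        report, _ = cohort_report(t)
        row = report.set_index("measure").loc["age_years"]
        assert np.isnan(row["control_mean"]) and np.isnan(row["p_value"])

    def test_stratified_correlation_rows(self):
        report, _ = cohort_report(self._measured_table(),
                                  stratified_correlation=True)
        measures = set(report["measure"])
        assert {"spearman_perfusion_vs_D_control",
                "spearman_perfusion_vs_D_pd"} <= measures
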