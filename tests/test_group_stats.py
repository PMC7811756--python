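import numpy as np
import pandas as pd
import pytest

from bandspect import datasets
from bandspect.group_stats import (
    DesignSpec,
    adjust_covariate,
    cohen_d,
    cohen_d_from_data,
    correlate,
    correlate_interictal,
    describe,
    mann_whitney,
    pca_summary,
    permutation_cluster_test,
    pseudo_t_map,
    relative_mask,
    tfce_map,
)


class TestRelativeMask:
    def test_uniform_maps_keep_everything(self):
        maps = [np.ones((4, 4, 4))] * 3
        assert relative_mask(maps).all()

    def test_two_valued_image_keeps_high_voxels(self):
        img = np.full((10, 10, 10), 1.0)
        img[0] = 0.1  # 10% low voxels; grand mean 0.91, cut 0.728
        mask = relative_mask([img])
        assert mask[1:].all() and not mask[0].any()

    def test_threshold_zero_keeps_positive_voxels(self):
        img = np.zeros((3, 3, 3))
        img[1] = 2.0
        mask = relative_mask([img], threshold=0.0)
        assert mask.sum() == 9


class TestPseudoT:
    def test_swapping_groups_negates_map(self):
        rng = np.random.default_rng(0)
        maps = [1.0 + rng.random((8, 8, 8)) for _ in range(10)]
        mask = np.ones((8, 8, 8), bool)
        t_ab = pseudo_t_map(maps[:5], maps[5:], fwhm_mm=8.0, voxel_size_mm=3.0,
                            mask=mask)
        t_ba = pseudo_t_map(maps[5:], maps[:5], fwhm_mm=8.0, voxel_size_mm=3.0,
                            mask=mask)
        np.testing.assert_allclose(t_ba, -t_ab, atol=1e-10)

    def test_fwhm_zero_matches_classic_ancova_t(self):
        """Without variance smoothing the pseudo-T equals the ordinary
        covariate-adjusted two-sample t statistic, voxel by voxel."""
        rng = np.random.default_rng(1)
        n_a, n_b = 8, 12
        shape = (5, 5, 5)
        cov = rng.normal(size=n_a + n_b)
        maps = [rng.normal(size=shape) + 0.5 * c for c in cov]
        mask = np.ones(shape, bool)
        t = pseudo_t_map(maps[:n_a], maps[n_a:], covariate=cov, fwhm_mm=0.0,
                         voxel_size_mm=3.0, mask=mask)

        # oracle: per-voxel OLS with parameter covariance
        y = np.stack([m.ravel() for m in maps])
        x = np.column_stack(
            [np.ones(n_a + n_b), [1] * n_a + [0] * n_b, cov - cov.mean()]
        )
        expected = np.empty(y.shape[1])
        xtx_inv = np.linalg.inv(x.T @ x)
        for v in range(y.shape[1]):
            beta, res, *_ = np.linalg.lstsq(x, y[:, v], rcond=None)
            sigma2 = res[0] / (x.shape[0] - 3)
            expected[v] = beta[1] / np.sqrt(sigma2 * xtx_inv[1, 1])
        np.testing.assert_allclose(t.ravel(), expected, rtol=1e-8)

    def test_single_case_statistic_finite(self):
        rng = np.random.default_rng(2)
        shape = (6, 6, 6)
        controls = [1.0 + rng.normal(size=shape) * 0.1 for _ in range(23)]
        case = 1.5 + rng.normal(size=shape) * 0.1
        mask = np.ones(shape, bool)
        t = pseudo_t_map([case], controls, fwhm_mm=8.0, voxel_size_mm=3.0, mask=mask)
        assert np.all(np.isfinite(t[mask]))
        assert t[mask].mean() > 0

    def test_group_size_requirements(self):
        maps = [np.ones((3, 3, 3))] * 3
        with pytest.raises(ValueError):
            pseudo_t_map([], maps, mask=np.ones((3, 3, 3), bool))


class TestPermutationClusterTest:
    def test_single_case_enumerates_24_relabelings(self):
        """1-versus-23 design: all 24 distinct relabelings, so the minimum
        attainable corrected p is 1/24."""
        rng = np.random.default_rng(3)
        shape = (6, 6, 6)
        mask = np.ones(shape, bool)
        maps = [1.0 + 0.1 * rng.normal(size=shape) for _ in range(24)]
        res = permutation_cluster_test(
            maps[:1], maps[1:], DesignSpec(n_permutations=500, seed=0), mask=mask
        )
        assert res.n_null == 23
        assert res.min_attainable_p == pytest.approx(1 / 24)

    def test_planted_effect_detected_with_valid_p(self):
        rng = np.random.default_rng(4)
        shape = (10, 10, 10)
        mask = np.ones(shape, bool)
        effect = np.zeros(shape)
        effect[3:7, 3:7, 3:7] = 1.5
        maps_a = [1.0 + effect + 0.2 * rng.normal(size=shape) for _ in range(9)]
        maps_b = [1.0 + 0.2 * rng.normal(size=shape) for _ in range(12)]
        res = permutation_cluster_test(
            maps_a, maps_b, DesignSpec(n_permutations=200, seed=1), mask=mask
        )
        sig = res.significant()
        assert len(sig) >= 1
        peak = sig.iloc[0]
        assert effect[int(peak.peak_i), int(peak.peak_j), int(peak.peak_k)] > 0

    def test_few_relabelings_warns_on_granularity(self):
        rng = np.random.default_rng(5)
        shape = (4, 4, 4)
        maps = [rng.normal(size=shape) for _ in range(6)]
        with pytest.warns(UserWarning, match="granularity"):
            permutation_cluster_test(
                maps[:1], maps[1:], DesignSpec(n_permutations=100),
                mask=np.ones(shape, bool),
            )


class TestTfce:
    def test_zero_map_stays_zero(self):
        assert np.all(tfce_map(np.zeros((5, 5, 5))) == 0)

    def test_single_voxel_spike_matches_hand_computed_sum(self):
        vol = np.zeros((7, 7, 7))
        vol[3, 3, 3] = 1.0
        dh = 0.1
        got = tfce_map(vol, dh=dh)[3, 3, 3]
        hs = np.arange(dh, 1.0 + dh / 2, dh)
        expected = np.sum(1.0**0.5 * hs**2 * dh)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_larger_blob_enhanced_more_than_smaller(self):
        vol = np.zeros((20, 10, 10))
        vol[2:4, 4:6, 4:6] = 2.0      # small blob
        vol[12:17, 3:8, 3:8] = 2.0    # large blob, same height
        out = tfce_map(vol)
        assert out[14, 5, 5] > out[2, 4, 4]


class TestAdjustCovariate:
    def test_uncorrelated_balanced_covariate_keeps_raw_means(self):
        rng = np.random.default_rng(6)
        groups = np.array(["a"] * 20 + ["b"] * 20)
        cov = np.tile(rng.normal(size=20), 2)  # identical across groups
        values = np.where(groups == "a", 5.0, 7.0)
        adj = adjust_covariate(values, cov, groups)
        assert adj.emm["a"] == pytest.approx(5.0, abs=1e-9)
        assert adj.emm["b"] == pytest.approx(7.0, abs=1e-9)

    def test_pure_covariate_effect_removed(self):
        cov = np.linspace(0, 10, 12)
        values = 2.0 * cov
        groups = np.array(["a", "b"] * 6)
        adj = adjust_covariate(values, cov, groups)
        assert np.allclose(adj.residuals, adj.residuals.mean())
        assert adj.emm["a"] == pytest.approx(adj.emm["b"])
        assert adj.slope == pytest.approx(2.0)

    def test_known_offsets_recovered(self):
        rng = np.random.default_rng(7)
        cov = rng.normal(size=30)
        groups = np.array(["a"] * 15 + ["b"] * 15)
        values = 1.0 + 3.0 * cov + np.where(groups == "b", 2.5, 0.0)
        adj = adjust_covariate(values, cov, groups)
        assert adj.emm["b"] - adj.emm["a"] == pytest.approx(2.5, abs=1e-9)

    def test_constant_covariate_pins_slope(self):
        values = np.array([1.0, 2.0, 3.0, 4.0])
        adj = adjust_covariate(values, np.ones(4), np.array(["a", "a", "b", "b"]))
        assert adj.slope == 0.0
        np.testing.assert_array_equal(adj.residuals, values)


class TestMannWhitney:
    def test_complete_separation_exact_p(self):
        u, p = mann_whitney([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 * 1/C(6,3)

    def test_identical_samples_give_central_u(self):
        x = np.arange(10.0)
        u, p = mann_whitney(x, x + 0.0)
        assert u == pytest.approx(50.0)  # n_x * n_y / 2
        assert p > 0.9

    def test_exact_and_normal_agree_at_moderate_n(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=10)
        y = rng.normal(0.5, 1.0, size=10)
        from scipy import stats

        _, p_exact = mann_whitney(x, y)
        p_norm = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic"
        ).pvalue
        assert abs(p_exact - p_norm) < 0.01


class TestCohenD:
    def test_reference_memory_effect_sizes(self):
        """Published marginal means reproduce the printed effect sizes for
        the two verbal subtests (to the printed 1 decimal place)."""
        tle, ctl, sd = datasets.MEMORY_MARGINALS["list_learning"]
        assert round(cohen_d(ctl, tle, sd), 1) == 1.4
        tle, ctl, sd = datasets.MEMORY_MARGINALS["list_recall"]
        assert round(cohen_d(ctl, tle, sd), 1) == 1.3

    def test_equal_means_give_zero(self):
        assert cohen_d(3.0, 3.0, 1.0) == 0.0

    def test_pooled_sd_variant(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([4.0, 5.0, 6.0])
        assert cohen_d_from_data(x, y) == pytest.approx(-3.0)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            cohen_d(1.0, 0.0, 0.0)


class TestPcaSummary:
    def test_identical_columns_return_shared_z_score(self):
        rng = np.random.default_rng(9)
        col = rng.normal(size=20)
        scores = pd.DataFrame({f"s{k}": col for k in range(4)})
        age = rng.normal(45, 5, 20)
        comp, loadings = pca_summary(scores, age)
        # oracle: age-regress the shared column, then standardize
        x = np.column_stack([np.ones(20), age - age.mean()])
        beta, *_ = np.linalg.lstsq(x, col, rcond=None)
        resid = col - x @ beta
        z = resid / resid.std(ddof=1)
        np.testing.assert_allclose(comp, z, atol=1e-9)
        assert np.all(loadings >= 0)

    def test_dominant_factor_recovered(self):
        rng = np.random.default_rng(10)
        f = rng.normal(size=50)
        scores = pd.DataFrame(
            {f"s{k}": 2.0 * f + 0.4 * rng.normal(size=50) for k in range(4)}
        )
        comp, loadings = pca_summary(scores, rng.normal(45, 8, 50))
        assert np.corrcoef(comp, f)[0, 1] > 0.95
        assert comp.std(ddof=1) == pytest.approx(1.0)

    def test_invariant_to_column_order(self):
        rng = np.random.default_rng(11)
        f = rng.normal(size=30)
        cols = {f"s{k}": (k + 1) * f + 0.3 * rng.normal(size=30) for k in range(4)}
        age = rng.normal(45, 8, 30)
        a, _ = pca_summary(pd.DataFrame(cols), age)
        b, _ = pca_summary(pd.DataFrame({k: cols[k] for k in reversed(cols)}), age)
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestCorrelate:
    def test_perfect_negative_relation(self):
        x = np.arange(10.0)
        r_p, _ = correlate(x, -x, "pearson")
        r_s, _ = correlate(x, -x, "spearman")
        assert r_p == pytest.approx(-1.0)
        assert r_s == pytest.approx(-1.0)

    def test_monotone_nonlinear_relation(self):
        x = np.linspace(0, 5, 20)
        y = np.exp(x)
        r_s, _ = correlate(x, y, "spearman")
        r_p, _ = correlate(x, y, "pearson")
        assert r_s == pytest.approx(1.0)
        assert r_p < 1.0

    def test_interictal_transform_requires_positive_intervals(self):
        with pytest.raises(ValueError):
            correlate_interictal([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])


class TestDescribe:
    def test_reference_cohort_descriptives(self):
        """Median/IQR of the reference clinical columns match their printed
        summary row under the interpolated-quartile rule."""
        tab = datasets.load_tle_cohort()
        # (printed median, printed IQR, printed decimal places); the
        # computed value must round to the printed one, i.e. agree within
        # half a unit at the printed precision
        checks = {
            "global_total_vt": (2.98, 0.42, 2),
            "hippocampal_volume_left_mm3": (2010.0, 370.0, 0),
            "hippocampal_volume_right_mm3": (2037.0, 378.0, 0),
            "amipb_summary": (0.11, 1.78, 2),
            "interictal_interval_days": (6.0, 25.0, 0),
            "duration_years": (20.0, 19.5, 1),
            "age": (40.0, 7.5, 1),
        }
        for col, (med, iqr, dp) in checks.items():
            got_med, got_iqr = describe(tab[col].to_numpy())
            half_unit = 0.5 * 10.0**-dp + 1e-12
            assert abs(got_med - med) <= half_unit, col
            assert abs(got_iqr - iqr) <= half_unit, col

    def test_simple_sequence(self):
        med, iqr = describe([1, 2, 3, 4, 5])
        assert med == 3.0 and iqr == 2.0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            describe([1.0])
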