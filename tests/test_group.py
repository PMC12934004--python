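import numpy as np
import pytest

from reactfc.group import (
    ConnectivityMap,
    PermutationClusterFWE,
    extract_cluster_effects,
    format_z,
    group_t_map,
    roi_effect_correlation,
    session_contrast,
    t_to_z,
    threshold_clusters,
)
from reactfc.synth import SynthConfig, build_cohort_truth, simulate_group_contrasts


def _cmap(subject, session, data, target="dat"):
    return ConnectivityMap(subject, session, target, np.asarray(data, float))


class TestSessionContrast:
    def test_identical_maps_zero(self, rng):
        m = rng.standard_normal((4, 4, 2))
        out = session_contrast(_cmap("s1", "drug", m), _cmap("s1", "placebo", m))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_additive_shift_recovered(self, rng):
        base = rng.standard_normal((4, 4, 2))
        shift = np.zeros((4, 4, 2))
        shift[1:3, 1:3, :] = 0.5
        out = session_contrast(
            _cmap("s1", "drug", base + shift), _cmap("s1", "placebo", base)
        )
        np.testing.assert_allclose(out.data, shift, atol=1e-12)

    def test_subject_mismatch_rejected(self, rng):
        m = rng.standard_normal((2, 2, 2))
        with pytest.raises(ValueError, match="subject"):
            session_contrast(_cmap("s1", "drug", m), _cmap("s2", "placebo", m))


class TestGroupTMap:
    def test_one_sample_closed_form(self):
        data = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1, 1)
        t, df, sat = group_t_map(data)
        assert t[0, 0, 0] == pytest.approx(3.4641, abs=1e-4)
        assert df == 2
        assert not sat.any()

    def test_noiseless_covariate_slope_saturates(self):
        ki = np.array([0.008, 0.010, 0.012, 0.014])
        data = (2.0 + 5.0 * (ki - ki.mean())).reshape(4, 1, 1, 1)
        t, df, sat = group_t_map(data, covariate=ki)
        assert df == 2
        assert sat[0, 0, 0]
        assert np.isfinite(t[0, 0, 0])  # sentinel, never a non-finite number

    def test_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as sm

        n = 20
        ki = rng.normal(0.01, 0.002, n)
        data = rng.standard_normal((n, 5, 1, 1))
        t, df, _ = group_t_map(data, covariate=ki)
        X = sm.add_constant(ki - ki.mean())
        for v in range(5):
            fit = sm.OLS(data[:, v, 0, 0], X).fit()
            assert t[v, 0, 0] == pytest.approx(fit.tvalues[1], abs=1e-10)
        assert df == n - 2

    def test_one_sample_matches_textbook_formula(self, rng):
        data = rng.standard_normal((12, 4, 3, 2))
        t, df, _ = group_t_map(data)
        m = data.mean(axis=0)
        s = data.std(axis=0, ddof=1)
        np.testing.assert_allclose(t, m / (s / np.sqrt(12)), atol=1e-10)


class TestThresholdClusters:
    def test_all_zero_map_empty(self):
        labels, sizes = threshold_clusters(np.zeros((5, 5, 5)), df=10)
        assert sizes.size == 0

    def test_isolated_voxel_singleton(self):
        t = np.zeros((5, 5, 5))
        t[2, 2, 2] = 10.0
        labels, sizes = threshold_clusters(t, df=10)
        assert list(sizes) == [1]

    def test_corner_touch_connectivity(self):
        """Two blobs touching only at a corner merge under 26-connectivity
        and stay separate under 6-connectivity."""
        t = np.zeros((6, 6, 6))
        t[1:3, 1:3, 1:3] = 10.0
        t[3:5, 3:5, 3:5] = 10.0
        _, sizes26 = threshold_clusters(t, df=10, connectivity=26)
        _, sizes6 = threshold_clusters(t, df=10, connectivity=6)
        assert len(sizes26) == 1 and sizes26[0] == 16
        assert len(sizes6) == 2

    def test_negative_direction(self):
        t = np.zeros((4, 4, 4))
        t[0, 0, 0] = -9.0
        _, pos = threshold_clusters(t, df=8, direction="pos")
        _, neg = threshold_clusters(t, df=8, direction="neg")
        assert pos.size == 0 and list(neg) == [1]


class TestTToZ:
    def test_zero_maps_to_zero(self):
        for df in (1, 5, 100):
            z, sat = t_to_z(0.0, df)
            assert z == 0.0 and not sat

    def test_large_df_limit(self):
        z, _ = t_to_z(2.0, 10_000)
        assert z == pytest.approx(2.0, abs=0.01)

    def test_matches_high_precision_oracle(self):
        # frozen from quadrature of the t density + normal quantile inversion
        z, sat = t_to_z(2 * np.sqrt(3.0), 2)
        assert not sat
        assert z == pytest.approx(1.7855021665762227, abs=1e-9)

    def test_symmetry(self):
        zp, _ = t_to_z(3.0, 7)
        zn, _ = t_to_z(-3.0, 7)
        assert zn == pytest.approx(-zp, abs=1e-12)

    def test_saturated_rendering(self):
        z, sat = t_to_z(np.inf, 10)
        assert sat
        assert format_z(z, sat) == "Inf"


class TestPermutationFWE:
    def _blob_data(self, rng, n, amplitude=5.0):
        data = rng.standard_normal((n, 8, 8, 6)) * 0.1
        data[:, 2:5, 2:5, 2:4] += amplitude * (1 + 0.1 * np.arange(n))[:, None, None, None]
        return data

    def test_exhaustive_minimum_p_for_three_subjects(self, rng):
        """With n=3 all 8 sign-flips are enumerated; the pooled two-direction
        null is symmetric, so the smallest attainable p is 2/8."""
        data = self._blob_data(rng, 3)
        with pytest.warns(RuntimeWarning, match="subjects"):
            est = PermutationClusterFWE(n_perm=1000, random_state=0).fit(data)
        assert est.exhaustive_
        assert len(est.null_max_sizes_) == 8
        assert est.clusters_["p_fwe"].min() == pytest.approx(2 / 8)

    def test_boundary_p_when_observed_exceeds_all_permutations(self, rng):
        """A covariate effect no permuted alignment can match reaches the
        estimator's floor p = 1/(1+n_perm); the add-one rule always holds."""
        n = 16
        cov = np.arange(n, dtype=float)
        data = rng.standard_normal((n, 8, 8, 6)) * 0.3
        data[:, 2:5, 2:5, 2:4] += (cov - cov.mean())[:, None, None, None]
        est = PermutationClusterFWE(p_height=1e-4, n_perm=99, random_state=1).fit(
            data, covariate=cov
        )
        assert not est.exhaustive_
        assert est.clusters_["p_fwe"].min() == pytest.approx(1.0 / 100.0)
        for _, row in est.clusters_.iterrows():
            expected = (1 + (est.null_max_sizes_ >= row["extent_k"]).sum()) / 100.0
            assert row["p_fwe"] == pytest.approx(expected)

    def test_exhaustive_p_invariant_to_subject_relabeling(self, rng):
        data = self._blob_data(rng, 4)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            a = PermutationClusterFWE(n_perm=16, random_state=0).fit(data)
            b = PermutationClusterFWE(n_perm=16, random_state=0).fit(data[::-1])
        np.testing.assert_allclose(
            a.clusters_["p_fwe"].to_numpy(), b.clusters_["p_fwe"].to_numpy()
        )

    def test_covariate_model_detects_moderated_effect(self, rng):
        truth = build_cohort_truth(SynthConfig(seed=9))
        mask = np.ones(truth.config.shape, bool)
        ki = np.abs(rng.normal(0.010, 0.002, 16))
        Y = simulate_group_contrasts(
            16, mask, rng, delta_map=truth.delta[0], ki=ki, gamma=100.0
        )
        est = PermutationClusterFWE(n_perm=200, random_state=2).fit(
            Y, covariate=ki, mask=mask, affine=truth.affine
        )
        assert len(est.clusters_)
        assert est.clusters_["p_fwe"].min() < 0.05
        # peak of the best cluster lies inside the generating support
        best = est.clusters_.iloc[0]
        vox = np.linalg.inv(truth.affine) @ np.array(
            [best["peak_x_mm"], best["peak_y_mm"], best["peak_z_mm"], 1.0]
        )
        support = truth.delta[0] > 0.1 * truth.delta[0].max()
        assert support[tuple(np.round(vox[:3]).astype(int))]


class TestRegionalEffects:
    def test_single_voxel_cluster_returns_values(self, rng):
        data = rng.standard_normal((5, 3, 3, 3))
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        np.testing.assert_allclose(
            extract_cluster_effects(data, mask), data[:, 1, 1, 1]
        )

    def test_constant_cluster_value(self):
        data = np.full((4, 3, 3, 3), 2.5)
        mask = np.ones((3, 3, 3), bool)
        np.testing.assert_allclose(extract_cluster_effects(data, mask), 2.5)

    def test_matches_bruteforce_masked_mean(self, rng):
        data = rng.standard_normal((6, 4, 4, 4))
        mask = rng.random((4, 4, 4)) > 0.6
        got = extract_cluster_effects(data, mask)
        for j in range(6):
            acc = [data[j][idx] for idx in np.ndindex(4, 4, 4) if mask[idx]]
            assert got[j] == pytest.approx(float(np.mean(acc)))

    def test_identity_correlation(self, rng):
        x = rng.standard_normal(20)
        r, p = roi_effect_correlation(x, x.copy())
        assert r == pytest.approx(1.0)

    def test_null_correlation_centered_on_zero(self, rng):
        rs = []
        for _ in range(50):
            r, _ = roi_effect_correlation(
                rng.standard_normal(1000), rng.standard_normal(1000)
            )
            rs.append(r)
        assert abs(np.mean(rs)) < 0.05

    def test_shared_ki_driven_effects_correlate(self, rng):
        """Cohorts where both regional effects scale with ki show a positive
        correlation (the dopamine-synthesis moderation pattern)."""
        truth = build_cohort_truth(SynthConfig(seed=13))
        mask = np.ones(truth.config.shape, bool)
        core = truth.effect_mask[0]
        hits = 0
        for c in range(10):
            ki = np.abs(rng.normal(0.010, 0.002, 16))
            Y = simulate_group_contrasts(
                16, mask, rng, delta_map=truth.delta[0], ki=ki, gamma=100.0
            )
            rpe = (ki - ki.mean()) + rng.normal(0, 0.7 * 0.002, 16)
            eff = extract_cluster_effects(Y, core)
            r, p = roi_effect_correlation(eff, rpe)
            hits += (r > 0) and (p < 0.05)
        assert hits >= 9

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="non-constant"):
            roi_effect_correlation(np.ones(10), np.arange(10.0))
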