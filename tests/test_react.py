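import numpy as np
import pandas as pd
import pytest

from reactfc.hrf import condition_regressors
from reactfc.io import CONDITIONS
from reactfc.react import (
    CollinearTemplatesError,
    ReactExtractor,
    TargetTimeSeries,
    build_first_level_design,
    build_interaction_regressors,
    collinearity_diagnostics,
    extract_target_timeseries,
    fit_first_level,
    normalize_timeseries,
)
from reactfc.templates import TemplateMap

from conftest import make_img


def _tmpl(values, name="t", rescaled=True):
    values = np.asarray(values, dtype=float)
    return TemplateMap(
        name=name, img=make_img(values), domain=np.ones(values.shape, bool),
        rescaled=rescaled,
    )


def _ts(arr, run_id="run-1", normalized=False, names=None):
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    if arr.shape[0] == 1:
        arr = arr.T
    names = names or [f"t{k}" for k in range(arr.shape[1])]
    return TargetTimeSeries(pd.DataFrame(arr, columns=names), run_id, normalized)


class TestSpatialRegression:
    def test_exact_inversion_of_generative_model(self, rng):
        """BOLD built as c(t) * demeaned template returns c exactly."""
        shape = (6, 6, 4)
        x = rng.random(shape)
        mask = np.ones(shape, bool)
        c = rng.standard_normal(50)
        x_d = x - x.mean()
        bold = make_img(x_d[..., None] * c + 7.0, tr=2.0)
        ts = extract_target_timeseries(bold, [_tmpl(x)], mask)
        np.testing.assert_allclose(ts.data.to_numpy()[:, 0], c, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        """Per-volume coefficients equal an independent (X'X)^-1 X'y solve."""
        shape = (5, 4, 3)  # 60 voxels
        mask = np.ones(shape, bool)
        x1, x2 = rng.random(shape), rng.random(shape)
        bold_data = rng.standard_normal(shape + (12,))
        ts = extract_target_timeseries(
            make_img(bold_data, tr=2.0), [_tmpl(x1, "a"), _tmpl(x2, "b")], mask
        )
        X = np.column_stack([x1.ravel(), x2.ravel()])
        X = X - X.mean(axis=0)
        for t in range(12):
            y = bold_data.reshape(-1, 12)[:, t]
            y = y - y.mean()
            expected = np.linalg.inv(X.T @ X) @ X.T @ y
            np.testing.assert_allclose(ts.data.to_numpy()[t], expected, atol=1e-10)

    def test_output_shape_one_value_per_volume_per_target(self, rng):
        shape = (4, 4, 3)
        ts = extract_target_timeseries(
            make_img(rng.standard_normal(shape + (9,)), tr=2.0),
            [_tmpl(rng.random(shape), "a"), _tmpl(rng.random(shape), "b")],
            np.ones(shape, bool),
        )
        assert ts.data.shape == (9, 2)

    def test_invariant_to_spatial_constant(self, rng):
        """Spatial demeaning absorbs any per-volume constant offset."""
        shape = (5, 5, 3)
        mask = np.ones(shape, bool)
        data = rng.standard_normal(shape + (8,))
        offsets = rng.standard_normal(8) * 100
        ex = ReactExtractor(templates=[_tmpl(rng.random(shape))], mask=mask).fit()
        a = ex.transform(make_img(data, tr=2.0)).data.to_numpy()
        b = ex.transform(make_img(data + offsets, tr=2.0)).data.to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_collinear_templates_rejected_with_correlations(self, rng):
        shape = (5, 5, 3)
        x = rng.random(shape)
        with pytest.raises(CollinearTemplatesError, match="correlation"):
            ReactExtractor(
                templates=[_tmpl(x, "a"), _tmpl(x * 2.0 + 0.1, "b")],
                mask=np.ones(shape, bool),
            ).fit()

    def test_joint_equals_single_for_orthogonal_templates(self, rng):
        shape = (6, 5, 4)
        mask = np.ones(shape, bool)
        v1 = rng.random(shape)
        v2 = rng.random(shape)
        d1 = (v1 - v1.mean()).ravel()
        d2 = (v2 - v2.mean()).ravel()
        d2 -= d1 * (d1 @ d2) / (d1 @ d1)  # orthogonalize demeaned columns
        v2 = (d2 - d2.min()).reshape(shape)
        bold = make_img(rng.standard_normal(shape + (10,)), tr=2.0)
        joint = extract_target_timeseries(bold, [_tmpl(v1, "a"), _tmpl(v2, "b")], mask)
        single_a = extract_target_timeseries(bold, [_tmpl(v1, "a")], mask)
        single_b = extract_target_timeseries(bold, [_tmpl(v2, "b")], mask)
        np.testing.assert_allclose(joint.data["a"], single_a.data["a"], atol=1e-8)
        np.testing.assert_allclose(joint.data["b"], single_b.data["b"], atol=1e-8)

    def test_spatial_vif_reports_overlap(self, rng):
        shape = (6, 6, 4)
        base = rng.random(shape)
        v2 = 0.95 * base + 0.05 * rng.random(shape)
        ex = ReactExtractor(
            templates=[_tmpl(base, "a"), _tmpl(v2, "b")], mask=np.ones(shape, bool)
        ).fit()
        assert ex.spatial_vif_.max() > 5.0


class TestNormalization:
    def test_forced_standardization(self):
        out = normalize_timeseries(_ts([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out.data.to_numpy()[:, 0], [-1.0, 0.0, 1.0])
        assert out.normalized

    def test_idempotent(self, rng):
        once = normalize_timeseries(_ts(rng.standard_normal(40)))
        twice = normalize_timeseries(once)
        np.testing.assert_allclose(
            twice.data.to_numpy(), once.data.to_numpy(), atol=1e-12
        )

    def test_preserves_correlation_with_raw(self, rng):
        raw = rng.standard_normal(30) * 4 + 2
        out = normalize_timeseries(_ts(raw))
        assert np.corrcoef(raw, out.data.to_numpy()[:, 0])[0, 1] == pytest.approx(1.0)

    def test_constant_column_names_run_and_target(self):
        with pytest.raises(ValueError, match=r"t0.*run-7"):
            normalize_timeseries(_ts(np.ones(10), run_id="run-7"))


class TestInteractions:
    def test_zero_condition_absorbs(self, rng):
        ts = _ts(rng.standard_normal(20), normalized=True)
        regs = pd.DataFrame({c: np.zeros(20) for c in CONDITIONS})
        ix = build_interaction_regressors(ts, regs)
        assert ix.shape == (20, 4)
        np.testing.assert_array_equal(ix.to_numpy(), 0.0)

    def test_unit_target_reproduces_condition(self, rng):
        ts = _ts(np.ones(20), normalized=True)  # test mode: bypass contract
        regs = pd.DataFrame({c: rng.standard_normal(20) for c in CONDITIONS})
        ix = build_interaction_regressors(ts, regs)
        for c in CONDITIONS:
            np.testing.assert_allclose(ix[f"t0:{c}"], regs[c], atol=1e-12)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="length"):
            build_interaction_regressors(
                _ts(np.ones(10), normalized=True),
                pd.DataFrame({c: np.zeros(12) for c in CONDITIONS}),
            )


class TestDesign:
    def _components(self, rng, n_runs=1, n_scans=40, k=1, tr=2.0):
        ts_runs, cond_runs, ix_runs = [], [], []
        for r in range(n_runs):
            ts = normalize_timeseries(
                _ts(rng.standard_normal((n_scans, k)), run_id=f"run-{r + 1}")
            )
            events = pd.DataFrame(
                {"onset": [5.0, 20.0, 35.0, 50.0], "duration": 0.0,
                 "trial_type": list(CONDITIONS)}
            )
            regs = condition_regressors(events, tr, n_scans)
            ts_runs.append(ts)
            cond_runs.append(regs)
            ix_runs.append(build_interaction_regressors(ts, regs))
        return ts_runs, cond_runs, ix_runs

    def test_column_arithmetic_single_run_no_drift(self, rng):
        ts, cond, ix = self._components(rng)
        design = build_first_level_design(ts, cond, ix, tr=2.0, drift_cutoff_s=None)
        # 4 conditions + 1 target + 4 interactions + 1 intercept
        assert design.shape[1] == 10

    def test_drift_column_count_three_runs(self, rng):
        ts, cond, ix = self._components(rng, n_runs=3, n_scans=100, tr=2.32)
        design = build_first_level_design(ts, cond, ix, tr=2.32, drift_cutoff_s=128.0)
        expected_per_run = int(np.floor(2 * 100 * 2.32 / 128)) + 1
        drift_cols = [c for c in design.columns if c.startswith("drift_")]
        assert len(drift_cols) == 3 * expected_per_run

    def test_duplicate_target_rank_deficiency_names_pair(self, rng):
        ts = normalize_timeseries(_ts(rng.standard_normal((40, 1)), run_id="run-1"))
        dup = TargetTimeSeries(
            pd.concat([ts.data, ts.data.rename(columns={"t0": "t1"})], axis=1),
            "run-1", True,
        )
        events = pd.DataFrame({"onset": [5.0], "duration": [0.0],
                               "trial_type": [CONDITIONS[0]]})
        regs = condition_regressors(events, 2.0, 40)
        with pytest.raises(ValueError, match="rank deficient"):
            build_first_level_design([dup], [regs], None, tr=2.0, drift_cutoff_s=None)


class TestFirstLevelFit:
    def test_exact_fit_of_single_regressor(self, rng):
        shape = (4, 4, 2)
        mask = np.ones(shape, bool)
        col = rng.standard_normal(30)
        col = (col - col.mean()) / col.std(ddof=1)
        ts = _ts(col, normalized=True)
        regs = pd.DataFrame({c: np.zeros(30) for c in CONDITIONS})
        design = build_first_level_design([ts], [regs], None, tr=2.0, drift_cutoff_s=None)
        bold = make_img(np.broadcast_to(col, shape + (30,)).copy(), tr=2.0)
        res = fit_first_level([bold], design, mask)
        np.testing.assert_allclose(res.beta_map("target_t0")[mask], 1.0, atol=1e-10)
        np.testing.assert_allclose(res.residual_variance, 0.0, atol=1e-18)
        for c in CONDITIONS:
            np.testing.assert_allclose(res.beta_map(c)[mask], 0.0, atol=1e-10)

    def test_matches_pseudoinverse_oracle(self, rng):
        shape = (3, 3, 2)
        mask = np.ones(shape, bool)
        ts = normalize_timeseries(_ts(rng.standard_normal(25)))
        events = pd.DataFrame({"onset": [4.0, 20.0], "duration": 0.0,
                               "trial_type": [CONDITIONS[0], CONDITIONS[1]]})
        regs = condition_regressors(events, 2.0, 25)
        design = build_first_level_design([ts], [regs], None, tr=2.0, drift_cutoff_s=None)
        data = rng.standard_normal(shape + (25,))
        res = fit_first_level([make_img(data, tr=2.0)], design, mask)
        X = design.to_numpy()
        pinv = np.linalg.pinv(X)
        for idx in np.ndindex(shape):
            expected = pinv @ data[idx]
            got = res.betas[:, np.ravel_multi_index(idx, shape)]
            np.testing.assert_allclose(got, expected, atol=1e-10)
        assert res.df == 25 - np.linalg.matrix_rank(X)

    def test_fewer_scans_than_columns_rejected(self, rng):
        shape = (2, 2, 1)
        design = pd.DataFrame(
            rng.standard_normal((8, 10)), columns=[f"c{i}" for i in range(10)]
        )
        with pytest.raises(ValueError, match="fewer time points"):
            fit_first_level(
                [make_img(rng.standard_normal(shape + (8,)), tr=2.0)],
                design, np.ones(shape, bool),
            )


class TestCollinearityDiagnostics:
    def test_orthogonal_design_unit_vif(self):
        n = 32
        t = np.arange(n)
        design = pd.DataFrame({
            "a": np.cos(2 * np.pi * t / n),
            "b": np.sin(2 * np.pi * t / n),
            "c": np.cos(4 * np.pi * t / n),
        })
        vif = collinearity_diagnostics(design)["vif"]
        np.testing.assert_allclose(vif, 1.0, atol=1e-8)

    def test_duplicated_column_infinite_vif(self, rng):
        col = rng.standard_normal(30)
        design = pd.DataFrame({"a": col, "b": col, "c": rng.standard_normal(30)})
        vif = collinearity_diagnostics(design)["vif"]
        assert np.isinf(vif["a"]) and np.isinf(vif["b"])
        assert np.isfinite(vif["c"])

    def test_constructed_collinearity_exceeds_threshold(self, rng):
        shared = rng.standard_normal(60)
        design = pd.DataFrame({
            "a": shared + 0.2 * rng.standard_normal(60),
            "b": shared + 0.2 * rng.standard_normal(60),
            "c": rng.standard_normal(60),
        })
        vif = collinearity_diagnostics(design)["vif"]
        # verify against the defining R^2 regression
        X = design.to_numpy()
        others = X[:, 1:]
        coef, *_ = np.linalg.lstsq(others, X[:, 0], rcond=None)
        r2 = 1 - ((X[:, 0] - others @ coef) ** 2).sum() / (
            (X[:, 0] - X[:, 0].mean()) ** 2
        ).sum()
        assert vif["a"] == pytest.approx(1 / (1 - r2), rel=1e-6)
        assert vif["a"] > 5.0
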