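import numpy as np
import pytest
from scipy import integrate

from reactfc.io import extract_roi_mean
from reactfc.patlak import (
    DEFAULT_FRAME_BLOCKS,
    FrameSchedule,
    cumulative_integral,
    frame_midtimes,
    ki_map,
    patlak_fit,
    subject_ki,
    window_frames,
)

from conftest import make_img


@pytest.fixture(scope="module")
def schedule():
    return FrameSchedule.from_blocks(DEFAULT_FRAME_BLOCKS)


@pytest.fixture(scope="module")
def ref_tac(schedule):
    t = schedule.mid_min
    c = (t / 10.0) ** 1.5 * np.exp(-t / 10.0) + 0.3 * (1 - np.exp(-t / 10.0))
    return c / c.max()


class TestSchedule:
    def test_standard_24_frame_midtimes(self, schedule):
        mids = frame_midtimes(schedule)
        assert len(schedule) == 24
        assert mids[0] == pytest.approx(0.5)
        assert mids[-1] == pytest.approx(86.5)
        assert schedule.end_min[-1] == pytest.approx(89.0)

    def test_single_frame_midtime(self):
        s = FrameSchedule(start_s=np.array([0.0]), end_s=np.array([60.0]))
        assert s.mid_min[0] == pytest.approx(0.5)

    def test_overlapping_frames_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            FrameSchedule(start_s=np.array([0.0, 30.0]), end_s=np.array([60.0, 90.0]))

    def test_tsv_roundtrip(self, tmp_path, schedule):
        path = tmp_path / "frames.tsv"
        schedule.write_tsv(path)
        back = FrameSchedule.read_tsv(path)
        np.testing.assert_allclose(back.start_s, schedule.start_s)
        np.testing.assert_allclose(back.end_s, schedule.end_s)


class TestCumulativeIntegral:
    def test_exact_for_constant(self, schedule):
        out = cumulative_integral(np.full(24, 3.0), schedule)
        np.testing.assert_allclose(out, 3.0 * schedule.mid_min, atol=1e-12)

    def test_exact_for_linear(self, schedule):
        a = 0.4
        out = cumulative_integral(a * schedule.mid_min, schedule)
        np.testing.assert_allclose(out, a * schedule.mid_min**2 / 2.0, atol=1e-10)

    def test_gamma_variate_matches_fine_quadrature(self, schedule):
        f = lambda t: (t / 8.0) ** 2 * np.exp(-t / 8.0)
        out = cumulative_integral(f(schedule.mid_min), schedule)
        for i, t in enumerate(schedule.mid_min):
            if t < 5.0:
                continue
            exact, _ = integrate.quad(f, 0.0, t)
            assert out[i] == pytest.approx(exact, rel=0.02)


class TestPatlakFit:
    def test_noiseless_generative_line_recovered_exactly(self, schedule, ref_tac):
        cum = cumulative_integral(ref_tac, schedule)
        target = 0.012 * cum + 0.4 * ref_tac
        res = patlak_fit(target, ref_tac, schedule)
        assert res.ki == pytest.approx(0.012, abs=1e-12)
        assert res.intercept == pytest.approx(0.4, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_window_selects_the_13_late_frames(self, schedule):
        used = window_frames(schedule, 24.0, 89.0)
        assert used.size == 13
        assert np.all(schedule.start_min[used] >= 24.0)
        assert np.all(schedule.end_min[used] <= 89.0)
        np.testing.assert_allclose(schedule.durations_min[used], 5.0)

    def test_scale_invariance(self, schedule, ref_tac):
        cum = cumulative_integral(ref_tac, schedule)
        target = 0.01 * cum + 0.3 * ref_tac
        a = patlak_fit(target, ref_tac, schedule)
        b = patlak_fit(37.4 * target, 37.4 * ref_tac, schedule)
        assert b.ki == pytest.approx(a.ki, rel=1e-12)

    def test_too_few_frames_rejected(self, schedule, ref_tac):
        with pytest.raises(ValueError, match="frames"):
            patlak_fit(ref_tac, ref_tac, schedule, t_star=80.0)

    def test_nonpositive_reference_rejected(self, schedule, ref_tac):
        bad = ref_tac.copy()
        bad[-5:] = 0.0
        with pytest.raises(ValueError, match="reference"):
            patlak_fit(bad, bad, schedule)

    def test_monte_carlo_unbiased_and_matches_closed_form(self, schedule, ref_tac, rng):
        """Noisy slope estimates are unbiased (<2%) and each equals the
        closed-form covariance/variance slope."""
        cum = cumulative_integral(ref_tac, schedule)
        true_ki, v = 0.010, 0.4
        clean = true_ki * cum + v * ref_tac
        noise_sd = 0.05 * clean.max()
        used = window_frames(schedule, 24.0, 89.0)
        x = cum[used] / ref_tac[used]
        estimates = []
        for _ in range(500):
            target = clean + rng.normal(0, noise_sd, clean.shape)
            res = patlak_fit(target, ref_tac, schedule)
            y = target[used] / ref_tac[used]
            slope_oracle = ((x - x.mean()) * (y - y.mean())).sum() / (
                (x - x.mean()) ** 2
            ).sum()
            assert res.ki == pytest.approx(slope_oracle, rel=1e-10)
            estimates.append(res.ki)
        assert np.mean(estimates) == pytest.approx(true_ki, rel=0.02)

    def test_slope_stable_for_two_tissue_model(self, schedule):
        """For an irreversible two-tissue model the Patlak slope has
        stabilized by 24 min: t* = 24 vs 34 min agree within 5%."""
        K1, k2, k3 = 0.4, 0.5, 0.05
        dt = 0.01
        fine_t = np.arange(0.0, 89.0 + dt, dt)
        cp = (fine_t / 10.0) ** 1.5 * np.exp(-fine_t / 10.0) + 0.3 * (
            1 - np.exp(-fine_t / 10.0)
        )
        free = K1 * dt * np.convolve(np.exp(-(k2 + k3) * fine_t), cp)[: fine_t.size]
        trapped = k3 * dt * np.cumsum(free)
        tissue = free + trapped
        idx = np.round(schedule.mid_min / dt).astype(int)
        target, ref = tissue[idx], cp[idx]
        a = patlak_fit(target, ref, schedule, t_star=24.0)
        b = patlak_fit(target, ref, schedule, t_star=34.0)
        assert b.ki == pytest.approx(a.ki, rel=0.05)


class TestKiMap:
    def _phantom(self, schedule, ref_tac, ki_arr, v=0.4):
        cum = cumulative_integral(ref_tac, schedule)
        shape = ki_arr.shape
        data = ki_arr[..., None] * cum + v * ref_tac
        ref_mask = np.zeros(shape)
        ref_mask[0, 0, :] = 1
        data[0, 0, :, :] = ref_tac  # pure reference voxels
        return make_img(data, tr=1.0), make_img(ref_mask)

    def test_phantom_recovered_voxelwise(self, schedule, ref_tac, rng):
        ki_arr = rng.uniform(0.005, 0.02, (10, 10, 6))
        pet, ref_mask = self._phantom(schedule, ref_tac, ki_arr)
        kmap = np.asanyarray(ki_map(pet, ref_mask, schedule).dataobj)
        inner = np.ones(ki_arr.shape, bool)
        inner[0, 0, :] = False
        np.testing.assert_allclose(kmap[inner], ki_arr[inner], atol=1e-10)

    def test_smoothed_roi_mean_close_to_unsmoothed(self, schedule, ref_tac, rng):
        ki_arr = rng.uniform(0.009, 0.011, (12, 12, 8))
        pet, ref_mask = self._phantom(schedule, ref_tac, ki_arr)
        roi = np.zeros(ki_arr.shape)
        roi[4:8, 4:8, 3:5] = 1
        plain = extract_roi_mean(ki_map(pet, ref_mask, schedule), make_img(roi))
        smoothed = extract_roi_mean(
            ki_map(pet, ref_mask, schedule, smooth_fwhm_mm=8.0), make_img(roi)
        )
        assert smoothed == pytest.approx(plain, rel=0.01)

    def test_empty_reference_rejected(self, schedule, ref_tac):
        pet, _ = self._phantom(schedule, ref_tac, np.full((6, 6, 4), 0.01))
        with pytest.raises(ValueError, match="empty"):
            ki_map(pet, make_img(np.zeros((6, 6, 4))), schedule)


class TestSubjectKi:
    def test_constant_roi_exact(self, schedule, ref_tac):
        ki_arr = np.full((8, 8, 4), 0.01)
        pet, ref_mask = TestKiMap()._phantom(schedule, ref_tac, ki_arr)
        roi = np.zeros(ki_arr.shape)
        roi[3:6, 3:6, 1:3] = 1
        assert subject_ki(pet, ref_mask, make_img(roi), schedule) == pytest.approx(
            0.01, abs=1e-10
        )

    def test_split_roi_averages(self, schedule, ref_tac):
        ki_arr = np.full((8, 8, 4), 0.01)
        ki_arr[:, :4] = 0.008
        ki_arr[:, 4:] = 0.012
        pet, ref_mask = TestKiMap()._phantom(schedule, ref_tac, ki_arr)
        roi = np.zeros(ki_arr.shape)
        roi[4, 2, 2] = 1  # one voxel per half
        roi[4, 6, 2] = 1
        assert subject_ki(pet, ref_mask, make_img(roi), schedule) == pytest.approx(0.010)
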