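import numpy as np
import pytest

from leafwave.calibration import CalibrationCurve
from leafwave.imaging import (
    ConcentrationMap,
    FrameStack,
    RoiSet,
    concentration_map,
    moving_average,
    ratiometric_series,
    roi_concentration_series,
    roi_intensity_series,
    series_to_concentration,
)


def make_stack(frames, dt=1.0, pixel=0.01, t_stress=5.0):
    frames = np.asarray(frames, dtype=float)
    times = np.arange(frames.shape[0]) * dt
    return FrameStack(times=times, frames=frames, pixel_size=pixel, t_stress=t_stress)


def two_spot_rois(shape=(20, 30)):
    masks = {
        "sa": np.zeros(shape, bool),
        "reference": np.zeros(shape, bool),
    }
    masks["sa"][5:15, 2:12] = True  # 100 px
    masks["reference"][5:15, 18:28] = True
    return RoiSet(masks=masks, stress_site=(0, 0))


class TestRoiIntensity:
    def test_uniform_frames_give_constant_series(self):
        rois = two_spot_rois()
        stack = make_stack(np.full((8, 20, 30), 100.0))
        import warnings

        for mode in ("mean", "top-quench"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                out = roi_intensity_series(stack, rois, "sa", mode=mode)
            np.testing.assert_allclose(out, 100.0)

    def test_top_quench_selects_decaying_subset(self):
        # 200 pixels fall to 50, 300 stay at 100: the fixed top-quench
        # subset is exactly the decaying 200
        shape = (25, 25)
        mask = np.zeros(shape, bool)
        mask.flat[:500] = True
        rois = RoiSet(masks={"h2o2": mask}, stress_site=(0, 0))
        frames = np.full((10, *shape), 100.0)
        decayers = np.flatnonzero(mask.ravel())[:200]
        for t in range(10):
            f = frames[t].ravel()
            f[decayers] = 100.0 - 50.0 * t / 9.0
        stack = make_stack(frames)
        out = roi_intensity_series(stack, rois, "h2o2", mode="top-quench")
        assert out[-1] == pytest.approx(50.0)
        assert out[0] == pytest.approx(100.0)

    def test_top_quench_matches_brute_force_ranking(self):
        rng = np.random.default_rng(5)
        shape = (30, 30)
        mask = np.zeros(shape, bool)
        mask[:, :20] = True
        rois = RoiSet(masks={"h2o2": mask}, stress_site=(0, 0))
        base = rng.uniform(80, 120, mask.sum())
        drop = rng.uniform(0, 40, mask.sum())
        T = 12
        frames = np.zeros((T, *shape))
        for t in range(T):
            frames[t][mask] = base - drop * t / (T - 1)
        stack = make_stack(frames)
        out = roi_intensity_series(stack, rois, "h2o2", mode="top-quench", n_top=150)
        # oracle: rank pixels by first-to-last intensity drop, take top 150
        pix = stack.frames[:, mask]
        order = np.argsort(pix[0] - pix[-1])[::-1][:150]
        np.testing.assert_allclose(out, pix[:, order].mean(axis=1))

    def test_small_roi_falls_back_with_warning(self):
        rois = two_spot_rois()
        stack = make_stack(np.full((5, 20, 30), 10.0))
        with pytest.warns(UserWarning, match="pixels"):
            out = roi_intensity_series(stack, rois, "sa", mode="top-quench")
        np.testing.assert_allclose(out, 10.0)

    def test_unknown_label_rejected(self):
        rois = two_spot_rois()
        stack = make_stack(np.full((5, 20, 30), 10.0))
        with pytest.raises(KeyError):
            roi_intensity_series(stack, rois, "h2o2")


class TestRatiometric:
    times = np.arange(20.0)

    def test_shared_drift_cancels_exactly(self):
        drift = 1.0 + 0.2 * np.sin(self.times / 3.0)
        act = 1000.0 * drift
        ref = 800.0 * drift
        r = ratiometric_series(act, ref, self.times, t_stress=5.0, window=10)
        np.testing.assert_allclose(r, 0.0, atol=1e-12)

    def test_active_halving_reads_half_quench(self):
        act = np.where(self.times >= 5.0, 500.0, 1000.0)
        ref = np.full(20, 900.0)
        r = ratiometric_series(act, ref, self.times, t_stress=5.0, window=1)
        np.testing.assert_allclose(r[self.times >= 5.0], 0.5)
        np.testing.assert_allclose(r[self.times < 5.0], 0.0)

    def test_zero_reference_frame_reported(self):
        ref = np.full(20, 900.0)
        ref[7] = 0.0
        with pytest.raises(ValueError, match=r"\[7\]"):
            ratiometric_series(ref * 0 + 1.0, ref, self.times, t_stress=5.0)

    def test_needs_three_prestress_frames(self):
        with pytest.raises(ValueError, match="pre-stress"):
            ratiometric_series(
                np.ones(20), np.ones(20), self.times, t_stress=1.0
            )


def test_moving_average_preserves_constants_and_identity():
    x = np.full(37, 4.2)
    np.testing.assert_allclose(moving_average(x, 10), x)
    rng = np.random.default_rng(2)
    y = rng.standard_normal(50)
    np.testing.assert_allclose(moving_average(y, 1), y)


class TestSeriesToConcentration:
    times = np.arange(10.0)

    def test_zero_quench_is_zero_concentration(self, sa_curve):
        s = series_to_concentration(np.zeros(10), self.times, sa_curve, 5.0)
        np.testing.assert_allclose(s.values, 0.0)

    def test_half_saturation_reads_kd(self, sa_curve):
        q = np.full(10, sa_curve.r_max / 2)
        s = series_to_concentration(q, self.times, sa_curve, 5.0)
        np.testing.assert_allclose(s.values, sa_curve.kd, rtol=1e-12)

    def test_saturation_hits_ceiling_and_is_counted(self, sa_curve):
        q = np.array([0.0, 0.1, 0.5, 0.99] + [0.0] * 6)
        diag = {}
        s = series_to_concentration(q, self.times, sa_curve, 5.0, diagnostics=diag)
        assert diag["saturated"] == 2
        assert s.values[2] == pytest.approx(10 * sa_curve.kd)
        assert s.values[3] == pytest.approx(10 * sa_curve.kd)

    def test_negative_quench_clips_and_counts(self, sa_curve):
        diag = {}
        s = series_to_concentration(
            np.array([-0.05] * 3 + [0.1] * 7), self.times, sa_curve, 5.0,
            diagnostics=diag,
        )
        assert diag["clipped"] == 3
        np.testing.assert_allclose(s.values[:3], 0.0)


class TestConcentrationMap:
    def test_static_stack_gives_zero_map(self, sa_curve):
        rois = two_spot_rois()
        stack = make_stack(np.full((12, 20, 30), 1000.0))
        cmap = concentration_map(stack, rois, {"sa": sa_curve})
        np.testing.assert_allclose(cmap.maps[:, rois.masks["sa"]], 0.0, atol=1e-9)
        assert np.all(np.isnan(cmap.maps[:, ~rois.masks["sa"]]))

    def test_single_quenched_pixel_reads_kd(self, sa_curve):
        rois = two_spot_rois()
        frames = np.full((12, 20, 30), 1000.0)
        frames[6:, 7, 5] = 1000.0 * (1 - sa_curve.r_max / 2)
        stack = make_stack(frames)
        cmap = concentration_map(stack, rois, {"sa": sa_curve}, window=1)
        assert cmap.maps[-1, 7, 5] == pytest.approx(sa_curve.kd, rel=1e-9)
        other = rois.masks["sa"].copy()
        other[7, 5] = False
        np.testing.assert_allclose(cmap.maps[-1, other], 0.0, atol=1e-9)

    def test_map_and_series_pathways_agree(self, sa_curve, xcc_stack):
        """Averaging the pixel-wise map over the SA ROI matches the scalar
        ROI-series pathway within smoothing/noise tolerance."""
        cfg, truth, stack, rois = xcc_stack
        cmap = concentration_map(stack, rois, {"sa": sa_curve})
        map_mean = np.nanmean(cmap.maps[:, rois.masks["sa"]], axis=1)
        series = roi_concentration_series(stack, rois, "sa", sa_curve)
        late = stack.times > 150.0  # once the SA plume is well developed
        assert np.corrcoef(map_mean[late], series.values[late])[0, 1] > 0.99
        assert np.mean(np.abs(map_mean[late] - series.values[late])) < 0.5


class TestIo:
    def test_stack_round_trip(self, tmp_path):
        stack = make_stack(np.random.default_rng(0).uniform(0, 1000, (6, 10, 12)))
        stack.save(tmp_path / "stack")
        back = FrameStack.load(tmp_path / "stack")
        np.testing.assert_allclose(back.frames, stack.frames, rtol=1e-6)
        np.testing.assert_allclose(back.times, stack.times)
        assert back.t_stress == stack.t_stress

    def test_roiset_round_trip(self, tmp_path):
        rois = two_spot_rois()
        rois.save(tmp_path)
        back = RoiSet.load(tmp_path)
        assert set(back.masks) == {"sa", "reference"}
        np.testing.assert_array_equal(back.masks["sa"], rois.masks["sa"])
        assert back.stress_site == rois.stress_site

    def test_overlapping_masks_rejected(self):
        m = np.zeros((5, 5), bool)
        m[1:3, 1:3] = True
        with pytest.raises(ValueError, match="overlap"):
            RoiSet(masks={"a": m, "b": m}, stress_site=(0, 0))
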