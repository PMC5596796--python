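import numpy as np
import pytest

from octdark.core_io import AcquisitionSchedule
from octdark.phantom import (
    AMPLITUDE_BLEACH_EXPONENT,
    ExposureField,
    NoiseModel,
    PhotoresponseKinetics,
    RetinaModel,
    ScanGrid,
    adaptometry_curve,
    band_depths,
    render_volume,
    simulate_session,
)

KIN = PhotoresponseKinetics()
MODEL = RetinaModel()
T_GRID = np.linspace(0.01, 30.0, 2000)


class TestKinetics:
    def test_zero_before_flash_and_without_bleach(self):
        t = np.array([-5.0, -0.1, 0.0])
        for f in (0.0, 0.96):
            inc = KIN.increments_um(t, f)
            for band in inc:
                np.testing.assert_array_equal(inc[band], 0.0)
        inc = KIN.increments_um(T_GRID, 0.0)
        for band in inc:
            np.testing.assert_array_equal(inc[band], 0.0)

    def test_cone_decays_below_5pct_by_5min(self):
        peak = KIN.cone_response_um(1e-6, 0.96)
        assert KIN.cone_response_um(5.0, 0.96) < 0.05 * peak

    @pytest.mark.parametrize("f", [0.54, 0.96])
    def test_rod_peaks_between_5_and_7_minutes(self, f):
        resp = KIN.rod_response_um(T_GRID, f)
        t_peak = T_GRID[np.argmax(resp)]
        assert 5.0 <= t_peak <= 7.0
        assert t_peak == pytest.approx(KIN.rod_peak_time_min(f), abs=0.02)

    @pytest.mark.parametrize("f", [0.54, 0.96])
    def test_rpe_bm_single_sign_change(self, f):
        resp = KIN.rpe_bm_response_um(T_GRID, f)
        signs = np.sign(resp[np.abs(resp) > 1e-9])
        changes = int((np.diff(signs) != 0).sum())
        assert changes == 1
        assert resp[np.argmax(T_GRID > KIN.osc_peak_min)] > 0  # peak first, then trough

    def test_rpe_bm_peak_and_trough_timing(self):
        resp = KIN.rpe_bm_response_um(T_GRID, 0.96)
        assert T_GRID[np.argmax(resp)] == pytest.approx(3.0, abs=0.5)
        assert 10.0 <= T_GRID[np.argmin(resp)] <= 15.0

    def test_amplitude_doubles_from_54_to_96(self):
        """Max response after a 96% bleach is twice that after a 54% bleach."""
        for resp in (KIN.cone_response_um, KIN.rod_response_um):
            ratio = resp(T_GRID, 0.96).max() / resp(T_GRID, 0.54).max()
            assert ratio == pytest.approx(2.0, abs=0.1)
        assert (0.96 / 0.54) ** AMPLITUDE_BLEACH_EXPONENT == pytest.approx(2.0, rel=1e-12)


class TestExposureField:
    def test_band_depths_control_increments_zero(self):
        base = MODEL.baseline_depths_um(1.0)
        d = band_depths(MODEL, KIN, 1.0, (0.0, 1.0), 5.0,
                        ExposureField(mode="full", bleach_fraction=0.0))
        for band in d:
            assert d[band] == pytest.approx(base[band], abs=0.0)

    def test_half_field_masks_superior_only(self):
        field = ExposureField(mode="half_inferior", bleach_fraction=0.96)
        base = MODEL.baseline_depths_um(1.0)
        sup = band_depths(MODEL, KIN, 1.0, (0.0, -1.0), 6.0, field)   # superior: y<0
        inf = band_depths(MODEL, KIN, 1.0, (0.0, +1.0), 6.0, field)   # inferior: y>0
        full = band_depths(MODEL, KIN, 1.0, (0.0, +1.0), 6.0,
                           ExposureField(mode="full", bleach_fraction=0.96))
        for band in base:
            assert sup[band] == pytest.approx(base[band], abs=0.0)
            assert inf[band] == pytest.approx(full[band], abs=0.0)

    def test_mask_monotone_and_clipped(self):
        field = ExposureField(mode="half_inferior", bleach_fraction=0.5)
        y = np.linspace(-1.0, 1.0, 401)
        m = field.mask(y)
        assert np.all(np.diff(m) >= 0)
        assert m[0] == 0.0 and m[-1] == 1.0
        assert np.all(m[np.abs(y) > 0.1] % 1.0 == 0.0)  # exactly 0/1 outside the ramp


class TestRender:
    def test_noise_free_peaks_at_configured_depths(self):
        grid = ScanGrid(n_bscans=1, n_ascans=1, n_depth=512)
        model = RetinaModel(fovea_center_mm=(0.0, 0.0))
        # single A-scan at the fovea (grid centre pixel offset ≈ 0.08 mm < RIZ cutoff)
        vol, truth = render_volume(model, KIN, 0.0, ExposureField(mode="none"),
                                   NoiseModel.quiet(), grid)
        a = vol.intensity[0, 0]
        inner = a[1:-1]
        maxima = 1 + np.nonzero((inner > a[:-2]) & (inner >= a[2:]) & (inner > 0.1))[0]
        dz = grid.axial_sampling_um
        expected = [truth.ez_px[0, 0]] + [
            truth.ez_px[0, 0] + truth.band_depth_um[b][0, 0] / dz
            for b in ("CIZ", "RPE", "BM")
        ]
        assert len(maxima) == len(expected)  # RIZ absent at the fovea
        for m, e in zip(sorted(maxima), sorted(expected)):
            assert abs(m - e) <= 0.5

    def test_riz_absent_below_min_eccentricity(self, quiet_phantom, small_grid):
        vol, truth = quiet_phantom
        x, y = small_grid.coords_mm()
        r = np.hypot(x[None, :], y[:, None])
        assert not truth.band_valid["RIZ"][r < MODEL.riz_min_eccentricity_mm].any()
        assert truth.band_valid["RIZ"][r >= MODEL.riz_min_eccentricity_mm].all()

    def test_speckle_is_mean_preserving(self):
        """Monte-Carlo pixel means of speckled renders match the noise-free volume."""
        grid = ScanGrid(n_bscans=2, n_ascans=2, n_depth=448)
        field = ExposureField(mode="none")
        noise = NoiseModel(motion_sigma_px=0.0)
        # reference: same mean model (incl. the additive pedestal), speckle off
        clean, _ = render_volume(
            MODEL, KIN, 0.0, field,
            NoiseModel(speckle=False, motion_sigma_px=0.0,
                       additive_noise_floor=noise.additive_noise_floor),
            grid,
        )
        rng = np.random.default_rng(123)
        acc = np.zeros_like(clean.intensity, dtype=np.float64)
        n = 300
        for _ in range(n):
            v, _ = render_volume(MODEL, KIN, 0.0, field, noise, grid, rng=rng)
            acc += v.intensity
        acc /= n
        rel = np.abs(acc - clean.intensity) / clean.intensity
        assert rel.max() < 0.05

    def test_ground_truth_band_ordering(self, speckle_phantom):
        _, truth = speckle_phantom
        d = truth.band_depth_um
        all_valid = truth.band_valid["RIZ"]
        assert (d["CIZ"][all_valid] < d["RIZ"][all_valid]).all()
        assert (d["RIZ"][all_valid] < d["RPE"][all_valid]).all()
        assert (d["RPE"] < d["BM"]).all()

    def test_depth_overflow_rejected(self):
        grid = ScanGrid(n_bscans=2, n_ascans=2, n_depth=256)  # retina does not fit
        with pytest.raises(ValueError):
            render_volume(MODEL, KIN, 0.0, ExposureField(mode="none"),
                          NoiseModel.quiet(), grid)


class TestSession:
    def test_schedule_counts_and_baseline_truth(self):
        grid = ScanGrid(n_bscans=2, n_ascans=2, n_depth=448)
        field = ExposureField(mode="full", bleach_fraction=0.0)
        out = list(simulate_session(MODEL, KIN, field, AcquisitionSchedule(),
                                    NoiseModel.quiet(), grid, seed=5))
        assert len(out) == 43
        assert sum(v.timestamp_s < 0 for v, _ in out) == 3
        base_truth = out[0][1]
        for _, truth in out[3:]:
            for band in ("CIZ", "RIZ", "RPE", "BM"):
                np.testing.assert_array_equal(
                    truth.band_depth_um[band], base_truth.band_depth_um[band]
                )

    def test_same_seed_identical_volumes(self):
        grid = ScanGrid(n_bscans=2, n_ascans=2, n_depth=448)
        field = ExposureField(mode="full", bleach_fraction=0.54)
        sched = AcquisitionSchedule(baseline_count=1, fast_window_s=60.0, total_s=60.0)
        a = list(simulate_session(MODEL, KIN, field, sched, NoiseModel(), grid, seed=9))
        b = list(simulate_session(MODEL, KIN, field, sched, NoiseModel(), grid, seed=9))
        assert len(a) == len(b)
        for (va, _), (vb, _) in zip(a, b):
            np.testing.assert_array_equal(va.intensity, vb.intensity)


class TestAdaptometry:
    def test_control_is_flat_zero(self):
        t = np.linspace(0, 30, 61)
        np.testing.assert_array_equal(adaptometry_curve(0.0, t), 0.0)

    def test_monotone_non_increasing(self):
        t = np.linspace(0.0, 30.0, 301)
        for f in (0.23, 0.54, 0.96):
            assert np.all(np.diff(adaptometry_curve(f, t)) <= 1e-12)

    def test_stronger_bleach_completes_later(self):
        t = np.linspace(0.0, 40.0, 4001)
        def completion(f):
            return t[np.argmax(adaptometry_curve(f, t) < 0.1)]
        assert completion(0.96) > completion(0.23)
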