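import numpy as np
import pytest

from octdark.core_io import AcquisitionSchedule, DifferenceMap, ThicknessMap
from octdark.photoresponse import (
    PhotoresponseSeries,
    ROISpec,
    average_baseline,
    difference_map,
    ez_jitter_px,
    find_fovea,
    process_session,
    roi_mean,
    smooth_masked,
)
from octdark import phantom as ph


def _tmap(values, valid=None, band="CIZ", fovea=(0.0, 0.0), extent=(6.0, 6.0)):
    values = np.asarray(values, dtype=float)
    valid = np.ones_like(values, dtype=bool) if valid is None else valid
    return ThicknessMap(values_um=values, band=band, valid=valid,
                        transverse_extent_mm=extent, fovea_mm=fovea)


def _dmap(values, valid=None, fovea=(0.0, 0.0), extent=(6.0, 6.0)):
    values = np.asarray(values, dtype=float)
    valid = np.ones_like(values, dtype=bool) if valid is None else valid
    return DifferenceMap(values_um=values, band="RIZ", valid=valid,
                         transverse_extent_mm=extent, fovea_mm=fovea)


class TestBaseline:
    def test_three_identical_maps(self):
        m = _tmap(np.full((8, 8), 30.0))
        out = average_baseline([m, m, m])
        np.testing.assert_array_equal(out.values_um, 30.0)
        assert out.valid.all()

    def test_pixelwise_mean(self):
        maps = [_tmap(np.full((4, 4), v)) for v in (29.0, 30.0, 31.0)]
        out = average_baseline(maps)
        np.testing.assert_allclose(out.values_um, 30.0)

    def test_majority_validity(self):
        valid1 = np.ones((4, 4), bool); valid1[0, 0] = False
        valid2 = np.ones((4, 4), bool); valid2[0, 0] = False
        maps = [
            _tmap(np.full((4, 4), 30.0), valid=valid1),
            _tmap(np.full((4, 4), 30.0), valid=valid2),
            _tmap(np.full((4, 4), 33.0)),
        ]
        out = average_baseline(maps)
        assert not out.valid[0, 0]          # valid in only 1 of 3
        assert out.values_um[1, 1] == pytest.approx(31.0)

    def test_no_valid_maps_rejected(self):
        m = _tmap(np.full((4, 4), 30.0), valid=np.zeros((4, 4), bool))
        with pytest.raises(ValueError):
            average_baseline([m, m, m])


class TestFindFovea:
    def test_offset_fovea_recovered(self):
        grid = ph.ScanGrid(n_bscans=100, n_ascans=100, n_depth=512)
        model = ph.RetinaModel(fovea_center_mm=(0.3, -0.2))
        rng = np.random.default_rng(5)
        vol, truth = ph.render_volume(model, ph.PhotoresponseKinetics(), 0.0,
                                      ph.ExposureField(mode="none"),
                                      ph.NoiseModel(), grid, rng=rng)
        from octdark import process_volume, PipelineConfig
        maps, _ = process_volume(vol, PipelineConfig())
        fx, fy = find_fovea(maps["CIZ"])
        assert abs(fx - 0.3) <= 0.15 and abs(fy + 0.2) <= 0.15

    def test_symmetric_map_centre(self):
        n = 64
        x = np.linspace(-3, 3, n)
        r = np.hypot(x[None, :], x[:, None])
        m = _tmap(32.0 - 3.0 * np.minimum(r, 3.0))
        fx, fy = find_fovea(m)
        pitch = 6.0 / n
        assert abs(fx) <= pitch and abs(fy) <= pitch

    def test_invalid_centre_rejected(self):
        m = _tmap(np.full((32, 32), 30.0), valid=np.zeros((32, 32), bool))
        with pytest.raises(ValueError, match="manually"):
            find_fovea(m)


class TestDifferenceMap:
    def test_identical_maps_zero(self):
        m = _tmap(np.random.default_rng(0).uniform(25, 35, (16, 16)))
        d = difference_map(m, m)
        np.testing.assert_allclose(d.values_um, 0.0, atol=1e-12)

    def test_uniform_offset_survives_smoothing(self):
        base = _tmap(np.full((32, 32), 30.0))
        shifted = _tmap(np.full((32, 32), 31.0))
        d = difference_map(shifted, base, smooth_sigma_px=9.0)
        np.testing.assert_allclose(d.values_um[d.valid], 1.0, atol=1e-9)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        base = _tmap(np.full((16, 16), 30.0))
        a = _tmap(30.0 + rng.uniform(-1, 1, (16, 16)))
        b = _tmap(30.0 + rng.uniform(-1, 1, (16, 16)))
        combo = _tmap(0.6 * a.values_um + 0.4 * b.values_um)
        d = difference_map(combo, base)
        expected = (
            0.6 * difference_map(a, base).values_um
            + 0.4 * difference_map(b, base).values_um
        )
        np.testing.assert_allclose(d.values_um, expected, atol=1e-9)

    def test_insufficient_overlap_rejected(self):
        valid = np.zeros((16, 16), bool); valid[:2, :2] = True
        base = _tmap(np.full((16, 16), 30.0))
        m = _tmap(np.full((16, 16), 30.0), valid=valid)
        with pytest.raises(ValueError, match="overlap"):
            difference_map(m, base)

    def test_subpixel_alignment_translates_map(self):
        n = 64
        x = np.linspace(-3, 3, n)
        bump = 30.0 + 3.0 * np.exp(-(np.hypot(x[None, :], x[:, None]) ** 2))
        base = _tmap(bump, fovea=(0.0, 0.0))
        moved = _tmap(np.roll(bump, 2, axis=1), fovea=(2 * 6.0 / n, 0.0))
        d = difference_map(moved, base, fovea_t=moved.fovea_mm, fovea_base=(0.0, 0.0))
        assert np.abs(d.values_um[d.valid]).max() < 1e-6


class TestROIMean:
    def test_uniform_map_any_roi(self):
        d = _dmap(np.full((64, 64), 0.7))
        for roi in (ROISpec((0.0, 3.0)), ROISpec((1.5, 5.5)),
                    ROISpec((0.0, 5.5), hemifield="inferior")):
            mean, n = roi_mean(d, roi)
            assert mean == pytest.approx(0.7)
            assert n > 0

    def test_matches_brute_force_enumeration(self):
        n = 80
        x = (np.arange(n) + 0.5) * 6.0 / n - 3.0
        r = np.hypot(x[None, :], x[:, None])
        rng = np.random.default_rng(2)
        valid = rng.random((n, n)) > 0.1
        d = _dmap(r.copy(), valid=valid)
        roi = ROISpec((1.5, 5.5))
        mean, count = roi_mean(d, roi)
        acc, cnt = 0.0, 0
        for b in range(n):
            for a in range(n):
                rr = np.hypot(x[a], x[b])
                if valid[b, a] and 0.75 <= rr <= 2.75:
                    acc += r[b, a]; cnt += 1
        assert count == cnt
        assert mean == pytest.approx(acc / cnt, rel=1e-12)

    def test_hemifield_split_antisymmetric_map(self):
        n = 64
        y = (np.arange(n) + 0.5) * 6.0 / n - 3.0
        d = _dmap(np.tile(y[:, None], (1, n)))
        inf, n_i = roi_mean(d, ROISpec((0.0, 5.0), hemifield="inferior"))
        sup, n_s = roi_mean(d, ROISpec((0.0, 5.0), hemifield="superior"))
        assert n_i == n_s
        assert inf == pytest.approx(-sup, rel=1e-12)
        assert inf > 0  # inferior is +y

    def test_empty_roi_rejected(self):
        d = _dmap(np.zeros((16, 16)), valid=np.zeros((16, 16), bool))
        with pytest.raises(ValueError):
            roi_mean(d, ROISpec((0.0, 3.0)))


class TestSmoothMasked:
    def test_no_bleed_from_invalid_region(self):
        values = np.zeros((32, 32))
        values[:, 16:] = 100.0
        valid = np.ones((32, 32), bool)
        valid[:, 16:] = False
        out = smooth_masked(values, valid, 3.0)
        assert np.abs(out[valid]).max() < 1e-9

    def test_constant_preserved(self):
        valid = np.random.default_rng(3).random((32, 32)) > 0.3
        out = smooth_masked(np.full((32, 32), 5.0), valid, 4.0)
        np.testing.assert_allclose(out[valid], 5.0, atol=1e-9)


def test_rod_difference_map_peak_matches_injected_amplitude():
    """At the rod peak time, the smoothed RIZ difference map's maximum is
    within 15% of the injected rod amplitude."""
    grid = ph.ScanGrid(n_bscans=100, n_ascans=100, n_depth=512)
    model = ph.RetinaModel()
    kin = ph.PhotoresponseKinetics()
    field = ph.ExposureField(mode="full", bleach_fraction=0.96)
    rng = np.random.default_rng(12)
    from octdark import PipelineConfig, process_volume
    cfg = PipelineConfig()
    base_maps = []
    for _ in range(3):
        vol, _ = ph.render_volume(model, kin, -1.0, field, ph.NoiseModel(), grid, rng=rng)
        base_maps.append(process_volume(vol, cfg)[0]["RIZ"])
    t_p = kin.rod_peak_time_min(0.96)
    vol, truth = ph.render_volume(model, kin, t_p, field, ph.NoiseModel(), grid, rng=rng)
    peak_map = process_volume(vol, cfg)[0]["RIZ"]
    baseline = average_baseline(base_maps)
    d = difference_map(peak_map, baseline, smooth_sigma_px=9.0)
    injected = kin.rod_amp_um * kin.amplitude_scale(0.96)
    interior = d.radius_mm() < 2.5  # away from map edges
    assert d.values_um[d.valid & interior].max() == pytest.approx(injected, rel=0.15)


def test_process_session_small_smoke():
    """A tiny session produces per-band series with the QC and ROI plumbing."""
    grid = ph.ScanGrid(n_bscans=48, n_ascans=48, n_depth=512)
    sched = AcquisitionSchedule(baseline_count=2, fast_interval_s=30.0,
                                fast_window_s=60.0, slow_interval_s=60.0, total_s=120.0)
    field = ph.ExposureField(mode="full", bleach_fraction=0.96)
    from octdark import PipelineConfig
    sess = ph.simulate_session(ph.RetinaModel(), ph.PhotoresponseKinetics(), field,
                               sched, ph.NoiseModel(), grid, seed=21)
    res = process_session(sess, PipelineConfig(), session_id="smoke")
    assert set(s.band for s in res.series.values()) == {"CIZ", "RIZ", "RPE", "BM"}
    ciz = res.get("CIZ")
    assert len(ciz.times_s) == 3  # 30, 60, 120 s
    assert np.all(np.diff(ciz.times_s) > 0)
    assert ciz.mean_diff_um[0] > 0.3  # immediate cone elongation visible


def test_series_invariants():
    with pytest.raises(ValueError):
        PhotoresponseSeries("CIZ", "full", [10.0, 10.0], [0.1, 0.2], [5, 5])
    with pytest.raises(ValueError):
        PhotoresponseSeries("CIZ", "full", [10.0, 20.0], [0.1, 0.2], [5, 0])


def test_ez_jitter_metric():
    from octdark.segmentation import EZSurface
    smooth = EZSurface(z_ez=np.tile(np.linspace(100, 104, 40)[:, None], (1, 16)),
                       quality=np.zeros(40))
    assert ez_jitter_px(smooth) < 0.3
    rng = np.random.default_rng(4)
    noisy = EZSurface(z_ez=smooth.z_ez + rng.normal(0, 6, size=(40, 1)),
                      quality=np.zeros(40))
    assert ez_jitter_px(noisy) > 3.0
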