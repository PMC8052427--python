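"""Unit tests for PE/SER mapping, hot-spot search and lesion summaries."""

import numpy as np
import pytest

from angiokin import kinetics as kin
from angiokin.kinetics import DceSeries, TumorMask
from angiokin.phantom import PhantomSpec, generate_lesion

SPACING = (0.5, 0.5, 1.3)


def _series_from(s0, s1, s2, spacing=SPACING):
    s0, s1, s2 = (np.asarray(a, dtype=float) for a in (s0, s1, s2))
    s_mid = (s1 + s2) / 2.0
    return DceSeries((s0, s1, s_mid, s2), spacing, (0.0, 120.0, 300.0, 480.0))


def _uniform(shape, v):
    return np.full(shape, float(v))


class TestPeMap:
    def test_direct_arithmetic(self):
        shape = (3, 3, 3)
        series = _series_from(_uniform(shape, 100), _uniform(shape, 250), _uniform(shape, 200))
        mask = TumorMask(np.ones(shape, bool), SPACING)
        pe = kin.compute_pe_map(series, mask)
        assert np.allclose(pe, 150.0)

    def test_no_enhancement_gives_zero(self):
        shape = (3, 3, 3)
        series = _series_from(_uniform(shape, 80), _uniform(shape, 80), _uniform(shape, 80))
        mask = TumorMask(np.ones(shape, bool), SPACING)
        assert np.allclose(kin.compute_pe_map(series, mask), 0.0)

    def test_zero_baseline_undefined_and_excluded(self):
        shape = (3, 3, 3)
        s0 = _uniform(shape, 100)
        s0[0, 0, 0] = 0.0
        series = _series_from(s0, _uniform(shape, 250), _uniform(shape, 150))
        mask = TumorMask(np.ones(shape, bool), SPACING)
        pe = kin.compute_pe_map(series, mask)
        assert np.isnan(pe[0, 0, 0])
        ser = kin.compute_ser_map(series, pe)
        wf = kin.compute_washout_fraction(pe, ser, mask)
        # denominator excludes the undefined voxel: 26 defined, all washout
        assert wf == pytest.approx(100.0)

    def test_mismatched_shapes_rejected(self):
        series = _series_from(*[_uniform((3, 3, 3), 100)] * 3)
        with pytest.raises(ValueError):
            kin.compute_pe_map(series, TumorMask(np.ones((4, 3, 3), bool), SPACING))


class TestSerMap:
    def test_direct_arithmetic(self):
        shape = (3, 3, 3)
        series = _series_from(_uniform(shape, 100), _uniform(shape, 300), _uniform(shape, 200))
        mask = TumorMask(np.ones(shape, bool), SPACING)
        pe = kin.compute_pe_map(series, mask)
        ser = kin.compute_ser_map(series, pe)
        assert np.allclose(ser, 2.0)

    def test_plateau_gives_unity(self):
        shape = (2, 2, 2)
        series = _series_from(_uniform(shape, 100), _uniform(shape, 260), _uniform(shape, 260))
        mask = TumorMask(np.ones(shape, bool), SPACING)
        ser = kin.compute_ser_map(series, kin.compute_pe_map(series, mask))
        assert np.allclose(ser, 1.0)

    def test_undefined_below_50pct_pe(self):
        shape = (2, 2, 2)
        series = _series_from(_uniform(shape, 100), _uniform(shape, 140), _uniform(shape, 120))
        mask = TumorMask(np.ones(shape, bool), SPACING)
        ser = kin.compute_ser_map(series, kin.compute_pe_map(series, mask))
        assert np.isnan(ser).all()

    def test_cleared_below_baseline_clamped(self):
        shape = (2, 2, 2)
        series = _series_from(_uniform(shape, 100), _uniform(shape, 300), _uniform(shape, 90))
        mask = TumorMask(np.ones(shape, bool), SPACING)
        ser = kin.compute_ser_map(series, kin.compute_pe_map(series, mask))
        assert np.allclose(ser, kin.SER_MAX)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        shape = (4, 4, 4)
        s0 = 100 + rng.random(shape) * 20
        s1 = s0 * (1.6 + rng.random(shape))
        s2 = s0 + (s1 - s0) / (0.8 + rng.random(shape))
        mask = TumorMask(np.ones(shape, bool), SPACING)
        sa = _series_from(s0, s1, s2)
        sb = _series_from(7.3 * s0, 7.3 * s1, 7.3 * s2)
        pe_a = kin.compute_pe_map(sa, mask)
        pe_b = kin.compute_pe_map(sb, mask)
        assert np.allclose(pe_a, pe_b)
        assert np.allclose(
            kin.compute_ser_map(sa, pe_a), kin.compute_ser_map(sb, pe_b)
        )


class TestHotspot:
    def test_constant_field(self):
        shape = (9, 9, 9)
        vmap = np.full(shape, np.nan)
        mask = np.zeros(shape, bool)
        mask[1:8, 1:8, 1:8] = True
        vmap[mask] = 100.0
        peak, _ = kin.find_hotspot_peak(vmap, TumorMask(mask, SPACING))
        assert peak == pytest.approx(100.0)

    def test_single_bright_voxel_window_mean(self):
        # 5^3 mask all 100 except one interior voxel at 127:
        # best window mean = (26*100 + 127) / 27 = 101
        shape = (5, 5, 5)
        vmap = np.full(shape, 100.0)
        vmap[2, 2, 2] = 127.0
        mask = TumorMask(np.ones(shape, bool), SPACING)
        peak, center = kin.find_hotspot_peak(vmap, mask)
        assert peak == pytest.approx((26 * 100 + 127) / 27)
        # several windows contain the bright voxel and tie at the max;
        # the returned center must be one of them (lowest z,y,x wins)
        assert all(abs(c - 2) <= 1 for c in center)
        assert center == (1, 1, 1)

    def test_exhaustive_window_enumeration(self):
        rng = np.random.default_rng(42)
        shape = (6, 7, 5)
        vmap = rng.random(shape) * 100
        mask_arr = rng.random(shape) < 0.9
        mask_arr[:2, :2, :2] = True
        vmap[~mask_arr] = np.nan
        mask = TumorMask(mask_arr, SPACING)
        best = -np.inf
        for cx in range(shape[0]):
            for cy in range(shape[1]):
                for cz in range(shape[2]):
                    vals = []
                    for dx in (-1, 0, 1):
                        for dy in (-1, 0, 1):
                            for dz in (-1, 0, 1):
                                p = (cx + dx, cy + dy, cz + dz)
                                if all(0 <= c < n for c, n in zip(p, shape)):
                                    if mask_arr[p] and np.isfinite(vmap[p]):
                                        vals.append(vmap[p])
                    if len(vals) >= 14:
                        best = max(best, float(np.mean(vals)))
        peak, _ = kin.find_hotspot_peak(vmap, mask)
        assert peak == pytest.approx(best, rel=1e-12)

    def test_pe_and_ser_peaks_in_different_lobes(self):
        # lobe A: huge PE, no washout; lobe B: modest PE, strong washout
        shape = (11, 5, 5)
        s0 = np.full(shape, 100.0)
        s1 = np.full(shape, 100.0)
        s2 = np.full(shape, 100.0)
        s1[:5] = 400.0  # lobe A: PE 300, SER = 300/200 = 1.5
        s2[:5] = 300.0
        s1[6:] = 250.0  # lobe B: PE 150, SER = 150/50 = 3.0
        s2[6:] = 150.0
        mask_arr = np.zeros(shape, bool)
        mask_arr[:5] = True
        mask_arr[6:] = True
        series = _series_from(s0, s1, s2)
        mask = TumorMask(mask_arr, SPACING)
        pe = kin.compute_pe_map(series, mask)
        ser = kin.compute_ser_map(series, pe)
        _, pe_center = kin.find_hotspot_peak(pe, mask)
        _, ser_center = kin.find_hotspot_peak(ser, mask)
        assert pe_center[0] < 5 and ser_center[0] >= 6

    def test_tiny_lesion_raises(self):
        shape = (6, 6, 6)
        vmap = np.full(shape, np.nan)
        mask = np.zeros(shape, bool)
        mask[2:4, 2, 2] = True
        vmap[mask] = 1.0
        with pytest.raises(ValueError, match="window"):
            kin.find_hotspot_peak(vmap, TumorMask(mask, SPACING))

    def test_peak_bounded_by_global_max(self, noisy_lesion):
        series, mask, _ = noisy_lesion
        pe = kin.compute_pe_map(series, mask)
        peak, _ = kin.find_hotspot_peak(pe, mask)
        assert peak <= np.nanmax(pe) + 1e-12


class TestFtvAndWf:
    def test_count_times_voxel_volume(self):
        shape = (10, 10, 10)
        pe = np.full(shape, 60.0)
        mask = TumorMask(np.ones(shape, bool), SPACING)
        # 1000 voxels at 0.325 mm^3 = 0.325 cm^3
        assert kin.compute_ftv(pe, mask) == pytest.approx(0.325)

    def test_no_qualifying_voxels(self):
        shape = (4, 4, 4)
        pe = np.full(shape, 30.0)
        mask = TumorMask(np.ones(shape, bool), SPACING)
        assert kin.compute_ftv(pe, mask) == 0.0

    def test_direct_ratio_and_inclusive_threshold(self):
        shape = (10, 10, 1)
        pe = np.full(shape, 100.0)
        ser = np.full(shape, 1.0)
        ser[:4, :, :] = 1.1  # exactly at threshold counts as washout
        mask = TumorMask(np.ones(shape, bool), SPACING)
        assert kin.compute_washout_fraction(pe, ser, mask) == pytest.approx(40.0)

    def test_wf_zero_when_no_washout(self):
        shape = (3, 3, 3)
        pe = np.full(shape, 100.0)
        ser = np.full(shape, 0.9)
        mask = TumorMask(np.ones(shape, bool), SPACING)
        assert kin.compute_washout_fraction(pe, ser, mask) == 0.0


class TestSummarize:
    def test_noise_free_single_class_exact(self):
        spec = PhantomSpec(
            noise_sd=0.0, class_fractions=(1.0, 0.0, 0.0),
            class_kinetics=((200.0, 2.0), (160.0, 1.0), (110.0, 0.65)), seed=0,
        )
        series, mask, truth = generate_lesion(spec)
        s = kin.summarize_lesion(series, mask)
        assert s.peak_pe_pct == pytest.approx(200.0, abs=1e-9)
        assert s.peak_ser == pytest.approx(2.0, abs=1e-9)
        assert s.wf_pct == pytest.approx(100.0, abs=1e-9)
        assert s.ftv_cm3 == pytest.approx(mask.n_voxels * mask.voxel_volume_mm3 / 1000)

    def test_all_below_threshold_reported_absent(self):
        spec = PhantomSpec(
            noise_sd=0.0, class_fractions=(0.0, 0.0, 1.0),
            class_kinetics=((200.0, 2.0), (160.0, 1.0), (40.0, 0.65)), seed=0,
        )
        series, mask, _ = generate_lesion(spec)
        s = kin.summarize_lesion(series, mask)
        assert s.ftv_cm3 == 0.0
        assert s.wf_pct == 0.0
        assert s.peak_ser is None and not s.ser_defined

    def test_mixed_lesion_wf_matches_design(self):
        spec = PhantomSpec(noise_sd=0.0, class_fractions=(0.25, 0.5, 0.25), seed=2)
        series, mask, truth = generate_lesion(spec)
        s = kin.summarize_lesion(series, mask)
        assert s.wf_pct == pytest.approx(truth.true_wf_pct, abs=1e-9)
        assert s.n_washout_voxels <= s.n_enhancing_voxels <= s.n_mask_voxels


class TestRoiGrow:
    def test_connectivity_isolates_blobs(self):
        shape = (9, 3, 3)
        pe = np.zeros(shape)
        pe[0:3] = 80.0
        pe[6:9] = 90.0
        roi = kin.grow_enhancing_roi(pe, (1, 1, 1), SPACING)
        assert roi.n_voxels == 27
        assert not roi.data[6:9].any()

    def test_diagonal_neighbor_included(self):
        shape = (3, 3, 3)
        pe = np.zeros(shape)
        pe[0, 0, 0] = 60.0
        pe[1, 1, 1] = 60.0
        roi = kin.grow_enhancing_roi(pe, (0, 0, 0), SPACING)
        assert roi.data[1, 1, 1]

    def test_seed_below_threshold_raises(self):
        pe = np.zeros((3, 3, 3))
        with pytest.raises(ValueError, match="seed"):
            kin.grow_enhancing_roi(pe, (1, 1, 1), SPACING)


class TestIO:
    def test_series_and_mask_round_trip(self, tmp_path, clean_lesion):
        series, mask, _ = clean_lesion
        p = kin.save_series(series, tmp_path / "s.nii")
        m = kin.save_mask(mask, tmp_path / "m.nii")
        series2 = kin.load_series(p)
        mask2 = kin.load_mask(m)
        assert mask2.n_voxels == mask.n_voxels
        assert series2.timing_s == series.timing_s
        assert np.allclose(series2.s1, series.s1, atol=1e-4)
        assert np.allclose(series2.spacing_mm, series.spacing_mm)
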