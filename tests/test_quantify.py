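"""Phase correction, masking, model fitting and repeatability metrics."""

import numpy as np
import pytest

from radialasl import signals as sig
from radialasl.protocol import AcquisitionProtocol, bin_frames, \
    build_spoke_schedule
from radialasl.quantify import (
    CalibrationResult,
    calibrate_m0b,
    fit_angio,
    fit_perfusion,
    fit_structural,
    make_vessel_mask,
    phase_correct,
    repeatability_r2,
)


@pytest.fixture(scope="module")
def frames12(protocol_full):
    sch = build_spoke_schedule(protocol_full)
    return bin_frames(sch, 12, tr=protocol_full.tr)


@pytest.fixture(scope="module")
def frames6(protocol_full):
    sch = build_spoke_schedule(protocol_full)
    return bin_frames(sch, 6, tr=protocol_full.tr)


@pytest.fixture(scope="module")
def readout(protocol_full):
    flips = protocol_full.flip_angles()
    return (protocol_full.excitation_times(), flips,
            sig.rf_attenuation(flips))


class TestPhaseCorrect:
    def test_recovers_globally_rotated_real_series(self):
        rng = np.random.default_rng(0)
        real = rng.standard_normal((4, 4, 4, 5)) + 3.0
        rotated = real * np.exp(1j * 1.234)
        corrected, flagged = phase_correct(rotated)
        assert np.allclose(corrected, real, atol=1e-12)
        assert not flagged.any()

    def test_reference_frame_becomes_magnitude(self):
        rng = np.random.default_rng(1)
        series = (rng.standard_normal((3, 3, 3, 4))
                  + 1j * rng.standard_normal((3, 3, 3, 4)))
        corrected, _ = phase_correct(series)
        assert np.allclose(corrected[..., -1], np.abs(series[..., -1]))

    def test_zero_reference_voxels_flagged(self):
        series = np.ones((2, 2, 2, 3), dtype=complex)
        series[0, 0, 0, -1] = 0
        _, flagged = phase_correct(series)
        assert flagged[0, 0, 0] and flagged.sum() == 1


class TestVesselMask:
    def _series(self):
        data = np.zeros((12, 12, 12, 3), dtype=complex)
        data[2:5, 2:5, 2:5, 1] = 10.0       # cluster A (27 voxels)
        data[8:11, 8:11, 8:11, 2] = 8.0     # cluster B (27 voxels)
        data[6, 6, 6, 0] = 20.0             # isolated bright noise voxel
        return data

    def test_keeps_two_largest_clusters_drops_noise_voxel(self):
        brain = np.ones((12, 12, 12), bool)
        mask = make_vessel_mask(self._series(), brain, threshold=1.0)
        assert mask[3, 3, 3] and mask[9, 9, 9]
        assert not mask[6, 6, 6]

    def test_threshold_above_maximum_errors(self):
        brain = np.ones((12, 12, 12), bool)
        with pytest.raises(ValueError):
            make_vessel_mask(self._series(), brain, threshold=100.0)

    def test_mask_within_brain(self):
        brain = np.zeros((12, 12, 12), bool)
        brain[:, :, :6] = True
        mask = make_vessel_mask(self._series(), brain, threshold=1.0)
        assert not mask[~brain].any()


class TestFitAngio:
    def test_noiseless_recovery_within_one_percent(self, protocol_full,
                                                   frames12, readout):
        t_i, flips, r_i = readout
        truth = dict(s0v=5.0, transit_delay=0.3, sharpness=20.0,
                     time_to_peak=0.1)
        ap = sig.AngioParams(**truth)
        curve = sig.frame_average(
            sig.angio_signal_closed(ap, t_i, flips, r_i,
                                    protocol_full.labeling_duration),
            frames12)
        maps = fit_angio(curve.reshape(1, 1, 1, -1), np.ones((1, 1, 1), bool),
                         protocol_full, frames12)
        for key, val in truth.items():
            assert maps[key][0, 0, 0] == pytest.approx(val, rel=0.01)
        assert maps.converged[0, 0, 0]

    def test_all_zero_voxel_flagged_without_crash(self, protocol_full,
                                                  frames12):
        maps = fit_angio(np.zeros((1, 1, 1, 12)), np.ones((1, 1, 1), bool),
                         protocol_full, frames12)
        assert not maps.converged[0, 0, 0]

    def test_bias_field_divides_amplitude(self, protocol_full, frames12,
                                          readout):
        t_i, flips, r_i = readout
        ap = sig.AngioParams(s0v=4.0)
        curve = sig.frame_average(
            sig.angio_signal_closed(ap, t_i, flips, r_i, 1.8), frames12)
        bias = np.full((1, 1, 1), 2.0)
        maps = fit_angio(curve.reshape(1, 1, 1, -1), np.ones((1, 1, 1), bool),
                         protocol_full, frames12, bias_field=bias)
        assert maps["s0v"][0, 0, 0] == pytest.approx(2.0, rel=0.01)


class TestFitPerfusion:
    def _raw(self, protocol, binning, readout, cbf, att):
        t_i, flips, r_i = readout
        pp = sig.PerfusionParams(cbf=cbf, att=att, t1_tissue=1.3, m0b=1.0)
        curve = sig.frame_average(
            sig.perfusion_signal(pp, t_i, flips, r_i,
                                 protocol.labeling_duration), binning)
        # raw convention: inverted contrast, scaled by efficiency and m0b
        return (-curve * 0.85).reshape(1, 1, 1, -1)

    def test_noiseless_multi_pld_recovery(self, protocol_full, frames6,
                                          readout):
        raw = self._raw(protocol_full, frames6, readout, 60.0, 0.8)
        cal = CalibrationResult(m0_wm=0.82, m0b=1.0)
        maps = fit_perfusion(raw, np.ones((1, 1, 1), bool), protocol_full,
                             frames6, cal, mode="multi_pld")
        assert maps["cbf"][0, 0, 0] == pytest.approx(60.0, rel=0.02)
        assert maps["att"][0, 0, 0] == pytest.approx(0.8, abs=0.02)

    def test_zero_flow_voxel_fits_to_zero(self, protocol_full, frames6,
                                          readout):
        raw = self._raw(protocol_full, frames6, readout, 0.0, 0.8)
        cal = CalibrationResult(m0_wm=0.82, m0b=1.0)
        maps = fit_perfusion(raw, np.ones((1, 1, 1), bool), protocol_full,
                             frames6, cal, mode="multi_pld")
        assert abs(maps["cbf"][0, 0, 0]) <= 1e-6

    def test_single_pld_agrees_with_multi_on_matched_att(self, protocol_full,
                                                         frames6, readout):
        raw = self._raw(protocol_full, frames6, readout, 45.0, 1.3)
        cal = CalibrationResult(m0_wm=0.82, m0b=1.0)
        multi = fit_perfusion(raw, np.ones((1, 1, 1), bool), protocol_full,
                              frames6, cal, mode="multi_pld")
        single = fit_perfusion(raw, np.ones((1, 1, 1), bool), protocol_full,
                               frames6, cal, mode="single_pld", fixed_att=1.3)
        assert single["cbf"][0, 0, 0] == pytest.approx(
            multi["cbf"][0, 0, 0], rel=0.01)

    def test_late_att_in_single_pld_mode_rejected(self, protocol_full,
                                                  frames6, readout):
        raw = self._raw(protocol_full, frames6, readout, 45.0, 1.3)
        cal = CalibrationResult(m0_wm=0.82, m0b=1.0)
        with pytest.raises(ValueError):
            fit_perfusion(raw, np.ones((1, 1, 1), bool), protocol_full,
                          frames6, cal, mode="single_pld", fixed_att=10.0)


class TestCalibrateM0b:
    def test_recovers_known_wm_magnetization(self, protocol_full, frames6):
        tp = sig.TissueParams(m0=1000.0, t1=0.9, inv_efficiency=0.95)
        mxy, _ = sig.static_tissue_signal(tp, protocol_full)
        curve = sig.frame_average(mxy, frames6)
        series = np.tile(curve, (2, 2, 2, 1))
        cal = calibrate_m0b(series, np.ones((2, 2, 2), bool), protocol_full,
                            frames6)
        assert cal.m0b == pytest.approx(1000.0 / 0.82, rel=0.01)
        assert cal.wm_fit["t1"] == pytest.approx(0.9, rel=0.01)

    def test_partition_coefficient_normalization(self, protocol_full,
                                                 frames6):
        tp = sig.TissueParams(m0=0.82, t1=0.9, inv_efficiency=0.95)
        mxy, _ = sig.static_tissue_signal(tp, protocol_full)
        curve = sig.frame_average(mxy, frames6)
        cal = calibrate_m0b(curve.reshape(1, 1, 1, -1),
                            np.ones((1, 1, 1), bool), protocol_full, frames6)
        assert cal.m0b == pytest.approx(1.0, rel=0.01)

    def test_empty_mask_rejected(self, protocol_full, frames6):
        with pytest.raises(ValueError):
            calibrate_m0b(np.zeros((2, 2, 2, 6)), np.zeros((2, 2, 2), bool),
                          protocol_full, frames6)


class TestFitStructural:
    def test_noiseless_gm_t1_within_one_percent(self, protocol_full,
                                                frames6):
        tp = sig.TissueParams(m0=800.0, t1=1.3, inv_efficiency=0.95)
        mxy, _ = sig.static_tissue_signal(tp, protocol_full)
        curve = sig.frame_average(mxy, frames6)
        maps = fit_structural(curve.reshape(1, 1, 1, -1),
                              np.ones((1, 1, 1), bool), protocol_full,
                              frames6)
        assert maps["t1"][0, 0, 0] == pytest.approx(1.3, rel=0.01)

    def test_fitted_values_respect_bounds(self, protocol_full, frames6):
        rng = np.random.default_rng(5)
        series = rng.standard_normal((3, 1, 1, 6)) * 100 + 400
        maps = fit_structural(series, np.ones((3, 1, 1), bool),
                              protocol_full, frames6)
        assert np.all(maps["t1"][maps.mask] >= 0.1)
        assert np.all(maps["t1"][maps.mask] <= 10.0)
        assert np.all(maps["inv_efficiency"][maps.mask] >= 0.5)
        assert np.all(maps["inv_efficiency"][maps.mask] <= 1.0)
        assert np.all(maps["b1_rel"][maps.mask] >= 0.9)
        assert np.all(maps["b1_rel"][maps.mask] <= 1.1)

    def test_coarse_initialization_is_used(self, protocol_full, frames6):
        tp = sig.TissueParams(m0=500.0, t1=1.1, inv_efficiency=0.93)
        mxy, _ = sig.static_tissue_signal(tp, protocol_full)
        curve = sig.frame_average(mxy, frames6)
        coarse = fit_structural(curve.reshape(1, 1, 1, -1),
                                np.ones((1, 1, 1), bool), protocol_full,
                                frames6)
        fine = fit_structural(np.tile(curve, (2, 2, 2, 1)),
                              np.ones((2, 2, 2), bool), protocol_full,
                              frames6, coarse_init=coarse)
        assert np.allclose(fine["t1"][fine.mask], 1.1, rtol=0.01)


class TestRepeatability:
    def test_identical_maps_have_unit_r2(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((6, 6, 6))
        res = repeatability_r2(a, a, np.ones(a.shape, bool))
        assert res["r2"] == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((6, 6, 6))
        res = repeatability_r2(a, 2 * a + 3, np.ones(a.shape, bool))
        assert res["r2"] == pytest.approx(1.0)
        assert res["mean_b"] == pytest.approx(2 * a.mean() + 3)

    def test_independent_noise_maps_uncorrelated(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((22, 22, 22))
        b = rng.standard_normal((22, 22, 22))
        res = repeatability_r2(a, b, np.ones(a.shape, bool))
        assert res["r2"] <= 0.01

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError):
            repeatability_r2(np.ones((3, 3, 3)), np.ones((3, 3, 3)),
                             np.ones((3, 3, 3), bool))
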