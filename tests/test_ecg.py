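"""Pseudo-ECG, repolarisation features and T-wave morphology tags."""

import numpy as np
import pytest

from pvstrand.ecg import (
    TWaveReference,
    compute_pseudo_ecg,
    compute_qt_tpe,
    repolarization_times,
    tag_twave_morphology,
    twave_window,
)
from pvstrand.errors import ParameterError
from pvstrand.synthetic import (
    ead_bump_trace,
    repolarization_map_result,
    square_ap_trace,
    synthetic_result,
    uniform_map_result,
)


def _ecg_from_map(v, cl=600.0, output_dt=0.5):
    res = synthetic_result(v, cl=cl, n_beats=1, output_dt=output_dt)
    return res, compute_pseudo_ecg(res)


class TestComputePseudoECG:
    def test_uniform_map_gives_zero_signal(self):
        res = uniform_map_result(n_cells=8, value=-20.0)
        ecg = compute_pseudo_ecg(res)
        np.testing.assert_allclose(ecg.phi, 0.0, atol=1e-12)

    def test_electrode_inside_tissue_rejected(self):
        res = uniform_map_result()
        with pytest.raises(ParameterError):
            compute_pseudo_ecg(res, electrode_distance_cm=0.0)

    def test_linear_in_voltage(self):
        rng = np.random.default_rng(1)
        n_cells, n_t = 8, 41
        v1 = rng.uniform(-80, 20, (n_cells, n_t))
        v2 = rng.uniform(-80, 20, (n_cells, n_t))
        a, b = 0.7, -1.3
        # same geometry for all three maps
        _, e1 = _ecg_from_map(v1, cl=20.0)
        _, e2 = _ecg_from_map(v2, cl=20.0)
        _, e12 = _ecg_from_map(a * v1 + b * v2, cl=20.0)
        np.testing.assert_allclose(e12.phi, a * e1.phi + b * e2.phi,
                                   rtol=1e-10, atol=1e-12)

    def test_mirror_antisymmetry(self):
        """Flipping the strand (with a uniform lead field) flips the sign
        of the gradient sum."""
        rng = np.random.default_rng(2)
        v = rng.uniform(-80, 20, (8, 21))
        res, _ = _ecg_from_map(v, cl=10.0)
        # uniform faces and uniform weights isolate the gradient antisymmetry
        dv = np.diff(v, axis=0).sum(axis=0)
        dv_flip = np.diff(v[::-1], axis=0).sum(axis=0)
        np.testing.assert_allclose(dv_flip, -dv, atol=1e-12)

    def test_control_twave_upright(self, control_full):
        """Epicardial cells repolarise before midmyocardial cells, so the
        post-plateau deflection at the distal electrode is positive."""
        ecg = compute_pseudo_ecg(control_full)
        lo, hi = twave_window(control_full, -1)
        sel = (ecg.times >= lo) & (ecg.times < hi)
        phi = ecg.phi[sel]
        assert phi.max() > 0
        assert phi.max() > -phi.min()


class TestRepolarizationTimes:
    def test_square_ap_repolarises_at_apd(self):
        res = repolarization_map_result(np.full(8, 300.0), cl=1000.0,
                                        t_act=5.0)
        repol = repolarization_times(res, 0)
        np.testing.assert_allclose(repol, 305.0, atol=1.0)

    def test_ead_bump_postpones_to_last_crossing(self):
        """An AP crossing -70 mV at 400 ms followed by an EAD that only
        finally repolarises at 520 ms: the last crossing wins."""
        times = 0.5 * np.arange(1400)
        primary = square_ap_trace(times, t_act=5.0, apd=395.0)
        ead = square_ap_trace(times, t_act=410.0, apd=110.0,
                              v_plateau=-30.0)
        v = np.maximum(primary, ead)
        res = synthetic_result(np.tile(v, (4, 1)), cl=700.0, n_beats=1)
        repol = repolarization_times(res, 0)
        assert repol[0] == pytest.approx(520.0, abs=2.0)

    def test_never_repolarising_marked(self):
        times = 0.5 * np.arange(800)
        v = np.tile(ead_bump_trace(times, plateau_v=-20.0, t_repol=1e9),
                    (4, 1))
        res = synthetic_result(v, cl=400.0, n_beats=1)
        repol = repolarization_times(res, 0)
        assert np.isnan(repol).all()


class TestQtTpe:
    def test_equal_repol_times_zero_tpe(self):
        res = repolarization_map_result(np.full(8, 250.0))
        f = compute_qt_tpe(res, 0)
        assert f.t_pe == pytest.approx(0.0, abs=1.0)

    def test_arithmetic_on_constructed_map(self):
        offsets = np.linspace(200.0, 260.0, 8)
        res = repolarization_map_result(offsets, t_act=0.0)
        f = compute_qt_tpe(res, 0)
        assert f.qt == pytest.approx(260.0, abs=1.0)
        assert f.t_pe == pytest.approx(60.0, abs=1.0)
        assert f.first_repol_cell == 0
        assert f.last_repol_cell == 7

    def test_beat_to_beat_qt_pair(self):
        """Two consecutive beats with different repolarisation spans give
        per-beat QT values (the beat-to-beat QT-alternans representation)."""
        cl, output_dt = 1000.0, 0.5
        times = output_dt * np.arange(int(2 * cl / output_dt) + 1)
        v = np.stack([
            np.maximum(square_ap_trace(times, 5.0, 320.0),
                       square_ap_trace(times, cl + 5.0, 600.0))
            for _ in range(4)])
        res = synthetic_result(v, cl=cl, n_beats=2)
        q0 = compute_qt_tpe(res, 0).qt
        q1 = compute_qt_tpe(res, 1).qt
        assert q0 == pytest.approx(325.0, abs=1.0)
        assert q1 == pytest.approx(605.0, abs=1.0)

    def test_stimulus_shift_covariance(self):
        """t_pe is invariant under a shift of the activation time; qt
        shifts one-for-one."""
        offsets = np.linspace(200.0, 240.0, 8)
        r0 = repolarization_map_result(offsets, t_act=5.0)
        r1 = repolarization_map_result(offsets, t_act=55.0)
        f0, f1 = compute_qt_tpe(r0, 0), compute_qt_tpe(r1, 0)
        assert f1.t_pe == pytest.approx(f0.t_pe, abs=1e-6)
        assert f1.qt - f0.qt == pytest.approx(50.0, abs=1e-6)

    def test_undefined_when_nothing_repolarises(self):
        times = 0.5 * np.arange(800)
        v = np.tile(ead_bump_trace(times, plateau_v=-20.0, t_repol=1e9),
                    (4, 1))
        res = synthetic_result(v, cl=400.0, n_beats=1)
        f = compute_qt_tpe(res, 0)
        assert not f.defined
        assert f.n_unrepolarized == 4


def _lobe_wave(times, t0, width, amp):
    """Triangular T-wave lobe."""
    half = width / 2.0
    up = np.clip((times - t0) / half, 0, 1)
    down = np.clip((times - t0 - half) / half, 0, 1)
    return amp * (up - down)


class TestTWaveTags:
    control = TWaveReference(peak_amp=1.0, half_max_duration=40.0, qt=300.0)

    def _tags(self, phi, times=None, qt=300.0):
        from pvstrand.ecg import PseudoECG
        times = np.arange(len(phi)) * 1.0 if times is None else times
        ecg = PseudoECG(times=times, phi=phi, electrode_distance_cm=2.0)
        return tag_twave_morphology(ecg, (times[0], times[-1] + 1.0),
                                    self.control, qt=qt)

    def test_negative_single_lobe_inverted(self):
        t = np.arange(300.0)
        tags = self._tags(-_lobe_wave(t, 100, 80, 1.0))
        assert tags == {"inverted"}

    def test_two_signed_lobes_biphasic(self):
        t = np.arange(300.0)
        phi = _lobe_wave(t, 80, 60, 1.0) - _lobe_wave(t, 160, 60, 1.0)
        tags = self._tags(phi)
        assert "biphasic" in tags

    def test_two_positive_peaks_notched_upright(self):
        t = np.arange(300.0)
        phi = _lobe_wave(t, 80, 60, 1.0) + _lobe_wave(t, 170, 60, 0.9)
        tags = self._tags(phi)
        assert {"notched", "upright"} <= tags

    def test_wide_wave_broad_based(self):
        t = np.arange(300.0)
        tags = self._tags(_lobe_wave(t, 60, 200, 1.0))
        assert "broad_based" in tags

    def test_late_narrow_wave_late_pointed(self):
        t = np.arange(300.0)
        tags = self._tags(_lobe_wave(t, 260, 30, 1.0), qt=300.0)
        assert "late_pointed" in tags

    def test_missing_control_rejected(self):
        from pvstrand.ecg import PseudoECG
        t = np.arange(100.0)
        ecg = PseudoECG(times=t, phi=np.zeros(100),
                        electrode_distance_cm=2.0)
        with pytest.raises(ParameterError):
            tag_twave_morphology(ecg, (0.0, 99.0), None)

    def test_tagging_is_pure(self):
        t = np.arange(300.0)
        phi = _lobe_wave(t, 80, 60, 1.0)
        assert self._tags(phi) == self._tags(phi)


class TestDirectionalProlongation:
    def test_kr_block_prolongs_qt(self, control_small):
        """80% I_Kr block at the same cycle length yields a per-beat QT
        strictly above control (directional, not an absolute target)."""
        from pvstrand.ionic import ChannelScaling
        from pvstrand.tissue import PacingProtocol, build_tissue, simulate
        from tests.conftest import SMALL_CONFIG
        blocked = simulate(
            build_tissue(SMALL_CONFIG, ChannelScaling(s_kr=0.2)),
            PacingProtocol(cl=750.0, n_beats=6, record_last=2))
        qt_ctl = compute_qt_tpe(control_small, -1).qt
        f = compute_qt_tpe(blocked, -2)
        qt_blk = f.qt if np.isfinite(f.qt) else 750.0
        assert qt_blk > qt_ctl
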