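"""EAD detection, alternans, categorisation and spatial patterns."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pvstrand.ead import (
    AlternansDetail,
    EadThresholds,
    classify_run,
    classify_spatial_pattern,
    detect_alternans,
    detect_eads,
    detect_eads_in_result,
)
from pvstrand.ecg import compute_qt_tpe, repolarization_times
from pvstrand.errors import ParameterError
from pvstrand.synthetic import (
    ead_bump_trace,
    square_ap_trace,
    synthetic_result,
)

THR = EadThresholds()


def brute_force_events(times, v, window, thr=THR):
    """Independent oracle: exhaustive scan over all local extremum pairs.

    Finds the primary complex bounds the same way as the contract states
    (scan from max(primary peak, activation + merge) to the final -70 mV
    downward crossing), then pairs every local minimum with the next local
    maximum and applies the amplitude and sustained-slope rules directly.
    """
    t0, t1 = window
    sel = (times >= t0) & (times <= t1)
    t, x = times[sel], v[sel]
    if len(x) < 3 or x.max() < thr.v_act:
        return []
    up = np.nonzero((x[:-1] < thr.v_act) & (x[1:] >= thr.v_act))[0]
    t_act = t[up[0] + 1] if up.size else t[0]
    start = max(int(np.argmax(x)),
                int(np.searchsorted(t, t_act + thr.primary_merge_ms)))
    down = np.nonzero((x[:-1] >= thr.v_rep) & (x[1:] < thr.v_rep))[0]
    end = int(down[-1] + 1) if down.size else len(x) - 1
    minima = [i for i in range(max(start, 1), end)
              if x[i] <= x[i - 1] and x[i] < x[i + 1]]
    maxima = [i for i in range(1, end + 1)
              if x[i] >= x[i - 1] and (i + 1 > end or x[i] > x[i + 1])]
    out = []
    for i in minima:
        nxt = [j for j in maxima if j > i]
        if not nxt:
            continue
        j = nxt[0]
        rise = x[j] - x[i]
        if rise < thr.a_min:
            continue
        # sustained-slope check on the rise segment
        seg_t, seg_x = t[i:j + 1], x[i:j + 1]
        run = 0.0
        ok = False
        for k in range(len(seg_t) - 1):
            dt = seg_t[k + 1] - seg_t[k]
            if seg_x[k + 1] - seg_x[k] >= thr.slope_min * dt - 1e-12:
                run += dt
                if run >= thr.slope_dur - 1e-9:
                    ok = True
                    break
            else:
                run = 0.0
        if ok:
            out.append((float(t[i]), float(rise)))
    return out


class TestDetectEads:
    times = 0.5 * np.arange(1600)

    def test_monotone_repolarisation_clean(self):
        v = square_ap_trace(self.times, 5.0, 300.0)
        assert detect_eads(self.times, v, (0.0, 700.0)) == []

    def test_recovers_constructed_takeoff_and_amplitude(self):
        """Plateau descending to -22 mV then a 31.18 mV secondary upstroke:
        the detector reports that takeoff and amplitude to within a
        sample."""
        v = ead_bump_trace(self.times, plateau_v=-22.0, plateau_until=450.0,
                           bumps=[(250.0, 80.0, 31.18)])
        events = detect_eads(self.times, v, (0.0, 700.0))
        assert len(events) == 1
        ev = events[0]
        assert ev.takeoff_v == pytest.approx(-22.0, abs=0.5)
        assert ev.amplitude == pytest.approx(31.18, abs=0.5)
        assert ev.onset_time == pytest.approx(250.0, abs=1.0)

    def test_subthreshold_ripples_ignored(self):
        v = ead_bump_trace(self.times, plateau_v=-22.0, plateau_until=450.0,
                           bumps=[(200.0, 30.0, 0.5), (250.0, 30.0, 0.5),
                                  (300.0, 30.0, 0.5)])
        assert detect_eads(self.times, v, (0.0, 700.0)) == []

    def test_no_primary_ap_returns_empty(self):
        v = np.full_like(self.times, -84.0)
        assert detect_eads(self.times, v, (0.0, 700.0)) == []

    def test_events_sorted_by_onset(self):
        v = ead_bump_trace(self.times, plateau_v=-25.0, plateau_until=500.0,
                           bumps=[(350.0, 60.0, 12.0), (200.0, 60.0, 8.0)])
        events = detect_eads(self.times, v, (0.0, 700.0))
        onsets = [e.onset_time for e in events]
        assert onsets == sorted(onsets)
        assert len(events) == 2

    @given(st.lists(st.tuples(st.floats(180.0, 520.0), st.floats(10.0, 60.0),
                              st.floats(0.2, 30.0)),
                    min_size=0, max_size=4))
    def test_matches_brute_force_oracle(self, bumps):
        """On piecewise-linear plateau-and-bump fixtures the production
        detector and the exhaustive extremum-scan oracle agree."""
        v = ead_bump_trace(self.times, plateau_v=-24.0, plateau_until=620.0,
                           bumps=bumps)
        events = detect_eads(self.times, v, (0.0, 790.0))
        oracle = brute_force_events(self.times, v, (0.0, 790.0))
        assert len(events) == len(oracle)
        for ev, (onset, rise) in zip(events, oracle):
            assert ev.onset_time == pytest.approx(onset)
            assert ev.amplitude == pytest.approx(rise)


class TestDetectAlternans:
    @staticmethod
    def _two_beat_result(apd0, apd1, cl=1000.0, n_cells=4,
                         second_activates=True):
        times = 0.5 * np.arange(int(2 * cl / 0.5) + 1)
        rows = []
        for _ in range(n_cells):
            tr = square_ap_trace(times, 5.0, apd0)
            if second_activates:
                tr = np.maximum(tr, square_ap_trace(times, cl + 5.0, apd1))
            rows.append(tr)
        return synthetic_result(np.stack(rows), cl=cl, n_beats=2)

    @staticmethod
    def _repol(res):
        return {b: repolarization_times(res, b) for b in res.recorded_beats}

    def test_identical_beats_negative(self):
        res = self._two_beat_result(250.0, 250.0)
        det = detect_alternans(res, self._repol(res))
        assert not det.any

    def test_apd_difference_positive(self):
        res = self._two_beat_result(200.0, 230.0)
        det = detect_alternans(res, self._repol(res))
        assert det.apd_alternans
        assert det.max_apd_delta == pytest.approx(30.0, abs=2.0)

    def test_conduction_two_to_one(self):
        """A beat that never reaches the distal end after one that does is
        the 2:1 stimulus-to-response pattern."""
        res = self._two_beat_result(250.0, 250.0, second_activates=False)
        det = detect_alternans(res, self._repol(res))
        assert det.conduction_alternans

    def test_single_beat_rejected(self):
        times = 0.5 * np.arange(800)
        v = np.tile(square_ap_trace(times, 5.0, 200.0), (4, 1))
        res = synthetic_result(v, cl=400.0, n_beats=1)
        with pytest.raises(ParameterError):
            detect_alternans(res, {0: repolarization_times(res, 0)})


class TestClassifyRun:
    @staticmethod
    def _result_with(category_shape, cl=1000.0):
        times = 0.5 * np.arange(int(2 * cl / 0.5) + 1)
        rows = []
        for _ in range(4):
            if category_shape == "quiet":
                rows.append(np.full_like(times, -84.0))
            else:
                tr = np.maximum(square_ap_trace(times, 5.0, 250.0),
                                square_ap_trace(times, cl + 5.0, 250.0))
                rows.append(tr)
        return synthetic_result(np.stack(rows), cl=cl, n_beats=2)

    def _features(self, res):
        return [compute_qt_tpe(res, b) for b in res.recorded_beats]

    def test_quiet_run_is_no_excitation(self):
        res = self._result_with("quiet")
        cat = classify_run(res, self._features(res), [], control_qt=250.0)
        assert cat == "no_excitation"

    def test_ead_takes_precedence_over_alternans(self):
        res = self._result_with("normal")
        from pvstrand.ead import EADEvent
        ev = [EADEvent(cell_index=1, beat_index=1, onset_time=1200.0,
                       takeoff_v=-22.0, amplitude=10.0)]
        alt = AlternansDetail(apd_alternans=True, conduction_alternans=False,
                              max_apd_delta=30.0)
        cat = classify_run(res, self._features(res), ev, control_qt=250.0,
                           alternans=alt)
        assert cat == "ead"

    def test_prolongation_above_ten_percent(self):
        res = self._result_with("normal")  # qt ~ 255
        assert classify_run(res, self._features(res), [],
                            control_qt=200.0) == "ap_prolongation"
        assert classify_run(res, self._features(res), [],
                            control_qt=250.0) == "control"

    def test_missing_control_rejected(self):
        res = self._result_with("normal")
        with pytest.raises(ParameterError):
            classify_run(res, self._features(res), [], control_qt=np.nan)

    def test_control_run_classified_control(self, control_small):
        events = detect_eads_in_result(control_small)
        feats = [compute_qt_tpe(control_small, b)
                 for b in control_small.recorded_beats]
        repol = {b: f.repol_times for b, f in
                 zip(control_small.recorded_beats, feats)}
        alt = detect_alternans(control_small, repol)
        cat = classify_run(control_small, feats, events,
                           control_qt=feats[-1].qt, alternans=alt)
        assert cat == "control"


def _pattern_result(onset_by_cell, cl=1000.0, n_cells=40, bump_amp=20.0,
                    n_bumps=1, repolarise=True, bump_spacing=60.0):
    """Strand where selected cells carry EAD bumps at given onsets."""
    times = 0.5 * np.arange(int(cl / 0.5) + 1)
    rows = []
    for i in range(n_cells):
        if i in onset_by_cell:
            onset = onset_by_cell[i]
            bumps = [(onset + k * bump_spacing, 40.0, bump_amp)
                     for k in range(n_bumps)]
            t_rep = (onset + n_bumps * bump_spacing + 60.0 if repolarise
                     else 1e9)
            rows.append(ead_bump_trace(times, plateau_v=-24.0,
                                       plateau_until=t_rep, bumps=bumps,
                                       t_repol=t_rep))
        else:
            rows.append(square_ap_trace(times, 5.0, 250.0))
    return synthetic_result(np.stack(rows), cl=cl, n_beats=1)


class TestSpatialPatterns:
    def test_synchronized_across_all_types(self):
        """EAD onsets in all four tissue types within the synchrony window."""
        onsets = {i: 300.0 + (i % 4) * 2.0 for i in range(0, 40, 3)}
        res = _pattern_result(onsets)
        events = detect_eads_in_result(res)
        sub, cv = classify_spatial_pattern(res, events)
        assert sub == "synchronized"
        assert cv is None

    def test_localized_to_m_layer(self):
        onsets = {i: 300.0 for i in range(20, 30)}  # M layer of 40 cells
        res = _pattern_result(onsets)
        events = detect_eads_in_result(res)
        sub, _ = classify_spatial_pattern(res, events)
        assert sub == "localized"

    def test_unidirectional_antegrade_with_cv(self):
        """Onsets advancing 0.5 ms per 100 um cell toward the epicardium:
        an antegrade EAD wave at 0.2 m/s."""
        onsets = {i: 300.0 + 0.5 * (i - 20) for i in range(20, 40)}
        res = _pattern_result(onsets)
        events = detect_eads_in_result(res)
        sub, cv = classify_spatial_pattern(res, events)
        assert sub == "unidirectional_antegrade"
        assert cv == pytest.approx(0.2, rel=0.05)

    def test_unidirectional_retrograde(self):
        onsets = {i: 300.0 + 0.5 * (39 - i) for i in range(20, 40)}
        res = _pattern_result(onsets)
        events = detect_eads_in_result(res)
        sub, cv = classify_spatial_pattern(res, events)
        assert sub == "unidirectional_retrograde"
        assert cv == pytest.approx(0.2, rel=0.05)

    def test_discordant_groups(self):
        onsets = {i: 300.0 for i in range(0, 8)}
        onsets.update({i: 400.0 for i in range(30, 38)})
        res = _pattern_result(onsets)
        events = detect_eads_in_result(res)
        sub, _ = classify_spatial_pattern(res, events)
        assert sub == "discordant"

    def test_oscillatory_self_terminated(self):
        onsets = {i: 250.0 for i in range(20, 30)}
        res = _pattern_result(onsets, n_bumps=4, repolarise=True)
        events = detect_eads_in_result(res)
        sub, _ = classify_spatial_pattern(res, events)
        assert sub == "oscillatory_self_terminated"

    def test_oscillatory_sustained(self):
        onsets = {i: 250.0 for i in range(20, 30)}
        res = _pattern_result(onsets, n_bumps=4, repolarise=False,
                              bump_spacing=120.0)
        events = detect_eads_in_result(res)
        sub, _ = classify_spatial_pattern(res, events)
        assert sub == "oscillatory_sustained"

    def test_requires_events(self):
        res = _pattern_result({})
        with pytest.raises(ParameterError):
            classify_spatial_pattern(res, [])

    def test_order_invariance(self):
        """Shuffling event order never changes the label (pure function of
        the event set)."""
        onsets = {i: 300.0 + 0.5 * (i - 20) for i in range(20, 40)}
        res = _pattern_result(onsets)
        events = detect_eads_in_result(res)
        rng = np.random.default_rng(3)
        shuffled = list(events)
        rng.shuffle(shuffled)
        assert (classify_spatial_pattern(res, events)
                == classify_spatial_pattern(res, shuffled))
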