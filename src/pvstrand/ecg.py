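"""Pseudo-ECG, repolarisation maps, QT/T_pe and T-wave morphology tags.

The extracellular unipolar potential at a virtual electrode on the strand
axis beyond the epicardial end is the lead-field weighted sum of the axial
voltage gradient:

    phi(t) = -K * sum_faces D_f * (dV/dx)|_f * d(1/r)/dx|_f * dx

with r the distance from the face midpoint to the electrode and K = 1
(amplitudes are reported in arbitrary units). QT of a beat is the time from
its stimulus to the last complete repolarisation anywhere in the strand;
T_pe (the transmural-dispersion index) is the spread between the first and
the last repolarising cell. "Complete repolarisation" is the last downward
crossing of V_rep = -70 mV inside the beat's analysis window, so a
re-depolarisation (an EAD) postpones it.

All interpretive constants (thresholds, window fractions) live in one
configuration block, `EcgThresholds`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy.signal import find_peaks

from .errors import ParameterError
from .tissue import SimulationResult

TWaveTag = str  # {"upright", "inverted", "biphasic", "notched", "broad_based", "late_pointed"}


@dataclass(frozen=True)
class EcgThresholds:
    """Operational constants of the feature extractor.

    v_rep: complete-repolarisation threshold (mV, last downward crossing).
    qrs_exclusion_ms: part of the beat after ventricular activation that is
        never scanned for T-waves (the QRS analogue).
    amp_floor_frac: lobes and notches count only above this fraction of the
        control T-peak amplitude at the same cycle length.
    broad_factor: a T-wave is broad-based when its half-maximum duration
        exceeds this multiple of control.
    late_frac / pointed_factor: late_pointed requires the T-peak after this
        fraction of QT and a half-maximum width below this multiple of
        control.
    """

    v_rep: float = -70.0
    qrs_exclusion_ms: float = 80.0
    amp_floor_frac: float = 0.05
    broad_factor: float = 1.5
    late_frac: float = 0.70
    pointed_factor: float = 0.6


DEFAULT_THRESHOLDS = EcgThresholds()


@dataclass
class PseudoECG:
    """Electrode signal on the source result's output time grid."""

    times: np.ndarray
    phi: np.ndarray
    electrode_distance_cm: float


@dataclass
class TWaveReference:
    """Control T-wave quantities used by the relative morphology tags."""

    peak_amp: float
    half_max_duration: float
    qt: float


@dataclass
class BeatFeatures:
    """Per-beat repolarisation features; qt is NaN when no cell repolarises."""

    beat_index: int
    stim_time: float
    qt: float
    t_pe: float
    repol_times: np.ndarray
    first_repol_cell: int
    last_repol_cell: int
    n_unrepolarized: int
    t_wave_tags: set = field(default_factory=set)

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.qt))


def compute_pseudo_ecg(result: SimulationResult,
                       electrode_distance_cm: float = 2.0,
                       k: float = 1.0) -> PseudoECG:
    """Unipolar electrode potential beyond the epicardial end of the strand."""
    if electrode_distance_cm <= 0:
        raise ParameterError("electrode must sit outside the tissue "
                             "(distance > 0)")
    cfg = result.config
    dx = cfg.dx_cm
    n = result.n_cells
    # face midpoints at (i+1) dx for faces between cells i and i+1;
    # electrode on the axis at L + distance
    x_face = dx * (np.arange(n - 1) + 1.0)
    x_e = cfg.length_cm + electrode_distance_cm
    r = x_e - x_face
    from .tissue import build_tissue  # face coefficients of this geometry
    face_d = build_tissue(cfg, result.scaling).face_d
    # d(1/r)/dx = +1/r^2 for an electrode beyond the far end
    weights = face_d / r ** 2
    dv = np.diff(result.v, axis=0)          # (n-1, n_times), (dV/dx)*dx
    phi = -k * (weights[:, None] * dv).sum(axis=0)
    return PseudoECG(times=result.times.copy(), phi=phi,
                     electrode_distance_cm=electrode_distance_cm)


def repolarization_times(result: SimulationResult, beat_index: int,
                         thresholds: EcgThresholds = DEFAULT_THRESHOLDS
                         ) -> np.ndarray:
    """Per-cell last downward crossing of V_rep in the beat window (ms).

    NaN marks cells that do not completely repolarise inside the window
    (including cells that never activated and so never cross at all).
    """
    if beat_index < 0:
        beat_index = result.protocol.n_beats + beat_index
    sl = result.window_slice(beat_index)
    t = result.times[sl]
    v = result.v[:, sl]
    if v.shape[1] < 2:
        raise ParameterError("beat window not inside the recorded interval")
    thr = thresholds.v_rep
    down = (v[:, :-1] >= thr) & (v[:, 1:] < thr)
    out = np.full(result.n_cells, np.nan)
    for i in range(result.n_cells):
        idx = np.nonzero(down[i])[0]
        if idx.size:
            k = idx[-1]
            frac = (v[i, k] - thr) / (v[i, k] - v[i, k + 1])
            out[i] = t[k] + frac * (t[k + 1] - t[k])
    return out


def compute_qt_tpe(result: SimulationResult, beat_index: int,
                   thresholds: EcgThresholds = DEFAULT_THRESHOLDS
                   ) -> BeatFeatures:
    """QT (stimulus to last repolarisation) and T_pe (first-to-last spread)."""
    if beat_index < 0:
        beat_index = result.protocol.n_beats + beat_index
    stim_time = float(result.stim_times[beat_index])
    repol = repolarization_times(result, beat_index, thresholds)
    finite = np.isfinite(repol)
    n_unrep = int(result.n_cells - finite.sum())
    if not finite.any():
        return BeatFeatures(beat_index=beat_index, stim_time=stim_time,
                            qt=np.nan, t_pe=np.nan, repol_times=repol,
                            first_repol_cell=-1, last_repol_cell=-1,
                            n_unrepolarized=n_unrep)
    first = int(np.nanargmin(repol))
    last = int(np.nanargmax(repol))
    return BeatFeatures(
        beat_index=beat_index, stim_time=stim_time,
        qt=float(repol[last] - stim_time),
        t_pe=float(repol[last] - repol[first]),
        repol_times=repol, first_repol_cell=first, last_repol_cell=last,
        n_unrepolarized=n_unrep)


def _dominant_lobe(t, phi, floor):
    """(sign, peak_time, peak_amp) of the largest |phi| lobe, or None."""
    if len(phi) == 0:
        return None
    i = int(np.argmax(np.abs(phi)))
    amp = abs(phi[i])
    if amp < floor:
        return None
    return int(np.sign(phi[i])), float(t[i]), float(amp)


def _half_max_duration(t, y, peak_amp):
    """Total time y spends above half the peak amplitude."""
    above = y >= 0.5 * peak_amp
    if not above.any():
        return 0.0
    dt = np.diff(t)
    return float(np.sum(dt[above[:-1]]))


def twave_window(result: SimulationResult, beat_index: int,
                 thresholds: EcgThresholds = DEFAULT_THRESHOLDS
                 ) -> tuple[float, float]:
    """Beat window minus the QRS analogue after ventricular activation."""
    if beat_index < 0:
        beat_index = result.protocol.n_beats + beat_index
    t0, t1 = result.beat_window(beat_index)
    act = result.act_times[beat_index]
    n_p = result.config.cells_per_layer
    vent_act = act[n_p:]
    t_arr = np.nanmin(vent_act) if np.isfinite(vent_act).any() else t0
    return float(t_arr + thresholds.qrs_exclusion_ms), float(t1)


def control_twave_reference(ecg: PseudoECG, result: SimulationResult,
                            beat_index: int,
                            thresholds: EcgThresholds = DEFAULT_THRESHOLDS
                            ) -> TWaveReference:
    """Measure the control T-wave (amplitude, width, QT) for relative tags."""
    lo, hi = twave_window(result, beat_index, thresholds)
    sel = (ecg.times >= lo) & (ecg.times < hi)
    t, phi = ecg.times[sel], ecg.phi[sel]
    lobe = _dominant_lobe(t, phi, 0.0)
    if lobe is None:
        raise ParameterError("control window contains no T-wave")
    sign, _, amp = lobe
    dur = _half_max_duration(t, sign * phi, amp)
    feats = compute_qt_tpe(result, beat_index, thresholds)
    return TWaveReference(peak_amp=amp, half_max_duration=dur, qt=feats.qt)


def tag_twave_morphology(ecg: PseudoECG, window: tuple[float, float],
                         control: TWaveReference,
                         qt: float | None = None,
                         stim_time: float = 0.0,
                         thresholds: EcgThresholds = DEFAULT_THRESHOLDS
                         ) -> set:
    """Deterministic morphology tags for one beat's T-wave window.

    Rules (all relative quantities against the control reference at the
    same cycle length): polarity from the dominant-lobe sign; biphasic when
    both signed lobes clear the amplitude floor; notched when two
    same-sign peaks with prominence above the floor flank a trough;
    broad_based when the half-maximum duration exceeds broad_factor x
    control; late_pointed when the T-peak falls after late_frac of QT and
    the half-maximum width is below pointed_factor x control.
    """
    if control is None:
        raise ParameterError("tag_twave_morphology requires the control "
                             "T-wave reference at the same cycle length")
    lo, hi = window
    sel = (ecg.times >= lo) & (ecg.times < hi)
    t, phi = ecg.times[sel], ecg.phi[sel]
    floor = thresholds.amp_floor_frac * control.peak_amp
    tags: set = set()
    lobe = _dominant_lobe(t, phi, floor)
    if lobe is None:
        return tags
    sign, t_peak, amp = lobe
    tags.add("upright" if sign > 0 else "inverted")
    if phi.max() >= floor and -phi.min() >= floor:
        tags.add("biphasic")
    peaks, props = find_peaks(sign * phi, prominence=floor)
    if len(peaks) >= 2:
        tags.add("notched")
    dur = _half_max_duration(t, sign * phi, amp)
    if dur > thresholds.broad_factor * control.half_max_duration:
        tags.add("broad_based")
    qt_ref = qt if qt is not None and np.isfinite(qt) else control.qt
    late = (t_peak - stim_time) > thresholds.late_frac * qt_ref
    pointed = dur < thresholds.pointed_factor * control.half_max_duration
    if late and pointed:
        tags.add("late_pointed")
    return tags


def beat_features(result: SimulationResult, beat_index: int,
                  ecg: PseudoECG | None = None,
                  control: TWaveReference | None = None,
                  thresholds: EcgThresholds = DEFAULT_THRESHOLDS
                  ) -> BeatFeatures:
    """QT/T_pe features of a beat, with T-wave tags when a control is given."""
    feats = compute_qt_tpe(result, beat_index, thresholds)
    if ecg is not None and control is not None:
        window = twave_window(result, beat_index, thresholds)
        feats.t_wave_tags = tag_twave_morphology(
            ecg, window, control, qt=feats.qt, stim_time=feats.stim_time,
            thresholds=thresholds)
    return feats
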