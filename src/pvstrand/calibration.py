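"""Conduction-velocity and junctional-delay measurement and calibration.

Conduction velocity is measured from activation times (first upward
crossing of -20 mV) between probes at 25% and 75% of a segment, away from
stimulus and boundary artefacts. The Purkinje and ventricular diffusion
coefficients are tuned by bisection on homogeneous strands against the
experimental targets (2 m/s and 0.5 m/s); the junctional ratio E_R is then
tuned on the full heterogeneous strand so the activation delay between the
last Purkinje cell and the first endocardial cell matches the 4.364 ms
experimental junction delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .errors import CalibrationError, MeasurementError, ParameterError
from .ionic import (
    CONTROL_SCALING,
    DT_MAX,
    DT_MIN,
    initial_state,
    make_cell,
)
from .tissue import (
    PacingProtocol,
    SimulationResult,
    TissueConfig,
    V_ACT,
    build_tissue,
    simulate,
)

CV_TARGET_PURKINJE = 2.0      # m/s
CV_TARGET_VENTRICULAR = 0.5   # m/s
PVJ_DELAY_TARGET = 4.364      # ms

CV_REL_TOL = 0.02
DELAY_ABS_TOL = 0.05          # ms

# per-kind brackets (mm^2/ms): the upper ends are ignition-limited (a very
# strong coupling sinks the stimulus charge before a wavefront can form)
D_BRACKETS = {"Purkinje": (0.3, 3.0), "ventricular": (0.1, 2.0)}
# the lower end sits just above junctional conduction block for the shipped model
ER_BRACKET = (0.06, 5.0)

_SEGMENT_KINDS = {"Purkinje": "P", "ventricular": "Endo"}


@dataclass
class ConductionMeasurement:
    """CV (m/s) over a segment plus the underlying activation times."""

    cv: float
    activation_times: np.ndarray
    segment: tuple[int, int]
    pvj_delay: float | None = None


def activation_times(result: SimulationResult, beat_index: int) -> np.ndarray:
    """Per-cell first upward crossing of the activation threshold (ms).

    Cells that never cross within the beat window are NaN (non-activated).
    Uses the kernel-precise crossing times recorded during integration.
    """
    if beat_index < 0:
        beat_index = result.protocol.n_beats + beat_index
    if not (0 <= beat_index < result.protocol.n_beats):
        raise ParameterError(f"beat_index {beat_index} out of range")
    if beat_index not in result.recorded_beats:
        # activation times are tracked for every beat by the kernel, so the
        # request is still answerable; guard only against nonsense indices
        pass
    return result.act_times[beat_index].copy()


def activation_times_from_v(times: np.ndarray, v: np.ndarray,
                            threshold: float = V_ACT) -> np.ndarray:
    """Threshold-crossing activation times from a sampled voltage map.

    Fallback for analysis-only inputs where kernel-precise times are not
    available; linear interpolation between samples.
    """
    n_cells, _ = v.shape
    out = np.full(n_cells, np.nan)
    for i in range(n_cells):
        below = v[i, :-1] < threshold
        above = v[i, 1:] >= threshold
        idx = np.nonzero(below & above)[0]
        if idx.size:
            k = idx[0]
            frac = (threshold - v[i, k]) / (v[i, k + 1] - v[i, k])
            out[i] = times[k] + frac * (times[k + 1] - times[k])
    return out


def measure_cv(times: np.ndarray, segment: tuple[int, int],
               dx_cm: float) -> float:
    """CV in m/s from per-cell activation times over [segment) cell indices.

    Probes sit at 25% and 75% of the segment; a non-activated probe or a
    zero time difference is a measurement error (conduction failure or
    effectively infinite CV).
    """
    lo, hi = segment
    n = hi - lo
    if n < 2:
        raise ParameterError("segment must contain at least 2 cells")
    i25 = lo + int(round(0.25 * (n - 1)))
    i75 = lo + int(round(0.75 * (n - 1)))
    if i25 == i75:
        raise ParameterError("segment too short for distinct probes")
    t25, t75 = times[i25], times[i75]
    if np.isnan(t25) or np.isnan(t75):
        raise MeasurementError("probe cell did not activate (conduction failure)")
    dt_ms = t75 - t25
    if dt_ms <= 0:
        raise MeasurementError("non-positive activation-time difference "
                               "(infinite or retrograde CV)")
    dist_mm = (i75 - i25) * dx_cm * 10.0
    return (dist_mm / dt_ms)  # mm/ms == m/s


def pvj_delay(result: SimulationResult, beat_index: int = -1) -> float:
    """Activation-time difference (ms) across the junctional face."""
    act = activation_times(result, beat_index)
    n_p = result.config.cells_per_layer
    t_p, t_endo = act[n_p - 1], act[n_p]
    if np.isnan(t_p) or np.isnan(t_endo):
        raise MeasurementError("junction cell did not activate")
    return float(t_endo - t_p)


# ---------------------------------------------------------------------------
# homogeneous-strand CV evaluation used by the bisection

def _homogeneous_cv(cell_type: str, d: float, n_cells: int = 400,
                    dx_cm: float = 0.01, cl: float = 700.0,
                    n_beats: int = 1) -> float:
    """CV on a uniform strand of one cell type with face coefficient d.

    The strand is long enough (4 cm) that the measurement segment
    (cells 100-300, probes at 150 and 250) sits many foot-lengths away from
    both the ignition region and the sealed far end, where the front speed
    has settled.
    """
    cell = make_cell(cell_type, CONTROL_SCALING)
    n = n_cells
    st = initial_state()
    v = np.full(n, st.v)
    y = np.tile(st.gates, (n, 1))
    cai = np.full(n, st.concentrations[0])
    g = np.tile(cell.conductance_vector(), (n, 1))
    face_d = np.full(n - 1, d)
    stim_idx = np.arange(10, dtype=np.int64)
    status, c_err, t_err, times, v_rec, act = K.integrate_strand(
        v, y, cai, g, cell.tables(), cell.tau_hl, face_d, dx_cm * 10.0,
        stim_idx, -100.0, 3.0, cl, n_beats, cl * (n_beats - 1), 1.0,
        DT_MIN, DT_MAX, V_ACT)
    if status != K.STATUS_OK:
        raise CalibrationError(f"integration diverged at D = {d}")
    return measure_cv(act[n_beats - 1], (100, 300), dx_cm)


def calibrate_diffusion(segment_kind: str, target_cv: float,
                        bracket: tuple[float, float] | None = None,
                        rel_tol: float = CV_REL_TOL,
                        max_iter: int = 60) -> tuple[float, float]:
    """Bisect the diffusion coefficient to a CV target on a uniform strand.

    Returns (d, achieved_cv). CV is monotone in D over the bracket, which
    the bisection checks as it proceeds.
    """
    if target_cv <= 0:
        raise ParameterError("target_cv must be > 0")
    if segment_kind not in _SEGMENT_KINDS:
        raise ParameterError(
            f"segment_kind must be one of {sorted(_SEGMENT_KINDS)}")
    ct = _SEGMENT_KINDS[segment_kind]
    if bracket is None:
        bracket = D_BRACKETS[segment_kind]
    lo, hi = bracket

    def cv_at(d):
        try:
            return _homogeneous_cv(ct, d)
        except MeasurementError:
            return 0.0  # conduction failure at very small D

    cv_lo, cv_hi = cv_at(lo), cv_at(hi)
    if not (cv_lo < target_cv < cv_hi):
        raise CalibrationError(
            f"bracket D = {bracket} gives CV in [{cv_lo:.3f}, {cv_hi:.3f}] "
            f"m/s which does not straddle {target_cv}; expand the bracket")
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)  # log-midpoint: CV ~ sqrt(D)
        cv_mid = cv_at(mid)
        if abs(cv_mid - target_cv) / target_cv < rel_tol:
            return float(mid), float(cv_mid)
        if cv_mid < target_cv:
            lo, cv_lo = mid, cv_mid
        else:
            hi, cv_hi = mid, cv_mid
    raise CalibrationError("bisection failed to converge")


def calibrate_er(target_delay: float = PVJ_DELAY_TARGET,
                 d_p: float | None = None, d_v: float | None = None,
                 bracket: tuple[float, float] = ER_BRACKET,
                 abs_tol: float = DELAY_ABS_TOL,
                 cells_per_layer: int = 50,
                 max_iter: int = 60) -> tuple[float, float]:
    """Bisect E_R so the PVJ activation delay matches the target (ms).

    The delay is monotone non-increasing in E_R (stronger junctional
    coupling conducts sooner); returns (e_r, achieved_delay).
    """
    if target_delay <= 0:
        raise CalibrationError(
            "a junction always delays conduction; target must be > 0")
    from .tissue import DEFAULT_D_P, DEFAULT_D_V
    d_p = DEFAULT_D_P if d_p is None else d_p
    d_v = DEFAULT_D_V if d_v is None else d_v

    def delay_at(e_r):
        cfg = TissueConfig(cells_per_layer=cells_per_layer, d_p=d_p, d_v=d_v,
                           e_r=e_r,
                           length_cm=2.0 * cells_per_layer / 50.0)
        tissue = build_tissue(cfg, CONTROL_SCALING)
        res = simulate(tissue, PacingProtocol(cl=400.0, n_beats=1,
                                              record_last=1), output_dt=1.0)
        return pvj_delay(res, 0)

    lo, hi = bracket
    try:
        dl_lo, dl_hi = delay_at(lo), delay_at(hi)
    except MeasurementError as exc:
        raise CalibrationError(f"conduction block inside bracket: {exc}")
    if not (dl_hi < target_delay < dl_lo):
        raise CalibrationError(
            f"bracket E_R = {bracket} gives delays [{dl_hi:.3f}, {dl_lo:.3f}]"
            f" ms which do not straddle {target_delay}")
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)
        dl = delay_at(mid)
        if abs(dl - target_delay) < abs_tol:
            return float(mid), float(dl)
        if dl > target_delay:
            lo = mid
        else:
            hi = mid
    raise CalibrationError("bisection failed to converge")


def calibrate_profile(cells_per_layer: int = 50) -> dict:
    """Run the full calibration and return the diffusion profile report."""
    d_p, cv_p = calibrate_diffusion("Purkinje", CV_TARGET_PURKINJE)
    d_v, cv_v = calibrate_diffusion("ventricular", CV_TARGET_VENTRICULAR)
    e_r, delay = calibrate_er(PVJ_DELAY_TARGET, d_p=d_p, d_v=d_v,
                              cells_per_layer=cells_per_layer)
    return {
        "d_p": d_p, "cv_p": cv_p, "cv_p_target": CV_TARGET_PURKINJE,
        "d_v": d_v, "cv_v": cv_v, "cv_v_target": CV_TARGET_VENTRICULAR,
        "e_r": e_r, "pvj_delay": delay, "pvj_delay_target": PVJ_DELAY_TARGET,
    }
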