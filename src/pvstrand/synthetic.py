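"""Constructed voltage maps and traces for exercising the analysis stack
without running the solver.

Every generator returns genuine `SimulationResult` objects (or plain
traces) with analytically known activation, repolarisation and EAD
properties, so feature extractors and classifiers can be tested against
exact expectations.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .errors import ParameterError
from .ionic import ChannelScaling
from .tissue import PacingProtocol, SimulationResult, TissueConfig

V_REST = -84.0
V_PEAK = 20.0
V_PLATEAU = 10.0


def synthetic_result(v: np.ndarray, cl: float, n_beats: int,
                     output_dt: float = 0.5,
                     config: TissueConfig | None = None,
                     record_last: int | None = None) -> SimulationResult:
    """Wrap a constructed cells x times map into a SimulationResult.

    The map is assumed to start at t = 0 (beat 0); activation times are
    extracted from the map itself with the standard -20 mV upward-crossing
    rule, so constructed upstrokes yield exact known values.
    """
    n_cells, n_times = v.shape
    if n_cells % 4:
        raise ParameterError("synthetic strands need a multiple of 4 cells")
    if record_last is None:
        record_last = n_beats
    cfg = config or TissueConfig(cells_per_layer=n_cells // 4,
                                 length_cm=0.01 * n_cells)
    if cfg.n_cells != n_cells:
        raise ParameterError("config geometry does not match the map")
    times = output_dt * np.arange(n_times)
    protocol = PacingProtocol(cl=cl, n_beats=n_beats, record_last=record_last)
    act = np.full((n_beats, n_cells), np.nan)
    for b in range(n_beats):
        t0, t1 = b * cl, (b + 1) * cl
        sel = (times >= t0) & (times < t1)
        ts = times[sel]
        for i in range(n_cells):
            x = v[i, sel]
            up = np.nonzero((x[:-1] < -20.0) & (x[1:] >= -20.0))[0]
            if up.size:
                k = up[0]
                frac = (-20.0 - x[k]) / (x[k + 1] - x[k])
                act[b, i] = ts[k] + frac * (ts[k + 1] - ts[k])
    return SimulationResult(
        times=times, v=v, stim_times=cl * np.arange(n_beats),
        act_times=act, cell_types=cfg.cell_types(), config=cfg,
        protocol=protocol, scaling=ChannelScaling(), output_dt=output_dt)


def square_ap_trace(times: np.ndarray, t_act: float, apd: float,
                    v_rest: float = V_REST, v_plateau: float = V_PLATEAU,
                    ramp: float = 1.0) -> np.ndarray:
    """Trapezoidal action potential: upstroke at t_act, repolarised by
    t_act + apd (the -70 mV downward crossing sits at t_act + apd)."""
    v = np.full_like(times, v_rest, dtype=float)
    up = np.clip((times - t_act) / ramp, 0.0, 1.0)
    down_start = t_act + apd - ramp * (v_plateau - (-70.0)) / (v_plateau - v_rest)
    down = np.clip((times - down_start) / ramp, 0.0, 1.0)
    v = v_rest + (v_plateau - v_rest) * up - (v_plateau - v_rest) * down
    return v


def ead_bump_trace(times: np.ndarray, t_act: float = 0.0,
                   plateau_v: float = -22.0, plateau_until: float = 300.0,
                   bumps: Sequence[tuple[float, float, float]] = (),
                   t_repol: float | None = None,
                   v_rest: float = V_REST, v_peak: float = V_PEAK
                   ) -> np.ndarray:
    """AP with a descending plateau and triangular secondary upstrokes.

    `bumps` is a sequence of (onset, duration, amplitude); each bump rises
    linearly from the plateau level at its onset to plateau + amplitude at
    onset + duration/2 and falls back by onset + duration. The trace
    repolarises to rest at `t_repol` (default: plateau_until).
    """
    t_repol = plateau_until if t_repol is None else t_repol
    v = np.full_like(times, v_rest, dtype=float)
    # primary upstroke and early repolarisation toward the plateau level
    rising = (times >= t_act) & (times < t_act + 2.0)
    v[rising] = v_rest + (v_peak - v_rest) * (times[rising] - t_act) / 2.0
    settling = (times >= t_act + 2.0) & (times < t_act + 50.0)
    v[settling] = v_peak + (plateau_v - v_peak) * (times[settling] - t_act - 2.0) / 48.0
    plate = (times >= t_act + 50.0) & (times < t_repol)
    v[plate] = plateau_v
    for onset, dur, amp in bumps:
        half = dur / 2.0
        seg = (times >= onset) & (times < onset + dur)
        tt = times[seg]
        shape = np.where(tt < onset + half,
                         (tt - onset) / half,
                         1.0 - (tt - onset - half) / half)
        v[seg] = np.maximum(v[seg], plateau_v + amp * shape)
    # final repolarisation
    tail = (times >= t_repol) & (times < t_repol + 4.0)
    v[tail] = plateau_v + (v_rest - plateau_v) * (times[tail] - t_repol) / 4.0
    v[times >= t_repol + 4.0] = v_rest
    return v


def linear_activation_map(n_cells: int, dt_per_cell: float, cl: float,
                          n_beats: int = 1, apd: float = 200.0,
                          t_first: float = 5.0, output_dt: float = 0.5
                          ) -> SimulationResult:
    """Strand where activation advances exactly dt_per_cell per cell."""
    n_times = int(round(cl * n_beats / output_dt)) + 1
    times = output_dt * np.arange(n_times)
    v = np.empty((n_cells, n_times))
    for i in range(n_cells):
        trace = np.full(n_times, V_REST)
        for b in range(n_beats):
            t_act = b * cl + t_first + i * dt_per_cell
            trace = np.maximum(trace, square_ap_trace(times, t_act, apd))
        v[i] = trace
    return synthetic_result(v, cl=cl, n_beats=n_beats, output_dt=output_dt)


def repolarization_map_result(repol_offsets: np.ndarray, cl: float = 1000.0,
                              t_act: float = 5.0, output_dt: float = 0.5
                              ) -> SimulationResult:
    """Strand of simultaneous activation with per-cell repolarisation at
    t_act + repol_offsets[i] (square APs)."""
    repol_offsets = np.asarray(repol_offsets, dtype=float)
    n_cells = len(repol_offsets)
    n_times = int(round(cl / output_dt)) + 1
    times = output_dt * np.arange(n_times)
    v = np.stack([square_ap_trace(times, t_act, off)
                  for off in repol_offsets])
    return synthetic_result(v, cl=cl, n_beats=1, output_dt=output_dt)


def uniform_map_result(n_cells: int = 8, value: float = -30.0,
                       cl: float = 100.0, output_dt: float = 0.5
                       ) -> SimulationResult:
    """Spatially uniform (possibly time-varying) map; zero pseudo-ECG."""
    n_times = int(round(cl / output_dt)) + 1
    v = np.full((n_cells, n_times), value)
    return synthetic_result(v, cl=cl, n_beats=1, output_dt=output_dt)
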