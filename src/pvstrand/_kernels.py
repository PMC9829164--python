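"""Compiled inner loops: reaction step, diffusion substeps, tissue integrator.

State layout per cell: v (mV), gates y = [m, h, j, d, f, x, xs, r, s, hl],
cai (mM). Conductance layout per cell:
g = [g_na, g_nal, g_cal, g_kr, g_ks, g_k1, g_to, g_kp, g_b, k_naca]
(channel-block scalings are folded into g_kr and g_cal before the kernel runs).

The integrator uses Lie (first-order) operator splitting: one adaptive
reaction step, then the diffusion operator sub-cycled at its explicit
stability bound within the same interval. Gate updates are Rush-Larsen
(exponential) for the stiff gates m, h, j, d and forward Euler for the slow
gates; all gates are clamped to [0, 1], Cai to a positive floor.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._rates import (
    E_B, E_K1, E_KR, E_KS, E_NA, TAB_DV, TAB_N, TAB_VMIN,
)

# status codes returned by integrate_strand
STATUS_OK = 0
STATUS_DIVERGED = 1

CAI_FLOOR = 1e-7
V_DIVERGE = 200.0

NG = 10  # gates per cell
NP = 10  # conductances per cell


@njit(cache=True, inline="always")
def _look(tab, k, w, col):
    return tab[k, col] + w * (tab[k + 1, col] - tab[k, col])


@njit(cache=True)
def reaction_step(v, y, cai, g, tab, dt, istim, tau_hl, dv_out):
    """Advance gates/Cai by dt and write the membrane-voltage increment.

    `dv_out[i]` receives dt * (-I_ion - I_stim); the caller owns applying it
    (the tissue integrator adds diffusion, the single-cell path adds it
    directly). Returns the total ionic current of the last cell evaluated
    (unused; kept for debugging hooks).
    """
    n = v.shape[0]
    inv_dv = 1.0 / TAB_DV
    for i in range(n):
        vi = v[i]
        u = (vi - TAB_VMIN) * inv_dv
        k = int(u)
        if k < 0:
            k = 0
        elif k > TAB_N - 2:
            k = TAB_N - 2
        w = u - k

        m = y[i, 0]
        h = y[i, 1]
        jg = y[i, 2]
        d = y[i, 3]
        f = y[i, 4]
        x = y[i, 5]
        xs = y[i, 6]
        r = y[i, 7]
        s = y[i, 8]
        hl = y[i, 9]
        ca = cai[i]

        esi = 7.7 - 13.0287 * np.log(ca)
        i_na = g[i, 0] * m * m * m * h * jg * (vi - E_NA)
        i_nal = g[i, 1] * _look(tab, k, w, 19) * hl * (vi - E_NA)
        i_cal = g[i, 2] * d * f * (vi - esi)
        i_kr = g[i, 3] * x * _look(tab, k, w, 20) * (vi - E_KR)
        i_ks = g[i, 4] * xs * xs * (vi - E_KS)
        i_k1 = g[i, 5] * _look(tab, k, w, 21) * (vi - E_K1)
        i_to = g[i, 6] * r * s * (vi - E_K1)
        i_kp = g[i, 7] * _look(tab, k, w, 22) * (vi - E_K1)
        i_b = g[i, 8] * (vi - E_B)
        i_ncx = g[i, 9] * (_look(tab, k, w, 23) - _look(tab, k, w, 24) * ca)
        i_ion = (i_na + i_nal + i_cal + i_kr + i_ks + i_k1 + i_to
                 + i_kp + i_b + i_ncx)

        # stiff gates: exponential (Rush-Larsen) update
        minf = _look(tab, k, w, 0)
        m = minf + (m - minf) * np.exp(-dt / _look(tab, k, w, 1))
        hinf = _look(tab, k, w, 2)
        h = hinf + (h - hinf) * np.exp(-dt / _look(tab, k, w, 3))
        jinf = _look(tab, k, w, 4)
        jg = jinf + (jg - jinf) * np.exp(-dt / _look(tab, k, w, 5))
        dinf = _look(tab, k, w, 6)
        d = dinf + (d - dinf) * np.exp(-dt / _look(tab, k, w, 7))
        # slow gates: forward Euler
        f += dt * (_look(tab, k, w, 8) - f) / _look(tab, k, w, 9)
        x += dt * (_look(tab, k, w, 10) - x) / _look(tab, k, w, 11)
        xs += dt * (_look(tab, k, w, 12) - xs) / _look(tab, k, w, 13)
        r += dt * (_look(tab, k, w, 14) - r) / _look(tab, k, w, 15)
        s += dt * (_look(tab, k, w, 16) - s) / _look(tab, k, w, 17)
        hl += dt * (_look(tab, k, w, 18) - hl) / tau_hl

        y[i, 0] = min(max(m, 0.0), 1.0)
        y[i, 1] = min(max(h, 0.0), 1.0)
        y[i, 2] = min(max(jg, 0.0), 1.0)
        y[i, 3] = min(max(d, 0.0), 1.0)
        y[i, 4] = min(max(f, 0.0), 1.0)
        y[i, 5] = min(max(x, 0.0), 1.0)
        y[i, 6] = min(max(xs, 0.0), 1.0)
        y[i, 7] = min(max(r, 0.0), 1.0)
        y[i, 8] = min(max(s, 0.0), 1.0)
        y[i, 9] = min(max(hl, 0.0), 1.0)

        ca += dt * (-1e-4 * i_cal + 0.07 * (1e-4 - ca))
        if ca < CAI_FLOOR:
            ca = CAI_FLOOR
        cai[i] = ca

        dv_out[i] = dt * (-(i_ion + istim[i]))
    return 0


@njit(cache=True)
def diffusion_substeps(v, face_d, dx_mm, dt):
    """Flux-conservative no-flux diffusion over an interval dt, sub-cycled
    at 90% of the explicit stability bound dx^2 / (2 max D)."""
    n = v.shape[0]
    if n < 2 or face_d.shape[0] == 0:
        return
    dmax = 0.0
    for k in range(face_d.shape[0]):
        if face_d[k] > dmax:
            dmax = face_d[k]
    if dmax <= 0.0:
        return
    h_stab = 0.9 * dx_mm * dx_mm / (2.0 * dmax)
    nsub = int(np.ceil(dt / h_stab))
    if nsub < 1:
        nsub = 1
    h = dt / nsub
    coef = h / (dx_mm * dx_mm)
    flux = np.empty(n - 1)
    for _ in range(nsub):
        for k in range(n - 1):
            flux[k] = face_d[k] * (v[k + 1] - v[k])
        v[0] += coef * flux[0]
        for i in range(1, n - 1):
            v[i] += coef * (flux[i] - flux[i - 1])
        v[n - 1] += coef * (-flux[n - 2])


@njit(cache=True)
def integrate_strand(v, y, cai, g, tab, tau_hl, face_d, dx_mm,
                     stim_idx, stim_amp, stim_dur, cl, n_beats,
                     record_start, output_dt, dt_min, dt_max, v_act):
    """Paced integration of the (possibly single-cell) strand.

    Returns (status, err_cell, err_time, times, v_rec, act_times).
    act_times[b, i] is the first upward crossing of v_act by cell i inside
    beat window b (NaN if none), located by in-step linear interpolation.
    """
    n = v.shape[0]
    t_end = cl * n_beats
    n_out = int(round((t_end - record_start) / output_dt)) + 1
    times = np.empty(n_out)
    for k in range(n_out):
        times[k] = record_start + k * output_dt
    v_rec = np.empty((n, n_out))
    act = np.full((n_beats, n), np.nan)

    istim = np.zeros(n)
    v_prev = np.empty(n)

    i_out = 0
    if record_start <= 0.0:
        for i in range(n):
            v_rec[i, 0] = v[i]
        i_out = 1

    dv_out = np.empty(n)
    t = 0.0
    dt = dt_min
    stim_on = False
    while t < t_end - 1e-9:
        beat = int(t / cl + 1e-9)
        t_in = t - beat * cl
        # stimulus gating for the current time
        stim_on = t_in < stim_dur - 1e-12
        if stim_on:
            for k in range(stim_idx.shape[0]):
                istim[stim_idx[k]] = stim_amp
        else:
            for k in range(stim_idx.shape[0]):
                istim[stim_idx[k]] = 0.0

        # clip dt to the next event (stimulus edge, beat start, sample, end)
        step = dt
        if stim_on:
            edge = beat * cl + stim_dur - t
            if edge < step:
                step = edge
        else:
            nxt = (beat + 1) * cl - t
            if nxt < step:
                step = nxt
        if i_out < n_out:
            samp = times[i_out] - t
            if samp < step:
                step = samp
        rem = t_end - t
        if rem < step:
            step = rem
        if step < 1e-12:
            step = 1e-12

        for i in range(n):
            v_prev[i] = v[i]

        reaction_step(v, y, cai, g, tab, step, istim, tau_hl, dv_out)
        for i in range(n):
            v[i] += dv_out[i]
        diffusion_substeps(v, face_d, dx_mm, step)

        t_new = t + step

        # divergence guard + adaptive dt from the realised rate of change
        max_rate = 0.0
        for i in range(n):
            vi = v[i]
            if not np.isfinite(vi) or vi > V_DIVERGE or vi < -V_DIVERGE:
                return (STATUS_DIVERGED, i, t_new, times, v_rec, act)
            rate = abs(vi - v_prev[i]) / step
            if rate > max_rate:
                max_rate = rate

        # activation-time tracking (first upward crossing per beat window)
        for i in range(n):
            if v_prev[i] < v_act and v[i] >= v_act:
                tc = t + step * (v_act - v_prev[i]) / (v[i] - v_prev[i])
                b = int(tc / cl)
                if b >= n_beats:
                    b = n_beats - 1
                if np.isnan(act[b, i]):
                    act[b, i] = tc

        # record sample (steps are clipped to land exactly on sample times)
        if i_out < n_out and t_new >= times[i_out] - 1e-9:
            for i in range(n):
                v_rec[i, i_out] = v[i]
            i_out += 1

        t = t_new
        if max_rate > 0.0:
            dt = 0.5 / max_rate
        else:
            dt = dt_max
        if dt > dt_max:
            dt = dt_max
        elif dt < dt_min:
            dt = dt_min

    # fill any trailing samples (end-of-run round-off)
    while i_out < n_out:
        for i in range(n):
            v_rec[i, i_out] = v[i]
        i_out += 1

    return (STATUS_OK, -1, -1.0, times, v_rec, act)
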