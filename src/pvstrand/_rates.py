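"""Gate kinetics and current auxiliaries of the reference ventricular model.

All voltages in mV, times in ms, concentrations in mM, currents in uA/uF.
The formulations are classic Hodgkin-Huxley alpha/beta and inf/tau sigmoids
(Luo-Rudy 1991 lineage for INa/ICaL/IKr/IK1/IKp, ten Tusscher-style Ito gates,
an ORd-style late sodium inactivation gate, and a saturating Na/Ca exchanger).
Every equation is written out in docs/model.md.

This module has two faces: exact vectorised numpy formulas (used by the
public `evaluate_currents` and to build tables) and a dense voltage-indexed
lookup table consumed by the compiled kernels.
"""

from __future__ import annotations

import numpy as np

# Reversal potentials (mV) and fixed ionic milieu
E_NA = 54.4
E_KR = -77.0     # delayed rectifiers carry a small Na permeability
E_KS = -77.0
E_K1 = -87.2     # inward rectifier / Ito / plateau K
E_B = -59.87

# Na/Ca exchanger constants
NCX_GAMMA = 0.35
NCX_F_RT = 0.0374        # 1/mV at 37 C
NCX_NAI = 10.0           # mM (fixed intracellular Na)
NCX_NAO = 140.0
NCX_CAO = 1.8
NCX_KM_NA = 87.5
NCX_KM_CA = 1.38
NCX_KSAT = 0.1

# Lookup-table geometry
TAB_VMIN = -120.0
TAB_VMAX = 80.0
TAB_DV = 0.05
TAB_N = int(round((TAB_VMAX - TAB_VMIN) / TAB_DV)) + 1
TAB_NCOL = 25

# Column indices (shared with _kernels)
(C_MINF, C_TAUM, C_HINF, C_TAUH, C_JINF, C_TAUJ, C_DINF, C_TAUD, C_FINF,
 C_TAUF, C_XINF, C_TAUX, C_XSINF, C_TAUXS, C_RINF, C_TAUR, C_SINF, C_TAUS,
 C_HLINF, C_MLINF, C_XI, C_K1INF, C_KP, C_NCXP, C_NCXQ) = range(TAB_NCOL)


def _safe_ratio(num, den, limit):
    """num/den with the removable singularity den -> 0 replaced by `limit`."""
    den = np.asarray(den, dtype=float)
    small = np.abs(den) < 1e-9
    out = np.where(small, limit, num / np.where(small, 1.0, den))
    return out


def alpha_m(v):
    v = np.asarray(v, dtype=float)
    dv = v + 47.13
    return _safe_ratio(0.32 * dv, 1.0 - np.exp(-0.1 * dv), 3.2)


def beta_m(v):
    return 0.08 * np.exp(-np.asarray(v, dtype=float) / 11.0)


def alpha_h(v):
    v = np.asarray(v, dtype=float)
    return np.where(v < -40.0, 0.135 * np.exp(-(80.0 + v) / 6.8), 0.0)


def beta_h(v):
    v = np.asarray(v, dtype=float)
    lo = 3.56 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.35 * v)
    hi = 1.0 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1)))
    return np.where(v < -40.0, lo, hi)


def alpha_j(v):
    v = np.asarray(v, dtype=float)
    num = (-1.2714e5 * np.exp(0.2444 * v) - 3.474e-5 * np.exp(-0.04391 * v))
    lo = num * (v + 37.78) / (1.0 + np.exp(0.311 * (v + 79.23)))
    return np.where(v < -40.0, lo, 0.0)


def beta_j(v):
    v = np.asarray(v, dtype=float)
    lo = 0.1212 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14)))
    hi = 0.3 * np.exp(-2.535e-7 * v) / (1.0 + np.exp(-0.1 * (v + 32.0)))
    return np.where(v < -40.0, lo, hi)


def alpha_d(v):
    v = np.asarray(v, dtype=float)
    return 0.095 * np.exp(-0.01 * (v - 5.0)) / (1.0 + np.exp(-0.072 * (v - 5.0)))


def beta_d(v):
    v = np.asarray(v, dtype=float)
    return 0.07 * np.exp(-0.017 * (v + 44.0)) / (1.0 + np.exp(0.05 * (v + 44.0)))


def alpha_f(v):
    v = np.asarray(v, dtype=float)
    return 0.012 * np.exp(-0.008 * (v + 28.0)) / (1.0 + np.exp(0.15 * (v + 28.0)))


def beta_f(v):
    v = np.asarray(v, dtype=float)
    return 0.0065 * np.exp(-0.02 * (v + 30.0)) / (1.0 + np.exp(-0.2 * (v + 30.0)))


def alpha_x(v):
    v = np.asarray(v, dtype=float)
    return 0.0005 * np.exp(0.083 * (v + 50.0)) / (1.0 + np.exp(0.057 * (v + 50.0)))


def beta_x(v):
    v = np.asarray(v, dtype=float)
    return 0.0013 * np.exp(-0.06 * (v + 20.0)) / (1.0 + np.exp(-0.04 * (v + 20.0)))


def xi_rect(v):
    """Inward-rectification factor of the rapid delayed rectifier."""
    v = np.asarray(v, dtype=float)
    dv = v + 77.0
    expr = 2.837 * _safe_ratio(np.exp(0.04 * dv) - 1.0, dv, 0.04) \
        / np.exp(0.04 * (v + 35.0))
    return np.where(v <= -100.0, 1.0, expr)


def xs_inf(v):
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + np.exp(-(v - 1.5) / 16.7))


def tau_xs(v):
    v = np.asarray(v, dtype=float)
    dv = v + 30.0
    a = _safe_ratio(7.19e-5 * dv, 1.0 - np.exp(-0.148 * dv), 7.19e-5 / 0.148)
    b = _safe_ratio(1.31e-4 * dv, np.exp(0.0687 * dv) - 1.0, 1.31e-4 / 0.0687)
    return 1.0 / (a + b)


def r_inf(v):
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + np.exp((20.0 - v) / 6.0))


def tau_r(v):
    v = np.asarray(v, dtype=float)
    return 9.5 * np.exp(-((v + 40.0) ** 2) / 1800.0) + 0.8


def s_inf(v):
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + np.exp((v + 20.0) / 5.0))


def tau_s(v):
    v = np.asarray(v, dtype=float)
    return (85.0 * np.exp(-((v + 45.0) ** 2) / 320.0)
            + 5.0 / (1.0 + np.exp((v - 20.0) / 5.0)) + 3.0)


def hl_inf(v):
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + np.exp((v + 87.61) / 7.488))


def ml_inf(v):
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + np.exp(-(v + 42.85) / 5.264))


def k1_inf(v):
    v = np.asarray(v, dtype=float)
    dv = v - E_K1
    a = 1.02 / (1.0 + np.exp(0.2385 * (dv - 59.215)))
    b = ((0.49124 * np.exp(0.08032 * (dv + 5.476))
          + np.exp(0.06175 * (dv - 594.31)))
         / (1.0 + np.exp(-0.5143 * (dv + 4.753))))
    return a / (a + b)


def kp_factor(v):
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + np.exp((7.488 - v) / 5.98))


def ncx_pq(v):
    """Voltage factors of I_NaCa = k_naca * (p(V) - q(V) * Cai)."""
    v = np.asarray(v, dtype=float)
    ea = np.exp(NCX_GAMMA * NCX_F_RT * v)
    eb = np.exp((NCX_GAMMA - 1.0) * NCX_F_RT * v)
    denom = ((NCX_KM_NA ** 3 + NCX_NAO ** 3) * (NCX_KM_CA + NCX_CAO)
             * (1.0 + NCX_KSAT * eb))
    p = ea * NCX_NAI ** 3 * NCX_CAO / denom
    q = eb * NCX_NAO ** 3 / denom
    return p, q


def e_si(cai):
    """Reversal potential of the L-type calcium current (mV, Cai in mM)."""
    return 7.7 - 13.0287 * np.log(np.asarray(cai, dtype=float))


def build_tables(kinetics: dict) -> np.ndarray:
    """Dense (TAB_N x TAB_NCOL) rate table on the kernel voltage grid.

    `kinetics` carries the model-level time-constant scale factors
    (tau_d_scale, tau_f_scale, tau_x_scale, tau_xs_scale); inf curves are
    scale-invariant.
    """
    v = TAB_VMIN + TAB_DV * np.arange(TAB_N)
    tab = np.empty((TAB_N, TAB_NCOL))
    am, bm = alpha_m(v), beta_m(v)
    # fast-sodium inactivation may be shifted (negative = leftward, i.e.
    # inactivating at more negative potentials: slow depolarising feet
    # accommodate and lose their sodium spikelet)
    vh = v - kinetics.get("shift_h_mv", 0.0)
    ah, bh = alpha_h(vh), beta_h(vh)
    aj, bj = alpha_j(vh), beta_j(vh)
    # the L-type activation curve may be shifted (negative = leftward, a
    # wider window current); the shift is a model-level kinetic parameter
    vd = v - kinetics.get("shift_d_mv", 0.0)
    ad, bd = alpha_d(vd), beta_d(vd)
    af, bf = alpha_f(v), beta_f(v)
    ax, bx = alpha_x(v), beta_x(v)
    tab[:, C_MINF] = am / (am + bm)
    tab[:, C_TAUM] = 1.0 / (am + bm)
    tab[:, C_HINF] = ah / (ah + bh)
    tab[:, C_TAUH] = 1.0 / (ah + bh)
    tab[:, C_JINF] = aj / (aj + bj)
    tab[:, C_TAUJ] = 1.0 / (aj + bj)
    tab[:, C_DINF] = ad / (ad + bd)
    tab[:, C_TAUD] = kinetics["tau_d_scale"] / (ad + bd)
    tab[:, C_FINF] = af / (af + bf)
    tab[:, C_TAUF] = kinetics["tau_f_scale"] / (af + bf)
    tab[:, C_XINF] = ax / (ax + bx)
    tab[:, C_TAUX] = kinetics["tau_x_scale"] / (ax + bx)
    tab[:, C_XSINF] = xs_inf(v)
    tab[:, C_TAUXS] = kinetics["tau_xs_scale"] * tau_xs(v)
    tab[:, C_RINF] = r_inf(v)
    tab[:, C_TAUR] = tau_r(v)
    tab[:, C_SINF] = s_inf(v)
    tab[:, C_TAUS] = tau_s(v)
    tab[:, C_HLINF] = hl_inf(v)
    tab[:, C_MLINF] = ml_inf(v)
    tab[:, C_XI] = xi_rect(v)
    tab[:, C_K1INF] = k1_inf(v)
    tab[:, C_KP] = kp_factor(v)
    p, q = ncx_pq(v)
    tab[:, C_NCXP] = p
    tab[:, C_NCXQ] = q
    return tab
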