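# The reference ventricular membrane model

One Hodgkin–Huxley-type equation set serves all four tissue types of the
strand (Purkinje `P`, endocardial `Endo`, midmyocardial `M`, epicardial
`Epi`); the variants differ **only** by conductance multipliers, never by
equations. Voltages are in mV, time in ms, concentrations in mM, current
densities in µA/µF (membrane capacitance 1 µF/cm²).

The membrane equation is

    dV/dt = −(I_ion + I_stim),
    I_ion = I_Na + I_NaL + I_CaL + I_Kr + I_Ks + I_K1 + I_to + I_Kp + I_b + I_NaCa.

The current formulations are classic: the fast sodium current, L-type
calcium current, rapid delayed rectifier and inward rectifier follow the
Luo–Rudy (1991) guinea-pig formulations; the transient outward gates are
ten Tusscher-style sigmoids; the late sodium inactivation gate follows the
O'Hara-Rudy convention; the Na/Ca exchanger is the standard saturating
single-energy-barrier form. Channel block enters as linear scalings
`s_kr`, `s_cal` ∈ [0, 1] (fraction of current *remaining*) multiplying the
I_Kr and I_CaL maximal conductances.

## State vector

`V`, ten gates `m, h, j, d, f, x, xs, r, s, hL` (each in [0, 1]) and one
concentration `Cai` (> 0).

## Currents

| current | expression | reversal |
|---|---|---|
| I_Na   | g_Na · m³ h j · (V − E_Na)            | E_Na = +54.4 |
| I_NaL  | g_NaL · mL∞(V) · hL · (V − E_Na)      | E_Na |
| I_CaL  | s_cal · g_CaL · d f · (V − E_si(Cai)) | E_si = 7.7 − 13.0287 ln Cai |
| I_Kr   | s_kr · g_Kr · x · Xi(V) · (V − E_Kr)  | E_Kr = −77 |
| I_Ks   | g_Ks · xs² · (V − E_Ks)               | E_Ks = −77 |
| I_K1   | g_K1 · K1∞(V) · (V − E_K1)            | E_K1 = −87.2 |
| I_to   | g_to · r s · (V − E_K1)               | E_K1 |
| I_Kp   | g_Kp · Kp(V) · (V − E_K1)             | E_K1 |
| I_b    | g_b · (V + 59.87)                     | −59.87 |
| I_NaCa | k_NaCa · (p(V) − q(V) · Cai)          | — |

Calcium balance (single pool, Luo–Rudy form):

    dCai/dt = −10⁻⁴ · I_CaL + 0.07 · (10⁻⁴ − Cai)

The exchanger voltage factors are

    p(V) = e^{γFV/RT} Nai³ Cao / Z,   q(V) = e^{(γ−1)FV/RT} Nao³ / Z,
    Z = (Km_Na³ + Nao³)(Km_Ca + Cao)(1 + k_sat e^{(γ−1)FV/RT}),

with γ = 0.35, F/RT = 0.0374 mV⁻¹, Nai = 10, Nao = 140, Cao = 1.8,
Km_Na = 87.5, Km_Ca = 1.38, k_sat = 0.1.

## Gate kinetics

α/β rate constants (ms⁻¹); `dg/dt = α(1−g) − βg`.

    α_m = 0.32 (V+47.13) / (1 − e^{−0.1(V+47.13)})     β_m = 0.08 e^{−V/11}
    V < −40:  α_h = 0.135 e^{−(80+V)/6.8}
              β_h = 3.56 e^{0.079V} + 3.1·10⁵ e^{0.35V}
    V ≥ −40:  α_h = 0,  β_h = 1 / (0.13 (1 + e^{−(V+10.66)/11.1}))
    V < −40:  α_j = (−1.2714·10⁵ e^{0.2444V} − 3.474·10⁻⁵ e^{−0.04391V})
                     · (V+37.78) / (1 + e^{0.311(V+79.23)})
              β_j = 0.1212 e^{−0.01052V} / (1 + e^{−0.1378(V+40.14)})
    V ≥ −40:  α_j = 0,  β_j = 0.3 e^{−2.535·10⁻⁷V} / (1 + e^{−0.1(V+32)})
    α_d = 0.095 e^{−0.01(V−5)} / (1 + e^{−0.072(V−5)})
    β_d = 0.07 e^{−0.017(V+44)} / (1 + e^{0.05(V+44)})
    α_f = 0.012 e^{−0.008(V+28)} / (1 + e^{0.15(V+28)})
    β_f = 0.0065 e^{−0.02(V+30)} / (1 + e^{−0.2(V+30)})
    α_x = 0.0005 e^{0.083(V+50)} / (1 + e^{0.057(V+50)})
    β_x = 0.0013 e^{−0.06(V+20)} / (1 + e^{−0.04(V+20)})

Rectification and plateau factors:

    Xi = 2.837 (e^{0.04(V+77)} − 1) / ((V+77) e^{0.04(V+35)})   (V > −100; 1 below)
    K1∞ = α_K1/(α_K1+β_K1) with the Luo–Rudy α_K1, β_K1 at E_K1 = −87.2
    Kp = 1 / (1 + e^{(7.488−V)/5.98})

Slow delayed rectifier (inf/τ form):

    xs∞ = 1 / (1 + e^{−(V−1.5)/16.7})
    τ_xs = 1 / (7.19·10⁻⁵ u/(1−e^{−0.148u}) + 1.31·10⁻⁴ u/(e^{0.0687u}−1)),  u = V+30

Transient outward:

    r∞ = 1/(1+e^{(20−V)/6}),    τ_r = 9.5 e^{−(V+40)²/1800} + 0.8
    s∞ = 1/(1+e^{(V+20)/5}),    τ_s = 85 e^{−(V+45)²/320} + 5/(1+e^{(V−20)/5}) + 3

Late sodium:

    mL∞ = 1/(1+e^{−(V+42.85)/5.264})   (instantaneous activation)
    hL∞ = 1/(1+e^{(V+87.61)/7.488}),   τ_hL = 500 ms (constant)

## Kinetic scale factors

Model-level factors multiply selected time constants (they shape the
action potential and the afterdepolarisation dynamics; see
docs/methods.md for the rationale):

| factor | value | effect |
|---|---|---|
| τ_d scale  | 0.4 | faster L-type activation (sharper dome upstroke) |
| τ_f scale  | 0.6 | faster L-type inactivation/recovery (stable fast pacing) |
| τ_x scale  | 0.3 | rapidly saturating I_Kr activation |
| τ_xs scale | 2.5 | slowly accumulating I_Ks (rate-dependence memory) |
| shift_d, shift_h | 0 mV | optional activation/inactivation shifts (unused by default) |

## Baseline conductances and transmural profile

Baseline (endocardial) maximal conductances, mS/µF:

    g_Na 2.5   g_NaL 0.02   g_CaL 0.06   g_Kr 0.45   g_Ks 0.8
    g_K1 0.6047   g_to 0.02   g_Kp 0.0183   g_b 0.02   k_NaCa 1000

Transmural/Purkinje multipliers (all other parameters ×1):

| type | multipliers | phenotype |
|---|---|---|
| Endo | — | baseline |
| M    | g_NaL ×5, g_CaL ×1.2, g_Ks ×0.25 | longest APD; afterdepolarisation-prone under I_Kr block |
| Epi  | g_to ×6, g_Ks ×4, g_NaL ×0.2 | shortest APD (earliest repolarisation → upright T-wave) |
| P    | g_Na ×6, g_NaL ×1.6, g_to ×2, g_K1 ×0.6, g_Ks ×0.6, g_CaL ×0.9 | fast upstroke, long intrinsic plateau |

The Na/Ca exchanger transmural scaling defaults to 1 in every type and is
configurable through `make_cell(..., overrides=...)`.

Representative single-cell values of this parameter set (paced at
CL = 750 ms, 8 beats): APD90 ≈ 188 (Endo), 258 (M), 164 (Epi), 193 (P) ms;
resting potentials ≈ −83 mV (ventricular types), −80 mV (P).
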