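"""Single-cell membrane models for the four strand tissue types.

One Hodgkin-Huxley-type equation set serves all four cell types (Purkinje,
endocardial, midmyocardial, epicardial); the variants differ only by
documented conductance multipliers (the transmural profile). The model
carries I_Na, I_NaL, I_CaL, I_Kr, I_Ks, I_K1, I_to, a plateau potassium and
background current, a simplified Na/Ca exchanger, and a single-pool
intracellular calcium balance. Channel block enters as linear scalings of
the I_Kr and I_CaL maximal conductances (s = fraction of current remaining).

Equations and the rationale for every constant are in docs/model.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import numpy as np

from . import _rates as R
from ._kernels import STATUS_OK, integrate_strand, reaction_step
from .errors import InvalidStateError, ParameterError

CELL_TYPES = ("P", "Endo", "M", "Epi")

GATE_NAMES = ("m", "h", "j", "d", "f", "x", "xs", "r", "s", "hl")
CONC_NAMES = ("cai",)

#: conductance order consumed by the compiled kernels
PARAM_NAMES = ("g_na", "g_nal", "g_cal", "g_kr", "g_ks", "g_k1", "g_to",
               "g_kp", "g_b", "k_naca")

# Baseline (endocardial) maximal conductances, mS/uF except k_naca (uA/uF
# per normalised exchanger flux). Tuned so the coupled strand meets the
# package's stated electrophysiological requirements (docs/model.md).
BASE_PARAMETERS: Dict[str, float] = {
    "g_na": 2.5,
    "g_nal": 0.02,
    "g_cal": 0.06,
    "g_kr": 0.45,
    "g_ks": 0.8,
    "g_k1": 0.6047,
    "g_to": 0.02,
    "g_kp": 0.0183,
    "g_b": 0.02,
    "k_naca": 1000.0,
}

# Transmural/Purkinje multipliers on the baseline set. M cells carry the
# largest late sodium and the smallest slow delayed rectifier (longest APD);
# Epi the largest transient outward; Purkinje a fast upstroke, reduced
# inward rectifier and a long intrinsic plateau. The Na/Ca exchanger
# transmural scaling defaults to 1 everywhere (configurable).
TRANSMURAL_MULTIPLIERS: Dict[str, Dict[str, float]] = {
    "Endo": {},
    "M": {"g_nal": 5.0, "g_cal": 1.2, "g_ks": 0.15, "g_to": 1.0},
    "Epi": {"g_to": 6.0, "g_ks": 4.0, "g_nal": 0.2},
    "P": {"g_na": 6.0, "g_nal": 1.6, "g_k1": 0.6, "g_to": 2.0,
          "g_ks": 0.6, "g_cal": 0.9},
}

# Model-level gating time-constant scale factors (dimensionless) and the
# late-sodium inactivation time constant (ms). tau_x_scale slows rapid
# delayed rectifier activation/deactivation, which both permits EAD
# formation under I_Kr block and makes it rate dependent (accumulated
# activation at short cycle lengths suppresses EADs).
KINETICS: Dict[str, float] = {
    "tau_d_scale": 0.4,
    "tau_f_scale": 0.6,
    "tau_x_scale": 0.3,
    "tau_xs_scale": 2.5,
    "shift_d_mv": 0.0,
    "shift_h_mv": 0.0,
    "tau_hl": 500.0,
}

DT_MIN = 0.001
DT_MAX = 0.05

#: default single-cell/tissue stimulus (depolarising, uA/uF and ms)
STIM_AMPLITUDE = -52.0
STIM_DURATION = 1.0

_TABLE_CACHE: Dict[Tuple[float, ...], np.ndarray] = {}


def rate_tables(kinetics: Mapping[str, float] | None = None) -> np.ndarray:
    """Voltage-indexed gate/current lookup table for the compiled kernels."""
    kin = dict(KINETICS)
    if kinetics:
        kin.update(kinetics)
    key = tuple(kin[k] for k in ("tau_d_scale", "tau_f_scale",
                                 "tau_x_scale", "tau_xs_scale", "shift_d_mv",
                                 "shift_h_mv"))
    tab = _TABLE_CACHE.get(key)
    if tab is None:
        tab = R.build_tables(kin)
        _TABLE_CACHE[key] = tab
    return tab


@dataclass(frozen=True)
class ChannelScaling:
    """Fractions of I_Kr and I_CaL remaining (1 = no block, 0 = full block)."""

    s_kr: float = 1.0
    s_cal: float = 1.0

    def __post_init__(self):
        for name in ("s_kr", "s_cal"):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ParameterError(f"{name} must lie in [0, 1], got {val}")

    @classmethod
    def from_block(cls, block_kr: float = 0.0, block_cal: float = 0.0):
        """Build from block fractions (block = 1 - remaining)."""
        return cls(s_kr=1.0 - block_kr, s_cal=1.0 - block_cal)


CONTROL_SCALING = ChannelScaling(1.0, 1.0)


@dataclass
class IonicState:
    """Membrane potential, gating variables and intracellular concentrations."""

    v: float
    gates: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self):
        self.gates = np.asarray(self.gates, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.gates.shape != (len(GATE_NAMES),):
            raise InvalidStateError(
                f"expected {len(GATE_NAMES)} gates, got {self.gates.shape}")
        if self.concentrations.shape != (len(CONC_NAMES),):
            raise InvalidStateError(
                f"expected {len(CONC_NAMES)} concentrations")

    def validate(self):
        if not np.isfinite(self.v):
            raise InvalidStateError("non-finite state component: v")
        for name, val in zip(GATE_NAMES, self.gates):
            if not np.isfinite(val):
                raise InvalidStateError(f"non-finite state component: {name}")
            if not (0.0 <= val <= 1.0):
                raise InvalidStateError(f"gate out of [0, 1]: {name}={val}")
        for name, val in zip(CONC_NAMES, self.concentrations):
            if not np.isfinite(val):
                raise InvalidStateError(f"non-finite state component: {name}")
            if val <= 0.0:
                raise InvalidStateError(f"non-positive concentration: {name}")

    def copy(self) -> "IonicState":
        return IonicState(self.v, self.gates.copy(),
                          self.concentrations.copy())

    @property
    def cai(self) -> float:
        return float(self.concentrations[0])


@dataclass(frozen=True)
class CellModel:
    """A tissue-type variant of the reference model plus its block scaling.

    `parameters` are the effective (transmurally multiplied) maximal
    conductances before channel-block scaling; `kinetics` the model-level
    time-constant factors shared by all cell types.
    """

    cell_type: str
    parameters: Mapping[str, float]
    scaling: ChannelScaling = CONTROL_SCALING
    kinetics: Mapping[str, float] = field(default_factory=lambda: dict(KINETICS))

    def conductance_vector(self) -> np.ndarray:
        """Kernel-ordered conductances with channel block folded in."""
        g = np.array([self.parameters[k] for k in PARAM_NAMES])
        g[PARAM_NAMES.index("g_kr")] *= self.scaling.s_kr
        g[PARAM_NAMES.index("g_cal")] *= self.scaling.s_cal
        return g

    def tables(self) -> np.ndarray:
        return rate_tables(self.kinetics)

    @property
    def tau_hl(self) -> float:
        return float(self.kinetics["tau_hl"])


def make_cell(cell_type: str, scaling: ChannelScaling = CONTROL_SCALING,
              overrides: Mapping[str, float] | None = None) -> CellModel:
    """Build the documented transmural variant of the reference model."""
    if cell_type not in CELL_TYPES:
        raise ParameterError(
            f"unknown cell_type {cell_type!r}; expected one of {CELL_TYPES}")
    params = dict(BASE_PARAMETERS)
    for key, mult in TRANSMURAL_MULTIPLIERS[cell_type].items():
        params[key] = params[key] * mult
    if overrides:
        for key, val in overrides.items():
            if key not in params:
                raise ParameterError(f"unknown parameter {key!r}")
            params[key] = float(val)
    return CellModel(cell_type=cell_type, parameters=params, scaling=scaling)


def evaluate_currents(model: CellModel, state: IonicState):
    """Total ionic current density (uA/uF) and the per-current breakdown.

    Pure function of (model, state); the I_Kr and I_CaL entries scale
    exactly linearly with the model's s_kr and s_cal.
    """
    state.validate()
    v = state.v
    m, h, j, d, f, x, xs, r, s, hl = state.gates
    cai = state.cai
    p = model.parameters
    sc = model.scaling
    pv, qv = R.ncx_pq(v)
    currents = {
        "I_Na": p["g_na"] * m ** 3 * h * j * (v - R.E_NA),
        "I_NaL": p["g_nal"] * float(R.ml_inf(v)) * hl * (v - R.E_NA),
        "I_CaL": sc.s_cal * p["g_cal"] * d * f * (v - float(R.e_si(cai))),
        "I_Kr": sc.s_kr * p["g_kr"] * x * float(R.xi_rect(v)) * (v - R.E_KR),
        "I_Ks": p["g_ks"] * xs ** 2 * (v - R.E_KS),
        "I_K1": p["g_k1"] * float(R.k1_inf(v)) * (v - R.E_K1),
        "I_to": p["g_to"] * r * s * (v - R.E_K1),
        "I_Kp": p["g_kp"] * float(R.kp_factor(v)) * (v - R.E_K1),
        "I_b": p["g_b"] * (v - R.E_B),
        "I_NaCa": p["k_naca"] * (float(pv) - float(qv) * cai),
    }
    total = float(sum(currents.values()))
    return total, currents


def step_state(model: CellModel, state: IonicState, dt: float,
               i_stim: float = 0.0) -> IonicState:
    """One single-cell step: gates/concentrations and the membrane voltage.

    In coupled (tissue) mode the voltage update is owned by the tissue
    solver; here forward Euler advances v with dt * (-I_ion - I_stim).
    """
    if dt <= 0.0:
        raise ParameterError(f"dt must be positive, got {dt}")
    if dt > DT_MAX:
        raise ParameterError(f"dt above admissible maximum {DT_MAX} ms")
    state.validate()
    v = np.array([state.v])
    y = state.gates[np.newaxis, :].copy()
    cai = state.concentrations.copy()
    g = model.conductance_vector()[np.newaxis, :]
    istim = np.array([i_stim], dtype=float)
    dv = np.empty(1)
    reaction_step(v, y, cai, g, model.tables(), dt, istim, model.tau_hl, dv)
    return IonicState(float(v[0] + dv[0]), y[0], cai)


def initial_state(v: float = -84.0, cai: float = 1.0e-4) -> IonicState:
    """Gates at their steady state for `v`; a generic diastolic start point."""
    gates = np.array([
        float(R.alpha_m(v) / (R.alpha_m(v) + R.beta_m(v))),
        float(R.alpha_h(v) / (R.alpha_h(v) + R.beta_h(v))),
        float(R.alpha_j(v) / (R.alpha_j(v) + R.beta_j(v))),
        float(R.alpha_d(v) / (R.alpha_d(v) + R.beta_d(v))),
        float(R.alpha_f(v) / (R.alpha_f(v) + R.beta_f(v))),
        float(R.alpha_x(v) / (R.alpha_x(v) + R.beta_x(v))),
        float(R.xs_inf(v)),
        float(R.r_inf(v)),
        float(R.s_inf(v)),
        float(R.hl_inf(v)),
    ])
    return IonicState(v, gates, np.array([cai]))


def dump_parameters(path) -> None:
    """Write the full parameter set (baseline conductances, transmural
    multipliers, kinetic factors) as structured YAML text."""
    import yaml
    doc = {
        "baseline_conductances_mS_per_uF": dict(BASE_PARAMETERS),
        "transmural_multipliers": {k: dict(v) for k, v in
                                   TRANSMURAL_MULTIPLIERS.items()},
        "kinetics": dict(KINETICS),
    }
    with open(path, "w") as f:
        f.write("# reference ventricular model parameters\n"
                "# conductances in mS/uF (k_naca: exchanger scale);"
                " time-constant factors dimensionless; shifts in mV;"
                " tau_hl in ms\n")
        yaml.safe_dump(doc, f, sort_keys=True)


def load_parameters(path) -> dict:
    """Read a parameter document written by dump_parameters."""
    import yaml
    with open(path) as f:
        return yaml.safe_load(f)


def find_rest_state(model: CellModel, duration: float = 20000.0) -> IonicState:
    """Quiescent steady state by long unstimulated integration."""
    run = pace_single_cell(model, cl=duration, n_beats=1, stim_amplitude=0.0,
                           record_last=1, output_dt=duration / 2)
    return run.final_state


@dataclass
class SingleCellRun:
    """Paced single-cell trace on the recorded output grid."""

    times: np.ndarray
    v: np.ndarray
    stim_times: np.ndarray
    act_times: np.ndarray          # (n_beats,) first -20 mV upward crossing
    final_state: IonicState
    cl: float


def pace_single_cell(model: CellModel, cl: float, n_beats: int,
                     record_last: int | None = None, output_dt: float = 0.5,
                     stim_amplitude: float = STIM_AMPLITUDE,
                     stim_duration: float = STIM_DURATION,
                     state: IonicState | None = None,
                     v_act: float = -20.0) -> SingleCellRun:
    """Pace an isolated cell through `n_beats` cycles of length `cl` (ms)."""
    if cl <= 0 or n_beats < 1:
        raise ParameterError("cl must be > 0 and n_beats >= 1")
    if record_last is None:
        record_last = n_beats
    record_last = min(record_last, n_beats)
    st = (state or initial_state()).copy()
    v = np.array([st.v])
    y = st.gates[np.newaxis, :].copy()
    cai = st.concentrations.copy()
    g = model.conductance_vector()[np.newaxis, :]
    face_d = np.empty(0)
    stim_idx = np.array([0], dtype=np.int64)
    record_start = cl * (n_beats - record_last)
    status, cell, t_err, times, v_rec, act = integrate_strand(
        v, y, cai, g, model.tables(), model.tau_hl, face_d, 1.0,
        stim_idx, stim_amplitude, stim_duration, float(cl), int(n_beats),
        float(record_start), float(output_dt), DT_MIN, DT_MAX, v_act)
    if status != STATUS_OK:
        from .errors import DivergenceError
        raise DivergenceError(cell, t_err)
    return SingleCellRun(
        times=times, v=v_rec[0], stim_times=np.arange(n_beats) * float(cl),
        act_times=act[:, 0], final_state=IonicState(float(v[0]), y[0], cai),
        cl=float(cl))


def apd90(run: SingleCellRun, beat: int = -1) -> float:
    """Action-potential duration to 90% repolarisation of the given beat."""
    n_beats = len(run.stim_times)
    if beat < 0:
        beat = n_beats + beat
    t0, t1 = beat * run.cl, (beat + 1) * run.cl
    sel = (run.times >= t0) & (run.times <= t1)
    t, v = run.times[sel], run.v[sel]
    if len(v) == 0:
        raise ParameterError("beat not inside the recorded window")
    v_rest = v[0]
    v_peak = v.max()
    if v_peak < -40.0:
        raise ParameterError("no action potential in beat")
    v90 = v_peak - 0.9 * (v_peak - v_rest)
    i_peak = int(np.argmax(v))
    below = np.where(v[i_peak:] <= v90)[0]
    if len(below) == 0:
        return float(t[-1] - t0)
    k = i_peak + below[0]
    # linear interpolation of the downward crossing
    if k > 0 and v[k - 1] > v90:
        frac = (v[k - 1] - v90) / (v[k - 1] - v[k])
        tc = t[k - 1] + frac * (t[k] - t[k - 1])
    else:
        tc = t[k]
    return float(tc - t0)
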