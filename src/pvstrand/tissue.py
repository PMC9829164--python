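"""1D heterogeneous cable: P-Endo-M-Epi strand with junctional coupling.

The strand is a cell-centred finite-difference grid. Diffusion coefficients
live on the faces between cells: D_P inside the Purkinje layer, D_v inside
and between the ventricular layers, and D_Pv = E_R * D_v on the single face
forming the Purkinje-ventricular junction (PVJ). Ends are sealed (no-flux).

Integration is operator-split: an adaptive reaction step (the ionic model)
followed by the diffusion operator sub-cycled at its explicit stability
bound. The adaptive step is dt = clip(0.5 / max|dV/dt|, dt_min, dt_max).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
import h5py
import numpy as np

from . import _kernels as K
from .errors import ConfigurationError, DivergenceError, ParameterError, StabilityError
from .ionic import (
    CELL_TYPES,
    CONTROL_SCALING,
    DT_MAX,
    DT_MIN,
    ChannelScaling,
    initial_state,
    make_cell,
)

LAYER_ORDER = ("P", "Endo", "M", "Epi")

#: activation threshold (mV, upward crossing) shared with the calibration module
V_ACT = -20.0

# Default diffusion profile (mm^2/ms) and junctional ratio for the shipped
# ionic model, produced by the calibration module against the targets
# CV_P = 2 m/s, CV_v = 0.5 m/s and a 4.364 ms PVJ delay (docs/methods.md).
DEFAULT_D_P = 1.177257
DEFAULT_D_V = 0.945742
DEFAULT_E_R = 0.071315

#: the published canine diffusion profile; kept as a named alternative, but
#: it will not reproduce the target conduction velocities under the shipped
#: ionic model
CANINE_PROFILE = {"d_p": 1.2, "d_v": 0.1, "e_r": 3.13}


@dataclass(frozen=True)
class TissueConfig:
    """Geometry, diffusion profile and stimulus of the strand."""

    cells_per_layer: int = 50
    length_cm: float = 2.0
    d_p: float = DEFAULT_D_P
    d_v: float = DEFAULT_D_V
    e_r: float = DEFAULT_E_R
    n_stim_cells: int | None = None
    stim_amplitude: float = -100.0
    stim_duration: float = 2.0

    def __post_init__(self):
        if self.n_stim_cells is None:
            # default: up to 5 cells at the Purkinje end
            object.__setattr__(self, "n_stim_cells",
                               min(5, self.cells_per_layer))
        problems = []
        if self.cells_per_layer < 1:
            problems.append("cells_per_layer must be >= 1")
        if self.length_cm <= 0:
            problems.append("length_cm must be > 0")
        if self.d_p <= 0 or self.d_v <= 0:
            problems.append("diffusion coefficients must be > 0")
        if self.e_r <= 0:
            problems.append("e_r must be > 0")
        if not (1 <= self.n_stim_cells <= self.cells_per_layer):
            problems.append("n_stim_cells must lie in [1, cells_per_layer]")
        if self.stim_duration <= 0:
            problems.append("stim_duration must be > 0")
        if problems:
            raise ConfigurationError("; ".join(problems))

    @property
    def n_cells(self) -> int:
        return 4 * self.cells_per_layer

    @property
    def dx_cm(self) -> float:
        return self.length_cm / self.n_cells

    @property
    def dx_mm(self) -> float:
        return 10.0 * self.dx_cm

    @property
    def d_pv(self) -> float:
        return self.e_r * self.d_v

    @property
    def pvj_face(self) -> int:
        """Index of the face between the last P and the first Endo cell."""
        return self.cells_per_layer - 1

    def cell_types(self) -> list[str]:
        return [ct for ct in LAYER_ORDER for _ in range(self.cells_per_layer)]

    def layer_slice(self, cell_type: str) -> slice:
        i = LAYER_ORDER.index(cell_type)
        n = self.cells_per_layer
        return slice(i * n, (i + 1) * n)


@dataclass(frozen=True)
class PacingProtocol:
    """Pacing cycle length (ms), total beats and how many are recorded."""

    cl: float
    n_beats: int = 10
    record_last: int = 2

    def __post_init__(self):
        if self.cl <= 0:
            raise ConfigurationError("cl must be > 0")
        if not (self.n_beats >= self.record_last >= 1):
            raise ConfigurationError("need n_beats >= record_last >= 1")


@dataclass
class Tissue:
    """An assembled strand ready to integrate."""

    config: TissueConfig
    scaling: ChannelScaling
    face_d: np.ndarray           # (n_cells - 1,) mm^2/ms
    conductances: np.ndarray     # (n_cells, n_params)
    tables: np.ndarray
    tau_hl: float
    cell_types: list[str] = field(default_factory=list)


def build_tissue(config: TissueConfig,
                 scaling: ChannelScaling = CONTROL_SCALING) -> Tissue:
    """Assemble per-cell models and per-face diffusion coefficients."""
    n = config.n_cells
    types = config.cell_types()
    g = np.empty((n, 10))
    tau_hl = None
    tables = None
    for ct in CELL_TYPES:
        cell = make_cell(ct, scaling)
        sl = config.layer_slice(ct)
        g[sl, :] = cell.conductance_vector()
        tau_hl = cell.tau_hl
        tables = cell.tables()

    face_d = np.full(n - 1, config.d_v)
    # faces internal to the Purkinje layer
    face_d[: config.pvj_face] = config.d_p
    # the single junctional face
    face_d[config.pvj_face] = config.d_pv
    return Tissue(config=config, scaling=scaling, face_d=face_d,
                  conductances=g, tables=tables, tau_hl=tau_hl,
                  cell_types=types)


def diffusion_step(v: np.ndarray, face_coeffs: np.ndarray, dx_cm: float,
                   dt: float) -> np.ndarray:
    """One explicit flux-conservative diffusion step with sealed ends.

    v_i += (dt/dx^2) * [D_{i+1/2} (v_{i+1} - v_i) - D_{i-1/2} (v_i - v_{i-1})]

    Raises StabilityError if dt exceeds dx^2 / (2 max D).
    """
    v = np.asarray(v, dtype=float)
    face_coeffs = np.asarray(face_coeffs, dtype=float)
    if face_coeffs.shape[0] != v.shape[0] - 1:
        raise ParameterError("need exactly one face coefficient per cell pair")
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    dx_mm = 10.0 * dx_cm
    bound = dx_mm ** 2 / (2.0 * face_coeffs.max())
    if dt > bound:
        raise StabilityError(
            f"dt = {dt} ms exceeds the explicit stability bound {bound:.6f} ms")
    flux = face_coeffs * np.diff(v)
    out = v.copy()
    coef = dt / dx_mm ** 2
    out[:-1] += coef * flux
    out[1:] -= coef * flux
    return out


@dataclass
class SimulationResult:
    """Recorded membrane-potential map of the paced strand.

    `v` is cells x times (mV) on the uniform `times` grid (ms); `act_times`
    holds kernel-precise first upward crossings of the activation threshold
    per (beat, cell), NaN where a cell never activated in that beat.
    """

    times: np.ndarray
    v: np.ndarray
    stim_times: np.ndarray
    act_times: np.ndarray
    cell_types: list[str]
    config: TissueConfig
    protocol: PacingProtocol
    scaling: ChannelScaling
    output_dt: float

    @property
    def n_cells(self) -> int:
        return self.v.shape[0]

    @property
    def recorded_beats(self) -> list[int]:
        return list(range(self.protocol.n_beats - self.protocol.record_last,
                          self.protocol.n_beats))

    def beat_window(self, beat: int) -> tuple[float, float]:
        """[stimulus, next stimulus) window of a beat (ms)."""
        if not (0 <= beat < self.protocol.n_beats):
            raise ParameterError(f"beat {beat} outside protocol")
        return beat * self.protocol.cl, (beat + 1) * self.protocol.cl

    def window_slice(self, beat: int) -> slice:
        t0, t1 = self.beat_window(beat)
        i0 = int(np.searchsorted(self.times, t0 - 1e-9))
        i1 = int(np.searchsorted(self.times, t1 - 1e-9))
        return slice(i0, i1)


def simulate(tissue: Tissue, protocol: PacingProtocol,
             output_dt: float = 0.5,
             initial_v: float = -84.0,
             dt_max: float = DT_MAX) -> SimulationResult:
    """Pace the strand from the Purkinje end and record the last beats."""
    if output_dt <= 0:
        raise ParameterError("output_dt must be > 0")
    cfg = tissue.config
    n = cfg.n_cells
    st = initial_state(v=initial_v)
    v = np.full(n, st.v)
    y = np.tile(st.gates, (n, 1))
    cai = np.full(n, st.concentrations[0])
    stim_idx = np.arange(cfg.n_stim_cells, dtype=np.int64)
    record_start = protocol.cl * (protocol.n_beats - protocol.record_last)
    status, cell, t_err, times, v_rec, act = K.integrate_strand(
        v, y, cai, tissue.conductances, tissue.tables, tissue.tau_hl,
        tissue.face_d, cfg.dx_mm, stim_idx, cfg.stim_amplitude,
        cfg.stim_duration, float(protocol.cl), int(protocol.n_beats),
        float(record_start), float(output_dt), DT_MIN, float(dt_max), V_ACT)
    if status != K.STATUS_OK:
        raise DivergenceError(cell, t_err)
    stim_times = np.arange(protocol.n_beats) * float(protocol.cl)
    return SimulationResult(
        times=times, v=v_rec, stim_times=stim_times, act_times=act,
        cell_types=tissue.cell_types, config=cfg, protocol=protocol,
        scaling=tissue.scaling, output_dt=output_dt)


def run_strand(scaling: ChannelScaling = CONTROL_SCALING,
               cl: float = 750.0, n_beats: int = 10, record_last: int = 2,
               config: TissueConfig | None = None,
               output_dt: float = 0.5) -> SimulationResult:
    """Convenience wrapper: build the default strand and pace it."""
    cfg = config or TissueConfig()
    tissue = build_tissue(cfg, scaling)
    return simulate(tissue, PacingProtocol(cl=cl, n_beats=n_beats,
                                           record_last=record_last),
                    output_dt=output_dt)


# ---------------------------------------------------------------------------
# persistence

def save_result(result: SimulationResult, path) -> None:
    """Persist a voltage map to HDF5 (/times, /v, /stim_times, /act_times)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=result.times)
        f.create_dataset("v", data=result.v)
        f.create_dataset("stim_times", data=result.stim_times)
        f.create_dataset("act_times", data=result.act_times)
        f.attrs["config"] = json.dumps(asdict(result.config))
        f.attrs["protocol"] = json.dumps(asdict(result.protocol))
        f.attrs["scaling"] = json.dumps(asdict(result.scaling))
        f.attrs["cell_types"] = json.dumps(result.cell_types)
        f.attrs["output_dt"] = result.output_dt


def load_result(path) -> SimulationResult:
    with h5py.File(path, "r") as f:
        cfg = TissueConfig(**json.loads(f.attrs["config"]))
        protocol = PacingProtocol(**json.loads(f.attrs["protocol"]))
        scaling = ChannelScaling(**json.loads(f.attrs["scaling"]))
        return SimulationResult(
            times=f["times"][:], v=f["v"][:], stim_times=f["stim_times"][:],
            act_times=f["act_times"][:],
            cell_types=json.loads(f.attrs["cell_types"]),
            config=cfg, protocol=protocol, scaling=scaling,
            output_dt=float(f.attrs["output_dt"]))


def export_map_csv(result: SimulationResult, path) -> None:
    """Cells x time voltage map as CSV (rows = cells, columns = sample times)."""
    header = ",".join(f"{t:g}" for t in result.times)
    np.savetxt(path, result.v, delimiter=",", header=header, comments="")
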