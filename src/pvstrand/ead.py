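"""EAD detection, alternans detection, run categorisation and spatial
EAD-pattern classification.

An early afterdepolarisation (EAD) is a secondary depolarising upstroke
during repolarisation: after the primary action-potential complex and
before the cell's final complete repolarisation, every local minimum that
is followed by a net rise of at least A_min with a sustained minimum slope
spawns one event. Runs are categorised with the fixed precedence

    no_excitation > ead > ap_alternans > ap_prolongation > control

and EAD-bearing runs receive a spatial subtype with the precedence

    oscillatory > unidirectional > discordant > synchronized > localized.

All operational constants sit in `EadThresholds`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence

import numpy as np

from .ecg import BeatFeatures
from .errors import ParameterError
from .tissue import LAYER_ORDER, SimulationResult

CATEGORIES = ("control", "ap_prolongation", "ap_alternans", "ead",
              "no_excitation")
SUBTYPES = ("synchronized", "localized", "unidirectional_antegrade",
            "unidirectional_retrograde", "discordant",
            "oscillatory_sustained", "oscillatory_self_terminated")


@dataclass(frozen=True)
class EadThresholds:
    """Operational constants of the detector and classifiers.

    a_min: minimum net rise of a secondary upstroke (mV).
    slope_min / slope_dur: the rise must sustain at least slope_min mV/ms
        over slope_dur ms.
    primary_merge_ms: dead time after activation inside which deflections
        belong to the primary spike-notch-dome complex, not to EADs.
    tau_sync: onset-time span below which EAD groups count as synchronous.
    n_osc: successive events in one cell that make a pattern oscillatory.
    apd_delta: beat-to-beat APD difference that counts as alternans (ms).
    prolong_frac: QT excess over control that counts as AP prolongation.
    activation_frac: fraction of cells that must be excited for a beat
        to count as excited.
    v_excite: a cell counts as excited in a beat when its peak potential
        exceeds this overshoot level; sub-threshold electrotonic humps
        (which may still cross the -20 mV timing threshold) are not
        excitation.
    min_unidir_cells: smallest EAD-bearing region for which a spatial
        onset gradient is called propagation.
    """

    a_min: float = 1.0
    slope_min: float = 0.05
    slope_dur: float = 2.0
    primary_merge_ms: float = 100.0
    tau_sync: float = 20.0
    n_osc: int = 3
    apd_delta: float = 5.0
    prolong_frac: float = 0.10
    activation_frac: float = 0.90
    min_unidir_cells: int = 4
    v_act: float = -20.0
    v_rep: float = -70.0
    v_excite: float = 0.0


DEFAULT_EAD_THRESHOLDS = EadThresholds()


@dataclass
class EADEvent:
    """One secondary upstroke: onset at the local minimum before the rise."""

    cell_index: int
    beat_index: int
    onset_time: float
    takeoff_v: float
    amplitude: float


@dataclass
class PatternLabel:
    """Category of a run plus, for EAD runs, the spatial subtype."""

    category: str
    ead_subtype: str | None = None
    ead_cv: float | None = None


def detect_eads(times: np.ndarray, v: np.ndarray,
                window: tuple[float, float],
                cell_index: int = 0, beat_index: int = 0,
                thresholds: EadThresholds = DEFAULT_EAD_THRESHOLDS
                ) -> List[EADEvent]:
    """Detect secondary upstrokes in one cell's trace inside a beat window.

    The scan runs from the later of (the primary peak, activation +
    primary_merge_ms) to the final complete repolarisation (the last
    downward crossing of v_rep; window end if the cell never repolarises).
    Returns events sorted by onset; an empty list when the window holds no
    primary action potential.
    """
    t0, t1 = window
    sel = (times >= t0) & (times <= t1)
    t = times[sel]
    x = v[sel]
    if len(x) < 3 or x.max() < thresholds.v_act:
        return []
    # activation = first upward crossing of v_act (window start if the cell
    # enters the window already depolarised, e.g. a carried-over plateau)
    up = np.nonzero((x[:-1] < thresholds.v_act) & (x[1:] >= thresholds.v_act))[0]
    t_act = t[up[0] + 1] if up.size else t[0]
    i_peak = int(np.argmax(x))
    start = max(i_peak, int(np.searchsorted(t, t_act + thresholds.primary_merge_ms)))
    down = np.nonzero((x[:-1] >= thresholds.v_rep) & (x[1:] < thresholds.v_rep))[0]
    end = int(down[-1] + 1) if down.size else len(x) - 1
    if start >= end:
        return []

    events: List[EADEvent] = []
    i = start
    while i < end:
        if x[i] <= x[i - 1] and x[i] < x[i + 1]:
            j = i
            while j + 1 <= end and x[j + 1] >= x[j]:
                j += 1
            rise = x[j] - x[i]
            if rise >= thresholds.a_min and _sustained_slope(
                    t[i:j + 1], x[i:j + 1], thresholds):
                events.append(EADEvent(
                    cell_index=cell_index, beat_index=beat_index,
                    onset_time=float(t[i]), takeoff_v=float(x[i]),
                    amplitude=float(rise)))
            i = j + 1
        else:
            i += 1
    return events


def _sustained_slope(t, x, thresholds: EadThresholds) -> bool:
    """True if dV/dt >= slope_min holds over a contiguous slope_dur run."""
    if len(t) < 2:
        return False
    dv = np.diff(x)
    dt = np.diff(t)
    ok = dv >= thresholds.slope_min * dt - 1e-12
    run = 0.0
    for k in range(len(ok)):
        if ok[k]:
            run += dt[k]
            if run >= thresholds.slope_dur - 1e-9:
                return True
        else:
            run = 0.0
    return False


def detect_eads_in_result(result: SimulationResult,
                          thresholds: EadThresholds = DEFAULT_EAD_THRESHOLDS
                          ) -> List[EADEvent]:
    """All EAD events of the recorded beats, all cells.

    A beat's analysis window runs from its stimulus to the next stimulus or
    the recording end; a cell whose action potential carries past the next
    stimulus without repolarising keeps contributing events to the beat
    where the AP began (the next window then has no primary activation of
    its own for that cell, because activation requires an upward crossing).
    """
    events: List[EADEvent] = []
    for beat in result.recorded_beats:
        t0, t1 = result.beat_window(beat)
        # extend the last window to the end of the recording
        if beat == result.protocol.n_beats - 1:
            t1 = float(result.times[-1])
        for cell in range(result.n_cells):
            acted = np.isfinite(result.act_times[beat, cell])
            carried = (beat - 1 in result.recorded_beats
                       and result.v[cell, result.window_slice(beat).start]
                       > thresholds.v_act)
            if carried and not acted:
                # plateau carried over from the previous beat: those events
                # belong to the previous beat and were found there
                continue
            events.extend(detect_eads(
                result.times, result.v[cell], (t0, t1), cell_index=cell,
                beat_index=beat, thresholds=thresholds))
    return events


# ---------------------------------------------------------------------------
# alternans

@dataclass
class AlternansDetail:
    apd_alternans: bool
    conduction_alternans: bool
    max_apd_delta: float

    @property
    def any(self) -> bool:
        return self.apd_alternans or self.conduction_alternans


def detect_alternans(result: SimulationResult,
                     repol_by_beat: Dict[int, np.ndarray],
                     thresholds: EadThresholds = DEFAULT_EAD_THRESHOLDS
                     ) -> AlternansDetail:
    """Beat-to-beat APD or conduction (2:1) alternation over the last
    two recorded beats.

    `repol_by_beat` maps beat index -> per-cell repolarisation times.
    """
    beats = result.recorded_beats
    if len(beats) < 2:
        raise ParameterError("alternans needs at least 2 recorded beats")
    b0, b1 = beats[-2], beats[-1]

    # conduction: does each beat excite the epicardial end?
    reach0 = np.isfinite(result.act_times[b0, -1])
    reach1 = np.isfinite(result.act_times[b1, -1])
    conduction = reach0 != reach1

    max_delta = 0.0
    apd_alt = False
    r0, r1 = repol_by_beat.get(b0), repol_by_beat.get(b1)
    if r0 is not None and r1 is not None:
        apd0 = r0 - result.act_times[b0]
        apd1 = r1 - result.act_times[b1]
        both = np.isfinite(apd0) & np.isfinite(apd1)
        if both.any():
            max_delta = float(np.max(np.abs(apd1[both] - apd0[both])))
            apd_alt = max_delta >= thresholds.apd_delta
    return AlternansDetail(apd_alternans=apd_alt,
                           conduction_alternans=bool(conduction),
                           max_apd_delta=max_delta)


# ---------------------------------------------------------------------------
# categorisation

def classify_run(result: SimulationResult,
                 features: Sequence[BeatFeatures],
                 events: Sequence[EADEvent],
                 control_qt: float,
                 alternans: AlternansDetail | None = None,
                 thresholds: EadThresholds = DEFAULT_EAD_THRESHOLDS) -> str:
    """Category of a run by fixed precedence (see module docstring)."""
    if control_qt is None or not np.isfinite(control_qt):
        raise ParameterError("classify_run requires the control QT at the "
                             "same cycle length")
    n = result.n_cells
    excited = []
    for b in result.recorded_beats:
        peaks = result.v[:, result.window_slice(b)].max(axis=1)
        excited.append((peaks > thresholds.v_excite).sum()
                       >= thresholds.activation_frac * n)
    if not any(excited):
        return "no_excitation"
    if len(events) > 0:
        return "ead"
    if alternans is not None and alternans.any:
        return "ap_alternans"
    qts = [f.qt for f in features if f.defined]
    if not qts:
        # excited but never completely repolarising, without EAD upstrokes:
        # an unbounded QT, reported as prolongation
        return "ap_prolongation"
    if max(qts) > (1.0 + thresholds.prolong_frac) * control_qt:
        return "ap_prolongation"
    return "control"


# ---------------------------------------------------------------------------
# spatial patterns

def _first_onset_by_cell(events: Iterable[EADEvent]) -> Dict[int, float]:
    out: Dict[int, float] = {}
    for ev in events:
        if ev.cell_index not in out or ev.onset_time < out[ev.cell_index]:
            out[ev.cell_index] = ev.onset_time
    return out


def _contiguous_groups(cells: Sequence[int]) -> List[List[int]]:
    groups: List[List[int]] = []
    for c in sorted(cells):
        if groups and c == groups[-1][-1] + 1:
            groups[-1].append(c)
        else:
            groups.append([c])
    return groups


def classify_spatial_pattern(result: SimulationResult,
                             events: Sequence[EADEvent],
                             thresholds: EadThresholds = DEFAULT_EAD_THRESHOLDS
                             ) -> tuple[str, float | None]:
    """Spatial subtype of an EAD-bearing run (and a CV for unidirectional).

    Evaluated per recorded beat, most severe beat wins by the precedence
    oscillatory > unidirectional > discordant > synchronized > localized.
    """
    if not events:
        raise ParameterError("spatial pattern classification requires EAD "
                             "events (category must be 'ead')")
    best: tuple[int, str, float | None] | None = None
    order = {name: i for i, name in enumerate((
        "localized", "synchronized", "discordant",
        "unidirectional_retrograde", "unidirectional_antegrade",
        "oscillatory_self_terminated", "oscillatory_sustained"))}
    for beat in result.recorded_beats:
        beat_events = [ev for ev in events if ev.beat_index == beat]
        if not beat_events:
            continue
        sub, cv = _classify_beat_pattern(result, beat_events, thresholds)
        rank = order[sub]
        if best is None or rank > best[0]:
            best = (rank, sub, cv)
    assert best is not None
    return best[1], best[2]


def _classify_beat_pattern(result: SimulationResult,
                           events: Sequence[EADEvent],
                           thresholds: EadThresholds):
    cfg = result.config
    n_layer = cfg.cells_per_layer
    onset = _first_onset_by_cell(events)
    cells = sorted(onset)

    # oscillatory: any cell with >= n_osc successive events in this beat
    per_cell_counts: Dict[int, int] = {}
    for ev in events:
        per_cell_counts[ev.cell_index] = per_cell_counts.get(ev.cell_index, 0) + 1
    if max(per_cell_counts.values()) >= thresholds.n_osc:
        end_v = result.v[:, -1]
        sustained = bool((end_v[list(per_cell_counts)] > thresholds.v_rep).any())
        return ("oscillatory_sustained" if sustained
                else "oscillatory_self_terminated", None)

    groups = _contiguous_groups(cells)

    # unidirectional: strictly monotone onsets across a large enough region
    big = max(groups, key=len)
    if len(big) >= thresholds.min_unidir_cells:
        ts = np.array([onset[c] for c in big])
        d = np.diff(ts)
        if np.all(d > 0) or np.all(d < 0):
            lo = int(round(0.25 * (len(big) - 1)))
            hi = int(round(0.75 * (len(big) - 1)))
            span = abs(ts[hi] - ts[lo])
            if span > 0:
                cv = (hi - lo) * cfg.dx_cm * 10.0 / span  # mm/ms == m/s
                direction = "antegrade" if ts[-1] > ts[0] else "retrograde"
                return (f"unidirectional_{direction}", float(cv))

    # discordant: >= 2 separated groups with desynchronised onsets
    if len(groups) >= 2:
        medians = [float(np.median([onset[c] for c in g])) for g in groups]
        if max(medians) - min(medians) > thresholds.tau_sync:
            return ("discordant", None)

    # synchronized: every tissue type carries events, onsets within tau_sync
    layer_of = lambda c: LAYER_ORDER[c // n_layer]
    by_layer: Dict[str, List[float]] = {}
    for c, t in onset.items():
        by_layer.setdefault(layer_of(c), []).append(t)
    if set(by_layer) == set(LAYER_ORDER):
        meds = [np.median(ts) for ts in by_layer.values()]
        if max(meds) - min(meds) <= thresholds.tau_sync:
            return ("synchronized", None)

    # localized: events confined to a contiguous subset of layers with no
    # appreciable onset gradient
    layers_hit = sorted({LAYER_ORDER.index(l) for l in by_layer})
    contiguous_layers = layers_hit == list(range(layers_hit[0],
                                                 layers_hit[-1] + 1))
    ts = np.array([onset[c] for c in cells])
    if contiguous_layers and (ts.max() - ts.min()) <= thresholds.tau_sync:
        return ("localized", None)

    # fallback: spatially irregular onsets count as desynchronised
    return ("discordant", None)
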