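"""Parameter-space sweep over (S_Kr, S_CaL, CL) and its bookkeeping.

The default grid inhibits I_Kr and I_CaL at 0%, 10%, ..., 100% (11 x 11 =
121 dual-block settings) and paces at cycle lengths 250, 300, ..., 1000 ms
(16 rates; 1936 runs in total). Each run is simulated, analysed and given
exactly one category; EAD runs additionally carry a spatial subtype.
Run order is lexicographic in (S_Kr, S_CaL, CL) and the output is
deterministic for a fixed configuration.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .ecg import (
    TWaveReference,
    beat_features,
    compute_pseudo_ecg,
    control_twave_reference,
)
from .ead import (
    DEFAULT_EAD_THRESHOLDS,
    EadThresholds,
    PatternLabel,
    classify_run,
    classify_spatial_pattern,
    detect_alternans,
    detect_eads_in_result,
)
from .errors import ConfigurationError, DivergenceError
from .ionic import ChannelScaling
from .tissue import (
    LAYER_ORDER,
    PacingProtocol,
    SimulationResult,
    TissueConfig,
    build_tissue,
    simulate,
)

DEFAULT_BLOCK_LEVELS = tuple(round(0.1 * i, 1) for i in range(11))
DEFAULT_CLS = tuple(range(250, 1001, 50))


@dataclass(frozen=True)
class SweepGrid:
    """Block levels (fraction of current removed) and pacing cycle lengths."""

    s_kr_levels: tuple = DEFAULT_BLOCK_LEVELS
    s_cal_levels: tuple = DEFAULT_BLOCK_LEVELS
    cls: tuple = DEFAULT_CLS

    def __post_init__(self):
        for name in ("s_kr_levels", "s_cal_levels", "cls"):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise ConfigurationError(f"{name} must not be empty")
        for lv in tuple(self.s_kr_levels) + tuple(self.s_cal_levels):
            if not (0.0 <= lv <= 1.0):
                raise ConfigurationError("block levels must lie in [0, 1]")
        if any(cl <= 0 for cl in self.cls):
            raise ConfigurationError("cycle lengths must be positive")

    @property
    def n_settings(self) -> int:
        return len(self.s_kr_levels) * len(self.s_cal_levels)

    @property
    def n_runs(self) -> int:
        return self.n_settings * len(self.cls)

    def triples(self):
        """Lexicographic (s_kr_block, s_cal_block, cl) enumeration."""
        return itertools.product(self.s_kr_levels, self.s_cal_levels,
                                 self.cls)


def enumerate_grid(s_kr_levels: Sequence[float] | None = None,
                   s_cal_levels: Sequence[float] | None = None,
                   cls: Sequence[float] | None = None,
                   subsample: int | None = None,
                   seed: int | None = None) -> SweepGrid:
    """Build a sweep grid (defaults reproduce the full 121 x 16 design).

    `subsample` draws that many random settings (with an explicit seed)
    instead of the exhaustive grid.
    """
    grid = SweepGrid(
        s_kr_levels=tuple(s_kr_levels) if s_kr_levels is not None
        else DEFAULT_BLOCK_LEVELS,
        s_cal_levels=tuple(s_cal_levels) if s_cal_levels is not None
        else DEFAULT_BLOCK_LEVELS,
        cls=tuple(cls) if cls is not None else DEFAULT_CLS)
    if subsample is not None:
        if seed is None:
            raise ConfigurationError("subsampling requires an explicit seed")
        rng = np.random.default_rng(seed)
        pairs = list(itertools.product(grid.s_kr_levels, grid.s_cal_levels))
        take = rng.choice(len(pairs), size=min(subsample, len(pairs)),
                          replace=False)
        chosen = [pairs[i] for i in sorted(take)]
        grid = SweepGrid(
            s_kr_levels=tuple(sorted({p[0] for p in chosen})),
            s_cal_levels=tuple(sorted({p[1] for p in chosen})),
            cls=grid.cls)
    return grid


@dataclass
class RunRecord:
    """Analysis summary of one (s_kr_block, s_cal_block, cl) run."""

    s_kr_block: float
    s_cal_block: float
    cl: float
    category: str
    ead_subtype: str | None = None
    ead_cv: float | None = None
    qt: List[float] = field(default_factory=list)
    t_pe: List[float] = field(default_factory=list)
    t_wave_tags: List[List[str]] = field(default_factory=list)
    n_events: int = 0
    events_per_layer: Dict[str, int] = field(default_factory=dict)
    error: str | None = None


@dataclass
class SweepResult:
    grid: SweepGrid
    records: List[RunRecord]
    config_hash: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = asdict(r)
            row["qt"] = ";".join(f"{q:.1f}" for q in r.qt)
            row["t_pe"] = ";".join(f"{q:.1f}" for q in r.t_pe)
            row["t_wave_tags"] = ";".join("|".join(sorted(t))
                                          for t in r.t_wave_tags)
            row["events_per_layer"] = json.dumps(r.events_per_layer,
                                                 sort_keys=True)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as f:
            for r in self.records:
                f.write(json.dumps(asdict(r), sort_keys=True) + "\n")

    def category_counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for r in self.records:
            out[r.category] = out.get(r.category, 0) + 1
        return out


@dataclass
class ControlReference:
    """Per-cycle-length control quantities for relative classification."""

    qt: float
    twave: TWaveReference | None


def analyze_run(result: SimulationResult, control: ControlReference,
                thresholds: EadThresholds = DEFAULT_EAD_THRESHOLDS
                ) -> tuple[PatternLabel, RunRecord]:
    """Full analysis of one run against its control reference."""
    sc = result.scaling
    ecg = compute_pseudo_ecg(result)
    feats = []
    repol_by_beat = {}
    for b in result.recorded_beats:
        f = beat_features(result, b, ecg=ecg, control=control.twave)
        feats.append(f)
        repol_by_beat[b] = f.repol_times
    events = detect_eads_in_result(result, thresholds)
    alternans = (detect_alternans(result, repol_by_beat, thresholds)
                 if len(result.recorded_beats) >= 2 else None)
    category = classify_run(result, feats, events, control.qt, alternans,
                            thresholds)
    label = PatternLabel(category=category)
    if category == "ead":
        sub, cv = classify_spatial_pattern(result, events, thresholds)
        label.ead_subtype = sub
        label.ead_cv = cv
    per_layer: Dict[str, int] = {l: 0 for l in LAYER_ORDER}
    n_layer = result.config.cells_per_layer
    for ev in events:
        per_layer[LAYER_ORDER[ev.cell_index // n_layer]] += 1
    record = RunRecord(
        s_kr_block=round(1.0 - sc.s_kr, 10),
        s_cal_block=round(1.0 - sc.s_cal, 10),
        cl=result.protocol.cl,
        category=category, ead_subtype=label.ead_subtype,
        ead_cv=label.ead_cv,
        qt=[float(f.qt) for f in feats],
        t_pe=[float(f.t_pe) for f in feats],
        t_wave_tags=[sorted(f.t_wave_tags) for f in feats],
        n_events=len(events), events_per_layer=per_layer)
    return label, record


def run_sweep(grid: SweepGrid,
              config: TissueConfig | None = None,
              n_beats: int = 10, record_last: int = 2,
              output_dt: float = 0.5,
              thresholds: EadThresholds = DEFAULT_EAD_THRESHOLDS,
              progress: bool = False, workers: int = 1,
              maps_path=None) -> SweepResult:
    """Simulate and analyse every triple of the grid.

    Control references are computed once per cycle length from the
    unblocked strand. A run that diverges numerically is recorded with
    category "numeric_failure" and the sweep continues. With workers > 1
    independent runs execute concurrently; per-run determinism plus the
    ordered reduction keep the output identical to serial execution.
    `maps_path` stores every run's recorded voltage map (the analysed
    last beats only) in one HDF5 file under /runs/<id>/.
    """
    cfg = config or TissueConfig()
    provenance = {
        "grid": asdict(grid), "config": asdict(cfg),
        "n_beats": n_beats, "record_last": record_last,
        "output_dt": output_dt,
    }
    config_hash = hashlib.sha256(
        json.dumps(provenance, sort_keys=True).encode()).hexdigest()[:16]

    controls: Dict[float, ControlReference] = {}
    control_results: Dict[float, SimulationResult] = {}
    for cl in grid.cls:
        res = simulate(build_tissue(cfg, ChannelScaling(1.0, 1.0)),
                       PacingProtocol(cl=cl, n_beats=n_beats,
                                      record_last=record_last), output_dt)
        ecg = compute_pseudo_ecg(res)
        from .ecg import compute_qt_tpe
        qt = compute_qt_tpe(res, res.recorded_beats[-1]).qt
        twave = control_twave_reference(ecg, res, res.recorded_beats[-1])
        controls[cl] = ControlReference(qt=qt, twave=twave)
        control_results[cl] = res

    store = None
    if maps_path is not None:
        import h5py
        store = h5py.File(maps_path, "w")
        store.attrs["config_hash"] = config_hash

    def one(kr_block, cal_block, cl):
        scaling = ChannelScaling.from_block(kr_block, cal_block)
        try:
            if kr_block == 0.0 and cal_block == 0.0:
                res = control_results[cl]
            else:
                res = simulate(build_tissue(cfg, scaling),
                               PacingProtocol(cl=cl, n_beats=n_beats,
                                              record_last=record_last),
                               output_dt)
            _, record = analyze_run(res, controls[cl], thresholds)
            if store is not None:
                gid = (f"runs/kr{kr_block:g}_cal{cal_block:g}_cl{cl:g}")
                grp = store.create_group(gid)
                grp.create_dataset("times", data=res.times)
                grp.create_dataset("v", data=res.v.astype(np.float32))
                grp.create_dataset("act_times", data=res.act_times)
                grp.attrs["category"] = record.category
        except DivergenceError as exc:
            record = RunRecord(s_kr_block=kr_block, s_cal_block=cal_block,
                               cl=cl, category="numeric_failure",
                               error=str(exc))
        if progress:
            print(f"  block_kr={kr_block:.2f} block_cal={cal_block:.2f} "
                  f"cl={cl:.0f} -> {record.category}", flush=True)
        return record

    triples = list(grid.triples())
    if workers > 1 and maps_path is None:
        from joblib import Parallel, delayed
        records = Parallel(n_jobs=workers)(
            delayed(one)(*t) for t in triples)
    else:
        records = [one(*t) for t in triples]
    if store is not None:
        store.close()
    return SweepResult(grid=grid, records=list(records),
                       config_hash=config_hash)
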