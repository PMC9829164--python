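# pvstrand

A 1D tissue simulator of the Purkinje–ventricular system (PVS) for
studying how cell-level early afterdepolarisations (EADs) organise
spatially and shape T-wave morphology.

Sudden cardiac death is mostly caused by ventricular arrhythmias, and
EADs — secondary depolarisations during action-potential repolarisation —
are a key trigger under reduced repolarisation reserve (e.g. long-QT
conditions). `pvstrand` models the conduction pathway as a heterogeneous
cable of four electrically coupled layers (Purkinje → endocardium →
midmyocardium → epicardium, 50 cells each, 2 cm), solves the monodomain
cable equation

    ∂V/∂t = ∇·(D ∇V) − I_ion

with a fully documented Hodgkin–Huxley-type membrane model
(`docs/model.md`), and analyses the result: pseudo-ECG at a virtual
electrode beyond the epicardial end, QT and T_peak–end (T_pe, the
transmural-dispersion index), T-wave morphology tags (inverted, biphasic,
notched, broad-based, late/pointed), EAD detection with spatial-pattern
classification (synchronized, localized, unidirectional
antegrade/retrograde, discordant, oscillatory), and a parameter-space map
of excitation categories over (I_Kr block, I_CaL block, pacing cycle
length) — 121 dual-block settings × 16 rates = 1936 runs in the full
design.

Tissue-specific conduction is calibrated to experimental targets:
Purkinje CV = 2 m/s, ventricular CV = 0.5 m/s, and a 4.364 ms conduction
delay across the Purkinje–ventricular junction (set by the junctional
coupling ratio E_R). The membrane model is the package's own reference
formulation; the canine models used in the source experiments can be
plugged in through the same `CellModel` interface.

For whom: computational cardiac electrophysiologists and students who
want a self-contained, fast (seconds per strand run) testbed for
repolarisation-reserve experiments, EAD pattern analysis, and
pseudo-ECG feature extraction.

## Worked example

```python
from pvstrand import (ChannelScaling, TissueConfig, PacingProtocol,
                      build_tissue, simulate, compute_qt_tpe)
from pvstrand.ead import detect_eads_in_result, classify_spatial_pattern

cfg = TissueConfig()                      # 200 cells, calibrated profile
control = simulate(build_tissue(cfg, ChannelScaling()),
                   PacingProtocol(cl=750, n_beats=8, record_last=2))
f = compute_qt_tpe(control, -1)
print(f"control  CL=750  QT = {f.qt:.1f} ms   T_pe = {f.t_pe:.1f} ms")

blocked = simulate(build_tissue(cfg, ChannelScaling(s_kr=0.3)),
                   PacingProtocol(cl=1000, n_beats=8, record_last=2))
events = detect_eads_in_result(blocked)
sub, cv = classify_spatial_pattern(blocked, events)
print(f"70% I_Kr block  CL=1000  {len(events)} EAD events -> {sub}")
```

prints

```
control  CL=750  QT = 217.6 ms   T_pe = 9.9 ms
70% I_Kr block  CL=1000  100 EAD events -> localized
```

QT is the time from the stimulus to the last cell completing
repolarisation anywhere in the strand; T_pe the spread between the first
and last repolarising cell. Blocking 70% of I_Kr at a slow rate more than
doubles QT and fills the strand with secondary depolarisations, here
confined to contiguous layers (a "localized" pattern).

The same workflow is available from a shell:

```sh
pvstrand calibrate --out calibration.json
pvstrand simulate --cl 750 --n-beats 8 --out control.h5
pvstrand simulate --cl 750 --n-beats 8 --block-kr 0.8 --out blocked.h5
pvstrand analyze blocked.h5 control.h5 --out analysis.json
pvstrand sweep --scaled --out-prefix sweep        # 4x4x4 category map data
pvstrand render --labels sweep_labels.csv --out categories.png
```

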