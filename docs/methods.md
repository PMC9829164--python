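# Methods

## The system

`pvstrand` simulates electrical excitation in a one-dimensional strand of
the Purkinje–ventricular system: 4 layers (Purkinje, endocardial,
midmyocardial, epicardial), 50 cells each by default, 2 cm in total, paced
at the Purkinje end. Propagation follows the monodomain cable equation

    ∂V/∂t = ∇·(D ∇V) − I_ion

discretised on a cell-centred grid (dx = length / n_cells = 100 µm by
default) with face-located diffusion coefficients and sealed (no-flux)
ends: D_P on faces inside the Purkinje layer, D_v inside and between the
ventricular layers, and D_Pv = E_R·D_v on the single face forming the
Purkinje–ventricular junction (PVJ). I_ion is supplied per cell by the
membrane model of docs/model.md; the four layer variants differ only by
documented conductance multipliers.

## Numerics

Operator splitting (Lie): each step advances the reaction term with an
adaptive step dt = clip(0.5 / max|dV/dt|, 0.001, 0.05) ms, then applies
the diffusion operator sub-cycled at 90% of its explicit stability bound
dx²/(2 max D) inside the same interval. Sub-cycling the cheap diffusion
operator instead of capping the global step keeps the expensive membrane
evaluations an order of magnitude fewer during plateau and diastole with
no measurable accuracy cost (halving the adaptive ceiling moves
activation times by well under 0.5 ms; the suite asserts this). Gates are
advanced by exponential (Rush–Larsen) updates for the stiff gates
m, h, j, d and forward Euler for the slow gates, then clamped to [0, 1];
Cai is floored at 10⁻⁷ mM. Gate rates are evaluated from a dense lookup
table on a 0.05 mV grid (linear interpolation); steps are clipped to land
exactly on stimulus edges and output sample times, so recordings are
deterministic. Voltage maps are recorded at output_dt = 0.5 ms;
activation times (first upward crossing of −20 mV) are located inside the
integrator by in-step linear interpolation, so conduction measurements do
not depend on the output sampling. Integration aborts with a diagnostic
(cell index, time) if |V| exceeds 200 mV.

The exposed `diffusion_step` operation is flux-conservative (the sum of
the update telescopes to the boundary fluxes, i.e. zero) and raises a
stability error when a single explicit step would exceed the bound.

## Stimulus

Tissue runs stimulate the first 5 Purkinje cells with −100 µA/µF for 2 ms
(the slow, calcium-assisted ventricular upstroke of the shipped model
needs a larger ignition charge than a fast-sodium tissue would); both the
site count and the waveform are configurable. Single-cell protocols use
−52 µA/µF for 1 ms, a suprathreshold but non-overdriving standard pulse.

## Calibration

Conduction velocities are measured from activation times between probes at
25%/75% of a segment. The diffusion coefficients are bisected (in log-D,
since CV ≈ √D) on homogeneous 400-cell strands — long enough that the
front speed has settled and the measurement segment (cells 100–300) sits
several foot-lengths from both the ignition region and the sealed end —
against the experimental targets CV_P = 2 m/s and CV_v = 0.5 m/s (2%
tolerance). Brackets: D_P ∈ [0.3, 3], D_v ∈ [0.1, 2] mm²/ms; outside
these, ignition fails (high end) or conduction fails (low end). The
junctional ratio E_R is then bisected on the full heterogeneous strand
until the activation delay between the last Purkinje and first
endocardial cell matches 4.364 ms within 0.05 ms (bracket [0.06, 5]; the
junction blocks below ≈ 0.05 for this model — the delay target itself
sits close to the conduction-block margin, as a real PVJ does). The
calibrated profile for the shipped model,

    D_P = 1.177 mm²/ms,  D_v = 0.946 mm²/ms,  E_R = 0.0713,

is the package default; the published canine profile
(D_P = 1.2, D_v = 0.1, E_R = 3.13) remains available as the named
`canine` profile for users plugging in the canine ionic models, but
will not reproduce the target CVs under the shipped membrane model (its
ventricular upstroke is slower than the canine one, so matching 0.5 m/s
needs a larger D_v, and its junction must be weaker to produce the same
delay). E_R multiplies the junction face coefficient symmetrically; the
calibrated observable is the delay, not a current asymmetry.

## Pseudo-ECG and repolarisation features

The extracellular unipolar potential at an electrode on the strand axis
2 cm beyond the epicardial end is

    φ(t) = −K Σ_faces D_f (∂V/∂x)|_f (∂(1/r)/∂x)|_f dx,  K = 1 (arbitrary units).

QT of a beat is the time from its stimulus to the last complete
repolarisation anywhere in the strand; T_pe (the transmural-dispersion
index) is the spread between first and last repolarising cell. "Complete
repolarisation" is operationalised as the **last** downward crossing of
V_rep = −70 mV inside the beat's analysis window (stimulus to next
stimulus, or recording end), so a secondary depolarisation postpones it;
cells that never cross are flagged and excluded from T_pe. The threshold
is configurable (`EcgThresholds.v_rep`).

T-wave morphology tags are deterministic rules relative to the control
T-wave at the same cycle length (amplitude floor 5% of the control
T-peak): polarity from the dominant-lobe sign; *biphasic* if both signed
lobes clear the floor; *notched* if two same-sign peaks with prominence
above the floor flank a trough; *broad_based* if the half-maximum
duration exceeds 1.5× control; *late_pointed* if the T-peak falls after
70% of QT **and** the half-maximum width is below 0.6× control. The first
80 ms after ventricular activation (the QRS analogue) are excluded. These
thresholds are the module's interpretive layer and live in one
configuration block (`EcgThresholds`).

## EAD detection and classification

A secondary upstroke counts as an early afterdepolarisation when, after
the primary action-potential complex and before the final complete
repolarisation, a local minimum is followed by a net rise ≥ 1 mV whose
slope sustains ≥ 0.05 mV/ms over ≥ 2 ms. The "primary complex" extends to
100 ms after activation (`primary_merge_ms`): the shipped model's action
potential has a spike–notch–dome shape, and without the merge window the
notch→dome transition of a perfectly normal beat would register as a
false event whenever the sodium spike tops the dome. Events in a cell
whose plateau carries past the next stimulus stay attributed to the beat
where the action potential began.

Runs are categorised by fixed precedence
`no_excitation > ead > ap_alternans > ap_prolongation > control`:

- *no_excitation*: no recorded beat **excites** ≥ 90% of cells. A cell
  counts as excited when its peak potential overshoots 0 mV in the beat
  window — the same criterion as the model's excitability property.
  Sub-threshold electrotonic humps can cross the −20 mV *timing*
  threshold (used for activation times and CV) without being excitation,
  and using the overshoot criterion here keeps the category physiological.
- *ead*: any detected event; *ap_alternans*: any cell's APD differs ≥ 5 ms
  between the last two beats, or conduction alternates 2:1 between them;
  *ap_prolongation*: QT exceeding the control QT at the same cycle length
  by > 10% (a run that excites but never completely repolarises and has
  no events is reported here — an unbounded QT).

EAD-bearing runs get a spatial subtype by the precedence
`oscillatory > unidirectional > discordant > synchronized > localized`:
oscillatory when any cell carries ≥ 3 successive events (sustained if the
trace is still depolarised at the recording end, self-terminated
otherwise); unidirectional when onsets are strictly monotone in space
over a region of ≥ 4 cells (the reported EAD conduction velocity uses the
25%/75% probes of that region, the same convention as the calibration
module); discordant when ≥ 2 spatially separated groups differ in median
onset by > 20 ms (τ_sync); synchronized when all four tissue types carry
events with per-type median onsets within τ_sync; localized when events
are confined to contiguous layers with no appreciable onset gradient.
Spatially irregular event sets that fit none of the shapes fall back to
*discordant*. All constants live in `EadThresholds`.

## The parameter sweep

The full design blocks I_Kr and I_CaL at 0, 10, …, 100% (121 settings)
and paces at CL = 250, 300, …, 1000 ms (16 rates; 1936 runs), 10 beats
per run with the last 2 recorded and analysed. The grid is enumerated
exhaustively and deterministically (random subsampling is available with
an explicit seed); runs execute in lexicographic order, optionally in
parallel workers with an ordered, serial-identical reduction. Control
references (QT, T-wave amplitude/width) are computed once per cycle
length from the unblocked strand. A numerically diverging run is recorded
as `numeric_failure` and the sweep continues.

The scaled test design used by the acceptance checks is a 4×4×4 grid
(I_Kr block 0/25/50/75%, I_CaL block 0/20/40/80%, CL 250/500/750/1000 ms)
on a 40-cell strand (10 cells per layer, 0.4 cm at the standard 100 µm
resolution) with 6 beats per run; it finishes in well under a minute on
one CPU and reproduces the qualitative region layout of the full design:
EAD labels only in the (major I_Kr block, long CL) corner, loss of
excitation wherever I_CaL is blocked ≥ 70%, alternans only at short
cycle lengths, and an all-control unblocked row.

## What the shipped model does and does not represent

The membrane model is a minimal mammalian ventricular formulation tuned
so the coupled strand meets the stated electrophysiological requirements:
M cells repolarise last (coupled strand: last repolarisation in the M
layer; upright control T-wave); a single M cell develops detector-grade
EADs under ≥ 50% I_Kr block at CL = 1000 ms and none in control; ≥ 70%
I_CaL block abolishes the action-potential overshoot; pacing at
CL = 250 ms is stable in control. Its EAD engine is the classic L-type
window-current oscillation, fed by the M-cell late sodium current, made
rate-dependent by slowly accumulating I_Ks activation and late-sodium
availability (both favour EADs at long cycle lengths only).

Known limitations, deliberate under the 1D scope: the ventricular
upstroke is slower than a real canine myocyte's (a design consequence of
requiring excitation loss under calcium-channel block with a single
trigger current), so absolute QT/T_pe millisecond values and category
counts of the full 1936-run design under the published canine models are
*not* quantitative reproductions — region layout and feature directions
are; the coupled
strand's transmural repolarisation spread (T_pe ≈ 10 ms in control) is
smaller than in loosely coupled real tissue; no 3D or branching Purkinje
anatomy, no apicobasal or left–right heterogeneity, no bidomain effects;
the calcium subsystem is a single pool (no sarcoplasmic-reticulum
release), so calcium-driven (delayed) afterdepolarisations are out of
scope. The synthetic fixture generators produce piecewise-linear action
potentials and EAD bumps with exactly known onsets and amplitudes; tests
passing on them establish the correctness of the analysis stack, not the
realism of the solver's waveforms.
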