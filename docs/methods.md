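# Methods

This note records the models implemented in `meascreen`, the defaults
that matter, the design choices made where the design was genuinely
open, and what the tests do and do not establish.

## Single-cell electrophysiology

`meascreen.ordmodel` implements the O'Hara–Rudy dynamic human
ventricular model: 41 state variables (membrane potential; myoplasmic,
subspace and SR concentrations of Na⁺, K⁺, Ca²⁺; the INa/INaL/Ito/
ICaL/IKr/IKs/IK1 gating variables; CaMK trapping) with the published
epicardial, mid-myocardial and endocardial parameter variants encoded
as cell-type switches in one numba kernel vectorised over nodes.

Numerics. The default stepper is fixed-step hybrid: Rush–Larsen
exponential updates for every state with a steady-state/time-constant
form (gates, the `nca` fraction, the SR-release fluxes), forward
updates for potential, concentrations and CaMK. Default step 0.005 ms
(protocol code typically uses 0.01 ms, which changes APD by well under
1 ms); recording interval 0.5 ms. An adaptive scipy BDF path on the
same kernel exists as an independent numerical route; the two agree to
~0.1 mV rms over a beat, with identical APD90. Fixed-step runs are
bitwise reproducible.

Validation targets are physiological, not trace-level: resting
potential ≈ −88 mV, overshoot ≈ +40 mV, APD90 ordering
mid > endo > epi (≈ 364/269/236 ms at 1 Hz in this implementation),
monotone APD prolongation as g_Kr is scaled down.

Drug action is pore-block scaling `g = g_ctrl/(1 + ([D]/IC50)^n)`
applied to g_Na (Nav1.5), g_Kr (hERG) and the P_Ca permeability group
I_CaL/I_CaNa/I_CaK (Cav1.2). The Hill coefficient defaults to 1;
`hill_sensitivity` quantifies how weakly the channel activity depends
on n ∈ [0.6, 1.4] near therapeutic doses, which is the rationale for
that default. Censored table potencies (">30", "<1") are parsed as the
bound with a flag; "NA" disables block of that channel.

Early afterdepolarizations. The detector flags every maximal run where
dV/dt > 0.05 mV/ms for ≥ 5 ms while Vm ∈ (−40, +20) mV; the pacing
upstroke crosses that window in under a millisecond and never
qualifies. All thresholds are config keys. The reference EAD protocol
(cycle length, cell type, pre-pacing) is a package choice: 93.5% I_Kr
block robustly produces EADs in the mid-myocardial cell at CL 1000 ms
(and in endo/epi at CL ≥ 2000 ms) while no baseline protocol does.

## Tissue and electrode model

`meascreen.tissue` solves the bidomain equations on a structured
rectangular grid (5-point Laplacian, no-flux edges, boundary nodes
grounded to φₑ = 0) by operator splitting: ionic sub-steps (default 5
per PDE step) then a semi-implicit diffusion solve for Vm at
dt = 0.1 ms, then a direct sparse solve for φₑ. Feedback of electrode
currents into the φₑ equation is neglected (one-way coupling); the
electrode currents here are far too small for the second-order
correction to matter at the grid scales used.

Passive constants are physiologically plausible **stand-ins** chosen
for hiPSC-monolayer behaviour, not literature point estimates:
A_m = 1000 cm⁻¹, C_m = 1 µF/cm², σ_i = 0.5 mS/cm, σ_e = 2.0 mS/cm,
z_thick = 20 µm. With the reference stimulus (−130 pA/pF Gaussian in
time, σ_t = Δt/6, Δt = 4 ms, disc radius 50 µm) these give full
capture and a conduction velocity of ~6 cm/s, inside the reported
hiPSC monolayer range. On grids where the node spacing exceeds the
source radius, the disc is represented by all nodes within
max(r, 1.5 dx) of the centre — a pure discretization device: a
sub-grid source cannot excite a discrete sheet, while at
finite-element resolution the same disc covers several elements.

Heterogeneity. Cell types are assigned from a Gaussian random field
with kernel `exp(-|Δx|²/2 l_c²)` (l_c = 0.25 mm), sampled by
Karhunen–Loève expansion truncated at 99% of the kernel trace and
mapped to uniform marginals through the normal CDF; thresholds at 1/3
and 2/3 give epicardial / endocardial / mid-myocardial nodes. The
empirical field correlation at lag l_c matches exp(−1/2) within ±0.1
over 200 draws. Heterogeneity is what gives the extracellular signal a
visible repolarization phase; a homogeneous sheet repolarises almost
simultaneously and produces a much weaker wave.

Electrode. φₑ is disc-averaged, then passed through
dI/dt + I/τ = (C_el/τ) dφ/dt with φ_f = R_i I (exponential integrator,
exact for piecewise-linear input). Defaults R_el = 100 kΩ,
C_el = 1 µF, R_i = 1 MΩ give τ ≈ 1.1 s (0.14 Hz high-pass corner, HF
gain R_i/(R_i+R_el) ≈ 0.91) so the slow repolarization wave survives
filtering; these too are stand-ins. Measurement noise: zero-mean
Gaussian, 10 µV on FPs and 10⁻³ µM on the well-averaged calcium.

Pairing. A control and a drug well simulated with the same seed share
the heterogeneity field, stimulus position and noise draws, so
ratio-to-control features cancel the field-level variability by
construction.

## Surrogate well generator

`meascreen.surrogate` is a fast parametric generator of per-electrode
FP templates and a calcium transient whose dose-response mirrors the
conductance-block model acting on the full simulator: Na-block slows
conduction and shrinks the depolarization spike, K-block prolongs the
spike-to-repolarization interval (calibrated once against single-cell
APD dose-response: APD90 269 → 425 ms for g_Kr 1 → 0.4), Ca-block
shortens repolarization and shrinks the calcium transient;
electrode-level variability is driven deterministically by the shared
heterogeneity field. It exists so that study-scale databases
(hundreds to thousands of paired wells) are a seconds-scale
computation; it does **not** model tissue electrophysiology, EADs,
conduction block or morphology changes beyond those monotone trends.
The dataset builders default to it; `backend="bidomain"` switches any
builder to the full solver. Consequently, pipeline-level results on
surrogate data validate the feature/optimisation machinery and the
study design — not tissue-level predictions, which rest on the
bidomain tests.

## Feature dictionary

Biomarker operational definitions (the upstream pseudo-code is not
public; every threshold is a config key):

* Spike = max |dV| sample, accepted if above median + 5×MAD of |dV|;
  otherwise the well is quiescent and dropped with a logged reason.
* Depolarization window = spike ± 25 ms; DA = max − min inside it;
  FPN = largest baseline deviation within 50 ms after the window.
* Repolarization centre RC: most prominent peak of the 25 ms-smoothed
  |FP − baseline| at least 50 ms after the depolarization window, with
  a prominence floor of 6× the noise level (estimated from the
  high-frequency residual) — robust to the slow RC-circuit decay tail
  after the spike. When no distinct peak exists (wave merged with the
  post-spike plateau, common at weak far electrodes) the falling-edge
  midpoint of the plateau is used instead. FPD = RC − spike time;
  RA = |FP(RC) − baseline|; RW = width at half RA; AUCr = ∫|FP −
  baseline| over the repolarization window. On clean Gaussian-wave
  fixtures these definitions are exact (RW = 2σ√(2 ln 2) within one
  sample).
* Calcium: CA = peak − diastolic baseline (median of the lowest 30% of
  samples); CDX = time above baseline + (1 − X/100)·CA, X = 90 by
  default; DC = time from peak to 90% recovery.
* Ratios drug/control are computed per electrode and aggregated by the
  per-well median (robust to dead electrodes); zero-control ratios
  become NaN and are imputed with the training-column median at matrix
  assembly (recorded in provenance).
* K1–K5 compare the drug and control repolarization windows of the
  "gold" electrode (largest control RA), linearly resampled to 256
  common points; K5 is measured from the window start.
* Wavelets: Daubechies-4, periodization mode, windows padded to a
  power of two. Positions are selected on the training split only as
  the union of coefficients of |drug − control| (plateau +
  repolarization) exceeding 50 µV — about 3.5× the folded-noise DWT
  coefficient scale at 10 µV FP noise, so the retained set represents
  the signal "up to the noise level" (typically ~10 positions at
  default noise). At transform time a reconstruction whose L2 error
  exceeds the configured tolerance reports the missing positions (the
  dictionary-refresh hook) rather than degrading silently.

## Classifier and optimisation

Costs. Binary labels in {−1, +1}: the cost averages confidence-
weighted, class-frequency-normalised correct/incorrect indicators with
a false-positive weight α ≥ 1 (a risky compound predicted safe);
bounds [−2, 1 + α] are attained exactly at confidence 1. With α = 1,
balanced classes and confidence 1 the cost is an affine map of
balanced accuracy. The k-class form is bounded by [−k, Σ α_j]. The
regularization `β Σ_k (1 − ‖ω_k‖²)²` (β = 0.1 default) pins row norms
near 1; the linear form of that penalty is retained as
`penalty_mode="as_printed"` but is unbounded below when minimised,
which contradicts its purpose — hence the squared default.

Search. Outer loop over input dimensions (d_max), inner loop over
support components; each candidate support's weights are optimised by
a compact in-package (μ/μ_w, λ)-CMA-ES (population 4+⌊3 ln n⌋, initial
step 0.3, weight box ±5, stagnation stop 10⁻⁴ over 20 evaluations,
budget 200 evaluations by default; a deterministic coordinate search
is available as `optimizer="coordinate"`). Candidate scores are
cross-validated (randomized stratified 2-fold, 10 repetitions inside
the loop by default; 500 for final reporting) so the greedy choice
cannot overfit the training predictions. Ties at the argmin go to the
lowest entry index. A candidate component whose cost variation falls
below the 5% tolerance — or which worsens the cost — is rejected and
the dimension closes; a dimension that fails the same test is
discarded, so accepted costs are non-increasing within each dimension
and `tol=inf` yields exactly one component in one dimension.
Previously fixed dimensions' weights stay frozen while a new dimension
is grown.

Cross-validation follows the probability-averaging scheme: each
repetition splits stratified into N_fold folds, every sample is tested
exactly once per repetition, and its class probabilities accumulate;
predictions are the argmax of the averaged probabilities (ties to the
lexicographically first class) and the confidence is that maximum.

## Study builders

* TdP study: per compound × repetition, a paired well at the EFTPC;
  binary risk labels; the split follows the compound table (76
  training / 10 validation compounds at full scale → 1520/200 rows at
  20 repetitions). The published 86-compound table is not public, so a
  synthetic generator draws IC50 triples (hERG 10^[−2.5,2] µM, Cav1.2
  and Nav1.5 10^[−2,2.5] µM) and EFTPC (10^[−3,1.5] µM) log-uniformly
  and labels a compound torsadogenic when EFTPC/IC50_hERG exceeds a
  threshold (0.03 default). For benchmark use the generator redraws
  compounds whose margin lies within a factor 4 of the threshold
  (`margin_gap`), so the label is always carried by a signal-visible
  hERG block — the separable-label design the benchmark calls for;
  `margin_gap=1` disables the gap. This generator emulates the margin
  structure of real compound panels, not their chemistry: real
  torsadogenicity also involves multichannel balance, which the
  rule-based label ignores, so benchmark performance demonstrates the
  pipeline, not clinical predictivity.
* Channel study: 140 samples by default; per sample one target channel
  drawn uniformly from {Na, K, Ca}, blocked Uniform(0, 50)%, the
  others Uniform(0, 5)%; ternary and three binary label sets; 80/20
  split by sample order.
* Both builders fit the wavelet dictionary and imputation statistics
  on the training split only (leakage is tested), default to the
  surrogate backend, and derive every random draw from the master
  seed, making feature matrices bit-reproducible.

## Problem sizes used in the shipped checks

Tissue physics is verified on 21×21 grids (2.4 mm well, dx = 0.12 mm,
one beat, 700 ms) with paired control / 50% g_Kr / 50% g_Na runs;
dataset-size checks build the full 1520/200 and 140-row databases on
the surrogate backend at nx = 15; the TdP benchmark runs five seeded
scaled studies (≈26 compounds × 6 repetitions) and requires ≥ 90%
training sensitivity at α = 2 in at least four of them. These sizes
are package choices balancing resolution against the cost of a
single-CPU run; the solver accepts arbitrary grid resolutions and the
41×41 default grid is used when realism matters more than turnaround.

## Known limitations

* The ORd parameter set is the published adult-ventricular model;
  hiPSC-CM-specific electrophysiology (pacemaking, immature calcium
  handling) is not modelled, and all wells are externally stimulated
  rather than spontaneously beating.
* Structured-grid finite differences replace the unstructured meshes
  of real MEA devices; electrode positions are idealised 3×3 layouts.
* Bidomain passive constants and electrode RC values are plausible
  stand-ins (see above), so absolute FP amplitudes are indicative
  only; ratio-to-control features are insensitive to this by design.
* The surrogate generator reproduces monotone dose-response trends
  only; studies that depend on waveform morphology beyond those trends
  must use the bidomain backend.
* Dynamic (state-dependent) drug binding, temperature effects and
  multi-beat rate phenomena are out of scope.
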