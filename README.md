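# meascreen

In-silico multi-electrode-array (MEA) cardiac safety pharmacology:
simulate drug-modulated field potentials and calcium transients from
human cardiomyocyte monolayers, extract an informed + agnostic feature
dictionary, and train sparse optimal classifiers that predict
Torsade-de-Pointes (TdP) risk and ion-channel blockade.

## Who this is for

Safety pharmacologists and computational electrophysiologists who work
with hiPSC-cardiomyocyte MEA assays (CiPA-style screens) and want (a) a
controllable in-silico generator of MEA recordings under known channel
block, and (b) an optimisation-driven, interpretable alternative to
hand-picked biomarker cutoffs for classifying compounds.

## What it computes

**Signal model.** A monolayer well is a 2-D bidomain sheet of
O'Hara–Rudy (ORd) ventricular cells (epi-/mid-/endocardial variants
assigned from a correlated random field with squared-exponential kernel
`exp(-|Δx|²/2l_c²)`, `l_c = 0.25 mm`, drawn by Karhunen–Loève
expansion). Activation starts from a randomly placed stimulus disc
(`I₀ = −130 pA/pF`, `r = 50 µm`). Electrode discs average the
extracellular potential φₑ; an imperfect-electrode RC circuit
(`τ = C_el (R_i + R_el)`, output `φ_f = R_i I_el`) and 10 µV Gaussian
noise produce the recorded field potential. Drugs act by conductance
block, `g = g_ctrl / (1 + ([D]/IC50)ⁿ)`, mapping hERG → g_Kr,
Cav1.2 → P_Ca (I_CaL, I_CaNa, I_CaK), Nav1.5 → g_Na.

**Dictionary.** Per paired (control, drug) well: seven field-potential
biomarker ratios (DA, FPD, RC, FPN, AUCr, RA, RW), three calcium
ratios (CA, DC, CDX), five repolarization-distortion markers K1–K5
(max squared distance, ℓ² norm, mean/max deviation and its time), and
discrete-wavelet coefficients of |drug − control| over the plateau +
repolarization window at training-selected positions (informed vs
agnostic split).

**Classifier.** The input is `x = Ω · b(z)` with a sparse weight matrix
Ω ∈ R^{d×N_b}. Ω minimises a confidence-weighted, class-balanced cost:
for binary labels the cost lies in `[−2, 1+α]` (−2 = all correct at
confidence 1; `α ≥ 1` penalises calling a risky compound safe), for k
classes in `[−k, Σα_j]`, plus a penalty `β Σ_k (1−‖ω_k‖²)²` that
breaks scaling invariance. The minimisation is double-greedy: grow the
input dimension d, and within each dimension grow the support entry by
entry, tuning weights with an in-package CMA-ES; each candidate is
scored by randomized stratified 2-fold cross-validation with
probability averaging around an LDA base classifier. Growth stops when
the relative cost change drops below 5%.

`GreedySparseLDA` is a scikit-learn estimator (`fit` / `predict` /
`predict_proba`, `get_params`, clonable) and composes with sklearn
model selection.

## Worked example

Build the in-silico channel-blockade study at half scale (70 paired
wells; one channel blocked 0–50%, off-targets 0–5%) and train the
potassium-blocker classifier:

```python
from meascreen import (StudyConfig, build_channel_dataset, GreedySparseLDA,
                       confusion_and_metrics)

cfg = StudyConfig(study="channel_binary", grid="96w8e", grid_nx=15, seed=7,
                  scale=0.5)
ds = build_channel_dataset(cfg)
print(f"dataset: {ds.features.n_samples} paired wells, "
      f"{len(ds.features.entry_names)} dictionary entries")

y = ds.labels["k"]                       # +1: potassium-channel blocker
train = ds.train_mask
clf = GreedySparseLDA(alpha=2.0, beta=0.1, d_max=2, n_comp_max=3,
                      max_evals=60, cv_n_kfold=5, random_state=0)
clf.fit(ds.features.values.loc[train], y[train])
print(clf.report())

rep = confusion_and_metrics(y[~train],
                            clf.predict(ds.features.values.loc[~train]),
                            positive=1)
print(f"validation: sensitivity={rep.sensitivity:.2f} "
      f"specificity={rep.specificity:.2f} accuracy={rep.accuracy:.2f}")
```

Output:

```
dataset: 70 paired wells, 23 dictionary entries
greedy sparse LDA classifier
  x1 = +0.473*da_ratio, +0.961*dc_ratio
  x2 = +0.321*auc_r_ratio, +0.934*ca_ratio
  stop: dimension 0: component change < tol after 2 components
  stop: dimension 1: component change < tol after 2 components
validation: sensitivity=1.00 specificity=1.00 accuracy=1.00
```

The selected entries are physiologically sensible: potassium block
prolongs repolarization, which shows in the calcium decay (`dc_ratio`)
and the repolarization-wave area (`auc_r_ratio`), modulated against
the depolarization and calcium amplitudes. Sensitivity/specificity are
measured on the held-out 20% of wells.

A command-line interface covers the same pipeline:

```bash
meascreen simulate --compound Ibutilide --concentration 0.018 --out well/
meascreen run-study --study channel_binary --scale 0.5 --out study/
```

## Layout

| module | contents |
|---|---|
| `meascreen.ordmodel` / `cell` | ORd ionic model (numba kernel), paced AP protocols, EAD detection |
| `meascreen.compounds` | conductance-block model, compound tables (12-compound CiPA fixture) |
| `meascreen.tissue` | bidomain grid solver, KL heterogeneity, electrode RC + noise, well simulation |
| `meascreen.surrogate` | fast parametric well surrogate for pipeline-scale studies |
| `meascreen.features` | biomarkers, K-markers, wavelet dictionary, feature matrix |
| `meascreen.classifier` / `optimize` | costs, greedy sparse LDA estimator, CMA-ES |
| `meascreen.validation` | randomized stratified k-fold with probability averaging, reports |
| `meascreen.datasets` / `cli` | study builders (TdP, channel), end-to-end runner, CLI |

See `docs/methods.md` for the model assumptions, parameter defaults
and known limitations.
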