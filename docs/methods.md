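# Methods

This note documents the models implemented in `physiomap`, the defaults and
why they were chosen, the numerical strategies, and the limits of what the
synthetic experiments demonstrate.

## 1. Biophysical models

### qBOLD oxygen metabolism

The reversible transverse relaxation-rate offset R₂′ = R₂\* − R₂ of a voxel
is attributed to deoxygenated blood in the static-dephasing regime:

    R₂′ = k · CBV · OEF,      k = (4/3)·π·γ·Δχ·Hct·B₀

with γ = 2.67502×10⁸ rad/s/T, Δχ = 0.264×10⁻⁶, Hct = 0.42·0.85 (systemic
haematocrit with a small-vessel correction) and B₀ = 3 T, giving
k ≈ 316.8 s⁻¹ per unit blood-volume fraction. Inverting this relation yields
the oxygen extraction fraction; the oxygen turnover follows Fick's principle
CMRO₂ = Ca·CBF·OEF with Ca = 8.68 (arterial O₂ content, carried in its
printed unit so CMRO₂ is reported in Ca×flow units — no unit conversion is
attempted because the printed unit is ambiguous). The proportionality
constant in the turnover relation is deliberately chosen equal to the k
above: it is the only choice under which the rate-difference form reduces to
Fick's principle, and it makes the two relations mutually consistent.

Capillary and mitochondrial oxygen tensions follow the Hill/Gjedde model:
capiPO₂ = P₅₀·(2/OEF − 1)^(1/h) with P₅₀ = 27 mmHg and h = 2.7, and
mitoPO₂ = capiPO₂ − CMRO₂/L with L = 4.4. The 1/h exponent placement is the
standard Gjedde form. OEF is clamped to [0, 1] (out-of-range voxels
flagged), capiPO₂ is undefined at OEF = 0 (flagged), and negative mitoPO₂ is
floored at 0 and flagged — a floor that is reached in strongly hypoxic
(wildtype-like) tissue, where it is read as "severe hypoxia" rather than as
a numerical failure.

### DSC perfusion

The dynamic signal converts to ΔR₂(t) = −(1/TE)·ln(S(t)/S̄_baseline). The
first bolus passage of each voxel is fitted with a gamma-variate
K·(t−t₀)^α·exp(−(t−t₀)/b) over a window that ends at the post-peak crossing
of 20% of the peak, a common recirculation-exclusion convention. Relative CBV is the tissue/AIF ratio of
fitted first-pass areas; the area is evaluated analytically
(K·Γ(α+1)·b^(α+1)) rather than by trapezoid, which is what makes the
noise-free round trip exact to 1e-6. Relative CBF comes from block-circulant
(zero-padded) SVD deconvolution with truncation at λ = 0.2 of the largest
singular value by default; λ is a free parameter and noise-free tests use a
near-zero λ because a dispersion-free (delta) residue needs the full
singular spectrum. The AIF is selected automatically: candidate voxels are
scored by the rank sum of early fitted arrival, high fitted peak and narrow
width (α·b), and the top 10 fitted curves are averaged; the spin-echo series
gets its own AIF for µCBV. All CBV/CBF values are relative (no absolute
calibration); the simulator and the inverse share one proportionality
convention, which is what parameter-recovery tests verify.

### Vascular architecture

The vascular hysteresis loop is the parametric curve of ΔR₂,GE against
(ΔR₂,SE)^(3/2) over the first pass, built from the fitted (smoothed) curves
because raw noise inflates unsigned area. Its signed area (shoelace formula;
clockwise positive) is the microvessel type indicator MTI. Q_max is the
ratio of the GE peak to the 3/2-power SE peak, computed per voxel from that
voxel's fits. MVD and VSI follow the semi-empirical relations given in the
README with β = 1.6781 and mean vessel radius R̄ = 3 µm. The printed
typography of these relations admits more than one grouping; the adopted
parses are
`MVD=(Qmax/beta)*(CBV/(2^4*pi^2*ADC*R^4))^(1/3)` and
`VSI=(CBV*ADC*beta^3/(2*pi*Qmax^3))^(1/2)`, each implemented in a single
formula function (a one-line change to swap) and recorded as metadata with
every output. The Q_max denominator is likewise adopted as the SE term —
the only reading consistent with the VHL axes.

## 2. The synthetic cohort generator

The generator defines the study conditions; it emulates a two-class glioma
cohort with *IDH*-wildtype prevalence 0.74 and the two site protocols
(site A: separate 60-frame GE-DSC and SE-DSC, 1 s frames, single dose;
site B: one 80-frame hybrid GESE series, 1.5 s frames, double dose,
different echo times). Class-conditional tumor distributions (mean, SD)
default to:

| field | normal | IDHwt | IDHmut |
|---|---|---|---|
| OEF | 0.35 (0.02) | 0.60 (0.05) | 0.38 (0.05) |
| CBV | 0.030 (0.003) | 0.060 (0.006) | 0.040 (0.005) |
| CBF mL/100g/min | 50 (4) | 70 (6) | 55 (5) |
| ADC mm²/s | 0.8e-3 (5e-5) | 1.0e-3 (1e-4) | 1.3e-3 (1.2e-4) |
| µCBV | 0.012 (0.0015) | 0.024 (0.003) | 0.013 (0.002) |
| loop orientation | +1 | +1 (clockwise) | −1 |

Class-conditional biomarker distributions are not available from clinical
cohorts, so these means encode the qualitative genotype physiology (hypoxic,
neovascularized wildtype vs oxygenated mutant) at magnitudes a
neuro-imaging reader would call plausible; they are configurable, and an
`effect_scale` knob interpolates the class means toward their midpoint
(0 = null configuration for specificity checks). Within each compartment the
smooth spatial texture is renormalised so the sample mean and SD match the
configured values exactly.

Forward models: mono-exponential echo decay with the qBOLD offset on R₂\*;
gamma-variate ΔR₂ responses whose area is proportional to (dose × blood
volume) and whose width encodes the mean transit time CBV/CBF; a designated
arterial sphere with unit blood volume, 3 s earlier arrival and fast
transit anchors the AIF and the absolute CBV scale. The SE bolus is shifted
by one frame (the smallest shift producing a nondegenerate loop), signed by
the class's loop orientation; with the VHL axis convention, a lagging SE
curve closes the loop clockwise, matching the arteriole-dominated reading.
Noise is Gaussian on magnitude (Rician optional), specified relative to the
baseline signal; the cohort default is 0.3%.

Not emulated: realistic anatomy, partial-volume and motion artifacts,
susceptibility distortions, contrast-agent leakage beyond a baseline drift,
and T1 effects. Passing tests therefore demonstrate the correctness and
internal consistency of the computational chain under its own forward
model — not clinical-grade robustness on patient data.

## 3. Radiomics

Each map is preprocessed per its kind: anatomical images are z-scored over
the brain mask and discretized with fixed bin width 0.1; quantitative maps
are clipped to per-map ranges and discretized with bin width = range/64
(inside the 60–67-bin target window). Default ranges: OEF [0,1], capiPO₂
and mitoPO₂ [0,100] mmHg, CMRO₂ [0,350], CBV and µCBV [0,0.2], ADC
[0,4×10⁻³] mm²/s, MVD [0,5000] mm⁻², VSI [0,50 µm], MTI symmetric with the
limit set per training cohort at the 99th percentile of |MTI|. Intensities
are resampled trilinearly to 1 mm³, masks nearest-neighbour.

The 107-feature vector (14 shape, 18 first-order, 24 GLCM, 16 GLRLM, 16
GLSZM, 14 GLDM, 5 NGTDM) is implemented in-package in the IBSI style: 3-D
texture matrices over the 13 unique offsets with per-offset features
averaged, zones by 26-connectivity, mesh-based shape features via marching
cubes. The ordered name manifest is pinned in the repository and contract
tested; per-patient vectors concatenate four maps (428) or eight (856) in a
fixed canonical order.

## 4. Learning

The selection pipeline is fixed: ReliefF ranking (k = 10 neighbours,
features min-max scaled, every instance used) → top-25% shortlist →
forward best-first wrapper search scored by 10-fold CV accuracy of the
wrapped learner, stopping when the best expansion improves by <0.01 over
the current subset (the empty subset scores at the majority-class rate).
SMOTE (k = 5) balances the classes afterwards — training data only — by
interpolating synthetic minority points on nearest-neighbour segments,
followed by a seeded shuffle. For wide shortlists the wrapper exposes an
optional per-round candidate cap (best-ranked remaining features first) and
a subset-size bound; the desk-scale experiment configuration uses cap 10–15
and bound 5–8 so a full cohort study runs in minutes on one CPU. Feature
selection applies to the classical models; the deep models consume the full
428/856 vectors.

Classifiers: MLP with one hidden layer of width n_features + n_classes
(SGD, learning rate 0.3, momentum 0.2 — the defaults of the classical
toolkit this mirrors); AdaBoost over entropy-split decision trees (a
C4.5-style stand-in); random forest with 100 trees. The 1D-CNN is
conv–pool–conv–pool–conv–pool–flatten–dense–dense with ReLU convolutions,
dropout 0.2 after the second and third convolution and the first dense
layer, and a single sigmoid output unit; filter counts default to 32/64/64
with kernels 7/5/3; the architecture shape is the tested contract and the
widths are configurable. The LSTM assigns one
layer per biomarker map, each consuming that map's 107 features as a
107-step sequence (4 branches for 428 inputs, 8 for 856), with tanh
activation, hard-sigmoid recurrent activation, forward/recurrent dropout
0.2, sigmoid dense head, hidden width 64 by default. Both deep models are
plain numpy (forward + backprop) and train with Adam (lr 0.001, β₁ 0.9,
β₂ 0.999, ε 1e-8), batch 28, an 80/20 stratified split of the balanced
data reshuffled every epoch, up to 300 epochs with no early stopping; the
best-validation-epoch weights are retained. Inputs are standardized by
training-set statistics stored with the model. All stages take explicit
seeds fanned out from one experiment seed.

## 5. Evaluation

Test cohorts are unbalanced, so sensitivity, specificity, precision and F1
(harmonic mean) are computed one-vs-rest per class and combined by the
support-weighted mean — the reading under which the 16-patient worked
example yields precision 0.917; weighted sensitivity then equals plain
accuracy, which is tested as an identity. AUROC uses the Mann–Whitney
rank-sum formulation with average-rank tie correction, cross-checked
against an independent library implementation. Result matrices mirror the
7-metric × (model, category) heat-map layout with explicit NAs.

## 6. Numerical choices

* **Gamma-variate fitting** is a variable projection: for a trial arrival
  t₀ the log-model is linear in (ln K, α, 1/b) and solved in closed form
  with weights y² (making the log-domain fit approximate the linear-domain
  one); the 1-D profile over t₀ is minimised by golden-section search.
  On noise-free gamma data the fit is exact to solver precision, which the
  1e-6 recovery criteria exploit. The fit window starts after the last
  pre-peak frame below max(5% of peak, 4 baseline SDs) — the noise floor
  prevents pre-bolus noise from dragging the arrival estimate early — and
  curves whose peak is under 4 baseline SDs are flagged invalid rather
  than fitted.
* **Degenerate inputs**: nonpositive signals in log transforms are floored
  and flagged; ADC voxels with S ≤ 0 or S > S₀ clamp to 0 with a flag so
  downstream masks stay usable; division-by-zero sites (CBV = 0, OEF = 0,
  Q_max = 0, zero AIF area) flag rather than propagate infinities.
* **Determinism**: fixed seeds reproduce cohorts, selections, and trained
  weights bit-for-bit (single-threaded); rerunning an experiment writes
  byte-identical CSV artifacts.
* **Desk-scale problem sizes**: phantoms default to 64³ voxels at 1 mm
  (cohort studies use 24³–32³ with proportionally smaller tumors), cohorts
  to 100 training / 40 test patients; these sizes make the full study a
  minutes-scale single-CPU computation while leaving every contract
  testable.

## 7. Known limitations

* Acquisition-specific artifact corrections used on clinical scanners
  (background-field R₂\* correction, stimulated-echo R₂ correction, full
  contrast-leakage correction) are not implemented; the synthetic
  data carries neither artifact, and the first-pass gamma fit is the only
  leakage mitigation. This is a documented fidelity gap with respect to
  patient data.
* CBV/CBF/µCBV are relative; CMRO₂ units are Ca×flow without conversion.
* The wrapper search realises "features selected at least once" as the
  final best-first subset; with an all-noise shortlist, best-of-pool
  selection bias admits a few features at chance-level CV accuracy — an
  inherent property of threshold-based wrapper selection.
* mitoPO₂ saturates at its 0 floor in strongly hypoxic simulated tumors,
  so its radiomic vector degenerates toward a shape-plus-constant
  description there; class contrast survives through the other maps.
* Patient-level clinical accuracies cannot be established from synthetic
  data; the experiments validate the computational pipeline, not clinical
  performance.
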