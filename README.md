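# physiomap

Physio-metabolic MRI analysis for preoperative glioma *IDH*-status
classification, as a tested, reusable Python pipeline driven entirely by a
synthetic phantom/cohort generator — every stage runs with no data download.

## The problem

The isocitrate dehydrogenase (*IDH*) mutation status of a glioma shapes
treatment and prognosis, and the two genotypes differ metabolically:
*IDH*-wildtype tumors are glycolytic, hypoxic and strongly neovascularized,
while *IDH*-mutant tumors prefer an oxygenated microenvironment and show
weaker vascular signatures. Quantitative BOLD (qBOLD) MRI and vascular
architecture mapping (VAM) expose exactly these axes, so radiomic features of
the resulting biomarker maps can feed machine-learning classifiers of *IDH*
status.

## What the package computes

**Oxygen metabolism (qBOLD)** — from multi-echo gradient-echo/spin-echo
relaxometry (R₂\*, R₂) and DSC perfusion (CBV, CBF):

- OEF = (R₂\* − R₂) / (k·CBV), with k = (4/3)π·γ·Δχ·Hct·B₀ ≈ 316.8 s⁻¹ per
  unit blood-volume fraction
- CMRO₂ = Ca·CBF·OEF (Fick's principle)
- capiPO₂ = P₅₀·(2/OEF − 1)^(1/h) (Hill model, P₅₀ = 27 mmHg, h = 2.7)
- mitoPO₂ = capiPO₂ − CMRO₂/L (L = 4.4; floored at 0)

**Vascular architecture (VAM)** — from paired GE/SE first-pass bolus curves
fitted per voxel with a gamma-variate K(t−t₀)^α e^(−(t−t₀)/b):

- the vascular hysteresis loop (VHL): ΔR₂,GE against (ΔR₂,SE)^(3/2)
- MTI: the signed VHL area (clockwise positive = arteriole-dominated)
- Q_max = max[ΔR₂,GE] / max[(ΔR₂,SE)^(3/2)]
- MVD = (Q_max/β)·[CBV/(2⁴π²·ADC·R̄⁴)]^(1/3), VSI = [CBV·ADC·β³/(2π·Q_max³)]^(1/2)
- µCBV from the spin-echo series with its own automatically selected AIF

**Radiomics and learning** — per map, a pinned 107-feature IBSI-style vector
(14 shape, 18 first-order, 75 texture) from the tumor mask after
normalisation, 1 mm³ resampling and 60–67-bin grey-level discretization;
per-category concatenation to 428 features (cMRI, oxygen metabolism, VAM) or
856 (combined); ReliefF ranking → top-25% shortlist → best-first wrapper
selection under 10-fold CV; SMOTE class balancing; and five classifiers
(MLP, AdaBoost, random forest, 1D-CNN, LSTM — the deep models are compact
numpy implementations). Test cohorts are scored with support-weighted
confusion-matrix metrics and rank-sum AUROC.

**Synthetic cohorts** — `physiomap.phantom` generates two-class brain
phantoms (74% *IDH*wt prevalence) with forward-simulated multi-echo,
DSC (60-frame separate GE/SE, or 80-frame hybrid GESE at a second "site"
with different timing and dose), DWI and anatomical composites, so the whole
pipeline is testable end to end and parameter recovery can be verified
against ground truth.

## Worked example

Simulate one noisy *IDH*-wildtype patient, run the mapping chain, and look at
tumor-median biomarkers:

```python
import numpy as np
from physiomap import phantom as ph
from physiomap.experiment import map_patient

spec = ph.PhantomSpec(grid_shape=(32, 32, 32), tumor_radii=(5, 6, 4.5),
                      class_label="IDHwt", seed=42)
bundle = ph.simulate_patient(spec, noise_sd=0.003)
mapped = map_patient(bundle)
m = mapped["tumor_mask"]
for name in ("OEF", "CMRO2", "capiPO2", "mitoPO2", "CBV", "uCBV", "MVD", "VSI", "MTI"):
    print(f"{name:>8s}  tumor median = {np.median(mapped['maps'][name][m]):.4g}")
```

prints

```
     OEF  tumor median = 0.5727
   CMRO2  tumor median = 436.2
 capiPO2  tumor median = 37.87
 mitoPO2  tumor median = 0
     CBV  tumor median = 0.06232
    uCBV  tumor median = 0.02503
     MVD  tumor median = 3609
     VSI  tumor median = 0.001006
     MTI  tumor median = 0.1791
```

The phantom was generated with tumor-median OEF ≈ 0.60 and CBV ≈ 0.06: the
mapped medians recover them within a few percent at this noise level (and to
1e-6 noise-free). The profile is the wildtype signature: high oxygen
extraction with mitochondrial PO₂ driven to the floor (severe hypoxia —
CMRO₂/L exceeds the capillary tension), elevated blood volume, and a positive
MTI, i.e. a clockwise hysteresis loop marking arteriole-dominated
neovascularization. An *IDH*-mutant phantom yields lower OEF, positive
mitoPO₂ and a negative MTI.

A full experiment — simulate cohorts, map, extract features, select, balance,
train, evaluate — is one call (or `physiomap run --config ...` from a shell):

```python
from physiomap.experiment import ExperimentConfig, run_experiment
res = run_experiment(ExperimentConfig(n_train=100, n_test=40, seed=1,
                                      categories=("oxymet",), models=("RF",)))
print(res.matrix.round(3))
```

CLI subcommands: `physiomap simulate`, `physiomap map`, `physiomap features`,
`physiomap run`.

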