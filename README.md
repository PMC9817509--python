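# qmripath

Quantitative-MRI analysis of solid lesions: voxel-wise **diffusion-kurtosis
imaging (DKI)** and **two-compartment (Tofts) DCE-MRI** model fitting,
**first-order histogram radiomics** over a volume of interest (VOI), and a
nonparametric **imaging–pathology association battery** — together with a
digital-phantom module that makes the whole pipeline testable end to end
without any patient data.

The package is aimed at quantitative-imaging researchers who want a
transparent, fully scripted alternative to scanner-console or commercial
map-fitting tools, and who need to validate every stage (fitting accuracy,
feature definitions, statistical calibration) against known ground truth.

## Models

**DKI.** The trace-weighted diffusion signal at weighting `b` (s/mm²) follows

```
S(b) = S0 · exp(−b·D + b²·D²·K/6)
```

with `D` (mm²/s) the kurtosis-corrected diffusion coefficient and `K` the
dimensionless diffusional kurtosis. Each voxel is fitted by bound-constrained
nonlinear least squares on the linear signal scale (`D ∈ [0.3, 3]·10⁻³ mm²/s`,
`K ∈ [0, 3]`) from 10 random starting points; the lowest-residual solution is
kept and non-convergent voxels become NaN and drop out of all statistics.

**DCE.** Tissue contrast-agent concentration follows the standard Tofts model

```
Ct(t) = Ktrans · ∫₀ᵗ Cp(τ) · exp(−kep·(t−τ)) dτ ,   ve = Ktrans / kep
```

driven by the Parker population arterial input function. The convolution uses
the exponential recursion that is exact for piecewise-linear `Cp`; fitting
exploits linearity in `Ktrans` (variable projection) so the constrained
least-squares problem reduces to a one-dimensional search over `kep`.

**Features.** Twelve first-order statistics per parameter and lesion: median,
IQR, P10/P25/P75/P90, skewness, kurtosis (Pearson convention), mean, SD, and
histogram energy `Σpᵢ²` / entropy `−Σpᵢ·log₂pᵢ` on fixed-width bins anchored
at zero (0.2 and 0.5 min⁻¹ for Ktrans and kep, 0.025 for ve, 0.1·10⁻³ mm²/s
for D, 0.1 for K — the same grid for every patient).

**Statistics.** Shapiro–Wilk screening, Kruskal–Wallis across pathology factor
levels, Spearman rank correlation against continuous covariates (TILs %,
tumor–stroma ratio %), chi-squared or Fisher's exact tests for categorical
pairs, and cohort frequency summaries. Exact permutation p-values are used
automatically at tiny sample sizes; cells are flagged at two-sided p < 0.05
with no multiplicity correction by default.

**Phantoms.** Ellipsoidal lesions with smooth intra-lesion texture on all
truth maps, forward-simulated through the 5-b-value DWI protocol (0–2000
s/mm², NEX 4/4/4/8/8, Rician noise of scale `σ/√NEX`) and the 70-frame, 5-s
DCE protocol with 3 pre-contrast baselines. Synthetic cohorts attach
pathology labels; tumor-infiltrating-lymphocyte (TILs) scores are coupled to
each lesion's diffusion truth through a Gaussian copula so that population
Spearman correlations (negative with median D, positive with median K) can
be planted at configurable strength.

## Worked example

```python
import numpy as np
from qmripath import (AcquisitionConfig, LesionSpec, FitSettings, generate_phantom,
                      simulate_dwi, fit_dki_map, extract_values, compute_features)

cfg = AcquisitionConfig(seed=42, noise_sigma=2.0)   # Rician scale at NEX=1
truth = generate_phantom(cfg, LesionSpec(semi_axes=(11.3, 11.3, 15.0)))
dwi = simulate_dwi(truth, cfg)

fit = fit_dki_map(dwi, truth.lesion_mask, cfg.b_values, FitSettings(seed=0))
print(f"fitted {fit['n_valid']} voxels ({fit['n_invalid']} invalid)")

d_values, n_excluded = extract_values(fit["d"], truth.lesion_mask)
feats = compute_features(d_values * 1e3, bin_size=0.1)   # D in 1e-3 mm^2/s
print(f"median D = {feats.median:.2f}  IQR = {feats.iqr:.2f}  "
      f"P10 = {feats.p10:.2f}  P90 = {feats.p90:.2f}")
print(f"skewness = {feats.skewness:.2f}  kurtosis = {feats.kurtosis:.2f}  "
      f"energy = {feats.energy:.3f}  entropy = {feats.entropy:.2f} bits")
```

prints

```
fitted 496 voxels (0 invalid)
median D = 1.38  IQR = 0.48  P10 = 1.02  P90 = 1.97
skewness = 0.38  kurtosis = 2.69  energy = 0.082  entropy = 3.81 bits
```

The ~500-voxel lesion was generated around a mean D of 1.40·10⁻³ mm²/s with
25% smooth heterogeneity; at this noise level the fitted median lands within
a couple of percent of the truth, and the histogram features describe the
within-lesion distribution (energy near 0.08 = many occupied 0.1-wide bins,
entropy ≈ 3.8 bits of spread).

A command-line interface wraps the same functions for NIfTI volumes on disk:
`qmripath simulate`, `qmripath fit-dki`, `qmripath fit-dce`,
`qmripath associate` (see `qmripath --help`).

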