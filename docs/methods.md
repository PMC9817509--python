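# Methods

This note documents the models implemented in `qmripath`, the defaults and
numerical choices behind them, what the synthetic phantoms do and do not
emulate, and the known limitations.

## Diffusion-kurtosis fitting (`qmripath.dki`)

The signal model is `S(b) = S0·exp(−b·D + b²·D²·K/6)` with five diffusion
weightings (0, 500, 1000, 1500, 2000 s/mm²). Inputs are assumed
trace-weighted (directional averaging happens upstream); no tensorial
kurtosis is modelled.

Fitting is bound-constrained nonlinear least squares on the **linear**
signal scale — not a log-linearisation — so the noise model of the measured
magnitude data is respected. Bounds are `D ∈ [0.3, 3]·10⁻³ mm²/s` and
`K ∈ [0, 3]`; they act as constraints, so a solution resting on a bound is
kept. Only voxels whose optimisation fails to converge (or whose input is
degenerate: missing b=0, nonpositive or non-finite intensities) are flagged
invalid, reported as NaN, and excluded from every downstream statistic.

`S0` is fitted as a third, positivity-constrained parameter by default;
fixing it to the measured b=0 intensity is available via
`FitSettings(s0_mode="fixed")`. Fitting S0 is the more robust choice because
the b=0 measurement is itself noisy.

Each voxel is optimised from `n_starts = 10` starting points with (D, K)
drawn uniformly between the bounds from a seeded generator; the
lowest-residual converged solution wins, first-found on exact ties. The
optimiser is a damped Gauss–Newton (Levenberg–Marquardt) iteration with box
projection, vectorised across all voxels and starts of a map. Two details
matter for correctness at the bounds:

- *Active-set handling.* Parameters pinned at a bound whose descent
  direction points outside the box are frozen out of each subproblem.
  Without this, projected steps stall against an active bound (typically
  K = 0) and voxels are falsely reported non-convergent.
- *Stopping rules.* Iteration stops when the free-space (projected)
  gradient vanishes (`< 1e-11·(1+SSE)`), when the accepted step is below
  the relative tolerance (`1e-10`), or when damping exhausts descent
  directions. The cap is 200 iterations.

Internally the problem is rescaled (`D` in 10⁻³ mm²/s, signal normalised by
the b=0 intensity) so all free parameters are of order one. On noiseless
phantoms the fit recovers truth to ~1e-11 relative; single-voxel fits agree
with a dense 500×500 (D, K) grid-search oracle — the fitted SSE dominates
the grid optimum, and parameters agree within the grid's own resolution
(the (D, K) valley is shallow enough that the discrete argmin wobbles by a
few grid steps).

## Tofts DCE quantification (`qmripath.dce`)

The two-compartment model `Ct(t) = Ktrans·∫Cp(τ)·e^(−kep(t−τ))dτ` is driven
by a population AIF; `ve = Ktrans/kep` by construction, so the identity
holds exactly on every valid voxel. No plasma-volume (extended-Tofts) term
and no per-voxel bolus-arrival estimation are included: exactly three
parameters are derived.

- *AIF.* The Parker population form (two Gaussians plus sigmoid-modulated
  exponential), converted from blood to plasma with hematocrit 0.42, with a
  configurable bolus-arrival shift; zero before arrival. Any AIF sampled on
  the acquisition grid can be substituted. In synthetic studies the
  simulator and the fitter share the AIF, so the functional form does not
  bias parameter recovery.
- *Convolution.* Exponential recursion, exact for piecewise-linear `Cp`;
  halving the 5-s sampling changes a boxcar-AIF curve by well under 0.5%.
- *Fitting.* `Ct` is linear in `Ktrans`, so for any `kep` the optimal
  `Ktrans` is closed-form (variable projection). The 1-D problem over
  `kep ∈ [0.01, 20] min⁻¹` is solved by a 64-point geometric grid followed
  by 60 golden-section steps in log kep; `Ktrans` is clipped to
  `[0, 10] min⁻¹`. Defaults cover reported tumor ranges with margin and are
  configurable. Noiseless recovery is ~1e-13 relative — far inside the 1e-4
  documented accuracy target.
- *ve > 1* invalidates a voxel rather than being silently capped;
  `PKFitSettings(clip_ve=True)` restores the capping behaviour of some
  commercial tools. All-zero curves are valid no-enhancement voxels with
  `Ktrans = 0`.
- *Signal conversion.* Two documented modes: linear
  (`Ct = (S/S_pre − 1)/calibration`) and SPGR inversion of the spoiled
  gradient-echo equation (defaults TR 4.7 ms, flip 30°, T10 1 s,
  r1 3.7 s⁻¹mM⁻¹). The baseline is the mean of the first three pre-contrast
  frames. Real acquisitions rarely publish their conversion internals, so
  both modes are explicit configuration rather than inferred behaviour.

## VOI handling (`qmripath.voi`)

Masks carry NIfTI-style affines; propagation from the DCE grid to the DKI
grid applies a rigid world-space transform (identity = header geometry)
with nearest-neighbour lookup, which preserves binary labels exactly and is
idempotent under the identity. Value extraction removes NaN (invalid-fit)
voxels and reports the excluded count; an empty propagated mask raises with
a pointer to manual contour adjustment, since geometric distortion
correction is out of scope.

## Histogram features (`qmripath.features`)

Percentiles use linear interpolation between closest ranks; mean/SD
(sample SD, ddof 1) and skewness/kurtosis (population moment estimators)
are computed from the **raw** voxel values — binning is used only for
energy and entropy, which is the stricter reading of fixed-bin-width
first-order radiomics. Kurtosis is reported in the Pearson convention
(normal = 3), matching the scale of published tumor tables; an excess
switch exists. Histograms share one grid across patients: fixed widths
(0.2 / 0.5 min⁻¹, 0.025, 0.1·10⁻³ mm²/s, 0.1 for Ktrans/kep/ve/D/K),
anchored at zero, extended to each sample's maximum; empty bins contribute
nothing to entropy (base 2). Zero-variance samples keep energy 1 and
entropy 0 but report NaN skewness/kurtosis (undefined). Second-order
(GLCM-type) texture features are out of scope.

## Association battery (`qmripath.stats`)

Kruskal–Wallis (tie-corrected, chi-squared reference with g−1 df) is used
across the levels of every categorical factor — including two-level
factors, for consistency of the report. Spearman correlation handles the
continuous covariates. Exact permutation p-values replace the asymptotics
automatically for tiny samples (total n ≤ 9 for Kruskal–Wallis, n ≤ 8 for
Spearman, where full enumeration is cheap). Categorical-vs-categorical
tests use chi-squared without continuity correction when all expected
counts are ≥ 5, Fisher's exact for 2×2 tables otherwise, and a seeded
Monte-Carlo chi-squared p (random tables with fixed margins) for larger
sparse tables. Missing cells are handled by pairwise deletion, matching
per-test sample sizes of observational reports; factors with fewer than
two populated levels are skipped and logged. No multiplicity correction is
applied by default — the report's cells are calibrated at the nominal 0.05
level, which the null-cohort simulation confirms (~5% flagged cells); a
Benjamini–Hochberg option exists and logs a caveat when used.

## Synthetic phantoms and cohorts (`qmripath.phantom`)

A phantom is an ellipsoidal lesion on a regular grid (default 16×16×10 at
2×2×4 mm; the validation lesion of ~500 voxels uses 11.3/11.3/15 mm
semi-axes). Truth maps are smooth Gaussian-filtered noise textures scaled
to a fractional heterogeneity (default 25%) around configurable means — by
default D 1.4·10⁻³ mm²/s, K 0.75, kep 2.08 min⁻¹, ve 0.70 (hence
Ktrans ≈ 1.46 min⁻¹), values typical of reported tumor medians — and are
clipped to sit strictly inside the fitting bounds. The texture field is
centred (median) and scaled **within the lesion mask**, so the lesion-level
median of every map equals its configured mean exactly; this matters for
cohort studies because planted lesion-level couplings would otherwise be
diluted by texture sampling noise.

Forward simulation follows the protocol: five b-values with NEX 4/4/4/8/8,
Rician noise applied as `σ/√NEX` on the complex components before taking
magnitude (averaging reduces the noise scale; individual averages are not
simulated), background voxels noise-only; 70 DCE frames at 5 s with three
pre-contrast baselines, Tofts-driven enhancement converted to signal
(default linear mode, calibration 0.5 per mM), optional additive Gaussian
temporal noise. `noise_sigma` is the Rician scale at NEX = 1; the
validation studies use `noise_sigma = S0/50` ("SNR 50"), a deliberately
documented choice since per-lesion SNR is rarely reported.

Cohorts draw per-patient latent normals `(z_D, z_K)` that set each lesion's
mean D and K through strictly monotone maps (uniform ranges
0.9–2.0·10⁻³ mm²/s and 0.45–1.10). The TILs latent is a linear Gaussian
copula combination of `(z_D, z_K)` with weights `2·sin(π·ρ/6)` chosen so
the **population Spearman** correlations equal the planted values (defaults
−0.393 with D, +0.445 with K); TILs percentages are a lognormal transform
(median 15%, IQR 25%) clipped to [0, 100], TSR a clipped normal (65%/35%).
Categorical pathology factors are drawn independently from fixed marginal
frequencies typical of an oral squamous-cell-carcinoma series. Realized
sample correlations at n = 35 sit slightly below the plant (finite-sample
Spearman bias plus occasional clipping ties), comfortably within the ±0.15
validation band.

What the phantoms do **not** emulate: anatomy (no organs, vessels or bone —
the analysis is mask-restricted), scanner artifacts (distortion, motion,
bias fields), directional diffusion, T1/T2 relaxation effects on the DWI
arm, and any real biological link between pathology and microstructure
beyond the planted monotone couplings. Passing tests therefore demonstrate
correctness of the estimators and calibration of the statistics under the
stated models — not clinical validity on patient data.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use: a ~500-voxel lesion for
forward–inverse checks (noiseless and SNR 50); 20 random voxels against the
500×500 grid oracle; 200-seed batteries for the null type-I rate (35
truth-level lesions per seed, 60 feature columns) and for planted-effect
recovery (35 fully simulated lesions per seed, DKI arm fitted voxel-wise).
These sizes give Monte-Carlo standard errors of ~0.01 on recovered
correlations while keeping a full run in the minutes range on one CPU.

## Known limitations

- The DCE fit assumes the AIF is known; AIF misspecification on real data
  biases Ktrans/ve in ways the synthetic studies cannot reveal.
- The 1-D VARPRO search assumes a single SSE basin over kep; with heavily
  non-Tofts curves the coarse grid mitigates but does not guarantee global
  optimality.
- Exact permutation tests switch on at fixed small-n thresholds; p-values
  straddling a threshold change discretely with sample size.
- The cohort generator plants associations only through TILs; all other
  pathology factors are independent of the imaging truth by design, which
  is what makes the null calibration measurable.
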