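# Methods

## Scope and model

`qmriskin` analyzes multi-contrast quantitative MR microimages of skin
biopsies. Every acquisition is a single-slice spin-echo magnitude image
series stepped in one variable, and every contrast is modeled as a
monoexponential with a constant offset term:

| contrast  | stepped variable | model | mapped parameter |
|-----------|------------------|-------|------------------|
| CPMG multi-echo | TE (ms), 64 echoes at 5.3 ms spacing | S = A·e^(−TE/T2) + C | T2 (ms) |
| saturation recovery | TR (s), 12 values in [0.1, 15] | S = A·(1 − e^(−TR/T1)) + C | T1 (s) |
| off-resonance saturation | t_sat (s), 8 values in [0.1, 4.6] | M = M_ss + (M0 − M_ss)·e^(−k_m·t) | k_m (s⁻¹), MTR = 1 − M_ss/M0 |
| Stejskal–Tanner diffusion | G (mT/m), 9 values in [0, 900] | S = A·e^(−b·ADC) + C | ADC (mm²/s) |

with b = (γGδ)²(Δ − δ/3) + b0, δ = 5 ms, Δ = 10.25 ms, γ = 2.675×10⁸
rad s⁻¹ T⁻¹. The TR and saturation-time schedules are logarithmically
spaced (the spacing of the original acquisitions is not published;
log-spacing is the standard choice for exponential-recovery sampling).
b0 defaults to 0: the published b-value range exceeds the pure
Stejskal–Tanner value at the maximum gradient, implying imaging-gradient
contributions that are not specified, so the printed range is treated as
nominal metadata only. Likewise the reported presaturation amplitude
("12 mT", physically implausible for B1, presumably µT) is carried as
metadata and never used in computation.

In the MT fit the steady-state plateau *is* the offset: M_ss = C and
M0 = A + C, so MTR = 1 − C/(A + C). M0 is a free fit parameter by default;
an option pins it per pixel to the shortest-saturation frame.

## Fitting

Maps are produced by bounded trust-region nonlinear least squares
(`scipy.optimize.least_squares`, analytic Jacobians) applied pixel-wise,
with ordinary (Gaussian) least squares on the magnitude data — matching
the original analysis — rather than Rician maximum likelihood.
Initialization is deterministic: the offset starts at the minimum observed
signal, the rate comes from a log-linear regression of the
offset-subtracted signal (for saturation recovery, from the half-recovery
point). Bounds: T2 ∈ (0, 10⁴] ms, T1 ∈ (0, 20] s, k_m ∈ (0, 10²] s⁻¹,
ADC ∈ (0, 10⁻¹] mm²/s, A ≥ 0, C ≥ 0. Convergence: relative tolerance
10⁻⁸, at most 500 function evaluations; a pixel that fails to converge is
flagged and carries NaN instead of propagating garbage, and flagged pixels
are excluded (not imputed) from ROI means, with a warning when more than
10% of an ROI is excluded. MTR values are clipped to [0, 1] with clipping
logged.

**Known estimator bias.** Least squares with an additive offset on Rician
magnitude data is intrinsically biased wherever the decay runs into the
noise floor. Fitting the *exact* Rician expectation curve (no sampling
noise at all) at per-frame SNR 50 with the 64-echo CPMG schedule and
dermal T2 ≈ 30 ms underestimates T2 by ≈ 7%, and overestimates ADC by
≈ 5%; T1, k_m and MTR are essentially unbiased because their curves never
approach the floor. Separately, the per-pixel k_m precision at SNR 50 is
only ≈ 8% because the MT series has just 8 points for a 3-parameter fit —
the dermal-ROI mean of k_m is still accurate to ≈ 0.1%. These are
properties of the specified estimator and acquisition, not of the
implementation; the test suite asserts tight recovery only where the
estimator can deliver it (noiseless inversion ≤ 0.1% everywhere) and
reports the SNR-50 figures as measured.

## Synthetic data

The phantom is a single-slice 2-D grid (default 128×256 pixels at
19.5×46.9 µm) partitioned into bath / epidermis / dermis layers stacked
perpendicular to the epidermal surface, plus an optional elliptical
follicle blob inside the dermis. Each compartment carries one parameter
set; truth maps are piecewise constant. Magnitude noise is Rician:
√((S+g₁)² + g₂²) with independent zero-mean Gaussians of SD σ — which is
exactly why the fit model carries the offset term C.

The default cohort is 9 control + 9 OI subjects with ages, sexes and
severity strata (mild n=2, moderate n=5, severe n=2) taken from the
published patient-characteristics table. Parameters are drawn per group
from normal distributions truncated at zero. Control dermis means are
realistic ex-vivo values chosen once — MTR 0.55, k_m 2.0 s⁻¹, T2 30 ms,
T1 1.2 s, ADC 1.0×10⁻³ mm²/s — because the human study publishes no
numeric group means; they are *not* calibrated to the study's plots. The
T2 dispersions use the published per-group SDs (control 3.46 ms, OI
1.86 ms). The OI effect defaults follow the murine osteogenesis-imperfecta
result the study builds on: k_m ×0.50 and T2 ×1.30, other parameters
unchanged. All of this is overridable in the YAML config.

What the generator does **not** emulate: age–parameter correlations (each
subject's parameters are independent of its age, so age-correlation
statistics on synthetic cohorts are null), partial-volume and B1/B0
effects, spatial heterogeneity within a compartment, and the true overlap
structure of the human cohort. Consequently, passing classification tests
on the default synthetic cohort demonstrates the *machinery* (fold
hygiene, metrics, determinism) — with a 30%/50% two-parameter effect the
groups are far more separable than the real biopsies were — and recovery
tests demonstrate the fitting chain, but neither certifies performance on
real data.

## Classification

*Univariate.* The value x is assigned to the group g minimizing
|x − μ_g| / σ_g (group-SD-normalized distance); ties go to control
(deterministic, favors non-disease). Leave-one-out: group means and SDs
are recomputed on each 17-sample training fold. Test metrics pool the 18
held-out assignments; training metrics are per-fold resubstitution rates
averaged over folds (the only reading of the published training values,
which are not multiples of 1/18 or 1/9, that is arithmetically
consistent).

*Multivariate.* RBF-kernel soft-margin SVM on every parameter subset of
size ≥ 2 (26 combinations of 5 parameters). Feature columns are divided by
their training-fold SD — pooled across groups by default; a
per-class-SD-average mode is available — computed inside each outer fold
so the held-out sample never influences its own scaling. Kernel breadth γ
and penalty Cost are selected per outer fold by inner leave-one-out on the
17 training samples over exponentially spaced grids, γ ∈ [2⁻⁶, 2³] and
Cost ∈ [2^−1.5, 2⁴], 10 points per axis; inner-accuracy ties resolve to
the smallest penalty, then the smallest breadth (the smoother model). The
solver is libsvm via scikit-learn's low-level binding (predictions
verified identical to `sklearn.svm.SVC` in the tests; the low-level path
removes per-fit estimator overhead, which matters at ~30 k fits per
combination).

Metrics (OI positive): sensitivity = correct OI / all OI, specificity =
correct control / all control, accuracy = correct / all; for balanced
groups accuracy = (sensitivity + specificity)/2, an identity the reports
assert. All metrics are exact rational counts; the report layer rounds
half-up to two decimals.

**Small-sample null behavior.** On permuted labels at n = 9+9, LOO is
pessimistic for frequency-sensitive classifiers: each training fold holds
9 of the opposite class against 8 of the held-out sample's class, so a
majority-rule classifier scores exactly 0 and the grid-searched SVM
averages ≈ 0.38–0.41 (measured over 100 permutations; stable across grid
resolutions). The Mahalanobis rule, being distance- not
frequency-based, averages ≈ 0.49. This below-chance SVM null is a known
artifact of leave-one-out at tiny n, worth keeping in mind when reading
small LOO accuracy differences.

## Statistics

Two-tailed unpaired Student t-tests (classical equal-variance, as
specified in the original analysis; Welch available as an option), Pearson
age correlations within groups, and one-way fixed-effects ANOVA across the
OI severity strata, all via `scipy.stats`. No multiple-testing correction
is applied, matching the original reporting of raw p-values. Degenerate
inputs (zero variance) are rejected or flagged rather than returning
misleading numbers.

## Numerical and design choices

- Single global seed fanned out through `numpy.random.SeedSequence` child
  seeds per stage/subject; every pipeline output is bit-reproducible.
- Truncated-normal cohort draws redraw at zero (logged); parameters are
  physical quantities and must stay positive.
- Feature tables are validated on read (required columns, numeric MR
  values, known group/severity labels, unique subject ids); a config-driven
  column map adapts externally produced spreadsheets without code changes.
- ROI masks are inputs, not computed: the original dermis ROIs were drawn
  manually on the T2 map and copied to the other maps; the package verifies
  grid alignment on propagation and refuses shape mismatches.
- Problem sizes used by the shipped acceptance script: 32×64 phantom grids
  for the 18-subject study, 32×32 uniform crops for recovery and oracle
  checks, a 3×3 hyperparameter grid for the 100-permutation SVM null
  (means agree with the 10×10 grid to within their spread), full 10×10
  grid everywhere else.

## Limitations

- 2-D single-slice phantoms only; no coil/B1 inhomogeneity, no
  partial-volume modeling, no registration between contrasts (frames are
  assumed co-registered, appropriate for fixed ex-vivo biopsies).
- The magnitude-data least-squares biases quantified above are inherited
  by design; a Rician-likelihood fitter would remove them at the cost of
  fidelity to the original analysis.
- No additional classifiers, no feature selection beyond exhaustive subset
  enumeration, no probability calibration, no multi-exponential or
  two-pool quantitative MT models.
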