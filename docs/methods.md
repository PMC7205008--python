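# Methods

## The problem and the model

BOLD task activity is neurovascular: at a voxel, the evoked amplitude
reflects neural activity *and* the local baseline physiology, most notably
resting perfusion (CBF), which varies between subjects and declines with
age. `boldsense` removes the inter-subject baseline-CBF component from
z-scored task activity by group-level voxel-wise regression
residualization. For segment *i*, voxel *j* and subjects *s = 1…n*:

    Z_ij(s) = A_ij + B_ij · CBF_j(s) + ε_ij(s)

fit by ordinary least squares over subjects; the sensitized activity is the
residual Z_ij(s) − (Â_ij + B̂_ij·CBF_j(s)). Because the model is linear in
(A, B), the closed-form OLS solution coincides with any converged iterative
nonlinear least-squares fit while being deterministic and free of
tolerance parameters, which is why it is used here.

Two comparators are implemented. *Division* normalization divides each
subject's activity voxel-wise by their CBF; it mishandles the intercept A
(activity not proportional to CBF), so a nonzero A turns inter-subject CBF
spread into extra variance instead of removing it. *Age-corrected-CBF*
sensitization first removes the linear age trend from CBF and residualizes
on what remains; since most inter-subject CBF variance is age-linked, this
variant leaves the age-related vascular variance inside the activity and
serves as the control showing that the age component of CBF must be
retained for sensitization to work.

### Statistical conventions

- A `RegressionSummary` derives t and p from r and n via
  t = r·√(n−2)/√(1−r²), guaranteeing internal consistency.
- Fisher-z model comparison transforms per-fold correlations as atanh(r)
  with the sign of r retained (atanh of R² is not variance-stabilizing);
  the transform used is recorded in the output.
- Leave-one-out validation refits the coupling on n−1 subjects per fold;
  cve_k = (obs − pred)², PE_k = 100·(obs − pred)/obs, with PE undefined
  (excluded with a warning) when |obs| < 1e−8.
- Achieved power of the two-sided slope test at df = n−2: the slope and
  the two marginal SDs imply ρ = slope·sd_x/sd_y; the default method
  integrates the exact bivariate-normal sampling density of the sample
  correlation over |r| > r_crit. The classical noncentral-t approximation
  (δ = ρ√n/√(1−ρ²)) is available as `method="approx"`; it ignores
  predictor sampling variability and is liberal by ≈ 0.04 at ρ = 0.5,
  n = 24, which is why it is not the default.
- Group maps: one-sample t within group, pooled-variance two-sample t
  between groups (Welch optional). Within-group "sensitized" maps test
  Â + residual (equivalently Z − B̂·CBF): in-sample OLS residuals are
  identically mean-zero across the fitting subjects, so testing the pure
  residual would be degenerate; restoring the intercept makes the test
  target the activation level with the CBF-driven component removed.
  Correlation-type analyses are invariant to this constant shift and use
  the literal residual.
- Cluster inference: voxel-wise two-sided p < 0.01, then a Monte-Carlo
  extent threshold — smooth Gaussian null fields (configurable FWHM) are
  simulated on the analysis mask, standardized, thresholded at the same
  voxel p, and the smallest extent k with P(max null cluster ≥ k) ≤ 5 %
  is used. Connectivity is 6-neighbour (faces). FP / FN / R labels:
  a cluster significant only in the standard analysis is a false positive,
  only after sensitization a recovered false negative, and any shared
  voxel between the two analyses marks a retained cluster.

## HRF estimation

The paradigm is sparse-sampled (TR = 4 s, one volume per trial) with
8-trial blocks. Each run is scaled to percent change against its initial
12 s active-baseline window; volumes with framewise displacement > 0.3 mm
are censored (FD = max absolute backward difference of the six rigid-body
parameters, rotations converted to arc length on a 50 mm sphere — the
displacement metric itself is a package choice). The block response is
estimated by FIR deconvolution with 13 tent functions at −4…44 s (4 s
spacing) plus per-run Legendre drift polynomials of order
1 + ⌊run duration/150 s⌋. Tent regressors never cross run boundaries.

Segment areas are signed trapezoidal integrals of the piecewise-linear
response over Seg1 (0,16], Seg2 (16,32], Seg3 (32,44] s — half-open so the
three areas are exactly additive and boundary knots are not double-counted
— plus the whole-response segment (0,44]. Deactivation contributes
negatively. Areas are z-transformed over the in-mask voxel population
within subject and segment (sample SD); all subsequent analyses run on the
junction mask, the intersection of BOLD and CBF coverage.

## CBF quantification

Control/label pairs are censored pairwise (either member's FD > 0.5 mm
drops the pair; > 25 % dropped pairs fails QC with a hard error), the mean
control-minus-label difference ΔM is formed, and CBF in mL/100 g/min is
obtained from the single-compartment model

    CBF = 6000·λ·ΔM·exp(PLD/T1b) / (2·α·T1b·M0·(1 − exp(−τ/T1b)))

with consensus 3 T defaults τ = 1.5 s, PLD = 1.8 s, T1b = 1.65 s,
α = 0.85, λ = 0.9 mL/g, all exposed in configuration and echoed into the
QC record. Non-positive M0 voxels are excluded; values < 0 or
> 250 mL/100 g/min are flagged, not altered. Maps can be resampled
trilinearly to the analysis grid; optional isotropic Gaussian smoothing is
specified as FWHM in mm.

## The synthetic cohort generator

The generator produces a complete two-group study (default 11 young + 13
old) with known ground truth, so every downstream stage is testable
without any external data.

- **Impulse response.** Difference of two unit-peak gamma lobes: positive
  peak at 6 s, undershoot trough at 22 s (relative depth 0.35), causal and
  within 1e−3 of zero well before 48 s. The 8-trial block response is its
  linear superposition sampled at the tent knots and normalized to unit
  peak — *exactly representable in the tent basis*, so a noiseless cohort
  is recovered to machine precision (the round-trip oracle).
- **Perfusion.** A smooth spatial template (mean 1, CV 0.15) scaled by a
  subject level that declines linearly with age between the group means
  (default 60 → 45 mL/100 g/min, ≈ 0.35 per year) with 8 mL/100 g/min of
  additional inter-subject spread. pCASL series are generated by
  inverting the quantification model, so quantification recovers the
  truth exactly at zero noise and unbiasedly otherwise.
- **Activity.** Per-voxel peak amplitude (% BOLD)
  A* + B*·w·CBF + amp·blob·ν: coupling intercept A* = 0.5 %, slope
  B* = −0.03 % per mL/100 g/min (inverse activity–CBF relation), a fixed
  linear coupling-weight gradient w ∈ [0.3, 1.7] across the first axis
  emulating the vessel-size dependence of BOLD–CBF coupling (a spatially
  uniform subject effect would be removed entirely by the per-subject
  z-transform; spatial heterogeneity of the coupling is what makes the
  vascular component both present in z-scored data and removable by
  Eq.-style regression), and a Gaussian activation blob (peak 1 % per unit
  of the subject neural amplitude ν ~ N(1, 0.2)).
- **Behaviour.** Trial-level Bernoulli draws: per-trial success
  probability 0.85 + 0.3·(ν − 1) in the first block half, dropping by
  0.12 in the second half — behaviour depends on the neural amplitude
  only, never on CBF, which is what makes the mode comparison a
  ground-truth test.
- **Nuisance.** Per-run quadratic drift, white BOLD volume noise, ASL
  volume noise at the per-pair difference scale, random-walk motion with
  occasional large steps sized to exercise the censoring paths.

Effect-size defaults were calibrated once, at design time, so that the
cluster-level variance partition of the synthetic cohorts reproduces the
regime of the study the package models (standard activity–behaviour
R² ≈ 0.3, sensitized ≈ 0.4, division lowest; group dependence of activity
reduced by age-retained-CBF sensitization and unchanged by age-corrected
sensitization). The BOLD volume noise default (0.2 %) reflects that the
phantom's task cluster (~14 voxels on the default 10×10×8 grid) is about
thirty-fold smaller than a ≥ 1000 mm³ cortical cluster, so volume noise is
scaled to keep cluster-mean SNR at the study's scale.

**What the generator does not emulate** — and what passing tests therefore
do not establish about real data: physiological noise spectra and
spin-history artifacts, EPI distortion and registration error, arterial
transit-time heterogeneity (a single-compartment inversion generates the
ASL signal), partial-volume effects, spatially varying HRF shape, and any
nonlinearity in the activity–CBF coupling. Tests demonstrate that the
implementation is correct and that the method behaves as designed when its
model assumptions hold.

## Problem sizes and numerical choices

Default analyses run on a 10×10×8 grid (ellipsoidal mask, ≈ 300 voxels),
three runs of ≈ 77 volumes, 47 ASL pairs; Monte-Carlo suites use 50 cohort
seeds, 300 null-field simulations for the cluster-extent threshold and
10,000 replicates for power checks — sizes chosen so the full suite runs
in well under a minute of compute per property while keeping Monte-Carlo
error small against the tested margins. Degenerate inputs fail loudly:
constant maps cannot be z-transformed, zero-variance voxels are excluded
from fits with a warning, empty censoring survivals and > 25 % ASL pair
loss raise QC errors, rank-deficient designs name their dependent columns.
Division by CBF is floored at 1 mL/100 g/min (masked, with a warning).

## Known limitations

- The pipeline consumes spatially preprocessed data (slice-timing, motion,
  distortion correction and template normalization are upstream tools'
  jobs); the run orchestration is simulation-driven, with per-stage CLI
  commands for real volumes.
- The sensitization removes *baseline*-CBF variance only; it cannot
  dissociate task-induced CBF from task-induced neural activity.
- With n = 24 subjects the behaviour-level comparisons have limited
  per-cohort power; the method's advantage is established across seeds,
  not guaranteed within any single cohort.
- Cluster-extent calibration assumes stationary Gaussian smoothness of the
  null field at a user-supplied FWHM; it does not estimate the noise
  autocorrelation from the data.
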