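# Methods

## Forward model and system matrix

The scanner model is a 2-D parallel beam: for each view angle θ a
linear detector of `n_det` bins (spacing = pixel size) measures line
integrals of the image.  The system weight `q_ij` is the exact length
of the chord that ray `i` cuts from pixel `j`'s square — the same
quantity Siddon-style ray tracing produces.  For a parallel beam this
length depends only on the perpendicular offset between ray and pixel
center (a trapezoid profile with plateau `s/max(|cosθ|,|sinθ|)` and
half-width `s(|cosθ|+|sinθ|)/2`), which makes the construction fully
vectorizable per view.  Axis-aligned views use a half-open boundary
convention (a ray running exactly along a pixel edge is assigned to the
pixel on its left) so that even-sized grids keep full coverage and
per-view mass.

Weights are unnormalized intersection lengths.  The EM update divides
by the per-pixel sensitivity `Σ_i q_ij`, so any global scale cancels;
no row normalization is applied.

Two accuracy notes, both verified in the test suite:

- The matrix equals an independent dense rectangle-clipping oracle to
  machine precision, i.e. the chords themselves are exact for the
  discrete image.
- With one line per detector bin, per-view total mass
  (`Σ_i y_i ≈ s·Σ_j g_j`) carries a residual detector-sampling
  (aliasing) spread across views of a few tenths of a percent at
  256×256 (≈0.8% at 64×64).  Removing it would require a strip/footprint
  or sub-ray quadrature model, which would widen each ray's support
  beyond the `2n` pixels a single line can cross; the single-line model
  is kept deliberately.  The effect is irrelevant to the reconstruction
  experiments, which use the same matrix for simulation and
  reconstruction.

## Phantom

The standard ten-ellipse Shepp-Logan head phantom, rasterized by
evaluating the ellipse table at pixel centers and clipping to ≥ 0.  The
contrast-adjusted (Toft) intensity table is used — skull ring 1.0,
brain tissue 0.2, ventricles 0.0, small features 0.3 — so intensities
span exactly [0, 1]; the historical low-contrast table (skull 2.0,
interior ≈ 1.02) makes error metrics nearly insensitive to the interior
structure and is not offered.  Note the phantom is *not* exactly
mirror-symmetric: the two ventricle ellipses and the three small lower
features have different sizes and positions by construction.

Default geometry: 180 views over [0°, 180°) at 1° (parallel-beam data
are redundant over 360°), detector count = smallest odd integer ≥ n√2
(363 at n = 256) so every pixel is covered at every view.

## MLEM and OSEM

Both run the multiplicative Poisson-EM update; MLEM is implemented as
OSEM with the single all-view subset, so the degeneracy `OSEM(L=1) ≡
MLEM` holds bitwise.  Initialization is a uniform all-ones image: any
positive constant works for EM, and ones make the first correction
factor directly interpretable as a backprojected residual.

Numerical safeguards: the residual `y/ŷ` and the log-likelihood use a
division guard ε = 1e−12 (`r = y / max(ŷ, ε)`, so an empty ray with
`y = ŷ = 0` contributes residual 0); pixels with zero subset
sensitivity receive a correction factor of exactly 1 (no update).
Images stay non-negative throughout; pixels seen only by empty rays are
driven to exactly 0 (an absorbing state of the multiplicative update —
the standard EM behaviour, which is why "strict positivity" holds only
on pixels some non-empty ray intersects).

### Subset construction and ordering

With `n` views and `p` views per subset, subset `m` (of `L = n/p`)
holds the stride-`L` interleave `{m, m+L, m+2L, …}`: all subsets are
balanced and each one samples the semicircle uniformly (its angles are
`180/p` degrees apart).  The default experiment uses 6 views per
subset, hence 30 subsets at 1° spacing.

Processing order ("optimized" strategy): greedy farthest-first.
Starting from subset 1, each successive subset maximizes the *minimum*
circular angular distance between its angle set and the angle sets of
all previously processed subsets, ties broken by lowest subset index.
For 4 subsets of lead angles {0°, 22.5°, 45°, 67.5°} this yields the
order S1, S3, S2, S4.  The distance is evaluated between full angle
sets (equivalently lead angles modulo the within-subset spacing), which
is what makes consecutive updates maximally complementary.  The
"sequential" strategy (index order, nearly parallel consecutive
subsets) is retained as the baseline; on the noiseless 256×256
experiment one optimized iteration reaches relative RMSE 0.205 versus
0.230 for sequential.

### Error metric and iteration counts

The reconstruction error is the relative RMSE against the ground-truth
phantom, `‖g − g_true‖₂/‖g_true‖₂` — the standard phantom-study
choice; reported error levels depend on this choice and are documented
wherever they appear.  The headline experiment runs 20 full OSEM
iterations on noiseless data and reports the minimum error reached
(the curve is monotone there, so this is the 20th-iteration value);
the MLEM comparison runs up to 40 iterations and reports the first
iteration whose error comes within 10% of OSEM's one-iteration error.
The default experiment injects no noise; Poisson noise can be added to
any sinogram by the caller (the EM ascent test does exactly that).

## EAT volumetry

Fat is everything inside the inclusive HU window, default −150 to −50
HU (the universal CT fat window), restricted to an inclusive axial
slice range.  The slice range mirrors the manual anatomical bounds
(origin of the left pulmonary artery to the left-ventricular apex) a
reader marks on a workstation; automating those landmarks would need an
anatomy model and is out of scope, as is pericardium delineation.
Volume = voxel count × voxel volume, in mL.  A two-reader averaging
helper reproduces the dual-observer protocol.

The synthetic torso generator builds a soft-tissue ellipsoid (+40 HU)
with a concentric ellipsoidal fat shell (−100 HU, thickness set so the
shell holds the requested fraction of body voxels) in air (−1000 HU),
plus optional Gaussian HU noise, and returns the exact shell voxel
count.  With noise sd 10 HU the window edges sit 5σ from both tissue
classes, so threshold recovery stays within 2% of truth.  The generator
emulates only what thresholding sees — HU contrast and noise — not
partial-volume effects, contrast enhancement, motion, or non-pericardial
fat depots; passing tests therefore validate the measurement
arithmetic, not reader-level clinical accuracy.

## Gensini score and vessel count

Severity points per lesion: ≤25% → 1, 26–50% → 2, 51–75% → 4,
76–90% → 8, 91–99% → 16, 100% → 32; 0% (no lesion) scores 0.  Bracket
edges are closed on the right.  Segment coefficients: LM 5; proximal
LAD/LCX 2.5; mid LAD 1.5; distal LAD/LCX, OM, RCA (prox/mid/dist), PDA
1; second diagonal 0.5.  Total = Σ points × coefficient.

A major vessel (LAD, LCX, RCA) counts as stenosed when any of its
segments carries a lesion at or above the threshold (default 50%, the
angiographic disease definition; configurable); left-main disease marks
both LAD and LCX, i.e. counts as two-vessel disease.  Categories:
none / single / double / multi.

## Synthetic cohort and statistics

Controls draw EAT from Normal(124.50, 26.72²) mL and diseased patients
from Normal(159.41, 38.51²) mL, both truncated at zero (the truncation
is 4.7σ out and shifts the means by < 0.01 mL).  For diseased patients
a 3-dimensional Gaussian copula links EAT, Gensini and vessel count;
the latent Pearson correlation for a target Spearman `r_s` is
`2·sin(π·r_s/6)` (defaults r = 0.327 for Gensini, 0.416 for vessel
count), and the Gensini–vessel-count latent correlation is set to the
product of the two (conditional independence given EAT), which keeps
the correlation matrix positive definite for every admissible pair.
Gensini values are Gamma(2, 16) quantile-transformed (mean 32, right
skew typical of severity scores); vessel-count categories cut the
latent at the 10:19:19 single:double:multi mix.  Discretizing to three
categories attenuates the observable EAT–NSCV Spearman correlation to
≈ 0.38; the stated 0.416 applies to the latent association.  Controls
carry Gensini 0 and category "none".

Covariates are drawn per group: age Normal(59.85, 7.67²) vs
Normal(61.67, 6.28²); male sex 28/42 vs 42/68; and fixed plausible
settings for the quantities whose group distributions are not published
— BMI Normal(24.6, 3.1²)/(25.1, 3.2²), uric acid Normal(338, 72²)/(352,
78²) µmol/L, smoking 24%/46%, hypertension 31%/54%, diabetes 14%/32% —
chosen once so that age, smoking, hypertension, diabetes and EAT are
higher in the diseased group in expectation.  The generator encodes
marginals and the EAT copula only; it does not model covariate–covariate
dependence, measurement error, or selection effects, so recovery tests
validate the estimators, not clinical effect sizes.

Statistics: logistic regression by maximum likelihood (Newton/IRLS via
statsmodels) with observed-information standard errors, Wald `(B/SE)²`
chi-square p-values, OR = exp(B) and 95% CI exp(B ± 1.96·SE) — perfect
separation or non-convergence raises an error rather than returning
estimates; Spearman correlation as the Pearson correlation of midranks
with the t-approximation on n−2 df (scipy); empirical ROC with
trapezoidal AUC (equal to the tie-corrected Mann–Whitney statistic) and
a Youden-J operating threshold chosen among midpoints between
consecutive distinct scores (rule: score ≥ t is called positive; ties
take the lower threshold); group comparisons by Welch's t-test for
numeric fields and continuity-corrected chi-square for binary fields —
robust defaults, stated because the choice affects p-values.  No
multiple-testing correction is applied.  CI level is fixed at 95%.

## Problem sizes and determinism

The default experiments are the full 256×256 / 180-view phantom (system
matrix ≈ 15 M nonzeros, built in seconds and shared by all runs) and
100,000 patients per cohort group; the scaled bench (64×64, 60 views,
10 subsets) exercises the same L-fold acceleration law in a fraction of
a second.  The reconstruction pipeline is fully deterministic; all
cohort randomness flows from a single integer seed through numpy's
`default_rng`, and every CLI run records its seed.

## Known limitations

- 2-D parallel-beam only; no fan/cone beam, no scatter, beam hardening
  or polychromatic physics, no detector blur.
- Wall-clock iteration-time comparisons are hardware-bound and are not
  part of the package's claims; the acceleration is quantified in
  iteration counts instead.
- The cohort generator is calibrated to group-level summary parameters;
  it cannot reproduce patient-level clinical tables, and logistic/ROC
  results on synthetic cohorts are parameter-recovery exercises.
- EAT segmentation assumes the anatomical slice bounds and (implicitly)
  a delineated pericardial region are supplied by the caller.
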