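# Methods

## Diffusion phantom

The phantom is a small Cartesian grid (default 40×40×20 voxels at
1.5 mm isotropic; the analysis scripts use 32×32×16 to keep a 50-subject
study under a minute of imaging per stage) laid out like the
periventricular white matter at the level of the lateral ventricles,
with a fixed axis convention shared by the generator, the tensor fit and
the ALPS module: x = right–left, y = anterior–posterior, z =
inferior–superior.

Regions, mirror-symmetric about the midsagittal plane:

- a central **ventricle proxy** — an isotropic slab with CSF-like
  diffusivity (3.0e-3 mm²/s) that gives ROI placement and PVS counting a
  "level of the lateral ventricle" landmark;
- bilateral medial **projection blocks** with axially symmetric fiber
  tensors `diag(λ⊥ + d_pvs, λ⊥, λ∥)` (principal axis z);
- bilateral lateral **association blocks** with
  `diag(λ⊥ + d_pvs, λ∥, λ⊥)` (principal axis y);
- isotropic background at 0.7e-3 mm²/s elsewhere.

Defaults λ∥ = 1.5e-3 and λ⊥ = 0.4e-3 mm²/s are typical deep-white-matter
values. `d_pvs` (the phenomenological glymphatic-function parameter, not
a flow simulation) is added to the xx element of every block tensor —
perivascular spaces around medullary veins run along x, orthogonal to
both tracts — so the phantom's exact index is

    ALPS = (λ⊥ + d_pvs) / λ⊥,

the oracle every pipeline-level test compares against.

Signals follow the tensor model `S = S0·exp(−b·gᵀDg)` on a two-shell
scheme (b = 1500 and 3000 s/mm², spherical-Fibonacci direction sets per
shell, default 98 directions each) plus b=0 baselines. Clinical
protocols of this kind do not always report their b=0 count; the
simulator default is 7, configurable. Noise, when enabled, is Rician:
the magnitude of the complex signal with i.i.d. Gaussian perturbations
of scale `noise_sigma·S0` per channel, from an explicitly passed seeded
generator (no global RNG state anywhere in the package).

## Tensor fitting

Per voxel, the log-linearized model `ln S = ln S0 − b·gᵀDg` is solved by
weighted least squares with weights equal to the squared predicted
signal — the variance-stabilizing weight for log-transformed magnitude
data — using one OLS pass to form predictions and one reweighted pass.
S0 is the intercept term of the same fit rather than a separate b=0
average. Both shells enter one fit by default (`b_max` restricts to the
lower shell when the Rician floor at b = 3000 is a concern). Numerical
choices: design-matrix columns are scaled to unit norm before forming
normal equations (the intercept and the b-weighted quadratic columns
differ by ~3 orders of magnitude); non-positive signals are excluded per
voxel, and voxels with fewer than seven usable measurements are flagged
unfitted rather than zeroed; eigenvalues are clamped to a 1e-6 mm²/s
floor and the tensor is rebuilt from the clamped eigensystem so the
diagonal (Dxx, Dyy, Dzz) stays consistent with the eigenvalue trace;
clamped-voxel counts are recorded. A rank-deficient gradient table
(fewer than six non-collinear directions plus baseline) is a hard error.

The diffusivities the ALPS index consumes are the diagonal tensor
elements in the image frame — the standard ALPS convention — not
projections onto the local eigensystem.

## ROI placement and the ALPS index

The four ROIs (projection/association × left/right) are in-plane
squares, 5 mm nominal edge rounded to the nearest odd voxel count, on
one axial slice. The slice defaults to the center of the ventricle-proxy
landmark, detected as high-MD (>1.0e-3 mm²/s — deliberately below
free-water diffusivity, since Rician bias pulls fitted CSF diffusivity
down at b = 3000), low-FA (<0.25) voxels; it can always be supplied
explicitly.

Automatic placement searches each hemisphere of that slice for the ROI
square maximizing the ROI-mean dominance score `|v1_z|·FA` (projection)
or `|v1_y|·FA` (association), requiring every voxel of the square to
exceed the eigenvector-dominance threshold 0.7. Scoring whole squares
rather than single voxels matters under noise: the voxelwise argmax is
noise-favoured at tract edges, and an edge-centered ROI leaks into
adjacent tissue (≈12% low bias in the index at SNR 50 in our
experiments); square-level scoring removes that bias and reduces to the
same rule on noise-free data, where exact score ties are broken toward
the centroid of the tied candidates so the ROI sits mid-tract. If no
square passes the threshold — isotropic or near-isotropic data — the
placement errors out and manual coordinates (always available, and used
by the pipeline as a fallback via the generator's layout) take over.

Per hemisphere, `ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj,
Dzz_assoc)` with each term an arithmetic ROI mean; the ratio of means
(not the mean of voxelwise ratios) matches the index's standard
definition. Left and right indices are averaged for analysis, with both
retained. ROI-mean FA and MD are carried along as white-matter-integrity
covariates.

## PVS quantification

Enhancement divides the total-variation-denoised T2w by the denoised T1w
(weight 0.02; weight 0 disables smoothing), guarded against near-zero
denominators, so CSF-filled tubules (bright T2, dark T1) attain high
values. Segmentation applies Frangi vesselness at scales 0.8 and 1.2
voxels (the generator's tubules are one voxel thick), thresholds at 0.15
inside the white-matter mask, and removes 26-connected components below
5 voxels. On noise-free default phantoms this threshold sits roughly
half an order of magnitude above the strongest background edge response
and below the weakest tubule response; both threshold and minimum
cluster size are exposed in config because real-data contrast differs.
Volume is exactly mask-voxel-count × voxel volume, reported in mL and as
% of intracranial volume (the full grid, in the phantom); because the
absolute scale of reported PVS volumes is convention-dependent, both
forms are always emitted. The single-slice count uses 8-connectivity
in-plane on the slice one above the superior extent of the ventricle
proxy (3D operations use 26-connectivity; counts depend on this, hence
it is fixed and documented). The severity score uses the common
visual-rating bins 0 / 1–10 / 11–20 / 21–40 / >40 → 0–4, configurable.

## Cohort generator

Each subject carries a true ALPS-scale glymphatic parameter

    alps_true = group_mean + age_slope·(age − 53) + N(0, alps_sd),

with defaults group means 1.336 (TBI) / 1.389 (control), age_slope
−0.006/yr and alps_sd 0.125 — jointly chosen so the raw within-group SD
is ≈0.16, the scale clinical ALPS cohorts report, with the age effect
accounting for its share. The phantom's `d_pvs` is `(alps_true − 1)·λ⊥`
(floored at 0; the table keeps the untruncated draw so cohort statistics
stay Gaussian). Plasma NfL (pg/mL) is linear in the true parameter and
age, `NfL = 72 − 47·alps_true + 0.3·age + N(0, 9)`: a standardized ALPS
effect near −0.5 and an R² near 0.6 at n≈37, the magnitudes such
regressions report, with the biologically expected signs (worse
glymphatic function and older age → higher NfL). Tubule burden is
Poisson with an age-increasing rate (12 at the reference age +0.1/yr);
it is deliberately not linked to NfL, so the regression's PVS term has a
true null. Ages are uniform on 19–85 (TBI) and 33–86 (controls), sex
frequencies 75.7%/53.8% male, days-since-injury uniform on 62–241, GCS
a clipped normal (12.3 ± 2.9, range 3–15) available in ~46% of TBI
subjects; controls carry no injury covariates, and missingness is
explicit NaN.

Cohort tables are pure functions of (spec, seed); the table initially
holds parameter-level values in the observable columns so the
statistics chain can run on thousands of table-level simulations without
imaging, and the pipeline overwrites those columns with measured values
when it images subjects (per-subject seeds derive as master seed +
subject index).

What the generator does **not** emulate: partial-volume and
crossing-fiber effects, anatomical variability of tract geometry,
susceptibility/eddy/motion artifacts (inputs are distortion-free by
construction), non-tubular PVS morphology, and any mechanistic link
between tubule burden and diffusivity. Tests passing on these phantoms
show the estimators are correct and calibrated under the stated model;
they do not show robustness to real-data confounds.

## Statistics

Correlations are product-moment with pairwise deletion and t-based
two-sided p (n − 2 df); zero variance and n < 3 are errors. ANCOVA is
OLS of `metric ~ group + age` with partial (Type-III) F for each term
computed by nested-model residual-sum-of-squares comparison — for this
two-group additive design, identical to the SPSS default convention —
and adjusted means evaluated at the covariate grand mean. A perfect full
fit (RSS ≈ 0 relative to the centered sum of squares) is flagged as
exact separation (F = ∞) rather than propagating round-off. The NfL
regression uses listwise deletion with n reported, raw coefficients from
the OLS fit, standardized coefficients from the same fit after z-scoring
(so b_std = b_raw·SD(x)/SD(y) holds identically), a condition-number
guard (>1e8) naming the most collinear pair, and partial-regression
residual pairs for added-variable plots. All tests are two-sided at
α = 0.05 with no multiplicity correction, matching the reporting
conventions of the studies this battery mirrors.

Simulation-based checks use the generator's defaults: null calibration
(equal group means) over 1000 cohorts of 37/13; sign-recovery power for
a 0.05-ALPS-unit group difference over balanced 25/25 cohorts — the
conventional balanced split for a power check at total n = 50, where the
analytic recovery probability is ≈0.92 (an unbalanced 37/13 split puts
it at ≈0.89 by the same arithmetic); and NfL-direction recovery over 200
default cohorts.

## Pipeline

A run is fully described by one YAML-serializable config (every tunable
of every stage is reachable from it; a copy is written into the output
directory). Per-subject failures are isolated, logged and summarized;
the run aborts only if every subject fails or no statistics input
survives. The manifest records a SHA-256 per artifact; identical
config + seed reproduces identical bytes. NIfTI-1 volumes carry a
diagonal affine from the isotropic voxel size; gradient tables use the
FSL bval/bvec dialect.

## Known limitations

- The block-and-slab geometry makes automatic ROI placement nearly
  trivial; on real direction-encoded maps the same dominance rule would
  need a tighter search region and human review (the manual mode exists
  for exactly that reason).
- The Rician floor at b = 3000 biases fitted diffusivities in
  high-ADC/low-signal regimes (visible in the ventricle proxy, handled
  in landmark detection); the package offers shell restriction but no
  Rician-likelihood fit.
- PVS tubules are straight one-voxel segments; curvature, caliber
  variation and beading are absent, so segmentation performance here is
  an upper bound.
- The NfL model is a two-predictor linear structure with Gaussian noise;
  it reproduces the direction and rough magnitude of reported effects,
  not any specific cohort's joint distribution.
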