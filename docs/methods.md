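# Methods

## The problem

Automated morphometry pipelines are validated almost exclusively on healthy
brains. When a focal lesion (here: pediatric traumatic brain injury on
T1-weighted MRI) is present, two kinds of measurement error are possible:
*focal* error at the lesion site, and *global* error transmitted to tissue
the lesion never touched — most tellingly, to the contralesional hemisphere.
Distinguishing the two on patient data is impossible because no lesion-free
version of the patient's brain exists. The chimeric-image design solves
this: take a lesion-free control image (the *ground truth*), transplant a
real or synthetic lesion into it, and re-measure. Any difference between the
chimeric measurement and the ground-truth measurement is, by construction,
algorithm-induced; any difference in the contralesional hemisphere is
*globally transmitted* algorithm error.

## Transplantation model

T1w intensities carry no absolute units, so lesion tissue cannot be pasted
across subjects directly. Both images are mapped to a **unit-invariant
space**: z-scores with respect to the mean μ and sample SD σ (n−1
denominator, used throughout the package) of the *non-lesion* voxels of a
reference set. The reference set defaults to the whole image; a brain mask
can be supplied instead and the choice is recorded with the lesion's
characteristics.

* Extraction: `z = (patient − μ_p) / σ_p`, kept only inside the lesion mask.
* Transplantation: inside the (resampled) mask the chimeric image is
  `μ_c + σ_c·z`; μ_c, σ_c are computed over the control's reference voxels
  *excluding* the transplanted mask, mirroring extraction. This makes
  self-transplantation an identity (idempotence) and keeps the map exactly
  invertible.
* Conservation: every voxel outside the transplanted mask is copied from
  the control bit-exactly. No edge feathering is applied — blending would
  destroy the bit-exactness that lets conservation be asserted rather than
  approximated.

Spatial transforms are pluggable: `"identity"` for grid-matched images
(used for all phantom work) or a user-supplied 4×4 world-to-world affine,
applied by trilinear interpolation (scipy.ndimage). Masks are binarized at
0.5 after interpolation, which preserves voxel counts exactly under
integer-voxel translations. A lesion that lands bilaterally on the control
grid (minority-hemisphere fraction above `bilateral_fraction`, default 0.02)
is rejected, because the lesioned/contralesional recoding is undefined for
it; the crossed builder records the rejection in its manifest and continues
unless strict mode is on.

The default crossed design is 16 lesions × 11 controls = 176 chimeric
cases, the scale at which all study-size checks are run.

## Synthetic study material

Real clinical MRI cannot be redistributed, so the package generates its own:

* **Phantoms** — two mirrored sets of nested ellipsoids per hemisphere
  (outer CSF shell, middle GM shell, WM core) on a 64³ 1-mm grid, centred
  ±14 mm from the mid-sagittal plane. The affine places voxel centres at
  ±0.5, ±1.5, … mm so no voxel sits exactly on x = 0. Class mean
  intensities default to 30/70/110 (CSF/GM/WM, arbitrary units, the T1w
  ordering) with per-class Gaussian noise (SD 2 by default; 0 for
  noise-free work). Ground-truth hemispheric volumes are label counts ×
  voxel volume. A control cohort shares the base geometry but gets a seeded
  ±5% perturbation of the ellipsoid semi-axes per control, giving a genuine
  control-level variance component. A 1 × 0.5 × 0.5 mm preset reproduces
  finer acquisition granularity (0.25 mm³ voxels) for volume-resolution
  tests. The 64³ default keeps a full 176-case run under a minute on one
  CPU.
* **Lesions** — grown inside one hemisphere's tissue, either quasi-spherical
  (nearest-n voxels around a seeded centre) or multifocal (k independently
  region-grown foci). The default 16-lesion cohort spans 15–12,081.5 mm³ —
  the volume range of visible pediatric TBI lesions, every value a multiple
  of 0.25 mm³ — with 7 left / 9 right lateralities. Intensity targets are
  drawn per lesion as unit-invariant mean ~ N(−1.5, 0.5) and SD ~
  |N(0.5, 0.2)|: acute TBI lesions are predominantly hypointense on T1w.
  Drawn intensities are affinely pinned to the target mean/SD, so realized
  unit-invariant statistics match the specification to float precision.
* **Generative statistical datasets** — direct draws from each hypothesis
  family's mixed model (below), used for parameter-recovery checks of the
  solver independent of the imaging pipeline.

What the phantoms do **not** emulate: cortical folding, partial-volume
gradients, bias fields, motion, true segmenter behaviour. Passing tests
demonstrate the *logic* of the design (conservation, recoding, statistics)
and the *mechanism* of global error transmission, not the error magnitudes
any particular real segmenter would produce.

## Mock segmenter and the error mechanism

The external surface segmenter the design targets is closed, heavy and out
of scope; an adapter (`run_external_segmenter` + a stats-file parser) is
provided but never required. The built-in mock segmenter measures
hemispheric cortex and cerebral-WM volumes by threshold classification with
thresholds midway between the known class means (background counts as a
fourth class at intensity 0). Hemispheres are split by the sign of world x;
the x = 0 plane belongs to neither. Two modes:

* **local** — thresholds applied to raw intensities. Classification is
  voxel-wise, so a unilateral lesion cannot change contralesional volumes:
  contralesional error is exactly zero.
* **global-normalized** — the image is first affinely rescaled so that its
  mean/SD over the reference phantom's anatomical brain mask match the
  reference brain statistics, then the same thresholds are applied. A
  lesion inside the brain mask shifts the image's global statistics, the
  rescaling therefore moves *every* voxel's effective class boundary, and
  error appears in the contralesional hemisphere — a minimal working model
  of how image-wide intensity normalization steps inside real pipelines
  propagate focal abnormality globally.

Brain-vs-background membership is decided once, from raw intensities, in
both modes (the analogue of skull-stripping preceding normalization); hence
total brain volume is mode-invariant by construction. On a noise-free
phantom with hard thresholds the global mode responds discretely: a lesion
must shift the rescaled intensities of some class across a threshold before
any voxel is reclassified. The standard demonstration scenario therefore
uses a large (8,000 mm³), strongly hypointense (unit-invariant mean −2)
lesion, which pushes the rescaled CSF class across the CSF/GM boundary;
small faint lesions produce exactly zero contralesional error in this
segmenter, which is a property of hard-threshold classification, not of the
mechanism.

## Error metrics

Volumes are recoded from lh/rh to **lesioned/contralesional** using the
lesion's laterality on the control grid; the matched ground-truth control is
recoded with the same mapping. Each lesion × control pair contributes eight
long-table rows ({simulated, ground_truth} × {lesioned, contralesional} ×
{cortex, cWM}); ground-truth rows carry lesion code "0". Percent volume
difference,

    PVD = 100 · |V_sim − V_gt| / (½ (V_sim + V_gt)),

is unsigned, symmetric, scale-invariant and bounded by 200. A signed
simulated-minus-truth difference is kept as a diagnostic column because the
direction of error is interpretable even though PVD is a magnitude.
Descriptives report the 20% trimmed mean (floor(trim·n) values discarded
per tail — the floor rule is stated so tests can be exact), median, maximum,
and the count of cases exceeding 1% PVD.

## Mixed models

All inference uses the Gaussian linear mixed model
`y = Xβ + Zb + ε, b ~ N(0, σ²ΛΛᵀ), ε ~ N(0, σ²I)` with **crossed** random
effects: the lesion used and the control image used vary independently
(every lesion meets every control), and the pair (one chimeric case plus its
matched ground truth) is a third grouping. The three families:

* **(a)** volume ~ case (simulated vs. ground truth), random = correlated
  random slope of case within pair + intercepts for lesion and control;
  within a single-hemisphere subset only one observation per pair × case
  remains, so the pair term reduces to an intercept.
* **(b)** PVD ~ hemisphere role, random intercepts for pair, lesion,
  control.
* **(c)** PVD ~ z-scored lesion volume, mean lesion intensity, SD of lesion
  intensity; random intercept for control only (the lesion covariates are
  meant to absorb lesion-level variance), fitted per hemisphere role.
  Covariates are z-scored over the rows entering the model.

Implementation: β and σ² are profiled out of the (RE)ML deviance, leaving
an optimization over the relative covariance parameters θ (one scale per
random intercept; a 2×2 lower-triangular factor per level for a correlated
slope). The linear algebra works on the q×q system `ΛᵀZᵀZΛ + I` via
Cholesky, with per-block structure exploited so one deviance evaluation at
the study design size costs a few milliseconds. The deviance is minimized
with Powell's direction-set method on log-scaled diagonal coordinates
(variance components in these designs span orders of magnitude; log
coordinates make the search scale-free, and the profiled deviance has flat
boundary regions where finite-difference quasi-Newton methods stall), from a
deterministic variance-partition start: group-mean variances of OLS
residuals, corrected for coarser groupings nested inside finer ones, divided
by a within-finest-group residual estimate. A Nelder-Mead polish runs only
if Powell reports failure. Fits at the study design size were verified
against an independent reference implementation (lme4) to ~1e-4 in fixed
effects, SEs and log-likelihoods; one such cross-check is kept in the test
suite. Zero variance estimates are boundary results, reported as such.

Reported p-values are the normal approximation p = 2·Φ(−|t|), t = B/SE —
deliberately, with no Satterthwaite/Kenward–Roger correction. Random-effect
justification uses a likelihood-ratio test of the ML fit against the
fixed-effects-only Gaussian linear model (itself the q = 0 case of the same
code path); df is the count of fixed + variance + covariance parameters that
differ, the residual variance being common to both models. If a maximal
model with a correlated slope fails to converge, the slope–intercept
correlation is removed and the fit flagged; the df of the comparison then
drops from 5 to 4 for the family-(a) maximal model.

## Numerical and design choices

* Sample SD (n−1) everywhere; stated once so all statistics agree.
* Grid compatibility (shape equality, affines within 1e-4 per entry) is
  asserted at every image/mask pairing; nothing is silently resampled.
* 4-D or complex NIfTI inputs are rejected, not squeezed.
* Mask binarization threshold 0.5; laterality `bilateral_fraction` 0.02
  (absorbs midline-straddling edge voxels; any larger minority is genuinely
  bilateral and excluded).
* Trim rule floor(trim·n); trim = 0.2 by default.
* Optimizer convergence: Powell with xtol 1e-5 / ftol 1e-10 on the profiled
  deviance; all starts deterministic; same inputs and seeds give
  byte-identical outputs (NIfTI writing pins qform/sform and uses fixed
  dtypes).
* Degenerate inputs raise with the offending name (empty masks, zero
  variance reference sets, rank-deficient designs, missing stats keys).
* Parameter-recovery checks compare the median estimate over 200 replicates
  to the generating value, with a tolerance of 10% of the generative model's
  residual SD per reported effect. At the 16 × 11 design that bound sits an
  order of magnitude above the Monte-Carlo noise floor of the median, so the
  check is insensitive to simulation luck and fails only for genuine
  estimator bias. (Bounds expressed in units of the *empirical* SD of the
  estimates are not usable here: at 200 replicates the Monte-Carlo noise of
  the mean or median is itself of that order, so such a check would fail for
  a perfectly unbiased estimator on a non-trivial fraction of seed choices.)

## Known limitations

* The mock segmenter's hard thresholds make global-mode error discrete:
  all-or-nothing reclassification of a tissue class, so synthetic PVD
  magnitudes are not comparable to those of any real surface segmenter.
* Only affine (including identity) spatial transforms; no diffeomorphic
  registration, no pathology growth model, single contrast (T1w-like).
* Hypothesis (c) needs more lesions than covariates; the 3-lesion demo
  configuration fits families (a) and (b) only.
* The external-segmenter adapter executes a user command template and
  parses one stats-file dialect; it is exercised with a stub command in
  tests, never with the real tool.
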