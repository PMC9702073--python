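# Methods

This note documents the models and procedures implemented in `lesionfd`,
the defaults chosen where the design was genuinely open, and what the
synthetic cohort does and does not establish about real imaging data.

## Spatial conventions

All images share one axis-aligned grid (`GridSpec`): `shape` voxels of
`voxel_size_mm` edge length (default 1 mm isotropic, the standard output
resolution for track-density maps), with a world origin in mm. Voxel
(i, j, k) is the half-open box [origin + i·h, origin + (i+1)·h): a point on
a shared face belongs to the higher-index voxel, so boxes partition space
with no double counting. NIfTI affines encode voxel *centers*; only
axis-aligned affines are supported because all inputs are assumed already
registered to the shared template space (spatial normalization is upstream
and out of scope).

## Track-density mapping

A fiber-density (FD) voxel value is the number of *distinct* streamlines
whose polyline intersects the voxel, divided by the voxel volume
(fibers/mm³). A streamline re-entering a voxel counts once. Traversal uses
the Amanatides–Woo voxel walk per polyline segment, which is exact: a
streamline cutting an arbitrarily thin corner of a voxel is still counted,
which no finite point-sampling scheme can guarantee. Streamlines are
clipped to the grid; out-of-grid excursions contribute nothing. Distinct
counting (rather than visitation counting or length weighting) is the
default because it keeps "fibers per voxel" interpretable and admits an
exact geometric oracle; a length-weighted mode (`length_weighted=True`,
units mm of path per mm³) is available behind a flag.

## Synthetic cohort generator

The generator emulates the design of a treated-glioma fiber-density study:

* **Control template.** A smooth nonnegative field built from 3–8 oriented
  Gaussian-profile ridges ("tracts"): amplitude 40–120 fibers/mm³ (the
  range of healthy per-region means in such cohorts), cross-sectional σ of
  10–22% of the grid's smallest extent. The superposition is spatially
  inhomogeneous on purpose, so the reference-homogeneity criterion has
  something to reject.
* **Subject noise.** Multiplicative lognormal, mean one
  (exp(N(−σ²/2, σ²)) with σ = `noise_sd`, default 0.1). FD stays
  nonnegative without truncation, zero noise is the exact identity, and
  cohort means converge to the template. The lognormal form is a modeling
  convenience; no distributional form across subjects is implied by real
  data.
* **Patients.** Four ellipsoidal lesions (cavity, T1CE, FET, FLAIR) in the
  grid quadrants, radii jittered per subject (scale U(0.75, 1.15) on a base
  radius of 14% of grid extent), non-overlapping by default. Inside each
  mask the template is multiplied by the lesion type's suppression ratio;
  where non-cavity masks do overlap, factors compound (a cavity overlapping
  any other lesion is rejected). Default ratios 0.15 / 0.45 / 0.50 / 0.55
  for cavity / T1CE / FET / FLAIR — the relative-density ordering these
  lesion types show in clinical cohorts. Mask volumes recorded in the
  manifest are exact voxel counts × voxel volume.
* **TBR.** 1.0 outside the FET lesion; inside, a radial ramp from 5.2 at
  the center to 1.7 at the rim, so all four uptake bins are populated. With
  `fet_tbr_coupling=True` the FET suppression becomes per-voxel
  `tbr_intercept + tbr_slope × TBR` (defaults 0.59 and −0.074), making
  relative FD linear in TBR before noise; with the flag off (default) the
  FET lesion uses its constant ratio like the other types.
  `tbr_intercept_sd` (default 0.05) is the between-subject SD of the
  intercept used by the bin-level generator.
* **ECOG.** Impairment (ECOG ≥ 1) is Bernoulli with logit
  α + Σ β_type · fiberloss_type. Default β put the strongest effects on the
  T1CE and FLAIR losses (the types that drive performance status), and
  α = −4.5 places the marginal impaired fraction near the roughly even
  normal/impaired split of treated-glioma populations at the default lesion
  scale. Impaired subjects draw a grade in 1–4 skewed heavily toward 1.
* **Determinism.** All randomness derives from one integer seed; each
  subject gets a sub-seed by SHA-256 hashing of (seed, subject id), so
  cohorts are reproducible element-wise and insensitive to generation
  order.

Parameter-recovery studies of the mixed model use the bin-level generator
`generate_tbr_bin_cohort` (random intercept + linear TBR term + residual
noise, one row per subject × bin) rather than re-synthesizing images per
replicate; the image-based route through segmentation and binning is
exercised end-to-end at smaller n.

## Reference atlas and matching

The reference map is the voxelwise mean FD of matched controls. Matching
fits a main-effects logistic propensity model (patient membership on age,
gender, education), then matches greedily 1:ratio on the logit of the
propensity, without replacement, patients in descending propensity order,
ties broken by subject id — a deterministic variant of standard
nearest-neighbor propensity matching. An optional caliper (max logit
distance) leaves patients unmatched instead of accepting poor matches.
Covariates with a single level are dropped with a warning. On small or
separable samples the propensity fit falls back to a ridge-penalized
logistic fit; only the propensity ordering matters for matching, not its
standard errors.

## Segment statistics and inclusion rules

Per lesion segment: patient mean FD, reference mean FD and the spatial
(population) SD of the reference map within the segment; relative FD is
the ratio of the means. Masks are cleaned first: 26-connected component
analysis keeps the largest component (or all components above
`min_component_voxels` for genuinely multifocal lesions), then enclosed
background holes (necrotic cores) are filled under 6-connectivity — the
standard morphology pairing that avoids tunnel leakage. The cleaning is
idempotent. The FET segment is all voxels with TBR strictly above 1.6,
then cleaned.

The "reference SD" in the homogeneity rule (SD strictly smaller than the
mean) is the *spatial* SD of the control-average map within the segment —
the criterion asks whether the segment sits on homogeneous underlying
tract anatomy, not how variable controls are across subjects.
Across-subject SD is computable separately if wanted. All thresholds are
strict inequalities: TBR > 1.6, SD < mean, bin volume exclusion < 0.25 mL,
edema > 10 mL, gliosis < 0.1 mL and > 6 months.

Overlapping lesion masks are analyzed independently per type (clinical
cohorts report per-type statistics despite partial overlap, e.g. between
T1CE and FET lesions); `overlap_report` lists pairwise overlap volumes.

## TBR binning and models

Bins are half-open (low, high]: (1.6, 2.6], (2.6, 3.6], (3.6, 4.6],
(4.6, ∞), matching the strictly-above-1.6 segmentation at the bottom edge.
Bin voxel sets partition the cleaned FET segment exactly. A subject is
excluded altogether (reasons reported, never raised) when the reference is
inhomogeneous or when the full-segment relative FD exceeds 1.0 — displaced
rather than lost fibers; the exceedance threshold is configurable since no
canonical value exists. The pooled OLS fit uses all included bins from all
subjects; the mixed model adds a subject-level random intercept (no random
slope) and is fit by maximum likelihood rather than REML so nested-model
comparisons remain valid. Whether pooling or per-subject averaging is the
better estimand is genuinely open; pooling is the default and per-subject
aggregation can be done on the returned frame.

## Cohort statistics

Absolute FD (patient vs reference) is compared by two-sided Mann-Whitney
U; relative FD against 100% by a two-sided one-sample Wilcoxon signed-rank
test with Pratt zero handling (zeros ranked, then dropped — deterministic);
when every difference is zero the test is reported as p = 1 directly.
Across types: Kruskal-Wallis omnibus plus pairwise Mann-Whitney post-hoc,
uncorrected by default (Bonferroni/Holm available) — uncorrected post-hoc
is what such cohort reports typically print, and correction is a
presentation choice the caller can make. An outlier rule runs before
summarizing (default: drop segments with relative FD > 1.5); every
exclusion is counted in the returned summary and the run report.

ECOG models are maximum-likelihood logistic regressions; the multivariate
mode fits the four fiber-loss predictors jointly, optionally with clinical
covariates (age, gender, RT interval, …). Perfect separation is detected,
flagged, and handled by an L2-penalized refit whose p-values are withheld
(reported as NaN) — penalized Wald p-values would be misleading. One
calibration caveat worth knowing: with extremely heavy-tailed predictors
the finite-sample Wald test is conservative (rejection well below nominal
5% at n = 200); under the generator's own fiber-loss spread it is
calibrated, and the acceptance checks verify this at 1000 replicates.

## Problem sizes and numerical choices

* Default pipeline: 48³ grid at 1 mm, 30 patients + 30 controls — large
  enough that every lesion clears the 0.25 mL bin threshold and small
  enough that a full run takes a few seconds; multi-seed studies use 32³.
* Zero-noise runs are closed-form: relative FD equals the suppression
  ratio and total fiber loss equals (1 − ratio) × volume to float
  round-off (~1e-15 relative), which the tests assert.
* Determinism: identical config + seed give byte-identical output tables;
  report lines and JSON keys are sorted, and no timestamps enter any
  artifact.
* Degenerate inputs are explicit errors, not silent zeros: empty masks,
  single-class ECOG outcomes, grid mismatches, <2 included bins, mixed
  models on one subject.

## What the synthetic cohort does not show

The generator has no real anatomy: no gyral geometry, no partial-volume
effects at lesion borders, no registration error between subjects, no
spatial autocorrelation in the noise, and lesions are ellipsoids rather
than infiltrative shapes. Passing recovery tests therefore demonstrates
that the *estimators and rules* are implemented correctly and are unbiased
under the stated generative model — not that the clinical effect sizes
would be recovered from real scanner data, where segmentation and
registration error dominate. Headline clinical values (per-type relative
densities near 16–57%, a negative TBR slope around −0.07 to −0.08) are
recoverable here only because the generator plants them as truths.
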