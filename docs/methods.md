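# Methods

## The analysis in brief

`periconnect` quantifies how white matter hyperintensities (WMH) relate to
the cortex they are structurally connected to.  The pipeline takes
co-registered label volumes (ventricles, white matter, cortical ribbon,
WM/GM boundary, cerebellar reference, lobar labels), a WMH mask, a per-voxel
fiber orientation field, and scalar metric maps (cortical thickness, PET
tracer uptake), and produces per-parcel connected/unconnected metric ratios
plus cohort-level statistics.  All inputs can be simulated by the phantom
module with known ground truth.

## Lesion parcellation

The distance field is a Euclidean distance transform of the ventricle mask
(`scipy.ndimage.distance_transform_edt` with the voxel spacing as sampling),
i.e. voxel-center-to-voxel-center distance in mm.  A WMH voxel with distance
< 10 mm is periventricular, ≥ 10 mm deep; the tie at exactly 10 mm goes to
deep ("within 10 mm" reading — the threshold and the convention are
configurable).  Depth classes crossed with the four lobar white-matter
labels give the eight parcels; lesion voxels without a lobar label are
excluded from parcels but retained in the depth totals.  Volumes are voxel
count × voxel volume, in mL.

## Probabilistic tracking

The tracker is a minimal voxel-space streamline sampler:

- Each seed voxel emits `samples_per_voxel` (default 5000) streamlines from
  start positions jittered uniformly over the voxel cube.
- At each step the local principal direction is perturbed by rotating it by
  |N(0, σ)| (σ = the local angular dispersion) toward a uniform azimuth,
  sign-aligned with the previous step direction (fiber directions are
  axial); the position advances by `step_mm` (default 0.5 × min spacing).
- A streamline **succeeds** on first entry into a boundary voxel and
  **fails** on leaving the brain mask or grid, losing orientation support
  (e.g. stepping into ventricle or cerebellum), turning more than the
  curvature threshold (default 80°) in one step, or exhausting `max_steps`
  (default 2000).  Emitted = successes + failures holds exactly.
- Every seed voxel uses an RNG substream derived from (master seed, flat
  voxel index), so results are independent of seed ordering and counts are
  additive over seed sets.

Thresholding: the low-level ROI keeps boundary voxels with count ≥
3.08 × 10⁻⁵ % of the emitted total (real-valued comparison, ≥ by
convention).  Medium and high levels are found by scanning the sorted
distinct count values for the smallest threshold whose ROI size is ≤ 50 %
respectively ≤ 25 % of the low-level surface size; since ROI size is
non-increasing in the threshold, the result is the maximal ROI under the
bound, and the three levels are nested.  A description of this step as
"increasing the number of samples" cannot shrink an ROI under a fixed
relative threshold, so the monotone threshold search is the implemented
mechanism; the surface-size criterion is identical.  Surface size is the
boundary-voxel count (the phantom has no mesh).

The reference rROI at each level is the boundary complement of the full
ROI; per cortical region, ROI_r = ROI ∩ region and rROI_r = (boundary ∩
region) \ ROI.

## Metrics and ratios

SUVR(v) = uptake(v) / mean uptake over the cerebellar reference mask,
sampled at boundary voxels.  PET-like metrics are smoothed on the boundary
surface; thickness is not smoothed.

**Surface smoothing.**  Smoothing is a single pass of a Gaussian kernel
w_ij = exp(−d²_ij / 2σ²) over boundary voxel centers within a 3σ Euclidean
radius (σ = FWHM / 2.355; the boundary shell is thin and gently curved at
this scale, so Euclidean distance approximates geodesic distance), made
doubly stochastic by symmetric Sinkhorn balancing.  Unit row sums leave
constant maps fixed; unit column sums conserve the boundary total to
machine precision.  An iterated nearest-neighbor diffusion was considered
and rejected: at FWHM ≈ 2.5 voxels the target variance corresponds to only
one or two effective voxel jumps, so any lazy-walk kernel is either boxy or
center-spiked and its measured FWHM misses the request by ~30 %.  The
balanced Gaussian kernel measures within 5 % of the requested FWHM on a
flat patch (impulse-response test in the suite).  Requests below one voxel
return the metric unchanged with a warning.

**Ratios.**  Per region, the ratio of ROI mean to rROI mean is reported
only when both masks hold at least `min_voxels` (default 10) boundary
voxels; this stabilizes means in regions barely touched by the ROI and
mirrors the region-dependent availability seen in practice.  The averaged
ratio is the unweighted mean of available regional ratios; unavailable
regions are dropped, not imputed as 1.  Ratios are scale-invariant in the
metric.  Month-12 ratios use the identical computation with the follow-up
metric inside the ROIs identified at baseline.

## Statistics

- **One-sample vs 1**: Shapiro–Wilk at α = 0.05 gates a one-sample t test
  against the Wilcoxon signed-rank test vs 1.  (A two-sample rank test is
  sometimes quoted for this role; for a one-sample comparison against a
  constant the signed-rank test is the coherent nonparametric choice.)
  Zero-variance inputs are flagged degenerate rather than tested.
- **Group comparison**: per-group Shapiro–Wilk gates ANOVA vs
  Kruskal–Wallis; pairwise contrasts report mean difference, pooled SE and
  an uncorrected two-sample p, matching the convention of reporting
  uncorrected pairwise group effects for sensitivity.
- **Adjusted regression**: OLS of the cognitive score on a ratio plus age,
  years of education and WMH volume; rank-deficient designs are flagged,
  not fitted.
- **Benjamini–Hochberg**: step-up p̃(i) = min_{j≥i} (m/j) p(j) capped at 1,
  returned in input order; the default family is one analysis × level.
- **Longitudinal**: baseline mean/SD standardize both timepoints.  With two
  timepoints the repeated-measures ANOVA for time reduces algebraically to
  the paired t test (F = t², asserted against an independent
  repeated-measures implementation in the tests), and the mixed-model
  measure × time interaction reduces to a one-sample test of
  d_i = Δz_ratio,i − Δz_MMSE,i against 0 (negative d = the ratio declines
  faster than cognition).  Embedding a general mixed-model solver for an
  algebraically redundant case was deliberately avoided.
- All p-values are two-tailed at α = 0.05.

## The phantom

Geometry: on a default 64³ grid at 2 mm isotropic spacing (desk-scale, yet
distances remain meaningful in mm), concentric ellipsoids form ventricles
(axes ≈ 0.22/0.32/0.16 × the grid half-extent), a white-matter shell, and a
1–3 voxel cortical ribbon; the WM/GM boundary is exactly the WM layer
26-adjacent to the ribbon.  A small sphere in the inferior white matter
serves as the cerebellar SUVR reference compartment.  Six cortical regions
partition the ribbon/boundary: cingulate and insula as para-midline bands
(|x offset| < 6 mm and < 14 mm), then parietal/temporal by elevation
(≥ 40° / ≤ −40°) and frontal/occipital by the anterior–posterior side; the
four lobar WM labels use the same rules without the midline bands.  Any
6-region partition with these names serves the analysis; no claim of
anatomical fidelity is made.

Orientation field: the unit radial direction (local
ventricle-to-cortex axis) on WM ∪ WMH ∪ boundary, with constant angular
dispersion (default 10°; set 0 for exact geometric tracking).

Lesions: spheres (default 4 mm radius, one periventricular + one deep per
lobe) placed deterministically at the admissible voxel maximizing a margin
score; admissibility requires the ball to fit inside white matter and the
depth constraint to hold against the ventricle distance map (deep: every
lesion voxel ≥ 10 mm; periventricular: minimum distance < 10 mm), verified
after rasterization with an explicit placement error otherwise.

Ground-truth connected patch: deterministic outward marching from a 6³
sub-voxel grid of start points per lesion voxel, following the same
per-voxel radial directions the field encodes, marking first boundary
entry.  This is the noise-free limit of what a dispersion-free tracker
samples; at 5000 samples per voxel the stochastic low-level ROI matches it
at Dice ≈ 0.98.

Metrics: region-specific baselines (thickness 2.0–3.0 mm; tracer uptake
patterns loosely shaped after amyloid, tau and SV2A PET with cerebellar
uptake 1.0) multiplied by the planted effect inside the true connected
patch (defaults: thickness 0.95, Aβ 1.045, tau 1.05, SV2A 0.92 — mild
thinning, amyloid/tau excess, synaptic loss) and by mean-one multiplicative
lognormal noise (SD fraction 0.05), which keeps thickness and SUVR
positive.  With zero noise every planted ratio is recovered exactly by
averaging over the truth masks.

Follow-up: the month-12 thickness map adds the planted annual change
(default −0.10 mm in connected, −0.02 mm in unconnected cortex, chosen so
the ratio drop ≈ −0.033 matches a realistic 12-month decline) before fresh
noise; geometry and ROIs are unchanged.

Cohort: 59 AD / 27 MCI / 21 CN by default, with group-specific ages
(≈ 70–71 ± 7–8 y), education 10.7 ± 4.5 y, lognormal WMH volumes, and
per-subject true ratios drawn around the planted effects (between-subject
SDs 0.035/0.041/0.10/0.038 for thickness/Aβ/tau/SV2A).  The cognitive
score follows score = intercept + Σ β_m ratio_m + β_age age + β_edu edu +
β_wmh WMHvol + N(0, σ); the default couples the score to the amyloid ratio
with slope −37.8.  Diagnosis follows the CDR convention (> 0.5 AD, = 0.5
MCI, = 0 CN).  The first 23 impaired subjects carry 12-month follow-up
values: MMSE change N(−1.8, 3.0) and thickness-ratio change N(−0.033,
0.02).  The distribution of WMH volumes and lesion counts per subject is a
config choice with no claim of epidemiological realism.
`make_cohort` returns the subject table plus per-subject phantom configs;
volumes are materialized lazily via `Cohort.phantom(i)`.

## What the phantom does and does not show

Passing tests demonstrate that the *pipeline machinery* is correct: exact
streamline accounting, correct distance classification, maximal adaptive
thresholds under the size bounds, unbiased ratio recovery at planted effect
sizes, calibrated type-I error and adequate longitudinal power under the
stated generative model.  The phantom deliberately omits realistic MRI
contrast, bias fields, crossing fibers, distortion, partial-volume effects
and anatomical parcellation error, so green tests do not certify
performance on real MRI/PET data — they certify the analysis applied
downstream of those acquisition issues.

## Numerical choices and degenerate inputs

- Voxel indexing is 0-based; world coordinates come from the NIfTI affine
  (volumes co-analyzed together must agree in shape exactly and in affine
  entries to 1e-4); all distances are in mm.
- Seeds derive hierarchically: master → per-subject → per-parcel →
  per-seed-voxel, so outputs are independent of execution order and
  bit-reproducible (manifest hashes are asserted stable in the tests).
- Tie-breaks: lesion placement picks the lowest flat index among maximal
  scores; the adaptive search scans ascending distinct counts and takes the
  first admissible threshold; at exactly the depth threshold a voxel is
  deep; the low-threshold comparison is ≥.
- Degenerate cases: empty ventricle or seed masks, zero/negative reference
  uptake, zero baseline SD and rank-deficient designs raise or are flagged;
  zero-variance test inputs return flagged degenerate results; an
  unreachable adaptive target returns an empty ROI with a warning.

## Problem sizes used in the checks

The shipped checks run the default 64³ phantom (≈ 1.3 M streamlines for the
full WMH mask), 50 random ≤ 17³ grids for the distance oracle, 100 phantom
replicates for ratio recovery, 10 000 replicates (n = 59) for test
calibration, 500 cohort replicates for longitudinal power and 100 for
regression coverage — sizes chosen so the whole suite runs on a laptop in
a couple of minutes while keeping Monte-Carlo error well below the asserted
tolerances.
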