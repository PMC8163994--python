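# Methods

This note documents the models, numerical choices, and limitations behind
`tractoprofile`. It is written for users who need to know exactly what the
package computes, not just how to call it.

## Along-tract coordinate system

A bundle is a set of streamlines (3D polylines in world-space mm). Its
profile axis is the **centroid fiber**: every streamline is resampled to
101 equidistant points (by arc length, endpoints preserved), the pairwise
distance between two resampled streamlines is the mean Euclidean distance
between corresponding points, minimized over the direct and the flipped
point ordering, and the centroid is the *member* streamline minimizing the
mean distance to all others (ties broken by lowest index). The centroid's
101 resampled points define 100 segments; segment indices 0–99 are the
along-tract coordinate.

Streamlines are then oriented (flipped when the flipped correspondence to
the centroid is closer), resampled to 101 points, and each of their 100
small segments is assigned the index of the nearest centroid-segment
midpoint. A subject's profile value at segment *i* is the arithmetic mean
of the metric sampled at the midpoints of all streamline segments assigned
to *i*; segments receiving no points are marked missing (NaN) and excluded
from statistics, never imputed. Sampling at segment midpoints, with the
segment direction as the tangent, is a choice; per-segment sub-sampling
would be a refinement but changes values only at the interpolation scale.

All of these operations are brute-force testable, and the test suite
verifies centroid selection and segment assignment against exhaustive
search on small bundles.

## Metrics

Three voxelwise metrics are evaluated at arbitrary world-space points.
Spherical-harmonic (SH) coefficients and tensor components are
interpolated trilinearly and componentwise; by linearity of SH synthesis,
interpolating coefficients equals interpolating amplitudes.

**SH basis.** Real, even-order only (FODs are antipodally symmetric),
ordered by degree `l = 0, 2, …, lmax` and within degree by
`m = −l … +l`, with `m<0 ↦ √2·Im(Y_l^|m|)`, `m=0 ↦ Y_l^0`,
`m>0 ↦ √2·Re(Y_l^m)` (orthonormal complex harmonics with Condon–Shortley
phase, polar angle from +z). The basis is orthonormal, so the sphere
integral of an expansion is `c₀·2√π`. A round-trip (coefficients →
amplitudes → least-squares fit) test pins the convention.

**AFD (apparent fiber density).** The integral of one FOD lobe. Lobes are
found on a subdivided-icosahedron tessellation (default 2562 vertices,
antipodally symmetric, per-vertex solid angles normalized to 4π): vertex
amplitudes are clamped at zero, vertices above `amplitude_floor_frac`
(default 0.1) times the maximum are partitioned into steepest-ascent
basins on the mesh graph, and antipodal basin pairs are merged because the
FOD is symmetric. A lobe's integral is the solid-angle-weighted amplitude
sum over its basin. `afd_along` returns the integral of the lobe whose
peak axis maximizes |dot| with the reference direction (the local
streamline tangent); ties go to the larger integral.

Accuracy notes, measured and frozen in tests: lobe integrals agree within
1% between one mesh refinement level and the next (at floor 0.05, where
the basin structure is stable); a 90° two-population crossing with 0.6/0.4
volume fractions is recovered with each integral within ~3% (the deficit
is kernel overlap across the basin ridge plus floor truncation); the
default floor 0.1 truncates up to ~10% of a single lobe's tail — floor
choice trades ringing suppression against tail truncation, and profiles
use a single floor consistently so group contrasts are unaffected.

**FOD peak amplitude.** The FOD value at the selected lobe's peak vertex,
refined by one quadratic-fit ascent step on the continuous SH surface. A
purely isotropic FOD has no lobe structure and returns 0 by convention.

**FA.** From a 6-component symmetric tensor field (component order Dxx,
Dxy, Dxz, Dyy, Dyz, Dzz): `FA = √(3/2)·‖λ−λ̄‖/‖λ‖` over the eigenvalues of
the interpolated tensor, with negative eigenvalues clamped to zero and the
zero tensor mapping to FA 0.

**Z-normalization.** For cross-metric display, a profile matrix is
z-scored over all subjects × segments of one bundle and metric; constant
matrices map to zero with a warning.

## Group statistics

The cohort design is two groups (tinnitus, control; default n = 19 + 19)
with three confounds: hearing loss (dB), THI (Tinnitus Handicap Inventory,
0–100), and tinnitus duration (years). THI and duration exist only for the
tinnitus group and are stored as 0 for controls.

**Confound adjustment.** Per segment, OLS of the metric on
[intercept, HL, THI, duration], with each confound mean-centered *within
group* by default. Centering is essential, not cosmetic: zero-filled
one-group covariates are near-perfect group proxies, and a pooled
regression would absorb essentially any group difference (a δ = 2 injected
effect drops from max|t| ≈ 7.9 to ≈ 1.4 without centering). Within-group
centering removes within-group confound variation while leaving the
between-group contrast untouched. Pooled residualization is available as
`confound_centering="pooled"`.

**Testing.** Pooled-variance two-sample Student t per bundle and segment
(df = n₁+n₂−2). Family-wise error over *all bundles × segments of one
metric* is controlled by maxT permutation: group labels are permuted
(default 5000 times; exact enumeration when the number of distinct label
assignments is smaller), the confound adjustment is **replayed inside
every permutation** (centering on the permuted grouping), and the maximum
|t| over the family is recorded. `p_FWE = (1+b)/(B+1)` with the add-one
estimator for sampled permutations, the plain proportion for exhaustive
enumeration, floored at the parametric uncorrected p. Replaying the
adjustment matters: residualizing once and permuting residuals deflates
the permutation null and inflated the measured family-wise error rate to
0.095; with per-permutation adjustment the measured rate on 200 null
cohorts is 0.050.

Significance requires `p_FWE < α / n_metrics` (default 0.05/3, one
Bonferroni division per metric analyzed) *and* membership in a run of at
least `cluster_extent_min` contiguous significant segments (default 5; 2
reproduces the package's supplementary-style sensitivity variant).

**Effect sizes and power.** Cohen's `d = 2|t|/√(n₁+n₂−2)` (exact for equal
group sizes; direction kept separately as the sign of t), `f² = r²/(1−r²)`
for correlations, and post-hoc power from the noncentral t distribution
with noncentrality `d·√(n₁n₂/(n₁+n₂))` at a configurable `power_alpha`
(default two-sided 0.05; published tractometry tables sometimes use the
data-dependent corrected threshold instead, which is why this is exposed
as a parameter rather than hard-coded).

**Cofactor correlations.** Semi-partial: fit OLS of the metric on all
confounds jointly, subtract the fitted contributions of the *other*
confounds, and Pearson-correlate the adjusted metric with the cofactor —
over the full cohort for hearing loss, over the tinnitus group only for
THI and duration. FWE correction permutes the cofactor across subjects and
re-fits the full model per permutation (max |r| statistic). The parametric
p uses the t transform `t = r√((n−2)/(1−r²))`.

## Synthetic cohorts

No MRI data ship with the package; the generator produces every input.

**Bundles.** A cubic spline through control points, resampled to
`points_per_streamline` points; each streamline adds a constant radial
offset (Gaussian amplitude, sd `radial_dispersion_mm`, uniformly random
direction in the local normal plane) plus per-point isotropic jitter with
sd at 5% of the dispersion. Deterministic per seed.

**Fields.** In voxels traversed by a bundle, the FOD is an axially
symmetric kernel `exp(−κ sin²θ)` (κ = 8, chosen so order-8 truncation
error stays below ~1.5% of peak) aligned with the voxel's principal
streamline direction and scaled so its analytic sphere integral equals the
requested AFD — optionally modulated along the tract through the
centroid's segment index, and optionally mixed with a second population
for crossings. Tensor fields are axially symmetric with eigenvalues
`MD(1+2δ), MD(1−δ), MD(1−δ)` where `δ = FA·√(3/(9−6FA²))` inverts the FA
closed form; background voxels hold an isotropic tensor at the same mean
diffusivity so edge interpolation degrades FA smoothly. Default grid
spacing is 1.3 mm isotropic; tests and the demo use 2.5 mm.

**Cohorts.** Confounds are drawn per group from Gaussians truncated at
zero. The published group statistics are moments of *observed*
(nonnegative) data, so the truncated mean is moment-matched: the latent
mean solves `E[X | X ≥ 0] = target`. Age and hearing loss are drawn
jointly; the within-group latent correlation is inflated by the analytic
pooled-attenuation factor (pooling groups with different HL means and sds
attenuates the pooled r) so the full-cohort sample correlation targets the
configured value (default 0.545). Residual truncation attenuation of about
2–3% remains (measured mean pooled r ≈ 0.53); this is a known limitation,
not corrected numerically.

Group effects are injected as `δ·noise_sd` added to the tinnitus group's
baseline inside contiguous segment windows. Two generator levels exist:
`make_profile_cohort` samples profiles directly (smooth per-bundle
baseline + i.i.d. Gaussian segment noise) and is used for statistical
calibration at scale; `make_cohort` builds per-subject streamlines and
voxel fields so the full geometric pipeline is exercised end to end. With
all δ = 0 the groups are exchangeable by construction (metrics do not
depend on the confounds), which is what the family-wise error calibration
relies on.

The Gaussian subject-noise model is a choice the data cannot constrain
(the study reports no subject-level variance model); `noise_sd` is a
config knob, default 0.05 against metric baselines of ~0.5.

## What the synthetic tests do and do not show

The calibration results (family-wise error 0.050 on 200 null cohorts;
δ = 2 effects over segments 40–59 detected with a surviving cluster in
100% of 50 replicates with no spurious bundle) validate the *procedure*
under the generator's assumptions: Gaussian noise, independent segments,
exact exchangeability under the null. Real along-tract data have spatially
correlated noise, registration and segmentation error, and non-Gaussian
tails; the permutation test remains valid under exchangeability but
detection rates on real data will differ. The anatomical findings of any
particular study (which bundles and segments differ in which cohort)
require that study's subject data and are out of scope here.

## Problem sizes

Defaults are desk-scale: 3 bundles × 100 segments, 19 + 19 subjects,
500 streamlines per bundle (tests use 15–60), 1000–5000 permutations,
sphere meshes of 642 (tests) or 2562 (default) vertices. All are
configuration, not code limits.

## Numerical conventions

* Coordinates: world space, mm, RAS+; voxel indexing 0-based; intervals
  half-open.
* NIfTI affines: nibabel's preferred transform (sform over qform).
* Sub-voxel queries outside the grid raise `OutOfBoundsError`; callers
  decide whether to skip.
* Zero pooled variance → t = 0, p = 1; constant cofactor → error; |r| → 1
  → f² flagged infinite.
* All stochastic stages take explicit seeds; identical seeds give
  bit-identical outputs (tested).
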