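# Methods

This note documents the models and numerical conventions behind
`sctdoseval`, the choices made where several conventions are defensible, and
the limits of what the synthetic cohort can establish.

## Data model and geometry

All images live on axis-aligned lattices (`Grid`): shape, strictly positive
spacing in mm, and the world coordinate of the *center* of voxel (0,0,0).
Indices are 0-based; `world = origin + index · spacing`; oblique or sheared
grids are rejected at I/O time.  This keeps every distance computation
(surface metrics, gamma DTA) unambiguous at the cost of not ingesting
oblique acquisitions — acceptable because evaluation happens after
resampling to the planning grid anyway.

Resampling uses spline interpolation through `scipy.ndimage`
(cubic by default for scalar volumes, nearest-neighbour always for masks);
samples outside the source take the unit's fill value (−1000 HU, 0 Gy,
False).  Rigid motions are intrinsic Z-Y-X Euler rotations about the volume
center plus a world-frame translation, applied by resampling through the
inverse; `RigidTransform.scaled(f)` scales angles and translations — exact
for translations and a small-angle approximation for rotations, which is
adequate for the ≤ a-few-degree offsets modelled here.  HU volumes are
clamped to [−1024, 3071] (12-bit CT convention) on write.

## Segmentation

The body is `HU ≥ −250`, largest 26-connected component, with enclosed
cavities filled (6-connected complement — the standard digital-topology
pairing), so internal airways remain part of the body.  Tissue classes
partition the body exhaustively: soft tissue on the *closed* interval
[−250, 250] HU, bone above, air below.  The closed interval is a choice —
"between −250 and 250" leaves the endpoints ambiguous — made so that the
partition identity |soft| + |bone| + |air| = |body| holds exactly, which the
tests enforce on random volumes.

## Image agreement

MAE is computed over the intersection of the pCT-derived and sCT-derived
class masks (each CT segmented independently).  Surfaces are boundary voxel
centers (mask voxels with a face-neighbour outside); ASSD pools directed
nearest-neighbour distances over both surfaces, HD is the exact maximum (no
percentile — plain "Hausdorff distance" is reported).  Voxel-center surfaces
are bit-reproducible but can differ from marching-cubes tools at the
sub-voxel level.  The beam-visibility criterion for misregistration volumes
("where the beams passed through") is deliberately a dose-footprint proxy:
XOR voxels receiving ≥ 5 % of the prescription in the corresponding
sCT-calculated plan.  It is configurable; a geometric ray-cast alternative
was considered and rejected as harder to reproduce across dose engines.

## DVH metrics

D_v is computed from the structure's voxel doses by order statistics with
linear interpolation at the 1-based fractional rank `k = n(1 − v/100) + 1`.
This convention agrees exactly with a brute-force threshold scan ("largest
dose received by ≥ v % of voxels") at every attainable volume fraction,
returns the minimum at v = 100 and tends to the maximum as v → 0.  All
voxels weigh equally (no sub-voxel volume model); the cumulative DVH curve
(default bin 0.01 Gy) is reporting-only — point metrics are always computed
voxelwise.

## Gamma analysis

The Low-style index is minimized over a cubic displacement lattice of step
DTA/10 (default 0.2 mm) inside a search sphere of radius 3×DTA, with the
evaluated dose sampled by trilinear interpolation and the reference kept at
voxel centers (the method's standard asymmetry).  Conventions chosen where
the literature varies: the reference is the pCT-calculated dose; the dose
threshold (10 % or 90 % of the 68 Gy prescription) applies to the reference;
global normalization is the prescription, not the dose maximum; in local
mode zero-reference voxels are excluded.  The evaluation domain is the ROI
(body overlap, or the CTV union intersected with it) ∩ threshold.

`gamma_map` visits displacements in order of increasing |d| and abandons a
voxel once the distance term alone exceeds its current best γ — an exact
pruning.  An optional cap (pipeline default 1.1) stops refining voxels whose
γ provably exceeds it; pass/fail at γ ≤ 1 is unaffected, only the magnitude
of reported failures saturates.  `gamma_brute_force` evaluates every lattice
displacement with no pruning and bounds the truncation choices: the two
agree to 1e-6 on random dose pairs (acceptance suite).  A search radius of
3×DTA discards only matches that would imply γ ≥ 3.

A note on the shifted-ramp closed form (interior γ = 0.5 for a 1 Gy/mm ramp
shifted 1 mm): it holds in the DTA-dominated regime, where the dose term
penalizes any displacement off the exact 1 mm lattice point.  With a soft
dose criterion the continuum minimum dips below 0.5 by trading dose error
against distance; the tests therefore exercise the closed form with a 20 Gy
global normalization, where the lattice minimum is exactly at 1 mm.

## Statistics

Wilcoxon signed-rank: zeros dropped, midranks over tied |differences|,
statistic = smaller signed-rank sum; exact two-sided p by dynamic
programming over the generating polynomial of the (doubled) ranks for
n ≤ 25 — equivalent to enumerating all 2^n sign patterns — else a normal
approximation with tie correction and continuity correction.  Pearson r uses
the t-transform p-value (`scipy.stats.pearsonr`); at n = 20 it reproduces
the significance pattern expected of r = −0.60 (p ≈ 0.007) and r = −0.73
(p < 0.001).  Quartiles interpolate linearly at position (n − 1)q.

## Synthetic cohort: what it emulates

Each case draws, from one integer seed split via numpy `SeedSequence`
spawn keys (bit-reproducible across platforms):

- **Anatomy** — elliptic body (semi-axes 68 × 82 mm, widening to ≈ 110 mm
  at the shoulders), vertebral column at 950 ± 150 HU with a cord canal,
  mandible 1200 HU, shoulder bones 850 HU, trachea/pharyngeal air, oral
  cavity with an air pocket, parotids, brainstem, oesophagus, larynx; ± 30 HU
  smooth soft-tissue texture; per-case scale jitter (σ 4 %); tonsil (65 %)
  or base-of-tongue (35 %) primary; bilateral (90 %) or unilateral elective
  volumes extending to the supraclavicular level so beams traverse the
  shoulder slices.  Bone HU values are cortical-like on purpose: with bone
  near the 250 HU class threshold, large negative errors eject voxels from
  the class intersection and cap the measurable bone MAE below its target.
- **pCT extras** — contrast vessels (+200 HU) and a couch slab, which the
  pipeline overrides to water and air respectively before analysis.
- **sCT errors** — per-class smooth Gaussian fields (correlation 8 mm) with
  class biases (bone negative, air positive), plus a band-limited stochastic
  erosion/dilation of the bone edge.  Field scales are *self-calibrated*:
  after applying the residual transform the realized class-intersection MAE
  is measured and the scales adjusted over three fixed-point iterations
  toward the targets (soft 43, bone 298, air 118 HU), because class-membership
  changes, misalignment and resampling otherwise bias the realized MAE.
- **Misregistration** — a rigid offset per case (translation σ 3.5 mm/axis,
  rotation σ 1.5°) of which 30 % survives "registration", plus an extra
  lateral shoulder displacement (σ 6 mm) blended below the shoulder line,
  mimicking the posture changes rigid registration cannot resolve.  The
  shoulder component is the dominant driver of body-contour XOR volumes and
  photon gamma failures, consistent with misregistration being concentrated
  there.

Dose surrogates are analytic and deliberately simple; they are **not**
treatment-planning engines.  HU maps to proton stopping power through a
two-segment ramp (air 0, water 1, bone flattened at 0.0005/HU).  Photon arcs
(72 equally weighted coplanar beams) accumulate `exp(−0.005/mm · WET)` with
a beam's-eye fluence covering the targets (elective volumes at 50/68 weight,
4 mm margin, smoothed penumbra).  Proton fields (five bilateral /
four unilateral gantry angles) deposit per-ray SOBPs in WET coordinates:
gently rising entrance (~70 % of the flat top), flat top spanning the
target's WET interval + 2 mm margins, Gaussian distal falloff (σ 3 mm).
Plans are "optimized" on the pCT — fluence, per-ray WET intervals and the
scale that puts the CTVp68 median at 68 Gy are frozen there — and
*recalculated* on the sCT, so HU errors shift the proton distal edge in
geometric depth (slope 1 per mm of WET error, verified to half a voxel)
while photons change only by attenuation (< 1 %/2 mm WET).  WET line
integrals use a world-anchored piecewise-linear reconstruction at half-voxel
steps, making them exactly additive in depth.

## What passing tests do and do not show

The cohort reproduces the *structure* of the clinical findings: per-class
MAE medians within 15 % of their calibration targets; bone the least
congruent class; proton pass rates below photon ones; and strong negative
correlations between the local pass rate and both body ASSD and the
beam-visible misregistration volume.  The *magnitudes* of pass rates and DVH
differences are not calibrated to any clinic: the surrogate dose models have
no scatter, no penumbra physics, no optimizer, and VMAT arc averaging makes
the photon surrogate nearly immune to the modelled errors (medians sit at
~100 % rather than the high-90s).  Two further artifacts worth knowing: the
proton SOBP flat top is exactly WET-independent, so structures lying wholly
in plateau regions can show literally zero dose difference (the proton D2
of the target is such a case, and its Wilcoxon test is then flagged
degenerate); and gamma maps computed with the pipeline's cap of 1.1 report
failure magnitudes saturated at that cap.

## Problem sizes

Defaults follow the study conditions: 20 cases on 2 mm isotropic
128 × 128 × 80 grids, 68 Gy/34 fractions to the high-risk CTVs and 50 Gy
elective.  At these sizes one case costs ≈ 14 s (generation + full
analysis) and the cohort ≈ 5 min on one core; the gamma oracle-equivalence
checks run on 12³ grids where exhaustive search is feasible.  Small-grid
variants (64 × 64 × 40 at 4 mm) are used for determinism and integration
tests; they exercise identical code paths.
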