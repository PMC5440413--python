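# Methods

This note documents the models, numerical choices, and synthetic study
conditions behind `osteorough`, and what the test suite does and does not
demonstrate about real data.

## VOI extraction

The paw finder operates on an 8-bit, in-plane-downsampled copy of the scan:
16→8-bit conversion is per-stack min–max linear scaling with round-half-up
(robust to scanner offsets and strictly monotone, so the fixed binarization
threshold of 75 keeps its meaning); downsampling is block-mean over x/y only,
because the z-space filters (object must start at slice ≥ 300 and span ≥ 300
slices) are calibrated to full z resolution.  Connectivity for 3D components
is 26 (the volumetric extension of in-plane 8-connectivity); 6-connectivity
is available as a parameter.  The foreground rule at the threshold value is
inclusive (intensity ≥ threshold).

The filter constants (more than 85,000 foreground voxels, z-cuts at 300)
target 2048×2048-pixel acquisitions and are plain parameters; the synthetic
scan scenes pass proportionally scaled values (2000 voxels, z-cuts 30/40,
downsample factor 2 for 192²-pixel scenes).

The calcaneus endpoint is found by scanning per-slice 2D 8-connected
component counts from the distal end: the endpoint is the first slice of the
first run of at least `run_length` (default 5) equal counts whose count
exceeds the count of the immediately preceding run.  Short excursions
(imaging noise, sesamoid-like fragments) are ignored by the run-length
requirement; a VOI with no such pattern is flagged and kept untrimmed.

## Surface reconstruction

Iso-surfaces are extracted with the Lewiner marching-cubes variant at a
one-voxel grid size, on the intensity threshold given by Otsu's method for
the individual VOI.  Otsu is computed over the full-bit-depth histogram; a
plateau of optimal cut points (which always occurs when the two intensity
modes are separated by an empty gap) returns its midpoint, making the
threshold independent of which end of the gap an implementation happens to
scan first.  One layer of sub-threshold padding closes every component;
triangle winding is oriented so per-triangle normals point away from the
suprathreshold (bone) region.  Duplicate vertices are merged on exact
coordinate equality only — tolerance welding would move vertices and bias
the roughness statistic, which is also why no smoothing or decimation is
offered.

Endosteal/periosteal separation defines cavities as background voxels not
reachable by a 6-connected flood fill seeded from the x- and y-face borders.
The z faces are excluded from seeding because long bones run along z and are
cut open at the VOI ends; an open medullary canal therefore counts as
cavity.  The outer surface is meshed after re-assigning cavity voxels a
suprathreshold fill; the inner surface is meshed on a mirrored field
(`2·t − intensity` on bone and cavity voxels, deep background elsewhere)
that is suprathreshold exactly on the cavity and crosses the threshold at
the same sub-voxel positions as the complete surface's endosteal interface.
Consequently area(os) + area(is) equals area(cs) exactly (up to ambiguous-
cell resolution) on phantoms whose cavity is fully enclosed; on open-ended
VOIs the identity is broken only by the padding caps at the volume boundary.
Inner-surface normals point from the cavity into the cortical wall.

## Roughness statistic and calibration

The vicinity of a triangle is the set of other triangles of the *same*
edge-connected component whose centroids lie within `r × pitch` (Euclidean
metric).  The component restriction prevents the metric ball from jumping
across to a neighbouring bone; the Euclidean (rather than geodesic)
construction is the package's choice where the original formulation is
ambiguous.  Angles are between oriented outward unit normals, in degrees;
the per-triangle statistic is the mean over its vicinity, and triangles with
an empty vicinity are excluded and counted.  Internally a k-d tree is used
for small vicinities and a blocked dense evaluation when the expected
pair count exceeds 3·10⁷; both paths are verified against an all-pairs
brute-force oracle to 10⁻⁹ degrees.

Calibration pools per-triangle angles of all baseline meshes (one sample per
triangle, no per-mesh weighting) into a 0.5°-bin histogram on [0°, 180°] and
fits the two-parameter lognormal density by nonlinear least squares on the
bin-centre densities, initialized from the histogram's log-moments.  The
threshold angle is T = µ_p + 2σ_p from the closed-form lognormal mean and
SD.  One calibration is kept per (surface kind, radius).  The roughness
score R is the relative frequency of triangles above T — a fraction in
[0, 1], invariant under mesh duplication and therefore minimally affected
by bone growth.

Radii of 1, 3, 5, 10, 15, 20 voxels correspond to ≈ 15, 44, 73, 146, 219,
292 µm at the 14.609 µm CT pitch.  Radii are sensible only while the
vicinity does not wrap around the bone: once `r × pitch` approaches the bone
radius, the mean-angle distribution degenerates (narrow and, for multi-
component surfaces, bimodal), the lognormal tail fit loses meaning, and R
becomes unstable.  On the small test phantom (bone radius 11 voxels) this
happens for r ≥ 15; real mouse metatarsals are large enough for all six
radii, which is exactly why the radii were chosen not to wrap.  At r = 1 the
vicinity contains only edge-adjacent triangles and the angle distribution is
nearly discrete; the fitted T is then far above any observed angle and R is
pinned at 0 — r ≥ 3 is the informative range on voxel-grid meshes.

## Quantification

V_VOI is the voxel count of the largest 26-connected suprathreshold object
times the voxel volume (3.11·10⁻⁶ mm³ at 14.609 µm isotropic pitch),
using the same Otsu threshold as the surface reconstruction; a sweep over
80–120 % of that threshold (9 steps) quantifies threshold sensitivity.
SUV = concentration (Bq/ml) / injected activity (Bq) × body weight (g),
assuming 1 g/ml tissue density, restricted to an optional axis-aligned
ellipsoid and to voxels at or above 40 % of the maximum SUV (30–50 % is the
documented stable range).  The reported SD is the population SD of retained
voxels.  No radioactive-decay correction is applied — the acquisition
protocol fixes the injection-to-scan timing.

## Group statistics

The ratio of group means µ_AR/CO carries the propagated SD
|µ_AR/CO|·√((σ_AR/µ_AR)² + (σ_CO/µ_CO)²) (group SDs are sample SDs).
Bootstrap CIs are percentile intervals of mean(AR resample)/mean(CO
resample) over within-group resamples with replacement (default 10,000);
control resamples with exactly zero mean are redrawn and counted.  The
resampling unit is the paw.  Significance between two groups is declared
when their bootstrap mean CIs are disjoint as closed intervals (a shared
endpoint counts as overlap); `intervals_overlap` applies the same rule to
two ratio CIs when comparing conditions.  A caveat measured here: for a
ratio of means with n = 10 per group, the true coverage of the nominal 95 %
percentile interval is ≈ 92 % (BCa is no better at this sample size), so
CI-based decisions at small n are slightly anticonservative.  Mann–Whitney
U (two-tailed; exact enumeration when min(n, m) ≤ 8 without ties, otherwise
the tie-corrected normal approximation) and Spearman rank correlation
complete the layer.  No multiple-testing correction is applied, by design;
users scanning many (surface, radius, timepoint) combinations should keep
this in mind.

## Synthetic study conditions

The phantom module emulates the data the pipeline was built for and defines
the conditions under which the tests run:

* **Bone phantom** — a voxelized hollow cylinder (outer radius 20, inner
  radius 13 voxels; wall ≈ 102 µm at CT pitch), fully enclosed in
  background with rounded dome ends, 16-bit intensities of 20,000 ± 500
  (cortical bone) over 2,000 ± 500 (soft tissue/air).  Flat end discs are
  available (`cap_style="flat"`) but put a near-zero-angle spike into the
  composite histogram that destabilizes the lognormal fit; dome ends have
  cylinder-like curvature and are the bone-like default for roughness work.
* **Wall perturbation** — per-surface radial displacement fields on the
  unrolled (θ, z) surface: Gaussian noise smoothed to the stated correlation
  length (wrap in θ), scaled to SD = amplitude, clipped at ±(wall/2 − 0.5)
  voxels so extremes cannot breach the wall.  Controls carry a natural
  texture of amplitude 0.5 voxels at correlation length 2; "arthritic"
  erosion is modelled as amplitudes 0.75–2.0.  Within an amplitude ladder
  the same seed is reused, so the geometry deforms monotonically with
  amplitude.
* **Scan scene** — 200×192×192 voxels with two "paws" (a main rod joined by
  a proximal bridge to a second rod that appears at the true endpoint
  slice) in the lower left/right, distractor cubes below the pixel filter
  in the upper half, and one large low-z slab that only the z-filters
  reject.  Object edges sit on even coordinates so factor-2 block averaging
  cannot blur them.

All ground truth (foreground/cavity masks, boxes, endpoints) comes from
per-voxel geometry tests independent of the analysis pipeline.  What the
phantoms do **not** emulate: anatomical shape variety, trabecular bone,
partial-volume and beam-hardening effects, motion artifacts, PET physics.
Passing tests demonstrate the pipeline's internal correctness and its
sensitivity/specificity on controlled geometry, not clinical performance.

## Problem sizes and determinism

Test and acceptance runs use 64–72-voxel-cube bone phantoms (≈ 40,000
triangles per complete surface), 20 scan scenes, 10-seed amplitude ladders,
10⁵-sample fit recoveries, 10⁷-draw Monte-Carlo checks, and 1,000-replicate
coverage simulations — sizes chosen so the whole suite runs on a single CPU
in minutes while every statistic keeps enough resolution (R resolution
≈ 2.5·10⁻⁵ per mesh).  Every random quantity is seeded; identical
configuration and seed reproduce byte-identical outputs.

## Known limitations

* The lognormal is fitted to a histogram by unweighted least squares (the
  documented alternative of MLE on samples is closed-form for the lognormal
  but weights the tail differently); on strongly non-lognormal angle
  distributions the fitted T can exceed all observed angles, pinning R at 0.
* Endosteal/periosteal separation assumes cavities never touch the x/y
  borders of the VOI; a bone cut open sideways would leak its canal into
  the exterior and lose its endosteal surface (logged when foreground
  touches a z face).
* Whether the 85,000-voxel and 300-slice constants refer to downsampled or
  original coordinates is ambiguous in the original description; both are
  exposed as parameters and the defaults assume original z, downsampled
  x/y counts.
* SUV and volume modules trust the input volumes to be quantitatively
  calibrated; no attenuation, partial-volume, or decay corrections are
  applied.
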