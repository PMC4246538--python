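# Methods

`angioct` quantifies the vascular network of a contrast-perfused joint
in high-resolution μCT.  Because perfusion contrast agent and bone have
similar CT values, the analysis is a multi-step procedure: virtual bone
removal, anatomical definition of the analysis volume, hybrid vessel
segmentation inside it, and histomorphometry of the resulting binary
vessel mask.  A digital-phantom harness provides ground truth for
accuracy validation.  This note records the models, the parameters that
matter, and the design choices made where the procedure is genuinely
open.

## Digital vascular-tree phantoms

A phantom is a random binary tree of curved cylindrical segments.  Each
segment is a polyline with a constant radius; a step advances by
`step_length` (default 24 μm) along a direction bent by a curving angle
drawn uniformly from `curving_angle_range` (default 0–20° per step)
about a random perpendicular axis.  With probability
`branch_probability_per_step` (default 0.05) the segment ends in a
bifurcation: the child cross-sectional area fraction is drawn uniformly
in [0.3, 0.7] and radii satisfy `r_p² = r_c1² + r_c2²` exactly, so
total cross-sectional area is conserved through every branch.  A
bifurcation that would produce a child thinner than `min_radius` is
rejected and growth continues; segments terminate at the domain margin.
The minimum radius defaults to one voxel, so the thinnest vessels have
a two-voxel diameter (24 μm at the default 12 μm voxel size) — below
that, a vessel cannot be represented meaningfully on the grid at all.

The defaults — 200³ voxels at 12 μm, root radius 72 μm (so diameters
span ≈24–144 μm, the range over which thickness accuracy is assessed),
and ten models as the standard validation set — are the framework's
standard study conditions.  The angle ranges and branch probability are
not constrained by any physical measurement; they were chosen once to
produce trees that fill a 2.4 mm cube with realistically tortuous,
multi-generation branching.

Rasterization uses the union-of-balls rule on a centerline densified to
half-voxel spacing: a voxel belongs to the vessel iff its center lies
within the local radius (closed ball, `≤`).  The closed ball was chosen
over the open one because it reproduces analytic cylinder volumes much
better at small radii (a radius-3-voxel cylinder rasterizes 2.6% above
the analytic volume instead of 12% below it); the residual bias of
either rule vanishes as resolution grows.

Simulated CT degradation is `blur → noise`: Gaussian blur of the
intensity-coded mask (background 100, vessels 500, arbitrary units)
followed by additive white Gaussian noise.  Defaults: blur σ = 12 μm
(one voxel, a typical point-spread width at this voxel size) and noise
σ = 40 = 10% of the vessel–background contrast.  These two numbers are
the single biggest influence on every accuracy figure the validation
harness produces: thin-vessel intensities are strongly reduced by
partial-volume averaging (a 24 μm vessel peaks far below the nominal
vessel intensity), which is what makes sub-50 μm thickness measurement
hard.  The phantoms emulate geometry, partial volume and noise only —
no beam hardening (a simple exponential near-bone intensity halo can be
added to the bone phantom to emulate it), no projection physics, no
scanner-specific noise correlation.  Consequently, passing phantom
tests demonstrates correctness of the measurement chain under known
geometry, not performance on any particular scanner.

## Virtual bone removal and anatomical VOIs

Bone is segmented by 26-connected volume growing from user seeds with a
threshold re-estimated as `μ_region − 2σ_region` each iteration
(initialized halfway between the volume median and the robust
maximum), followed by a morphological closing (ball radius 3) to fill
intracortical gaps.  A coarse vessel mask — threshold at a fraction
(default 0.6) of the robust maximum, minus components containing bone
seeds — is blocked from the growing so it cannot leak into large
vessels that touch bone.

The knee joint cavity is `VOI_KJC = largest component of
(closing(VOI_TF) \ VOI_TF)`, with `VOI_TF` the tibia+femur union and
the closing ball radius an explicit parameter (default 30 voxels; it
must exceed half the inter-bone gap and is otherwise unconstrained, so
it is always stated with results).  Closings use Euclidean distance
transforms, exactly equivalent to the discrete ball structuring element
`{offset : |offset| ≤ r}` (the test suite verifies equality against
explicit dilation/erosion) but fast for large radii.

The capsule sphere sits at the voxel-count centroid of `VOI_KJC`
(robust to irregular cavity shapes, unlike a bounding-box center) with
radius 2.5 × the cavity bounding-sphere radius; the factor is the
empirical joint-capsule scale of the original procedure.  The capsule
is divided into four concentric shells at equal radial quarters
(configurable boundary fractions; the original partition was empirical
and is not recoverable), each minus bone, and the shells partition the
capsule-minus-bone mask exactly.  Shells clipped away entirely by the
image border or bone report zero volumes rather than aborting.  For the
hybrid segmentation the capsule is split into a near-bone band `VOI_2S`
(voxels within `band_width` voxels of the bone surface, default 10) and
its complement `VOI_1S`.

## Vessel segmentation

**Soft-tissue statistics.**  μ_ST and σ_ST come from a Gaussian fitted
to the dominant mode of the VOI intensity histogram (256 bins; the fit
region is the contiguous run of bins above 20% of the peak, with a
moment fallback for degenerate peaks).  `H_max` is taken as the 99.9th
percentile intensity in the VOI: the defining phrase for it mixes "fit"
and "maximum", but the upper threshold `T_high = 0.65·H_max` must be an
intensity well above `T_low`, which only a robust-maximum reading
provides.  This choice matters: H_max tracks the brightest vessel
cores, so VOIs dominated by thin (partial-volume-dimmed) vessels get a
lower `T_high`.

**LAT** (local adaptive threshold volume growing): seeds are voxels
≥ `T_high`; voxels in `[T_low, T_high)` with `T_low = μ_ST + 2σ_ST` are
accepted when their 26-neighbourhood (center excluded, population SD)
satisfies `σ/μ < α·τ` with `τ = σ_ST/μ_ST` and `α = 1`; the inequality
is strict, so a voxel exactly at the bound is soft tissue.  The result
is the union of 26-connected components of the accepted set containing
a seed.  LAT has no shape prior: it keeps the vessel network connected
but includes the blurred halo around vessels, overestimating volume.

**MS** (multi-scale Hessian vesselness): at each scale σ ∈ {1,2,3,4}
voxels the volume is Gaussian-smoothed, the Hessian is computed by
central differences (reflect boundary) and normalized by σ² — the
standard scale-space normalization used by the ITK multi-scale filters,
without which the smallest scale always dominates the maximum and the
noise response drowns the vessels.  The eigenvalue response for a
bright tube (λ1 ≥ λ2 ≥ λ3, λc = min(−λ2, −λ3)) is

    R_s = λc · exp(−λ1² / (2(α1·λc)²))   for λ1 ≤ 0
    R_s = λc · exp(−λ1² / (2(α2·λc)²))   for λ1 > 0
    R_s = 0                              for λc ≤ 0

with α1 = 0.5, α2 = 2.0.  The leading λc factor follows the common ITK
formulation of this response; a flag drops it to evaluate the bare
exponential.  The scale ladder covers vessel radii of about one to four
voxels and is configurable; the per-voxel maximum over scales is kept.
Eigenvalues come from a closed-form (trigonometric) symmetric-3×3
solver, vectorized over the volume; it matches LAPACK to ~1e-9 and is
what makes 200³ volumes tractable on one core.  Classification is
2-class K-means on the response inside the VOI with deterministic
initialization at the 10th/99th percentiles; the higher-centroid
cluster is vessel.  MS is volume-accurate and robust near bone but
fragments the tree wherever the tubularity signature breaks
(bifurcations, very thin vessels) — an inherent property, reproduced by
the validation study.

**GT** thresholds at `T_high` by default.  **MSLAT** applies LAT in
`VOI_1S` and MS in `VOI_2S` and unions the results, using the shape
prior exactly where beam hardening makes intensities unreliable.
Manual corrections enter only as externally supplied add/remove masks
applied after segmentation.

## Morphometry

`TV`, `VV` and `VV/TV` are voxel counts times the voxel volume.  `VS`
is the marching-cubes isosurface area at level 0.5 with a Gaussian
pre-smoothing of σ = 1 voxel: raw binary meshing overestimates a
digital ball's area by ~8% (staircase bias) while the smoothed mesh is
within 1%; two-voxel tubes still cross the 0.5 level, and if a
structure is thinner than the kernel the raw binary mesh is used so the
surface never vanishes.  `V.Th3D` is twice the Euclidean distance
transform at centerline voxels obtained by 3D thinning (Lee); a
component the thinning erases completely (small even-sided blobs)
contributes its innermost voxel instead, so the skeleton preserves the
26-component count.  The thickness histogram attributes each vessel
voxel's volume to the thickness bin of its nearest centerline voxel
(15 μm bins from 0 by default), so bin volumes sum to VV exactly.

The rod model assumes cylindrical vessels:

    V.Th2D = 4·VV/VS
    V.N2D  = sqrt((4/π)·(VV/TV)) / V.Th2D
    V.Sp2D = V.Th2D · (sqrt((4/π)·(TV/VV)) − 1)

For an ideal cylinder `4·VV/VS` is the exact diameter.  The default
computes these from global 3D totals (reproducible and unit-consistent)
with an optional slice-by-slice variant (per-slice area/Crofton-
perimeter analogues averaged weighted by slice tissue area) for
fidelity to 2D-style histomorphometry.  Vessels are 26-connected and
background 6-connected throughout.

## Validation

The accuracy study generates the standard phantom set (seeded, so
bit-identically reproducible), segments each phantom with each method,
and measures: the vessel volume ratio (measured/true), the 26-component
count (truth is a single connected tree), and thickness accuracy —
every measured centerline voxel is paired with the nearest true
centerline sample (discarded beyond 2 voxels and counted, never
silently dropped) and `|measured − true| / true` is aggregated in 15 μm
true-diameter bins from 24 to 204 μm.  Both absolute and signed
per-bin errors are reported, since either reading of a "difference
from truth" plot is defensible.  Maximum-bin summaries consider only
bins with ≥ 10 pairs.  With ground-truth segmentation the study
returns volume ratio exactly 1 and component count 1, which pins down
the harness itself.

Precision uses `CV_rms`: per subject the coefficient of variation of
replicate measurements (sample SD over mean, in %), root-mean-squared
across subjects.

## Known limitations

* All accuracy figures depend on the chosen degradation defaults; the
  study conditions (10 models, 200³, 12 μm, blur σ = 12 μm, noise = 10%
  of contrast) are fixed as the framework's standard and stated with
  every report.
* At this noise level, `T_high` can sit only ~4σ above the background
  for thin-vessel-dominated VOIs, so a few hundred isolated noise
  voxels exceed it and appear as singleton seed components in LAT and
  GT masks; the vessel tree itself remains one connected component
  (the largest one).  A lower noise-to-contrast ratio removes the
  effect entirely.
* No connectivity repair is attempted on fragmented segmentations, and
  branching metrics (branch counts, segment lengths, bifurcation
  angles) are not computed.
* Bone/vessel seeds are supplied by the user or fixture; there is no
  automatic anatomical landmarking.
* Anisotropic volumes are rejected, not resampled; DICOM is not read.
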