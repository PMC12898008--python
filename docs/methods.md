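# Methods

This note documents the model behind `osteomargin`, the choices made where
the design was genuinely open, and what the synthetic tests do and do not
demonstrate.

## The dangerous region

Let T be the tumor, represented as the set of foreground voxel *centers* of a
binary mask on a grid with per-axis spacing (s₁, s₂, s₃) mm. For a safety
margin m the dangerous region is

    D(m) = { x : min_{f ∈ T} ‖x − f‖ ≤ m },

the Minkowski dilation of the center set by a ball of radius m, measured in
world millimetres. Distances are taken to voxel centers — the simplest
self-consistent discrete reading of "distance from the tumor surface". For
points outside the tumor this differs from a surface-based distance by at
most half a voxel diagonal, which the accuracy analysis below absorbs; the
threshold d ≤ m is inclusive, so a point exactly at the margin counts as
dangerous (conservative for safety).

## Exact anisotropic distance transform

The ADT solves, per voxel v,

    d²(v) = min_f Σᵢ sᵢ² (vᵢ − fᵢ)²

by three separable passes of the lower-envelope (parabola) algorithm on
squared distances, each pass weighted by that axis's spacing squared. The
result is exact up to floating-point rounding; the suite checks it against a
brute-force all-pairs computation (max error < 1e−9 mm on anisotropic grids
up to 20³) and against an independent library implementation. The per-line
kernel is JIT-compiled (numba), giving O(n) work per voxel line.

## Two-resolution combination

Computing the dense map everywhere is wasteful; the sparse map is cheap but
its per-voxel decision can be off by up to half a source voxel diagonal near
the isosurface. The pipeline therefore:

* trusts the **coarse region** (sparse d ≤ m) wholesale, upsampled to the
  dense grid by nearest world position, and
* unions it with the **fine ring**, the dense-grid shell m − b < d ≤ m.

Accuracy argument, with dense spacing = source/2 per axis (the default) and
h = half source voxel diagonal = one dense voxel diagonal:

* *No over-inclusion beyond one dense diagonal*: an upsampled coarse voxel's
  center lies within h of a sparse center with true distance ≤ m, so its own
  true distance is ≤ m + h. Ring voxels have dense-map distance ≤ m measured
  to the resampled solid, which extends at most h beyond the center set, so
  their true distance is ≤ m + h as well.
* *No holes*: any dense voxel with true distance ≤ m − h has a nearest
  sparse neighbour within h, whose distance is then ≤ m, so the coarse
  region covers it.

Hence the dense mask agrees with the exact region everywhere outside a
one-dense-voxel-diagonal shell of the margin isosurface — the property the
oracle tests assert. The ring contributes sub-voxel boundary detail the
upsampled blocks miss.

**Refinement band.** The default band b is one source voxel diagonal. A
narrower band (e.g. half a diagonal) admits *gap shells*: the upsampled
coarse region can stop short of the ring's inner edge (nearest-neighbour
placement error is ±half a source diagonal), leaving thin interior voids
whose walls become spurious boundary points about 1.5 mm inside the
isosurface on the sphere phantom. One full diagonal makes the overlap
unconditional. The band is configurable; correctness of the final mask does
not depend on it, only boundary smoothness does.

**Resampling dialect.** Binary masks are resampled by trilinear
interpolation of the 0/1 indicator followed by thresholding at 0.5 (exact
ties → foreground). For a solid block this reproduces the physical voxel
boundary; corner and edge voxels of the continuous solid are chamfered (the
trilinear field of a separable indicator is the product of per-axis ramps,
0.125 at corners). The output grid keeps the input origin and is the
smallest center-span cover of the input extent. Because the dense map
measures distance to the resampled solid rather than to the original center
set, dense distances can under-read by up to h; the combination analysis
above already accounts for this. A consequence worth stating: refining the
dense spacing below half the source spacing does *not* shrink the
disagreement shell further — the h offset between the two distance readings
is a property of the source voxelization, not of the dense grid.

## ROI padding

The crop extends the tumor's tight bounding box by `pad = m + 20 mm`
(configurable), and the pipeline refuses to proceed if the thresholded
region reaches the crop boundary (`pad-too-small`), which can only happen
when the parent grid itself is too small — truncating the region silently
would understate the dangerous volume.

## Surface reconstruction and the shrink factor

The region's boundary voxel centers (foreground voxels with a background
6-neighbour) are tetrahedralized (Delaunay) and boundary tetrahedra are
peeled in descending circumradius order. The *shrink* parameter in [0, 1]
interpolates the circumradius threshold between the convex hull (0) and the
smallest threshold — found by an incremental union-find pass plus a bisected
feasibility search — at which the kept complex still (a) contains every
input point as a vertex, (b) forms a single face-connected component, and
(c) has an edge-manifold boundary forming a single closed surface (1).
Thresholding is tie-inclusive, so fully degenerate inputs (e.g. cospherical
clouds whose tetrahedra share one circumsphere) fall back to the hull rather
than being carved arbitrarily.

Boundary faces are wound by combinatorial propagation across shared edges,
with the global orientation fixed by requiring positive enclosed volume.
Propagation is used instead of per-tetrahedron geometric tests because
lattice point clouds make qhull emit exactly-degenerate (zero-volume)
tetrahedra for which an outward normal is undefined. Exactly coplanar or
sub-4-point inputs are rejected (`degenerate-geometry`), never jittered —
the pipeline is deterministic end to end.

Point containment (used by the enclosure tests) is computed with the
generalized winding number, which is robust for watertight meshes and
requires no spatial-index dependencies.

## Plane clearance

A cutting plane is given as a point p₀ and unit normal n, with the
convention that the dangerous region must lie in the −n half-space. The
clearance is

    c = − max_{x ∈ ∂D} (x − p₀)·n ,

positive when the whole region clears the plane by c millimetres and
negative (depth of violation) when the plane cuts into it. The maximum of a
linear functional over a region is attained on its boundary, so the boundary
point set suffices. The reported value is exact at dense-voxel resolution;
tolerances of one dense voxel diagonal apply when comparing against
continuum geometry.

## Phantoms

Phantoms voxelize analytic solids by the voxel-center rule (a voxel is
foreground iff its center is inside), keeping oracles exact:

* **sphere** — closed-form volume and dilated volume (4/3)π(r+m)³;
* **ellipsoid** — volume 4/3·πabc; dilated volume from the Steiner formula
  V + S·m + M·m² + (4/3)π·m³ with surface area S and integrated mean
  curvature M obtained by dense trapezoidal quadrature of the fundamental
  forms (error far below the percent-level tolerances it is compared at);
* **two_lobe** — two spheres with the exact union (lens) volume;
* **blob** — a seeded union of 3–7 random ellipsoids clustered in the
  central fifth of the grid (leaving headroom for margin + pad), for
  exercising the ring logic on irregular shapes; reproducible by seed.

The optional bone is a partial spherical shell minus the tumor. Phantoms
emulate geometry only: no anatomy, no image intensities, no segmentation
noise. Passing phantom tests therefore demonstrates geometric correctness of
the pipeline, not robustness to annotation variability.

Voxelized sphere volumes converge to the analytic value as spacing shrinks
(checked at 2 / 1 / 0.5 mm); at radius r the half-voxel surface shell makes
volumes uncertain by roughly 3δ/r relative, which is why percent-level
volume assertions are made at the large-phantom scale (dilated radius 28 mm,
error < 3%) while small smoke-scale checks use proportionally looser bounds.

## Cohort statistics

The 19-patient series ships as two CSV fixtures (demographics/follow-up and
operative/outcome tables) validated on load (19 records, deaths for patients
2 and 6, one missing MSTS for patient 14, margins ∈ {10, 15, 20} mm).
Conventions:

* **Survival** — Kaplan–Meier product-limit (via lifelines), each death
  placed at that patient's recorded follow-up duration, survivors censored
  at theirs; at tied times events precede censorings. Five-year overall
  survival is the right-continuous step function at 60 months.
* **MSTS** — the functional cohort is the 16 surviving limb-salvage
  patients with recorded scores; recovery = score/30 × 100.
* **Marginal subgroup** — the two marginal-resection patients are not
  hard-coded: they are the unique (type I+II, type II+III) pair whose mean
  operative time equals the reported marginal-group mean (367.5 min), found
  by exhaustive search over the eight candidate pairs.
* **Rounding** — half-up at the published precision (integers for
  minutes/mL/months, one decimal for MSTS means, percentages and survival
  × 100).

The recorded mean age of the series is internally inconsistent with the
per-patient ages and is therefore not reproduced.

## Problem sizes used in the checks

Oracle-equivalence runs use 20 seeded random masks of extent ≤ 20³ voxels
with anisotropic spacings in [0.6, 2.5] mm; the analytic-dilation check uses
the radius-8 mm sphere with margin 20 mm on 1 mm source / 0.5 mm dense
grids; monotonicity/containment sweeps margins {0, 5, 10, 15, 20} mm on 72³
phantoms at matched dense grids; surface checks use the unit-cube corners, a
4000-point radius-10 mm sphere cloud, and phantom-region boundary clouds.

## Known limitations

* Distances are to voxel centers; sub-voxel tumor surface geometry is not
  modelled. Accuracy is bounded by the source voxelization (half a source
  diagonal), not by the dense grid.
* Only axis-aligned, diagonal-affine NIfTI geometry is supported; oblique
  acquisitions must be resampled upstream.
* The shrink-factor semantics between 0 and 1 are a monotone interpolation
  of the peeling threshold; intermediate values have no clinical meaning
  beyond "tighter than the hull".
* Single-region scenes: multi-tumor masks are processed as one foreground
  set (one combined region), not per component.
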