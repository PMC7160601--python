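# Methods

This note documents the models, sampling designs and numerical choices
behind `mesoshape`, in the spirit of a stereology methods section.
Units are µm, µm² and µm³ throughout; voxel grids use axis order
(z, y, x) with z the stack ("vertical") axis.

## Synthetic cells and ground truth

The shape factory builds implicit solids and voxelizes them with a
voxel-center membership test: a voxel is foreground iff its center lies
inside the solid. This matches how a binary segmentation of real
microCT data behaves and keeps voxel-count volume exact. Every
voxelization is padded with at least one background voxel per face so
isosurface extraction always closes, and a shape whose narrowest feature
would span fewer than 4 voxels is rejected rather than silently
under-resolved.

Families and closed forms:

- sphere: V = (4/3)πR³, S = 4πR²;
- cylinder (axis z): V = πr²L, S = 2πrL + 2πr²;
- capsule (spherocylinder, tip-to-tip length L ≥ 2r):
  V = πr²(L−2r) + (4/3)πr³, S = 2πr(L−2r) + 4πr²;
- prolate spheroid (a ≥ b, e = √(1−b²/a²)): V = (4/3)πab²,
  S = 2πb²(1 + (a/(be))·arcsin e), degenerating to the sphere at a = b;
- lobed: union of a core capsule and protrusion capsules — no closed
  form; ground truth comes from the isosurface mesh of a voxelization at
  half the working voxel size (provenance `reference_mesh`). The same
  route serves tapered capsules (a rounded cone: the convex hull of a
  base sphere and a smaller tip sphere), used for palisade-like cells.

The default benchmark suite (voxel size 0.5 µm, in the range of
synchrotron microCT of leaf tissue) contains a sphere (R = 10),
a capsule (r = 5, L = 40), a palisade-like tapered capsule
(r = 6, L = 50, tip/base diameter ratio 0.8 — the taper is a free
parameter, defaulting to a mild narrowing), a trilobed body (three
r = 5, L = 20 capsule arms 120° apart), and a body with four long thin
protrusions (r = 2, L = 22) radiating from a capsule core with seeded
placement jitter. These dimensions are typical of angiosperm mesophyll
cells (tens of µm). Seeded runs are bit-reproducible.

## 3D reference measurement

Volume is foreground-voxel count × voxel volume — exact by
construction. Surface is the total triangle area of a marching-cubes
isosurface at the 0.5 level, with physical spacing applied before area
summation. One numerical subtlety dominates here: the isosurface of a
*raw* 0/1 grid is a staircase whose area exceeds a smooth surface's by
roughly 9% regardless of resolution. The binary field is therefore
anti-aliased with a Gaussian of σ = 1 voxel before extraction, which
brings sphere and capsule surface errors below 1% once features span
~20 voxels. This is field smoothing, not mesh smoothing — vertices are
never relaxed, and the (optional, off by default) Laplacian mesh
smoothing flag is not used anywhere in the benchmark. Objects too small
to survive the blur (about one voxel) fall back to the raw staircase
surface, so degenerate inputs still return a positive area.

Connected objects are extracted with 26-connectivity for foreground
(6-connectivity implicitly for background — the standard digital
topology pairing), discarding components under 64 voxels by default.
Watertight external meshes are measured directly: area as Σ triangle
areas, volume as |Σ signed tetrahedra| (translation-invariant).

## Section sampling

"A few random but evenly spaced sections" is implemented as systematic
uniform random (SUR) sampling: period t = (tight foreground extent)/n
along the section axis, start offset u ~ U[0, t), section k = the voxel
slice containing coordinate u + k·t. Sections are nearest-slice — the
binary mask is never interpolated — so a section is always a genuine
voxel slice and empty sections are kept (dropping them would bias
Cavalieri). With one section per slice the Cavalieri sum reproduces the
voxel-count volume exactly, which pins the implementation.

Profile metrics: area by pixel counting; perimeter by the Crofton
(line-intercept) estimate, which is rotation-robust where naive boundary
pixel counting overestimates by up to √2; equivalent radius
r_eq = √(area/π). Length L and width W are caliper extents of the
sub-pixel 0.5-level contour along and perpendicular to the profile's
major principal axis (second-moment orientation, lowest-angle
tie-break). The principal axis is used rather than the farthest
contour-point pair because pixel jitter at flat profile tips tilts the
farthest-pair direction and corrupts W by >10%; on convex elongated
profiles the two definitions of L agree to within a pixel, and on
rasterized discs, rectangles, stadia and ellipses the principal-axis
calipers recover the exact dimensions. When a section contains several
profile components only the largest is measured (single-cell
assumption).

## Estimators

**Geometric models.** All four are fed the same SUR stack's profile
metrics, averaged over nonempty sections before the model is applied
(pooling first, as the classical methods do with measured dimensions):
sphere on r̄_eq; cylinder with r = W̄/2, h = L̄; capsule with r = W̄/2
and tip-to-tip L̄ (sphere fallback, flagged, when L̄ < W̄); prolate
spheroid with a = L̄/2, b = W̄/2 (axes swapped with a flag if needed).
The published variants of these methods differ in detail from one
another; the implementations here are the canonical shape-model forms
and are not claimed to match any specific historical variant number for
number.

**Single-section sphere bias.** Closed form: E[r_c]/Rₛ = π/4, volume
shortfall 1 − (π/4)³ ≈ 52%, surface shortfall 1 − (π/4)² ≈ 38%. The
Monte Carlo verification draws uniformly random sections of a digital
sphere and applies the sphere model to the *pooled mean* radius — the
convention behind the 0.79R/52%/38% statements. Averaging per-draw
volume errors instead would give 1 − 3π/16 ≈ 41% (E[r³] ≠ E[r]³); the
Monte Carlo reports that value as a secondary diagnostic. Because a
random plane offset maps to one of the sphere's ~80 distinct slices,
per-slice metrics are computed once and sampled 10⁵ times — numerically
identical to measuring every draw.

**Projection method.** The silhouette (logical OR along the viewing
axis, a digital stand-in for photographing macerated cells) is aligned
to its major principal axis and treated as a solid of revolution per
pixel-width slab: V = Σπ(wᵢ/2)²Δx; S = Σπ·w̄ᵢ·√(Δx² + (Δwᵢ/2)²) over
slab boundaries plus two end-cap discs. Widths come from the Gaussian
anti-aliased silhouette (σ = 1 px): integer pixel widths jump in whole
pixels and those jumps inflate the slant terms by several percent.
Slabs thinner than 2 px raise a metadata warning, not an error.

**Cavalieri volume.** V̂ = t·ΣAₖ over the SUR stack, areas by pixel
counting or by a random-phase point grid (Aₖ = hits·d²), emulating
manual point counting. The plain sum is the unbiased SUR estimator;
trapezoid end-correction exists behind a flag but is off by default.

**Vertical spatial grid surface.** Vertical sections (planes containing
the z axis, i.e. perpendicular to x or y) with the object's azimuth
about z randomized per replicate; each section carries a cycloid test
grid with one full arch (arc length 8ρ, span 2πρ × 2ρ) per tile of area
a, random phase per stack, and the arch's minor (2ρ) axis parallel to
vertical — the cycloid's arc-length-weighted tangent density is
proportional to the sine of the angle from its minor axis, exactly the
weighting the vertical design needs. Ŝ = 2·t·(a/l)·ΣI with I the
foreground/background crossings along the arcs. Crossings are counted
on the 0.5 level of the Gaussian anti-aliased section (σ = 1.5 px,
bilinear sampling at arc steps ≤ 0.25 px): counting raw staircase
transitions instead registers bursts of spurious crossings wherever an
arc runs near-tangent to pixel jags and inflated sphere estimates by
+31% when measured. With anti-aliasing the digital-pipeline bias on a
40-voxel-radius sphere is +0.5 ± 0.3% (2000 replicates), and a
continuum-geometry Monte Carlo of the identical grid is unbiased
(−0.4 ± 0.7%) — the residual is discretization, not design. Default
ρ = 2 µm gives ≈100 expected intersections on a 10 µm-radius cell at
n = 20, comfortably above the ~30 needed for stable counts. Alternate
tile columns carry mirrored arches (variance reduction only). A grid
coarser than the object returns 0 with a warning flag.

**estimate_all** runs the 3D reference plus all seven estimators on one
object, feeding Cavalieri, the vertical grid and the geometric models
from a single vertical SUR stack (so every section-based method sees the
same material) and the projection method from the same azimuth-rotated
object. Each result reports only its own quantity; the other is NaN.

## Benchmark design

Full factorial: shapes × methods × {volume, surface} × replicates ×
n_sections (default 5 and 20, replicates 20, master-seeded). The
reference for every relative difference, RD = 100·(estimate −
reference)/reference, is the 3D voxel measurement of the same object —
not the analytic truth — mirroring comparisons against automated 3D
image analysis. Replicates vary only section offset, grid phase and
azimuth; voxelizations are fixed, so spread isolates sampling noise.
Summaries report mean/median/SD of RD and the fractions within ±10% and
±25%; the band plot shades exactly those intervals. Azimuth rotation
uses nearest-neighbor resampling (binary-preserving); it can lengthen
the tight extent by one sliver slice, which slightly dilutes
section-radius averages of rotated objects — a real property of digital
SUR sampling, visible as a percent-level shift in geometric-model means
but immaterial to the stereological estimators.

## What the synthetic suite does and does not show

The generator emulates single, already-segmented cells with smooth
implicit boundaries, isotropic voxels and no imaging noise,
partial-volume effects, organelles, or cell–cell contacts. Passing
benchmarks therefore demonstrate the *sampling* properties of the
estimators (unbiasedness, shape-model bias, section-count trade-offs) on
realistic geometries; they do not validate segmentation quality on real
microCT or SBF-SEM data, and real tissue adds variance sources (cell
packing, anisotropic resolution) the suite deliberately excludes.
External data can enter the same benchmark path as labeled TIFF stacks
or watertight OBJ/STL meshes via `load_external_cells`; non-watertight
meshes are skipped with a logged reason.

## Problem sizes and tolerances

Default test and benchmark sizes: spheres/capsules at 0.25 µm voxels
(feature spans of 40+ voxels) for estimator calibration checks; the
five-shape suite at 0.5 µm for the factorial benchmark; 200 offsets for
Cavalieri and 500 replicates for the vertical grid in unbiasedness
checks; 10⁵ draws for the single-section Monte Carlo. At these sizes
the observed accuracies are: voxel-count volume <1%, isosurface surface
<1–3%, Cavalieri mean <1%, vertical-grid mean <2%, geometric model
consistency on matched mid-profiles <0.5%. Master seeds make every
reported number reproducible; with different seeds the stochastic means
move within the quoted Monte Carlo errors.

## Known limitations

- The vertical-grid estimator needs features a few voxels wide; its
  anti-aliasing (σ = 1.5 px) shrinks very thin protrusions (a ~4 px
  radius arm loses ~7% of its local circumference), a small conservative
  bias on protrusion-rich shapes.
- Oblique (isotropic uniform random) section orientations are not
  implemented; sections are axis-aligned with azimuth randomization,
  which is exactly what the vertical design requires but rules out
  IUR-plane estimators.
- The per-section stack spans each object's own extent (per-cell
  sampling), not a fixed tissue window.
- Profile L/W use principal-axis calipers, not the farthest-point Feret
  pair; on strongly concave profiles L can undershoot the true maximum
  Feret diameter by a few percent.
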