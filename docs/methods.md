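# Methods

This note records how `braincast` computes what it computes, the numerical
conventions involved, what the phantom generator does and does not emulate,
and the design choices that were genuinely open.

## Coordinate and grid conventions

A labeled volume is a 3-D integer grid indexed `(i, j, k)` along the world
axes `(x, y, z)`, with per-axis voxel spacing (mm) and the world position of
the centre of voxel `(0, 0, 0)`:

    world = origin + index * spacing

Indices are 0-based and address voxel *centres*. All meshes, transforms and
distances live in world millimetres. The default anatomical reading is
x = left–right, y = dorso-ventral, z = antero-posterior, so "length" is the
z-extent, "width" the x-extent and "height" the y-extent; the mapping is a
parameter, not an assumption.

Files without stated physical spacing (a bare TIFF stack) are refused: voxel
size is metadata the user must assert, never a default the software invents.

## Meshing

Surfaces are extracted by marching cubes at iso-level 0.5 on {0, 1} grids
with linear interpolation, so the surface passes through the half-voxel
midpoints between foreground and background voxel centres — a
resolution-consistent convention under which a digitized ball of radius `r`
voxels meshes to a surface of radius close to `r`. Masks are padded by one
background layer before extraction so surfaces are closed (watertight) even
when foreground touches the grid border; faces are oriented outward (positive
divergence-theorem volume). Meshes are neither smoothed nor decimated: all
measurements are taken on the raw iso-surface, and no smoothing option is
exposed.

Mesh volume is the (absolute) signed volume of the closed surface; open
meshes are a topology error, not a warning. Voxelization (the inverse
operation, needed to compare a mesh against a grid) marks a voxel foreground
iff its centre is inside the mesh, decided by crossing parity of an axis ray.
Ray origins are offset by fixed sub-voxel amounts `0.0625(√2−1)·h` in x and
`0.125(√5−2)·h` in y: the two offsets are irrational and mutually irrational,
so no ray can pass exactly through a mesh edge or vertex (marching-cubes
vertices have half-integer coordinates, all edge lines are rational), which
makes the parity test deterministic without per-case tie handling.

## Registration

Superposition is point-to-surface ICP: each iteration projects the moving
vertices onto the *exact closest points* of the fixed triangulated surface
(not nearest vertices) and solves the closed-form least-squares rigid update
by SVD (Kabsch), with a possible reflection corrected by flipping the
smallest singular direction. Closest-point queries are accelerated by a
KD-tree over triangle centroids: a seed pass over a few nearest centroids
gives an upper bound `u`, and every triangle whose centroid lies within
`u + r_max` (`r_max` = largest centroid-to-vertex radius) is then checked
exactly, so results equal the brute-force minimum — the acceleration is
internal to the contract.

Defaults: centroid-alignment initialization (a principal-axes mode with
heavier-half sign disambiguation is available for grossly mis-oriented
inputs), `max_iter = 100`, convergence when the RMS correspondence distance
changes by less than `tol = 1e-6` mm, no outlier trimming (a trimming
fraction is exposed but defaults to 0 — an organ and its own cavity are
near-superimposed already). With exact correspondences and the optimal
update, the RMS trace is non-increasing; the trace object records it and can
assert it. For meshes above ~5000 vertices a seeded deterministic subsample
drives the update step; the returned transform applies to the full mesh. No
scale is estimated: both structures come from the same specimen and scan.

Registering a surface onto a rigidly moved copy of itself recovers the
transform essentially exactly (≤ 1e-3 degrees/mm for perturbations up to 20°
and half the object diameter; the test suite checks ten random cases).
Registering the *organ* onto the *cavity* is a different problem: the
asymmetric wall-gap field biases the optimum away from the generating
misalignment by a few tenths of a degree and a few hundredths of a
millimetre, an intrinsic property of ICP between non-identical surfaces, not
an implementation error. The phantom tests therefore separate the two
claims: transform recovery is asserted on identical-surface pairs (to 1e-2
degrees/mm at the emulated 16.5 µm scan resolution, where the
re-voxelization noise floor allows it), while the organ-vs-cavity pipeline is
judged on its end metrics (occupancy, maximum gap, hotspot localization),
which tolerate the small registration bias.

## Surface distances

Distances are sampled at the vertices of the source mesh and measured to the
full surface of the target by exact point-to-triangle distance (Voronoi
region case analysis, vectorized; degenerate triangles fall through to the
segment/point cases). Vertex-to-vertex distances would systematically
overestimate and are not used. "Absolute" means unsigned — no inside/outside
sign is attached.

The symmetric mean absolute distance is the mean of the *pooled* per-vertex
sets of both directions; the symmetric max is the larger of the two directed
maxima (the vertex-sampled symmetric Hausdorff distance). Pooling, rather
than averaging the two directed means, was an open choice; both directed
means are retained in the report so either reading can be reconstructed. No
area weighting is applied by default (marching-cubes vertices are nearly
uniform on the surface); the per-vertex sets are exported for any custom
weighting. The vertex-sampled max is a lower bound on the continuous
Hausdorff distance; the gap is bounded by one source-mesh edge length, which
the suite verifies by subdividing the source mesh.

Distance maps store the *unclipped* per-vertex distances as the mesh's
scalar channel (PLY `quality`); clipping affects only the colour mapping.
Two presets mirror standard practice for brain–endocast figures: the full
range [0, 0.59] mm and a low-range view [0, 0.25] mm that resolves the small
gaps; darkest colour = contact, warmest = clip maximum.

## Overlap and morphometrics

Dice is computed on the fixed (cavity) grid after nearest-neighbour
resampling of the registered organ mask — exact voxel counting on a common
grid, cross-checkable against the mesh route (`voxelize_mesh`). The
occupancy denominator is the *cavity* volume (the fraction of endocranial
space filled), and organ voxels protruding outside the cavity are reported
as a QC count. Extents are bounding-box spans of foreground voxel centres
plus one spacing per axis (matching the iso-0.5 surface extent; a single
voxel reports one spacing). Regional length fractions divide each brain
division's antero-posterior span by the whole organ's span, measured along
the straight AP axis (not the curved neuraxis — a known simplification).
Overlapping spans are either reported raw (sums may exceed 100 %) or
partitioned at the midpoints of the overlaps so fore/mid/hindbrain sum to
100 %; partition is the default and the reported mode.

Reports serialize with fixed key order and fixed float formatting (`%.9g`),
so identical inputs give byte-identical JSON.

## The phantom generator

The generator emulates the situation the pipeline exists for: a small lobed
lungfish-like brain nested in an endocranial cavity that fits tightly over
the forebrain and labyrinth and loosely over the midbrain and the dorsal
spinal-cord region. Its defaults encode that morphology: organ length 6.0 mm
with fore/mid/hindbrain AP spans near 40/10/50 %, width 3.1 mm across the
labyrinth lobes, height 1.7 mm, wall clearance ~0.04 mm over tight regions,
~0.2 mm over the midbrain band, and a dorsal posterior hotspot whose
clearance is clamped at 0.59 mm; the resulting cavity occupancy comes out a
little above four fifths (≈ 80 %). None of these numbers is fitted at run
time — they are construction inputs, and every truth value is obtained by
exact voxel counting.

Construction: lobes are superellipsoids evaluated analytically at voxel
centres (overlaps resolved by the smallest normalized lobe value); the
clearance field is a smoothed per-group AP profile plus a Gaussian hotspot
bump plus seeded band-limited noise, clamped to [0, 0.59] mm; the cavity is
the organ generalized-dilated by that field (Euclidean distance transform
thresholded against it), hence a guaranteed superset of the unmisaligned
organ. The hotspot amplitude (1.0 mm before clamping) deliberately exceeds
the clamp so a *plateau* of 0.59 mm clearance forms around the peak — this
makes the realized maximum gap hit 0.59 mm robustly instead of depending on
where the growing cavity surface happens to intersect a decaying bump. The
generator also designates its large-gap region (clearance ≥ 0.12 mm, dilated
two voxels) as part of the truth, so distance-map hotspot localization can
be scored. The emitted organ volume is evaluated analytically in the
misaligned frame — no resampling — so the true misalignment transform is
exact and the same seed reproduces bit-identical volumes.

Default spacing is 0.04 mm. The emulated scan was acquired at 16.5 µm; the
package default is ~2.4× coarser so that the ten-phantom validation battery
(generation plus full pipeline per seed) completes in a few minutes on one
CPU. Resolution-sensitive claims (the 1e-2-degree misalignment recovery) are
tested at `spacing=0.0165` directly. Phantoms at any spacing are available
through `PhantomSpec`.

What the phantom does *not* emulate: semicircular-canal tori (labyrinth
lobes are plain ellipsoid pairs), nerve canals and foramina in the cavity
wall, segmentation noise or staining-contrast artefacts, grayscale CT data,
and anatomically realistic lobe shapes beyond counts, positions and
proportions. Passing the phantom battery therefore demonstrates the
*pipeline's* correctness on known geometry, not robustness to segmentation
error in real material.

## Numerical choices and degenerate inputs

* Kabsch requires ≥ 3 non-collinear pairs; collinearity is detected via the
  second singular value and rejected (the rotation is unidentifiable).
* Connected-component cleanup defaults to 26-connectivity (most permissive,
  avoids splitting thin canals); size ties are broken toward the component
  containing the lexicographically smallest voxel, for determinism.
* Dice of two empty masks is an error (0/0), not zero; occupancy with an
  empty cavity likewise.
* Degenerate (zero-area) triangles are legal everywhere: they contribute
  zero area and behave as segments/points in distance queries.
* Empty label selections produce a warning and an empty mask; operations
  that cannot proceed on empty input (meshing, extents, components) raise.
* Marching-cubes meshes of anisotropic grids use the true per-axis spacing;
  nothing assumes isotropy.

## Validation problem sizes

The shipped suite runs, on one CPU: analytic fixtures at ≤ 130³ voxels;
ICP recovery on a ~640-vertex asymmetric blob (ten random transforms);
meshing fidelity on a radius-20-voxel digitized sphere; ten default phantoms
(~2.3 M voxels each) through the complete pipeline; and one phantom at the
full 16.5 µm emulated scan resolution (~61 M voxels) for the
misalignment-recovery bound. These sizes are the package's validation
choices; all generators accept larger grids.

## Known limitations

* Occupancy and Dice inherit a small negative bias (≲ 1 percentage point at
  the default spacing) from nearest-neighbour resampling of the registered
  organ mask in tight-contact regions.
* The vertex-sampled symmetric max underestimates the continuous Hausdorff
  distance by up to one mesh edge length.
* Regional fractions are straight-axis spans; strongly curved neuraxes would
  need a centreline parameterization that is out of scope.
* ICP between non-identical surfaces converges to a gap-weighted optimum,
  not to the generating misalignment; see the registration section.
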