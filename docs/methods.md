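# Methods

This note documents the models and numerical choices behind `meshunwrap`,
in the order the pipeline applies them, together with what the synthetic
fixtures do and do not establish.

## Discrete operators

The mass matrix is barycentric (lumped): each diagonal entry is one third
of the total area of the faces incident on the vertex, so the matrix trace
equals the surface area exactly. The Laplacian uses standard FEM cotangent
weights, assembled positive semi-definite with zero row sums; the implicit
flow systems therefore read `(M + δt·L) v' = M v`. The `robust` kind
applies intrinsic mollification: all edge lengths are inflated just enough
that every triangle satisfies the triangle inequality with a margin of
`1e-5` times the mean edge length, which keeps cotangents finite on
near-degenerate faces without changing the mesh.

## Conformalized mean curvature flow

cMCF freezes the Laplacian at its initial assembly; the mass matrix is
rebuilt every iteration. After each implicit step the surface is rescaled
to unit total area and recentered at the origin. The flow runs in this
unit-area frame throughout: the per-motif time steps (`δt = 5e-4` for
bleb- and lamellipodium-class surfaces, `1e-5` for ruffle-class) are
meaningful only under that normalization, because the relative stiffness
`δt·L/M` scales with vertex count over surface area. Callers get
snapshots in the unit-area frame; the pipeline rescales the selected
snapshot so its enclosed volume matches the input's before voxelization.
Volume matching (not area matching) is deliberate: protrusions carry
substantial extra area, and an area-matched cortex proxy would inflate
past the cell body and absorb most of the protrusion height.

**Automatic stopping.** The reference (cortical) shape is the elbow of
the mean absolute Gaussian curvature `K̄(t)` (angular-deficit curvature,
averaged over vertices), not the spherical limit. The rule implemented:
stop at the first iteration where `|ΔK̄| < Δ_thresh` *or* `ΔK̄ > 0`
(curvature stops decreasing), bounded below by `t_min`. A strict-literal
mode that triggers only on `ΔK̄ > Δ_thresh` is available behind a flag;
on monotone decays it never fires and returns the final iteration, which
is why the elbow reading is the default.

## Voxelization and remeshing

Faces are midpoint-subdivided until the mean edge is below one voxel;
barycenters are rasterized; the binary is closed by dilate(ball r) → fill
→ erode(ball r). Because the rasterized shell straddles the true surface,
the shell voxels whose centers lie on the outer side (sign test against
the nearest face normal) are removed afterwards, so the foreground
approximates the set of voxel centers inside the mesh and volumes are
unbiased (a radius-10 ball voxelizes to within ~2% of `4πr³/3`; without
the correction the bias is +16% at that radius). Grids are padded by
`max(r+2, 4)` voxels so morphology never touches borders.

Meshing back uses marching cubes at isovalue 0.5 after Gaussian `σ = 1`
smoothing of the binary, keeps the largest connected component, and
remeshes by uniform vertex clustering: seeds drawn with probability
proportional to vertex area, a few Lloyd iterations of nearest-seed
assignment (KD-tree), cluster centers snapped back to the surface, and
one output face per input face whose corners land in three distinct
clusters. This is not a faithful approximated-centroidal-Voronoi
implementation, but it meets the same contract on dense inputs:
prescribed vertex count within a few percent, median radius-ratio
(2·r_in/r_circ) ≥ 0.7, near-equilateral faces. Occasional clustering
defects (slit holes) are closed by centroid fan-fill; if the result of an
aggressive decimation is still not watertight the remesh retries with a
different seeding and then a gentler fraction.

## Spherical parameterization

Genus is checked first via the Euler characteristic. The map to the unit
sphere runs cMCF to (near) its spherical limit — for genus-0 surfaces the
flow converges conformally — then projects vertices radially and applies
inversive (Möbius) centering so the area-weighted centroid sits at the
origin; the centering maps the sphere to itself and does not disturb
angles. If inverted spherical triangles remain the flow is extended, and
isolated survivors are resolved by local Tutte-style smoothing (flipped
faces and their one-ring move to the normalized neighbor average).
Defaults (`δt = 0.01`, 30 iterations in the unit-area frame) were chosen
as the point where the measured conformal error of smooth reference
fixtures saturates at its discretization floor (~1.003–1.01 at 10–25k
vertices); larger steps neither help nor harm.

## Equiareal relaxation

Per iteration: normalize face areas of the reference and the sphere;
`λ_f = a_ref/a_sphere`; average λ to vertices (area-weighted) and take
the per-face gradient of `log λ`; `V = −∇ log λ`; rescale V so its median
norm equals the mean edge length of the *sphere* mesh (the space being
advected); average V to vertices, project onto the tangent plane using
angle-weighted vertex normals; advect by one active-contour cMCF step
(`(M + δ·L) v' = M (v + ε·V)`, operators rebuilt on the current sphere);
recenter and renormalize to the unit sphere. Defaults `ε = 1`,
`δ = 0.1`, at most 100 iterations, with a `δ = 5e-3` retry on collapse.

Collapse is declared on any inverted spherical triangle, non-finite
vertex, or minimum interior angle below 0.5° — except that meshes which
*already* contain slivers below 0.5° get a floor of half their initial
minimum angle, otherwise the loop could never start on real remeshed
surfaces.

Stopping criteria: `equiareal` (first iteration with
`|median λ − 1| < 0.01`), `conformal_mips` (iteration 0 — the initial
map is conformal and `σ₂/σ₁ + σ₁/σ₂` is minimal there), `isometric_sum`
(argmin of `(1−θ)·𝒬 + θ·mean(ln λ)`, with the mean of `ln λ` rather than
`ln` of the mean so expansion and shrinkage are penalized symmetrically),
and `area_mips` (argmin of the area-preserving aggregate).

## Distortion accounting

Mesh-to-mesh: both triangles of each face correspondence are flattened
isometrically into 2D, the affine map between them is solved, and its
singular values give `𝒬_i = σ₂/σ₁ ≥ 1`. The global `𝒬` is the
source-area-weighted mean over faces with finite `𝒬_i`; infinite values
(collapsed targets) are excluded from the mean but counted and reported.
`λ_i` compares normalized area fractions, so it is scale-free, and its
per-face product under direction swap is exactly 1. One convention note:
the relaxation loop orients `λ = a_ref/a_sphere` (values < 1 mean the
sphere over-represents the region); reports state this orientation.
For UV grids the same quantities come from the Jacobian
`[∂S/∂u, ∂S/∂v]` by central differences, periodic in u; the differential
area `dA = |∂S/∂u × ∂S/∂v|` is also the weight for corrected averaging of
pulled-back signals.

Mesh comparison: Chamfer distance is the symmetric mean nearest-vertex
distance; the sliced Wasserstein-1 uses the max-sliced estimator with 50
seeded random projections averaged over 10 repeats (quantile-matched when
vertex counts differ); ΔA% from summed face areas; ΔV% from voxelized
volumes.

Mean curvature is measured volumetrically: `H = −½ ∇·(∇Φ/|∇Φ|)` with Φ
the signed distance transform (positive inside) of the voxelized surface,
sampled at vertices trilinearly. Convex protrusions score `H > 0`; a
radius-R ball scores `+1/R` within 15% for R between 8 and 24 voxels.
This is less sensitive to mesh quality than discrete differential
geometry at the cost of voxel-scale smoothing.

## Equirectangular UV mapping

Convention (fixed): rows are the polar angle `v ∈ [0, π]` with the north
pole at row 0, columns the azimuth `u ∈ [−π, π]`, point
`(sin v cos u, sin v sin u, cos v)`; grids are `N × (2N+1)` with an exact
duplicate seam column. The aspect 2:1 preserves the equator-to-meridian
length ratio. Pixels are located on the spherical mesh by central
projection (the mesh is star-shaped about the origin after centering):
KD-tree candidates over face centroids, exact ray-triangle barycentrics,
lowest-index tie-break. The unwrapping axis comes from weighted PCA of
the spherical vertex positions (weights: |mean curvature| of the
reference by default); the smallest-eigenvalue eigenvector becomes the
new z-axis through a proper rotation (sign-fixed eigenvectors, third axis
by cross product). Eigenvalue ties within 1e-6 relative fall back to the
identity rotation, since any axis is equivalent by symmetry.

Spherical padding for image-space operations wraps columns and reflects
rows across the poles with a flip in u.

## Topographic space

The `(u,v)` reference shell is propagated by explicit Euler steps of
`α = 0.5` voxels along the unit gradient of the signed distance function
of the reference volume, outward until the input surface is enclosed
(automatic `D_out` from the maximum exterior distance of input vertices,
plus margin) and inward for `D_in` steps. Each new shell's coordinate
images are smoothed with a separable 5-pixel box filter (wrap in u) to
suppress the characteristic instabilities of normal propagation; shells
beyond the medial axis may still collide — this is detected only as a
warning, not untangled. Volumes resample through the `(d,v,u) → (x,y,z)`
lookup trilinearly. The topographic binary is meshed *without* padding,
so foreground that reaches the array boundary stays open and the mesh is
the topographic height sheet rather than a closed box; `topographic cMCF`
flattens such sheets with 1D line operators on the boundary loop whose
u,v force components are cancelled (no-flux), letting boundary vertices
move only in depth.

## Protrusion segmentation

The reference depth image `d_ref(u,v)` is the asymmetric-least-squares
(2D Whittaker) baseline of the depth image `d = f(u,v)` (top index of
the longest contiguous foreground run per column): weights `p = 0.25`
above / `0.75` below, Laplacian penalty `λ = 1`, 10 reweighting
iterations, solved at 8× downsampling. The Laplacian uses Neumann
boundary rows (zero row sums), since Dirichlet-like end rows drag the
baseline toward zero at the image border. Protrusion height is
`h = d − d_ref`; the binary segmentation thresholds at the mean height,
removes components under 200 voxel² of Cartesian area, diffuses with
two-class label spreading (20 iterations, clamping 0.99, re-binarization
threshold 0.25), and removes components under 500 voxel².

**Label spreading semantics.** The clamping factor is implemented as
seed-confidence retention: `F ← (1−c)·S F + c·Y` with `c = 0.99` and `S`
the symmetrically normalized affinity. Seeds effectively hold their
label; unlabeled vertices adopt the affinity-weighted consensus of their
neighborhood. The alternative reading (`F ← c·S F + (1−c)·Y`) makes the
binary front grow by one mesh ring per iteration at the 0.25 threshold
regardless of the affinity values, which destroys the segmentation on
fixtures (measured vertex IoU against planted truth drops from 0.71 to
0.37); the retention reading is also what "clamping" denotes in
semi-supervised label propagation. Because finite iterations reach at
most one graph ring per iteration, the instance stage is completed to its
convergence limit afterwards: still-unlabeled vertices of binary
components that contain at least one seed take the label of their nearest
labeled vertex; seedless components stay background.

The affinity is restricted to mesh edges (one-ring):
`A = γ·A_dist + (1−γ)·A_conv`, `γ = 0.9`, with Gaussian kernels on edge
length and on the cosine distance `(1 − cos θ_ij)/2` of neighboring
vertex normals, bandwidths `μ(D)` equal to the mean of the included
off-diagonal entries. Instance seeds come from 3-class clustering of the
smoothed topographic mean curvature over surface-shell voxels (k-means on
a `σ = 1` feature for blebs/filopodia; a Gaussian mixture on `σ = 1,3,5`
features for lamellipodia; 10,000 seeded samples), keeping the
highest-mean class, dropping components under 500 voxels, expanding 3
voxels, and masking by the binary segmentation.

Under-segmented blebs are refined per label: interior holes imputed
(complement components below 10% of total area), the submesh unwrapped to
a 128² square (harmonic disk map with arc-length boundary, explicit
equiareal relaxation with inversion rejection, elliptical-grid
disk-to-square), the pulled-back curvature thresholded at the upper
3-class Otsu level, and conjoined pseudo-circular regions split by
watershed on the smoothed Euclidean distance transform (peaks at least
N/8 apart and 60% of the maximum depth; basins under 5% of the label
ignored). Splits are re-diffused on the full mesh and re-masked.

Volumization: surface labels are rasterized (3-voxel expansion, masked by
the topographic binary), propagated top-to-bottom by slice-wise marker
watershed on each slice's distance transform with previous-slice labels
taking precedence, masked by the inpainted reference cortical volume
(biharmonic inpainting of `d_ref` holes; fast-marching inpainting would
serve equally), and reduced to the largest connected region per label.

## Synthetic fixtures

Fixtures are icospheres (subdivision 4, 2562 vertices; base radius 32–72
voxels) displaced radially by planted motifs at rejection-sampled centers
whose pairwise angular separation exceeds 1.6× the sum of their widths:
blebs are flattened hemispherical caps `√(1 − (θ/w)⁸)` with a sharp neck,
lamellipodium-like ridges are elongated tangential Gaussians, and
filopodium-like spikes are narrow caps at 3× amplitude. Ground truth
labels vertices whose dominant motif displaces them above 50% of its
amplitude. All randomness flows through one seed; identical specs are
bit-identical. Matched binary volumes come from the voxelizer and the
intensity channel is a ±2-voxel cortical shell.

The experiment conditions are sized for a single CPU core: instance-count
experiments plant 5–12 blebs of width 0.26 rad on radius-40 spheres (caps
~700 voxel², comfortably above the printed 500 voxel² filter — at the
fixture scale that filter is a few bleb diameters, whereas on real
light-sheet cells it is a small fraction of any protrusion); the
area-recovery experiment plants five self-similar blebs spanning ~10× in
area on a radius-72 sphere, keeping the widest below ~0.36 rad because
wider structures are partially absorbed into the ALS baseline at the
printed regularization (a genuine regime limit of the method, visible in
any implementation).

What the fixtures do *not* model: segmentation noise, non-manifold
defects beyond the planted hole/handle generator, overhanging protrusion
geometry (radial displacement cannot overhang), anisotropic voxels, and
intensity photophysics. Passing tests therefore establish the geometric
correctness and internal consistency of the pipeline, not its performance
on raw microscopy.

## Known limitations

- Spherical parameterization by flow+projection can fail (flipped faces)
  on extremely high-genus-like spikes; the pipeline surfaces this as a
  structured error naming the residual defect.
- Equiareal relaxation is limited by mesh quality; on slivered inputs it
  stops at collapse and reports the last valid iteration.
- Topographic shells are not untangled past the medial axis.
- The ALS reference absorbs protrusions wider than a few downsampled
  pixels, bounding the detectable protrusion scale from above.
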