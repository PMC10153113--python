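"""Unsupervised protrusion segmentation in topographic space.

The pipeline: (1) infer a smooth reference depth image d_ref(u, v) from
the topographic binary with an asymmetric-least-squares (Whittaker)
baseline, (2) threshold protrusion height h = d - d_ref at its mean and
diffuse the binary with graph label spreading, (3) seed instances from
high-mean-curvature clusters of surface voxels, diffuse them through a
combined geodesic-distance / convexity affinity, and (4) optionally refine
conjoined bleb labels through per-protrusion disk/square unwrapping and a
distance-transform watershed.  Volumization propagates surface labels
through depth slice-by-slice and partitions the cell volume into cortex
plus per-protrusion volumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import ndimage
from scipy.sparse.csgraph import connected_components

from .mesh import SurfaceMesh, boundary_loop, surface_topology

log = logging.getLogger(__name__)


# ------------------------------------------------------------------ heights
def uv_height_image(topo_binary: np.ndarray) -> np.ndarray:
    """Depth image d = f(u, v): top index of the longest foreground run.

    ``topo_binary`` has axis order (d, v, u).  Columns without foreground
    get value 0 (counted in the log).
    """
    b = np.asarray(topo_binary, bool)
    if not b.any():
        raise ValueError("empty topographic binary")
    D = b.shape[0]
    nv, nu = b.shape[1:]
    # run-length encode along d, with run ids unique per (v, u) column
    padded = np.concatenate([np.zeros((1, nv, nu), bool), b], axis=0)
    starts = b & ~padded[:-1]
    run_id = np.cumsum(starts, axis=0) * b           # 0 outside runs
    col = np.broadcast_to(np.arange(nv * nu).reshape(1, nv, nu), b.shape)
    gid = (run_id + col * (D + 1))[b]                # global run id per voxel
    colv = col[b]
    dv = np.broadcast_to(np.arange(D)[:, None, None], b.shape)[b]
    uids, inv, counts = np.unique(gid, return_inverse=True,
                                  return_counts=True)
    ucol = uids // (D + 1)
    # longest run per column: lexsort by (column, length) and take the last
    order = np.lexsort((counts, ucol))
    best_per_col = np.zeros(nv * nu, dtype=np.int64)
    best_per_col[ucol[order]] = uids[order]
    # top d-index of the winning run
    out_flat = np.zeros(nv * nu, dtype=float)
    on_best = gid == best_per_col[colv]
    np.maximum.at(out_flat, colv[on_best], dv[on_best])
    out = out_flat.reshape(nv, nu)
    n_empty = int((~b.any(axis=0)).sum())
    if n_empty:
        log.info("%d (u,v) columns with no foreground", n_empty)
    return out


@dataclass
class ALSConfig:
    p: float = 0.25
    lambda_reg: float = 1.0
    iterations: int = 10
    downsample: int = 8

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError("asymmetry p must be in (0, 1)")


def _laplacian_2d(shape: tuple[int, int]) -> sp.csr_matrix:
    ny, nx = shape
    def lap1(n):
        # Neumann ends: row sums zero, so flat baselines are unpenalized
        main = np.full(n, -2.0)
        main[0] = main[-1] = -1.0
        return sp.diags([np.full(n - 1, 1.0), main,
                         np.full(n - 1, 1.0)], [-1, 0, 1])
    return (sp.kron(lap1(ny), sp.eye(nx)) + sp.kron(sp.eye(ny), lap1(nx))).tocsr()


def als_baseline(height: np.ndarray, cfg: Optional[ALSConfig] = None
                 ) -> np.ndarray:
    """2D asymmetric least squares baseline (Whittaker smoother).

    Solves argmin_z sum w (z - d)^2 + lambda ||Lap z||^2 with w = p above
    the baseline and 1 - p below, re-assigning weights each iteration.
    """
    cfg = cfg or ALSConfig()
    img = np.asarray(height, dtype=float)
    if not np.isfinite(img).all():
        raise ValueError("height image must be finite")
    from skimage.transform import resize

    small_shape = (max(img.shape[0] // cfg.downsample, 4),
                   max(img.shape[1] // cfg.downsample, 4))
    small = resize(img, small_shape, order=1, anti_aliasing=True,
                   preserve_range=True)
    d = small.ravel()
    L = _laplacian_2d(small_shape)
    P = cfg.lambda_reg * (L.T @ L)
    z = d.copy()
    for _ in range(cfg.iterations):
        w = np.where(d > z, cfg.p, 1.0 - cfg.p)
        A = sp.diags(w) + P
        z = spla.spsolve(A.tocsc(), w * d)
    return resize(z.reshape(small_shape), img.shape, order=1,
                  preserve_range=True)


@dataclass
class HeightField:
    height: np.ndarray            # h = d - d_ref per vertex
    d_ref: np.ndarray             # reference depth image
    raw_depth_image: np.ndarray   # d = f(u, v)


def protrusion_height(topo_mesh: SurfaceMesh, d_ref: np.ndarray,
                      raw_depth: Optional[np.ndarray] = None) -> HeightField:
    """Per-vertex height h = d - d_ref(u, v), d_ref sampled bilinearly.

    Topographic vertices are ordered (d, v, u); (v, u) index the reference
    image.
    """
    if topo_mesh.representation_tag != "topographic":
        raise ValueError("mesh must be topographic")
    img = np.asarray(d_ref, dtype=float)
    coords = topo_mesh.vertices[:, 1:].T
    ref = ndimage.map_coordinates(img, coords, order=1, mode="nearest")
    h = topo_mesh.vertices[:, 0] - ref
    return HeightField(h, img,
                       img if raw_depth is None else np.asarray(raw_depth))


# ------------------------------------------------------------------ affinity
@dataclass
class AffinityMatrix:
    matrix: sp.csr_matrix
    gamma: float


def _edge_list(mesh: SurfaceMesh) -> np.ndarray:
    e = np.concatenate([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]],
                        mesh.faces[:, [2, 0]]])
    return np.unique(np.sort(e, axis=1), axis=0)


def build_affinity(mesh: SurfaceMesh, gamma: float = 0.9) -> AffinityMatrix:
    """One-ring affinity A = gamma A_dist + (1 - gamma) A_convex.

    A_dist uses the Gaussian kernel of edge lengths with bandwidth mu(D),
    the mean of the included entries; A_convex the same kernel on the
    cosine distance (1 - cos theta_ij) / 2 of neighboring vertex normals.
    Diagonals are 1.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be in [0, 1]")
    edges = _edge_list(mesh)
    i, j = edges[:, 0], edges[:, 1]
    n = mesh.n_vertices

    ddist = np.linalg.norm(mesh.vertices[i] - mesh.vertices[j], axis=1)
    mu_d = max(float(ddist.mean()), 1e-12)
    a_dist = np.exp(-ddist**2 / (2.0 * mu_d**2))

    normals = mesh.vertex_normals()
    cosang = np.einsum("ij,ij->i", normals[i], normals[j])
    dconv = 0.5 * (1.0 - np.clip(cosang, -1.0, 1.0))
    mu_c = max(float(dconv.mean()), 1e-12)
    a_conv = np.exp(-dconv**2 / (2.0 * mu_c**2))

    vals = gamma * a_dist + (1.0 - gamma) * a_conv
    # keep strictly positive: kernel underflow on extreme edges would
    # disconnect the diffusion graph
    vals = np.maximum(vals, 1e-12)
    rows = np.concatenate([i, j, np.arange(n)])
    cols = np.concatenate([j, i, np.arange(n)])
    data = np.concatenate([vals, vals, np.ones(n)])
    A = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    return AffinityMatrix(A, gamma)


def _normalized_graph(A: sp.csr_matrix) -> sp.csr_matrix:
    d = np.asarray(A.sum(axis=1)).ravel()
    dinv = 1.0 / np.sqrt(np.maximum(d, 1e-300))
    Di = sp.diags(dinv)
    return (Di @ A @ Di).tocsr()


def label_spread(A: sp.csr_matrix, seed_labels: np.ndarray, iterations: int,
                 clamp: float = 0.99,
                 rebinarize_threshold: Optional[float] = None) -> np.ndarray:
    """Semi-supervised label spreading over a sparse affinity graph.

    ``seed_labels``: integers, 0 = unlabeled.  The clamping factor is the
    seed-confidence retention: each update mixes the diffused probabilities
    with the seed indicator as F <- (1 - clamp) * S F + clamp * Y, so seeds
    hold their class while unlabeled vertices adopt the affinity-weighted
    consensus of their neighborhood.  Returns the argmax class per vertex
    (0 where no seed influence reaches).  When ``rebinarize_threshold`` is
    set (binary stage), the foreground probability is re-thresholded at the
    start of every iteration.
    """
    S = _normalized_graph(A)
    if rebinarize_threshold is not None:
        Y = (seed_labels > 0).astype(float)
        F = Y.copy()
        for _ in range(iterations):
            F = (F >= rebinarize_threshold).astype(float)
            F = (1.0 - clamp) * (S @ F) + clamp * Y
        return (F >= 0.5).astype(np.int64)
    classes = np.unique(seed_labels[seed_labels > 0])
    Y = np.zeros((len(seed_labels), len(classes)))
    for c_idx, c in enumerate(classes):
        Y[seed_labels == c, c_idx] = 1.0
    F = Y.copy()
    for _ in range(iterations):
        F = (1.0 - clamp) * (S @ F) + clamp * Y
    out = classes[np.argmax(F, axis=1)]
    out[F.max(axis=1) <= 0] = 0          # untouched by any seed
    return out


# ------------------------------------------------------------------ binary seg
@dataclass
class LabelField:
    labels: np.ndarray
    provenance: str = "topographic"
    areas: Dict[int, float] = field(default_factory=dict)
    volumes: Dict[int, float] = field(default_factory=dict)


def _vertex_components(mesh: SurfaceMesh, mask: np.ndarray) -> np.ndarray:
    """Connected components (1-based) of the masked vertex subgraph."""
    edges = _edge_list(mesh)
    keep = mask[edges[:, 0]] & mask[edges[:, 1]]
    e = edges[keep]
    n = mesh.n_vertices
    g = sp.coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
    _, lab = connected_components(g, directed=False)
    out = np.zeros(n, dtype=np.int64)
    ids = np.unique(lab[mask])
    for k, c in enumerate(ids, start=1):
        out[(lab == c) & mask] = k
    return out


def _component_filter(mesh: SurfaceMesh, mask: np.ndarray,
                      vertex_area: np.ndarray, min_area: float) -> np.ndarray:
    comp = _vertex_components(mesh, mask)
    out = mask.copy()
    for c in range(1, comp.max() + 1):
        m = comp == c
        if vertex_area[m].sum() < min_area:
            out[m] = False
    return out


def binary_segment(h: HeightField, A: AffinityMatrix, mesh: SurfaceMesh,
                   vertex_area: np.ndarray,
                   min_seed_area: float = 200.0,
                   min_final_area: float = 500.0,
                   alpha: float = 1.0) -> LabelField:
    """Binary protrusion segmentation: threshold h at its mean, size-filter,
    diffuse with label spreading, size-filter again.

    ``alpha`` is the Cartesian voxel size of one depth step, used to state
    the flat-surface rule in voxels: when the mean height is below half a
    voxel and the 95th percentile below 2 voxels the segmentation is empty.
    """
    hv = np.asarray(h.height, dtype=float)
    hbar = float(hv.mean())
    if hbar * alpha < 0.5 and float(np.percentile(hv, 95)) * alpha < 2.0:
        log.warning("flat surface: empty binary segmentation")
        return LabelField(np.zeros(len(hv), dtype=np.int64), "topographic")
    seed = hv >= hbar
    seed = _component_filter(mesh, seed, vertex_area, min_seed_area)
    labels = label_spread(A.matrix, seed.astype(np.int64), iterations=20,
                          clamp=0.99, rebinarize_threshold=0.25)
    fg = labels > 0
    fg = _component_filter(mesh, fg, vertex_area, min_final_area)
    return LabelField(fg.astype(np.int64), "topographic")


# ------------------------------------------------------------------ instances
def instance_segment(topo_H: np.ndarray, topo_binary: np.ndarray,
                     mesh: SurfaceMesh, binary_seg: LabelField,
                     A: AffinityMatrix, vertex_area: np.ndarray,
                     mode: str = "bleb_filopodia", seed: int = 0,
                     min_voxels: int = 500, min_area: float = 100.0,
                     max_samples: int = 10_000) -> LabelField:
    """Curvature-seeded instance segmentation of protrusions.

    Clusters mean curvature over the surface shell voxels (k-means for
    blebs/filopodia with sigma=1 smoothing, a Gaussian mixture on multi-
    scale sigma=1,3,5 features for lamellipodia; 3 classes), keeps the
    highest-mean class, labels its connected components as seeds, expands
    and transfers them to the mesh, and diffuses with label spreading
    masked by the binary segmentation.
    """
    b = np.asarray(topo_binary, bool)
    ball = ndimage.generate_binary_structure(3, 1)
    shell = ndimage.binary_dilation(b, ball, iterations=2) & \
        ~ndimage.binary_erosion(b, ball, iterations=2)
    H = np.asarray(topo_H, float)
    if mode == "lamellipodia":
        feats = np.stack([ndimage.gaussian_filter(H, s) for s in (1, 3, 5)],
                         axis=-1)
    elif mode == "bleb_filopodia":
        feats = ndimage.gaussian_filter(H, 1.0)[..., None]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    voxels = np.argwhere(shell)
    x = feats[shell]
    rng = np.random.default_rng(seed)
    if len(x) > max_samples:
        pick = rng.choice(len(x), max_samples, replace=False)
        fit_x = x[pick]
    else:
        fit_x = x
    if mode == "lamellipodia":
        from sklearn.mixture import GaussianMixture

        model = GaussianMixture(3, random_state=int(rng.integers(2**31)))
        model.fit(fit_x)
        assign = model.predict(x)
        means = model.means_[:, 0]
    else:
        from sklearn.cluster import KMeans

        model = KMeans(3, random_state=int(rng.integers(2**31)), n_init=4)
        model.fit(fit_x)
        assign = model.predict(x)
        means = model.cluster_centers_[:, 0]
    if np.ptp(means) < 1e-6:
        log.warning("no separable high-curvature class; empty instances")
        return LabelField(np.zeros(mesh.n_vertices, dtype=np.int64))
    top = int(np.argmax(means))
    high = np.zeros_like(b)
    sel = voxels[assign == top]
    high[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    lab, _ = ndimage.label(high)
    counts = np.bincount(lab.ravel())
    small = np.nonzero(counts < min_voxels)[0]
    lab[np.isin(lab, small)] = 0
    from skimage.segmentation import relabel_sequential, expand_labels

    lab, _, _ = relabel_sequential(lab)
    lab = expand_labels(lab, distance=3)

    # transfer to mesh vertices (nearest voxel)
    idx = np.clip(np.round(mesh.vertices).astype(int), 0,
                  np.asarray(b.shape) - 1)
    vlab = lab[idx[:, 0], idx[:, 1], idx[:, 2]].astype(np.int64)
    vlab[binary_seg.labels == 0] = 0
    for c in np.unique(vlab[vlab > 0]):
        if vertex_area[vlab == c].sum() <= min_area:
            vlab[vlab == c] = 0
    if not (vlab > 0).any():
        return LabelField(np.zeros(mesh.n_vertices, dtype=np.int64))
    spread = label_spread(A.matrix, vlab, iterations=10, clamp=0.99)
    spread[binary_seg.labels == 0] = 0
    spread = _complete_within_components(mesh, spread,
                                         binary_seg.labels > 0)
    spread = _merge_across_seam(mesh, spread, n_u=b.shape[2])
    out, _, _ = relabel_sequential(spread)
    areas = {int(c): float(vertex_area[out == c].sum())
             for c in np.unique(out[out > 0])}
    return LabelField(out.astype(np.int64), "topographic", areas=areas)


def _merge_across_seam(mesh: SurfaceMesh, labels: np.ndarray, n_u: int,
                       tol: float = 3.0) -> np.ndarray:
    """Unify labels split by the periodic u-seam of the topographic sheet.

    The (d, v, u) mesh is cut at the u image boundary; a protrusion that
    straddles the seam appears as two labels.  Labels with vertices on
    opposite seam edges at matching (d, v) positions are merged.
    """
    from scipy.spatial import cKDTree

    out = labels.copy()
    u = mesh.vertices[:, 2]
    left = (u < 1.5) & (out > 0)
    right = (u > n_u - 2.5) & (out > 0)
    if not left.any() or not right.any():
        return out
    lt = cKDTree(mesh.vertices[left][:, :2])
    d, idx = lt.query(mesh.vertices[right][:, :2])
    llab = out[left][idx]
    rlab = out[right]
    for a, b in {(int(x), int(y)) for x, y, dd in
                 zip(llab, rlab, d) if dd < tol and x != y}:
        out[out == b] = a
    return out


def _complete_within_components(mesh: SurfaceMesh, labels: np.ndarray,
                                mask: np.ndarray) -> np.ndarray:
    """Finite-iteration spreading reaches one graph ring per iteration;
    extend it to its convergence limit by assigning still-unlabeled masked
    vertices to the nearest labeled vertex of their own binary component.
    Components without any seed stay unlabeled."""
    from scipy.spatial import cKDTree

    out = labels.copy()
    comp = _vertex_components(mesh, mask)
    for c in range(1, comp.max() + 1):
        inside = comp == c
        have = inside & (out > 0)
        need = inside & (out == 0)
        if not have.any() or not need.any():
            continue
        src = np.nonzero(have)[0]
        _, idx = cKDTree(mesh.vertices[src]).query(mesh.vertices[need])
        out[need] = out[src[idx]]
    return out


# ------------------------------------------------------------------ unwrap
def _disk_to_square(xy: np.ndarray) -> np.ndarray:
    """Elliptical grid mapping of the unit disk onto [-1, 1]^2."""
    x, y = xy[:, 0], xy[:, 1]
    t = 2.0 * np.sqrt(2.0)
    u = 0.5 * (np.sqrt(np.clip(2 + x**2 - y**2 + t * x, 0, None))
               - np.sqrt(np.clip(2 + x**2 - y**2 - t * x, 0, None)))
    v = 0.5 * (np.sqrt(np.clip(2 - x**2 + y**2 + t * y, 0, None))
               - np.sqrt(np.clip(2 - x**2 + y**2 - t * y, 0, None)))
    return np.column_stack([u, v])


def harmonic_disk_map(submesh: SurfaceMesh) -> np.ndarray:
    """Harmonic map of a disk-topology open mesh onto the unit disk.

    The boundary loop goes to the unit circle preserving arc-length
    fractions; interior vertices solve the cotangent Laplace equation.
    """
    topo = surface_topology(submesh)
    if topo.boundary_loops != 1 or topo.genus != 0:
        raise ValueError(
            "disk unwrapping needs genus 0 and exactly one boundary loop "
            f"(got genus={topo.genus}, loops={topo.boundary_loops}); "
            "impute holes first")
    loop = boundary_loop(submesh)
    pts = submesh.vertices[loop]
    seg = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
    frac = np.concatenate([[0.0], np.cumsum(seg)[:-1]]) / seg.sum()
    ang = 2.0 * np.pi * frac
    disk_b = np.column_stack([np.cos(ang), np.sin(ang)])

    from .operators import build_operators

    _, lap = build_operators(submesh, "robust")
    L = lap.matrix.tolil()
    n = submesh.n_vertices
    rhs = np.zeros((n, 2))
    for k, vtx in enumerate(loop):
        L.rows[vtx] = [vtx]
        L.data[vtx] = [1.0]
        rhs[vtx] = disk_b[k]
    interior = np.setdiff1d(np.arange(n), loop)
    # move boundary couplings of interior rows to the rhs
    Lcsr = lap.matrix.tocsr()
    mask = np.zeros(n, dtype=bool)
    mask[loop] = True
    A = Lcsr.tolil()
    b = np.zeros((n, 2))
    for vtx in interior:
        cols = Lcsr.indices[Lcsr.indptr[vtx]:Lcsr.indptr[vtx + 1]]
        vals = Lcsr.data[Lcsr.indptr[vtx]:Lcsr.indptr[vtx + 1]]
        bnd = mask[cols]
        b[vtx] = -(vals[bnd][:, None]
                   * rhs[cols[bnd]]).sum(axis=0)
        keepc = ~bnd
        A.rows[vtx] = cols[keepc].tolist()
        A.data[vtx] = vals[keepc].tolist()
    for vtx in loop:
        A.rows[vtx] = [vtx]
        A.data[vtx] = [1.0]
        b[vtx] = rhs[vtx]
    sol = spla.spsolve(A.tocsc(), b)
    uv = np.asarray(sol)
    r = np.linalg.norm(uv, axis=1)
    uv[r > 1.0] /= r[r > 1.0, None]
    return uv


def _relax_disk(submesh: SurfaceMesh, uv: np.ndarray, iterations: int = 30,
                step: float = 0.2) -> np.ndarray:
    """Equiareal relaxation of a disk parameterization (boundary fixed).

    Explicit Euler advection of interior vertices along -grad log(lambda),
    the 2D analogue of the spherical relaxation.
    """
    from .operators import face_gradient, faces_to_vertices

    loop = boundary_loop(submesh)
    fixed = np.zeros(submesh.n_vertices, dtype=bool)
    fixed[loop] = True
    a3 = submesh.face_areas()
    a3 = a3 / a3.sum()
    flat = SurfaceMesh(np.column_stack([uv, np.zeros(len(uv))]),
                       submesh.faces, "plane")
    best = uv.copy()
    for _ in range(iterations):
        a2 = flat.face_areas()
        lam = a3 / np.maximum(a2 / a2.sum(), 1e-300)
        lam_v = faces_to_vertices(flat, lam)
        g = -face_gradient(flat, np.log(np.maximum(lam_v, 1e-300)))
        gv = faces_to_vertices(flat, g)[:, :2]
        med = float(np.median(np.linalg.norm(gv, axis=1)))
        if med < 1e-14:
            break
        lbar = float(flat.edge_lengths().mean())
        gv *= step * lbar / med
        gv[fixed] = 0.0
        cand = flat.vertices.copy()
        cand[:, :2] += gv
        trial = flat.copy(vertices=cand)
        # reject steps that invert faces

        def det2(mesh2d):
            c2 = mesh2d.vertices[mesh2d.faces][:, :, :2]
            e1 = c2[:, 1] - c2[:, 0]
            e2 = c2[:, 2] - c2[:, 0]
            return e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]

        if (det2(trial) <= 0).any() and not (det2(flat) <= 0).any():
            break
        flat = trial
        best = flat.vertices[:, :2].copy()
    return best


def unwrap_protrusion(submesh: SurfaceMesh, N: int = 128,
                      relax_iterations: int = 30) -> dict:
    """Unwrap an open protrusion submesh to an N x N square lookup.

    Returns per-vertex square coordinates (pixel units) plus the disk map.
    """
    uv = harmonic_disk_map(submesh)
    uv = _relax_disk(submesh, uv, iterations=relax_iterations)
    square = _disk_to_square(uv)
    pix = (square + 1.0) * 0.5 * (N - 1)
    return {"disk": uv, "square": square, "pixels": pix, "N": N}


def rasterize_vertex_values(pix: np.ndarray, values: np.ndarray, N: int,
                            fill: float = np.nan) -> np.ndarray:
    """Nearest-vertex rasterization of per-vertex values onto N x N pixels."""
    from scipy.interpolate import griddata

    gy, gx = np.mgrid[0:N, 0:N]
    pts = np.column_stack([pix[:, 1], pix[:, 0]])   # row=y, col=x
    img = griddata(pts, values, (gy, gx), method="nearest")
    return np.asarray(img, float)


# ------------------------------------------------------------------ refinement
def refine_split_blebs(mesh: SurfaceMesh, labels: LabelField,
                       H: np.ndarray, vertex_area: np.ndarray,
                       N: int = 128, min_area: float = 10.0,
                       A: Optional[AffinityMatrix] = None) -> LabelField:
    """Split conjoined bleb labels with a distance-transform watershed.

    Per label: extract the (hole-imputed) submesh, unwrap to an N x N
    square, threshold the pulled-back mean curvature at the upper 3-class
    Otsu level, and split touching pseudo-circular regions by watershed on
    the Euclidean distance transform.  Splits are mapped back and
    re-diffused over the full mesh.
    """
    from skimage.filters import threshold_multiotsu
    from skimage.morphology import closing, disk
    from skimage.segmentation import watershed
    from skimage.feature import peak_local_max

    lv = labels.labels.copy()
    finite_H = H[np.isfinite(H)]
    if len(np.unique(finite_H)) < 3:
        return labels
    thresh = threshold_multiotsu(finite_H, classes=3)[-1]
    next_id = lv.max() + 1
    for c in np.unique(lv[lv > 0]):
        mask = lv == c
        # impute interior holes: complement components below 10% total area
        comp = _vertex_components(mesh, ~mask)
        total = vertex_area.sum()
        for cc in range(1, comp.max() + 1):
            m = comp == cc
            if vertex_area[m].sum() < 0.10 * total:
                mask |= m
        vid = np.nonzero(mask)[0]
        remap = -np.ones(mesh.n_vertices, dtype=np.int64)
        remap[vid] = np.arange(len(vid))
        fmask = mask[mesh.faces].all(axis=1)
        sub = SurfaceMesh(mesh.vertices[vid], remap[mesh.faces[fmask]],
                          mesh.representation_tag)
        try:
            unwrapped = unwrap_protrusion(sub, N=N, relax_iterations=10)
        except (ValueError, RuntimeError) as exc:
            log.info("label %d passed through unrefined (%s)", c, exc)
            continue
        img = rasterize_vertex_values(unwrapped["pixels"], H[vid], N)
        img = ndimage.gaussian_filter(img, 2.0)
        binary = closing(img > thresh, disk(1))
        binary = ndimage.binary_fill_holes(binary)
        if not binary.any():
            continue
        edt = ndimage.gaussian_filter(
            ndimage.distance_transform_edt(binary), 2.0)
        # peaks well inside pseudo-circular regions; shallow rim maxima are
        # suppressed by the absolute depth threshold
        peaks = peak_local_max(edt, min_distance=max(N // 8, 3),
                               threshold_abs=0.6 * float(edt.max()),
                               labels=binary)
        if len(peaks) < 2:
            continue
        markers = np.zeros_like(binary, dtype=np.int64)
        markers[peaks[:, 0], peaks[:, 1]] = np.arange(1, len(peaks) + 1)
        ws = watershed(-edt, markers, mask=binary)
        # map each submesh vertex to its watershed basin
        pr = np.clip(np.round(unwrapped["pixels"]).astype(int), 0, N - 1)
        basins = ws[pr[:, 1], pr[:, 0]]
        present = np.unique(basins[basins > 0])
        # ignore slivers below 5% of the labeled vertices
        present = [b for b in present
                   if (basins == b).sum() >= 0.05 * len(basins)]
        if len(present) < 2:
            continue
        for k, bsn in enumerate(present):
            sel = vid[basins == bsn]
            lv[sel] = c if k == 0 else next_id
            if k > 0:
                next_id += 1
        # vertices outside every basin become unlabeled so the re-diffusion
        # assigns them to the nearest split, not the first one
        lv[vid[~np.isin(basins, present)]] = 0
    if A is not None:
        spread = label_spread(A.matrix, lv, iterations=10, clamp=0.99)
        spread[labels.labels == 0] = 0
        lv = _complete_within_components(mesh, spread, labels.labels > 0)
    for c in np.unique(lv[lv > 0]):
        if vertex_area[lv == c].sum() < min_area:
            lv[lv == c] = 0
    from skimage.segmentation import relabel_sequential as _rs

    lv, _, _ = _rs(lv)
    return LabelField(lv.astype(np.int64), labels.provenance)


# ------------------------------------------------------------------ volumes
def inpaint_reference(d_ref: np.ndarray, hole_mask: np.ndarray) -> np.ndarray:
    """Inpaint masked pixels of the reference depth image."""
    img = np.asarray(d_ref, float)
    mask = np.asarray(hole_mask, bool)
    if mask.all():
        raise ValueError("cannot inpaint a fully masked image")
    if not mask.any():
        return img.copy()
    from skimage.restoration import inpaint_biharmonic

    return inpaint_biharmonic(img, mask)


def propagate_labels_depth(topo_binary: np.ndarray,
                           surface_labels: np.ndarray) -> np.ndarray:
    """Slice-wise marker watershed from the top (d max) down.

    ``surface_labels`` is a volumetric integer seed field (already
    rasterized and expanded); previous-slice labels take precedence over
    the current slice's own seeds.
    """
    from skimage.segmentation import watershed

    b = np.asarray(topo_binary, bool)
    seeds = np.asarray(surface_labels)
    out = np.zeros_like(seeds)
    prev = None
    for d in range(b.shape[0] - 1, -1, -1):
        sl = b[d]
        markers = seeds[d].copy()
        if prev is not None:
            carry = prev > 0
            markers[carry] = prev[carry]
        if not sl.any():
            prev = np.zeros_like(markers)
            continue
        if markers.any():
            edt = ndimage.distance_transform_edt(sl)
            out[d] = watershed(-edt, markers, mask=sl)
        prev = out[d]
    return out


def volumize_protrusions(vol_labels: np.ndarray, reference_binary: np.ndarray,
                         min_voxels: int = 1) -> tuple[np.ndarray, Dict[int, int]]:
    """Mask out cortical voxels; keep the largest region per label.

    Returns the cleaned volumetric labels and per-label voxel volumes.
    """
    lab = np.asarray(vol_labels).copy()
    lab[np.asarray(reference_binary, bool)] = 0
    volumes: Dict[int, int] = {}
    for c in np.unique(lab[lab > 0]):
        comp, n = ndimage.label(lab == c)
        if n == 0:
            continue
        counts = np.bincount(comp.ravel())[1:]
        keep = int(np.argmax(counts)) + 1
        drop = (lab == c) & (comp != keep)
        lab[drop] = 0
        vol = int(counts.max())
        if vol < min_voxels:
            lab[lab == c] = 0
            log.info("label %d vanished under the reference mask", c)
        else:
            volumes[int(c)] = vol
    return lab, volumes
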