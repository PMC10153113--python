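"""Curvature, distortion and mesh-comparison metrics.

Conformal error per face: both triangles of a correspondence are flattened
isometrically into 2D, the affine map J between them is solved, and the
ratio of its singular values sigma2/sigma1 >= 1 measures angular stretch
(1 = conformal).  The area-distortion factor lambda compares normalized
face-area fractions between the two meshes (1 = equiareal).  The same two
quantities are computed per pixel for equirectangular UV lookup grids from
the Jacobian [dS/du, dS/dv].

Mean curvature is measured volumetrically as H = -1/2 div(n) with n the
unit gradient of the signed distance transform (positive inside), so convex
protrusions such as blebs score H > 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .mesh import SurfaceMesh

__all__ = [
    "DistortionReport", "MeshDifference", "mean_curvature_sdf",
    "gaussian_curvature", "face_distortion", "uv_grid_distortion",
    "compare_meshes", "radius_ratio",
]


@dataclass
class DistortionReport:
    conformal_error: np.ndarray        # per element, >= 1 (inf on collapse)
    area_distortion: np.ndarray        # per element, > 0
    global_conformal_error: float      # area-weighted mean over finite Q
    global_area_distortion: float      # plain mean
    median_area_distortion: float
    criteria: Dict[str, float] = field(default_factory=dict)
    n_infinite: int = 0

    def to_json(self) -> str:
        return json.dumps({
            "global_conformal_error": self.global_conformal_error,
            "global_area_distortion": self.global_area_distortion,
            "median_area_distortion": self.median_area_distortion,
            "criteria": self.criteria,
            "n_infinite": self.n_infinite,
        }, indent=2)


@dataclass
class MeshDifference:
    chamfer_distance: float
    sliced_wasserstein_1: float
    delta_area_percent: float
    delta_volume_percent: Optional[float]
    projections: int = 50
    repeats: int = 10
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


# ------------------------------------------------------------------ curvature
def mean_curvature_sdf(mesh: SurfaceMesh, dilation_radius: int = 1,
                       smooth_sigma: float = 1.0) -> np.ndarray:
    """Per-vertex mean curvature from the signed distance transform (1/voxel)."""
    from .volumes import voxelize
    from .topography import signed_distance

    vol = voxelize(mesh, dilation_radius=dilation_radius)
    phi = signed_distance(vol).data
    if smooth_sigma > 0:
        phi = ndimage.gaussian_filter(phi, smooth_sigma)
    grad = np.stack(np.gradient(phi))
    norm = np.maximum(np.linalg.norm(grad, axis=0), 1e-12)
    n = grad / norm
    div = sum(np.gradient(n[k], axis=k) for k in range(3))
    # phi positive inside: H = -1/2 div(grad phi / |grad phi|), +1/R on a ball
    h_field = -0.5 * div
    coords = (mesh.vertices - vol.origin).T
    return ndimage.map_coordinates(h_field, coords, order=1, mode="nearest")


def gaussian_curvature(mesh: SurfaceMesh) -> np.ndarray:
    """Angular-deficit Gaussian curvature K = 2 pi - sum of incident angles.

    Closed manifold meshes only; the sum over vertices obeys Gauss-Bonnet,
    sum K = 2 pi chi.
    """
    c = mesh.face_corners()
    K = np.full(mesh.n_vertices, 2.0 * np.pi)
    for k in range(3):
        e1 = c[:, (k + 1) % 3] - c[:, k]
        e2 = c[:, (k + 2) % 3] - c[:, k]
        cosang = (np.einsum("ij,ij->i", e1, e2)
                  / np.maximum(np.linalg.norm(e1, axis=1)
                               * np.linalg.norm(e2, axis=1), 1e-300))
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        np.subtract.at(K, mesh.faces[:, k], ang)
    return K


# ------------------------------------------------------------------ distortion
def _flatten_triangles(corners: np.ndarray) -> np.ndarray:
    """Isometric 2D embedding of each 3D triangle: A->(0,0), B->(|AB|,0)."""
    ab = corners[:, 1] - corners[:, 0]
    ac = corners[:, 2] - corners[:, 0]
    lab = np.linalg.norm(ab, axis=1)
    x = np.einsum("ij,ij->i", ab, ac) / np.maximum(lab, 1e-300)
    y = np.linalg.norm(np.cross(ab, ac), axis=1) / np.maximum(lab, 1e-300)
    out = np.zeros((len(corners), 3, 2))
    out[:, 1, 0] = lab
    out[:, 2, 0] = x
    out[:, 2, 1] = y
    return out


def _singular_values(src2d: np.ndarray, dst2d: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Singular values (s1 <= s2) of the affine map taking each flattened
    source triangle to its destination."""
    e1s = src2d[:, 1] - src2d[:, 0]
    e2s = src2d[:, 2] - src2d[:, 0]
    e1d = dst2d[:, 1] - dst2d[:, 0]
    e2d = dst2d[:, 2] - dst2d[:, 0]
    Es = np.stack([e1s, e2s], axis=2)      # (m, 2, 2) columns = edges
    Ed = np.stack([e1d, e2d], axis=2)
    det = Es[:, 0, 0] * Es[:, 1, 1] - Es[:, 0, 1] * Es[:, 1, 0]
    ok = np.abs(det) > 1e-300
    inv = np.zeros_like(Es)
    inv[ok, 0, 0] = Es[ok, 1, 1]
    inv[ok, 0, 1] = -Es[ok, 0, 1]
    inv[ok, 1, 0] = -Es[ok, 1, 0]
    inv[ok, 1, 1] = Es[ok, 0, 0]
    inv[ok] /= det[ok, None, None]
    J = Ed @ inv
    JtJ = np.einsum("mki,mkj->mij", J, J)
    tr = JtJ[:, 0, 0] + JtJ[:, 1, 1]
    dt = JtJ[:, 0, 0] * JtJ[:, 1, 1] - JtJ[:, 0, 1] * JtJ[:, 1, 0]
    disc = np.sqrt(np.clip(tr * tr - 4.0 * dt, 0.0, None))
    lam1 = np.clip(0.5 * (tr - disc), 0.0, None)
    lam2 = np.clip(0.5 * (tr + disc), 0.0, None)
    s1, s2 = np.sqrt(lam1), np.sqrt(lam2)
    s1[~ok] = 0.0
    s2[~ok] = np.inf
    return s1, s2


def _assemble_report(s1: np.ndarray, s2: np.ndarray, lam: np.ndarray,
                     weights: np.ndarray, theta: float = 0.5
                     ) -> DistortionReport:
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        Q = np.where(s1 > 0, s2 / np.maximum(s1, 1e-300), np.inf)
    finite = np.isfinite(Q)
    w = weights[finite]
    gQ = float((w * Q[finite]).sum() / max(w.sum(), 1e-300))
    glam = float(np.mean(lam))
    med = float(np.median(lam))
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        mips = Q + 1.0 / Q
        prod = s1 * s2
        area_mips = (s1 / np.maximum(s2, 1e-300) + Q) * (prod + 1.0 / np.maximum(prod, 1e-300))
        loglam = np.log(np.maximum(lam, 1e-300))
    wfull = weights / max(weights.sum(), 1e-300)
    criteria = {
        "equiareal_gap": abs(med - 1.0),
        "mips": float((wfull[finite] * mips[finite]).sum()
                      / max(wfull[finite].sum(), 1e-300)),
        "area_mips": float((wfull[finite] * area_mips[finite]).sum()
                           / max(wfull[finite].sum(), 1e-300)),
        "isometric": (1.0 - theta) * gQ + theta * float(np.mean(loglam)),
    }
    return DistortionReport(Q, lam, gQ, glam, med, criteria,
                            n_infinite=int((~finite).sum()))


def face_distortion(src: SurfaceMesh, dst: SurfaceMesh,
                    theta: float = 0.5) -> DistortionReport:
    """Per-face conformal error and area distortion of a bijective map."""
    if src.n_faces != dst.n_faces or src.n_vertices != dst.n_vertices:
        raise ValueError("meshes must share vertex and face counts")
    s2d = _flatten_triangles(src.face_corners())
    d2d = _flatten_triangles(dst.face_corners())
    s1, s2 = _singular_values(s2d, d2d)
    a_src = src.face_areas()
    a_dst = dst.face_areas()
    lam = ((a_src / max(a_src.sum(), 1e-300))
           / np.maximum(a_dst / max(a_dst.sum(), 1e-300), 1e-300))
    return _assemble_report(s1, s2, lam, a_src, theta)


def uv_grid_distortion(uv, theta: float = 0.5) -> DistortionReport:
    """Distortion of an equirectangular UV lookup grid, per pixel.

    ``uv`` is a UVGrid (or any object with ``coordinates`` of shape
    (rows, cols, 3) periodic in u with a duplicated seam column).
    """
    S = np.asarray(uv.coordinates, dtype=float)
    if S.shape[0] < 3 or S.shape[1] < 3:
        raise ValueError("grid needs at least 3 rows and columns")
    periodic = getattr(uv, "periodic_u", True)
    core = S[:, :-1] if periodic and getattr(uv, "duplicate_seam", True) \
        else S
    if periodic:
        dSu = (np.roll(core, -1, axis=1) - np.roll(core, 1, axis=1)) / 2.0
    else:
        dSu = np.gradient(core, axis=1)
    dSv = np.gradient(core, axis=0)
    cross = np.cross(dSu, dSv)
    dA = np.linalg.norm(cross, axis=2)
    # first fundamental form of the (u, v) -> S map
    E = np.einsum("rci,rci->rc", dSu, dSu)
    F = np.einsum("rci,rci->rc", dSu, dSv)
    G = np.einsum("rci,rci->rc", dSv, dSv)
    tr = E + G
    dt = E * G - F * F
    disc = np.sqrt(np.clip(tr * tr - 4 * dt, 0.0, None))
    s1 = np.sqrt(np.clip(0.5 * (tr - disc), 0.0, None)).ravel()
    s2 = np.sqrt(np.clip(0.5 * (tr + disc), 0.0, None)).ravel()
    total = max(dA.sum(), 1e-300)
    lam = (1.0 / dA.size) / np.maximum(dA / total, 1e-300)
    return _assemble_report(s1, s2, lam.ravel(), dA.ravel(), theta)


# ------------------------------------------------------------------ comparison
def _sliced_w1(x: np.ndarray, y: np.ndarray, projections: int,
               rng: np.random.Generator) -> float:
    """Max-sliced Wasserstein-1 between two point clouds."""
    d = rng.normal(size=(projections, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    best = 0.0
    n = min(len(x), len(y))
    qs = (np.arange(n) + 0.5) / n
    for k in range(projections):
        px = np.sort(x @ d[k])
        py = np.sort(y @ d[k])
        if len(x) != len(y):
            px = np.quantile(px, qs)
            py = np.quantile(py, qs)
        best = max(best, float(np.abs(px - py).mean()))
    return best


def compare_meshes(m1: SurfaceMesh, m2: SurfaceMesh, projections: int = 50,
                   repeats: int = 10, seed: int = 0,
                   compute_volume: bool = True) -> MeshDifference:
    """Chamfer distance, sliced W1, and area/volume differences (m1 vs m2)."""
    if m1.n_vertices == 0 or m2.n_vertices == 0:
        raise ValueError("empty mesh")
    t1 = cKDTree(m1.vertices)
    t2 = cKDTree(m2.vertices)
    d12, _ = t2.query(m1.vertices)
    d21, _ = t1.query(m2.vertices)
    cd = 0.5 * (float(d12.mean()) + float(d21.mean()))
    rng = np.random.default_rng(seed)
    sw = float(np.mean([_sliced_w1(m1.vertices, m2.vertices, projections, rng)
                        for _ in range(repeats)]))
    a1, a2 = m1.area(), m2.area()
    dA = 100.0 * (a1 - a2) / a2
    dV = None
    if compute_volume:
        from .volumes import voxelize
        v1 = voxelize(m1, dilation_radius=3).volume()
        v2 = voxelize(m2, dilation_radius=3).volume()
        dV = 100.0 * (v1 - v2) / v2
    return MeshDifference(cd, sw, dA, dV, projections, repeats, seed)


def radius_ratio(mesh: SurfaceMesh) -> np.ndarray:
    """Per-face quality 2 r_in / r_circ in [0, 1]; 1 iff equilateral."""
    c = mesh.face_corners()
    a = np.linalg.norm(c[:, 1] - c[:, 2], axis=1)
    b = np.linalg.norm(c[:, 2] - c[:, 0], axis=1)
    d = np.linalg.norm(c[:, 0] - c[:, 1], axis=1)
    s = 0.5 * (a + b + d)
    area2 = np.clip(s * (s - a) * (s - b) * (s - d), 0.0, None)
    area = np.sqrt(area2)
    good = (area > 1e-300) & (a * b * d > 0)
    r_in = np.where(good, area / np.maximum(s, 1e-300), 0.0)
    r_circ = np.where(good, a * b * d / np.maximum(4.0 * area, 1e-300), np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(np.isfinite(r_circ), 2.0 * r_in / r_circ, 0.0)
    return np.clip(q, 0.0, 1.0)
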