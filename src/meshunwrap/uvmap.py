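"""Equirectangular (u, v) unwrapping of the spherically parameterized surface.

Convention (fixed here; stated once): rows index the polar angle
v in [0, pi] with the north pole at row 0, columns index the azimuth
u in [-pi, pi], and the unit-sphere point of a pixel is
(x, y, z) = (sin v cos u, sin v sin u, cos v).  Grids are stored
N x (2N + 1) with the last column an exact duplicate of the first (the
seam); exports may drop it.

The unwrapping axis is chosen by weighted PCA of the spherical vertex
positions: the eigenvector of the smallest eigenvalue of the weighted
covariance concentrates the high-weight vertices away from the poles,
where equirectangular distortion is worst.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .mesh import SurfaceMesh

log = logging.getLogger(__name__)


@dataclass
class RotationResult:
    rotation: np.ndarray          # applied rotation R'^T (proper, det +1)
    eigenvalues: np.ndarray       # descending
    degenerate: bool = False


@dataclass
class UVGrid:
    coordinates: np.ndarray       # (N, 2N+1, 3) mapped 3D coordinates
    face_index: np.ndarray        # (N, 2N+1) sphere-mesh face per pixel
    barycentric: np.ndarray       # (N, 2N+1, 3) convex weights
    differential_area: np.ndarray  # (N, 2N+1) |dS/du x dS/dv|
    rotation: np.ndarray          # rotation applied to the sphere
    duplicate_seam: bool = True
    periodic_u: bool = True
    mesh: Optional[SurfaceMesh] = None   # the target mesh that was pulled back

    @property
    def shape(self) -> tuple[int, int]:
        return self.coordinates.shape[:2]

    def save(self, path: str | Path) -> None:
        import tifffile

        path = Path(path)
        stack = np.concatenate(
            [np.moveaxis(self.coordinates, 2, 0),
             self.differential_area[None]], axis=0).astype(np.float32)
        tifffile.imwrite(path, stack)
        meta = {"rows": int(self.shape[0]), "cols": int(self.shape[1]),
                "duplicate_seam": self.duplicate_seam,
                "rotation": self.rotation.tolist()}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def optimal_rotation_weighted_pca(sphere: SurfaceMesh, weights: np.ndarray,
                                  tie_tol: float = 1e-6) -> RotationResult:
    """Unwrapping axis by weighted PCA of spherical vertex positions.

    Returns the proper rotation R'^T that maps the smallest eigenvector to
    the z-axis (the north-south unwrapping axis).  Degenerate spectra
    (eigenvalue ties within ``tie_tol`` relative) fall back to the identity.
    """
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    if w.sum() <= 0:
        raise ValueError("weights must not be all zero")
    v = sphere.vertices
    wv = w[:, None] * v
    A = wv.T @ v / w.sum()
    evals, evecs = np.linalg.eigh(A)       # ascending
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    rel = np.abs(np.diff(evals)) / max(abs(evals[0]), 1e-300)
    if (rel < tie_tol).any():
        log.info("degenerate PCA spectrum; identity rotation")
        return RotationResult(np.eye(3), evals, degenerate=True)
    e1 = evecs[:, 0] * np.sign(evecs[0, 0] or 1.0)
    e2 = evecs[:, 1] * np.sign(evecs[1, 1] or 1.0)
    e3 = np.cross(e1, e2)
    Rp = np.column_stack([e1, e2, e3])
    return RotationResult(Rp.T, evals)


def _sphere_pullback(sphere: SurfaceMesh, points: np.ndarray,
                     k_candidates: int = 16
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Locate unit-direction query points on a star-shaped spherical mesh.

    Central projection: intersect the ray origin->p with candidate faces
    found via a centroid KD-tree and keep the face whose barycentric
    coordinates are convex.  Returns (face_index, barycentric).
    """
    c = sphere.face_corners()
    centroids = c.mean(axis=1)
    tree = cKDTree(centroids / np.linalg.norm(centroids, axis=1, keepdims=True))
    k = min(k_candidates, sphere.n_faces)
    _, cand = tree.query(points, k=k)
    if k == 1:
        cand = cand[:, None]
    n = len(points)
    best_face = np.full(n, -1, dtype=np.int64)
    best_bary = np.zeros((n, 3))
    best_neg = np.full(n, -np.inf)
    for j in range(k):
        fi = cand[:, j]
        tri = c[fi]                       # (n, 3, 3)
        # solve p * t = b0*A + b1*B + b2*C with b0+b1+b2 = 1
        M = np.stack([tri[:, 0] - tri[:, 2], tri[:, 1] - tri[:, 2],
                      -points], axis=2)
        rhs = -tri[:, 2]
        det = np.linalg.det(M)
        ok = np.abs(det) > 1e-300
        sol = np.zeros((n, 3))
        sol[ok] = np.linalg.solve(M[ok], rhs[ok, :, None])[:, :, 0]
        b = np.column_stack([sol[:, 0], sol[:, 1],
                             1.0 - sol[:, 0] - sol[:, 1]])
        t = sol[:, 2]
        worst = np.where(ok & (t > 0), b.min(axis=1), -np.inf)
        upd = worst > best_neg
        best_neg[upd] = worst[upd]
        best_face[upd] = fi[upd]
        best_bary[upd] = b[upd]
    miss = best_neg < -1e-6
    if miss.any():
        log.warning("%d UV pixels fell outside candidate faces; "
                    "clamped to nearest", int(miss.sum()))
    best_bary = np.clip(best_bary, 0.0, None)
    best_bary /= best_bary.sum(axis=1, keepdims=True)
    return best_face, best_bary


def build_uv_grid(sphere: SurfaceMesh, target: SurfaceMesh, N: int = 256,
                  rotation: Optional[np.ndarray] = None,
                  duplicate_seam: bool = True) -> UVGrid:
    """Equirectangular pullback of ``target`` through the spherical map.

    ``target`` must be bijective to ``sphere`` (same face list): the
    reference mesh, the input mesh for direct unwrapping, or any sibling.
    """
    if N < 8:
        raise ValueError("N must be >= 8")
    if target.n_vertices != sphere.n_vertices:
        raise ValueError("target must share vertices with the sphere mesh")
    R = np.eye(3) if rotation is None else np.asarray(rotation, float)
    ncol = 2 * N + 1
    vpol = np.linspace(0.0, np.pi, N)
    uaz = np.linspace(-np.pi, np.pi, ncol)
    vv, uu = np.meshgrid(vpol, uaz, indexing="ij")
    pts = np.stack([np.sin(vv) * np.cos(uu), np.sin(vv) * np.sin(uu),
                    np.cos(vv)], axis=-1).reshape(-1, 3)
    # the rotation is applied to the sphere; equivalently rotate the queries
    pts = pts @ R
    # clamp pole rows to exact axis directions for stability
    face, bary = _sphere_pullback(sphere, pts)
    face = face.reshape(N, ncol)
    bary = bary.reshape(N, ncol, 3)
    # exact seam duplication
    face[:, -1] = face[:, 0]
    bary[:, -1] = bary[:, 0]
    tri = target.vertices[target.faces[face]]
    coords = np.einsum("rck,rckj->rcj", bary, tri)
    grid = UVGrid(coords, face, bary, np.zeros((N, ncol)), R,
                  duplicate_seam, mesh=target)
    grid.differential_area = _grid_dA(coords)
    return grid


def _grid_dA(coords: np.ndarray) -> np.ndarray:
    core = coords[:, :-1]
    dSu = (np.roll(core, -1, axis=1) - np.roll(core, 1, axis=1)) / 2.0
    dSv = np.gradient(core, axis=0)
    dA = np.linalg.norm(np.cross(dSu, dSv), axis=2)
    return np.concatenate([dA, dA[:, :1]], axis=1)


def pullback_scalar(uv: UVGrid, field: np.ndarray) -> np.ndarray:
    """Map a per-vertex field of the linked mesh onto the (u, v) image."""
    if uv.mesh is None:
        raise ValueError("grid carries no linked mesh")
    f = np.asarray(field, dtype=float)
    if f.shape[0] != uv.mesh.n_vertices:
        raise ValueError("field length mismatch")
    vals = f[uv.mesh.faces[uv.face_index]]
    if f.ndim == 1:
        return np.einsum("rck,rck->rc", uv.barycentric, vals)
    return np.einsum("rck,rck...->rc...", uv.barycentric, vals)


def pad_spherical(image: np.ndarray, pad: int) -> np.ndarray:
    """Spherical periodic padding of an equirectangular image.

    Columns wrap; rows beyond the poles reflect about the pole row and are
    flipped by half a period in u (walking over a pole lands on the
    antipodal meridian).
    """
    if pad >= min(image.shape[:2]):
        raise ValueError("pad too large")
    out = np.concatenate([image[:, -pad:], image, image[:, :pad]], axis=1)
    # reflect rows about the pole rows, flipping in u when crossing a pole
    top = out[pad:0:-1, ::-1]
    bottom = out[-2:-pad - 2:-1, ::-1]
    return np.concatenate([top, out, bottom], axis=0)


def weighted_uv_mean(image: np.ndarray, dA: np.ndarray,
                     mask: np.ndarray) -> float:
    """Differential-area-weighted mean of an image over a pixel mask."""
    image = np.asarray(image, float)
    dA = np.asarray(dA, float)
    mask = np.asarray(mask, bool)
    if image.shape != dA.shape or image.shape != mask.shape:
        raise ValueError("shape mismatch")
    if not mask.any():
        raise ValueError("empty mask")
    w = (dA * mask).sum()
    return float((image * dA * mask).sum() / w)
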