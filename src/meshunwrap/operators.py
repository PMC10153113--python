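"""Finite-element operators on triangle meshes.

Barycentric (lumped) mass matrix and cotangent Laplacian assembled the
standard FEM way; the ``robust`` Laplacian kind applies intrinsic
mollification — every edge length is inflated by a small fraction of the
mean edge length before the cotangents are computed — which keeps the
weights finite on near-degenerate faces.

Sign convention: ``laplacian`` is assembled positive semi-definite
(v^T L v >= 0), so the implicit flow system reads (M + dt * L) v_next = M v.
Row sums are zero: constants are in the kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .mesh import SurfaceMesh

MOLLIFY_FACTOR = 1e-5


@dataclass
class LinearOperator:
    matrix: sp.csr_matrix
    role: str            # "mass" | "laplacian"
    kind: str = ""       # for laplacian: "cotangent" | "robust"


def _corner_cotangents(lengths: np.ndarray) -> np.ndarray:
    """Cotangent of each corner angle from the three edge lengths.

    lengths[:, k] is the length of the edge *opposite* corner k.
    """
    a, b, c = lengths[:, 0], lengths[:, 1], lengths[:, 2]
    # Heron with clamping for near-degenerate triangles
    s = 0.5 * (a + b + c)
    area2 = np.clip(s * (s - a) * (s - b) * (s - c), 0.0, None)
    area = np.sqrt(area2)
    cots = np.empty_like(lengths)
    cots[:, 0] = (b**2 + c**2 - a**2)
    cots[:, 1] = (c**2 + a**2 - b**2)
    cots[:, 2] = (a**2 + b**2 - c**2)
    return cots / np.maximum(4.0 * area[:, None], 1e-300)


def build_operators(mesh: SurfaceMesh, laplacian_kind: str = "cotangent",
                    ) -> tuple[LinearOperator, LinearOperator]:
    """Assemble (mass, laplacian) for a triangle mesh.

    Raises on zero-area faces for the plain cotangent kind; the robust kind
    mollifies them instead.
    """
    if mesh.n_vertices < 4:
        raise ValueError("mesh needs at least 4 vertices")
    if laplacian_kind not in ("cotangent", "robust"):
        raise ValueError(f"unknown laplacian kind {laplacian_kind!r}")
    n = mesh.n_vertices
    c = mesh.face_corners()
    # edge opposite corner k joins corners k+1, k+2
    lengths = np.stack(
        [np.linalg.norm(c[:, (k + 2) % 3] - c[:, (k + 1) % 3], axis=1)
         for k in range(3)], axis=1)
    areas = mesh.face_areas()
    if laplacian_kind == "cotangent" and (areas < 1e-12).any():
        raise ValueError(
            "degenerate faces present; use laplacian_kind='robust'")
    if laplacian_kind == "robust":
        # intrinsic mollification: inflate all lengths so the triangle
        # inequality holds with margin delta
        delta = MOLLIFY_FACTOR * float(lengths.mean())
        eps = np.zeros(len(lengths))
        for k in range(3):
            need = lengths[:, k] + delta - (lengths[:, (k + 1) % 3]
                                            + lengths[:, (k + 2) % 3])
            eps = np.maximum(eps, need)
        lengths = lengths + eps[:, None]

    cots = _corner_cotangents(lengths)

    rows, cols, vals = [], [], []
    for k in range(3):
        i = mesh.faces[:, (k + 1) % 3]
        j = mesh.faces[:, (k + 2) % 3]
        w = 0.5 * cots[:, k]
        rows += [i, j, i, j]
        cols += [j, i, i, j]
        vals += [-w, -w, w, w]
    L = sp.coo_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(n, n)).tocsr()

    mass_diag = np.zeros(n)
    np.add.at(mass_diag, mesh.faces.ravel(), np.repeat(areas / 3.0, 3))
    # vertices not referenced by any face get a tiny positive mass
    mass_diag[mass_diag == 0] = 1e-12
    M = sp.diags(mass_diag).tocsr()

    return (LinearOperator(M, "mass"),
            LinearOperator(L, "laplacian", laplacian_kind))


def face_gradient(mesh: SurfaceMesh, vertex_values: np.ndarray) -> np.ndarray:
    """Per-face 3D gradient of a piecewise-linear vertex field.

    grad u = sum_k u_k (n x e_k) / (2 A) with e_k the edge opposite
    corner k, oriented counter-clockwise.
    """
    u = np.asarray(vertex_values, dtype=float)
    c = mesh.face_corners()
    n, a = mesh.face_normals_areas()
    g = np.zeros((mesh.n_faces, 3))
    for k in range(3):
        e = c[:, (k + 2) % 3] - c[:, (k + 1) % 3]
        g += u[mesh.faces[:, k]][:, None] * np.cross(n, e)
    return g / np.maximum(2.0 * a, 1e-300)[:, None]


def faces_to_vertices(mesh: SurfaceMesh, face_values: np.ndarray) -> np.ndarray:
    """Area-weighted average of per-face values onto vertices."""
    fv = np.asarray(face_values, dtype=float)
    a = mesh.face_areas()
    w = np.repeat(a / 3.0, 3)
    num_shape = (mesh.n_vertices,) + fv.shape[1:]
    num = np.zeros(num_shape)
    den = np.zeros(mesh.n_vertices)
    idx = mesh.faces.ravel()
    rep = np.repeat(fv, 3, axis=0)
    if fv.ndim == 1:
        np.add.at(num, idx, rep * w)
    else:
        np.add.at(num, idx, rep * w[:, None])
    np.add.at(den, idx, w)
    den = np.maximum(den, 1e-300)
    return num / (den if fv.ndim == 1 else den[:, None])
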