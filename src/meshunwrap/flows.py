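"""Conformalized mean curvature flow (cMCF) and its variants.

Plain MCF evolves vertices by the implicit system
(M_t + dt * L_t) v(t+dt) = M_t v(t).  cMCF freezes the Laplacian at its
initial assembly L_0, which constrains faces to keep their aspect ratio and
makes the flow conformal; watertight high-curvature meshes then shrink
toward a sphere without pinching.  After every iteration the surface is
rescaled to its original area and recentered at the origin, which
stabilizes the numerics without changing the shape.

The automatic stopping rule finds the elbow of the mean absolute Gaussian
curvature curve: the reference (cortical) shape is reached when curvature
stops decreasing appreciably, well before the spherical limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import SurfaceMesh, boundary_loop
from .metrics import gaussian_curvature
from .operators import build_operators


@dataclass
class FlowConfig:
    delta_t: float = 5e-4
    max_iterations: int = 50
    stop_threshold: float = 1e-5
    t_min: int = 0
    laplacian_kind: str = "cotangent"
    normalize: bool = True
    strict_literal_stop: bool = False

    def __post_init__(self) -> None:
        if self.delta_t < 0:
            raise ValueError("delta_t must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.t_min > self.max_iterations:
            raise ValueError("t_min must not exceed max_iterations")


@dataclass
class FlowHistory:
    snapshots: List[np.ndarray]          # vertex arrays, index 0 = input
    mean_abs_gaussian: np.ndarray        # K-bar per snapshot
    faces: np.ndarray
    stop_index: Optional[int] = None
    status: str = "ok"

    def mesh_at(self, t: int, template: SurfaceMesh) -> SurfaceMesh:
        return template.copy(vertices=self.snapshots[t])


def _normalize(v: np.ndarray, faces: np.ndarray, target_area: float) -> np.ndarray:
    c = v[faces]
    area = 0.5 * np.linalg.norm(
        np.cross(c[:, 1] - c[:, 0], c[:, 2] - c[:, 0]), axis=1).sum()
    v = v * np.sqrt(target_area / max(area, 1e-300))
    return v - v.mean(axis=0)


def run_cmcf(mesh: SurfaceMesh, cfg: FlowConfig) -> FlowHistory:
    """Run cMCF, recording vertex snapshots and the K-bar curve.

    The flow operates in the unit-area frame (the input is rescaled to
    total surface area 1 and centered); the per-motif time-step presets
    assume this normalization.  Snapshots are returned in that frame —
    rescale by sqrt(original area) to recover the input scale.
    """
    target_area = 1.0 if cfg.normalize else mesh.area()
    scale = np.sqrt(target_area / mesh.area())
    v = (mesh.vertices - mesh.vertices.mean(axis=0)) * scale \
        if cfg.normalize else mesh.vertices.copy()
    faces = mesh.faces
    work = mesh.copy(vertices=v)
    _, lap0 = build_operators(work, cfg.laplacian_kind)
    L0 = lap0.matrix
    snaps = [v.copy()]
    kbars = [float(np.abs(gaussian_curvature(work)).mean())]
    status = "ok"
    for _ in range(cfg.max_iterations):
        work = work.copy(vertices=v)
        mass, _ = build_operators(work, cfg.laplacian_kind)
        A = (mass.matrix + cfg.delta_t * L0).tocsc()
        try:
            solve = spla.factorized(A)
            v_new = np.column_stack([solve(mass.matrix @ v[:, k])
                                     for k in range(3)])
        except RuntimeError:
            status = "singular"
            break
        if not np.isfinite(v_new).all():
            status = "singular"
            break
        if cfg.normalize:
            v_new = _normalize(v_new, faces, target_area)
        v = v_new
        work = work.copy(vertices=v)
        snaps.append(v.copy())
        kbars.append(float(np.abs(gaussian_curvature(work)).mean()))
    hist = FlowHistory(snaps, np.asarray(kbars), faces, status=status)
    hist.stop_index = auto_stop_index(hist, cfg.stop_threshold, cfg.t_min,
                                      strict_literal=cfg.strict_literal_stop)
    return hist


def auto_stop_index(history: FlowHistory, stop_threshold: float,
                    t_min: int = 0, strict_literal: bool = False) -> int:
    """Elbow of the K-bar curve: stop = max(t_min, t_K).

    t_K is the first iteration whose change in mean absolute Gaussian
    curvature has either shrunk below the threshold or turned positive
    (curvature no longer decreasing).  ``strict_literal`` instead triggers
    on dK > threshold, which on monotone decays never fires and returns the
    final iteration.
    """
    kbar = history.mean_abs_gaussian
    if len(kbar) < 2:
        raise ValueError("history needs at least 2 iterations")
    dk = np.diff(kbar)
    T = len(kbar) - 1
    t_k = T
    for t, d in enumerate(dk, start=1):
        trigger = d > stop_threshold if strict_literal else (
            abs(d) < stop_threshold or d > 0)
        if trigger:
            t_k = t
            break
    return int(max(t_min, t_k))


def active_contour_cmcf_step(mesh: SurfaceMesh, force: np.ndarray,
                             delta_t: float,
                             laplacian_kind: str = "cotangent",
                             L0: Optional[sp.spmatrix] = None) -> SurfaceMesh:
    """One implicit step (M - dt*L) v' = M (v + force) of active-contour cMCF.

    ``force`` is a per-vertex 3D displacement; for normal stepping pass
    alpha times the unit gradient of a signed distance function evaluated
    at the vertices.  A positive normal force moves the surface outward.
    """
    force = np.asarray(force, dtype=float)
    if force.shape != mesh.vertices.shape:
        raise ValueError("force must be (n_vertices, 3)")
    mass, lap = build_operators(mesh, laplacian_kind)
    L = lap.matrix if L0 is None else L0
    A = (mass.matrix + delta_t * L).tocsc()
    rhs = mass.matrix @ (mesh.vertices + force)
    v_new = np.column_stack([spla.spsolve(A, rhs[:, k]) for k in range(3)])
    if not np.isfinite(v_new).all():
        raise RuntimeError("singular active-contour system")
    return mesh.copy(vertices=v_new)


def _line_operators(loop: np.ndarray, vertices: np.ndarray, n: int
                    ) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """1D mass and Laplacian of a closed polyline over the full vertex set."""
    pts = vertices[loop]
    seg = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
    seg = np.maximum(seg, 1e-12)
    m = len(loop)
    nxt = np.roll(loop, -1)
    prv = np.roll(loop, 1)
    w_next = 1.0 / seg                          # edge loop[i] -> loop[i+1]
    w_prev = np.roll(w_next, 1)
    rows = np.concatenate([loop, loop, loop])
    cols = np.concatenate([loop, nxt, prv])
    vals = np.concatenate([w_next + w_prev, -w_next, -w_prev])
    L = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    mdiag = np.zeros(n)
    mdiag[loop] = 0.5 * (seg + np.roll(seg, 1))
    M = sp.diags(mdiag).tocsr()
    return M, L


def topographic_cmcf(topo_mesh: SurfaceMesh, iterations: int = 10,
                     delta: float = 5e4,
                     laplacian_kind: str = "robust") -> SurfaceMesh:
    """Flatten an open topographic (d, u, v) mesh toward the (u, v) plane.

    Interior vertices follow standard cMCF.  Boundary vertices evolve with
    the 1D line mass/Laplacian of the boundary loop, and the (u, v)
    components of their Laplacian force are cancelled (no-flux): the
    boundary can move only in depth d, so the flow converges toward the
    planar (u, v) rectangle instead of a shrinking disk.

    Vertex coordinate order is (d, v, u): index 0 is depth.
    """
    loop = boundary_loop(topo_mesh)  # raises if closed or multi-loop
    n = topo_mesh.n_vertices
    v = topo_mesh.vertices.copy()
    mass0, lap0 = build_operators(topo_mesh, laplacian_kind)
    L0 = lap0.matrix
    on_boundary = np.zeros(n, dtype=bool)
    on_boundary[loop] = True
    interior = ~on_boundary
    for _ in range(max(iterations, 0)):
        work = topo_mesh.copy(vertices=v)
        mass, _ = build_operators(work, laplacian_kind)
        Mb, Lb = _line_operators(loop, v, n)

        # interior rows: (M + delta L0) v' = M v
        # boundary rows: (Mb + delta Lb) v' = Mb v + delta*(Lb v) in (u, v)
        Dint = sp.diags(interior.astype(float))
        Dbnd = sp.diags(on_boundary.astype(float))
        A = (Dint @ (mass.matrix + delta * L0)
             + Dbnd @ (Mb + delta * Lb)).tocsc()
        rhs = np.zeros_like(v)
        rhs[interior] = (mass.matrix @ v)[interior]
        base = Mb @ v
        flux = delta * (Lb @ v)
        rhs_b = base.copy()
        rhs_b[:, 1:] += flux[:, 1:]          # cancel u, v motion on boundary
        rhs[on_boundary] = rhs_b[on_boundary]
        solve = spla.factorized(A)
        v = np.column_stack([solve(rhs[:, k]) for k in range(3)])
        if not np.isfinite(v).all():
            raise RuntimeError("topographic cMCF diverged")
    out = topo_mesh.copy(vertices=v)
    out.representation_tag = "plane"
    return out
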