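"""Genus-0 spherical parameterization and equiareal relaxation.

The quasi-conformal map to the unit sphere is obtained by running cMCF to
its spherical limit and projecting vertices radially; cMCF converges
conformally for genus-0 surfaces, so the composition has bounded conformal
error.  A Moebius (inversive) centering then moves the area-weighted
centroid of the spherical mesh to the origin without changing angles.

Area distortion is subsequently relaxed by advecting vertices along the
negative gradient of log(lambda), the per-face area-distortion factor,
which solves the linear heat equation d(lambda)/dt = -Delta(lambda) on the
sphere.  Each iteration: normalize face areas of reference and sphere,
lambda_f = a_ref / a_sphere, V = -grad log(lambda) (per-face gradient of
the vertex-averaged field), normalize V by its median norm times the mean
edge length, average to vertices, project onto the tangent plane, advect
with one active-contour cMCF step of stiffness delta, and renormalize to
the unit sphere.  The loop stops at the selected criterion, on triangle
collapse, or at the iteration cap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .flows import FlowConfig, active_contour_cmcf_step, run_cmcf
from .mesh import SurfaceMesh, surface_topology
from .metrics import face_distortion
from .operators import build_operators, face_gradient, faces_to_vertices

log = logging.getLogger(__name__)


@dataclass
class RelaxationState:
    median_lambda: float
    iqr_lambda: float
    global_conformal: float
    criteria: Dict[str, float]


@dataclass
class SphereParam:
    sphere: SurfaceMesh
    reference: SurfaceMesh
    history: List[RelaxationState] = field(default_factory=list)
    stop_index: Optional[int] = None
    status: str = "ok"

    def distortion(self):
        return face_distortion(self.reference, self.sphere)


# ------------------------------------------------------------------ helpers
def flipped_face_count(sphere: SurfaceMesh) -> int:
    """Spherical triangles whose orientation disagrees with the outward
    normal (signed volume of the cone to the origin is negative)."""
    c = sphere.face_corners()
    vol = np.einsum("ij,ij->i", np.cross(c[:, 0], c[:, 1]), c[:, 2])
    return int((vol < 0).sum())


def _project_unit(v: np.ndarray) -> np.ndarray:
    c = v - v.mean(axis=0)
    return c / np.linalg.norm(c, axis=1, keepdims=True)


def _mobius_center(sphere: SurfaceMesh, max_iter: int = 50,
                   tol: float = 1e-4, step: float = 0.5) -> SurfaceMesh:
    """Inversive centering: drive the area-weighted vertex centroid of the
    spherical mesh to the origin with sphere-preserving Moebius maps."""
    v = sphere.vertices.copy()
    mesh = sphere
    for _ in range(max_iter):
        mesh = mesh.copy(vertices=v)
        w = mesh.vertex_areas()
        c = (w[:, None] * v).sum(axis=0) / w.sum()
        if np.linalg.norm(c) < tol:
            break
        a = -step * c
        na2 = float(a @ a)
        if na2 >= 1.0:
            a = a / np.sqrt(na2) * 0.5
            na2 = 0.25
        # sphere inversion centered at a/|a|^2: maps unit sphere to itself
        d = v + a
        v = (1.0 - na2) * d / np.maximum(
            np.einsum("ij,ij->i", d, d), 1e-300)[:, None] + a
        v /= np.linalg.norm(v, axis=1, keepdims=True)
    out = sphere.copy(vertices=v)
    return out


def spherical_parameterize(ref: SurfaceMesh, flow_dt: float = 0.01,
                           flow_iterations: int = 30,
                           laplacian_kind: str = "robust") -> SphereParam:
    """Map a genus-0 closed mesh bijectively onto the unit sphere.

    Raises if the mesh is not genus 0 or if the resulting spherical mesh
    contains inverted triangles.
    """
    topo = surface_topology(ref)
    if not topo.manifold:
        raise ValueError("non-manifold mesh cannot be parameterized")
    if topo.genus != 0 or topo.boundary_loops:
        raise ValueError(
            f"spherical parameterization needs a closed genus-0 surface, "
            f"got genus={topo.genus}, boundary loops={topo.boundary_loops}")
    # scale to unit mean radius so one dt preset suits all fixture sizes
    center = ref.vertices.mean(axis=0)
    scale = float(np.linalg.norm(ref.vertices - center, axis=1).mean())
    work = ref.copy(vertices=(ref.vertices - center) / scale)
    cfg = FlowConfig(delta_t=flow_dt, max_iterations=flow_iterations,
                     stop_threshold=0.0, laplacian_kind=laplacian_kind,
                     normalize=True)
    hist = run_cmcf(work, cfg)
    v = hist.snapshots[-1]
    sphere = ref.copy(vertices=_project_unit(v), representation_tag="sphere")
    # extend the flow while inverted triangles remain
    for _ in range(5):
        if flipped_face_count(sphere) == 0:
            break
        work = work.copy(vertices=hist.snapshots[-1])
        hist = run_cmcf(work, cfg)
        sphere = ref.copy(vertices=_project_unit(hist.snapshots[-1]),
                          representation_tag="sphere")
    if flipped_face_count(sphere):
        sphere = _untangle_local(sphere)
    sphere = _mobius_center(sphere)
    nflip = flipped_face_count(sphere)
    if nflip:
        raise RuntimeError(
            f"spherical parameterization produced {nflip} flipped faces")
    return SphereParam(sphere, ref)


def _untangle_local(sphere: SurfaceMesh, max_iter: int = 100) -> SurfaceMesh:
    """Resolve isolated inverted spherical triangles by local Tutte-style
    smoothing: vertices of flipped faces (and their one-ring) move to the
    normalized average of their neighbors until orientation is consistent."""
    import scipy.sparse as spm

    edges = np.concatenate([sphere.faces[:, [0, 1]], sphere.faces[:, [1, 2]],
                            sphere.faces[:, [2, 0]]])
    n = sphere.n_vertices
    adj = spm.coo_matrix(
        (np.ones(len(edges) * 2),
         (np.concatenate([edges[:, 0], edges[:, 1]]),
          np.concatenate([edges[:, 1], edges[:, 0]]))), shape=(n, n)).tocsr()
    adj.data[:] = 1.0
    deg = np.asarray(adj.sum(axis=1)).ravel()
    v = sphere.vertices.copy()
    mesh = sphere
    for _ in range(max_iter):
        c = mesh.face_corners()
        vol = np.einsum("ij,ij->i", np.cross(c[:, 0], c[:, 1]), c[:, 2])
        bad = vol <= 0
        if not bad.any():
            break
        region = np.zeros(n, dtype=bool)
        region[np.unique(mesh.faces[bad])] = True
        region |= np.asarray(adj @ region, dtype=bool)
        avg = (adj @ v) / deg[:, None]
        avg /= np.linalg.norm(avg, axis=1, keepdims=True)
        v = np.where(region[:, None], avg, v)
        mesh = mesh.copy(vertices=v)
    return mesh


# ------------------------------------------------------------------ relaxation
@dataclass
class RelaxConfig:
    epsilon: float = 1.0          # vertex step size
    delta: float = 0.1            # cMCF stiffness of the advection solve
    max_iterations: int = 100
    laplacian_kind: str = "robust"   # degenerate spherical slivers occur
    criterion: str = "equiareal"  # equiareal | conformal_mips | isometric_sum | area_mips
    theta: float = 0.5
    equiareal_tol: float = 0.01
    min_angle_deg: float = 0.5
    retry_delta: float = 5e-3


def _min_interior_angle(mesh: SurfaceMesh) -> float:
    c = mesh.face_corners()
    worst = np.inf
    for k in range(3):
        e1 = c[:, (k + 1) % 3] - c[:, k]
        e2 = c[:, (k + 2) % 3] - c[:, k]
        cosang = (np.einsum("ij,ij->i", e1, e2)
                  / np.maximum(np.linalg.norm(e1, axis=1)
                               * np.linalg.norm(e2, axis=1), 1e-300))
        worst = min(worst, float(np.arccos(np.clip(cosang, -1, 1)).min()))
    return np.degrees(worst)


def _state(ref: SurfaceMesh, sphere: SurfaceMesh, theta: float) -> RelaxationState:
    rep = face_distortion(ref, sphere, theta)
    lam = rep.area_distortion
    q1, q3 = np.percentile(lam, [25, 75])
    return RelaxationState(rep.median_area_distortion, float(q3 - q1),
                           rep.global_conformal_error, dict(rep.criteria))


def relax_area_distortion(sp: SphereParam, cfg: Optional[RelaxConfig] = None
                          ) -> SphereParam:
    """Advection-based equiareal relaxation of a spherical parameterization."""
    cfg = cfg or RelaxConfig()
    if cfg.epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    out = _relax_once(sp, cfg, cfg.delta)
    if out.status == "collapsed" and cfg.retry_delta and \
            cfg.retry_delta != cfg.delta:
        log.info("relaxation collapsed at delta=%g, retrying delta=%g",
                 cfg.delta, cfg.retry_delta)
        retry = _relax_once(sp, cfg, cfg.retry_delta)
        if retry.status != "collapsed" or \
                abs(retry.history[-1].median_lambda - 1.0) < \
                abs(out.history[-1].median_lambda - 1.0):
            out = retry
    return out


def _relax_once(sp: SphereParam, cfg: RelaxConfig, delta: float) -> SphereParam:
    ref = sp.reference
    sphere = sp.sphere.copy()
    a_ref = ref.face_areas()
    a_ref = a_ref / a_ref.sum()
    states = [_state(ref, sphere, cfg.theta)]
    snapshots = [sphere.vertices.copy()]
    status = "ok"
    # meshes that already contain slivers get a proportionally lower floor,
    # so pre-existing bad faces do not abort the loop before it starts
    angle_floor = min(cfg.min_angle_deg, 0.5 * _min_interior_angle(sphere))
    for _ in range(cfg.max_iterations):
        a_sph = sphere.face_areas()
        a_sph = a_sph / a_sph.sum()
        lam_f = a_ref / np.maximum(a_sph, 1e-300)
        lam_v = faces_to_vertices(sphere, lam_f)
        V_f = -face_gradient(sphere, np.log(np.maximum(lam_v, 1e-300)))
        norms = np.linalg.norm(V_f, axis=1)
        med = float(np.median(norms))
        if med < 1e-14:
            break
        lbar = float(sphere.edge_lengths().mean())
        V_f = V_f * (lbar / med)
        V_v = faces_to_vertices(sphere, V_f)
        n_v = sphere.vertex_normals()
        V_t = V_v - np.einsum("ij,ij->i", V_v, n_v)[:, None] * n_v
        try:
            advected = active_contour_cmcf_step(
                sphere, cfg.epsilon * V_t, delta,
                laplacian_kind=cfg.laplacian_kind)
        except RuntimeError:
            status = "collapsed"
            break
        v = advected.vertices - advected.vertices.mean(axis=0)
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        cand = sphere.copy(vertices=v)
        if (flipped_face_count(cand)
                or _min_interior_angle(cand) < angle_floor
                or not np.isfinite(v).all()):
            status = "collapsed"
            break
        sphere = cand
        snapshots.append(v.copy())
        states.append(_state(ref, sphere, cfg.theta))
        if cfg.criterion == "equiareal" and \
                abs(states[-1].median_lambda - 1.0) < cfg.equiareal_tol:
            break
    stop = evaluate_stop_criterion(states, cfg.criterion, cfg.theta,
                                   cfg.equiareal_tol)
    final = sp.sphere.copy(vertices=snapshots[stop])
    return SphereParam(final, ref, states, stop, status)


def evaluate_stop_criterion(history: List[RelaxationState], criterion: str,
                            theta: float = 0.5, tol: float = 0.01) -> int:
    """Index of the iteration selected by a relaxation stopping criterion."""
    if not history:
        raise ValueError("empty history")
    if criterion == "conformal_mips":
        # the initial parameterization is conformal, hence minimal MIPS
        return 0
    if criterion == "equiareal":
        for t, s in enumerate(history):
            if abs(s.median_lambda - 1.0) < tol:
                return t
        return len(history) - 1
    if criterion == "isometric_sum":
        vals = [s.criteria["isometric"] for s in history]
        return int(np.argmin(vals))
    if criterion == "area_mips":
        vals = [s.criteria["area_mips"] for s in history]
        return int(np.argmin(vals))
    raise ValueError(f"unknown criterion {criterion!r}")
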