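"""End-to-end orchestration of the six unwrapping steps.

Step 1: cMCF to the curvature elbow, voxelize and remesh to a smooth
genus-0 reference surface.  Step 2: quasi-conformal spherical
parameterization.  Step 3: equiareal relaxation.  Step 4: weighted-PCA
unwrapping axis and equirectangular UV grid.  Step 5: topographic (d,u,v)
space by normal propagation.  Step 6: topographic mesh and its Cartesian
re-embedding.  Genus-0 inputs may skip Step 1 (direct unwrapping).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Dict, Optional

import numpy as np

from .flows import FlowConfig, run_cmcf
from .mesh import SurfaceMesh, surface_topology, transfer_scalars
from .metrics import (compare_meshes, face_distortion, mean_curvature_sdf,
                      radius_ratio, uv_grid_distortion)
from .sphere import RelaxConfig, relax_area_distortion, spherical_parameterize
from .synthetic import FixtureSpec, make_fixture
from .topography import (build_topographic_space, resample_volume,
                         signed_distance, topo_to_cartesian, topographic_mesh)
from .uvmap import build_uv_grid, optimal_rotation_weighted_pca
from .volumes import mesh_from_volume, voxelize

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # Step 1
    cmcf_iterations: int = 50
    cmcf_dt: float = 5e-4
    cmcf_stop_threshold: float = 1e-5
    cmcf_t_min: int = 0
    dilation_radius: int = 5
    remesh_fraction_reference: float = 0.9
    # Steps 2-3
    relax_epsilon: float = 1.0
    relax_delta: float = 0.1
    relax_retry_delta: float = 5e-3
    relax_max_iterations: int = 100
    relax_criterion: str = "equiareal"
    theta: float = 0.5
    # Steps 4-6
    grid_n: int = 256
    alpha: float = 0.5
    d_in: int = 40
    remesh_fraction_topographic: float = 0.5
    topographic_cmcf_iterations: int = 10
    direct: bool = False
    seed: int = 0
    pca_weighting: str = "curvature"   # "curvature" | "none"
    compute_reports: bool = True

    def dump(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class RepresentationBundle:
    input_mesh: SurfaceMesh
    reference: SurfaceMesh
    sphere: SurfaceMesh
    uv_grid: object
    topo_space: object
    topo_binary: np.ndarray
    topo_mesh: SurfaceMesh
    cartesian_topo: SurfaceMesh
    config: PipelineConfig
    reports: Dict[str, object] = field(default_factory=dict)


def run_pipeline(mesh: SurfaceMesh, cfg: Optional[PipelineConfig] = None
                 ) -> RepresentationBundle:
    cfg = cfg or PipelineConfig()
    topo_in = surface_topology(mesh)
    log.info("input: %d vertices, genus %s", mesh.n_vertices, topo_in.genus)

    if cfg.direct and topo_in.genus == 0 and topo_in.watertight:
        reference = mesh.copy(representation_tag="reference")
    else:
        flow = run_cmcf(mesh, FlowConfig(
            delta_t=cfg.cmcf_dt, max_iterations=cfg.cmcf_iterations,
            stop_threshold=cfg.cmcf_stop_threshold, t_min=cfg.cmcf_t_min))
        smooth = flow.mesh_at(flow.stop_index, mesh)
        # cMCF normalizes scale; restore the input frame before voxelizing
        smooth = _match_frame(smooth, mesh)
        vol = voxelize(smooth, dilation_radius=cfg.dilation_radius)
        reference = mesh_from_volume(
            vol, remesh_fraction=cfg.remesh_fraction_reference, seed=cfg.seed)
        reference.representation_tag = "reference"
        ref_topo = surface_topology(reference)
        if ref_topo.genus != 0:
            raise RuntimeError(
                f"step 1 failed to reach genus 0 (residual genus "
                f"{ref_topo.genus})")

    sp = spherical_parameterize(reference)
    conformal_stage = face_distortion(reference, sp.sphere)
    sp = relax_area_distortion(sp, RelaxConfig(
        epsilon=cfg.relax_epsilon, delta=cfg.relax_delta,
        max_iterations=cfg.relax_max_iterations,
        criterion=cfg.relax_criterion, theta=cfg.theta,
        retry_delta=cfg.relax_retry_delta))

    if cfg.pca_weighting == "curvature":
        weights = np.abs(mean_curvature_sdf(reference))
        rot = optimal_rotation_weighted_pca(sp.sphere, weights)
        rotation = rot.rotation
    else:
        rotation = np.eye(3)
    uv = build_uv_grid(sp.sphere, reference, N=cfg.grid_n,
                       rotation=rotation)

    binary = voxelize(mesh, dilation_radius=cfg.dilation_radius)
    ref_binary = voxelize(reference, dilation_radius=cfg.dilation_radius)
    sdf = signed_distance(ref_binary)
    space = build_topographic_space(uv, sdf, alpha=cfg.alpha, d_in=cfg.d_in,
                                    enclose=mesh)
    topo_binary = resample_volume(space, binary.data.astype(np.float32),
                                  origin=binary.origin) >= 0.5
    topo_mesh = topographic_mesh(
        topo_binary, remesh_fraction=cfg.remesh_fraction_topographic,
        seed=cfg.seed)
    cart = topo_to_cartesian(space, topo_mesh)

    bundle = RepresentationBundle(mesh, reference, sp.sphere, uv, space,
                                  topo_binary, topo_mesh, cart, cfg)
    bundle.reports["sphere_distortion_conformal"] = conformal_stage
    if cfg.compute_reports:
        bundle.reports["sphere_distortion"] = face_distortion(reference,
                                                              sp.sphere)
        bundle.reports["uv_distortion"] = uv_grid_distortion(uv)
        bundle.reports["reconstruction"] = compare_meshes(cart, mesh,
                                                          seed=cfg.seed)
    return bundle


def _signed_volume(mesh: SurfaceMesh) -> float:
    c = mesh.face_corners()
    return abs(float(np.einsum("ij,ij->i", np.cross(c[:, 0], c[:, 1]),
                               c[:, 2]).sum())) / 6.0


def _match_frame(moved: SurfaceMesh, original: SurfaceMesh) -> SurfaceMesh:
    """Undo the normalization of a flow output: scale so the enclosed
    volume matches the input (the cortex proxy keeps the cell volume;
    matching area instead would inflate it by the protrusions' extra
    area) and restore the centroid."""
    centered = moved.vertices - moved.vertices.mean(axis=0)
    work = moved.copy(vertices=centered)
    scale = (_signed_volume(original) / max(_signed_volume(work), 1e-300)
             ) ** (1.0 / 3.0)
    v = centered * scale
    return moved.copy(vertices=v + original.vertices.mean(axis=0))


def metrics_report(bundle: RepresentationBundle) -> Dict[str, dict]:
    """Machine-readable per-representation summary table."""
    sphere_rep = bundle.reports["sphere_distortion"]
    uv_rep = bundle.reports["uv_distortion"]
    diff = bundle.reports["reconstruction"]
    conf_rep = bundle.reports["sphere_distortion_conformal"]
    rows = {
        "reference_to_sphere_conformal_stage": {
            "conformal_error": conf_rep.global_conformal_error,
            "median_area_distortion": conf_rep.median_area_distortion,
        },
        "reference_to_sphere": {
            "conformal_error": sphere_rep.global_conformal_error,
            "median_area_distortion": sphere_rep.median_area_distortion,
            "n_infinite": sphere_rep.n_infinite,
        },
        "sphere_to_uv": {
            "conformal_error": uv_rep.global_conformal_error,
            "median_area_distortion": uv_rep.median_area_distortion,
        },
        "topographic_vs_input": {
            "chamfer_distance": diff.chamfer_distance,
            "sliced_wasserstein_1": diff.sliced_wasserstein_1,
            "delta_area_percent": diff.delta_area_percent,
            "delta_volume_percent": diff.delta_volume_percent,
        },
        "mesh_quality": {
            "input_median_radius_ratio": float(np.median(
                radius_ratio(bundle.input_mesh))),
            "topographic_median_radius_ratio": float(np.median(
                radius_ratio(bundle.topo_mesh))),
        },
    }
    return rows
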