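"""Shared fixtures: small analytic meshes and one pipeline run reused
session-wide by the integration-level tests."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from meshunwrap import (FixtureSpec, PipelineConfig, SurfaceMesh,
                        make_fixture, run_pipeline)


@pytest.fixture(scope="session")
def icosphere():
    ico = trimesh.creation.icosphere(3)
    return SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


@pytest.fixture(scope="session")
def ball_mesh():
    """Radius-10 sphere positioned in a positive voxel frame."""
    ico = trimesh.creation.icosphere(3)
    return SurfaceMesh(np.asarray(ico.vertices) * 10.0 + 20.0,
                       np.asarray(ico.faces))


@pytest.fixture(scope="session")
def torus_mesh():
    tor = trimesh.creation.torus(major_radius=12.0, minor_radius=4.0,
                                 major_sections=48, minor_sections=24)
    return SurfaceMesh(np.asarray(tor.vertices) + 24.0,
                       np.asarray(tor.faces))


@pytest.fixture(scope="session")
def bumpy_fixture():
    """Bleb fixture with ground truth, used across segmentation tests."""
    return make_fixture(FixtureSpec(radius=32.0, motif="bleb", count=10,
                                    amplitude=0.3, seed=1))


@pytest.fixture(scope="session")
def pipeline_bundle(bumpy_fixture):
    """One full unwrapping run shared by UV / topography / segmentation
    tests (the expensive session fixture)."""
    cfg = PipelineConfig(grid_n=128, d_in=16, dilation_radius=3, seed=0)
    return run_pipeline(bumpy_fixture.mesh, cfg)


def single_triangle(scale: float = 1.0) -> SurfaceMesh:
    v = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                  [0.5, np.sqrt(3) / 2, 0.0]]) * scale
    return SurfaceMesh(v, np.array([[0, 1, 2]]))
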