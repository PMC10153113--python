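"""Curvature, distortion, mesh-difference and face-quality measures."""

import numpy as np
import pytest
import trimesh

from meshunwrap import (SurfaceMesh, compare_meshes, face_distortion,
                        gaussian_curvature, mean_curvature_sdf, radius_ratio,
                        uv_grid_distortion)


def ball(radius, subdiv=3, offset=None):
    ico = trimesh.creation.icosphere(subdiv)
    off = radius + 10.0 if offset is None else offset
    return SurfaceMesh(np.asarray(ico.vertices) * radius + off,
                       np.asarray(ico.faces))


class TestCurvature:
    @pytest.mark.parametrize("radius", [8.0, 12.0, 16.0, 24.0])
    def test_ball_mean_curvature_recovers_inverse_radius(self, radius):
        H = mean_curvature_sdf(ball(radius))
        assert abs(np.median(H) - 1.0 / radius) / (1.0 / radius) < 0.15

    def test_larger_ball_halves_curvature(self):
        h10 = np.median(mean_curvature_sdf(ball(10.0)))
        h20 = np.median(mean_curvature_sdf(ball(20.0)))
        assert abs(h20 / h10 - 0.5) < 0.15

    def test_flat_slab_face_is_flat(self):
        box = trimesh.creation.box(extents=(40, 40, 20))
        mesh = SurfaceMesh(np.asarray(box.subdivide().subdivide().subdivide()
                                      .vertices) + 30.0,
                           np.asarray(box.subdivide().subdivide().subdivide()
                                      .faces))
        H = mean_curvature_sdf(mesh)
        center = np.abs(mesh.vertices - 30.0)
        flat = (center[:, 2] > 9.5) & (center[:, 0] < 8) & (center[:, 1] < 8)
        assert np.abs(H[flat]).max() < 0.02

    def test_gauss_bonnet_sphere(self, icosphere):
        assert np.isclose(gaussian_curvature(icosphere).sum(), 4 * np.pi,
                          atol=1e-6)

    def test_gauss_bonnet_torus(self, torus_mesh):
        assert np.isclose(gaussian_curvature(torus_mesh).sum(), 0.0,
                          atol=1e-6)

    def test_tetrahedron_angular_deficit(self):
        tet = trimesh.creation.icosahedron()  # placeholder shape below
        v = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                     dtype=float)
        f = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
        K = gaussian_curvature(SurfaceMesh(v, f))
        assert np.allclose(K, np.pi, atol=1e-9)


class TestFaceDistortion:
    def test_identity_map(self, icosphere):
        rep = face_distortion(icosphere, icosphere)
        assert np.allclose(rep.conformal_error, 1.0, atol=1e-9)
        assert np.allclose(rep.area_distortion, 1.0, atol=1e-9)
        assert rep.global_conformal_error == pytest.approx(1.0)

    def test_uniform_scaling_is_isometric_in_fractions(self, icosphere):
        scaled = icosphere.copy(vertices=icosphere.vertices * 2.0)
        rep = face_distortion(icosphere, scaled)
        assert np.allclose(rep.conformal_error, 1.0, atol=1e-9)
        assert np.allclose(rep.area_distortion, 1.0, atol=1e-9)

    def test_anisotropic_stretch_gives_q_two(self):
        src = SurfaceMesh(
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float),
            np.array([[0, 1, 2]]))
        dst = src.copy(vertices=src.vertices * np.array([2.0, 1.0, 1.0]))
        rep = face_distortion(src, dst)
        assert rep.global_conformal_error == pytest.approx(2.0, abs=1e-9)

    def test_collapsed_face_counted_infinite(self, icosphere):
        bad = icosphere.copy()
        bad.vertices[icosphere.faces[0]] = bad.vertices[icosphere.faces[0][0]]
        rep = face_distortion(icosphere, bad)
        assert rep.n_infinite >= 1
        assert np.isfinite(rep.global_conformal_error)

    def test_lambda_reciprocal_under_swap(self, bumpy_fixture, icosphere):
        rng = np.random.default_rng(3)
        warped = icosphere.copy(
            vertices=icosphere.vertices
            * (1 + 0.2 * rng.normal(size=(icosphere.n_vertices, 1))))
        fwd = face_distortion(icosphere, warped).area_distortion
        back = face_distortion(warped, icosphere).area_distortion
        assert np.allclose(fwd * back, 1.0, atol=1e-8)


class TestUVGridDistortion:
    def _equirect_sphere_grid(self, N=64):
        from meshunwrap.uvmap import UVGrid

        v = np.linspace(0, np.pi, N)
        u = np.linspace(-np.pi, np.pi, 2 * N + 1)
        vv, uu = np.meshgrid(v, u, indexing="ij")
        coords = np.stack([np.sin(vv) * np.cos(uu),
                           np.sin(vv) * np.sin(uu), np.cos(vv)], axis=-1)
        return UVGrid(coords, np.zeros((N, 2 * N + 1), int),
                      np.zeros((N, 2 * N + 1, 3)),
                      np.zeros((N, 2 * N + 1)), np.eye(3))

    def test_unit_sphere_conformal_error_is_inverse_sin(self):
        grid = self._equirect_sphere_grid()
        rep = uv_grid_distortion(grid)
        N = 64
        v = np.linspace(0, np.pi, N)
        Q = rep.conformal_error.reshape(N, 2 * N)
        interior = slice(5, N - 5)
        expected = 1.0 / np.sin(v[interior])
        measured = np.median(Q[interior], axis=1)
        assert np.allclose(measured, expected, rtol=0.05)

    def test_planar_grid_is_isometric(self):
        from meshunwrap.uvmap import UVGrid

        y, x = np.mgrid[0:32, 0:65].astype(float)
        coords = np.stack([x, y, np.zeros_like(x)], axis=-1)
        grid = UVGrid(coords, np.zeros((32, 65), int),
                      np.zeros((32, 65, 3)), np.zeros((32, 65)), np.eye(3),
                      periodic_u=False)
        rep = uv_grid_distortion(grid)
        assert np.allclose(rep.conformal_error, 1.0, atol=1e-9)
        lam = rep.area_distortion
        assert np.allclose(lam, lam[0], rtol=1e-9)

    def test_small_grid_rejected(self):
        from meshunwrap.uvmap import UVGrid

        tiny = UVGrid(np.zeros((2, 3, 3)), np.zeros((2, 3), int),
                      np.zeros((2, 3, 3)), np.zeros((2, 3)), np.eye(3))
        with pytest.raises(ValueError):
            uv_grid_distortion(tiny)


class TestCompareMeshes:
    def test_identical_meshes_are_zero(self, icosphere):
        diff = compare_meshes(icosphere, icosphere, compute_volume=False)
        assert diff.chamfer_distance == 0.0
        assert diff.sliced_wasserstein_1 < 1e-12
        assert diff.delta_area_percent == 0.0

    def test_normal_translation_shows_in_chamfer(self):
        # a flat sheet moved along its normal: every nearest-vertex match
        # is exactly the offset
        y, x = np.mgrid[0:16, 0:16].astype(float)
        sheet = SurfaceMesh(
            np.column_stack([x.ravel(), y.ravel(), np.zeros(256)]),
            np.array([[i * 16 + j, i * 16 + j + 1, i * 16 + j + 16]
                      for i in range(15) for j in range(15)]))
        moved = sheet.copy(vertices=sheet.vertices + [0.0, 0.0, 3.0])
        diff = compare_meshes(sheet, moved, compute_volume=False)
        assert diff.chamfer_distance == pytest.approx(3.0, abs=1e-12)

    def test_area_difference_between_spheres(self):
        m10, m11 = ball(10.0), ball(11.0)
        diff = compare_meshes(m10, m11, compute_volume=False)
        expected = 100.0 * (100.0 - 121.0) / 121.0
        assert diff.delta_area_percent == pytest.approx(expected, abs=1.0)

    def test_chamfer_matches_brute_force(self, icosphere):
        rng = np.random.default_rng(5)
        other = icosphere.copy(
            vertices=icosphere.vertices + 0.1 * rng.normal(
                size=icosphere.vertices.shape))
        diff = compare_meshes(icosphere, other, compute_volume=False)
        d1 = np.linalg.norm(icosphere.vertices[:, None]
                            - other.vertices[None], axis=2)
        brute = 0.5 * (d1.min(axis=1).mean() + d1.min(axis=0).mean())
        assert diff.chamfer_distance == pytest.approx(brute, abs=1e-12)


class TestRadiusRatio:
    def test_equilateral_is_one(self):
        from conftest import single_triangle

        assert radius_ratio(single_triangle())[0] == pytest.approx(1.0,
                                                                   abs=1e-12)

    def test_needle_approaches_zero(self):
        needle = SurfaceMesh(
            np.array([[0, 0, 0], [1, 0, 0], [0.5, 1e-6, 0]], dtype=float),
            np.array([[0, 1, 2]]))
        assert radius_ratio(needle)[0] < 1e-3

    def test_right_isoceles_closed_form(self):
        # legs 1, 1: r_in = (2 - sqrt(2))/2, r_circ = sqrt(2)/2
        tri = SurfaceMesh(
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float),
            np.array([[0, 1, 2]]))
        expected = 2 * ((2 - np.sqrt(2)) / 2) / (np.sqrt(2) / 2)
        assert radius_ratio(tri)[0] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.8284, abs=1e-4)
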