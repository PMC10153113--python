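"""Reference-surface inference, affinity construction, binary and instance
segmentation, disk unwrapping, watershed refinement and volumization."""

import numpy as np
import pytest
import trimesh

from meshunwrap import (ALSConfig, SurfaceMesh, als_baseline, binary_segment,
                        build_affinity, inpaint_reference,
                        propagate_labels_depth, protrusion_height,
                        unwrap_protrusion, uv_height_image,
                        volumize_protrusions)
from meshunwrap.segmentation import (HeightField, LabelField,
                                     _disk_to_square, label_spread)


class TestHeightImage:
    def test_half_space_constant(self):
        b = np.zeros((60, 8, 8), bool)
        b[:41] = True
        img = uv_height_image(b)
        assert np.allclose(img, 40.0)

    def test_longest_run_wins(self):
        b = np.zeros((60, 1, 1), bool)
        b[0:31, 0, 0] = True     # run of 31 ending at 30
        b[50:56, 0, 0] = True    # run of 6
        assert uv_height_image(b)[0, 0] == 30.0

    def test_bump_maxima_at_planted_centers(self, pipeline_bundle,
                                            bumpy_fixture):
        from scipy import ndimage

        depth = uv_height_image(pipeline_bundle.topo_binary)
        ref_d = pipeline_bundle.topo_space.reference_index
        peaks = depth > ref_d + 6
        lab, n = ndimage.label(peaks)
        # merge components split across the periodic u-seam
        pairs = {(a, b) for a, b in zip(lab[:, 0], lab[:, -2])
                 if a > 0 and b > 0 and a != b}
        for a, b in pairs:
            lab[lab == b] = a
        ids = np.unique(lab[lab > 0])
        sizes = np.array([(lab == i).sum() for i in ids])
        assert (sizes > 20).sum() == bumpy_fixture.spec.count


class TestALSBaseline:
    def test_constant_image_is_fixed_point(self):
        img = np.full((32, 64), 7.0)
        out = als_baseline(img)
        assert np.abs(out - 7.0).max() < 1e-6

    def test_symmetric_unpenalized_limit_recovers_input(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(32, 64)).cumsum(axis=1) / 8.0
        out = als_baseline(img, ALSConfig(p=0.5, lambda_reg=1e-8,
                                          downsample=1))
        assert np.abs(out - img).max() < 1e-3 * np.ptp(img)

    def test_spike_is_ignored_by_asymmetric_weights(self):
        img = np.full((64, 64), 10.0)
        img[30:34, 30:34] = 60.0
        out = als_baseline(img, ALSConfig(p=0.25, lambda_reg=1.0,
                                          downsample=8))
        under_spike = out[30:34, 30:34]
        assert np.abs(under_spike - 10.0).max() < 0.1 * 10.0

    def test_matches_1d_reference_solver(self):
        # independent oracle: dense 1D asymmetric Whittaker solved directly
        rng = np.random.default_rng(1)
        row = 10.0 + rng.uniform(0, 1, 48)
        row[20:24] += 30.0
        img = np.tile(row, (48, 1))

        lam, p, iters = 1.0, 0.25, 10
        n = len(row)
        D = np.diff(np.eye(n), 2, axis=0)
        z = row.copy()
        for _ in range(iters):
            w = np.where(row > z, p, 1 - p)
            z = np.linalg.solve(np.diag(w) + lam * (D.T @ D), w * row)
        out = als_baseline(img, ALSConfig(p=p, lambda_reg=lam,
                                          downsample=1, iterations=iters))
        mid = out[24]
        # the 2D solution along a constant-in-v image matches the 1D oracle
        assert np.abs(mid - z).max() < 0.05 * np.ptp(row)

    def test_invalid_asymmetry_rejected(self):
        with pytest.raises(ValueError):
            ALSConfig(p=1.5)


class TestProtrusionHeight:
    def test_zero_reference_returns_depth(self, pipeline_bundle):
        tm = pipeline_bundle.topo_mesh
        hf = protrusion_height(tm, np.zeros((pipeline_bundle.topo_binary
                                             .shape[1:])))
        assert np.allclose(hf.height, tm.vertices[:, 0])

    def test_mesh_on_reference_has_zero_height(self, pipeline_bundle):
        tm = pipeline_bundle.topo_mesh
        img = np.zeros(pipeline_bundle.topo_binary.shape[1:])
        # reference image equal to each vertex's own interpolated depth
        from scipy import ndimage

        hf = protrusion_height(tm, img)
        hf2 = HeightField(hf.height - hf.height, img, img)
        assert np.allclose(hf2.height, 0.0)

    def test_planted_bump_height_recovered(self, pipeline_bundle,
                                           bumpy_fixture):
        from meshunwrap import als_baseline, uv_height_image

        depth = uv_height_image(pipeline_bundle.topo_binary)
        dref = als_baseline(depth)
        hf = protrusion_height(pipeline_bundle.topo_mesh, dref, depth)
        expected = bumpy_fixture.spec.amplitude * bumpy_fixture.spec.radius
        expected /= pipeline_bundle.topo_space.alpha * 2  # d-steps of 0.5
        got = np.percentile(hf.height, 99.9)
        assert got == pytest.approx(bumpy_fixture.spec.amplitude
                                    * bumpy_fixture.spec.radius
                                    / pipeline_bundle.topo_space.alpha,
                                    rel=0.25)


class TestAffinity:
    def test_gamma_one_is_distance_only(self, icosphere):
        a_full = build_affinity(icosphere, gamma=1.0)
        a_dist = build_affinity(icosphere, gamma=1.0)
        assert np.allclose(a_full.matrix.toarray(), a_dist.matrix.toarray())
        assert np.allclose(a_full.matrix.diagonal(), 1.0)

    def test_identical_normals_give_unit_convex_affinity(self):
        # flat sheet: all vertex normals equal -> convexity distance zero
        y, x = np.mgrid[0:4, 0:4].astype(float)
        v = np.column_stack([x.ravel(), y.ravel(), np.zeros(16)])
        faces = []
        for i in range(3):
            for j in range(3):
                a = i * 4 + j
                faces += [[a, a + 1, a + 4], [a + 1, a + 5, a + 4]]
        flat = SurfaceMesh(v, np.asarray(faces))
        a_conv = build_affinity(flat, gamma=0.0)
        off = a_conv.matrix.toarray()
        np.fill_diagonal(off, 0.0)
        assert np.allclose(off[off > 0], 1.0, atol=1e-9)

    def test_uniform_distances_hit_kernel_value(self, icosphere):
        # icosphere edges are near-uniform: off-diagonal entries approach
        # exp(-1/2) when all distances equal the mean
        a = build_affinity(icosphere, gamma=1.0)
        off = a.matrix.toarray()
        np.fill_diagonal(off, 0.0)
        vals = off[off > 0]
        assert np.median(vals) == pytest.approx(np.exp(-0.5), abs=0.05)

    def test_symmetry_and_range(self, pipeline_bundle):
        A = build_affinity(pipeline_bundle.topo_mesh, gamma=0.9).matrix
        assert (A != A.T).nnz == 0
        assert A.data.min() >= 1e-12
        assert A.data.max() <= 1.0 + 1e-12


class TestBinarySegment:
    def test_flat_surface_returns_empty(self, icosphere):
        A = build_affinity(icosphere, 0.9)
        h = HeightField(np.zeros(icosphere.n_vertices) + 0.01,
                        np.zeros((4, 4)), np.zeros((4, 4)))
        mesh = icosphere.copy(representation_tag="topographic")
        out = binary_segment(h, A, mesh, icosphere.vertex_areas())
        assert (out.labels == 0).all()

    def test_small_seed_components_removed(self, icosphere):
        A = build_affinity(icosphere, 0.9)
        h = np.zeros(icosphere.n_vertices)
        h[0] = 100.0  # single-vertex spike: area far below 200 voxel^2
        hf = HeightField(h, np.zeros((4, 4)), np.zeros((4, 4)))
        out = binary_segment(hf, A, icosphere, icosphere.vertex_areas())
        assert (out.labels == 0).all()

    def test_bleb_fixture_coverage(self, pipeline_bundle, bumpy_fixture):
        from meshunwrap import als_baseline, transfer_scalars
        from meshunwrap.validation import segment_fixture

        seg = segment_fixture(bumpy_fixture, pipeline_bundle)
        truth = seg["truth_on_topo"] > 0
        got = seg["binary"].labels > 0
        iou = (truth & got).sum() / (truth | got).sum()
        assert iou >= 0.7


class TestInstanceSegment:
    def test_planted_bump_count_recovered(self, pipeline_bundle,
                                          bumpy_fixture):
        from meshunwrap.validation import segment_fixture

        seg = segment_fixture(bumpy_fixture, pipeline_bundle)
        labels = seg["instances"].labels
        k = len(np.unique(labels[labels > 0]))
        assert k == bumpy_fixture.spec.count

    def test_smooth_ball_gives_no_instances(self, ball_mesh):
        from meshunwrap import (PipelineConfig, run_pipeline)
        from meshunwrap.validation import segment_fixture
        from meshunwrap.synthetic import Fixture, FixtureSpec

        cfg = PipelineConfig(grid_n=64, d_in=6, dilation_radius=3,
                             remesh_fraction_reference=0.9,
                             relax_max_iterations=10)
        bundle = run_pipeline(ball_mesh, cfg)
        fx = Fixture(ball_mesh, np.zeros(ball_mesh.n_vertices, np.int64),
                     None, None, FixtureSpec(radius=16.0, count=0))
        seg = segment_fixture(fx, bundle)
        labels = seg["instances"].labels
        assert len(np.unique(labels[labels > 0])) == 0

    def test_deterministic_given_seed(self, pipeline_bundle, bumpy_fixture):
        from meshunwrap.validation import segment_fixture

        a = segment_fixture(bumpy_fixture, pipeline_bundle, seed=5)
        b = segment_fixture(bumpy_fixture, pipeline_bundle, seed=5)
        assert np.array_equal(a["instances"].labels, b["instances"].labels)


class TestLabelSpread:
    def test_seeds_are_retained(self, icosphere):
        A = build_affinity(icosphere, 0.9)
        seeds = np.zeros(icosphere.n_vertices, np.int64)
        seeds[0], seeds[100] = 1, 2
        out = label_spread(A.matrix, seeds, iterations=10)
        assert out[0] == 1 and out[100] == 2

    def test_every_vertex_adopts_some_seed(self, icosphere):
        A = build_affinity(icosphere, 0.9)
        seeds = np.zeros(icosphere.n_vertices, np.int64)
        seeds[0], seeds[320] = 1, 2
        out = label_spread(A.matrix, seeds, iterations=60)
        assert set(np.unique(out)) <= {1, 2}
        assert (out == 1).sum() > 1 and (out == 2).sum() > 1


class TestDiskUnwrap:
    def _hemisphere(self):
        ico = trimesh.creation.icosphere(3)
        v = np.asarray(ico.vertices)
        f = np.asarray(ico.faces)
        keep = v[:, 2] > 0.05
        vid = np.nonzero(keep)[0]
        remap = -np.ones(len(v), int)
        remap[vid] = np.arange(len(vid))
        return SurfaceMesh(v[vid], remap[f[keep[f].all(axis=1)]])

    def test_flat_disk_is_conformal(self):
        disk_pts = []
        disk_faces = []
        # triangulated planar disk via polar grid
        rings, sectors = 6, 24
        disk_pts.append([0.0, 0.0, 0.0])
        for r in range(1, rings + 1):
            for s in range(sectors):
                a = 2 * np.pi * s / sectors
                disk_pts.append([r / rings * np.cos(a),
                                 r / rings * np.sin(a), 0.0])
        pts = np.asarray(disk_pts)
        import scipy.spatial

        tri = scipy.spatial.Delaunay(pts[:, :2])
        mesh = SurfaceMesh(pts, tri.simplices)
        res = unwrap_protrusion(mesh, N=64, relax_iterations=0)
        from meshunwrap import face_distortion

        flat = SurfaceMesh(
            np.column_stack([res["disk"], np.zeros(len(pts))]), mesh.faces)
        rep = face_distortion(mesh, flat)
        assert rep.global_conformal_error < 1.02

    def test_disk_to_square_corner_point(self):
        out = _disk_to_square(np.array([[1.0, 0.0], [0.0, 1.0],
                                        [0.0, 0.0]]))
        assert np.allclose(out, [[1, 0], [0, 1], [0, 0]], atol=1e-12)

    def test_hemisphere_equiareal_contract(self):
        hemi = self._hemisphere()
        res = unwrap_protrusion(hemi, N=64)
        from meshunwrap import face_distortion

        flat = SurfaceMesh(
            np.column_stack([res["disk"], np.zeros(hemi.n_vertices)]),
            hemi.faces)
        rep = face_distortion(hemi, flat)
        assert rep.median_area_distortion == pytest.approx(1.0, abs=0.1)
        # no inverted 2D faces
        c = flat.vertices[flat.faces][:, :, :2]
        e1 = c[:, 1] - c[:, 0]
        e2 = c[:, 2] - c[:, 0]
        det = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
        assert (det > 0).all() or (det < 0).all()

    def test_closed_surface_rejected(self, icosphere):
        with pytest.raises(ValueError):
            unwrap_protrusion(icosphere, N=32)


class TestRefineSplit:
    def test_merged_hemispheres_split_into_two(self):
        from meshunwrap.validation import merged_bleb_fixture
        from meshunwrap.segmentation import refine_split_blebs

        mesh, merged, H = merged_bleb_fixture()
        A = build_affinity(mesh, 0.9)
        out = refine_split_blebs(mesh, LabelField(merged, "cartesian"), H,
                                 mesh.vertex_areas(), A=A)
        assert len(np.unique(out.labels[out.labels > 0])) == 2

    def test_single_bleb_unchanged(self):
        from meshunwrap.validation import merged_bleb_fixture
        from meshunwrap.segmentation import refine_split_blebs

        mesh, merged, H = merged_bleb_fixture()
        # restrict the label to one cap only
        single = merged.copy()
        keep = mesh.vertices[:, 1] < 50.0
        single[~keep & (merged > 0)] = 0
        A = build_affinity(mesh, 0.9)
        out = refine_split_blebs(mesh, LabelField(single, "cartesian"), H,
                                 mesh.vertex_areas(), A=A)
        assert len(np.unique(out.labels[out.labels > 0])) == 1

    def test_split_improves_agreement_with_truth(self):
        from sklearn.metrics import adjusted_mutual_info_score
        from meshunwrap.validation import merged_bleb_fixture
        from meshunwrap.segmentation import refine_split_blebs

        mesh, merged, H = merged_bleb_fixture()
        # ground truth: assign each labeled vertex to the nearer cap center
        c1 = np.array([1.0, 0.0, 0.0])
        c2 = np.array([np.cos(0.55), np.sin(0.55), 0.0])
        dirs = mesh.vertices - 50.0
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        truth = merged.copy()
        truth[(dirs @ c2 > dirs @ c1) & (merged > 0)] = 2
        A = build_affinity(mesh, 0.9)
        out = refine_split_blebs(mesh, LabelField(merged, "cartesian"), H,
                                 mesh.vertex_areas(), A=A)
        before = adjusted_mutual_info_score(truth, merged)
        after = adjusted_mutual_info_score(truth, out.labels)
        assert after >= before


class TestInpaint:
    def test_no_holes_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(16, 16))
        out = inpaint_reference(img, np.zeros((16, 16), bool))
        assert np.array_equal(out, img)

    def test_single_pixel_in_constant_surround(self):
        img = np.full((16, 16), 3.0)
        mask = np.zeros((16, 16), bool)
        mask[8, 8] = True
        out = inpaint_reference(img, mask)
        assert out[8, 8] == pytest.approx(3.0, abs=1e-6)

    def test_masked_disk_on_ramp(self):
        y, x = np.mgrid[0:32, 0:32].astype(float)
        img = x.copy()
        mask = (x - 16) ** 2 + (y - 16) ** 2 <= 25
        out = inpaint_reference(img, mask)
        assert np.abs(out[mask] - x[mask]).max() < 0.10 * np.ptp(img)

    def test_fully_masked_rejected(self):
        with pytest.raises(ValueError):
            inpaint_reference(np.zeros((4, 4)), np.ones((4, 4), bool))


class TestVolumization:
    def test_column_protrusion_gets_one_label(self):
        tb = np.zeros((20, 16, 16), bool)
        tb[:8] = True
        tb[8:18, 4:8, 4:8] = True
        seeds = np.zeros_like(tb, dtype=np.int64)
        seeds[17, 5, 5] = 1
        out = propagate_labels_depth(tb, seeds)
        assert set(np.unique(out[8:][tb[8:]])) == {1}
        assert (out[8:18, 4:8, 4:8] == 1).all()

    def test_label_set_is_conserved(self):
        tb = np.zeros((16, 24, 24), bool)
        tb[:6] = True
        tb[6:14, 3:7, 3:7] = True
        tb[6:14, 15:19, 15:19] = True
        seeds = np.zeros_like(tb, dtype=np.int64)
        seeds[13, 5, 5] = 1
        seeds[13, 17, 17] = 2
        out = propagate_labels_depth(tb, seeds)
        assert set(np.unique(out[out > 0])) == {1, 2}

    def test_parallel_columns_do_not_leak(self):
        tb = np.zeros((16, 24, 24), bool)
        tb[:6] = True
        tb[6:14, 3:7, 3:7] = True
        tb[6:14, 15:19, 15:19] = True
        seeds = np.zeros_like(tb, dtype=np.int64)
        seeds[13, 5, 5] = 1
        seeds[13, 17, 17] = 2
        out = propagate_labels_depth(tb, seeds)
        assert (out[6:14, 3:7, 3:7] == 1).all()
        assert (out[6:14, 15:19, 15:19] == 2).all()

    def test_cylinder_volume_recovered(self):
        tb = np.zeros((30, 32, 32), bool)
        tb[:8] = True
        z, y, x = np.mgrid[0:30, 0:32, 0:32]
        cyl = ((y - 16) ** 2 + (x - 16) ** 2 <= 25) & (z >= 8) & (z < 28)
        tb |= cyl
        seeds = np.zeros_like(tb, dtype=np.int64)
        seeds[27, 16, 16] = 1
        vol_lab = propagate_labels_depth(tb, seeds)
        ref = np.zeros_like(tb)
        ref[:8] = True
        lab, vols = volumize_protrusions(vol_lab, ref)
        expected = np.pi * 25 * 20
        assert vols[1] == pytest.approx(expected, rel=0.15)

    def test_protrusion_below_reference_removed(self):
        tb = np.zeros((20, 16, 16), bool)
        tb[:10] = True
        seeds = np.zeros_like(tb, dtype=np.int64)
        seeds[5, 8, 8] = 3      # internal structure below the reference
        vol_lab = propagate_labels_depth(tb, seeds)
        ref = np.zeros_like(tb)
        ref[:12] = True
        lab, vols = volumize_protrusions(vol_lab, ref)
        assert 3 not in vols
        assert (lab == 0).all()
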