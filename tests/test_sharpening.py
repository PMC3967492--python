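import numpy as np
import pytest

import meshsharp as ms
from meshsharp.segmentation import FEATURE, SMOOTH, FaceLabels
from meshsharp.sharpening import (
    SharpenConfig,
    filter_normal,
    greedy_normal_propagation,
    sharpening_weight,
    update_vertex_positions,
    vertex_update_energy,
)


def _labels(mesh, feature_ids):
    labels = np.full(mesh.n_faces, SMOOTH, dtype=np.int64)
    labels[list(feature_ids)] = FEATURE
    return FaceLabels(labels=labels, energy=0.0)


class TestWeightsAndFilter:
    def test_weight_values(self):
        tri = ms.TriangleMesh(np.eye(3), np.array([[0, 1, 2]]))
        field = ms.DistanceField(values=np.array([1.0, 2.0, 3.0]), d_max=3.0)
        assert sharpening_weight(0, tri, field, alpha=0.0) == 1.0
        assert sharpening_weight(0, tri, field, alpha=1.0) == pytest.approx(np.exp(-3.0))
        zero = ms.DistanceField(values=np.zeros(3), d_max=1.0)
        assert sharpening_weight(0, tri, zero, alpha=0.5) == 1.0

    def test_filter_fixed_point_for_uniform_normals(self):
        normals = np.tile([0.0, 0.0, 1.0], (5, 1))
        w = np.array([0.2, 0.9, 0.4, 0.1, 0.6])
        np.testing.assert_allclose(
            filter_normal(0, normals, w, np.arange(5)), [0, 0, 1], atol=1e-15
        )

    def test_filter_dominant_weight_wins(self):
        normals = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        w = np.array([1e-6, 1.0])
        out = filter_normal(0, normals, w, [0, 1])
        angle = np.degrees(np.arccos(np.clip(out @ normals[1], -1, 1)))
        assert angle < 1.0

    def test_filter_cancellation_keeps_original(self):
        normals = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]])
        w = np.ones(2)
        np.testing.assert_array_equal(filter_normal(0, normals, w, [0, 1]), [0, 0, 1])


class TestPropagation:
    def test_empty_feature_region_is_noop(self, small_box):
        mesh = small_box.blurred
        adj = ms.build_adjacency(mesh)
        field = ms.DistanceField(values=np.zeros(mesh.n_vertices), d_max=1.0)
        nf = greedy_normal_propagation(
            mesh, adj, field, _labels(mesh, []), SharpenConfig()
        )
        np.testing.assert_array_equal(nf.current, nf.original)

    def test_single_tilted_face_adopts_plane_normal(self):
        # 3x3 grid of triangles in z=0; mark one interior face feature: its
        # coplanar smooth neighbourhood pulls it to the common plane normal
        xs, ys = np.meshgrid(np.arange(4.0), np.arange(4.0))
        v = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(16)])
        faces = []
        for r in range(3):
            for c in range(3):
                a = 4 * r + c
                faces.append((a, a + 1, a + 5))
                faces.append((a, a + 5, a + 4))
        mesh = ms.TriangleMesh(v, np.array(faces)).validate()
        adj = ms.build_adjacency(mesh)
        field = ms.DistanceField(values=np.ones(16), d_max=1.0)
        nf = greedy_normal_propagation(
            mesh, adj, field, _labels(mesh, [8]), SharpenConfig(alpha=0.5)
        )
        np.testing.assert_allclose(nf.current[8], [0, 0, 1], atol=1e-12)

    def test_smooth_normals_bit_identical(self, study_box, study_runs):
        _, noisy = study_box
        _, diag = study_runs[0.5]
        nf = diag["normals"]
        smooth = ~diag["labels"].feature_mask
        np.testing.assert_array_equal(nf.current[smooth], nf.original[smooth])

    def test_band_normals_align_with_planes_at_high_alpha(self, study_box):
        bundle, noisy = study_box
        attrs = ms.compute_face_attributes(noisy)
        adj = ms.build_adjacency(noisy)
        eig = ms.compute_vertex_tensors(noisy, attrs, adj)
        pts = ms.build_feature_points(eig)
        stats = ms.cluster_and_select_smooth(pts, 3, 0)
        field = ms.mahalanobis_distance_field(pts, stats)
        labels = ms.min_cut_segment(noisy, adj, field)
        gt = np.array(bundle.plane_normals)
        band = bundle.face_mask == ms.FILLET

        def aligned_fraction(alpha):
            nf = greedy_normal_propagation(
                noisy, adj, field, labels, SharpenConfig(alpha=alpha), attrs
            )
            cos = (nf.current[band] @ gt.T).max(axis=1)
            return (np.degrees(np.arccos(np.clip(cos, -1, 1))) < 5.0).mean()

        high, low = aligned_fraction(0.8), aligned_fraction(0.2)
        # scanner noise keeps some crest faces off the planes; the bulk of
        # the band must align, and more strongly than at low alpha
        assert high > 0.75
        assert high > low


class TestVertexUpdate:
    def test_energy_zero_for_consistent_normals(self, small_box):
        mesh = small_box.blurred
        attrs = ms.compute_face_attributes(mesh)
        assert vertex_update_energy(mesh.vertices, attrs.normals, mesh) < 1e-18

    def test_energy_lifted_vertex(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        mesh = ms.TriangleMesh(v, np.array([[0, 1, 2]]))
        target = np.array([[0.0, 0.0, 1.0]])
        h = 0.37
        lifted = v.copy()
        lifted[0, 2] += h
        assert vertex_update_energy(lifted, target, mesh) == pytest.approx(2 * h * h)

    def test_energy_translation_invariant(self, small_box):
        mesh = small_box.blurred
        attrs = ms.compute_face_attributes(mesh)
        rng = np.random.default_rng(5)
        normals = attrs.normals[rng.permutation(mesh.n_faces)]
        e0 = vertex_update_energy(mesh.vertices, normals, mesh)
        e1 = vertex_update_energy(mesh.vertices + [11.0, -3.0, 0.5], normals, mesh)
        assert e1 == pytest.approx(e0, rel=1e-9)

    def test_targets_equal_normals_is_fixed_point(self, small_box):
        mesh = small_box.blurred
        attrs = ms.compute_face_attributes(mesh)
        out, trace = update_vertex_positions(
            mesh, attrs.normals, _labels(mesh, range(mesh.n_faces)), SharpenConfig()
        )
        assert np.abs(out.vertices - mesh.vertices).max() < 1e-9

    def test_lifted_fan_returns_to_plane(self):
        rng = np.random.default_rng(2)
        angles = np.linspace(0, 2 * np.pi, 7)[:-1]
        ring = np.column_stack([np.cos(angles), np.sin(angles), np.zeros(6)])
        v = np.vstack([[0, 0, 0.43], ring])
        faces = np.array([(0, 1 + t, 1 + (t + 1) % 6) for t in range(6)])
        mesh = ms.TriangleMesh(v, faces)
        target = np.tile([0.0, 0.0, 1.0], (6, 1))
        out, trace = update_vertex_positions(
            mesh, target, _labels(mesh, range(6)), SharpenConfig()
        )
        # ring vertices are free too, but the unique minimum for the center
        # height is the plane of the ring
        assert abs(out.vertices[0, 2] - out.vertices[1:, 2].mean()) < 1e-6
        assert trace[-1] < 1e-12

    def test_trace_monotone_and_anchors_fixed(self, study_box, study_runs):
        _, noisy = study_box
        out, diag = study_runs[0.5]
        trace = diag["energy_trace"]
        assert all(trace[i + 1] <= trace[i] + 1e-15 for i in range(len(trace) - 1))
        feat_v = np.zeros(noisy.n_vertices, bool)
        feat_v[np.unique(noisy.faces[diag["labels"].feature_mask].ravel())] = True
        np.testing.assert_array_equal(
            out.vertices[~feat_v], noisy.vertices[~feat_v]
        )

    def test_no_free_vertices_returns_input(self, small_box):
        mesh = small_box.blurred
        attrs = ms.compute_face_attributes(mesh)
        out, _ = update_vertex_positions(
            mesh, attrs.normals, _labels(mesh, []), SharpenConfig()
        )
        np.testing.assert_array_equal(out.vertices, mesh.vertices)


class TestPipeline:
    def test_sharp_cube_is_fixed_point(self, small_box):
        out, _ = ms.sharpen_pipeline(small_box.sharp, SharpenConfig())
        assert np.abs(out.vertices - small_box.sharp.vertices).max() < 1e-6

    def test_smooth_region_invariance(self, small_box):
        out, diag = ms.sharpen_pipeline(small_box.blurred, SharpenConfig())
        mesh = small_box.blurred
        feat_v = np.zeros(mesh.n_vertices, bool)
        feat_v[np.unique(mesh.faces[diag["labels"].feature_mask].ravel())] = True
        disp = np.abs(out.vertices - mesh.vertices).max(axis=1)
        assert (~feat_v).sum() > 0
        assert disp[~feat_v].max() == 0.0

    def test_diagnostics_shape(self, small_box):
        out, diag = ms.sharpen_pipeline(small_box.blurred, SharpenConfig())
        assert diag["n_feature_faces"] + diag["n_smooth_faces"] == out.n_faces
        assert len(diag["displacements"]) == out.n_vertices
        assert out.n_faces == small_box.blurred.n_faces

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SharpenConfig(alpha=-0.1)
        with pytest.raises(ValueError):
            SharpenConfig(normal_tol_deg=0.0)
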