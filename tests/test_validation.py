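"""Metric scaling, similarity alignment, ICP, and distance statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

import trimesh as _trimesh

from torsoscan import (BeltSpec, TorsoPhantom, align_point_pairs,
                       clinical_threshold_check, cloud_to_mesh_distance,
                       electrode_error, estimate_scale, icp_refine, place_belt)
from torsoscan.electrodes import Electrode, ElectrodeSet
from torsoscan.errors import DegenerateGeometryError, EmptyResultError, \
    InvalidParameterError
from torsoscan.geometry import SimilarityTransform
from torsoscan.surface import SurfaceMesh
from torsoscan.validation import DistanceReport


def electrode_set(centers):
    return ElectrodeSet([Electrode(i, np.asarray(c, float),
                                   np.tile(np.asarray(c, float), (4, 1)), 1)
                         for i, c in centers.items()])


class TestEstimateScale:
    def test_single_pair_ratio(self):
        es = electrode_set({0: [0, 0, 0], 1: [0.5, 0, 0]})
        s = estimate_scale(es, [(0, 1, 0.250)])
        assert s == pytest.approx(0.5)  # 0.25 m per 0.5 units

    def test_recovers_generator_gauge(self):
        r = 1.0 / (2 * np.pi)
        ph = TorsoPhantom(r, r, 2.0, 0.4)
        truth = place_belt(ph, BeltSpec(belt_height_z=0.2))
        gauge = 0.0123
        es = electrode_set({i: truth.marker_centers[i] / gauge
                            for i in range(32)})
        refs = [(i, (i + 1) % 32,
                 float(np.linalg.norm(truth.marker_centers[i]
                                      - truth.marker_centers[(i + 1) % 32])))
                for i in range(32)]
        assert estimate_scale(es, refs) == pytest.approx(gauge, rel=1e-9)

    def test_matches_grid_search_oracle_on_noisy_pairs(self):
        rng = np.random.default_rng(0)
        d_rec = rng.uniform(0.5, 2.0, 20)
        d_ref = 0.75 * d_rec + rng.normal(0, 0.05, 20)
        es = electrode_set({i: [0, 0, 0] for i in range(21)})
        # place electrodes on a line so pair distances equal d_rec
        centers = {0: np.zeros(3)}
        acc = 0.0
        for i, d in enumerate(d_rec):
            acc += d
            centers[i + 1] = np.array([acc, 0, 0])
        es = electrode_set(centers)
        refs = [(i, i + 1, float(d)) for i, d in enumerate(d_ref)]
        s = estimate_scale(es, refs)

        def cost(x):
            return np.sum((d_ref - x * d_rec) ** 2)

        grid = np.linspace(0.5, 1.0, 100001)
        s_grid = grid[np.argmin([cost(g) for g in grid])]
        assert s == pytest.approx(s_grid, abs=1e-5)
        # and against the exact stationary point
        res = minimize(cost, 1.0).x[0]
        assert s == pytest.approx(res, abs=1e-8)

    def test_zero_reconstructed_distance_degenerate(self):
        es = electrode_set({0: [0, 0, 0], 1: [0, 0, 0]})
        with pytest.raises(DegenerateGeometryError):
            estimate_scale(es, [(0, 1, 0.1)])


class TestAlignment:
    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_exact_similarity_recovered(self, seed):
        rng = np.random.default_rng(seed)
        src = rng.normal(0, 1, (12, 3))
        from scipy.spatial.transform import Rotation
        true = SimilarityTransform(rng.uniform(0.3, 3.0),
                                   Rotation.random(random_state=seed).as_matrix(),
                                   rng.normal(0, 2, 3))
        tf = align_point_pairs(src, true.apply(src))
        assert np.allclose(tf.apply(src), true.apply(src), atol=1e-9)
        rt = tf.compose(tf.inverse())
        assert np.allclose(rt.apply(src), src, atol=1e-12)

    def test_reflection_guard(self):
        src = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0],
                        [0.3, 0.4, 0.5]])
        dst = src.copy()
        dst[:, 0] *= -1  # a reflection, not achievable by rotation
        tf = align_point_pairs(src, dst)
        assert np.linalg.det(tf.R) == pytest.approx(1.0)

    def test_collinear_points_rejected(self):
        src = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateGeometryError):
            align_point_pairs(src, src + 1.0)

    def test_residual_matches_nonlinear_optimizer_oracle(self):
        rng = np.random.default_rng(3)
        src = rng.normal(0, 1, (100, 3))
        from scipy.spatial.transform import Rotation
        true = SimilarityTransform(1.4, Rotation.random(random_state=3
                                                        ).as_matrix(),
                                   np.array([0.2, -0.1, 0.5]))
        dst = true.apply(src) + rng.normal(0, 0.01, (100, 3))
        tf = align_point_pairs(src, dst)
        rms = np.sqrt(np.mean(np.sum((tf.apply(src) - dst) ** 2, axis=1)))

        def cost(p):
            R = Rotation.from_rotvec(p[:3]).as_matrix()
            out = np.exp(p[6]) * src @ R.T + p[3:6]
            return np.sum((out - dst) ** 2)

        p0 = np.concatenate([Rotation.from_matrix(tf.R).as_rotvec() + 0.05,
                             tf.t + 0.05, [np.log(tf.scale) + 0.02]])
        res = minimize(cost, p0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14,
                                "maxiter": 20000})
        rms_oracle = np.sqrt(res.fun / len(src))
        assert rms <= rms_oracle + 1e-9


def square_plane_mesh():
    verts = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
    faces = np.array([[0, 1, 2], [0, 2, 3]])  # normal +z
    return SurfaceMesh(verts, faces)


class TestCloudToMesh:
    def test_points_on_mesh_are_zero(self):
        mesh = square_plane_mesh()
        rep = cloud_to_mesh_distance(np.array([[0.5, 0.5, 0.0],
                                               [0.25, 0.75, 0.0]]), mesh)
        assert rep.mean_signed == 0 and rep.std_signed == 0 and rep.max_abs == 0

    def test_signed_by_face_normal_side(self):
        mesh = square_plane_mesh()
        rep = cloud_to_mesh_distance(np.array([[0.5, 0.5, 2.0],
                                               [0.5, 0.5, -1.0]]), mesh)
        assert rep.distances.tolist() == [2000.0, -1000.0]
        assert rep.max_abs == 2000.0

    def test_matches_brute_force_scan(self):
        """Accelerated query equals an independent all-triangles scan
        (trimesh's exact point-triangle routine) on a random instance."""
        rng = np.random.default_rng(7)
        verts = rng.normal(0, 1, (60, 3))
        faces = rng.integers(0, 60, (100, 3))
        faces = faces[(faces[:, 0] != faces[:, 1])
                      & (faces[:, 1] != faces[:, 2])
                      & (faces[:, 0] != faces[:, 2])]
        mesh = SurfaceMesh(verts, faces)
        pts = rng.normal(0, 1.5, (1000, 3))
        rep = cloud_to_mesh_distance(pts, mesh)
        tri = mesh.triangles
        best = np.full(len(pts), np.inf)
        for t in tri:
            closest = _trimesh.triangles.closest_point(
                np.tile(t, (len(pts), 1, 1)), pts)
            d = np.linalg.norm(closest - pts, axis=1)
            best = np.minimum(best, d)
        assert np.allclose(np.abs(rep.distances) / 1e3, best, atol=1e-9)

    def test_report_invariants(self):
        rep = DistanceReport.from_distances_mm(np.array([-2.0, 1.0, 0.5]))
        assert rep.max_abs >= abs(rep.mean_signed)
        assert rep.std_signed >= 0
        assert rep.n == 3


class TestICP:
    def _torso_mesh(self):
        # asymmetric cross-section: all rigid motions observable by ICP
        return TorsoPhantom(0.17, 0.12, 2.5, 0.3).mesh(64, 8)

    def test_small_rigid_motion_recovered(self):
        from scipy.spatial.transform import Rotation
        mesh = self._torso_mesh()
        src = mesh.vertices[::3]
        dR = Rotation.from_euler("z", 0.5, degrees=True).as_matrix()
        moved = src @ dR.T + np.array([0.002, -0.001, 0.0015])
        # register moved points back onto the mesh
        tf, rms = icp_refine(moved, mesh, max_iter=80)
        assert rms[-1] < 1e-4
        assert np.abs(tf.apply(moved) - src).max() < 5e-4

    def test_already_aligned_is_fixed_point(self):
        mesh = self._torso_mesh()
        tf, rms = icp_refine(mesh.vertices[::4], mesh)
        assert len(rms) <= 2 or rms[0] == pytest.approx(rms[-1], abs=1e-12)
        assert rms[-1] < 1e-12

    def test_rms_monotone_non_increasing(self):
        rng = np.random.default_rng(11)
        mesh = self._torso_mesh()
        src = mesh.vertices[::2] + rng.normal(0, 0.003, (len(mesh.vertices[::2]), 3))
        _, rms = icp_refine(src, mesh, max_iter=30)
        assert all(b <= a + 1e-15 for a, b in zip(rms, rms[1:]))


class TestElectrodeError:
    def test_identical_sets_zero(self):
        truth = {i: np.array([i, 0.0, 0.0]) for i in range(8)}
        rep = electrode_error(truth, truth)
        assert rep.mean_signed == 0 and rep.max_abs == 0

    def test_single_displacement_statistics(self):
        truth = {i: np.array([float(i), 0.0, 0.0]) for i in range(32)}
        recon = {i: v.copy() for i, v in truth.items()}
        recon[5] = recon[5] + [0.0, 0.010, 0.0]
        rep = electrode_error(recon, truth)
        assert rep.mean_signed == pytest.approx(10.0 / 32)
        assert rep.max_abs == pytest.approx(10.0)

    def test_no_common_indices_is_error(self):
        with pytest.raises(EmptyResultError):
            electrode_error({0: np.zeros(3)}, {1: np.zeros(3)})

    def test_arc_length_layout_consistency(self):
        """Laying truth centers by cumulative adjacent distances around the
        circular cross-section reproduces the generator's centers."""
        r = 1.0 / (2 * np.pi)
        ph = TorsoPhantom(r, r, 2.0, 0.4)
        truth = place_belt(ph, BeltSpec(belt_height_z=0.2))
        spacing = ph.perimeter / 32
        s = np.arange(32) * spacing
        theta = ph.theta_at_arc_length(s)
        laid = ph.surface_point(theta, 0.2)
        for i in range(32):
            assert np.linalg.norm(laid[i] - truth.marker_centers[i]) < 1e-9


class TestClinicalCheck:
    def _report(self, mean, max_abs):
        return DistanceReport(mean, 1.0, max_abs, 32)

    def test_volunteer_grade_error_passes_with_margin(self):
        chk = clinical_threshold_check(self._report(7.0, 26.8), BeltSpec(),
                                       circumference_m=1.0)
        assert chk.passed
        assert chk.spacing_mm == pytest.approx(31.25)
        assert chk.margin_mm == pytest.approx(31.25 - 26.8)

    def test_one_place_shift_fails(self):
        chk = clinical_threshold_check(self._report(7.2, 57.4), BeltSpec(),
                                       circumference_m=1.0)
        assert not chk.passed

    def test_zero_error_full_margin(self):
        chk = clinical_threshold_check(self._report(0.0, 0.0), BeltSpec(),
                                       circumference_m=1.0)
        assert chk.passed and chk.margin_mm == pytest.approx(31.25)
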