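"""DLT triangulation, two-view initialization, registration, bundle
adjustment — checked against closed-form geometry and a midpoint oracle."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from torsoscan import (BeltSpec, CameraIntrinsics, TorsoPhantom,
                       TrajectorySpec, make_scene, project_scene)
from torsoscan.errors import DegenerateGeometryError, ReconstructionError
from torsoscan.features import (FeatureTrack, corner_tracks_from_observations,
                                tracks_from_observations)
from torsoscan.geometry import CameraPose, look_at_pose, project_points, \
    rotation_geodesic_angle
from torsoscan.sfm import (SfmSettings, SparseCloud, bundle_adjust,
                           initialize_two_view, register_next_view,
                           run_incremental_sfm, triangulate_dlt)
from torsoscan.validation import align_point_pairs


def midpoint_triangulation(x_a, x_b, P_a, P_b):
    """Independent oracle: midpoint of the common perpendicular of the two
    viewing rays (closed form, no SVD)."""
    def ray(x, P):
        M, p4 = P[:, :3], P[:, 3]
        center = -np.linalg.solve(M, p4)
        d = np.linalg.solve(M, np.array([x[0], x[1], 1.0]))
        return center, d / np.linalg.norm(d)

    c1, d1 = ray(x_a, P_a)
    c2, d2 = ray(x_b, P_b)
    # solve [d1 -d2][s;t] = c2-c1 in least squares (normal equations)
    a, b, c = d1 @ d1, d1 @ d2, d2 @ d2
    w = c2 - c1
    denom = a * c - b * b
    s = (c * (d1 @ w) - b * (d2 @ w)) / denom
    t = (b * (d1 @ w) - a * (d2 @ w)) / denom
    return 0.5 * (c1 + s * d1 + c2 + t * d2)


def random_two_view(rng):
    """Two cameras on a random sphere looking at the origin; a point near
    the origin is visible from both."""
    K = CameraIntrinsics(900.0, 900.0, 480.0, 320.0)

    def random_camera():
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        if abs(d[2]) > 0.98:  # avoid up-vector degeneracy in look-at
            d[2] = 0.9 * np.sign(d[2])
            d /= np.linalg.norm(d)
        return look_at_pose(d * rng.uniform(2.0, 4.0), np.zeros(3))

    pa, pb = random_camera(), random_camera()
    while np.linalg.norm(pa.center - pb.center) < 0.3:
        pb = random_camera()
    X = rng.uniform(-0.4, 0.4, 3)
    return K, pa, pb, X


class TestTriangulateDLT:
    def test_exact_two_view_geometry(self):
        K = CameraIntrinsics(100.0, 100.0, 0.0, 0.0)
        pa = CameraPose.from_center(np.eye(3), [-0.5, 0.0, 0.0])
        pb = CameraPose.from_center(np.eye(3), [0.5, 0.0, 0.0])
        X = np.array([0.0, 0.0, 2.0])
        xa, _ = project_points(X, pa, K)
        xb, _ = project_points(X, pb, K)
        rec, in_front = triangulate_dlt(xa[0], xb[0],
                                        pa.projection_matrix(K),
                                        pb.projection_matrix(K))
        assert in_front
        assert np.linalg.norm(rec - X) < 1e-9

    def test_matches_midpoint_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(300):
            K, pa, pb, X = random_two_view(rng)
            Pa, Pb = pa.projection_matrix(K), pb.projection_matrix(K)
            xa, _ = project_points(X, pa, K)
            xb, _ = project_points(X, pb, K)
            rec, _ = triangulate_dlt(xa[0], xb[0], Pa, Pb)
            oracle = midpoint_triangulation(xa[0], xb[0], Pa, Pb)
            worst = max(worst, np.linalg.norm(rec - oracle),
                        np.linalg.norm(rec - X))
        assert worst < 1e-6

    def test_zero_baseline_is_degenerate(self):
        K = CameraIntrinsics(100.0, 100.0, 0.0, 0.0)
        p = CameraPose(np.eye(3), np.zeros(3))
        P = p.projection_matrix(K)
        with pytest.raises(DegenerateGeometryError):
            triangulate_dlt([1.0, 2.0], [1.0, 2.0], P, P)

    def test_behind_camera_sets_cheirality_flag(self):
        K = CameraIntrinsics(100.0, 100.0, 0.0, 0.0)
        pa = CameraPose.from_center(np.eye(3), [-0.5, 0.0, 0.0])
        pb = CameraPose.from_center(np.eye(3), [0.5, 0.0, 0.0])
        X = np.array([0.0, 0.0, -2.0])  # behind both cameras
        # projections of a behind-camera point (virtual image)
        xa = (X - pa.center)[:2] / (X - pa.center)[2] * 100.0
        xb = (X - pb.center)[:2] / (X - pb.center)[2] * 100.0
        rec, in_front = triangulate_dlt(xa, xb, pa.projection_matrix(K),
                                        pb.projection_matrix(K))
        assert not in_front


@pytest.fixture(scope="module")
def sfm_scene(intrinsics):
    r = 1.0 / (2 * np.pi)
    ph = TorsoPhantom(r, r, 2.0, 0.4)
    return make_scene(ph, BeltSpec(belt_height_z=0.2),
                      TrajectorySpec(100.0, 0.70, 9), n_surface_points=150)


def scene_tracks(scene, intrinsics, sigma=0.0, seed=0):
    obs = project_scene(scene, intrinsics, sigma, seed if sigma else None)
    return (tracks_from_observations(obs)
            + corner_tracks_from_observations(obs))


class TestTwoViewInit:
    def test_noiseless_pose_recovery(self, sfm_scene, intrinsics):
        tracks = scene_tracks(sfm_scene, intrinsics)
        poses, points, _ = initialize_two_view(tracks, (3, 5), intrinsics)
        R_true = sfm_scene.poses[5].R @ sfm_scene.poses[3].R.T
        R_rec = poses[5].R @ poses[3].R.T
        assert rotation_geodesic_angle(R_rec, R_true) < 1e-6
        t_true = sfm_scene.poses[5].center - sfm_scene.poses[3].center
        # recovered baseline direction, mapped back to world
        t_rec = poses[5].center - poses[3].center
        t_rec_world = sfm_scene.poses[3].R.T @ poses[3].R @ t_rec
        cos = abs(np.dot(t_true, t_rec_world)
                  / (np.linalg.norm(t_true) * np.linalg.norm(t_rec_world)))
        assert np.arccos(np.clip(cos, -1, 1)) < 1e-6

    def test_pure_rotation_pair_rejected(self, intrinsics):
        rng = np.random.default_rng(2)
        X = rng.uniform([-0.3, -0.3, 1.5], [0.3, 0.3, 2.5], (60, 3))
        pa = CameraPose(np.eye(3), np.zeros(3))
        Rb = Rotation.from_euler("y", 8, degrees=True).as_matrix()
        pb = CameraPose(Rb, np.zeros(3))  # same center, rotated
        tracks = []
        for k, Xk in enumerate(X):
            xa, _ = project_points(Xk, pa, intrinsics)
            xb, _ = project_points(Xk, pb, intrinsics)
            tr = FeatureTrack(k)
            tr.observations = {0: tuple(xa[0]), 1: tuple(xb[0])}
            tracks.append(tr)
        with pytest.raises(ReconstructionError):
            initialize_two_view(tracks, (0, 1), intrinsics)

    def test_planar_scene_still_yields_valid_pose(self, intrinsics):
        rng = np.random.default_rng(3)
        X = np.column_stack([rng.uniform(-0.3, 0.3, 80),
                             rng.uniform(-0.1, 0.1, 80),
                             np.full(80, 2.0)])  # belt-plane points
        pa = CameraPose(np.eye(3), np.zeros(3))
        pb = CameraPose.from_center(
            Rotation.from_euler("y", -5, degrees=True).as_matrix(),
            [0.25, 0.02, 0.0])
        tracks = []
        for k, Xk in enumerate(X):
            xa, _ = project_points(Xk, pa, intrinsics)
            xb, _ = project_points(Xk, pb, intrinsics)
            tr = FeatureTrack(k)
            tr.observations = {0: tuple(xa[0]), 1: tuple(xb[0])}
            tracks.append(tr)
        poses, points, _ = initialize_two_view(tracks, (0, 1), intrinsics)
        R = poses[1].R
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-8)
        assert np.linalg.det(R) > 0
        assert len(points) >= 8


class TestRegistration:
    def test_frame_without_overlap_fails_cleanly(self, sfm_scene, intrinsics):
        tracks = scene_tracks(sfm_scene, intrinsics)
        points = {}  # no triangulated tracks at all
        with pytest.raises(ReconstructionError):
            register_next_view(points, tracks, 4, intrinsics)

    def test_full_arc_registration_noiseless(self, sfm_scene, intrinsics):
        tracks = scene_tracks(sfm_scene, intrinsics)
        cloud = run_incremental_sfm(tracks, intrinsics, SfmSettings(seed=0))
        assert len(cloud.poses) == len(sfm_scene.poses)

    def test_noisy_cloud_reprojection_error_bounded(self, sfm_scene,
                                                    intrinsics):
        tracks = scene_tracks(sfm_scene, intrinsics, sigma=1.0, seed=4)
        cloud = run_incremental_sfm(tracks, intrinsics, SfmSettings(seed=4))
        mean_err = np.mean(list(cloud.point_errors.values()))
        assert mean_err <= 1.5


class TestBundleAdjustment:
    def _noiseless_cloud(self, scene, intrinsics):
        tracks = scene_tracks(scene, intrinsics)
        cloud = run_incremental_sfm(tracks, intrinsics, SfmSettings(seed=0))
        return cloud, tracks

    def test_objective_non_increasing_and_fixed_point(self, sfm_scene,
                                                      intrinsics):
        cloud, tracks = self._noiseless_cloud(sfm_scene, intrinsics)
        before = sum(cloud.point_errors.values())
        refined = bundle_adjust(cloud, tracks)
        after = sum(refined.point_errors.values())
        assert after <= before + 1e-10

    def test_pose_perturbation_recovered(self, sfm_scene, intrinsics):
        cloud, tracks = self._noiseless_cloud(sfm_scene, intrinsics)
        perturbed = SparseCloud(dict(cloud.points), dict(cloud.point_errors),
                                dict(cloud.poses), intrinsics)
        frames = sorted(perturbed.poses)
        target = frames[3]
        dR = Rotation.from_rotvec([0.01, -0.005, 0.008]).as_matrix()
        old = perturbed.poses[target]
        perturbed.poses[target] = CameraPose(dR @ old.R, old.t + 0.002)
        refined = bundle_adjust(perturbed, tracks)
        assert rotation_geodesic_angle(refined.poses[target].R, old.R) < 1e-6
        assert np.mean(list(refined.point_errors.values())) < 1e-6


def test_noise_scaling_of_reprojection_error(sfm_scene, intrinsics):
    """Final RMS reprojection error grows about linearly with the injected
    pixel noise."""
    rms = []
    for sigma in (0.5, 1.0, 2.0):
        tracks = scene_tracks(sfm_scene, intrinsics, sigma=sigma, seed=8)
        cloud = run_incremental_sfm(tracks, intrinsics, SfmSettings(seed=8))
        rms.append(np.sqrt(np.mean(np.square(
            list(cloud.point_errors.values())))))
    assert rms[0] < rms[1] < rms[2]
    # linearity within a factor-of-two band
    assert 0.5 * 2 * rms[0] <= rms[1] <= 2 * 2 * rms[0]
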