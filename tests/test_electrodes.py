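"""Marker detection, harmonization, pairwise corner triangulation, merging,
and electrode assembly."""

import warnings

import numpy as np
import pytest

from torsoscan import BeltSpec, CameraIntrinsics, TorsoPhantom, TrajectorySpec, \
    make_scene, project_scene
from torsoscan.electrodes import (CornerEstimate, MarkerDetection,
                                  assemble_electrodes, detect_markers,
                                  harmonize_pair, merge_corner_vertices,
                                  triangulate_marker_corners)
from torsoscan.errors import EmptyResultError
from torsoscan.scene import render_marker_image, _speckle_background


class TestDetection:
    def test_frontoparallel_marker_detected_accurately(self):
        img, px = render_marker_image(7)
        dets = detect_markers(img)
        assert len(dets) == 1
        assert dets[0].marker_id == 7
        assert np.linalg.norm(dets[0].corners - px, axis=1).max() < 0.5

    def test_inplane_rotation_renormalizes_corner_order(self):
        for roll in (90, 180, 270):
            img, px = render_marker_image(13, roll_deg=roll)
            dets = detect_markers(img)
            assert len(dets) == 1 and dets[0].marker_id == 13
            # canonical order: detection corners equal the projections of
            # the physical TL, TR, BR, BL corners regardless of roll
            assert np.linalg.norm(dets[0].corners - px, axis=1).max() < 0.5

    def test_speckle_only_image_yields_empty_list(self):
        img = _speckle_background((600, 600), np.random.default_rng(0))
        assert detect_markers((img * 255).astype(np.uint8)) == []


class TestHarmonize:
    @staticmethod
    def _det(frame, mid):
        c = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], dtype=float) + mid
        return MarkerDetection(frame, mid, c)

    def test_intersection_of_id_sets(self):
        pairs = harmonize_pair([self._det(0, 3), self._det(0, 4),
                                self._det(0, 5)],
                               [self._det(1, 4), self._det(1, 5),
                                self._det(1, 6)])
        assert [p[0] for p in pairs] == [4, 5]

    def test_duplicate_id_within_frame_dropped(self):
        pairs = harmonize_pair([self._det(0, 4), self._det(0, 4),
                                self._det(0, 5)],
                               [self._det(1, 4), self._det(1, 5)])
        assert [p[0] for p in pairs] == [5]

    def test_identical_sets_fully_paired(self):
        a = [self._det(0, i) for i in range(5)]
        b = [self._det(1, i) for i in range(5)]
        assert len(harmonize_pair(a, b)) == 5


@pytest.fixture(scope="module")
def marker_scene(intrinsics):
    r = 1.0 / (2 * np.pi)
    ph = TorsoPhantom(r, r, 2.0, 0.4)
    return make_scene(ph, BeltSpec(belt_height_z=0.2),
                      TrajectorySpec(100.0, 0.70, 7), n_surface_points=0)


def detections_from(obs):
    return {o.frame_index: [MarkerDetection(o.frame_index, mid, c)
                            for mid, c in o.marker_corners.items()]
            for o in obs}


class TestTriangulation:
    def test_noiseless_estimates_match_ground_truth(self, marker_scene,
                                                    intrinsics):
        obs = project_scene(marker_scene, intrinsics, 0.0)
        poses = dict(enumerate(marker_scene.poses))  # true poses: no gauge
        est = triangulate_marker_corners(detections_from(obs), poses,
                                         intrinsics)
        assert len(est) > 100
        for e in est:
            truth = marker_scene.marker_corners[e.marker_id][e.corner_index]
            assert np.linalg.norm(e.position - truth) < 1e-6
            assert e.in_front

    def test_five_frames_give_four_pairs_per_corner(self, intrinsics):
        # one marker fully visible in 5 consecutive frames
        r = 1.0 / (2 * np.pi)
        ph = TorsoPhantom(r, r, 2.0, 0.4)
        scene = make_scene(ph, BeltSpec(belt_height_z=0.2),
                           TrajectorySpec(20.0, 0.70, 5), n_surface_points=0)
        obs = project_scene(scene, intrinsics, 0.0)
        always = set.intersection(*[set(o.marker_corners) for o in obs])
        mid = sorted(always)[0]
        est = triangulate_marker_corners(detections_from(obs),
                                         dict(enumerate(scene.poses)),
                                         intrinsics)
        per_corner = [sum(1 for e in est
                          if e.marker_id == mid and e.corner_index == k)
                      for k in range(4)]
        assert per_corner == [4, 4, 4, 4]

    def test_unregistered_frames_skipped(self, marker_scene, intrinsics):
        obs = project_scene(marker_scene, intrinsics, 0.0)
        poses = {0: marker_scene.poses[0], 1: marker_scene.poses[1]}
        est = triangulate_marker_corners(detections_from(obs), poses,
                                         intrinsics)
        assert {e.frame_pair for e in est} == {(0, 1)}


class TestMerge:
    @staticmethod
    def _est(mid, k, pos, err=0.5, in_front=True, pair=(0, 1)):
        return CornerEstimate(mid, k, pair, np.asarray(pos, float), err,
                              in_front)

    def test_median_of_gated_survivors(self):
        ests = []
        for k in range(4):
            ests += [self._est(0, k, (0, 0, 1.0), 0.5),
                     self._est(0, k, (0, 0, 1.002), 0.7),
                     self._est(0, k, (0, 0, 50.0), 9.0)]  # gated out
        merged = merge_corner_vertices(ests, reproj_threshold_px=2.0)
        assert len(merged) == 1
        assert np.allclose(merged[0].corners3d[:, 2], 1.001)

    def test_single_estimate_passes_through(self):
        ests = [self._est(3, k, (k, 0, 2.0)) for k in range(4)]
        merged = merge_corner_vertices(ests)
        assert len(merged) == 1
        assert np.allclose(merged[0].corners3d[:, 0], [0, 1, 2, 3])

    def test_marker_missing_a_corner_dropped_with_warning(self):
        ests = [self._est(1, k, (0, 0, 1.0)) for k in range(3)]  # corner 3 missing
        with pytest.warns(UserWarning, match="dropped"):
            assert merge_corner_vertices(ests) == []

    def test_exactly_four_vertices_and_center_identity(self, marker_scene,
                                                       intrinsics):
        obs = project_scene(marker_scene, intrinsics, 0.5, seed=6)
        est = triangulate_marker_corners(detections_from(obs),
                                        dict(enumerate(marker_scene.poses)),
                                        intrinsics)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            merged = merge_corner_vertices(est)
        assert merged
        for m in merged:
            assert m.corners3d.shape == (4, 3)
            assert len({tuple(c) for c in m.corners3d}) == 4
            assert np.array_equal(m.center, m.corners3d.mean(axis=0))

    def test_aggregation_beats_single_pair_estimates(self, marker_scene,
                                                     intrinsics):
        """At sigma=1 px the merged corner RMS is below the RMS of raw
        per-pair estimates."""
        obs = project_scene(marker_scene, intrinsics, 1.0, seed=9)
        est = triangulate_marker_corners(detections_from(obs),
                                        dict(enumerate(marker_scene.poses)),
                                        intrinsics)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            merged = merge_corner_vertices(est)
        raw_sq, merged_sq = [], []
        for e in est:
            truth = marker_scene.marker_corners[e.marker_id][e.corner_index]
            raw_sq.append(np.sum((e.position - truth) ** 2))
        for m in merged:
            truth = marker_scene.marker_corners[m.marker_id]
            merged_sq.extend(np.sum((m.corners3d - truth) ** 2, axis=1))
        assert np.sqrt(np.mean(merged_sq)) < np.sqrt(np.mean(raw_sq))


class TestAssemble:
    @staticmethod
    def _marker(mid):
        corners = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]],
                           dtype=float) + mid
        from torsoscan.electrodes import MarkerModel3D
        return MarkerModel3D(mid, corners, support=2)

    def test_full_belt(self):
        es = assemble_electrodes([self._marker(i) for i in range(32)],
                                 BeltSpec())
        assert [e.index for e in es.electrodes] == list(range(32))
        assert es.missing == []

    def test_missing_index_reported(self):
        es = assemble_electrodes([self._marker(i) for i in range(31)],
                                 BeltSpec())
        assert es.missing == [31]

    def test_out_of_range_id_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="outside"):
            es = assemble_electrodes([self._marker(0), self._marker(49)],
                                     BeltSpec())
        assert [e.index for e in es.electrodes] == [0]

    def test_no_electrodes_is_an_error(self):
        with pytest.raises(EmptyResultError):
            assemble_electrodes([], BeltSpec())
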