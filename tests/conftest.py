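"""Shared fixtures: small synthetic scenes and end-to-end chain helpers."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from torsoscan import (BeltSpec, CameraIntrinsics, TorsoPhantom,
                       TrajectorySpec, make_scene, project_scene)
from torsoscan.electrodes import (MarkerDetection, assemble_electrodes,
                                  merge_corner_vertices,
                                  triangulate_marker_corners)
from torsoscan.features import (corner_tracks_from_observations,
                                tracks_from_observations)
from torsoscan.geometry import SimilarityTransform
from torsoscan.sfm import SfmSettings, run_incremental_sfm
from torsoscan.validation import align_point_pairs, electrode_error, estimate_scale

# 1 m circumference circular phantom: the scale at which electrode errors
# are reported (spacing 1000/32 = 31.25 mm)
UNIT_RADIUS = 1.0 / (2 * np.pi)


@pytest.fixture(scope="session")
def intrinsics():
    return CameraIntrinsics(1400.0, 1400.0, 800.0, 450.0, 1600, 900)


@pytest.fixture(scope="session")
def circular_phantom():
    return TorsoPhantom(UNIT_RADIUS, UNIT_RADIUS, 2.0, 0.4)


@pytest.fixture(scope="session")
def arc_scene(circular_phantom):
    """The recording-protocol scene: 100-degree arc, 0.70 m, 21 frames."""
    return make_scene(circular_phantom, BeltSpec(belt_height_z=0.2),
                      TrajectorySpec(arc_degrees=100.0, distance=0.70,
                                     n_frames=21),
                      n_surface_points=300)


class ChainResult:
    """Everything an end-to-end run produced, for downstream assertions."""

    def __init__(self, **kw):
        self.__dict__.update(kw)


def observation_chain(truth, intrinsics, sigma, seed, pair_window=1,
                      reproj_threshold=2.0):
    """Synthetic-observation end-to-end electrode chain.

    project -> id-labeled tracks -> SfM -> pairwise corner DLT -> merge ->
    metric scale from adjacent-electrode distances -> rigid alignment of
    the metric reconstruction onto the ground truth.
    """
    obs = project_scene(truth, intrinsics, sigma, seed)
    tracks = (tracks_from_observations(obs)
              + corner_tracks_from_observations(obs))
    cloud = run_incremental_sfm(tracks, intrinsics, SfmSettings(seed=seed))
    dets = {o.frame_index: [MarkerDetection(o.frame_index, mid, c)
                            for mid, c in o.marker_corners.items()]
            for o in obs}
    estimates = triangulate_marker_corners(dets, cloud.poses, intrinsics,
                                           pair_window=pair_window)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        markers = merge_corner_vertices(estimates, reproj_threshold)
        es = assemble_electrodes(markers, truth.belt)
    scale = estimate_scale(es, truth.adjacent_center_distances())
    scale_tf = SimilarityTransform(scale=scale)
    es = es.transformed(scale_tf)
    centers = es.centers()
    common = sorted(set(centers) & set(truth.marker_centers))
    tf = align_point_pairs(np.array([centers[i] for i in common]),
                           np.array([truth.marker_centers[i] for i in common]),
                           with_scale=False)
    aligned = {i: tf.apply(centers[i]) for i in common}
    report = electrode_error(aligned, truth.marker_centers)
    # full world-alignment (scale then rigid) for clouds and meshes
    world_tf = tf.compose(scale_tf)
    return ChainResult(truth=truth, obs=obs, tracks=tracks, cloud=cloud,
                       detections=dets, markers=markers, electrodes=es,
                       scale=scale, align=tf, world_transform=world_tf,
                       aligned_centers=aligned, report=report)
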