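"""End-to-end reconstruction pipeline with per-stage wall-clock timings.

Stages (named after the reconstruction report columns they feed):
``sparse_point_cloud`` (features, matching, tracking, SfM),
``electrode_position`` (marker detection, harmonized pairwise DLT, merge,
metric scaling), ``densify_point_cloud`` (all-pairs track fusion), and
``mesh`` (outlier filter + cylindrical-grid meshing).

Marker corners double as high-quality tracks for camera registration: they
are uniquely identified across frames and subpixel-refined, which anchors
SfM even when background texture is weak.  Marker detection therefore runs
first; its wall time is charged to ``electrode_position``.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import features as ft
from . import electrodes as el
from .config import PipelineConfig
from .errors import ReconstructionError, TorsoscanError
from .geometry import SimilarityTransform
from .media import FrameSequence, extract_frames, write_ply_mesh, write_ply_points
from .sfm import SfmSettings, run_incremental_sfm
from .surface import densify, filter_outliers, mesh_cylindrical_grid
from .validation import estimate_scale

log = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "StageTimer"]

STAGES = ("sparse_point_cloud", "electrode_position",
          "densify_point_cloud", "mesh")


class StageTimer:
    """Accumulates monotonic wall time per named stage, in milliseconds."""

    def __init__(self) -> None:
        self.ms: dict[str, float] = {}
        self._t0 = time.monotonic()

    def add(self, stage: str, seconds: float) -> None:
        self.ms[stage] = self.ms.get(stage, 0.0) + seconds * 1e3

    def total_ms(self) -> float:
        return (time.monotonic() - self._t0) * 1e3

    @staticmethod
    def hhmmss(ms: float) -> str:
        s = int(round(ms / 1e3))
        return f"{s // 3600:02d}:{s % 3600 // 60:02d}:{s % 60:02d}"

    def report(self) -> dict:
        total = self.total_ms()
        return {
            "stages_ms": {k: round(v, 3) for k, v in self.ms.items()},
            "stages_hhmmss": {k: self.hhmmss(v) for k, v in self.ms.items()},
            "total_ms": round(total, 3),
            "total_hhmmss": self.hhmmss(total),
        }


class _Stage:
    def __init__(self, timer: StageTimer, name: str):
        self.timer, self.name = timer, name

    def __enter__(self):
        self._t = time.monotonic()
        return self

    def __exit__(self, exc_type, exc, tb):
        self.timer.add(self.name, time.monotonic() - self._t)
        if exc is not None and isinstance(exc, TorsoscanError):
            raise ReconstructionError(
                f"stage '{self.name}' failed: {exc}") from exc
        return False


@dataclass
class PipelineResult:
    cloud: "object"
    electrodes: el.ElectrodeSet
    mesh: "object" = None
    timings: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig, source,
                 write_outputs: bool = True) -> PipelineResult:
    """Run frames -> sparse cloud -> electrodes -> dense cloud -> mesh.

    ``source`` is anything :func:`torsoscan.media.extract_frames` accepts,
    or an already-extracted :class:`FrameSequence` / list of images.
    """
    timer = StageTimer()
    intr = config.intrinsics()
    settings = SfmSettings(ransac_threshold_px=config.triangulation_reproj_px,
                           seed=config.seed)
    if isinstance(source, FrameSequence):
        seq = source
    elif isinstance(source, (list, tuple)):
        seq = FrameSequence(list(source), np.arange(len(source), dtype=float))
    else:
        seq = extract_frames(source, config.extraction_rate)
    counts = {"frames": len(seq)}

    # marker detection (charged to electrode_position)
    with _Stage(timer, "electrode_position"):
        detections = {i: el.detect_markers(frame, frame_index=i)
                      for i, frame in enumerate(seq.frames)}
    counts["marker_detections"] = int(sum(len(v) for v in detections.values()))
    corner_tracks = ft.marker_corner_tracks(detections)

    with _Stage(timer, "sparse_point_cloud"):
        fsets = {i: ft.mask_regions(
                    ft.detect_features(frame, config.n_feature_keypoints,
                                       frame_index=i),
                    [d.corners for d in detections[i]])
                 for i, frame in enumerate(seq.frames)}
        rng = np.random.default_rng(config.seed)
        matches = []
        n = len(seq)
        for i in range(n):
            for j in range(i + 1, min(i + 1 + config.match_window, n)):
                matches.append(ft.match_pair(fsets[i], fsets[j],
                                             config.match_ratio,
                                             config.match_ransac_px, rng))
        tracks = ft.build_tracks([m for m in matches if not m.degenerate])
        ft.attach_positions(tracks, fsets)
        counts["feature_tracks"] = len(tracks)
        all_tracks = tracks + corner_tracks
        cloud = run_incremental_sfm(all_tracks, intr, settings)
    counts["registered_frames"] = len(cloud.poses)
    counts["sparse_points"] = len(cloud.points)
    log.info("pipeline counts: %s", counts)

    with _Stage(timer, "electrode_position"):
        estimates = el.triangulate_marker_corners(
            detections, cloud.poses, intr,
            pair_window=config.marker_pair_window)
        markers = el.merge_corner_vertices(
            estimates, config.triangulation_reproj_px)
        electrodes = el.assemble_electrodes(markers, config.belt_spec)
        if config.reference_distances:
            s = estimate_scale(electrodes, config.reference_distances)
            scale_tf = SimilarityTransform(scale=s)
            electrodes = electrodes.transformed(scale_tf)
        else:
            scale_tf = None
    counts["electrodes"] = len(electrodes.electrodes)

    with _Stage(timer, "densify_point_cloud"):
        dense = densify(cloud, all_tracks, config.triangulation_reproj_px)
    counts["dense_points"] = len(dense.points)

    mesh = None
    with _Stage(timer, "mesh"):
        # mesh only well-supported structure: a point observed in >= 3
        # registered frames is real surface, a 2-view-only point may be a
        # chance correspondence
        supported = {tr.track_id for tr in all_tracks
                     if sum(1 for f in tr.observations
                            if f in cloud.poses) >= 3}
        ids, pts = dense.point_array()
        keep = np.isin(ids, list(supported))
        pts = pts[keep] if keep.any() else pts
        if scale_tf is not None:
            pts = scale_tf.apply(pts)
        if len(pts) >= 16:
            pts, _ = filter_outliers(pts, k=min(8, len(pts) - 1))
            mesh = mesh_cylindrical_grid(pts, angular_bins=config.mesh_angular_bins,
                                         vertical_bins=config.mesh_vertical_bins)
        else:
            log.warning("too few dense points (%d); mesh skipped", len(pts))

    result = PipelineResult(cloud=dense, electrodes=electrodes, mesh=mesh,
                            timings=timer.report(), counts=counts)
    if write_outputs:
        _write_outputs(config, result, scale_tf)
    return result


def _write_outputs(config: PipelineConfig, result: PipelineResult,
                   scale_tf) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _, pts = result.cloud.point_array()
    if scale_tf is not None:
        pts = scale_tf.apply(pts)
    errs = np.array([result.cloud.point_errors.get(t, 0.0)
                     for t in sorted(result.cloud.points)], dtype=np.float32)
    write_ply_points(out / "cloud.ply", pts, scalars=errs)
    if result.mesh is not None:
        write_ply_mesh(out / "mesh.ply", result.mesh)
    (out / "electrodes.json").write_text(
        json.dumps(result.electrodes.report_dict(), sort_keys=True, indent=1))
    report = {"timings": result.timings, "counts": result.counts}
    (out / "report.json").write_text(json.dumps(report, sort_keys=True,
                                                indent=1))
    poses = {str(f): {"rotation": result.cloud.poses[f].R.ravel().round(12).tolist(),
                      "center": result.cloud.poses[f].center.round(12).tolist()}
             for f in sorted(result.cloud.poses)}
    (out / "poses.json").write_text(json.dumps(poses, sort_keys=True, indent=1))
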