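"""Feature detection, robust pairwise matching, and track building.

Detection uses an oriented multi-scale corner detector with binary
descriptors (scikit-image ORB), which is deterministic for identical
input.  Matching stacks three filters: Lowe ratio test, mutual best match
(cross-check), and a seeded random-sample-consensus epipolar fit at a pixel
threshold.  Tracks are connected components of the match graph; any
component observing one frame twice is inconsistent and discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from skimage.feature import ORB, match_descriptors

from .errors import InvalidParameterError
from .sfm import _eight_point  # fundamental estimation shares the linear core

log = logging.getLogger(__name__)

__all__ = [
    "FeatureSet",
    "PairMatches",
    "FeatureTrack",
    "detect_features",
    "match_pair",
    "filter_epipolar",
    "build_tracks",
    "tracks_from_observations",
    "marker_corner_tracks",
]


@dataclass
class FeatureSet:
    frame_index: int
    keypoints: np.ndarray     # (N,2) px, (x, y)
    scales: np.ndarray
    orientations: np.ndarray
    descriptors: np.ndarray   # (N,256) bool

    def __len__(self) -> int:
        return len(self.keypoints)


@dataclass
class PairMatches:
    """Inlier correspondences between frames i < j; ``usable`` is False when
    fewer than 8 matches survived or the geometry was degenerate."""

    pair: tuple[int, int]
    indices: np.ndarray       # (M,2) keypoint index in i, in j
    usable: bool = True
    degenerate: bool = False


@dataclass
class FeatureTrack:
    track_id: int
    observations: dict[int, tuple[float, float]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.observations)


def detect_features(image: np.ndarray, n_keypoints: int = 800,
                    frame_index: int = 0) -> FeatureSet:
    """ORB keypoints + 256-bit binary descriptors; deterministic."""
    img = np.asarray(image)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=2)
    if min(img.shape) < 64:
        raise InvalidParameterError("image smaller than 64x64")
    img = img.astype(float)
    if img.max() > 1.5:
        img /= 255.0
    if np.ptp(img) < 1e-12:
        return FeatureSet(frame_index, np.zeros((0, 2)), np.zeros(0),
                          np.zeros(0), np.zeros((0, 256), dtype=bool))
    orb = ORB(n_keypoints=n_keypoints)
    try:
        orb.detect_and_extract(img)
    except RuntimeError:  # no keypoints found
        return FeatureSet(frame_index, np.zeros((0, 2)), np.zeros(0),
                          np.zeros(0), np.zeros((0, 256), dtype=bool))
    kp_xy = orb.keypoints[:, ::-1].copy()  # (row, col) -> (x, y)
    return FeatureSet(frame_index, kp_xy, orb.scales, orb.orientations,
                      orb.descriptors)


def mask_regions(fset: FeatureSet, boxes: list[np.ndarray],
                 margin: float = 6.0) -> FeatureSet:
    """Drop keypoints inside any of the given corner quadrilaterals
    (by bounding box, enlarged by ``margin`` px).

    Fiducial markers are near-identical to a local descriptor, so keypoints
    on them produce confident matches between *different* markers; marker
    geometry is handled by its own id-verified pipeline instead.
    """
    if not boxes or len(fset) == 0:
        return fset
    keep = np.ones(len(fset), dtype=bool)
    for quad in boxes:
        lo = quad.min(axis=0) - margin
        hi = quad.max(axis=0) + margin
        inside = ((fset.keypoints[:, 0] >= lo[0])
                  & (fset.keypoints[:, 0] <= hi[0])
                  & (fset.keypoints[:, 1] >= lo[1])
                  & (fset.keypoints[:, 1] <= hi[1]))
        keep &= ~inside
    return FeatureSet(fset.frame_index, fset.keypoints[keep],
                      fset.scales[keep], fset.orientations[keep],
                      fset.descriptors[keep])


def filter_epipolar(pts_i: np.ndarray, pts_j: np.ndarray,
                    threshold_px: float, rng: np.random.Generator,
                    max_trials: int = 300) -> tuple[np.ndarray, bool]:
    """Robust fundamental-matrix inlier mask (seeded RANSAC, 8-point,
    Sampson distance).  Returns (inlier mask, degenerate flag); degenerate
    means the pair has (near-)zero baseline and the epipolar constraint
    does not discriminate."""
    pts_i = np.asarray(pts_i, dtype=float)
    pts_j = np.asarray(pts_j, dtype=float)
    n = len(pts_i)
    if n < 8:
        return np.zeros(n, dtype=bool), False
    # zero-baseline guard: displacement statistics
    disp = np.linalg.norm(pts_j - pts_i, axis=1)
    if np.median(disp) < 1.0:
        return np.ones(n, dtype=bool), True
    best = np.zeros(n, dtype=bool)
    for _ in range(max_trials):
        idx = rng.choice(n, 8, replace=False)
        try:
            F = _fundamental(pts_i[idx], pts_j[idx])
        except np.linalg.LinAlgError:
            continue
        d = _sampson_px(F, pts_i, pts_j)
        inl = d < threshold_px ** 2
        if inl.sum() > best.sum():
            best = inl
    if best.sum() >= 8:
        # least-squares refit on the consensus set; keep it only if the
        # support does not shrink (a single leaked outlier can skew the
        # algebraic fit badly)
        F = _fundamental(pts_i[best], pts_j[best])
        refit = _sampson_px(F, pts_i, pts_j) < threshold_px ** 2
        if refit.sum() >= best.sum():
            best = refit
    return best, False


def _fundamental(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Normalized 8-point fundamental matrix (rank 2 enforced)."""
    return _eight_point(p1, p2, essential=False)


def _sampson_px(F, p1, p2):
    h1 = np.hstack([p1, np.ones((len(p1), 1))])
    h2 = np.hstack([p2, np.ones((len(p2), 1))])
    Fx1 = h1 @ F.T
    Ftx2 = h2 @ F
    num = np.einsum("ni,ni->n", h2, Fx1) ** 2
    den = Fx1[:, 0] ** 2 + Fx1[:, 1] ** 2 + Ftx2[:, 0] ** 2 + Ftx2[:, 1] ** 2
    return num / np.maximum(den, 1e-300)


def match_pair(f_i: FeatureSet, f_j: FeatureSet, ratio: float = 0.8,
               ransac_threshold_px: float = 1.5,
               rng: np.random.Generator | None = None) -> PairMatches:
    """Ratio test + cross-check + robust epipolar filter.

    Pairs with fewer than 8 surviving matches are flagged unusable rather
    than raising; a zero-baseline pair keeps its matches but is flagged
    degenerate (no triangulation possible).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    pair = (f_i.frame_index, f_j.frame_index)
    if len(f_i) == 0 or len(f_j) == 0:
        return PairMatches(pair, np.zeros((0, 2), dtype=int), usable=False)
    idx = match_descriptors(f_i.descriptors, f_j.descriptors,
                            metric="hamming", cross_check=True,
                            max_ratio=ratio)
    if len(idx) < 8:
        return PairMatches(pair, idx, usable=False)
    inl, degenerate = filter_epipolar(f_i.keypoints[idx[:, 0]],
                                      f_j.keypoints[idx[:, 1]],
                                      ransac_threshold_px, rng)
    kept = idx[inl]
    # 8 inliers are necessary for two-view geometry, but a random-sample
    # consensus over unrelated matches finds ~8-12 chance inliers; demand
    # clear support before declaring the pair usable
    usable = len(kept) >= 12 and len(kept) >= 0.2 * len(idx)
    return PairMatches(pair, kept, usable=usable, degenerate=degenerate)


def build_tracks(all_matches: list[PairMatches]) -> list[FeatureTrack]:
    """Connected components of the match graph become tracks.

    Nodes are (frame, keypoint index); components containing two distinct
    keypoints of one frame are inconsistent and discarded, as are
    single-observation components.  Keypoint positions are attached later
    (see :func:`attach_positions`) or by the caller via the feature sets.
    """
    g = nx.Graph()
    for pm in all_matches:
        if not pm.usable:
            continue
        i, j = pm.pair
        for a, b in pm.indices:
            g.add_edge((i, int(a)), (j, int(b)))
    tracks = []
    tid = 0
    for comp in sorted(nx.connected_components(g),
                       key=lambda c: sorted(c)[0]):
        frames = [n[0] for n in comp]
        if len(frames) != len(set(frames)):
            continue  # inconsistent: one frame observed twice
        if len(frames) < 2:
            continue
        tr = FeatureTrack(tid)
        tr.observations = {f: (np.nan, np.nan) for f, _ in comp}
        tr._nodes = sorted(comp)  # keypoint provenance for position lookup
        tracks.append(tr)
        tid += 1
    return tracks


def attach_positions(tracks: list[FeatureTrack],
                     feature_sets: dict[int, FeatureSet]) -> None:
    """Fill track observations with keypoint pixel positions in place."""
    for tr in tracks:
        for f, k in getattr(tr, "_nodes", []):
            kp = feature_sets[f].keypoints[k]
            tr.observations[f] = (float(kp[0]), float(kp[1]))


def tracks_from_observations(observations, kind: str = "surface",
                             id_offset: int = 0) -> list[FeatureTrack]:
    """Ground-truth-labeled tracks from synthetic frame observations
    (:class:`torsoscan.scene.FrameObservations`) — one track per surface
    point id, bypassing photometric matching."""
    by_id: dict[int, FeatureTrack] = {}
    for obs in observations:
        src = obs.surface_points if kind == "surface" else obs.marker_corners
        for pid, xy in src.items():
            tr = by_id.setdefault(pid, FeatureTrack(pid + id_offset))
            tr.observations[obs.frame_index] = (float(np.asarray(xy).ravel()[0]),
                                                float(np.asarray(xy).ravel()[1]))
    return [by_id[k] for k in sorted(by_id) if len(by_id[k]) >= 2]


def marker_corner_tracks(detections_per_frame, id_offset: int = 1_000_000
                         ) -> list[FeatureTrack]:
    """Tracks from marker corner detections: marker identity gives exact
    correspondence across frames (track id = offset + 4*marker_id + corner).

    Corner observations are subpixel-refined and uniquely identified, which
    makes them high-quality anchors for camera registration on frames whose
    background texture is not matchable."""
    by_key: dict[int, FeatureTrack] = {}
    for frame, dets in detections_per_frame.items():
        ids = [d.marker_id for d in dets]
        for d in dets:
            if ids.count(d.marker_id) > 1:
                continue  # ambiguous duplicate within the frame
            for k in range(4):
                key = id_offset + 4 * d.marker_id + k
                tr = by_key.setdefault(key, FeatureTrack(key))
                tr.observations[frame] = (float(d.corners[k, 0]),
                                          float(d.corners[k, 1]))
    return [by_key[k] for k in sorted(by_key) if len(by_key[k]) >= 2]


def corner_tracks_from_observations(observations, id_offset: int = 1_000_000
                                    ) -> list[FeatureTrack]:
    """Marker-corner tracks from synthetic observations (id-labeled)."""
    by_key: dict[int, FeatureTrack] = {}
    for obs in observations:
        for mid, corners in obs.marker_corners.items():
            for k in range(4):
                key = id_offset + 4 * mid + k
                tr = by_key.setdefault(key, FeatureTrack(key))
                tr.observations[obs.frame_index] = (float(corners[k, 0]),
                                                    float(corners[k, 1]))
    return [by_key[k] for k in sorted(by_key) if len(by_key[k]) >= 2]
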