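"""Fiducial-marker detection and 3D electrode localization.

Detection follows the classic square-fiducial recipe: adaptive threshold,
contour extraction, quadrilateral fit, perspective rectification, cell
binarization and dictionary lookup with rotation disambiguation, then
subpixel corner refinement by fitting straight lines to the border edges.

Localization mirrors the validated pipeline contract: detections of the
same marker id in *adjacent* frames are paired (harmonized), each of the
four corners is triangulated per pair with the DLT, the per-pair estimates
are filtered and merged so every marker ends up with exactly four unique 3D
vertices, and the electrode center is the exact centroid of those vertices.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_fill_holes, map_coordinates
from skimage.filters import threshold_local
from skimage.measure import approximate_polygon, find_contours, label, regionprops
from skimage.transform import ProjectiveTransform

from .dictionary import DICT_4X4_50, MarkerDictionary
from .errors import DegenerateGeometryError, EmptyResultError
from .geometry import CameraIntrinsics, CameraPose
from .scene import BeltSpec, projective_from_points
from .sfm import triangulate_dlt

log = logging.getLogger(__name__)

__all__ = [
    "MarkerDetection",
    "MarkerModel3D",
    "Electrode",
    "ElectrodeSet",
    "DetectionParams",
    "detect_markers",
    "harmonize_pair",
    "triangulate_marker_corners",
    "merge_corner_vertices",
    "assemble_electrodes",
    "CornerEstimate",
]


@dataclass
class MarkerDetection:
    """One marker seen in one frame; corners (4,2) px, TL clockwise."""

    frame_index: int
    marker_id: int
    corners: np.ndarray

    def __post_init__(self) -> None:
        self.corners = np.asarray(self.corners, dtype=float).reshape(4, 2)


@dataclass
class MarkerModel3D:
    """A marker merged to exactly four unique 3D vertices (m)."""

    marker_id: int
    corners3d: np.ndarray            # (4,3)
    support: int                     # contributing frame pairs

    def __post_init__(self) -> None:
        self.corners3d = np.asarray(self.corners3d, dtype=float).reshape(4, 3)

    @property
    def center(self) -> np.ndarray:
        """Exact centroid of the four corner vertices."""
        return self.corners3d.mean(axis=0)


@dataclass
class Electrode:
    index: int
    center: np.ndarray
    corners3d: np.ndarray
    support: int


@dataclass
class ElectrodeSet:
    """Electrodes ordered by marker id, plus scaling state and gaps."""

    electrodes: list[Electrode]
    scale_state: str = "unscaled"    # "unscaled" | "metric"
    missing: list[int] = field(default_factory=list)

    def centers(self) -> dict[int, np.ndarray]:
        return {e.index: e.center for e in self.electrodes}

    def transformed(self, transform) -> "ElectrodeSet":
        """Apply a similarity transform (e.g. metric scaling) to all
        geometry; marks the set metric when the transform rescales."""
        new = [Electrode(e.index, transform.apply(e.center),
                         transform.apply(e.corners3d), e.support)
               for e in self.electrodes]
        state = "metric" if transform.scale != 1.0 or self.scale_state == "metric" \
            else self.scale_state
        return ElectrodeSet(new, state, list(self.missing))

    def adjacent_distances_mm(self) -> list[float]:
        cs = self.centers()
        ids = sorted(cs)
        return [float(np.linalg.norm(cs[i] - cs[j]) * 1e3)
                for i, j in zip(ids, ids[1:])]

    def report_dict(self) -> dict:
        """JSON-ready report (millimeters)."""
        return {
            "scale_state": self.scale_state,
            "missing": list(map(int, self.missing)),
            "electrodes": [
                {
                    "index": int(e.index),
                    "center_mm": [round(v * 1e3, 6) for v in e.center],
                    "corners_mm": [[round(v * 1e3, 6) for v in c]
                                   for c in e.corners3d],
                    "support": int(e.support),
                }
                for e in self.electrodes
            ],
        }


# ---------------------------------------------------------------------------
# Detection


@dataclass(frozen=True)
class DetectionParams:
    block_size: int = 51         # adaptive-threshold window (odd, px)
    threshold_offset: float = 0.06
    min_area_px: float = 100.0
    max_area_frac: float = 0.25
    min_side_px: float = 5.0
    cell_subgrid: int = 3
    refine_subpixel: bool = True
    refine_halfwidth: float = 2.5


def _as_gray_float(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=2)
    img = img.astype(float)
    if img.max() > 1.5:
        img = img / 255.0
    return img


def _order_clockwise(quad: np.ndarray) -> np.ndarray:
    """Order the 4 points clockwise in image coords (x right, y down)."""
    c = quad.mean(axis=0)
    ang = np.arctan2(quad[:, 1] - c[1], quad[:, 0] - c[0])
    order = np.argsort(ang)  # increasing angle = clockwise with y down
    return quad[order]


def _is_convex(quad: np.ndarray) -> bool:
    crosses = []
    for i in range(4):
        a = quad[(i + 1) % 4] - quad[i]
        b = quad[(i + 2) % 4] - quad[(i + 1) % 4]
        crosses.append(a[0] * b[1] - a[1] * b[0])
    crosses = np.array(crosses)
    return bool(np.all(crosses > 0) or np.all(crosses < 0))


def _fit_quad(contour_xy: np.ndarray, perimeter: float) -> np.ndarray | None:
    for tol_frac in (0.02, 0.04, 0.07, 0.10):
        approx = approximate_polygon(contour_xy, tol_frac * perimeter)
        if len(approx) and np.allclose(approx[0], approx[-1]):
            approx = approx[:-1]
        if len(approx) == 4:
            return approx
    return None


def _sample_cells(img: np.ndarray, tf: ProjectiveTransform, cells: int,
                  subgrid: int) -> np.ndarray:
    offs = (np.arange(subgrid) + 0.5) / subgrid * 0.6 + 0.2  # interior samples
    gx, gy = np.meshgrid(offs, offs)
    means = np.empty((cells, cells))
    for r in range(cells):
        for c in range(cells):
            can = np.column_stack([c + gx.ravel(), r + gy.ravel()])
            pts = tf(can)  # (x, y)
            vals = map_coordinates(img, [pts[:, 1], pts[:, 0]], order=1,
                                   mode="nearest")
            means[r, c] = vals.mean()
    return means


def _refine_corners(img: np.ndarray, quad: np.ndarray,
                    halfwidth: float) -> np.ndarray:
    """Subpixel corners: gradient-centroid edge points + total-least-squares
    line per border edge, corners from adjacent-line intersection."""
    H, W = img.shape
    lines = []
    for e in range(4):
        p0, p1 = quad[e], quad[(e + 1) % 4]
        L = np.linalg.norm(p1 - p0)
        m = int(np.clip(L * 0.5, 8, 24))
        ts = np.linspace(0.15, 0.85, m)
        pts = p0 + ts[:, None] * (p1 - p0)
        d = (p1 - p0) / L
        nrm = np.array([-d[1], d[0]])
        offs = np.arange(-halfwidth, halfwidth + 1e-9, 0.25)
        coords = pts[:, None, :] + offs[None, :, None] * nrm
        ys = np.clip(coords[..., 1], 0, H - 1)
        xs = np.clip(coords[..., 0], 0, W - 1)
        vals = map_coordinates(img, [ys.ravel(), xs.ravel()], order=1
                               ).reshape(m, len(offs))
        g = np.abs(np.gradient(vals, axis=1))
        kmax = np.argmax(g, axis=1)
        edge_pts = []
        for i in range(m):
            k = kmax[i]
            lo, hi = max(k - 4, 0), min(k + 5, len(offs))
            w = g[i, lo:hi]
            if w.sum() < 1e-9:
                continue
            w = np.where(w > 0.3 * w.max(), w, 0.0)
            off_star = float((w * offs[lo:hi]).sum() / w.sum())
            edge_pts.append(pts[i] + off_star * nrm)
        if len(edge_pts) < 4:
            return quad
        P = np.asarray(edge_pts)
        mu = P.mean(axis=0)
        _, _, Vt = np.linalg.svd(P - mu)
        lines.append((mu, Vt[0]))
    refined = np.empty_like(quad)
    for i in range(4):
        mu1, v1 = lines[(i - 1) % 4]
        mu2, v2 = lines[i]
        A = np.column_stack([v1, -v2])
        det = np.linalg.det(A)
        if abs(det) < 1e-9:
            refined[i] = quad[i]
            continue
        ab = np.linalg.solve(A, mu2 - mu1)
        cand = mu1 + ab[0] * v1
        refined[i] = cand if np.linalg.norm(cand - quad[i]) < 3.0 else quad[i]
    return refined


def detect_markers(image: np.ndarray,
                   dictionary: MarkerDictionary = DICT_4X4_50,
                   params: DetectionParams = DetectionParams(),
                   frame_index: int = 0) -> list[MarkerDetection]:
    """Detect all decodable markers in one image (empty list is valid).

    Dictionary lookup uses Hamming tolerance 0 (the 4x4 code space is small
    enough that any tolerance invites confusions); the decoded rotation
    renormalizes the corner order to canonical TL, TR, BR, BL.
    """
    img = _as_gray_float(image)
    Himg, Wimg = img.shape
    thr = threshold_local(img, params.block_size, method="mean")
    dark = img < thr - params.threshold_offset
    lbl = label(dark, connectivity=2)
    detections: list[MarkerDetection] = []
    for region in regionprops(lbl):
        if region.area < params.min_area_px:
            continue
        if region.area > params.max_area_frac * Himg * Wimg:
            continue
        r0, c0, r1, c1 = region.bbox
        pad = 2
        mask = np.zeros((r1 - r0 + 2 * pad, c1 - c0 + 2 * pad), dtype=bool)
        mask[pad:-pad, pad:-pad] = region.image
        mask = binary_fill_holes(mask)
        contours = find_contours(mask.astype(float), 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)
        # (row, col) -> (x, y) in full-image coordinates
        contour_xy = np.column_stack([contour[:, 1] + c0 - pad,
                                      contour[:, 0] + r0 - pad])
        per = np.linalg.norm(np.diff(contour_xy, axis=0), axis=1).sum()
        quad = _fit_quad(contour_xy, per)
        if quad is None or not _is_convex(quad):
            continue
        quad = _order_clockwise(quad)
        sides = np.linalg.norm(quad - np.roll(quad, -1, axis=0), axis=1)
        if sides.min() < params.min_side_px:
            continue
        cells = 6
        src = np.array([[0.0, 0.0], [cells, 0.0], [cells, cells], [0.0, cells]])
        tf = projective_from_points(src, quad)
        if tf is None:
            continue
        means = _sample_cells(img, tf, cells, params.cell_subgrid)
        mid = (means.min() + means.max()) / 2.0
        if means.max() - means.min() < 0.15:
            continue
        bits = (means > mid).astype(np.uint8)
        border = np.concatenate([bits[0], bits[-1], bits[1:-1, 0],
                                 bits[1:-1, -1]])
        if border.any():
            continue
        decoded = dictionary.decode(bits[1:-1, 1:-1])
        if decoded is None:
            continue
        mid_id, rot = decoded
        if params.refine_subpixel:
            quad = _refine_corners(img, quad, params.refine_halfwidth)
        corners = np.roll(quad, -rot, axis=0)
        detections.append(MarkerDetection(frame_index, mid_id, corners))
    detections.sort(key=lambda d: d.marker_id)
    return detections


# ---------------------------------------------------------------------------
# Harmonization + triangulation + merging


def harmonize_pair(dets_i: list[MarkerDetection], dets_j: list[MarkerDetection]
                   ) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """Keep only marker ids present exactly once in both frames; pair the
    corner quadruples by id (corner correspondence by canonical order)."""

    def unique_by_id(dets):
        seen: dict[int, list[MarkerDetection]] = {}
        for d in dets:
            seen.setdefault(d.marker_id, []).append(d)
        dropped = [k for k, v in seen.items() if len(v) > 1]
        for k in dropped:
            log.info("marker id %d duplicated within a frame, dropped", k)
        return {k: v[0] for k, v in seen.items() if len(v) == 1}

    ui, uj = unique_by_id(dets_i), unique_by_id(dets_j)
    common = sorted(set(ui) & set(uj))
    if not common:
        log.info("harmonize: no common marker ids in pair")
    return [(mid, ui[mid].corners, uj[mid].corners) for mid in common]


@dataclass
class CornerEstimate:
    marker_id: int
    corner_index: int
    frame_pair: tuple[int, int]
    position: np.ndarray
    reproj_error_px: float
    in_front: bool


def triangulate_marker_corners(detections_per_frame: dict[int, list[MarkerDetection]],
                               poses: dict[int, CameraPose],
                               intrinsics: CameraIntrinsics,
                               pair_window: int = 1,
                               min_angle_rad: float = 1e-6
                               ) -> list[CornerEstimate]:
    """Pairwise DLT of harmonized corner observations over adjacent frames.

    ``pair_window`` = 1 pairs consecutive extracted frames (k, k+1); larger
    windows add (k, k+2) ... pairs.  Pairs with an unregistered frame are
    skipped; degenerate pairs are dropped per corner.
    """
    frames = sorted(detections_per_frame)
    proj = {f: poses[f].projection_matrix(intrinsics) for f in poses}
    estimates: list[CornerEstimate] = []
    for a_pos, fa in enumerate(frames):
        for off in range(1, pair_window + 1):
            if a_pos + off >= len(frames):
                break
            fb = frames[a_pos + off]
            if fa not in proj or fb not in proj:
                log.info("pair (%d,%d) skipped: unregistered frame", fa, fb)
                continue
            for mid, ca, cb in harmonize_pair(detections_per_frame[fa],
                                              detections_per_frame[fb]):
                for k in range(4):
                    try:
                        X, in_front = triangulate_dlt(
                            ca[k], cb[k], proj[fa], proj[fb],
                            min_angle_rad=min_angle_rad)
                    except DegenerateGeometryError:
                        continue
                    err = max(
                        _reproj(X, ca[k], proj[fa]),
                        _reproj(X, cb[k], proj[fb]))
                    estimates.append(CornerEstimate(
                        mid, k, (fa, fb), X, err, in_front))
    return estimates


def _reproj(X, x, P) -> float:
    p = P @ np.append(X, 1.0)
    if p[2] == 0:
        return np.inf
    return float(np.linalg.norm(p[:2] / p[2] - np.asarray(x)))


def merge_corner_vertices(estimates: list[CornerEstimate],
                          reproj_threshold_px: float = 2.0
                          ) -> list[MarkerModel3D]:
    """Collapse per-pair corner estimates to exactly four vertices/marker.

    Estimates behind a camera or with reprojection error above the threshold
    are discarded; the final vertex is the coordinate-wise median of the
    survivors.  Markers missing any corner are dropped with a warning.
    """
    grouped: dict[int, dict[int, list[CornerEstimate]]] = {}
    for est in estimates:
        grouped.setdefault(est.marker_id, {}).setdefault(
            est.corner_index, []).append(est)
    markers: list[MarkerModel3D] = []
    for mid in sorted(grouped):
        corners = np.empty((4, 3))
        supports = []
        ok = True
        for k in range(4):
            cand = [e for e in grouped[mid].get(k, [])
                    if e.in_front and e.reproj_error_px <= reproj_threshold_px]
            if not cand:
                warnings.warn(
                    f"marker {mid}: corner {k} has no estimate passing the "
                    "gates; marker dropped", stacklevel=2)
                ok = False
                break
            corners[k] = np.median([e.position for e in cand], axis=0)
            supports.append(len(cand))
        if ok:
            markers.append(MarkerModel3D(mid, corners, min(supports)))
    return markers


def assemble_electrodes(markers: list[MarkerModel3D], belt: BeltSpec
                        ) -> ElectrodeSet:
    """Order markers by id into the electrode layout; ids outside
    [0, n_electrodes) are rejected with a warning, gaps are reported."""
    electrodes = []
    for m in sorted(markers, key=lambda m: m.marker_id):
        if not 0 <= m.marker_id < belt.n_electrodes:
            warnings.warn(f"marker id {m.marker_id} outside electrode range "
                          f"[0, {belt.n_electrodes - 1}], excluded",
                          stacklevel=2)
            continue
        electrodes.append(Electrode(m.marker_id, m.center, m.corners3d,
                                    m.support))
    if not electrodes:
        raise EmptyResultError("no electrodes found")
    present = {e.index for e in electrodes}
    missing = sorted(set(range(belt.n_electrodes)) - present)
    if missing:
        log.info("missing electrode indices: %s", missing)
    return ElectrodeSet(electrodes, "unscaled", missing)
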