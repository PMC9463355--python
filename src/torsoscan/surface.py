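"""Point-cloud filtering, densification, and cylindrical-grid meshing.

The densification stage replaces a patch-based multi-view-stereo step with a
defined, testable alternative: every feature track is re-triangulated from
*all* of its view pairs (not just one) and the per-pair estimates are fused
by a coordinate-wise median, so each surviving point is supported by many
baselines.  Meshing parameterizes the torso-like cloud in cylindrical
coordinates about its principal axis and takes a per-bin median radius,
which makes the reconstruction error of the mesh a simple function of bin
size and point noise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import InvalidParameterError, MeshingError

log = logging.getLogger(__name__)

__all__ = ["SurfaceMesh", "filter_outliers", "densify", "mesh_cylindrical_grid"]


@dataclass
class SurfaceMesh:
    """Triangle mesh: vertices (V,3) meters, faces (F,3) int indices."""

    vertices: np.ndarray
    faces: np.ndarray
    vertex_normals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise InvalidParameterError("face indices out of range")

    @property
    def triangles(self) -> np.ndarray:
        """(F,3,3) triangle vertex coordinates."""
        return self.vertices[self.faces]

    def face_normals(self) -> np.ndarray:
        tri = self.triangles
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm

    def face_areas(self) -> np.ndarray:
        tri = self.triangles
        return 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)


def filter_outliers(points: np.ndarray, k: int = 8, sigma_mult: float = 3.0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Statistical outlier removal.

    A point is dropped when its mean distance to its ``k`` nearest neighbors
    exceeds ``mean + sigma_mult * std`` of that statistic over the cloud.
    Returns (kept points, boolean keep-mask).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < k + 1:
        raise InvalidParameterError("need at least k+1 points")
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=k + 1)
    mean_d = dists[:, 1:].mean(axis=1)  # skip self at distance 0
    cutoff = mean_d.mean() + sigma_mult * mean_d.std()
    keep = mean_d <= cutoff
    return pts[keep], keep


def densify(cloud, tracks, reproj_threshold_px: float = 2.0,
            min_angle_rad: float = 1e-6):
    """Fuse all-pairs DLT estimates per track into one robust point each.

    ``cloud`` is a :class:`torsoscan.sfm.SparseCloud`; for every track with
    observations in >= 2 registered frames, all C(m,2) view pairs are
    triangulated, estimates failing the reprojection / cheirality gates are
    discarded, and survivors are fused by coordinate-wise median.  Tracks
    whose pairs all fail keep their sparse-cloud position.  Returns a new
    SparseCloud with the fused positions.
    """
    from .sfm import SparseCloud, triangulate_dlt_batch

    proj = {f: pose.projection_matrix(cloud.intrinsics)
            for f, pose in cloud.poses.items()}
    fused_points: dict[int, np.ndarray] = dict(cloud.points)
    fused_err: dict[int, float] = dict(cloud.point_errors)

    for track in tracks:
        obs = [(f, xy) for f, xy in sorted(track.observations.items())
               if f in proj]
        if len(obs) < 2:
            continue
        pairs = [(i, j) for i in range(len(obs)) for j in range(i + 1, len(obs))]
        xa = np.array([obs[i][1] for i, _ in pairs], dtype=float)
        xb = np.array([obs[j][1] for _, j in pairs], dtype=float)
        Pa = np.array([proj[obs[i][0]] for i, _ in pairs])
        Pb = np.array([proj[obs[j][0]] for _, j in pairs])
        X, in_front, ok = triangulate_dlt_batch(xa, xb, Pa, Pb,
                                                min_angle_rad=min_angle_rad)
        if not np.any(ok & in_front):
            continue
        cand = X[ok & in_front]
        # reprojection gate against both contributing views
        errs = _pair_reproj_errors(cand, xa[ok & in_front], xb[ok & in_front],
                                   Pa[ok & in_front], Pb[ok & in_front])
        good = cand[errs <= reproj_threshold_px]
        if len(good) == 0:
            continue
        fused_points[track.track_id] = np.median(good, axis=0)
        fused_err[track.track_id] = float(
            np.median(errs[errs <= reproj_threshold_px]))

    return SparseCloud(points=fused_points, point_errors=fused_err,
                       poses=cloud.poses, intrinsics=cloud.intrinsics)


def _pair_reproj_errors(X, xa, xb, Pa, Pb):
    """Max of the two per-view reprojection errors for each estimate."""
    Xh = np.hstack([X, np.ones((len(X), 1))])
    ea = _reproj(Xh, Pa) - xa
    eb = _reproj(Xh, Pb) - xb
    return np.maximum(np.linalg.norm(ea, axis=1), np.linalg.norm(eb, axis=1))


def _reproj(Xh, P):
    p = np.einsum("nij,nj->ni", P, Xh)
    return p[:, :2] / p[:, 2:3]


def estimate_principal_axis(points: np.ndarray) -> np.ndarray:
    """Axis of a roughly cylindrical cloud from its covariance.

    The two cross-section directions have comparable variance while the axis
    direction stands apart (larger for a tall cloud, smaller for a belt-like
    band); the eigenvector most separated from the other two is chosen.
    """
    pts = np.asarray(points, dtype=float)
    cov = np.cov(pts.T)
    w, v = np.linalg.eigh(cov)  # ascending
    if w[0] <= 0:
        raise MeshingError("degenerate cloud: specify the axis explicitly")
    r_low, r_high = w[1] / w[0], w[2] / w[1]
    if max(r_low, r_high) < 1.2:
        raise MeshingError(
            "principal axis undefined (isotropic cloud): specify the axis")
    axis = v[:, 0] if r_low > r_high else v[:, 2]
    if axis[2] < 0:  # deterministic sign: roughly +z
        axis = -axis
    return axis


def mesh_cylindrical_grid(points: np.ndarray, axis: np.ndarray | None = None,
                          angular_bins: int = 256, vertical_bins: int = 128,
                          gap_fill: int = 3, origin: np.ndarray | None = None
                          ) -> SurfaceMesh:
    """Mesh a torso-like cloud on a regular (theta, z) cylindrical grid.

    Radius per bin is the median of the member points (even count: the lower
    of the two central values — fixed deterministic rule); bins with no
    points are filled by angular linear interpolation across gaps of at most
    ``gap_fill`` bins, larger gaps stay holes.  The result is an open sheet
    (no top/bottom caps); cells spanning holes produce no faces.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 8:
        raise MeshingError("too few points to mesh")
    if axis is None:
        axis = estimate_principal_axis(pts)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    origin = pts.mean(axis=0) if origin is None \
        else np.asarray(origin, dtype=float)
    # orthonormal frame: e1 toward world +x (projected), e2 = axis x e1
    e1 = np.array([1.0, 0.0, 0.0]) - axis[0] * axis
    if np.linalg.norm(e1) < 1e-8:
        e1 = np.array([0.0, 1.0, 0.0]) - axis[1] * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    rel = pts - origin
    z = rel @ axis
    u, v = rel @ e1, rel @ e2
    theta = np.arctan2(v, u)
    r = np.hypot(u, v)

    ti = np.clip(((theta + np.pi) / (2 * np.pi) * angular_bins).astype(int),
                 0, angular_bins - 1)
    z0, z1 = z.min(), z.max()
    span = max(z1 - z0, 1e-12)
    zi = np.clip(((z - z0) / span * vertical_bins).astype(int),
                 0, vertical_bins - 1)

    radius = np.full((angular_bins, vertical_bins), np.nan)
    for a in range(angular_bins):
        sel_a = ti == a
        if not sel_a.any():
            continue
        zz, rr = zi[sel_a], r[sel_a]
        for b in np.unique(zz):
            vals = np.sort(rr[zz == b])
            radius[a, b] = vals[(len(vals) - 1) // 2]  # lower median

    _fill_angular_gaps(radius, gap_fill)

    occupied = ~np.isnan(radius)
    if occupied.sum() < 4:
        raise MeshingError("grid too sparse to mesh")

    theta_c = -np.pi + (np.arange(angular_bins) + 0.5) * 2 * np.pi / angular_bins
    z_c = z0 + (np.arange(vertical_bins) + 0.5) * span / vertical_bins

    vidx = np.full((angular_bins, vertical_bins), -1, dtype=int)
    verts = []
    for a in range(angular_bins):
        for b in range(vertical_bins):
            if occupied[a, b]:
                vidx[a, b] = len(verts)
                rr = radius[a, b]
                verts.append(origin + rr * np.cos(theta_c[a]) * e1
                             + rr * np.sin(theta_c[a]) * e2 + z_c[b] * axis)
    faces = []
    for a in range(angular_bins):
        a2 = (a + 1) % angular_bins
        for b in range(vertical_bins - 1):
            c00, c10 = vidx[a, b], vidx[a2, b]
            c01, c11 = vidx[a, b + 1], vidx[a2, b + 1]
            if min(c00, c10, c01, c11) < 0:
                continue
            # outward winding: theta increases CCW about +axis
            faces.append([c00, c10, c11])
            faces.append([c00, c11, c01])
    if not faces:
        raise MeshingError("no complete grid cells to triangulate")
    return SurfaceMesh(np.asarray(verts), np.asarray(faces, dtype=np.int64))


def _fill_angular_gaps(radius: np.ndarray, gap_fill: int) -> None:
    """In-place circular linear interpolation over short angular gaps."""
    A = radius.shape[0]
    for b in range(radius.shape[1]):
        col = radius[:, b]
        occ = np.flatnonzero(~np.isnan(col))
        if len(occ) == 0 or len(occ) == A:
            continue
        for gi in range(len(occ)):
            a0 = occ[gi]
            a1 = occ[(gi + 1) % len(occ)]
            gap = (a1 - a0) % A
            if gap <= 1 or gap - 1 > gap_fill:
                continue
            for step in range(1, gap):
                w = step / gap
                col[(a0 + step) % A] = (1 - w) * col[a0] + w * col[a1]
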