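"""Incremental structure from motion and DLT triangulation.

The chain is the classic one: seed from the two-view geometry of the best
frame pair (essential matrix within a seeded random-sample-consensus loop,
pose disambiguation by cheirality vote), grow by perspective-n-point
registration of one frame at a time, triangulate new tracks by the direct
linear transform (DLT), and refine everything with bundle adjustment.  The
reconstruction is defined up to a global similarity; the first camera is
fixed at the identity and the seed baseline is normalized to 1, metric
scale comes later from measured electrode distances.

``triangulate_dlt`` is the primitive the electrode-localization stage
reuses: the 3D point is the smallest-right-singular-vector solution of the
stacked cross-product system of both views, with rows normalized to unit
length for conditioning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.sparse import lil_matrix
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, ReconstructionError
from .geometry import CameraIntrinsics, CameraPose

log = logging.getLogger(__name__)

__all__ = [
    "SparseCloud",
    "triangulate_dlt",
    "triangulate_dlt_batch",
    "estimate_essential_ransac",
    "initialize_two_view",
    "register_next_view",
    "bundle_adjust",
    "run_incremental_sfm",
    "SfmSettings",
]


@dataclass
class SfmSettings:
    """Knobs of the incremental reconstruction (pixel units)."""

    ransac_threshold_px: float = 2.0
    ransac_max_trials: int = 500
    min_parallax_deg: float = 1.0
    prune_reproj_px: float = 4.0
    ba_every: int = 8
    seed: int = 0


@dataclass
class SparseCloud:
    """SfM output: 3D points per track, camera poses, shared intrinsics."""

    points: dict[int, np.ndarray]
    point_errors: dict[int, float]
    poses: dict[int, CameraPose]
    intrinsics: CameraIntrinsics

    def point_array(self) -> tuple[np.ndarray, np.ndarray]:
        """(track_ids (N,), positions (N,3)) in track-id order."""
        ids = np.array(sorted(self.points), dtype=np.int64)
        return ids, np.array([self.points[i] for i in ids])


# ---------------------------------------------------------------------------
# DLT triangulation


def _dlt_system(x: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Two cross-product rows of one view: x × (P X) = 0."""
    return np.stack([x[0] * P[2] - P[0], x[1] * P[2] - P[1]])


def _ray_angle(x_a, x_b, P_a, P_b) -> float:
    """Angle between the two viewing rays (rad)."""
    d = []
    for x, P in ((x_a, P_a), (x_b, P_b)):
        M = P[:, :3]
        d.append(np.linalg.solve(M, np.array([x[0], x[1], 1.0])))
    cos = abs(np.dot(d[0], d[1])) / (np.linalg.norm(d[0]) * np.linalg.norm(d[1]))
    return float(np.arccos(np.clip(cos, -1.0, 1.0)))


def _camera_center(P: np.ndarray) -> np.ndarray:
    return -np.linalg.solve(P[:, :3], P[:, 3])


def triangulate_dlt(x_a, x_b, P_a, P_b, min_angle_rad: float = 1e-6
                    ) -> tuple[np.ndarray, bool]:
    """Triangulate one point from two views.

    Parameters are pixel points (2,) and 3x4 projection matrices.  Returns
    ``(X, in_front)`` where ``in_front`` is the cheirality flag (positive
    depth in both cameras).  Raises :class:`DegenerateGeometryError` when
    the baseline is zero or the rays are parallel (angle <= min_angle_rad).
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    P_a = np.asarray(P_a, dtype=float)
    P_b = np.asarray(P_b, dtype=float)
    if np.linalg.matrix_rank(P_a) < 3 or np.linalg.matrix_rank(P_b) < 3:
        raise DegenerateGeometryError("projection matrix rank < 3")
    if np.linalg.norm(_camera_center(P_a) - _camera_center(P_b)) < 1e-12:
        raise DegenerateGeometryError("zero baseline")
    if _ray_angle(x_a, x_b, P_a, P_b) <= min_angle_rad:
        raise DegenerateGeometryError("viewing rays (nearly) parallel")
    A = np.vstack([_dlt_system(x_a, P_a), _dlt_system(x_b, P_b)])
    A /= np.linalg.norm(A, axis=1, keepdims=True)
    _, _, Vt = np.linalg.svd(A)
    Xh = Vt[-1]
    if abs(Xh[3]) < 1e-15:
        raise DegenerateGeometryError("point at infinity")
    X = Xh[:3] / Xh[3]
    in_front = bool(_depth(X, P_a) > 0 and _depth(X, P_b) > 0)
    return X, in_front


def _depth(X: np.ndarray, P: np.ndarray) -> float:
    """Signed depth of X in the camera of P (sign-corrected third row)."""
    M = P[:, :3]
    w = P[2] @ np.append(X, 1.0)
    return float(np.sign(np.linalg.det(M)) * w / np.linalg.norm(M[2]))


def triangulate_dlt_batch(xa, xb, Pa, Pb, min_angle_rad: float = 1e-6):
    """Vectorized two-view DLT over N independent pairs.

    Returns ``(X (N,3), in_front (N,), ok (N,))``; ``ok`` is False where the
    geometry was degenerate (those rows of X are NaN).
    """
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    Pa = np.asarray(Pa, dtype=float)
    Pb = np.asarray(Pb, dtype=float)
    n = len(xa)
    A = np.empty((n, 4, 4))
    A[:, 0] = xa[:, 0, None] * Pa[:, 2] - Pa[:, 0]
    A[:, 1] = xa[:, 1, None] * Pa[:, 2] - Pa[:, 1]
    A[:, 2] = xb[:, 0, None] * Pb[:, 2] - Pb[:, 0]
    A[:, 3] = xb[:, 1, None] * Pb[:, 2] - Pb[:, 1]
    A /= np.linalg.norm(A, axis=2, keepdims=True)
    _, s, Vt = np.linalg.svd(A)
    Xh = Vt[:, -1, :]
    ok = np.abs(Xh[:, 3]) > 1e-15
    # ray-angle degeneracy
    da = np.linalg.solve(Pa[:, :, :3],
                         np.hstack([xa, np.ones((n, 1))])[:, :, None])[:, :, 0]
    db = np.linalg.solve(Pb[:, :, :3],
                         np.hstack([xb, np.ones((n, 1))])[:, :, None])[:, :, 0]
    cos = np.abs(np.einsum("ni,ni->n", da, db)) / (
        np.linalg.norm(da, axis=1) * np.linalg.norm(db, axis=1))
    ok &= np.arccos(np.clip(cos, -1, 1)) > min_angle_rad
    X = np.full((n, 3), np.nan)
    X[ok] = Xh[ok, :3] / Xh[ok, 3, None]
    in_front = np.zeros(n, dtype=bool)
    if ok.any():
        Xh1 = np.hstack([X, np.ones((n, 1))])
        wa = np.einsum("nj,nj->n", Pa[:, 2], Xh1)
        wb = np.einsum("nj,nj->n", Pb[:, 2], Xh1)
        sa = np.sign(np.linalg.det(Pa[:, :, :3]))
        sb = np.sign(np.linalg.det(Pb[:, :, :3]))
        in_front = ok & (sa * wa > 0) & (sb * wb > 0)
    return X, in_front, ok


# ---------------------------------------------------------------------------
# Two-view initialization


def _eight_point(xn1: np.ndarray, xn2: np.ndarray,
                 essential: bool = True) -> np.ndarray:
    """Epipolar matrix from >= 8 correspondences (normalized linear fit).

    With ``essential=True`` the result is projected onto the essential
    manifold (singular values 1, 1, 0); otherwise only rank 2 is enforced,
    which is the correct constraint for a fundamental matrix.
    """
    m1 = xn1.mean(axis=0)
    m2 = xn2.mean(axis=0)
    s1 = np.sqrt(2.0) / max(np.mean(np.linalg.norm(xn1 - m1, axis=1)), 1e-12)
    s2 = np.sqrt(2.0) / max(np.mean(np.linalg.norm(xn2 - m2, axis=1)), 1e-12)
    p1 = (xn1 - m1) * s1
    p2 = (xn2 - m2) * s2
    A = np.column_stack([
        p2[:, 0] * p1[:, 0], p2[:, 0] * p1[:, 1], p2[:, 0],
        p2[:, 1] * p1[:, 0], p2[:, 1] * p1[:, 1], p2[:, 1],
        p1[:, 0], p1[:, 1], np.ones(len(p1)),
    ])
    _, _, Vt = np.linalg.svd(A)
    F = Vt[-1].reshape(3, 3)
    T1 = np.array([[s1, 0, -s1 * m1[0]], [0, s1, -s1 * m1[1]], [0, 0, 1]])
    T2 = np.array([[s2, 0, -s2 * m2[0]], [0, s2, -s2 * m2[1]], [0, 0, 1]])
    E = T2.T @ F @ T1
    U, s, Vt = np.linalg.svd(E)
    if essential:  # project to the essential manifold
        return U @ np.diag([1.0, 1.0, 0.0]) @ Vt
    return U @ np.diag([s[0], s[1], 0.0]) @ Vt


def _sampson_sq(E: np.ndarray, xn1: np.ndarray, xn2: np.ndarray) -> np.ndarray:
    h1 = np.hstack([xn1, np.ones((len(xn1), 1))])
    h2 = np.hstack([xn2, np.ones((len(xn2), 1))])
    Ex1 = h1 @ E.T
    Etx2 = h2 @ E
    num = np.einsum("ni,ni->n", h2, Ex1) ** 2
    den = Ex1[:, 0] ** 2 + Ex1[:, 1] ** 2 + Etx2[:, 0] ** 2 + Etx2[:, 1] ** 2
    return num / np.maximum(den, 1e-300)


def estimate_essential_ransac(xn1, xn2, threshold_norm: float,
                              rng: np.random.Generator,
                              max_trials: int = 500):
    """Seeded RANSAC 8-point essential estimate on normalized coordinates.

    Returns ``(E, inlier_mask)``; the model is re-fit on the inlier set.
    """
    xn1 = np.asarray(xn1, dtype=float)
    xn2 = np.asarray(xn2, dtype=float)
    n = len(xn1)
    if n < 8:
        raise DegenerateGeometryError("need >= 8 correspondences")
    best_E = None
    best_inliers = None
    best_count = -1
    thr2 = threshold_norm ** 2
    # samples larger than minimal: the linear estimate is noise-sensitive
    # and inlier contamination is already low after descriptor filtering
    sample = min(max(8, n // 4), 16, n)
    for _ in range(max_trials):
        idx = rng.choice(n, size=sample, replace=False)
        try:
            E = _eight_point(xn1[idx], xn2[idx])
        except np.linalg.LinAlgError:
            continue
        inl = _sampson_sq(E, xn1, xn2) < thr2
        if inl.sum() > best_count:
            best_count = int(inl.sum())
            best_inliers = inl
            best_E = E
    if best_E is None or best_count < 8:
        raise DegenerateGeometryError("essential-matrix estimation failed")
    # local optimization: refit on inliers while the support grows
    for _ in range(5):
        E = _eight_point(xn1[best_inliers], xn2[best_inliers])
        inl = _sampson_sq(E, xn1, xn2) < thr2
        if inl.sum() < best_count:
            break
        grew = inl.sum() > best_count
        best_E, best_inliers, best_count = E, inl, int(inl.sum())
        if not grew:
            break
    return best_E, best_inliers


def _cross_matrix(t: np.ndarray) -> np.ndarray:
    return np.array([[0.0, -t[2], t[1]], [t[2], 0.0, -t[0]],
                     [-t[1], t[0], 0.0]])


def _refine_relative_pose(xn1: np.ndarray, xn2: np.ndarray,
                          R0: np.ndarray, t0: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray, float]:
    """Minimize Sampson error over the 5-dof relative pose (rotation vector
    + translation direction), starting from (R0, t0).

    The linear essential-matrix estimate degrades badly when the
    correspondences occupy a thin strip (e.g. corners along an electrode
    belt); a nonlinear descent from a nearby seed recovers the geometry.
    Returns (R, t_unit, median Sampson distance).
    """
    t0 = t0 / max(np.linalg.norm(t0), 1e-12)
    rv0 = Rotation.from_matrix(R0).as_rotvec()
    # translation in spherical coordinates to stay on the unit sphere
    theta0 = np.arccos(np.clip(t0[2], -1, 1))
    phi0 = np.arctan2(t0[1], t0[0])

    def unpack(p):
        R = Rotation.from_rotvec(p[:3]).as_matrix()
        st = np.sin(p[3])
        t = np.array([st * np.cos(p[4]), st * np.sin(p[4]), np.cos(p[3])])
        return R, t

    def resid(p):
        R, t = unpack(p)
        E = _cross_matrix(t) @ R
        return np.sqrt(_sampson_sq(E, xn1, xn2) + 1e-300)

    p0 = np.concatenate([rv0, [theta0, phi0]])
    sol = least_squares(resid, p0, method="lm", max_nfev=400)
    R, t = unpack(sol.x)
    E = _cross_matrix(t) @ R
    med = float(np.median(np.sqrt(_sampson_sq(E, xn1, xn2))))
    return R, t, med


def _decompose_essential(E: np.ndarray):
    U, _, Vt = np.linalg.svd(E)
    if np.linalg.det(U) < 0:
        U = -U
    if np.linalg.det(Vt) < 0:
        Vt = -Vt
    W = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    R1, R2 = U @ W @ Vt, U @ W.T @ Vt
    t = U[:, 2]
    return [(R1, t), (R1, -t), (R2, t), (R2, -t)]


def initialize_two_view(tracks, pair: tuple[int, int],
                        intrinsics: CameraIntrinsics,
                        settings: SfmSettings | None = None,
                        rng: np.random.Generator | None = None):
    """Seed reconstruction from one frame pair.

    Returns ``(poses, points, point_errors)`` where poses maps the two frame
    indices to CameraPose (first at the identity, baseline normalized to 1)
    and points maps track_id -> 3D position for tracks passing the
    reprojection and cheirality gates.
    """
    settings = settings or SfmSettings()
    rng = rng if rng is not None else np.random.default_rng(settings.seed)
    i, j = pair
    tids, xi, xj = _pair_correspondences(tracks, i, j)
    if len(tids) < 8:
        raise ReconstructionError(f"pair {pair}: fewer than 8 correspondences")
    xn1 = intrinsics.normalize(xi)
    xn2 = intrinsics.normalize(xj)
    # the epipolar residual of noisy-but-correct matches reaches ~2 sigma;
    # gate at 1.5x the reprojection threshold to keep them
    thr = 1.5 * settings.ransac_threshold_px / ((intrinsics.fx + intrinsics.fy) / 2)
    candidates: list[tuple[np.ndarray, np.ndarray]] = []
    try:
        E, inliers = estimate_essential_ransac(xn1, xn2, thr, rng,
                                               settings.ransac_max_trials)
        candidates.extend(_decompose_essential(E))
    except DegenerateGeometryError:
        inliers = np.ones(len(xn1), dtype=bool)
        candidates.extend(_decompose_essential(_eight_point(xn1, xn2)))
    # small-baseline seed: identity rotation, translation from image flow
    flow = np.median(xn2 - xn1, axis=0)
    if np.linalg.norm(flow) > 1e-9:
        tf_ = np.array([-flow[0], -flow[1], 0.0])
        candidates.append((np.eye(3), tf_ / np.linalg.norm(tf_)))
    # polish every candidate on the Sampson error and keep the best
    best_rt = None
    best_med = np.inf
    for R0, t0 in candidates:
        try:
            R, t, med = _refine_relative_pose(xn1, xn2, R0, t0)
        except np.linalg.LinAlgError:
            continue
        if med < best_med:
            best_med = med
            best_rt = (R, t)
    if best_rt is None:
        raise ReconstructionError("relative pose refinement failed")
    R, t = best_rt
    E = _cross_matrix(t) @ R
    inliers = _sampson_sq(E, xn1, xn2) < thr ** 2
    if inliers.sum() < 8:
        raise ReconstructionError("too few epipolar inliers after refinement")
    pose_i = CameraPose(np.eye(3), np.zeros(3))
    P_i = intrinsics.K @ np.hstack([np.eye(3), np.zeros((3, 1))])
    best = None
    # the Sampson error is blind to the twisted-pair/translation-sign
    # ambiguity; vote over all four decompositions of the refined E
    for Rd, td in _decompose_essential(E):
        pose_j = CameraPose(Rd, td)
        P_j = pose_j.projection_matrix(intrinsics)
        Xs, in_front, ok = triangulate_dlt_batch(
            xi[inliers], xj[inliers], np.broadcast_to(P_i, (inliers.sum(), 3, 4)),
            np.broadcast_to(P_j, (inliers.sum(), 3, 4)))
        votes = int(in_front.sum())
        if best is None or votes > best[0]:
            best = (votes, pose_j, Xs, in_front)
    votes, pose_j, Xs, in_front = best
    if votes == 0:
        raise ReconstructionError("all pose decompositions fail cheirality")
    P_j = pose_j.projection_matrix(intrinsics)
    points: dict[int, np.ndarray] = {}
    errors: dict[int, float] = {}
    sel_ids = tids[inliers]
    exi, exj = xi[inliers], xj[inliers]
    for k in np.flatnonzero(in_front):
        X = Xs[k]
        e = max(_reproj_err(X, exi[k], P_i), _reproj_err(X, exj[k], P_j))
        # loose gate: the seed geometry is refined by bundle adjustment
        if e <= 3.0 * settings.ransac_threshold_px:
            points[int(sel_ids[k])] = X
            errors[int(sel_ids[k])] = e
    if len(points) < 8:
        raise ReconstructionError("two-view initialization produced too few points")
    return {i: pose_i, j: pose_j}, points, errors


def _reproj_err(X, x, P) -> float:
    p = P @ np.append(X, 1.0)
    if p[2] == 0:
        return np.inf
    return float(np.linalg.norm(p[:2] / p[2] - x))


def _pair_correspondences(tracks, i: int, j: int):
    tids, xi, xj = [], [], []
    for tr in tracks:
        if i in tr.observations and j in tr.observations:
            tids.append(tr.track_id)
            xi.append(tr.observations[i])
            xj.append(tr.observations[j])
    return (np.array(tids, dtype=np.int64),
            np.array(xi, dtype=float).reshape(-1, 2),
            np.array(xj, dtype=float).reshape(-1, 2))


# ---------------------------------------------------------------------------
# Incremental registration


def _pnp_dlt(X: np.ndarray, x: np.ndarray, intrinsics: CameraIntrinsics
             ) -> CameraPose:
    """Linear pose from >= 6 2D-3D correspondences (normalized DLT + SVD
    orthogonalization of the rotation block)."""
    xn = intrinsics.normalize(x)
    n = len(X)
    A = np.zeros((2 * n, 12))
    for k in range(n):
        Xh = np.append(X[k], 1.0)
        A[2 * k, 0:4] = Xh
        A[2 * k, 8:12] = -xn[k, 0] * Xh
        A[2 * k + 1, 4:8] = Xh
        A[2 * k + 1, 8:12] = -xn[k, 1] * Xh
    _, _, Vt = np.linalg.svd(A)
    P = Vt[-1].reshape(3, 4)
    if np.linalg.det(P[:, :3]) < 0:
        P = -P
    P = P / np.linalg.norm(P[2, :3])
    U, _, Vt2 = np.linalg.svd(P[:, :3])
    R = U @ Vt2
    if np.linalg.det(R) < 0:
        R = -R
    return CameraPose(R, P[:, 3])


def _refine_pose(pose: CameraPose, X, x, intrinsics) -> CameraPose:
    def resid(p):
        R = Rotation.from_rotvec(p[:3]).as_matrix()
        cam = X @ R.T + p[3:]
        proj = intrinsics.denormalize(cam[:, :2] / cam[:, 2:3])
        return (proj - x).ravel()

    p0 = np.concatenate([Rotation.from_matrix(pose.R).as_rotvec(), pose.t])
    sol = least_squares(resid, p0, method="lm", max_nfev=200)
    return CameraPose(Rotation.from_rotvec(sol.x[:3]).as_matrix(), sol.x[3:])


def register_next_view(points: dict[int, np.ndarray], tracks, frame: int,
                       intrinsics: CameraIntrinsics,
                       settings: SfmSettings | None = None,
                       rng: np.random.Generator | None = None) -> CameraPose:
    """Pose of ``frame`` from its observations of already-triangulated tracks
    (perspective-n-point within seeded random-sample consensus)."""
    settings = settings or SfmSettings()
    rng = rng if rng is not None else np.random.default_rng(settings.seed)
    X, x = [], []
    for tr in tracks:
        if frame in tr.observations and tr.track_id in points:
            X.append(points[tr.track_id])
            x.append(tr.observations[frame])
    X = np.asarray(X, dtype=float).reshape(-1, 3)
    x = np.asarray(x, dtype=float).reshape(-1, 2)
    if len(X) < 6:
        raise ReconstructionError(
            f"frame {frame}: only {len(X)} 2D-3D correspondences (< 6)")

    # registration tolerates marginally-noisy observations (oblique marker
    # views); bundle adjustment tightens everything afterwards
    inlier_px = 2.0 * settings.ransac_threshold_px

    def score(pose):
        err = _batch_reproj_err(pose, X, x, intrinsics)
        return int((err < inlier_px).sum())

    best_pose, best_count = None, -1
    # fast path: all-point linear fit + refinement (no outliers present)
    try:
        pose = _refine_pose(_pnp_dlt(X, x, intrinsics), X, x, intrinsics)
        best_pose, best_count = pose, score(pose)
    except np.linalg.LinAlgError:
        pass
    if best_count < max(6, int(0.7 * len(X))):
        for _ in range(min(settings.ransac_max_trials, 100)):
            idx = rng.choice(len(X), size=6, replace=False)
            try:
                pose = _refine_pose(_pnp_dlt(X[idx], x[idx], intrinsics),
                                    X[idx], x[idx], intrinsics)
            except np.linalg.LinAlgError:
                continue
            count = score(pose)
            if count > best_count:
                best_count, best_pose = count, pose
            if best_count >= int(0.9 * len(X)):
                break
    if best_pose is None or best_count < 6:
        raise ReconstructionError(f"frame {frame}: pose estimation failed")
    # iterate inlier refinement to convergence of the inlier set
    for _ in range(3):
        err = _batch_reproj_err(best_pose, X, x, intrinsics)
        inl = err < inlier_px
        if inl.sum() < 6:
            break
        best_pose = _refine_pose(best_pose, X[inl], x[inl], intrinsics)
    return best_pose


def _batch_reproj_err(pose: CameraPose, X, x, intrinsics) -> np.ndarray:
    cam = pose.transform(X)
    z = cam[:, 2]
    bad = z <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        proj = intrinsics.denormalize(cam[:, :2] / z[:, None])
    err = np.linalg.norm(proj - x, axis=1)
    err[bad] = np.inf
    return err


# ---------------------------------------------------------------------------
# Bundle adjustment


def bundle_adjust(cloud: SparseCloud, tracks, max_iter: int = 100,
                  ftol: float = 1e-12) -> SparseCloud:
    """Joint nonlinear refinement of all poses and points.

    Minimizes total squared reprojection error; the first registered pose is
    held fixed (gauge).  The optimizer guarantees a non-increasing
    objective; per-point mean reprojection errors are recomputed on output.
    """
    frames = sorted(cloud.poses)
    if len(frames) < 2:
        raise ReconstructionError("bundle adjustment needs >= 2 views")
    tids = sorted(cloud.points)
    tid_idx = {t: k for k, t in enumerate(tids)}
    frame_idx = {f: k for k, f in enumerate(frames)}
    obs = []  # (frame pos, point pos, x, y)
    for tr in tracks:
        k = tid_idx.get(tr.track_id)
        if k is None:
            continue
        for f, xy in tr.observations.items():
            if f in frame_idx:
                obs.append((frame_idx[f], k, xy[0], xy[1]))
    if not obs:
        raise ReconstructionError("no observations for bundle adjustment")
    obs = np.array(obs, dtype=float)
    cam_i = obs[:, 0].astype(int)
    pt_i = obs[:, 1].astype(int)
    meas = obs[:, 2:4]

    n_free = len(frames) - 1
    pose_params = []
    for f in frames[1:]:
        p = cloud.poses[f]
        pose_params.append(np.concatenate(
            [Rotation.from_matrix(p.R).as_rotvec(), p.t]))
    x0 = np.concatenate(
        [np.concatenate(pose_params) if pose_params else np.empty(0),
         np.concatenate([cloud.points[t] for t in tids])])
    R0, t0 = cloud.poses[frames[0]].R, cloud.poses[frames[0]].t
    K = cloud.intrinsics

    def unpack(x):
        Rs = [R0]
        ts = [t0]
        for k in range(n_free):
            seg = x[6 * k:6 * k + 6]
            Rs.append(Rotation.from_rotvec(seg[:3]).as_matrix())
            ts.append(seg[3:])
        pts = x[6 * n_free:].reshape(-1, 3)
        return np.array(Rs), np.array(ts), pts

    def resid(x):
        Rs, ts, pts = unpack(x)
        cam = np.einsum("nij,nj->ni", Rs[cam_i], pts[pt_i]) + ts[cam_i]
        z = cam[:, 2]
        z = np.where(np.abs(z) < 1e-12, 1e-12, z)
        proj = K.denormalize(cam[:, :2] / z[:, None])
        return (proj - meas).ravel()

    m = 2 * len(obs)
    n = 6 * n_free + 3 * len(tids)
    spars = lil_matrix((m, n), dtype=np.int8)
    for o in range(len(obs)):
        ci, pi = cam_i[o], pt_i[o]
        if ci > 0:
            spars[2 * o:2 * o + 2, 6 * (ci - 1):6 * ci] = 1
        spars[2 * o:2 * o + 2, 6 * n_free + 3 * pi:6 * n_free + 3 * pi + 3] = 1

    sol = least_squares(resid, x0, jac_sparsity=spars, method="trf",
                        ftol=ftol, xtol=1e-12, gtol=1e-12,
                        max_nfev=max_iter, x_scale="jac")
    Rs, ts, pts = unpack(sol.x)
    poses = {frames[0]: cloud.poses[frames[0]]}
    for k, f in enumerate(frames[1:]):
        poses[f] = CameraPose(Rs[k + 1], ts[k + 1])
    points = {t: pts[k] for k, t in enumerate(tids)}
    errors = _mean_reproj_errors(points, poses, tracks, K)
    return SparseCloud(points=points, point_errors=errors, poses=poses,
                       intrinsics=K)


def _mean_reproj_errors(points, poses, tracks, intrinsics):
    errors: dict[int, float] = {}
    for tr in tracks:
        if tr.track_id not in points:
            continue
        es = []
        X = points[tr.track_id]
        for f, xy in tr.observations.items():
            if f in poses:
                es.append(_reproj_err(X, np.asarray(xy, dtype=float),
                                      poses[f].projection_matrix(intrinsics)))
        if es:
            errors[tr.track_id] = float(np.mean(es))
    return errors


# ---------------------------------------------------------------------------
# Orchestration


def _covisibility(tracks):
    counts: dict[tuple[int, int], int] = {}
    for tr in tracks:
        fs = sorted(tr.observations)
        for a in range(len(fs)):
            for b in range(a + 1, len(fs)):
                counts[(fs[a], fs[b])] = counts.get((fs[a], fs[b]), 0) + 1
    return counts


def run_incremental_sfm(tracks, intrinsics: CameraIntrinsics,
                        settings: SfmSettings | None = None) -> SparseCloud:
    """Full incremental reconstruction over all frames present in ``tracks``.

    Frames that cannot be registered are skipped with a log message; points
    with mean reprojection error above ``settings.prune_reproj_px`` after
    the final bundle adjustment are pruned.
    """
    settings = settings or SfmSettings()
    rng = np.random.default_rng(settings.seed)
    tracks = list(tracks)
    frames = sorted({f for tr in tracks for f in tr.observations})
    if len(frames) < 2:
        raise ReconstructionError("need >= 2 frames")

    covis = _covisibility(tracks)
    max_count = max(covis.values())
    candidates = [p for p, c in sorted(covis.items(),
                                       key=lambda kv: (-kv[1], kv[0]))
                  if c >= max(8, max_count // 2)][:12]
    # evaluate candidates; keep the well-conditioned one with the widest
    # parallax-weighted support (wrap-around orbits make frame-index
    # separation a poor baseline proxy)
    best_init = None
    best_score = -1.0
    for (i, j) in candidates:
        try:
            poses, points, errors = initialize_two_view(
                tracks, (i, j), intrinsics, settings, rng)
        except (ReconstructionError, DegenerateGeometryError) as exc:
            log.info("init pair (%d,%d) rejected: %s", i, j, exc)
            continue
        # refine the seed pair jointly, then judge it on the refined errors
        seed_cloud = bundle_adjust(
            SparseCloud(points, errors, poses, intrinsics), tracks)
        good = {t for t, e in seed_cloud.point_errors.items()
                if e <= settings.ransac_threshold_px}
        seed_cloud.points = {t: p for t, p in seed_cloud.points.items()
                             if t in good}
        seed_cloud.point_errors = {t: e for t, e
                                   in seed_cloud.point_errors.items()
                                   if t in good}
        if len(seed_cloud.points) < 8:
            log.info("init pair (%d,%d): %d refined points, rejected",
                     i, j, len(seed_cloud.points))
            continue
        parallax = _median_parallax(seed_cloud.points,
                                    seed_cloud.poses[i], seed_cloud.poses[j])
        if parallax < np.deg2rad(settings.min_parallax_deg):
            log.info("init pair (%d,%d): parallax %.3f deg too small",
                     i, j, np.rad2deg(parallax))
            continue
        score = len(seed_cloud.points) * min(parallax, np.deg2rad(30.0))
        if score > best_score:
            best_score = score
            best_init = ((i, j), seed_cloud)
    if best_init is None:
        raise ReconstructionError("no usable initialization pair")
    pair, cloud = best_init
    log.info("initialized from pair %s with %d points", pair,
             len(cloud.points))

    remaining = [f for f in frames if f not in cloud.poses]
    failed: list[int] = []
    since_ba = 0
    while remaining:
        # frame with most 2D-3D correspondences next
        def n_corr(f):
            return sum(1 for tr in tracks
                       if f in tr.observations and tr.track_id in cloud.points)
        remaining.sort(key=lambda f: (-n_corr(f), f))
        frame = remaining.pop(0)
        try:
            pose = register_next_view(cloud.points, tracks, frame,
                                      intrinsics, settings, rng)
        except ReconstructionError as exc:
            log.warning("frame %d registration deferred: %s", frame, exc)
            failed.append(frame)
            continue
        cloud.poses[frame] = pose
        _triangulate_missing_tracks(cloud, tracks, settings, only_frame=frame)
        since_ba += 1
        if since_ba >= settings.ba_every:
            cloud = bundle_adjust(cloud, tracks)
            _triangulate_missing_tracks(cloud, tracks, settings)
            since_ba = 0
            if failed:  # give deferred frames another chance after refinement
                remaining.extend(failed)
                failed = []
    for frame in failed:  # final retry after the cloud has matured
        try:
            cloud.poses[frame] = register_next_view(
                cloud.points, tracks, frame, intrinsics, settings, rng)
            _triangulate_missing_tracks(cloud, tracks, settings,
                                        only_frame=frame)
        except ReconstructionError as exc:
            log.warning("skipping frame %d: %s", frame, exc)
    cloud = bundle_adjust(cloud, tracks)
    _triangulate_missing_tracks(cloud, tracks, settings)
    cloud = bundle_adjust(cloud, tracks)
    # prune high-error points
    bad = [t for t, e in cloud.point_errors.items()
           if e > settings.prune_reproj_px]
    for t in bad:
        cloud.points.pop(t, None)
        cloud.point_errors.pop(t, None)
    if bad:
        log.info("pruned %d high-error points", len(bad))
    return cloud


def _median_parallax(points, pose_a: CameraPose, pose_b: CameraPose) -> float:
    if not points:
        return 0.0
    X = np.array(list(points.values()))
    da = X - pose_a.center
    db = X - pose_b.center
    cos = np.einsum("ni,ni->n", da, db) / (
        np.linalg.norm(da, axis=1) * np.linalg.norm(db, axis=1))
    return float(np.median(np.arccos(np.clip(cos, -1, 1))))


def _triangulate_missing_tracks(cloud: SparseCloud, tracks,
                                settings: SfmSettings,
                                only_frame: int | None = None) -> None:
    """Triangulate tracks without a 3D point yet from their registered
    observations: view pairs are tried in order of decreasing baseline and
    the first estimate passing the reprojection/cheirality gates wins."""
    K = cloud.intrinsics
    proj = {f: cloud.poses[f].projection_matrix(K) for f in cloud.poses}
    centers = {f: cloud.poses[f].center for f in cloud.poses}
    for tr in tracks:
        if tr.track_id in cloud.points:
            continue
        if only_frame is not None and only_frame not in tr.observations:
            continue
        obs = [f for f in tr.observations if f in proj]
        if len(obs) < 2:
            continue
        pairs = [(a, b) for ai, a in enumerate(obs) for b in obs[ai + 1:]]
        pairs.sort(key=lambda p: -np.linalg.norm(centers[p[0]] - centers[p[1]]))
        for fa, fb in pairs[:8]:
            try:
                X, in_front = triangulate_dlt(tr.observations[fa],
                                              tr.observations[fb],
                                              proj[fa], proj[fb])
            except DegenerateGeometryError:
                continue
            if not in_front:
                continue
            e = max(_reproj_err(X, np.asarray(tr.observations[fa]), proj[fa]),
                    _reproj_err(X, np.asarray(tr.observations[fb]), proj[fb]))
            if e <= 2.0 * settings.ransac_threshold_px:
                cloud.points[tr.track_id] = X
                cloud.point_errors[tr.track_id] = e
                break
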