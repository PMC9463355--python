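"""Pinhole camera model and similarity transforms.

Conventions used throughout the package:

* World units are meters; reports convert to millimeters.
* Pixel coordinates are ``(x, y) = (column, row)``, 0-based, origin at the
  center of the top-left pixel.
* A :class:`CameraPose` maps world points into the camera frame as
  ``x_cam = R @ x_world + t``; the camera center is ``C = -R.T @ t``.
  The camera looks along its +z axis, image x is camera +x, image y is
  camera +y (pointing down in world terms when the camera is upright).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CameraIntrinsics",
    "CameraPose",
    "SimilarityTransform",
    "look_at_pose",
    "project_points",
]


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics with zero skew; distortion assumed corrected upstream."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int = 0
    height: int = 0

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")

    @property
    def K(self) -> np.ndarray:
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )

    @property
    def K_inv(self) -> np.ndarray:
        return np.array(
            [
                [1.0 / self.fx, 0.0, -self.cx / self.fx],
                [0.0, 1.0 / self.fy, -self.cy / self.fy],
                [0.0, 0.0, 1.0],
            ]
        )

    def normalize(self, px: np.ndarray) -> np.ndarray:
        """Pixel coordinates -> normalized image coordinates (z=1 plane)."""
        px = np.asarray(px, dtype=float)
        return (px - [self.cx, self.cy]) / [self.fx, self.fy]

    def denormalize(self, xn: np.ndarray) -> np.ndarray:
        xn = np.asarray(xn, dtype=float)
        return xn * [self.fx, self.fy] + [self.cx, self.cy]


@dataclass
class CameraPose:
    """World-to-camera rigid transform: ``x_cam = R @ x_world + t``."""

    R: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float).reshape(3, 3)
        self.t = np.asarray(self.t, dtype=float).reshape(3)
        if not np.allclose(self.R @ self.R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(self.R) < 0:
            raise ValueError("rotation matrix has negative determinant")

    @property
    def center(self) -> np.ndarray:
        return -self.R.T @ self.t

    @classmethod
    def from_center(cls, R: np.ndarray, center: np.ndarray) -> "CameraPose":
        R = np.asarray(R, dtype=float)
        return cls(R, -R @ np.asarray(center, dtype=float))

    def projection_matrix(self, intrinsics: CameraIntrinsics) -> np.ndarray:
        """3x4 matrix P = K [R | t]."""
        return intrinsics.K @ np.hstack([self.R, self.t[:, None]])

    def transform(self, points: np.ndarray) -> np.ndarray:
        """World points (N,3) -> camera frame (N,3)."""
        return np.asarray(points, dtype=float) @ self.R.T + self.t


def look_at_pose(center: np.ndarray, target: np.ndarray,
                 up: np.ndarray = (0.0, 0.0, 1.0)) -> CameraPose:
    """Pose of a camera at ``center`` whose optical axis passes through ``target``.

    Image x is chosen horizontal (perpendicular to ``up``), image y points
    "down" so that an upright world appears upright in the image.
    """
    center = np.asarray(center, dtype=float)
    forward = np.asarray(target, dtype=float) - center
    nf = np.linalg.norm(forward)
    if nf == 0:
        raise ValueError("camera center and look-at target coincide")
    forward = forward / nf
    up = np.asarray(up, dtype=float)
    right = np.cross(forward, up)
    nr = np.linalg.norm(right)
    if nr < 1e-12:
        raise ValueError("optical axis parallel to up vector")
    right /= nr
    down = np.cross(forward, right)
    R = np.stack([right, down, forward])  # rows: camera x, y, z in world coords
    return CameraPose.from_center(R, center)


def project_points(points: np.ndarray, pose: CameraPose,
                   intrinsics: CameraIntrinsics) -> tuple[np.ndarray, np.ndarray]:
    """Project world points; returns (pixels (N,2), depths (N,)).

    Points at or behind the camera plane get depth <= 0; their pixel values
    are computed with the raw (possibly negative) depth and should be masked
    by the caller.
    """
    cam = pose.transform(np.atleast_2d(points))
    z = cam[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        xn = cam[:, :2] / z[:, None]
    return intrinsics.denormalize(xn), z


@dataclass
class SimilarityTransform:
    """x -> scale * R @ x + t with R a proper rotation."""

    scale: float = 1.0
    R: np.ndarray = field(default_factory=lambda: np.eye(3))
    t: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float).reshape(3, 3)
        self.t = np.asarray(self.t, dtype=float).reshape(3)
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return self.scale * pts @ self.R.T + self.t

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return SimilarityTransform(
            self.scale * other.scale,
            self.R @ other.R,
            self.scale * self.R @ other.t + self.t,
        )

    def inverse(self) -> "SimilarityTransform":
        Rinv = self.R.T
        return SimilarityTransform(1.0 / self.scale, Rinv,
                                   -Rinv @ self.t / self.scale)

    def apply_to_pose(self, pose: CameraPose) -> CameraPose:
        """Pose of the same camera after the world is remapped by ``self``."""
        return CameraPose.from_center(pose.R @ self.R.T,
                                      self.apply(pose.center))


def rotation_geodesic_angle(Ra: np.ndarray, Rb: np.ndarray) -> float:
    """Angle (rad) of the relative rotation between two rotation matrices."""
    cos = (np.trace(Ra @ Rb.T) - 1.0) / 2.0
    return float(np.arccos(np.clip(cos, -1.0, 1.0)))
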