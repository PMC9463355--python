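"""Synthetic torso / belt / camera scenes with exact ground truth.

Everything downstream of video capture is testable against scenes built
here: a superellipse torso phantom wears a belt of square fiducial markers
(one per electrode), a handheld camera orbit is sampled at constant angular
speed, and the scene can be turned into either exact 2D observations (with
optional Gaussian pixel noise) or rendered grayscale frames in which the
markers are drawn as perspective-warped binary patterns.

Default geometry mirrors the acquisition protocol the package targets:
a 32-electrode belt with 17 mm markers, camera at 0.70 m from the surface
sweeping a 100-degree arc.  (The protocol description conflates the arc's
"radius" and angle; it is read here as a 100-degree arc at 0.70 m range.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import ProjectiveTransform

from .dictionary import DICT_4X4_50, MarkerDictionary
from .errors import InvalidParameterError
from .geometry import CameraIntrinsics, CameraPose, look_at_pose, project_points
from .phantom import TorsoPhantom

def projective_from_points(src: np.ndarray, dst: np.ndarray
                           ) -> ProjectiveTransform | None:
    """Exact homography from 4 point pairs; None on degenerate input."""
    tf = ProjectiveTransform.from_estimate(src, dst)
    return tf if tf else None


__all__ = [
    "BeltSpec",
    "TrajectorySpec",
    "SceneGroundTruth",
    "FrameObservations",
    "place_belt",
    "make_trajectory",
    "make_scene",
    "project_scene",
    "render_marker_frames",
    "render_marker_image",
]


@dataclass(frozen=True)
class BeltSpec:
    """Electrode belt: n markers of ``marker_side`` m, equally spaced along
    the worn perimeter at height ``belt_height_z`` on the phantom axis."""

    n_electrodes: int = 32
    rest_length: float = 0.70
    marker_side: float = 0.017
    electrode_side: float = 0.010
    dictionary_name: str = "4x4_50"
    belt_height_z: float = 0.20

    def __post_init__(self) -> None:
        if self.n_electrodes < 4:
            raise InvalidParameterError("need at least 4 electrodes")
        if self.marker_side <= 0:
            raise InvalidParameterError("marker side must be positive")


@dataclass(frozen=True)
class TrajectorySpec:
    """Handheld camera orbit: ``arc_degrees`` swept at constant angular
    speed, ``distance`` m from the nearest surface point."""

    arc_degrees: float = 100.0
    distance: float = 0.70
    n_frames: int = 21
    look_at: tuple[float, float, float] | None = None
    frame_rate: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.arc_degrees <= 360:
            raise InvalidParameterError("arc must be in (0, 360] degrees")
        if self.distance <= 0:
            raise InvalidParameterError("distance must be positive")
        if self.n_frames < 2:
            raise InvalidParameterError("need at least 2 frames")


@dataclass
class SceneGroundTruth:
    """Exact scene state shared by projection, rendering, and validation."""

    phantom: TorsoPhantom
    phantom_mesh: "object"
    belt: BeltSpec
    marker_corners: dict[int, np.ndarray]   # id -> (4,3) m, TL TR BR BL
    marker_centers: dict[int, np.ndarray]   # id -> (3,) m
    marker_normals: dict[int, np.ndarray]   # id -> outward unit normal
    poses: list[CameraPose] = field(default_factory=list)
    surface_points: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    surface_normals: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    surface_ids: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def adjacent_center_distances(self) -> list[tuple[int, int, float]]:
        """Chord distances between belt-adjacent electrode centers — the
        synthetic stand-in for tape measurements along the worn belt."""
        n = self.belt.n_electrodes
        out = []
        for i in range(n):
            j = (i + 1) % n
            d = float(np.linalg.norm(self.marker_centers[i]
                                     - self.marker_centers[j]))
            out.append((i, j, d))
        return out


@dataclass
class FrameObservations:
    """Noisy (or exact) 2D observations of one frame, tagged with truth ids."""

    frame_index: int
    marker_corners: dict[int, np.ndarray]     # id -> (4,2) px
    surface_points: dict[int, np.ndarray]     # point id -> (2,) px


def place_belt(phantom: TorsoPhantom, belt: BeltSpec) -> SceneGroundTruth:
    """Lay the belt on the phantom: centers equally spaced in arc length,
    each marker square on the local tangent plane, edges along the
    horizontal tangent and the phantom axis."""
    if not 0 <= belt.belt_height_z <= phantom.height:
        raise InvalidParameterError("belt height outside phantom")
    perimeter = phantom.perimeter
    if perimeter / belt.n_electrodes <= belt.marker_side:
        raise InvalidParameterError(
            f"markers overlap: spacing {perimeter / belt.n_electrodes:.4f} m "
            f"<= marker side {belt.marker_side:.4f} m")
    z_hat = np.array([0.0, 0.0, 1.0])
    half = belt.marker_side / 2.0
    corners: dict[int, np.ndarray] = {}
    centers: dict[int, np.ndarray] = {}
    normals: dict[int, np.ndarray] = {}
    # spacing measured on the phantom's own arc-length table so the
    # equal-spacing invariant holds to the table's full precision
    s_vals = np.arange(belt.n_electrodes) / belt.n_electrodes \
        * phantom._arc_table[-1]
    thetas = phantom.theta_at_arc_length(s_vals)
    for mid, theta in enumerate(thetas):
        c = phantom.surface_point(theta, belt.belt_height_z)
        n = phantom.outward_normal(theta)
        u = np.cross(z_hat, n)
        u /= np.linalg.norm(u)
        centers[mid] = c
        normals[mid] = n
        corners[mid] = np.stack([
            c - half * u + half * z_hat,   # top-left
            c + half * u + half * z_hat,   # top-right
            c + half * u - half * z_hat,   # bottom-right
            c - half * u - half * z_hat,   # bottom-left
        ])
    return SceneGroundTruth(
        phantom=phantom, phantom_mesh=None, belt=belt,
        marker_corners=corners, marker_centers=centers, marker_normals=normals)


def make_trajectory(spec: TrajectorySpec, phantom: TorsoPhantom,
                    belt_height_z: float) -> list[CameraPose]:
    """Camera poses on a horizontal arc about the phantom axis at belt
    height, each center at ``spec.distance`` from the nearest surface point
    (along the outward normal), optical axis through ``spec.look_at``."""
    look_at = (np.array(spec.look_at, dtype=float) if spec.look_at is not None
               else np.array([0.0, 0.0, belt_height_z]))
    half = np.deg2rad(spec.arc_degrees) / 2.0
    # a full circle would duplicate the end pose; drop the endpoint there
    closed = np.isclose(spec.arc_degrees, 360.0)
    angles = np.linspace(-half, half, spec.n_frames, endpoint=not closed)
    poses = []
    for ang in angles:
        p = phantom.surface_point(ang, belt_height_z)
        n = phantom.outward_normal(ang)
        center = p + spec.distance * n
        poses.append(look_at_pose(center, look_at))
    return poses


def make_scene(phantom: TorsoPhantom | None = None,
               belt: BeltSpec | None = None,
               trajectory: TrajectorySpec | None = None,
               n_surface_points: int = 300,
               mesh_resolution: tuple[int, int] = (128, 32),
               surface_seed: int = 7) -> SceneGroundTruth:
    """Assemble a complete ground-truth scene with sensible defaults.

    Surface sample points emulate trackable texture: they are drawn from a
    band around belt height (seeded, reproducible) and carry stable ids.
    """
    phantom = phantom or TorsoPhantom(0.17, 0.12, 2.5, 0.4)
    belt = belt or BeltSpec(belt_height_z=phantom.height / 2)
    trajectory = trajectory or TrajectorySpec()
    truth = place_belt(phantom, belt)
    truth.phantom_mesh = phantom.mesh(*mesh_resolution)
    truth.poses = make_trajectory(trajectory, phantom, belt.belt_height_z)
    rng = np.random.default_rng(surface_seed)
    theta = rng.uniform(0, 2 * np.pi, n_surface_points)
    band = 0.35 * phantom.height
    z = np.clip(belt.belt_height_z
                + rng.uniform(-band, band, n_surface_points),
                0.0, phantom.height)
    truth.surface_points = phantom.surface_point(theta, z)
    truth.surface_normals = phantom.outward_normal(theta)
    truth.surface_ids = np.arange(n_surface_points)
    return truth


def _in_bounds(px: np.ndarray, intrinsics: CameraIntrinsics) -> np.ndarray:
    if intrinsics.width <= 0 or intrinsics.height <= 0:
        return np.ones(len(px), dtype=bool)
    return ((px[:, 0] >= 0) & (px[:, 0] <= intrinsics.width - 1)
            & (px[:, 1] >= 0) & (px[:, 1] <= intrinsics.height - 1))


def project_scene(truth: SceneGroundTruth, intrinsics: CameraIntrinsics,
                  pixel_noise_sigma: float = 0.0, seed: int | None = None
                  ) -> list[FrameObservations]:
    """Exact projections of all visible marker corners and surface points,
    plus isotropic Gaussian pixel noise of the given sigma.

    Visibility: the supporting surface normal faces the camera and the
    projection lies inside the image bounds (no self-occlusion ray casting;
    adequate for convex-ish torso cross-sections).  Deterministic for a
    fixed seed.
    """
    if pixel_noise_sigma < 0:
        raise InvalidParameterError("noise sigma must be >= 0")
    if pixel_noise_sigma > 0 and seed is None:
        raise InvalidParameterError("a seed is required when sigma > 0")
    rng = np.random.default_rng(seed)
    out: list[FrameObservations] = []
    any_marker = False
    for fi, pose in enumerate(truth.poses):
        C = pose.center
        mk: dict[int, np.ndarray] = {}
        for mid in sorted(truth.marker_corners):
            n = truth.marker_normals[mid]
            if np.dot(n, C - truth.marker_centers[mid]) <= 0:
                continue
            px, z = project_points(truth.marker_corners[mid], pose, intrinsics)
            if np.any(z <= 0) or not _in_bounds(px, intrinsics).all():
                continue
            if pixel_noise_sigma > 0:
                px = px + rng.normal(0.0, pixel_noise_sigma, px.shape)
            mk[mid] = px
        sp: dict[int, np.ndarray] = {}
        if len(truth.surface_points):
            px, z = project_points(truth.surface_points, pose, intrinsics)
            facing = np.einsum(
                "ni,ni->n", truth.surface_normals,
                C[None, :] - truth.surface_points) > 0
            vis = facing & (z > 0) & _in_bounds(px, intrinsics)
            if pixel_noise_sigma > 0:
                px = px + rng.normal(0.0, pixel_noise_sigma, px.shape)
            for k in np.flatnonzero(vis):
                sp[int(truth.surface_ids[k])] = px[k]
        any_marker = any_marker or bool(mk)
        out.append(FrameObservations(fi, mk, sp))
    if not any_marker:
        warnings.warn("no marker visible in any frame", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# Rendering


def _rasterize_marker(image: np.ndarray, corners_px: np.ndarray,
                      pattern: np.ndarray, supersample: int = 4) -> None:
    """Draw a perspective-warped marker pattern (plus white quiet zone) into
    ``image`` in place.  ``corners_px`` are TL,TR,BR,BL of the black border
    square; the pattern is sampled nearest-neighbor at ``supersample``^2
    subpixel positions per pixel (area anti-aliasing)."""
    H, W = image.shape
    cells = pattern.shape[0]
    src = np.array([[0.0, 0.0], [cells, 0.0], [cells, cells], [0.0, cells]])
    tf = projective_from_points(src, corners_px)  # (x, y) point convention
    if tf is None:
        return
    margin = 0.75  # quiet zone, in cell units
    lo = np.floor(corners_px.min(axis=0)).astype(int) - 2
    hi = np.ceil(corners_px.max(axis=0)).astype(int) + 2
    x0, y0 = np.maximum(lo, 0)
    x1 = min(hi[0], W - 1)
    y1 = min(hi[1], H - 1)
    if x1 <= x0 or y1 <= y0:
        return
    sub = (np.arange(supersample) + 0.5) / supersample - 0.5
    xs = np.arange(x0, x1 + 1)
    ys = np.arange(y0, y1 + 1)
    base = image[y0:y1 + 1, x0:x1 + 1].ravel()
    acc = np.zeros_like(base)
    inv = tf.inverse
    for dy in sub:
        for dx in sub:
            gx, gy = np.meshgrid(xs + dx, ys + dy)
            can = inv(np.column_stack([gx.ravel(), gy.ravel()]))
            cx, cy = can[:, 0], can[:, 1]
            inside = (cx >= 0) & (cx < cells) & (cy >= 0) & (cy < cells)
            quiet = ((cx >= -margin) & (cx < cells + margin)
                     & (cy >= -margin) & (cy < cells + margin)) & ~inside
            val = base.copy()
            val[quiet] = 1.0
            ii = np.flatnonzero(inside)
            if len(ii):
                val[ii] = pattern[np.floor(cy[ii]).astype(int),
                                  np.floor(cx[ii]).astype(int)]
            acc += val
    image[y0:y1 + 1, x0:x1 + 1] = (acc / supersample ** 2).reshape(
        len(ys), len(xs))


def _speckle_background(shape: tuple[int, int], rng: np.random.Generator,
                        density: float = 0.30) -> np.ndarray:
    """Seeded speckle texture: base gray with dark dots, lightly smoothed so
    corner detectors find well-localized blobs."""
    img = np.full(shape, 0.58)
    mask = rng.random(shape) < density
    img[mask] = rng.uniform(0.05, 0.35, int(mask.sum()))
    return gaussian_filter(img, 0.7)


def render_marker_frames(truth: SceneGroundTruth, intrinsics: CameraIntrinsics,
                         image_size: tuple[int, int] | None = None,
                         seed: int = 0, dictionary: MarkerDictionary = DICT_4X4_50,
                         supersample: int = 4,
                         speckle_density: float = 0.30) -> list[np.ndarray]:
    """Render one grayscale uint8 frame per camera pose.

    Markers smaller than 8 px (projected shortest side) are skipped with a
    warning; invisible markers are simply absent.  Bit-identical output for
    identical seeds.
    """
    if image_size is None:
        image_size = (intrinsics.width, intrinsics.height)
    W, H = image_size
    if W < 480 or H < 480:
        raise InvalidParameterError("image size must be at least 480x480")
    seeds = np.random.SeedSequence(seed).spawn(len(truth.poses))
    frames = []
    for fi, pose in enumerate(truth.poses):
        rng = np.random.default_rng(seeds[fi])
        img = _speckle_background((H, W), rng, speckle_density)
        C = pose.center
        for mid in sorted(truth.marker_corners):
            if np.dot(truth.marker_normals[mid],
                      C - truth.marker_centers[mid]) <= 0:
                continue
            px, z = project_points(truth.marker_corners[mid], pose, intrinsics)
            if np.any(z <= 0):
                continue
            if not ((px[:, 0] >= -20) & (px[:, 0] <= W + 19)
                    & (px[:, 1] >= -20) & (px[:, 1] <= H + 19)).all():
                continue
            sides = np.linalg.norm(px - np.roll(px, -1, axis=0), axis=1)
            if sides.min() < 8.0:
                warnings.warn(
                    f"frame {fi}: marker {mid} projects to "
                    f"{sides.min():.1f} px, skipped", stacklevel=2)
                continue
            _rasterize_marker(img, px, dictionary.pattern(mid), supersample)
        frames.append((np.clip(img, 0, 1) * 255).round().astype(np.uint8))
    return frames


def render_marker_image(marker_id: int, image_size: int = 480,
                        side_px: float = 220.0, tilt_deg: float = 0.0,
                        roll_deg: float = 0.0,
                        dictionary: MarkerDictionary = DICT_4X4_50,
                        background: float = 0.58,
                        supersample: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """A single marker viewed fronto-parallel or at out-of-plane tilt.

    Returns (uint8 image, exact corner pixel positions TL,TR,BR,BL).
    Useful for codec round-trip checks.
    """
    f = 2.0 * image_size
    intr = CameraIntrinsics(f, f, image_size / 2 - 0.5, image_size / 2 - 0.5,
                            image_size, image_size)
    dist = 1.0
    side_m = side_px * dist / f
    half = side_m / 2
    local = np.array([[-half, -half, 0.0], [half, -half, 0.0],
                      [half, half, 0.0], [-half, half, 0.0]])
    tilt = np.deg2rad(tilt_deg)
    roll = np.deg2rad(roll_deg)
    Rt = np.array([[np.cos(tilt), 0, np.sin(tilt)], [0, 1, 0],
                   [-np.sin(tilt), 0, np.cos(tilt)]])
    Rr = np.array([[np.cos(roll), -np.sin(roll), 0],
                   [np.sin(roll), np.cos(roll), 0], [0, 0, 1]])
    world = local @ (Rt @ Rr).T + [0.0, 0.0, dist]
    pose = CameraPose(np.eye(3), np.zeros(3))
    px, _ = project_points(world, pose, intr)
    img = np.full((image_size, image_size), background)
    _rasterize_marker(img, px, dictionary.pattern(marker_id), supersample)
    return (np.clip(img, 0, 1) * 255).round().astype(np.uint8), px
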