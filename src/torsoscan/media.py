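"""Frame extraction and point-cloud / mesh file I/O.

Frame sources are a video file (decoded through imageio when a suitable
plugin is available), a directory of image frames (lexicographic order,
passthrough), or an in-memory :class:`ArraySource`.  Sampling picks, for
each target timestamp k/rate, the nearest source frame; a clip of duration
T yields ``max(1, floor(T * rate))`` frames including t = 0.

PLY writing is done by an in-package ascii writer with fixed formatting so
identical inputs produce byte-identical files; reading goes through
trimesh (ascii and binary little-endian) after a header sanity check that
names the offending line on malformed input.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import EmptyResultError, InvalidParameterError, ParseError
from .surface import SurfaceMesh

__all__ = [
    "FrameSequence",
    "ArraySource",
    "extract_frames",
    "write_ply_points",
    "write_ply_mesh",
    "write_obj_mesh",
    "read_cloud",
    "read_mesh",
]


@dataclass
class ArraySource:
    """In-memory video: a list of frames at a fixed native frame rate."""

    frames: list[np.ndarray]
    fps: float

    @property
    def duration(self) -> float:
        return len(self.frames) / self.fps


@dataclass
class FrameSequence:
    frames: list[np.ndarray]
    timestamps: np.ndarray            # seconds, strictly increasing
    source: str = ""
    extraction_rate: float = 0.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise InvalidParameterError("timestamps must strictly increase")

    def __len__(self) -> int:
        return len(self.frames)


def _read_image(path: Path) -> np.ndarray:
    import imageio.v3 as iio
    return iio.imread(path)


def extract_frames(source, rate: float = 2.0) -> FrameSequence:
    """Sample frames at ``rate`` frames/second from a video-like source.

    Directories are passed through unchanged (rate ignored, lexicographic
    order, nominal 1 s spacing).
    """
    if rate <= 0:
        raise InvalidParameterError("rate must be positive")
    if isinstance(source, ArraySource):
        return _sample(source.frames, source.fps, rate, "<memory>")
    path = Path(source)
    if path.is_dir():
        exts = {".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp"}
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in exts)
        if not files:
            raise EmptyResultError(f"no image frames in {path}")
        frames = [_read_image(p) for p in files]
        return FrameSequence(frames, np.arange(len(frames), dtype=float),
                             str(path), rate)
    if not path.exists():
        raise IOError(f"no such file or directory: {path}")
    try:
        import imageio.v3 as iio
        meta = iio.immeta(path)
        fps = float(meta.get("fps", 0) or 0)
        frames = list(iio.imiter(path))
    except Exception as exc:  # unreadable container
        raise IOError(f"cannot decode video {path}: {exc}") from exc
    if not frames:
        raise EmptyResultError(f"zero-duration video: {path}")
    if fps <= 0:
        fps = 30.0
    return _sample(frames, fps, rate, str(path))


def _sample(frames: list[np.ndarray], fps: float, rate: float,
            source: str) -> FrameSequence:
    if not frames:
        raise EmptyResultError("zero-duration video")
    duration = len(frames) / fps
    count = max(1, int(np.floor(duration * rate)))
    times = np.arange(count) / rate
    idx = np.clip(np.round(times * fps).astype(int), 0, len(frames) - 1)
    # enforce strictly increasing timestamps (one frame can only appear once)
    picked, seen = [], set()
    for t, i in zip(times, idx):
        if i in seen:
            continue
        seen.add(i)
        picked.append((t, i))
    return FrameSequence([frames[i] for _, i in picked],
                         np.array([t for t, _ in picked]), source, rate)


# ---------------------------------------------------------------------------
# PLY / OBJ


def _fmt(v: float) -> str:
    """Shortest repr of the float32 value (lossless at float32)."""
    return np.format_float_positional(np.float32(v), unique=True, trim="0")


def write_ply_points(path, points: np.ndarray,
                     colors: np.ndarray | None = None,
                     scalars: np.ndarray | None = None,
                     scalar_name: str = "quality") -> None:
    """Deterministic ascii PLY point cloud (float32 coordinates)."""
    pts = np.asarray(points, dtype=np.float32).reshape(-1, 3)
    lines = ["ply", "format ascii 1.0",
             f"element vertex {len(pts)}",
             "property float x", "property float y", "property float z"]
    if colors is not None:
        colors = np.asarray(colors, dtype=np.uint8).reshape(-1, 3)
        lines += ["property uchar red", "property uchar green",
                  "property uchar blue"]
    if scalars is not None:
        scalars = np.asarray(scalars, dtype=np.float32).ravel()
        lines.append(f"property float {scalar_name}")
    lines.append("end_header")
    body = []
    for i, p in enumerate(pts):
        row = [_fmt(p[0]), _fmt(p[1]), _fmt(p[2])]
        if colors is not None:
            row += [str(int(c)) for c in colors[i]]
        if scalars is not None:
            row.append(_fmt(scalars[i]))
        body.append(" ".join(row))
    Path(path).write_text("\n".join(lines + body) + "\n")


def write_ply_mesh(path, mesh: SurfaceMesh) -> None:
    """Deterministic ascii PLY triangle mesh."""
    v = np.asarray(mesh.vertices, dtype=np.float32)
    f = np.asarray(mesh.faces, dtype=np.int64)
    lines = ["ply", "format ascii 1.0",
             f"element vertex {len(v)}",
             "property float x", "property float y", "property float z",
             f"element face {len(f)}",
             "property list uchar int vertex_indices", "end_header"]
    body = [" ".join(_fmt(c) for c in p) for p in v]
    body += ["3 " + " ".join(str(int(i)) for i in tri) for tri in f]
    Path(path).write_text("\n".join(lines + body) + "\n")


def write_obj_mesh(path, mesh: SurfaceMesh) -> None:
    v = np.asarray(mesh.vertices, dtype=np.float32)
    f = np.asarray(mesh.faces, dtype=np.int64)
    lines = [f"v {_fmt(p[0])} {_fmt(p[1])} {_fmt(p[2])}" for p in v]
    lines += [f"f {a + 1} {b + 1} {c + 1}" for a, b, c in f]
    Path(path).write_text("\n".join(lines) + "\n")


def _check_ply_header(path: Path) -> None:
    with open(path, "rb") as fh:
        head = fh.read(4096).split(b"\n")
    if not head or head[0].strip() != b"ply":
        raise ParseError(f"{path}: line 1: not a PLY file "
                         f"(got {head[0][:20]!r})")
    known = (b"format", b"comment", b"element", b"property", b"end_header",
             b"obj_info")
    for ln, raw in enumerate(head[1:], start=2):
        tok = raw.strip().split(b" ")[0]
        if not tok:
            continue
        if tok not in known:
            raise ParseError(f"{path}: line {ln}: unexpected header token "
                             f"{tok[:30]!r}")
        if tok == b"end_header":
            return
    raise ParseError(f"{path}: header has no end_header line")


def read_cloud(path) -> tuple[np.ndarray, np.ndarray | None]:
    """Read a PLY point cloud -> (points (N,3), colors or None)."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        _check_ply_header(path)
    obj = trimesh.load(path, process=False)
    if isinstance(obj, trimesh.PointCloud):
        colors = np.asarray(obj.colors)[:, :3] if len(obj.colors) else None
        return np.asarray(obj.vertices, dtype=float), colors
    if hasattr(obj, "vertices"):
        return np.asarray(obj.vertices, dtype=float), None
    raise ParseError(f"{path}: no vertex data found")


def read_mesh(path) -> SurfaceMesh:
    """Read a PLY or OBJ triangle mesh."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        _check_ply_header(path)
    obj = trimesh.load(path, process=False)
    if not hasattr(obj, "faces") or len(getattr(obj, "faces", [])) == 0:
        # trimesh returns a PointCloud for faceless PLY
        if hasattr(obj, "vertices"):
            return SurfaceMesh(np.asarray(obj.vertices, dtype=float),
                               np.zeros((0, 3), dtype=np.int64))
        raise ParseError(f"{path}: no mesh data found")
    return SurfaceMesh(np.asarray(obj.vertices, dtype=float),
                       np.asarray(obj.faces, dtype=np.int64))
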