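"""Pipeline configuration with lossless YAML round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidParameterError
from .scene import BeltSpec

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    """Everything a reconstruction run needs, file-serializable."""

    # intrinsics (px); distortion assumed corrected upstream
    fx: float = 1400.0
    fy: float = 1400.0
    cx: float = 800.0
    cy: float = 450.0
    image_width: int = 1600
    image_height: int = 900

    extraction_rate: float = 2.0          # frames/s
    n_feature_keypoints: int = 800
    match_ratio: float = 0.8
    match_ransac_px: float = 1.5
    match_window: int = 3                 # temporal pair window for features
    triangulation_reproj_px: float = 2.0
    marker_pair_window: int = 1
    mesh_angular_bins: int = 256
    mesh_vertical_bins: int = 128
    seed: int = 0

    belt: dict = field(default_factory=lambda: asdict(BeltSpec()))
    output_dir: str = "torsoscan_out"
    # (electrode index i, index j, measured distance in meters)
    reference_distances: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("extraction_rate", "match_ransac_px",
                     "triangulation_reproj_px"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")

    @property
    def belt_spec(self) -> BeltSpec:
        return BeltSpec(**self.belt)

    def intrinsics(self):
        from .geometry import CameraIntrinsics
        return CameraIntrinsics(self.fx, self.fy, self.cx, self.cy,
                                self.image_width, self.image_height)


def save_config(config: PipelineConfig, path) -> None:
    data = asdict(config)
    data["reference_distances"] = [list(t) for t in data["reference_distances"]]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def load_config(path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise InvalidParameterError(f"{path}: config is not a mapping")
    data["reference_distances"] = [tuple(t) for t
                                   in data.get("reference_distances", [])]
    return PipelineConfig(**data)
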