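"""Run configuration: every tunable of the pipeline in one validated record.

Defaults follow the reference arena setup: binarization threshold 43,
calibration over the first 500 frames (20 s at 25 fps), and a contact
threshold of one body length for interaction detection.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline tunables with their defaults.

    Attributes
    ----------
    threshold:
        Gray-level difference (background minus frame) at or above which a
        pixel is foreground.
    connectivity:
        Pixel connectivity for component labeling: 1 (4-neighbour) or
        2 (8-neighbour).
    cleanup:
        If true, apply a one-pixel binary opening to each mask before
        labeling. Off by default.
    calib_frames:
        Number of initial frames used to calibrate the single-bee size range.
    bin_width:
        Histogram bin width (px^2) for the modal-area estimate.
    mode_window:
        Relative window around the modal area; regions outside
        ``[lo * mode, hi * mode]`` are excluded from calibration.
    rss_margin:
        Relative widening of the calibrated size interval (0 disables).
    search_radius_factor:
        Regional-matching search radius as a multiple of the body length.
    stitching, max_gap:
        Optional post-hoc joining of a dormant track to a fresh track that
        starts within ``max_gap`` frames and one body length.
    contact_dist:
        Encounter threshold in pixels; ``None`` means the calibrated body
        length (15 px in the reference setup).
    theta_deg:
        Heading change (degrees) above which a bee "changed direction".
    phi_deg:
        Incoming-heading cone (degrees) separating same-direction from
        opposite-direction approaches.
    v_stop:
        Stop speed in body lengths per second.
    heading_window:
        Frames averaged before/after an episode for pre/post headings.
    assoc_radius:
        Ground-truth association radius in pixels; ``None`` = body length.
    """

    threshold: int = 43
    connectivity: int = 2
    cleanup: bool = False
    calib_frames: int = 500
    bin_width: int = 2
    mode_window: tuple[float, float] = (0.5, 1.5)
    rss_margin: float = 0.0
    search_radius_factor: float = 1.0
    stitching: bool = False
    max_gap: int = 12
    contact_dist: Optional[float] = None
    theta_deg: float = 45.0
    phi_deg: float = 90.0
    v_stop: float = 0.1
    heading_window: int = 12
    assoc_radius: Optional[float] = None
    seed: int = 0
    background_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.connectivity not in (1, 2):
            raise ValueError("connectivity must be 1 or 2")
        if self.calib_frames < 1:
            raise ValueError("calib_frames must be >= 1")
        lo, hi = self.mode_window
        if not (0 < lo <= 1 <= hi):
            raise ValueError("mode_window must bracket 1.0")

    def replace(self, **kwargs: Any) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["mode_window"] = list(d["mode_window"])
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "mode_window" in data:
            data = dict(data)
            data["mode_window"] = tuple(data["mode_window"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def log_resolved(self) -> None:
        log.info("resolved config: %s", self.to_dict())
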