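"""Single-bee size calibration.

The tracker assumes all bees have nearly the same pixel area. The valid
single-bee size range (RSS) is estimated from the initial portion of the
movie (20 s = 500 frames at 25 fps by default): all foreground region areas
are pooled, the modal area ``m`` is found by histogram, regions in
``[0.5 m, 1.5 m]`` are taken as single-bee samples (this rejects merged
double-size blobs and sub-bee specks), and the RSS is the closed interval
``[min, max]`` of those samples. The mean major axis of the samples gives
the body length used as the motion/contact scale.
"""

from __future__ import annotations

import json
import logging
import warnings
from collections import Counter
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .io import FrameStack
from .segmentation import (
    DEFAULT_THRESHOLD,
    BackgroundModel,
    LabeledRegion,
    build_background,
    extract_regions,
    foreground_mask,
)

log = logging.getLogger(__name__)

DEFAULT_CALIB_FRAMES = 500  # 20 s at 25 fps

#: Size classes of a foreground region relative to the RSS.
SBS = "SBS"  # single-bee size: fits within the RSS (closed interval)
PBS = "PBS"  # plural-bee size: larger than the RSS maximum
NBS = "NBS"  # no-bee size: smaller than the RSS minimum


class CalibrationError(RuntimeError):
    """No usable regions in the calibration window."""


@dataclass(frozen=True)
class SizeRange:
    """Calibrated single-bee size interval plus a body-length estimate."""

    min_area: float
    max_area: float
    modal_area: float
    body_length: float
    n_samples: int

    def __post_init__(self) -> None:
        if not (0 < self.min_area <= self.modal_area <= self.max_area):
            raise ValueError("require 0 < min_area <= modal_area <= max_area")
        if self.body_length <= 0:
            raise ValueError("body_length must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2), encoding="utf-8")


def _modal_area(areas: np.ndarray, bin_width: int) -> float:
    """Most frequent area value within the fullest histogram bin."""
    lo, hi = areas.min(), areas.max()
    if lo == hi:
        return float(lo)
    edges = np.arange(lo, hi + bin_width + 1, bin_width)
    counts, _ = np.histogram(areas, bins=edges)
    b = int(np.argmax(counts))
    in_bin = areas[(areas >= edges[b]) & (areas < edges[b + 1])]
    values, freq = np.unique(in_bin, return_counts=True)
    return float(values[np.argmax(freq)])


def calibrate_from_regions(
    regions_per_frame: Sequence[Sequence[LabeledRegion]],
    bin_width: int = 2,
    mode_window: tuple[float, float] = (0.5, 1.5),
    margin: float = 0.0,
) -> SizeRange:
    """Estimate the RSS from per-frame region lists of the calibration window."""
    regions = [r for frame in regions_per_frame for r in frame]
    if not regions:
        raise CalibrationError("no foreground regions in the calibration window")
    areas = np.array([r.area for r in regions])
    mode = _modal_area(areas, bin_width)
    lo_f, hi_f = mode_window
    candidates = [r for r in regions if lo_f * mode <= r.area <= hi_f * mode]
    if not candidates:  # cannot happen: the modal region is its own candidate
        raise CalibrationError("no single-bee-sized regions near the modal area")
    cand_areas = np.array([r.area for r in candidates])
    min_area = float(cand_areas.min()) * (1.0 - margin)
    max_area = float(cand_areas.max()) * (1.0 + margin)
    body_length = float(np.mean([r.major_axis for r in candidates]))
    return SizeRange(
        min_area=min_area,
        max_area=max_area,
        modal_area=mode,
        body_length=body_length,
        n_samples=len(candidates),
    )


def calibrate_rss(
    stack: FrameStack,
    n_frames: int = DEFAULT_CALIB_FRAMES,
    *,
    background: Optional[BackgroundModel] = None,
    threshold: int = DEFAULT_THRESHOLD,
    connectivity: int = 2,
    cleanup: bool = False,
    bin_width: int = 2,
    mode_window: tuple[float, float] = (0.5, 1.5),
    margin: float = 0.0,
) -> SizeRange:
    """Calibrate the RSS from the first ``n_frames`` frames of a movie.

    If the movie is shorter than ``n_frames`` all frames are used and a
    warning is logged.
    """
    if stack.n_frames < n_frames:
        warnings.warn(
            f"movie has {stack.n_frames} frames < {n_frames} calibration frames; using all",
            stacklevel=2,
        )
        n_frames = stack.n_frames
    bg = background or build_background(stack)
    per_frame = []
    for t in range(n_frames):
        mask = foreground_mask(stack.frames[t], bg, threshold)
        per_frame.append(extract_regions(mask, connectivity, cleanup))
    return calibrate_from_regions(per_frame, bin_width, mode_window, margin)


def classify_size(region: LabeledRegion | int | float, rss: SizeRange) -> str:
    """Classify a region (or raw area) against the RSS.

    Returns ``SBS`` if the area fits within the closed RSS interval,
    ``PBS`` above its maximum, ``NBS`` below its minimum. The three classes
    partition all possible areas.
    """
    area = region.area if isinstance(region, LabeledRegion) else float(region)
    if area < rss.min_area:
        return NBS
    if area > rss.max_area:
        return PBS
    return SBS
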