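"""Process A: foreground extraction.

Dark animals on a bright, static arena are segmented in three steps:

1. a background image is built by taking the per-pixel *maximum* gray value
   over all frames (the brightest value a pixel ever takes is background,
   since bees only darken pixels);
2. each frame is subtracted from the background and binarized at a fixed
   gray-level threshold (difference clamped at zero — the comparison is
   ``background - frame >= threshold``);
3. 8-connected components of the binary mask become candidate bee regions,
   with centroid and ellipse axes from second-order moments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from skimage import measure, morphology

from .io import FrameStack

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 43  # gray levels; robust over roughly 38-53 on the reference footage


@dataclass
class BackgroundModel:
    """A static background image plus a tag recording how it was obtained."""

    image: np.ndarray
    method: str = "per-pixel-max"

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.uint8)
        if self.image.ndim != 2:
            raise ValueError("background image must be 2-D grayscale")


@dataclass(frozen=True)
class LabeledRegion:
    """One connected foreground component.

    ``coords`` is an ``(area, 2)`` array of (row, col) pixel coordinates.
    Centroid and bounding box are in (x, y) = (col, row) order.
    """

    label: int
    coords: np.ndarray
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]  # xmin, ymin, xmax, ymax (inclusive)
    major_axis: float
    minor_axis: float

    @property
    def area(self) -> int:
        return int(self.coords.shape[0])

    @cached_property
    def pixel_set(self) -> frozenset[tuple[int, int]]:
        """Member pixels as a set of (x, y) tuples."""
        return frozenset((int(c), int(r)) for r, c in self.coords)

    def flat_indices(self, width: int) -> np.ndarray:
        """Member pixels as flattened row-major indices for fast overlap."""
        return self.coords[:, 0] * width + self.coords[:, 1]


def build_background(
    stack: FrameStack, empty_arena: Optional[np.ndarray] = None
) -> BackgroundModel:
    """Model the background as the per-pixel maximum over all frames.

    If a pre-recorded empty-arena image is supplied it is used verbatim
    instead of the estimate.
    """
    if empty_arena is not None:
        empty = np.asarray(empty_arena, dtype=np.uint8)
        if empty.shape != stack.frames.shape[1:]:
            raise ValueError("empty-arena image size does not match the frames")
        return BackgroundModel(image=empty, method="supplied")
    if stack.n_frames < 1:
        raise ValueError("cannot build a background from an empty stack")
    return BackgroundModel(image=stack.frames.max(axis=0), method="per-pixel-max")


def foreground_mask(
    frame: np.ndarray, background: BackgroundModel | np.ndarray, threshold: int = DEFAULT_THRESHOLD
) -> np.ndarray:
    """Binary foreground: pixels where ``background - frame >= threshold``.

    The difference is clamped at zero, so pixels brighter than the
    background can never become foreground.
    """
    bg = background.image if isinstance(background, BackgroundModel) else np.asarray(background)
    frame = np.asarray(frame)
    if frame.shape != bg.shape:
        raise ValueError(f"frame shape {frame.shape} != background shape {bg.shape}")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    diff = np.clip(bg.astype(np.int16) - frame.astype(np.int16), 0, None)
    return diff >= threshold


def extract_regions(
    mask: np.ndarray, connectivity: int = 2, cleanup: bool = False
) -> list[LabeledRegion]:
    """Label connected components of a binary mask (8-connected by default)."""
    mask = np.asarray(mask, dtype=bool)
    if cleanup:
        mask = morphology.binary_opening(mask, morphology.disk(1))
    labeled = measure.label(mask, connectivity=connectivity)
    regions = []
    for rp in measure.regionprops(labeled):
        rmin, cmin, rmax, cmax = rp.bbox
        regions.append(
            LabeledRegion(
                label=int(rp.label),
                coords=np.asarray(rp.coords),
                centroid=(float(rp.centroid[1]), float(rp.centroid[0])),
                bbox=(int(cmin), int(rmin), int(cmax - 1), int(rmax - 1)),
                major_axis=float(rp.axis_major_length),
                minor_axis=float(rp.axis_minor_length),
            )
        )
    return regions


def threshold_sweep(
    stack: FrameStack,
    truth,
    thresholds: Sequence[int],
    config=None,
) -> pd.DataFrame:
    """Run the full tracker at each threshold and report the mean TCF.

    Supports robustness analyses of the binarization threshold: on the
    reference footage the mean TCF stays at 1.00 for thresholds between 38
    and 53. Thresholds at which tracking cannot even be calibrated (e.g.
    above the bee/background contrast) score a TCF of 0.
    """
    from . import metrics, trajectory
    from .config import RunConfig
    from .tracking import CalibrationError, track_movie

    if len(thresholds) == 0:
        raise ValueError("threshold list must not be empty")
    config = config or RunConfig()
    rows = []
    for thr in thresholds:
        cfg = config.replace(threshold=int(thr))
        try:
            result = track_movie(stack, cfg)
            table = trajectory.build_table(result.tracks, stack.fps)
            if table.empty:
                raise CalibrationError("no tracks")
            radius = cfg.assoc_radius or result.rss.body_length
            amap = metrics.associate(table, truth.to_table(), radius)
            _, mean_tcf = metrics.compute_tcf(amap)
        except CalibrationError as exc:
            log.warning("threshold %d: tracking failed (%s); TCF = 0", thr, exc)
            mean_tcf = 0.0
        rows.append({"threshold": int(thr), "mean_tcf": float(mean_tcf)})
    return pd.DataFrame(rows)
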