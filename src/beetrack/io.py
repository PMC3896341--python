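"""Frame containers and movie I/O.

The canonical interchange format is a directory of numbered PNG (or TIFF)
still frames; video files are read through :mod:`imageio` when a suitable
plugin is available for the container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

#: Rec. 601 luminance weights used for color-to-gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])

_FRAME_EXTENSIONS = (".png", ".tif", ".tiff")


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an image to 8-bit grayscale by luminance weighting."""
    img = np.asarray(image)
    if img.ndim == 3:
        img = img[..., :3] @ _LUMA
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


@dataclass
class FrameStack:
    """An ordered stack of 8-bit grayscale frames with a frame rate.

    ``frames`` has shape ``(n_frames, height, width)``. Pixel coordinates
    everywhere in this package are ``x`` = column, ``y`` = row, 0-based,
    origin at the top-left corner.
    """

    frames: np.ndarray
    fps: float = 25.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, height, width) array")
        if self.frames.shape[0] < 1:
            raise ValueError("a FrameStack needs at least one frame")
        if self.frames.dtype != np.uint8:
            self.frames = to_grayscale(self.frames)
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_size(self) -> tuple[int, int]:
        """(width, height) in pixels."""
        return int(self.frames.shape[2]), int(self.frames.shape[1])

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, t: int) -> np.ndarray:
        return self.frames[t]


def read_frames(path: str | Path, fps: float = 25.0) -> FrameStack:
    """Load a movie from a frame directory or a video file.

    A directory is read as lexicographically sorted PNG/TIFF stills; any
    other path is handed to imageio.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTENSIONS
        )
        if not files:
            raise FileNotFoundError(f"no frame images found in {path}")
        frames = np.stack([to_grayscale(iio.imread(p)) for p in files])
    else:
        if not path.exists():
            raise FileNotFoundError(path)
        raw = iio.imread(path)
        if raw.ndim == 2:
            raw = raw[None]
        frames = np.stack([to_grayscale(f) for f in raw])
    return FrameStack(frames=frames, fps=fps)


def write_frames(stack: FrameStack, outdir: str | Path, prefix: str = "frame") -> list[Path]:
    """Write a stack as numbered PNGs (``frame_000000.png`` ...)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in range(stack.n_frames):
        p = outdir / f"{prefix}_{t:06d}.png"
        iio.imwrite(p, stack.frames[t])
        paths.append(p)
    return paths
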