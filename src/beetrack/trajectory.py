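"""Process C: trajectories, kinematics, and export.

The trajectory of a bee is the sequence of centers of mass of its resolved
regions over all frames it was tracked. Speed, acceleration and heading
are discrete differences scaled by the frame rate; values that need more
history than a record has (speed on the first frame of a track,
acceleration on the first two) are missing, not zero — a zero would fake
resting. Dormant frames are not emitted: the position is unknown.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .io import FrameStack
from .tracking import BeeTrack

CSV_COLUMNS = ["frame", "id", "x", "y", "area", "speed", "heading"]


def kinematics(track: BeeTrack, fps: float) -> pd.DataFrame:
    """Per-frame speed (px/s), acceleration (px/s^2) and heading (rad).

    ``speed(t) = |p(t) - p(t-1)| * fps``; acceleration is the discrete
    difference of speed scaled by fps; heading is the direction of the
    displacement into frame t. All are NaN where undefined.
    """
    frames = np.array([r.frame for r in track.records])
    pos = track.centroids
    n = len(frames)
    speed = np.full(n, np.nan)
    heading = np.full(n, np.nan)
    if n >= 2:
        d = np.diff(pos, axis=0)
        step = np.hypot(d[:, 0], d[:, 1])
        contiguous = np.diff(frames) == 1
        speed[1:][contiguous] = step[contiguous] * fps
        heading[1:][contiguous] = np.arctan2(d[:, 1], d[:, 0])[contiguous]
    accel = np.full(n, np.nan)
    if n >= 3:
        ds = np.diff(speed)
        accel[1:] = ds * fps
        accel[np.isnan(speed)] = np.nan
    return pd.DataFrame(
        {"frame": frames, "speed": speed, "acceleration": accel, "heading": heading}
    )


def total_distance(track: BeeTrack) -> float:
    """Path length: sum of consecutive centroid displacements (px)."""
    pos = track.centroids
    if len(pos) < 2:
        return 0.0
    d = np.diff(pos, axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def build_table(tracks: Sequence[BeeTrack], fps: float) -> pd.DataFrame:
    """Long-format trajectory table with one row per (frame, id)."""
    pieces = []
    for tr in tracks:
        if not tr.records:
            continue
        kin = kinematics(tr, fps)
        pieces.append(
            pd.DataFrame(
                {
                    "frame": [r.frame for r in tr.records],
                    "id": tr.id,
                    "x": [r.x for r in tr.records],
                    "y": [r.y for r in tr.records],
                    "area": [r.area for r in tr.records],
                    "speed": kin["speed"].to_numpy(),
                    "heading": kin["heading"].to_numpy(),
                }
            )
        )
    if not pieces:
        return pd.DataFrame(columns=CSV_COLUMNS)
    table = pd.concat(pieces, ignore_index=True)
    return table.sort_values(["frame", "id"], ignore_index=True)


def export_csv(tracks: Sequence[BeeTrack] | pd.DataFrame, path: str | Path, fps: float = 25.0) -> None:
    """Write the trajectory table as CSV (UTF-8, 6-decimal floats).

    Missing kinematics are written as empty fields.
    """
    table = tracks if isinstance(tracks, pd.DataFrame) else build_table(tracks, fps)
    table.to_csv(path, index=False, float_format="%.6f", columns=CSV_COLUMNS)


def load_csv(path: str | Path) -> pd.DataFrame:
    """Re-import an exported trajectory CSV."""
    table = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"trajectory CSV is missing columns: {sorted(missing)}")
    return table[CSV_COLUMNS]


_PALETTE = [
    (230, 60, 60), (60, 120, 230), (60, 180, 75), (240, 160, 30),
    (150, 80, 200), (0, 170, 170), (220, 90, 160), (130, 130, 40),
]


def render_overlay(
    stack: FrameStack,
    tracks: Sequence[BeeTrack],
    outdir: str | Path,
    draw_ids: bool = True,
) -> list[Path]:
    """Draw each track's locus (polyline up to the current frame) and ID
    label on the source frames; writes ``frame_%06d.png`` files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    per_track = [
        (tr.id, {r.frame: (r.x, r.y) for r in tr.records}) for tr in tracks if tr.records
    ]
    paths = []
    for t in range(stack.n_frames):
        img = Image.fromarray(stack.frames[t]).convert("RGB")
        drw = ImageDraw.Draw(img)
        for k, (tid, rec) in enumerate(per_track):
            pts = [rec[f] for f in sorted(rec) if f <= t]
            if not pts:
                continue
            color = _PALETTE[k % len(_PALETTE)]
            if len(pts) > 1:
                drw.line(pts, fill=color, width=1)
            if draw_ids and t in rec:
                x, y = rec[t]
                drw.text((x + 4, y + 4), str(tid), fill=color)
        p = outdir / f"frame_{t:06d}.png"
        img.save(p)
        paths.append(p)
    return paths
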