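"""Encounter detection and interaction classification.

A bee-to-bee encounter is a maximal run of frames in which the centroid
distance of a pair drops below one body length (15 px in the reference
setup). Episodes that share a participant and overlap in time merge into a
single multi-participant episode. Each two-bee episode is then assigned one
of five categories by comparing mean headings over a short window before
and after the contact, stop flags during it, and whether the two bodies
merged:

- ``crossing``      both keep their direction, bodies touch but stay apart;
- ``touching``      both deflect, incoming directions similar;
- ``passing``       both deflect, incoming directions opposed;
- ``overlapping``   the bodies merge into one blob, directions kept;
- ``waiting``       one bee stands still from first contact until the other
                    has passed by;
- ``multiple``      three or more bees participate.

When several rules could fire, the more specific evidence wins:
multiple > waiting > overlapping > touching/passing > crossing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

CATEGORIES = ("crossing", "touching", "passing", "overlapping", "waiting", "multiple")

DEFAULT_CONTACT_DIST = 15.0  # px: major axis of a honeybee body in the reference setup


@dataclass
class InteractionEvent:
    """A contact episode.

    ``t1`` is the first frame at which the contact criterion holds; the
    episode spans ``start <= t1 <= end`` (inclusive frames).
    """

    participants: tuple[int, ...]
    t1: int
    start: int
    end: int
    category: Optional[str] = None
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.participants = tuple(sorted(int(p) for p in self.participants))
        if len(self.participants) < 2:
            raise ValueError("an interaction needs at least two participants")
        if not (self.start <= self.t1 <= self.end):
            raise ValueError("require start <= t1 <= end")

    def to_dict(self) -> dict:
        return {
            "participants": list(self.participants),
            "t1": int(self.t1),
            "start": int(self.start),
            "end": int(self.end),
            "category": self.category,
        }


@dataclass
class ClassifierParams:
    """Thresholds for the category rules (angles in degrees).

    ``v_stop`` is in body lengths per second; ``merge_dist`` (px) is the
    centroid distance below which two bodies are considered merged into one
    blob, default half a body length.
    """

    theta_deg: float = 45.0
    phi_deg: float = 90.0
    v_stop: float = 0.1
    window: int = 12
    body_length: float = DEFAULT_CONTACT_DIST
    merge_dist: Optional[float] = None

    @property
    def merge_threshold(self) -> float:
        return self.merge_dist if self.merge_dist is not None else 0.5 * self.body_length

    @property
    def v_stop_px_s(self) -> float:
        return self.v_stop * self.body_length


def _pair_runs(frames: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive integers in a sorted frame array."""
    if frames.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(frames) > 1)
    starts = np.r_[0, breaks + 1]
    ends = np.r_[breaks, frames.size - 1]
    return [(int(frames[s]), int(frames[e])) for s, e in zip(starts, ends)]


def detect_encounters(table: pd.DataFrame, contact_dist: float = DEFAULT_CONTACT_DIST) -> list[InteractionEvent]:
    """Find contact episodes in a trajectory table (frame, id, x, y).

    Pairwise episodes are maximal frame runs with centroid distance below
    ``contact_dist``; episodes sharing a bee within overlapping frame spans
    are merged into one multi-participant episode.
    """
    if contact_dist <= 0:
        raise ValueError("contact_dist must be positive")
    if table.empty:
        return []
    episodes: list[InteractionEvent] = []
    xs = table.pivot_table(index="frame", columns="id", values="x")
    ys = table.pivot_table(index="frame", columns="id", values="y")
    ids = list(xs.columns)
    frames_index = xs.index.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            dx = xs[ids[i]].to_numpy() - xs[ids[j]].to_numpy()
            dy = ys[ids[i]].to_numpy() - ys[ids[j]].to_numpy()
            dist = np.hypot(dx, dy)
            close = frames_index[np.flatnonzero(dist < contact_dist)]
            for start, end in _pair_runs(close):
                episodes.append(
                    InteractionEvent(
                        participants=(ids[i], ids[j]), t1=start, start=start, end=end
                    )
                )
    return _merge_overlapping(episodes)


def _merge_overlapping(episodes: list[InteractionEvent]) -> list[InteractionEvent]:
    """Union episodes that share a participant and overlap in frame span."""
    n = len(episodes)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(n):
        for b in range(a + 1, n):
            ea, eb = episodes[a], episodes[b]
            if set(ea.participants) & set(eb.participants) and not (
                ea.end < eb.start or eb.end < ea.start
            ):
                parent[find(a)] = find(b)
    groups: dict[int, list[InteractionEvent]] = {}
    for a in range(n):
        groups.setdefault(find(a), []).append(episodes[a])
    merged = []
    for group in groups.values():
        participants = sorted({p for e in group for p in e.participants})
        start = min(e.start for e in group)
        merged.append(
            InteractionEvent(
                participants=tuple(participants),
                t1=min(e.t1 for e in group),
                start=start,
                end=max(e.end for e in group),
            )
        )
    merged.sort(key=lambda e: (e.start, e.participants))
    return merged


def _angdiff(a: float, b: float) -> float:
    """Absolute angular difference in radians, in [0, pi]."""
    return abs(math.remainder(a - b, math.tau))


def _net_heading(track: pd.DataFrame, frames: Sequence[int]) -> Optional[float]:
    """Direction of the net displacement over the given frames, or None."""
    sub = track[track["frame"].isin(frames)].sort_values("frame")
    if len(sub) < 2:
        return None
    dx = sub["x"].iloc[-1] - sub["x"].iloc[0]
    dy = sub["y"].iloc[-1] - sub["y"].iloc[0]
    if math.hypot(dx, dy) < 0.5:
        return None
    return math.atan2(dy, dx)


def classify_interaction(
    episode: InteractionEvent,
    table: pd.DataFrame,
    params: Optional[ClassifierParams] = None,
) -> str:
    """Assign one category to an episode (total over all episodes)."""
    params = params or ClassifierParams()
    if episode.end < episode.start:
        raise ValueError("episode must span at least one frame")
    if len(episode.participants) >= 3:
        return "multiple"
    a, b = episode.participants
    W = params.window
    pre = range(episode.start - W, episode.start)
    post = range(episode.end + 1, episode.end + 1 + W)
    during = range(episode.start, episode.end + 1)
    after_t1 = [t for t in during if t > episode.t1]

    info = {}
    for pid in (a, b):
        track = table[table["id"] == pid]
        pre_h = _net_heading(track, pre)
        post_h = _net_heading(track, post)
        changed = (
            _angdiff(pre_h, post_h) > math.radians(params.theta_deg)
            if pre_h is not None and post_h is not None
            else False
        )
        speeds = track[track["frame"].isin(after_t1)]["speed"].to_numpy(dtype=float)
        speeds = speeds[~np.isnan(speeds)]
        stopped_frac = (
            float(np.mean(speeds < params.v_stop_px_s)) if speeds.size else 0.0
        )
        info[pid] = {"pre": pre_h, "post": post_h, "changed": changed, "stopped": stopped_frac}

    # merged: the two centroids came closer than the merge threshold
    ta = table[(table["id"] == a) & table["frame"].isin(during)].set_index("frame")
    tb = table[(table["id"] == b) & table["frame"].isin(during)].set_index("frame")
    common = ta.index.intersection(tb.index)
    merged = False
    if len(common):
        d = np.hypot(
            ta.loc[common, "x"].to_numpy() - tb.loc[common, "x"].to_numpy(),
            ta.loc[common, "y"].to_numpy() - tb.loc[common, "y"].to_numpy(),
        )
        merged = bool(np.min(d) < params.merge_threshold)

    episode.details = {
        "pre_headings": {p: info[p]["pre"] for p in (a, b)},
        "post_headings": {p: info[p]["post"] for p in (a, b)},
        "stopped": {p: info[p]["stopped"] for p in (a, b)},
        "merged": merged,
    }

    one_waits = (info[a]["stopped"] >= 0.9) != (info[b]["stopped"] >= 0.9)
    if one_waits and max(info[a]["stopped"], info[b]["stopped"]) >= 0.9:
        return "waiting"
    both_changed = info[a]["changed"] and info[b]["changed"]
    if merged and not (info[a]["changed"] or info[b]["changed"]):
        return "overlapping"
    if both_changed and info[a]["pre"] is not None and info[b]["pre"] is not None:
        incoming = _angdiff(info[a]["pre"], info[b]["pre"])
        if incoming < math.radians(params.phi_deg):
            return "touching"
        return "passing"
    return "crossing"


def classify_events(
    table: pd.DataFrame,
    params: Optional[ClassifierParams] = None,
    contact_dist: Optional[float] = None,
) -> list[InteractionEvent]:
    """Detect and classify all episodes in a trajectory table."""
    params = params or ClassifierParams()
    dist = contact_dist if contact_dist is not None else params.body_length
    events = detect_encounters(table, dist)
    for e in events:
        e.category = classify_interaction(e, table, params)
    return events


def distance_speed_report(
    table: pd.DataFrame,
    focal_id: int,
    contact_dist: float = DEFAULT_CONTACT_DIST,
) -> pd.DataFrame:
    """Per-frame distances from a focal bee to every other bee, plus its speed.

    Produces the data behind distance/speed encounter plots: columns
    ``frame, other, distance, focal_speed, in_contact``.
    """
    ids = set(table["id"].unique())
    if focal_id not in ids:
        raise KeyError(f"unknown id {focal_id}")
    focal = table[table["id"] == focal_id].set_index("frame")
    rows = []
    for other in sorted(ids - {focal_id}):
        tb = table[table["id"] == other].set_index("frame")
        common = focal.index.intersection(tb.index)
        d = np.hypot(
            focal.loc[common, "x"].to_numpy() - tb.loc[common, "x"].to_numpy(),
            focal.loc[common, "y"].to_numpy() - tb.loc[common, "y"].to_numpy(),
        )
        for frame, dist, spd in zip(common, d, focal.loc[common, "speed"].to_numpy()):
            rows.append(
                {
                    "frame": int(frame),
                    "other": int(other),
                    "distance": float(dist),
                    "focal_speed": float(spd) if not pd.isna(spd) else np.nan,
                    "in_contact": bool(dist < contact_dist),
                }
            )
    return pd.DataFrame(rows, columns=["frame", "other", "distance", "focal_speed", "in_contact"])


def export_events_json(events: Sequence[InteractionEvent], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([e.to_dict() for e in events], indent=2), encoding="utf-8"
    )


def category_summary(events: Sequence[InteractionEvent]) -> pd.DataFrame:
    """Counts per category, in the canonical category order."""
    counts = {c: 0 for c in CATEGORIES}
    for e in events:
        if e.category is not None:
            counts[e.category] = counts.get(e.category, 0) + 1
    return pd.DataFrame(
        [{"category": c, "count": n} for c, n in counts.items()]
    )
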