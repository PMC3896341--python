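"""Evaluation against ground truth: association, TFF, TCF, centroid errors
and event false rates.

TFF (trajectory fragmentation factor) is the number of computed track
segments needed to cover one true trajectory (1 is ideal); TCF (trajectory
completeness factor) is the fraction of a true trajectory's frames covered
by its associated computed tracks (1 is ideal). Association is declared,
not inferred: per frame, computed points are greedily matched to the
nearest true point within a radius (default one body length), and each
computed track is assigned to the true track it matches in the majority of
its frames, so one computed track counts toward one true track only.

Ratios are reported at the conventional printed precision: two decimals
for TFF/TCF, one decimal for percentages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class AssociationMap:
    """Frame-level matches between a computed and a true trajectory set."""

    radius: float
    truth_frames: dict[int, int]  # truth id -> number of truth frames
    assigned: dict[int, set[int]]  # truth id -> system ids assigned to it
    covered: dict[int, set[int]]  # truth id -> frames covered by assigned tracks
    pairs: pd.DataFrame  # frame, truth_id, system_id, distance (assigned only)
    system_truth: dict[int, int]  # system id -> its majority truth id
    matches: pd.DataFrame = None  # all per-frame greedy matches, pre-majority


def _as_table(obj) -> pd.DataFrame:
    if isinstance(obj, pd.DataFrame):
        return obj
    return obj.to_table()  # GroundTruth


def associate(system, truth, radius: float) -> AssociationMap:
    """Greedy nearest-point association within ``radius`` pixels.

    ``system`` and ``truth`` are trajectory tables (frame, id, x, y) or
    objects with a ``to_table()`` method. Ties in distance go to the lower
    truth id. A system track is assigned to the truth track it matches in
    the majority of its matched frames (ties to the lower truth id).
    """
    if radius <= 0:
        raise ValueError("association radius must be positive")
    system = _as_table(system)
    truth = _as_table(truth)
    truth_frames = truth.groupby("id")["frame"].count().to_dict()
    truth_frames = {int(k): int(v) for k, v in truth_frames.items()}

    match_rows = []
    sys_by_frame = dict(iter(system.groupby("frame"))) if not system.empty else {}
    for frame, tchunk in truth.groupby("frame"):
        schunk = sys_by_frame.get(frame)
        if schunk is None:
            continue
        tx = tchunk["x"].to_numpy()
        ty = tchunk["y"].to_numpy()
        tids = tchunk["id"].to_numpy()
        sx = schunk["x"].to_numpy()
        sy = schunk["y"].to_numpy()
        sids = schunk["id"].to_numpy()
        d = np.hypot(sx[:, None] - tx[None, :], sy[:, None] - ty[None, :])
        si, ti = np.nonzero(d <= radius)
        order = sorted(zip(d[si, ti], tids[ti], sids[si]), key=lambda z: (z[0], z[1], z[2]))
        used_s: set[int] = set()
        used_t: set[int] = set()
        for dist, tid, sid in order:
            if sid in used_s or tid in used_t:
                continue
            used_s.add(sid)
            used_t.add(tid)
            match_rows.append(
                {"frame": int(frame), "truth_id": int(tid), "system_id": int(sid), "distance": float(dist)}
            )
    matches = pd.DataFrame(match_rows, columns=["frame", "truth_id", "system_id", "distance"])

    system_truth: dict[int, int] = {}
    if not matches.empty:
        for sid, chunk in matches.groupby("system_id"):
            counts = chunk["truth_id"].value_counts()
            top = counts.max()
            system_truth[int(sid)] = int(min(counts[counts == top].index))

    assigned: dict[int, set[int]] = {g: set() for g in truth_frames}
    covered: dict[int, set[int]] = {g: set() for g in truth_frames}
    keep = []
    for row in matches.itertuples(index=False):
        if system_truth.get(row.system_id) == row.truth_id:
            assigned[row.truth_id].add(row.system_id)
            covered[row.truth_id].add(row.frame)
            keep.append(True)
        else:
            keep.append(False)
    pairs = matches[keep] if len(keep) else matches
    return AssociationMap(
        radius=radius,
        truth_frames=truth_frames,
        assigned=assigned,
        covered=covered,
        pairs=pairs.reset_index(drop=True),
        system_truth=system_truth,
        matches=matches,
    )


def mean_score(values: Sequence[float], ndigits: int = 2) -> float:
    """Mean of per-movie scores at the conventional printed precision."""
    return round(float(np.mean(values)), ndigits)


def compute_tff(amap: AssociationMap) -> tuple[dict[int, int], float]:
    """Per-truth fragmentation (number of assigned computed tracks) and the
    mean over covered truth tracks, rounded to two decimals. Truth tracks
    with zero coverage have no defined TFF and are excluded with a warning.
    """
    per_truth: dict[int, int] = {}
    for g in amap.truth_frames:
        n = len(amap.assigned[g])
        if n == 0:
            log.warning("truth track %d has zero coverage; TFF undefined", g)
            continue
        per_truth[g] = n
    mean = mean_score(list(per_truth.values())) if per_truth else float("nan")
    return per_truth, mean


def compute_tcf(amap: AssociationMap) -> tuple[dict[int, float], float]:
    """Per-truth completeness (covered / total frames, in [0, 1]) and the
    mean over all truth tracks, rounded to two decimals. An uncovered
    truth track scores 0."""
    per_truth = {
        g: len(amap.covered[g]) / amap.truth_frames[g] for g in amap.truth_frames
    }
    mean = mean_score(list(per_truth.values())) if per_truth else float("nan")
    return per_truth, mean


def centroid_errors(amap: AssociationMap) -> tuple[float, float, float]:
    """(min, max, mean) Euclidean distance over all associated frame pairs."""
    if amap.pairs.empty:
        raise ValueError("no associated frames; centroid errors undefined")
    d = amap.pairs["distance"].to_numpy()
    return float(d.min()), float(d.max()), float(d.mean())


def count_identity_swaps(amap: AssociationMap, min_frames: int = 4) -> int:
    """Computed tracks that start following one bee and end following another.

    For each computed track with at least ``min_frames`` matched frames,
    the majority truth id over the first and last quarter of its matched
    frames are compared; a mismatch is a swap. Brief cross-matches during
    a contact (when two bees are closer than the association radius) do
    not register because the quarter endpoints lie outside them.
    """
    all_matches = amap.matches if amap.matches is not None else amap.pairs
    if all_matches.empty:
        return 0
    swaps = 0
    for sid, chunk in all_matches.groupby("system_id"):
        chunk = chunk.sort_values("frame")
        if len(chunk) < min_frames:
            continue
        q = max(1, len(chunk) // 4)
        head = chunk["truth_id"].iloc[:q].mode().iloc[0]
        tail = chunk["truth_id"].iloc[-q:].mode().iloc[0]
        if head != tail:
            swaps += 1
    return swaps


def false_rate(failures: int, occurrences: int) -> Optional[float]:
    """Failure percentage rounded to one decimal; None if no occurrences."""
    if occurrences == 0:
        return None
    return round(100.0 * failures / occurrences, 1)


def accuracy(successes: int, occurrences: int) -> Optional[float]:
    """Success percentage rounded to one decimal; None if no occurrences."""
    if occurrences == 0:
        return None
    return round(100.0 * successes / occurrences, 1)


def event_preserved(
    amap: AssociationMap, event, guard: int = 6
) -> bool:
    """Whether all participants kept their identity across an event.

    For each truth participant, the computed track matched to it in the
    ``guard`` frames before the episode must also match it in the frames
    after; an event with a participant losing its computed track (or
    handing it to another bee) counts as a failure.
    """
    pairs = amap.pairs
    for g in event.participants:
        pre = pairs[
            (pairs["truth_id"] == g)
            & pairs["frame"].between(event.start - guard, event.start - 1)
        ]["system_id"]
        post = pairs[
            (pairs["truth_id"] == g)
            & pairs["frame"].between(event.end + 1, event.end + guard)
        ]["system_id"]
        if pre.empty or post.empty:
            return False
        if set(pre.unique()) != set(post.unique()) or len(pre.unique()) != 1:
            return False
    return True


def false_rate_table(
    truth_events: Sequence, amap: AssociationMap, guard: int = 6
) -> pd.DataFrame:
    """Per-category occurrence/failure counts with percentage rates.

    A failed event is a truth event whose participants' identities were
    not all preserved across the episode. Categories with zero
    occurrences report a blank (NaN) rate.
    """
    from .interaction import CATEGORIES

    occ = {c: 0 for c in CATEGORIES}
    fail = {c: 0 for c in CATEGORIES}
    for ev in truth_events:
        cat = ev.category
        if cat is None:
            continue
        occ[cat] += 1
        if not event_preserved(amap, ev, guard):
            fail[cat] += 1
    rows = []
    for c in CATEGORIES:
        rate = false_rate(fail[c], occ[c])
        rows.append(
            {"category": c, "occurrences": occ[c], "failures": fail[c],
             "false_rate_pct": np.nan if rate is None else rate}
        )
    total = false_rate(sum(fail.values()), sum(occ.values()))
    rows.append(
        {"category": "sum", "occurrences": sum(occ.values()), "failures": sum(fail.values()),
         "false_rate_pct": np.nan if total is None else total}
    )
    return pd.DataFrame(rows)
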