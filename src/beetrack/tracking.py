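"""Process B: persistent identity assignment.

Per frame, every candidate region is classified twice: by *size* against
the calibrated single-bee range (SBS within, PBS above, NBS below) and by
*overlap* with the previous frame's resolved bee masks (NBR none, OBR one,
TBR two or more). The tracker exploits a hard motion restriction — a bee
cannot move farther than its own body length between consecutive frames,
so its regions at t-1 and t must overlap — and applies one rule per region:

- SBS and NBR: a new bee; a fresh ID is assigned;
- SBS and OBR: the region inherits the single overlapping ID;
- SBS and TBR: several bees rendered as one single-bee-sized blob; every
  overlapping ID is kept, positioned by constant-velocity prediction
  projected into the blob;
- PBS and TBR: a merged blob of several bees is split by regional
  matching: each claimant's previous mask is rigidly translated around its
  predicted position to maximize overlap with the unclaimed part of the
  blob;
- anything else (NBS regions, PBS with fewer than two claimants): no
  processing — the region claims no identity.

Tracks that claim no region in a frame become dormant at their last
position and take no further part in overlap tests; a bee reappearing
later receives a fresh ID (an optional post-hoc stitching utility can
bridge such gaps, off by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .calibration import (
    NBS,
    PBS,
    SBS,
    CalibrationError,
    SizeRange,
    calibrate_from_regions,
    classify_size,
)
from .config import RunConfig
from .io import FrameStack
from .segmentation import (
    BackgroundModel,
    LabeledRegion,
    build_background,
    extract_regions,
    foreground_mask,
)

log = logging.getLogger(__name__)

ACTIVE = "active"
DORMANT = "dormant"

NBR = "NBR"
OBR = "OBR"
TBR = "TBR"


@dataclass(frozen=True)
class OverlapClass:
    """Overlap category of a current region against previous bee masks."""

    kind: str
    ids: tuple[int, ...]

    def __post_init__(self) -> None:
        expected = NBR if len(self.ids) == 0 else OBR if len(self.ids) == 1 else TBR
        if self.kind != expected:
            raise ValueError(f"kind {self.kind} inconsistent with {len(self.ids)} ids")


@dataclass
class TrackRecord:
    frame: int
    x: float
    y: float
    region_label: int
    coords: np.ndarray  # (area, 2) of (row, col): the resolved pixel mask
    merged: bool = False  # resolved out of a shared (multi-bee) region

    @property
    def area(self) -> int:
        return int(self.coords.shape[0])


@dataclass
class BeeTrack:
    """One identity's per-frame history."""

    id: int
    records: list[TrackRecord] = field(default_factory=list)
    status: str = ACTIVE

    @property
    def birth_frame(self) -> int:
        return self.records[0].frame

    @property
    def last_seen_frame(self) -> int:
        return self.records[-1].frame

    @property
    def centroids(self) -> np.ndarray:
        return np.array([[r.x, r.y] for r in self.records])

    def append(self, rec: TrackRecord) -> None:
        if self.records and rec.frame <= self.records[-1].frame:
            raise ValueError("frame indices must be strictly increasing")
        self.records.append(rec)


def count_overlaps(
    region: LabeledRegion, prev_masks: dict[int, np.ndarray], width: int
) -> OverlapClass:
    """Classify a region by the previous-frame bee masks it intersects.

    ``prev_masks`` maps track id to flattened pixel indices of the resolved
    mask at t-1. Overlap means a non-empty pixel intersection.
    """
    flat = set(region.flat_indices(width).tolist())
    ids = tuple(
        sorted(tid for tid, m in prev_masks.items() if flat.intersection(m.tolist()))
    )
    kind = NBR if not ids else OBR if len(ids) == 1 else TBR
    return OverlapClass(kind=kind, ids=ids)


def predict_position(track: BeeTrack) -> tuple[float, float]:
    """Constant-velocity extrapolation from the last two records.

    With one record the last position is returned unchanged.
    """
    if not track.records:
        raise ValueError("cannot predict from an empty track")
    if len(track.records) == 1:
        return (track.records[-1].x, track.records[-1].y)
    p1, p2 = track.records[-2], track.records[-1]
    return (2 * p2.x - p1.x, 2 * p2.y - p1.y)


@dataclass
class _Claimant:
    """What the splitter needs to know about one parent track."""

    id: int
    coords: np.ndarray  # previous-frame mask, (n, 2) of (row, col)
    centroid: tuple[float, float]  # (x, y) of that mask
    predicted: tuple[float, float]  # (x, y) predicted for the current frame


#: Body-axis rotations (radians) tried during regional matching, in
#: preference order. A walking bee rotates its body by at most ~20 degrees
#: between consecutive frames; matching the rotated body where it stands
#: beats sliding the unrotated mask onto a similarly aligned neighbour.
MATCH_ROTATIONS = tuple(
    math.radians(a) for a in (0.0, 10.0, -10.0, 20.0, -20.0)
)


def _rotate_mask(coords: np.ndarray, angle: float) -> np.ndarray:
    """Rigidly rotate a pixel mask about its centroid (unique rounded pixels)."""
    if angle == 0.0:
        return coords
    center = coords.mean(axis=0)
    rel = coords - center
    ca, sa = math.cos(angle), math.sin(angle)
    rot = np.column_stack(
        [ca * rel[:, 0] - sa * rel[:, 1], sa * rel[:, 0] + ca * rel[:, 1]]
    )
    return np.unique(np.rint(rot + center).astype(int), axis=0)


#: Overlap-pixels of advantage a placement must gain per pixel of extra
#: distance from the predicted position. Pure overlap maximization treats
#: two similar adjacent bodies as interchangeable; the linear-motion
#: prediction is what delineates identities, so placements far from it
#: must be clearly better supported before they can win.
MATCH_DISTANCE_PENALTY = 2.0


def _best_translation(
    coords: np.ndarray,
    base_offset: tuple[float, float],
    radius: float,
    available: np.ndarray,
) -> tuple[int, tuple[int, int], float]:
    """Best rigid translation of a mask onto the available pixels.

    Scans integer offsets within ``radius`` of ``base_offset`` (which moves
    the mask centroid onto the predicted position) and maximizes the
    distance-regularized overlap ``count - penalty * distance``; ties break
    toward the predicted position and then lexicographically. Returns
    ``(overlap, offset, value)`` of the winner; offsets with zero overlap
    never win (value ``-inf`` if no overlap exists anywhere).
    """
    h, w = available.shape
    base_r = int(round(base_offset[1]))
    base_c = int(round(base_offset[0]))
    R = max(1, int(math.ceil(radius)))
    best_score, best_off = 0, (base_r, base_c)
    best_value, best_d2 = -math.inf, 0.0
    for dr in range(-R, R + 1):
        for dc in range(-R, R + 1):
            d2 = dr * dr + dc * dc
            if d2 > radius * radius:
                continue
            rr = coords[:, 0] + base_r + dr
            cc = coords[:, 1] + base_c + dc
            ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            score = int(available[rr[ok], cc[ok]].sum())
            if score == 0:
                continue
            value = score - MATCH_DISTANCE_PENALTY * math.sqrt(d2)
            if value > best_value or (
                value == best_value
                and (d2, dr, dc) < (best_d2, best_off[0] - base_r, best_off[1] - base_c)
            ):
                best_score, best_off = score, (base_r + dr, base_c + dc)
                best_value, best_d2 = value, d2
    return best_score, best_off, best_value


def split_merged_region(
    region: LabeledRegion,
    parents: Sequence[_Claimant],
    body_length: float,
    frame_shape: tuple[int, int],
    search_radius_factor: float = 1.0,
) -> tuple[dict[int, np.ndarray], list[int]]:
    """Split a plural-bee region among its claimant tracks.

    Each parent's previous mask is rigidly translated over a search window
    of radius ``body_length`` centered on its predicted position to
    maximize pixel overlap with the region (ties toward the predicted
    position, so an unconstrained parent lands exactly where the linear
    motion assumption puts it). Pixels covered by a single placed mask go
    to that parent; pixels contested between placed masks go to the parent
    with the nearest placed center (ties broken by a half-pixel nudge
    along each parent's velocity, then to the lower ID), so each submask
    stays centered on its own bee even through long, deep merges. Leftover
    region pixels are attached to the mask owning the nearest claimed
    pixel. Returns ``(masks, centers, unmatched_ids)``: pairwise-disjoint
    masks whose union is contained in the region, and per-parent centers
    of the best-placed translated mask (the position estimate while the
    bodies are fused — the claimed pixels alone would be biased by the
    contest).
    """
    h, w = frame_shape
    region_map = np.zeros((h, w), dtype=bool)
    region_map[region.coords[:, 0], region.coords[:, 1]] = True
    radius = search_radius_factor * body_length

    placed = []  # (parent, center, footprint coords inside the region)
    centers: dict[int, tuple[float, float]] = {}
    unmatched: list[int] = []
    for p in sorted(parents, key=lambda q: q.id):
        base = (p.predicted[0] - p.centroid[0], p.predicted[1] - p.centroid[1])
        best = (-math.inf, 0, p.coords, (0, 0))
        for angle in MATCH_ROTATIONS:
            coords = _rotate_mask(p.coords, angle)
            score, off, value = _best_translation(coords, base, radius, region_map)
            if value > best[0]:
                best = (value, score, coords, off)
        _, score, coords, (offr, offc) = best
        if score == 0:
            unmatched.append(p.id)
            continue
        rr = coords[:, 0] + offr
        cc = coords[:, 1] + offc
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        rr, cc = rr[ok], cc[ok]
        hit = region_map[rr, cc]
        centers[p.id] = (p.centroid[0] + offc, p.centroid[1] + offr)
        placed.append((p, centers[p.id], np.column_stack([rr[hit], cc[hit]])))

    claimed: dict[int, np.ndarray] = {}
    if placed:
        cover = np.zeros((h, w), dtype=np.int16)
        for _, _, fp in placed:
            cover[fp[:, 0], fp[:, 1]] += 1
        contested = cover >= 2
        points = [ctr for _, ctr, _ in placed]
        velocities = [
            (p.predicted[0] - p.centroid[0], p.predicted[1] - p.centroid[1])
            for p, _, _ in placed
        ]
        contested_coords = np.column_stack(np.nonzero(contested))
        parts = (
            _voronoi_partition(contested_coords, points, velocities)
            if contested_coords.size
            else [np.empty((0, 2), dtype=int)] * len(placed)
        )
        for (p, _, fp), part in zip(placed, parts):
            solo = fp[cover[fp[:, 0], fp[:, 1]] == 1]
            mask = np.concatenate([solo, part]) if part.size else solo
            if mask.size == 0:
                unmatched.append(p.id)
                del centers[p.id]
            else:
                claimed[p.id] = mask

    covered = np.zeros((h, w), dtype=bool)
    for mask in claimed.values():
        covered[mask[:, 0], mask[:, 1]] = True
    leftover = np.column_stack(np.nonzero(region_map & ~covered))
    if leftover.size and claimed:
        owners = sorted(claimed)
        all_claimed = np.concatenate([claimed[i] for i in owners])
        labels = np.concatenate(
            [np.full(len(claimed[i]), k) for k, i in enumerate(owners)]
        )
        _, idx = cKDTree(all_claimed).query(leftover)
        for k, i in enumerate(owners):
            extra = leftover[labels[idx] == k]
            if extra.size:
                claimed[i] = np.concatenate([claimed[i], extra])
    return claimed, centers, unmatched


@dataclass
class TrackerState:
    """Mutable state of the stepper: all tracks plus the next fresh ID."""

    tracks: dict[int, BeeTrack] = field(default_factory=dict)
    next_id: int = 1
    diagnostics: list[dict] = field(default_factory=list)

    def active_tracks(self) -> dict[int, BeeTrack]:
        return {i: tr for i, tr in self.tracks.items() if tr.status == ACTIVE}


def _project_into(point: tuple[float, float], coords: np.ndarray) -> tuple[float, float]:
    """Nearest region pixel to a point (point in (x, y), coords in (row, col))."""
    d2 = (coords[:, 1] - point[0]) ** 2 + (coords[:, 0] - point[1]) ** 2
    k = int(np.argmin(d2))
    return (float(coords[k, 1]), float(coords[k, 0]))


def _voronoi_partition(
    coords: np.ndarray, points: list[tuple[float, float]], velocities: list[tuple[float, float]]
) -> list[np.ndarray]:
    """Partition region pixels by nearest projected point (ties: first point).

    Coincident points are disambiguated by a half-pixel nudge along each
    claimant's velocity so that bees passing exactly through each other
    keep separate masks.
    """
    pts = [np.array(p, dtype=float) for p in points]
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            if np.allclose(pts[i], pts[j], atol=1e-6):
                for k, v in ((i, velocities[i]), (j, velocities[j])):
                    n = math.hypot(*v)
                    if n > 1e-9:
                        pts[k] = pts[k] + 0.5 * np.array(v) / n
                    else:
                        pts[k] = pts[k] + np.array([0.25 * (k + 1), 0.0])
    d2 = np.stack(
        [(coords[:, 1] - p[0]) ** 2 + (coords[:, 0] - p[1]) ** 2 for p in pts]
    )
    owner = np.argmin(d2, axis=0)
    return [coords[owner == k] for k in range(len(pts))]


def step_tracker(
    state: TrackerState,
    regions: Sequence[LabeledRegion],
    rss: SizeRange,
    frame_index: int,
    frame_shape: tuple[int, int],
    search_radius_factor: float = 1.0,
) -> TrackerState:
    """Advance the tracker by one frame.

    Regions are processed in a canonical order (centroid scan order), so
    the result is invariant to the labeling of connected components. A
    previous-frame identity claimed by several current regions is granted
    to the region with the largest pixel overlap (ties to the earlier
    region in scan order); the others treat it as absent.
    """
    h, w = frame_shape
    regions = sorted(regions, key=lambda r: (r.centroid[1], r.centroid[0], r.area))
    active = state.active_tracks()

    # resolved masks of the previous frame as an id image
    id_map = np.full(h * w, -1, dtype=np.int64)
    for tid, tr in active.items():
        c = tr.records[-1].coords
        id_map[c[:, 0] * w + c[:, 1]] = tid

    # pixel-overlap counts between each current region and each previous id
    overlap_counts: list[dict[int, int]] = []
    for reg in regions:
        vals = id_map[reg.flat_indices(w)]
        vals = vals[vals >= 0]
        ids, counts = np.unique(vals, return_counts=True)
        overlap_counts.append({int(i): int(c) for i, c in zip(ids, counts)})

    # each previous id goes to the region overlapping it most
    claims: dict[int, int] = {}
    for tid in active:
        best, best_count = None, 0
        for ridx, oc in enumerate(overlap_counts):
            if oc.get(tid, 0) > best_count:
                best, best_count = ridx, oc[tid]
        if best is not None:
            claims[tid] = best

    assigned: set[int] = set()
    diag = {"frame": frame_index, "SBS": 0, "PBS": 0, "NBS": 0, "new": 0, "merged": 0}
    for ridx, reg in enumerate(regions):
        size_class = classify_size(reg, rss)
        diag[size_class] += 1
        ids = sorted(t for t, r in claims.items() if r == ridx)
        if size_class == SBS and len(ids) == 0:
            tid = state.next_id
            state.next_id += 1
            state.tracks[tid] = BeeTrack(id=tid)
            state.tracks[tid].append(
                TrackRecord(frame_index, reg.centroid[0], reg.centroid[1], reg.label, reg.coords)
            )
            assigned.add(tid)
            diag["new"] += 1
        elif size_class == SBS and len(ids) == 1:
            tr = active[ids[0]]
            tr.append(
                TrackRecord(frame_index, reg.centroid[0], reg.centroid[1], reg.label, reg.coords)
            )
            assigned.add(ids[0])
        elif size_class == SBS and len(ids) >= 2:
            # several bees rendered as one single-bee-sized blob: keep all
            # identities at their predicted positions inside the blob
            diag["merged"] += 1
            points, velocities = [], []
            for tid in ids:
                tr = active[tid]
                pred = predict_position(tr)
                points.append(_project_into(pred, reg.coords))
                last = tr.records[-1]
                prev = tr.records[-2] if len(tr.records) > 1 else last
                velocities.append((last.x - prev.x, last.y - prev.y))
            parts = _voronoi_partition(reg.coords, points, velocities)
            for tid, pt, part in zip(ids, points, parts):
                mask = part if part.size else reg.coords
                active[tid].append(
                    TrackRecord(frame_index, pt[0], pt[1], reg.label, mask, merged=True)
                )
                assigned.add(tid)
        elif size_class == PBS and len(ids) >= 2:
            diag["merged"] += 1
            claimants = []
            for tid in ids:
                tr = active[tid]
                last = tr.records[-1]
                claimants.append(
                    _Claimant(
                        id=tid,
                        coords=last.coords,
                        centroid=(last.x, last.y),
                        predicted=predict_position(tr),
                    )
                )
            masks, centers, unmatched = split_merged_region(
                reg, claimants, rss.body_length, frame_shape, search_radius_factor
            )
            for tid, mask in masks.items():
                cx, cy = centers[tid]
                active[tid].append(
                    TrackRecord(frame_index, cx, cy, reg.label, mask, merged=True)
                )
                assigned.add(tid)
            for tid in unmatched:
                log.debug("frame %d: parent %d found no overlap in split", frame_index, tid)
        else:
            # NBS regions, PBS with <2 claimants: no processing
            log.debug(
                "frame %d: region %d (%s, %d claimants) not processed",
                frame_index, reg.label, size_class, len(ids),
            )

    for tid, tr in active.items():
        if tid not in assigned:
            tr.status = DORMANT
    state.diagnostics.append(diag)
    return state


@dataclass
class TrackingResult:
    tracks: list[BeeTrack]
    rss: Optional[SizeRange]
    background: BackgroundModel
    fps: float
    diagnostics: list[dict] = field(default_factory=list)


def track_movie(stack: FrameStack, config: Optional[RunConfig] = None) -> TrackingResult:
    """Run the full pipeline on a movie: background, segmentation,
    size calibration, then the per-frame identity stepper. Deterministic.

    A movie with no foreground at all (e.g. an empty arena) yields an
    empty track list rather than a calibration failure.
    """
    config = config or RunConfig()
    bg = build_background(stack)
    if config.background_path:
        import imageio.v3 as iio

        from .io import to_grayscale

        bg = build_background(stack, empty_arena=to_grayscale(iio.imread(config.background_path)))
    h, w = stack.frames.shape[1:]

    n_calib = min(config.calib_frames, stack.n_frames)
    calib_regions = []
    for t in range(n_calib):
        mask = foreground_mask(stack.frames[t], bg, config.threshold)
        calib_regions.append(extract_regions(mask, config.connectivity, config.cleanup))
    try:
        rss = calibrate_from_regions(
            calib_regions, config.bin_width, config.mode_window, config.rss_margin
        )
    except CalibrationError:
        if any(calib_regions):
            raise
        log.warning("no foreground regions at all; returning an empty track set")
        return TrackingResult(tracks=[], rss=None, background=bg, fps=stack.fps)

    state = TrackerState()
    for t in range(stack.n_frames):
        if t < n_calib:
            regions = calib_regions[t]
        else:
            mask = foreground_mask(stack.frames[t], bg, config.threshold)
            regions = extract_regions(mask, config.connectivity, config.cleanup)
        step_tracker(state, regions, rss, t, (h, w), config.search_radius_factor)

    tracks = [state.tracks[i] for i in sorted(state.tracks)]
    if config.stitching:
        tracks = stitch_tracks(tracks, config.max_gap, rss.body_length)
    return TrackingResult(
        tracks=tracks, rss=rss, background=bg, fps=stack.fps, diagnostics=state.diagnostics
    )


def stitch_tracks(
    tracks: Sequence[BeeTrack], max_gap: int, max_dist: float
) -> list[BeeTrack]:
    """Join a track ending at frame t to one starting within ``max_gap``
    frames and ``max_dist`` pixels of its end (nearest candidate wins,
    ties to the lower ID). Off by default in the pipeline."""
    tracks = sorted(tracks, key=lambda tr: tr.id)
    merged_into: dict[int, int] = {}
    by_id = {tr.id: tr for tr in tracks}
    for tr in tracks:
        while True:
            end = tr.records[-1]
            candidates = []
            for other in tracks:
                if other.id == tr.id or other.id in merged_into:
                    continue
                if other.id == tr.id or not other.records:
                    continue
                start = other.records[0]
                gap = start.frame - end.frame
                if 1 <= gap <= max_gap:
                    d = math.hypot(start.x - end.x, start.y - end.y)
                    if d <= max_dist:
                        candidates.append((d, other.id))
            if not candidates:
                break
            _, oid = min(candidates)
            other = by_id[oid]
            for rec in other.records:
                tr.append(rec)
            tr.status = other.status
            merged_into[oid] = tr.id
    return [tr for tr in tracks if tr.id not in merged_into]
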