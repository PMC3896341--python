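"""Synthetic arena movies with exact ground truth.

Emulates infrared recordings of dark bees on a brighter circular arena:
600x600-pixel frames at 25 fps, up to 16 elliptical agents. Agent motion is
a simplified honeybee-inspired swarm rule set (BEECLUST): move straight
with small heading noise, reflect with jitter at the arena wall, stop and
wait for a random interval when coming within one body length of another
agent (then turn away), and occasionally rest in place. Agents are rendered
as hard-filled ellipses (no antialiasing) so the segmentation ground truth
is unambiguous; Gaussian pixel noise is added afterwards.

:func:`scripted_scenario` additionally produces short two- or three-agent
movies realizing each interaction category exactly (crossing, touching,
passing, overlapping, waiting, multiple), for round-trip testing of the
interaction classifier.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .interaction import DEFAULT_CONTACT_DIST, InteractionEvent, detect_encounters
from .io import FrameStack

STATE_MOVING = 0
STATE_STOPPED = 1  # waiting after a contact
STATE_RESTING = 2  # spontaneous rest

STATE_NAMES = {STATE_MOVING: "moving", STATE_STOPPED: "stopped", STATE_RESTING: "resting"}

#: Frames during which a contact check is suppressed after a wait ends,
#: so that the two agents can separate instead of re-triggering instantly.
CONTACT_REFRACTORY = 24

#: Jitter (radians) added to the specularly reflected heading at the wall;
#: produces wall-following paths rather than clean billiard bounces.
WALL_JITTER = math.radians(30.0)

#: Maximum body-axis rotation per frame (radians). Bees change direction
#: by rotating the body axis over several frames, not instantaneously;
#: large turns (wall reflections, turning away after a wait) are executed
#: in place at this rate before walking resumes.
MAX_TURN_PER_FRAME = math.radians(20.0)

#: Hard-core center distance, as a fraction of the major body axis, below
#: which a move is blocked: bodies are solid and cannot deeply
#: interpenetrate even while the post-wait contact check is suppressed
#: (partial tip overlap remains possible, as in real climbing contacts).
HARD_CORE_FRACTION = 0.6


class PlacementError(RuntimeError):
    """Agents could not be placed without mutual overlap."""


@dataclass
class AgentConfig:
    """Parameters of a synthetic arena movie.

    Defaults reproduce the reference recording geometry: 600x600-pixel
    frames at 25 fps, 1500 frames (one minute), sixteen agents with a
    15-px major body axis on a bright circular arena.
    """

    n_agents: int = 16
    arena_radius_px: float = 290.0
    frame_size: tuple[int, int] = (600, 600)  # (width, height)
    fps: float = 25.0
    n_frames: int = 1500
    body_axes: tuple[float, float] = (15.0, 9.0)  # (major, minor), full lengths
    speed_px_per_frame: float = 2.0
    stop_probability: float = 0.002
    stop_duration: tuple[int, int] = (25, 250)
    turn_noise_deg: float = 6.0
    wait_on_contact: tuple[int, int] = (12, 75)
    bee_gray: int = 60
    background_gray: int = 200
    surround_gray: int = 140
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_gray <= self.bee_gray:
            raise ValueError("arena background must be brighter than the bees")
        if min(self.n_agents, self.n_frames) < 0:
            raise ValueError("counts must be >= 0")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.body_axes[0] < self.body_axes[1]:
            raise ValueError("body_axes is (major, minor)")

    @property
    def center(self) -> tuple[float, float]:
        return (self.frame_size[0] / 2.0, self.frame_size[1] / 2.0)

    @property
    def wall_limit(self) -> float:
        """Maximum centroid distance from the arena center."""
        return self.arena_radius_px - self.body_axes[0] / 2.0 - 1.0


@dataclass
class GroundTruth:
    """Exact per-agent, per-frame poses plus any scripted interaction labels.

    Arrays are shaped ``(n_frames, n_agents)``; agent ``i`` has id ``i + 1``
    (matching the tracker's 1-based first-frame numbering when agent order
    coincides). ``state`` holds the integer codes of :data:`STATE_NAMES`.
    """

    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray
    state: np.ndarray
    fps: float
    arena_center: tuple[float, float]
    arena_radius: float
    body_length: float
    events: list[InteractionEvent] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return int(self.x.shape[0])

    @property
    def n_agents(self) -> int:
        return int(self.x.shape[1])

    def to_table(self) -> pd.DataFrame:
        """Long-format trajectory table: frame, id, x, y, heading, state, speed.

        Speed (px/s) is derived from frame-to-frame displacement and is NaN
        on the first frame, mirroring the tracker's kinematics convention.
        """
        rows = []
        for i in range(self.n_agents):
            dx = np.diff(self.x[:, i])
            dy = np.diff(self.y[:, i])
            speed = np.r_[np.nan, np.hypot(dx, dy) * self.fps]
            for t in range(self.n_frames):
                rows.append(
                    {
                        "frame": t,
                        "id": i + 1,
                        "x": self.x[t, i],
                        "y": self.y[t, i],
                        "heading": self.heading[t, i],
                        "state": STATE_NAMES[int(self.state[t, i])],
                        "speed": speed[t],
                    }
                )
        return pd.DataFrame(
            rows, columns=["frame", "id", "x", "y", "heading", "state", "speed"]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_table().drop(columns=["speed"]).to_csv(
            path, index=False, float_format="%.6f"
        )

    def events_to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps([e.to_dict() for e in self.events], indent=2), encoding="utf-8"
        )


def _arena_base(config: AgentConfig) -> np.ndarray:
    w, h = config.frame_size
    cx, cy = config.center
    yy, xx = np.ogrid[:h, :w]
    disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= config.arena_radius_px**2
    base = np.full((h, w), config.surround_gray, dtype=np.uint8)
    base[disc] = config.background_gray
    return base


def render_frame(
    positions: np.ndarray,
    headings: np.ndarray,
    config: AgentConfig,
    base: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render one frame: filled ellipses on the arena, optional pixel noise."""
    frame = (_arena_base(config) if base is None else base).copy()
    a, b = config.body_axes[0] / 2.0, config.body_axes[1] / 2.0
    for (px, py), hd in zip(positions, headings):
        rr, cc = draw_ellipse(
            py, px, b, a, shape=frame.shape, rotation=math.remainder(hd, math.tau)
        )
        frame[rr, cc] = config.bee_gray
    if config.noise_sd > 0 and rng is not None:
        noisy = frame + rng.normal(0.0, config.noise_sd, frame.shape)
        frame = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
    return frame


def _place_agents(config: AgentConfig, rng: np.random.Generator, max_tries: int = 5000):
    cx, cy = config.center
    limit = config.wall_limit
    min_sep = 1.2 * config.body_axes[0]
    placed: list[tuple[float, float]] = []
    tries = 0
    while len(placed) < config.n_agents:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {config.n_agents} agents without overlap "
                f"after {max_tries} tries"
            )
        tries += 1
        r = limit * math.sqrt(rng.random())
        phi = rng.uniform(-math.pi, math.pi)
        cand = (cx + r * math.cos(phi), cy + r * math.sin(phi))
        if all(math.dist(cand, p) > min_sep for p in placed):
            placed.append(cand)
    return np.array(placed, dtype=float).reshape(config.n_agents, 2)


def _reflect_heading(heading: float, pos: np.ndarray, center: tuple[float, float]) -> float:
    """Specular reflection of a heading about the wall normal at ``pos``."""
    nx, ny = pos[0] - center[0], pos[1] - center[1]
    norm = math.hypot(nx, ny)
    if norm == 0:
        return heading + math.pi
    nx, ny = nx / norm, ny / norm
    vx, vy = math.cos(heading), math.sin(heading)
    dot = vx * nx + vy * ny
    return math.atan2(vy - 2 * dot * ny, vx - 2 * dot * nx)


def simulate(config: AgentConfig) -> tuple[FrameStack, GroundTruth]:
    """Simulate and render a synthetic arena movie.

    Deterministic for a fixed ``config.seed``. Per-frame displacement of
    every agent never exceeds ``speed_px_per_frame``.
    """
    rng = np.random.default_rng(config.seed)
    n, T = config.n_agents, config.n_frames
    cx, cy = config.center
    limit = config.wall_limit
    contact_trigger = config.body_axes[0]

    pos = _place_agents(config, rng) if n > 0 else np.zeros((0, 2))
    heading = rng.uniform(-math.pi, math.pi, n)
    state = np.zeros(n, dtype=np.int8)
    timer = np.zeros(n, dtype=int)
    refractory = np.zeros(n, dtype=int)
    neighbor = np.full(n, -1, dtype=int)
    target = np.full(n, np.nan)  # pending body-axis turn, executed gradually

    X = np.zeros((T, n))
    Y = np.zeros((T, n))
    H = np.zeros((T, n))
    S = np.zeros((T, n), dtype=np.int8)

    turn_sd = math.radians(config.turn_noise_deg)
    for t in range(T):
        X[t], Y[t] = pos[:, 0], pos[:, 1]
        H[t], S[t] = heading, state
        if t == T - 1:
            break
        if n > 1:
            diff = pos[:, None, :] - pos[None, :, :]
            dmat = np.hypot(diff[..., 0], diff[..., 1])
            np.fill_diagonal(dmat, np.inf)
        for i in range(n):
            if state[i] != STATE_MOVING:
                timer[i] -= 1
                if timer[i] <= 0:
                    if state[i] == STATE_STOPPED:
                        # turn away from the contacted neighbor, then move on
                        j = neighbor[i]
                        if j >= 0:
                            away = math.atan2(pos[i, 1] - pos[j, 1], pos[i, 0] - pos[j, 0])
                        else:
                            away = rng.uniform(-math.pi, math.pi)
                        target[i] = away + rng.uniform(-math.pi / 3, math.pi / 3)
                        refractory[i] = CONTACT_REFRACTORY
                    state[i] = STATE_MOVING
                continue
            if refractory[i] > 0:
                refractory[i] -= 1
            if rng.random() < config.stop_probability:
                state[i] = STATE_RESTING
                timer[i] = int(rng.integers(config.stop_duration[0], config.stop_duration[1] + 1))
                continue
            if n > 1 and refractory[i] == 0:
                j = int(np.argmin(dmat[i]))
                if dmat[i, j] < contact_trigger:
                    state[i] = STATE_STOPPED
                    neighbor[i] = j
                    timer[i] = int(
                        rng.integers(config.wait_on_contact[0], config.wait_on_contact[1] + 1)
                    )
                    continue
            if not math.isnan(target[i]):
                # a large turn is executed in place, one body rotation
                # increment per frame, before walking resumes
                delta = math.remainder(target[i] - heading[i], math.tau)
                if abs(delta) > MAX_TURN_PER_FRAME:
                    heading[i] += math.copysign(MAX_TURN_PER_FRAME, delta)
                    continue
                heading[i] = target[i]
                target[i] = np.nan
            heading[i] += turn_sd * rng.standard_normal()
            step = config.speed_px_per_frame * np.array(
                [math.cos(heading[i]), math.sin(heading[i])]
            )
            new = pos[i] + step
            if math.hypot(new[0] - cx, new[1] - cy) > limit:
                target[i] = _reflect_heading(heading[i], pos[i], (cx, cy)) + rng.uniform(
                    -WALL_JITTER, WALL_JITTER
                )
                continue  # turn toward the reflected direction from next frame
            if n > 1:
                # solid bodies: a move may not push this agent deep into
                # another, even while the contact check is suppressed
                others = np.hypot(pos[:, 0] - new[0], pos[:, 1] - new[1])
                others[i] = np.inf
                new_min = float(others.min())
                if new_min < HARD_CORE_FRACTION * contact_trigger and new_min < dmat[i].min():
                    continue  # blocked this frame
            pos[i] = new

    base = _arena_base(config)
    frames = np.empty((T, config.frame_size[1], config.frame_size[0]), dtype=np.uint8)
    for t in range(T):
        frames[t] = render_frame(
            np.c_[X[t], Y[t]], H[t], config, base=base, rng=rng if config.noise_sd > 0 else None
        )

    truth = GroundTruth(
        x=X,
        y=Y,
        heading=H,
        state=S,
        fps=config.fps,
        arena_center=(cx, cy),
        arena_radius=config.arena_radius_px,
        body_length=config.body_axes[0],
    )
    return FrameStack(frames=frames, fps=config.fps), truth


# ---------------------------------------------------------------------------
# Scripted interaction scenarios
# ---------------------------------------------------------------------------

_SCENARIO_FRAME = (260, 260)
_SCENARIO_RADIUS = 120.0


def _scenario_config(n_frames: int, **overrides) -> AgentConfig:
    defaults = dict(
        n_agents=2,
        arena_radius_px=_SCENARIO_RADIUS,
        frame_size=_SCENARIO_FRAME,
        fps=25.0,
        n_frames=n_frames,
        noise_sd=0.0,
        seed=0,
    )
    defaults.update(overrides)
    return AgentConfig(**defaults)


def _heading_from_steps(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    hd = np.zeros_like(x)
    dx, dy = np.diff(x), np.diff(y)
    moved = np.hypot(dx, dy) > 1e-9
    ang = np.arctan2(dy, dx)
    last = ang[moved][0] if moved.any() else 0.0
    for t in range(len(dx)):
        if moved[t]:
            last = ang[t]
        hd[t] = last
    hd[-1] = last
    return hd


def _piecewise(n_frames: int, t1: int, p_t1, pre_deg: float, post_deg: float, speed: float):
    """Straight path through ``p_t1`` at frame ``t1``, deflecting there."""
    pre, post = math.radians(pre_deg), math.radians(post_deg)
    t = np.arange(n_frames, dtype=float)
    x = np.where(
        t <= t1,
        p_t1[0] - speed * (t1 - t) * math.cos(pre),
        p_t1[0] + speed * (t - t1) * math.cos(post),
    )
    y = np.where(
        t <= t1,
        p_t1[1] - speed * (t1 - t) * math.sin(pre),
        p_t1[1] + speed * (t - t1) * math.sin(post),
    )
    return x, y


def scripted_scenario(category: str, **params) -> tuple[FrameStack, GroundTruth]:
    """Produce a short movie realizing one interaction category exactly.

    ``category`` is one of crossing, touching, passing, overlapping,
    waiting, multiple. ``params`` may override ``noise_sd``, ``seed``,
    ``body_axes``, gray levels, and (for overlapping) ``lateral_offset``.
    """
    speed = float(params.pop("speed", 2.0))
    lateral = params.pop("lateral_offset", 0.0)
    builders = {
        "crossing": _build_crossing,
        "touching": _build_touching,
        "passing": _build_passing,
        "overlapping": _build_overlapping,
        "waiting": _build_waiting,
        "multiple": _build_multiple,
    }
    if category not in builders:
        raise ValueError(f"unknown interaction category: {category!r}")
    if category == "overlapping":
        X, Y, S, n_frames = builders[category](speed, lateral)
    else:
        X, Y, S, n_frames = builders[category](speed)
    n_agents = X.shape[1]
    config = _scenario_config(n_frames, n_agents=n_agents, **params)

    H = np.column_stack([_heading_from_steps(X[:, i], Y[:, i]) for i in range(n_agents)])
    truth = GroundTruth(
        x=X,
        y=Y,
        heading=H,
        state=S,
        fps=config.fps,
        arena_center=config.center,
        arena_radius=config.arena_radius_px,
        body_length=config.body_axes[0],
    )
    episodes = detect_encounters(truth.to_table(), contact_dist=config.body_axes[0])
    for e in episodes:
        e.category = category
    truth.events = episodes

    base = _arena_base(config)
    rng = np.random.default_rng(config.seed)
    frames = np.empty((n_frames, config.frame_size[1], config.frame_size[0]), dtype=np.uint8)
    for t in range(n_frames):
        frames[t] = render_frame(
            np.c_[X[t], Y[t]], H[t], config, base=base,
            rng=rng if config.noise_sd > 0 else None,
        )
    return FrameStack(frames=frames, fps=config.fps), truth


def _build_crossing(speed: float):
    # perpendicular straight paths, timed to come within ~12 px (touch,
    # no merge) near frame 50; headings unchanged throughout
    n = 100
    t = np.arange(n, dtype=float)
    ax = 130.0 - speed * (54.0 - t)
    ay = np.full(n, 126.0)
    bx = np.full(n, 130.0)
    by = 126.0 - speed * (45.5 - t)
    X = np.column_stack([ax, bx])
    Y = np.column_stack([ay, by])
    return X, Y, np.zeros((n, 2), dtype=np.int8), n

def _build_touching(speed: float):
    # same-direction approach (+/-20 deg), both deflect by 60 deg at T1
    n, t1 = 105, 55
    ax, ay = _piecewise(n, t1, (130.0, 120.0), 20.0, -40.0, speed)
    bx, by = _piecewise(n, t1, (130.0, 132.0), -20.0, 40.0, speed)
    X = np.column_stack([ax, bx])
    Y = np.column_stack([ay, by])
    return X, Y, np.zeros((n, 2), dtype=np.int8), n

def _build_passing(speed: float):
    # head-on approach on offset lines, both deflect by 60 deg at T1
    n, t1 = 105, 55
    ax, ay = _piecewise(n, t1, (130.0, 124.0), 0.0, 60.0, speed)
    bx, by = _piecewise(n, t1, (130.0, 136.0), 180.0, 120.0, speed)
    X = np.column_stack([ax, bx])
    Y = np.column_stack([ay, by])
    return X, Y, np.zeros((n, 2), dtype=np.int8), n

def _build_overlapping(speed: float, lateral: float = 0.0):
    # head-on on the same line: bodies merge into one blob at T1,
    # headings unchanged (agents pass through each other)
    n, t1 = 105, 55
    t = np.arange(n, dtype=float)
    ax = 130.0 - speed * (t1 - t)
    ay = np.full(n, 130.0)
    bx = 130.0 + speed * (t1 - t)
    by = np.full(n, 130.0 + lateral)
    X = np.column_stack([ax, bx])
    Y = np.column_stack([ay, by])
    return X, Y, np.zeros((n, 2), dtype=np.int8), n

def _build_waiting(speed: float, contact: float = DEFAULT_CONTACT_DIST):
    # B walks toward A on an offset line, freezes on first contact and
    # stays frozen until A has passed one body length away
    n = 108
    ax = 26.0 + speed * np.arange(n)
    ay = np.full(n, 126.0)
    bx = np.empty(n)
    by = np.full(n, 137.0)
    S = np.zeros((n, 2), dtype=np.int8)
    bx[0] = 200.0
    stopped = False
    for t in range(1, n):
        d = math.hypot(ax[t - 1] - bx[t - 1], ay[t - 1] - by[t - 1])
        if not stopped and d < contact:
            stopped = True
        elif stopped and d >= contact:
            stopped = False
        bx[t] = bx[t - 1] if stopped else bx[t - 1] - speed
        S[t, 1] = STATE_STOPPED if stopped else STATE_MOVING
    X = np.column_stack([ax, bx])
    Y = np.column_stack([ay, by])
    return X, Y, S, n

def _build_multiple(speed: float):
    # A and C pass a bee B on opposite sides with overlapping contact
    # spans; the shared participant joins the episodes. B walks in first
    # and rests at the meeting point (so the background model sees its
    # resting spot uncovered early on).
    n = 108
    t = np.arange(n, dtype=float)
    ax, ay = 20.0 + speed * t, np.full(n, 118.0)
    bx = np.minimum(60.0 + speed * t, 130.0)
    by = np.full(n, 130.0)
    cx, cy = 240.0 - speed * t, np.full(n, 142.0)
    X = np.column_stack([ax, bx, cx])
    Y = np.column_stack([ay, by, cy])
    S = np.zeros((n, 3), dtype=np.int8)
    S[bx >= 130.0, 1] = STATE_RESTING
    return X, Y, S, n
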