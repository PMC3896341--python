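import math
from functools import lru_cache

import hypothesis
import numpy as np
import pytest

import beetrack as bt
from beetrack.config import RunConfig

hypothesis.settings.register_profile(
    "default", deadline=None, derandomize=True, max_examples=25
)
hypothesis.settings.load_profile("default")


def flood_fill_components(mask: np.ndarray, connectivity: int = 2) -> list[set]:
    """Brute-force connected components by BFS flood fill.

    Independent oracle for region extraction; returns a list of pixel sets
    of (row, col) tuples.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if connectivity == 2:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask)
    comps = []
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                comp = set()
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    comp.add((rr, cc))
                    for dr, dc in nbrs:
                        r2, c2 = rr + dr, cc + dc
                        if 0 <= r2 < h and 0 <= c2 < w and mask[r2, c2] and not seen[r2, c2]:
                            seen[r2, c2] = True
                            stack.append((r2, c2))
                comps.append(comp)
    return comps


def exhaustive_translation_search(coords, region_coords, radius, shape):
    """Brute-force best rigid translation of ``coords`` onto a region.

    Scans every integer offset with Euclidean norm <= radius and returns
    (best_score, set of offsets achieving it). Independent oracle for the
    regional-matching search.
    """
    region = set(map(tuple, region_coords))
    R = int(math.ceil(radius))
    best, winners = 0, set()
    for dr in range(-R, R + 1):
        for dc in range(-R, R + 1):
            if dr * dr + dc * dc > radius * radius:
                continue
            score = sum(
                1 for (r, c) in coords if (r + dr, c + dc) in region
            )
            if score > best:
                best, winners = score, {(dr, dc)}
            elif score == best and score > 0:
                winners.add((dr, dc))
    return best, winners


@lru_cache(maxsize=None)
def _scenario(category: str):
    return bt.scripted_scenario(category)


@pytest.fixture
def scenario():
    """Factory for (cached) noise-free scripted interaction fixtures."""
    return _scenario


@pytest.fixture(scope="session")
def small_sim():
    """A small multi-agent arena movie with contacts and ground truth."""
    cfg = bt.AgentConfig(
        n_agents=4,
        n_frames=100,
        frame_size=(220, 220),
        arena_radius_px=100,
        stop_probability=0.005,
        stop_duration=(10, 30),
        seed=7,
    )
    return bt.simulate(cfg)


@pytest.fixture
def scenario_config():
    """Tracker settings for the two/three-agent scripted fixtures.

    The scenarios hold fixed body orientations during calibration, so the
    area sample lacks the orientation variety of a real arena; the
    documented relative margin absorbs the pose-dependent area change.
    """
    return RunConfig(calib_frames=40, rss_margin=0.1)
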