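import math

import numpy as np
import pandas as pd
import pytest

import beetrack as bt
from beetrack.interaction import (
    CATEGORIES,
    ClassifierParams,
    InteractionEvent,
    category_summary,
    classify_events,
    classify_interaction,
    detect_encounters,
    distance_speed_report,
)


def _table(tracks: dict[int, list[tuple[float, float]]], fps: float = 25.0) -> pd.DataFrame:
    rows = []
    for tid, pts in tracks.items():
        for t, (x, y) in enumerate(pts):
            if t == 0:
                speed = np.nan
            else:
                speed = math.dist(pts[t - 1], (x, y)) * fps
            rows.append({"frame": t, "id": tid, "x": x, "y": y, "speed": speed})
    return pd.DataFrame(rows)


def _line(start, velocity, n):
    return [(start[0] + velocity[0] * t, start[1] + velocity[1] * t) for t in range(n)]


class TestDetectEncounters:
    def test_parallel_tracks_at_50px_never_meet(self):
        table = _table({1: _line((0, 0), (2, 0), 60), 2: _line((0, 50), (2, 0), 60)})
        assert detect_encounters(table, 15) == []

    def test_default_threshold_is_one_body_length(self):
        near = _table({1: [(0.0, 0.0)] * 10, 2: [(14.0, 0.0)] * 10})
        far = _table({1: [(0.0, 0.0)] * 10, 2: [(16.0, 0.0)] * 10})
        assert len(detect_encounters(near)) == 1
        assert detect_encounters(far) == []

    def test_crossing_tracks_yield_episode_containing_contact_frame(self):
        # two tracks 5 px apart at frame 40
        a = _line((0, 100), (2, 0), 80)
        b = _line((80, 105), (0, 0), 80)
        table = _table({1: a, 2: b})
        (ep,) = detect_encounters(table, 15)
        assert ep.start <= 40 <= ep.end
        assert ep.t1 == ep.start

    def test_constant_contact_covers_all_frames(self):
        table = _table({1: [(0.0, 0.0)] * 30, 2: [(10.0, 0.0)] * 30})
        (ep,) = detect_encounters(table, 15)
        assert (ep.start, ep.end) == (0, 29)

    def test_pairs_sharing_a_bee_merge_into_multi_participant_episode(self):
        table = _table(
            {1: [(0.0, 0.0)] * 20, 2: [(10.0, 0.0)] * 20, 3: [(10.0, 10.0)] * 20}
        )
        events = detect_encounters(table, 15)
        assert len(events) == 1
        assert events[0].participants == (1, 2, 3)

    def test_every_close_frame_belongs_to_exactly_one_episode(self):
        rng = np.random.default_rng(4)
        tracks = {
            i: _line((rng.uniform(0, 60), rng.uniform(0, 60)),
                     (rng.uniform(-1, 1), rng.uniform(-1, 1)), 50)
            for i in range(1, 5)
        }
        table = _table(tracks)
        events = detect_encounters(table, 15)
        # membership: each (frame, pair-below-threshold) is inside exactly one episode
        xs = table.pivot_table(index="frame", columns="id", values="x")
        ys = table.pivot_table(index="frame", columns="id", values="y")
        for t in range(50):
            for i in range(1, 5):
                for j in range(i + 1, 5):
                    d = math.hypot(xs.loc[t, i] - xs.loc[t, j], ys.loc[t, i] - ys.loc[t, j])
                    if d < 15:
                        holders = [
                            e for e in events
                            if {i, j} <= set(e.participants) and e.start <= t <= e.end
                        ]
                        assert len(holders) == 1

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            detect_encounters(_table({1: [(0, 0)]}), 0)


class TestClassifyInteraction:
    @pytest.mark.parametrize("category", CATEGORIES)
    def test_scripted_scenarios_recover_their_own_label(self, scenario, category):
        _, truth = scenario(category)
        events = classify_events(truth.to_table(), ClassifierParams())
        assert [e.category for e in events] == [category]

    def test_classification_is_total(self, scenario):
        # every detected episode receives exactly one category
        _, truth = scenario("touching")
        for e in classify_events(truth.to_table()):
            assert e.category in CATEGORIES

    def test_three_participants_always_multiple(self):
        table = _table({1: [(0.0, 0.0)] * 20, 2: [(10.0, 0.0)] * 20, 3: [(10.0, 10.0)] * 20})
        (ep,) = detect_encounters(table, 15)
        assert classify_interaction(ep, table) == "multiple"

    def test_event_invariants(self):
        with pytest.raises(ValueError):
            InteractionEvent(participants=(1,), t1=5, start=0, end=9)
        with pytest.raises(ValueError):
            InteractionEvent(participants=(1, 2), t1=10, start=0, end=9)

    def test_category_summary_counts(self, scenario):
        _, truth = scenario("waiting")
        events = classify_events(truth.to_table())
        summary = category_summary(events)
        counts = dict(zip(summary["category"], summary["count"]))
        assert counts["waiting"] == 1
        assert sum(counts.values()) == 1


class TestDistanceSpeedReport:
    def test_single_bee_gives_empty_series(self):
        report = distance_speed_report(_table({1: [(0.0, 0.0)] * 5}), 1)
        assert report.empty

    def test_unknown_focal_id_rejected(self):
        with pytest.raises(KeyError):
            distance_speed_report(_table({1: [(0.0, 0.0)] * 5}), 99)

    def test_waiting_fixture_shows_speed_drop_during_contact(self, scenario):
        _, truth = scenario("waiting")
        (event,) = truth.events
        report = distance_speed_report(truth.to_table(), focal_id=2)
        during = report[report["frame"].between(event.t1 + 1, event.end)]
        params = ClassifierParams()
        assert (during["focal_speed"] < params.v_stop_px_s).all()
        assert during["in_contact"].all()

    def test_two_stationary_bees_in_continuous_contact(self):
        table = _table({1: [(0.0, 0.0)] * 12, 2: [(10.0, 0.0)] * 12})
        report = distance_speed_report(table, 1, contact_dist=15)
        assert report["in_contact"].all()
        assert (report["distance"] == 10.0).all()
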