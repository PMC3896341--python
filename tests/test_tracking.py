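import copy
import math

import numpy as np
import pytest

import beetrack as bt
from beetrack.calibration import SizeRange
from beetrack.segmentation import LabeledRegion
from beetrack.tracking import (
    _Claimant,
    BeeTrack,
    TrackerState,
    TrackRecord,
    count_overlaps,
    predict_position,
    split_merged_region,
    step_tracker,
    stitch_tracks,
    track_movie,
)
from beetrack.config import RunConfig

from conftest import exhaustive_translation_search


def _region(coords, label=1):
    coords = np.asarray(coords)
    return LabeledRegion(
        label=label,
        coords=coords,
        centroid=(float(coords[:, 1].mean()), float(coords[:, 0].mean())),
        bbox=(
            int(coords[:, 1].min()), int(coords[:, 0].min()),
            int(coords[:, 1].max()), int(coords[:, 0].max()),
        ),
        major_axis=float(max(np.ptp(coords[:, 0]), np.ptp(coords[:, 1])) + 1),
        minor_axis=1.0,
    )


def _rect(r0, c0, height, width):
    rr, cc = np.mgrid[r0 : r0 + height, c0 : c0 + width]
    return np.column_stack([rr.ravel(), cc.ravel()])


RSS = SizeRange(min_area=10, max_area=30, modal_area=20, body_length=6, n_samples=5)


class TestCountOverlaps:
    def test_disjoint_region_is_nbr(self):
        reg = _region(_rect(0, 0, 2, 2))
        oc = count_overlaps(reg, {5: np.array([90, 91])}, width=10)
        assert (oc.kind, oc.ids) == ("NBR", ())

    def test_single_shared_pixel_is_obr(self):
        reg = _region(_rect(0, 0, 2, 2))
        prev = {3: np.array([11, 12])}  # pixel (1,1) flat=11 shared
        oc = count_overlaps(reg, prev, width=10)
        assert (oc.kind, oc.ids) == ("OBR", (3,))

    def test_two_overlapping_ids_is_tbr(self):
        reg = _region(_rect(0, 0, 3, 3))
        prev = {7: np.array([0]), 3: np.array([22])}
        oc = count_overlaps(reg, prev, width=10)
        assert (oc.kind, oc.ids) == ("TBR", (3, 7))


class TestPredictPosition:
    def _track(self, *points):
        tr = BeeTrack(id=1)
        for t, (x, y) in enumerate(points):
            tr.append(TrackRecord(t, x, y, 0, np.empty((0, 2), dtype=int)))
        return tr

    def test_stationary_track_predicts_in_place(self):
        assert predict_position(self._track((10, 10), (10, 10))) == (10, 10)

    def test_constant_velocity_extrapolation(self):
        assert predict_position(self._track((0, 0), (3, 4))) == (6, 8)

    def test_single_record_returns_last_position(self):
        assert predict_position(self._track((5, 5))) == (5, 5)

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            predict_position(BeeTrack(id=1))


class TestSplitMergedRegion:
    def test_two_stationary_parents_recover_their_halves(self):
        # 10x4 blob whose left and right 5x4 halves were the parents
        region = _region(_rect(0, 0, 4, 10))
        left, right = _rect(0, 0, 4, 5), _rect(0, 5, 4, 5)
        parents = [
            _Claimant(1, left, (2.0, 1.5), (2.0, 1.5)),
            _Claimant(2, right, (7.0, 1.5), (7.0, 1.5)),
        ]
        masks, centers, unmatched = split_merged_region(region, parents, 6.0, (20, 20))
        assert unmatched == []
        assert set(map(tuple, masks[1])) == set(map(tuple, left))
        assert set(map(tuple, masks[2])) == set(map(tuple, right))
        assert centers[1] == (2.0, 1.5) and centers[2] == (7.0, 1.5)

    def test_agrees_with_exhaustive_translation_oracle(self):
        # the oracle's optimum for each stationary half is the identity
        # translation (possibly tied); the splitter must achieve the same
        # score and break the tie toward the predicted position
        region = _region(_rect(0, 0, 4, 10))
        left = _rect(0, 0, 4, 5)
        best, winners = exhaustive_translation_search(
            [tuple(p) for p in left], region.coords, 6.0, (20, 20)
        )
        assert best == 20 and (0, 0) in winners
        parents = [
            _Claimant(1, left, (2.0, 1.5), (2.0, 1.5)),
            _Claimant(2, _rect(0, 5, 4, 5), (7.0, 1.5), (7.0, 1.5)),
        ]
        masks, _, _ = split_merged_region(region, parents, 6.0, (20, 20))
        assert len(masks[1]) == best

    def test_masks_always_disjoint_and_within_region(self):
        region = _region(_rect(0, 0, 4, 12))
        parents = [
            _Claimant(1, _rect(0, 2, 4, 5), (4.0, 1.5), (5.0, 1.5)),
            _Claimant(2, _rect(0, 5, 4, 5), (7.0, 1.5), (6.0, 1.5)),
        ]
        masks, _, _ = split_merged_region(region, parents, 6.0, (20, 20))
        s1 = set(map(tuple, masks[1]))
        s2 = set(map(tuple, masks[2]))
        assert not s1 & s2
        assert (s1 | s2) <= set(map(tuple, region.coords))

    def test_single_claimant_takes_whole_region(self):
        region = _region(_rect(0, 0, 4, 8))
        parents = [_Claimant(1, _rect(0, 0, 4, 5), (2.0, 1.5), (2.0, 1.5))]
        masks, _, unmatched = split_merged_region(region, parents, 6.0, (20, 20))
        assert unmatched == []
        assert set(map(tuple, masks[1])) == set(map(tuple, region.coords))

    def test_unreachable_parent_reported_unmatched(self):
        region = _region(_rect(0, 0, 2, 2))
        far = _Claimant(9, _rect(15, 15, 2, 2), (15.5, 15.5), (15.5, 15.5))
        masks, _, unmatched = split_merged_region(region, [far], 3.0, (20, 20))
        assert unmatched == [9]
        assert masks == {}


def _step(state, regions, frame, shape=(40, 40)):
    return step_tracker(state, regions, RSS, frame, shape)


class TestStepTracker:
    def test_first_frame_assigns_sequential_ids_to_sbs(self):
        regions = [
            _region(_rect(0, 0, 4, 4), label=10),
            _region(_rect(10, 10, 4, 4), label=20),
            _region(_rect(20, 20, 4, 4), label=30),
        ]
        state = _step(TrackerState(), regions, 0)
        assert sorted(state.tracks) == [1, 2, 3]

    def test_undersized_and_oversized_regions_get_no_id(self):
        regions = [
            _region(_rect(0, 0, 1, 2)),  # area 2 < min
            _region(_rect(10, 10, 6, 8)),  # area 48 > max
            _region(_rect(30, 30, 4, 4)),  # single-bee sized
        ]
        state = _step(TrackerState(), regions, 0)
        assert len(state.tracks) == 1

    def test_stationary_regions_keep_ids_across_frames(self):
        regions = [
            _region(_rect(0, 0, 4, 4), label=1),
            _region(_rect(20, 20, 4, 4), label=2),
        ]
        state = TrackerState()
        for t in range(3):
            _step(state, regions, t)
        assert sorted(state.tracks) == [1, 2]
        for tr in state.tracks.values():
            assert [r.frame for r in tr.records] == [0, 1, 2]

    def test_moving_region_inherits_by_overlap(self):
        state = _step(TrackerState(), [_region(_rect(5, 5, 4, 4))], 0)
        _step(state, [_region(_rect(5, 7, 4, 4))], 1)  # shifted 2 px right
        assert list(state.tracks) == [1]
        assert state.tracks[1].records[-1].frame == 1

    def test_unclaimed_track_goes_dormant_and_reappearance_is_new_id(self):
        state = _step(TrackerState(), [_region(_rect(5, 5, 4, 4))], 0)
        _step(state, [], 1)
        assert state.tracks[1].status == "dormant"
        _step(state, [_region(_rect(5, 5, 4, 4))], 2)
        assert sorted(state.tracks) == [1, 2]  # fresh id, never reused

    def test_output_invariant_to_region_list_order(self):
        frames = [
            [_region(_rect(0, 0, 4, 4), label=1), _region(_rect(20, 20, 4, 4), label=2)],
            [_region(_rect(0, 2, 4, 4), label=7), _region(_rect(20, 22, 4, 4), label=9)],
            [_region(_rect(0, 4, 4, 4), label=2), _region(_rect(20, 24, 4, 4), label=1)],
        ]
        s1, s2 = TrackerState(), TrackerState()
        for t, regs in enumerate(frames):
            _step(s1, list(regs), t)
            _step(s2, list(reversed(regs)), t)
        assert sorted(s1.tracks) == sorted(s2.tracks)
        for tid in s1.tracks:
            p1 = [(r.x, r.y) for r in s1.tracks[tid].records]
            p2 = [(r.x, r.y) for r in s2.tracks[tid].records]
            assert p1 == p2


class TestTrackMovie:
    def test_empty_arena_yields_no_tracks(self):
        cfg = bt.AgentConfig(
            n_agents=0, n_frames=20, frame_size=(120, 120), arena_radius_px=50, noise_sd=0.0
        )
        stack, _ = bt.simulate(cfg)
        result = track_movie(stack, RunConfig(calib_frames=10))
        assert result.tracks == [] and result.rss is None

    def test_deterministic_output(self, small_sim):
        stack, _ = small_sim
        cfg = RunConfig(calib_frames=50)
        t1 = bt.build_table(track_movie(stack, cfg).tracks, stack.fps)
        t2 = bt.build_table(track_movie(stack, cfg).tracks, stack.fps)
        assert t1.equals(t2)

    def test_separated_agents_tracked_completely(self, small_sim):
        stack, truth = small_sim
        result = track_movie(stack, RunConfig(calib_frames=50))
        table = bt.build_table(result.tracks, stack.fps)
        amap = bt.associate(table, truth, result.rss.body_length)
        _, tcf_mean = bt.compute_tcf(amap)
        assert tcf_mean >= 0.99
        assert bt.count_identity_swaps(amap) == 0

    @pytest.mark.parametrize("category", ["crossing", "overlapping", "waiting", "multiple"])
    def test_identities_preserved_through_scripted_contacts(
        self, scenario, scenario_config, category
    ):
        stack, truth = scenario(category)
        result = track_movie(stack, scenario_config)
        table = bt.build_table(result.tracks, stack.fps)
        amap = bt.associate(table, truth, result.rss.body_length)
        assert len(result.tracks) == truth.n_agents
        assert bt.count_identity_swaps(amap) == 0
        _, tcf_mean = bt.compute_tcf(amap)
        assert tcf_mean == 1.0


class TestStitchTracks:
    def test_bridges_short_gap_within_body_length(self):
        a = BeeTrack(id=1)
        for t in range(5):
            a.append(TrackRecord(t, 10.0 + t, 10.0, 0, np.empty((0, 2), dtype=int)))
        a.status = "dormant"
        b = BeeTrack(id=2)
        for t in range(8, 12):
            b.append(TrackRecord(t, 15.0 + (t - 8), 10.0, 0, np.empty((0, 2), dtype=int)))
        (joined,) = stitch_tracks([a, b], max_gap=5, max_dist=6.0)
        assert joined.id == 1
        assert [r.frame for r in joined.records] == [0, 1, 2, 3, 4, 8, 9, 10, 11]

    def test_distant_fragments_left_alone(self):
        a = BeeTrack(id=1)
        a.append(TrackRecord(0, 0.0, 0.0, 0, np.empty((0, 2), dtype=int)))
        b = BeeTrack(id=2)
        b.append(TrackRecord(2, 50.0, 50.0, 0, np.empty((0, 2), dtype=int)))
        assert len(stitch_tracks([a, b], max_gap=5, max_dist=6.0)) == 2
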