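"""Track lifecycle, association rounds, and the population cap."""

import numpy as np
import pytest

from pigpen_mot.geometry import Box
from pigpen_mot.kalman import KalmanFilter
from pigpen_mot.tracker import (
    Detection,
    PopulationEstimate,
    Track,
    Tracker,
    TrackerConfig,
    TrackState,
    population_estimate,
)


def det(frame, cx, cy, w=40.0, h=40.0, behavior="stand", emb=None):
    return Detection(frame=frame, box=Box(cx, cy, w, h), behavior=behavior, embedding=emb)


def unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


class TestDetectionValidation:
    def test_bad_confidence(self):
        with pytest.raises(ValueError):
            Detection(frame=1, box=Box(0, 0, 1, 1), confidence=1.5)

    def test_bad_behavior(self):
        with pytest.raises(ValueError, match="unknown behavior"):
            Detection(frame=1, box=Box(0, 0, 1, 1), behavior="sleep")

    def test_non_unit_embedding(self):
        with pytest.raises(ValueError, match="unit-norm"):
            Detection(frame=1, box=Box(0, 0, 1, 1), embedding=np.array([1.0, 1.0]))


class TestPopulationEstimate:
    @pytest.mark.parametrize(
        "counts,expected",
        [([16, 15, 17], 16), ([16], 16), ([15, 16], 16), ([], 0), ([1, 2], 2), ([0, 1], 1)],
    )
    def test_round_half_up_mean(self, counts, expected):
        assert population_estimate(counts) == expected

    def test_ring_buffer_window(self):
        p = PopulationEstimate(window=3)
        for c in [5, 9, 9, 9]:
            p.push(c)
        assert list(p.history) == [9, 9, 9] and p.n == 9


class TestTrackLifecycle:
    def test_confirm_after_n_init_hits(self):
        kf = KalmanFilter()
        d = det(1, 100, 100)
        t = Track(1, kf.initiate(d.to_xyah()), d, n_init=3)
        assert t.state is TrackState.TENTATIVE
        for f in (2, 3):
            t.predict(kf)
            t.update(kf, det(f, 100, 100))
        assert t.state is TrackState.CONFIRMED
        assert t.time_since_update == 0

    def test_tentative_deleted_when_missed(self):
        kf = KalmanFilter()
        d = det(1, 100, 100)
        t = Track(1, kf.initiate(d.to_xyah()), d, n_init=3)
        t.predict(kf)
        t.mark_missed(max_age=30)
        assert t.is_deleted

    @pytest.mark.parametrize("missed,deleted", [(30, False), (31, True)])
    def test_max_age_boundary_is_strict(self, missed, deleted):
        kf = KalmanFilter()
        d = det(1, 100, 100)
        t = Track(1, kf.initiate(d.to_xyah()), d, n_init=1)
        t.predict(kf)
        t.update(kf, det(2, 100, 100))
        assert t.is_confirmed
        for _ in range(missed):
            t.predict(kf)
        t.mark_missed(max_age=30)
        assert t.is_deleted == deleted

    def test_behavior_majority_of_recent_window(self):
        kf = KalmanFilter()
        d = det(1, 0, 0, behavior="lie")
        t = Track(1, kf.initiate(d.to_xyah()), d, n_init=1)
        for f, b in [(2, "eat"), (3, "eat"), (4, "stand")]:
            t.predict(kf)
            t.update(kf, det(f, 0, 0, behavior=b))
        assert t.behavior(window=3) == "eat"
        assert t.behavior(window=1) == "stand"


class TestCreateOrDrop:
    def test_first_frame_creates_all(self):
        tr = Tracker(TrackerConfig())
        out_dets = [det(1, 100 * i, 100) for i in range(1, 17)]
        tr.step(out_dets)
        assert len(tr.tracks) == 16
        assert [t.id for t in tr.tracks] == list(range(1, 17))

    def test_cap_blocks_when_alive_equals_n(self):
        tr = Tracker(TrackerConfig())
        tr._population.push(2)
        tr._first_frame_seen = True
        tr.tracks = []
        for i in (1, 2):
            d = det(1, 200 * i, 100)
            tr.tracks.append(Track(i, tr.kf.initiate(d.to_xyah()), d, 3))
        created = tr._create_or_drop([det(1, 900, 900)], is_first_frame=False)
        assert created == []

    def test_cap_admits_exactly_the_shortfall(self):
        tr = Tracker(TrackerConfig())
        tr._population.push(3)
        tr._first_frame_seen = True
        for i in (1, 2):
            d = det(1, 200 * i, 100)
            tr.tracks.append(Track(i, tr.kf.initiate(d.to_xyah()), d, 3))
        created = tr._create_or_drop([det(1, 900, 900), det(1, 1200, 900)], is_first_frame=False)
        assert len(created) == 1

    def test_disabled_cap_always_creates(self):
        tr = Tracker(TrackerConfig.baseline())
        tr._population.push(1)
        tr._first_frame_seen = True
        d = det(1, 100, 100)
        tr.tracks.append(Track(1, tr.kf.initiate(d.to_xyah()), d, 3))
        created = tr._create_or_drop([det(1, 900, 900), det(1, 1200, 900)], is_first_frame=False)
        assert len(created) == 2


class TestAssociationRounds:
    def test_single_track_single_detection_matched(self):
        tr = Tracker(TrackerConfig())
        e = unit([1, 0, 0])
        for f in range(1, 5):
            out = tr.step([det(f, 100, 100, emb=e)])
        assert len(out) == 1 and out[0].track_id == 1

    def test_no_detections_increments_staleness(self):
        tr = Tracker(TrackerConfig())
        e = unit([1, 0, 0])
        for f in range(1, 5):
            tr.step([det(f, 100, 100, emb=e)])
        tr.step([])
        assert tr.tracks[0].time_since_update == 1

    def test_cascade_prefers_fresher_track_at_equal_cost(self):
        tr = Tracker(TrackerConfig())
        e = unit([1, 0, 0])
        # two identical-appearance tracks far apart; starve track 2 one frame
        tr.step([det(1, 100, 100, emb=e), det(1, 800, 100, emb=e)])
        for f in (2, 3):
            tr.step([det(f, 100, 100, emb=e), det(f, 800, 100, emb=e)])
        tr.step([det(4, 100, 100, emb=e)])  # track 2 misses
        out = tr.step([det(5, 100, 100, emb=e)])
        # detection is spatially gated for track 2, and the fresher track 1
        # is matched in an earlier cascade level regardless
        assert out[0].track_id == 1

    def test_second_round_recovers_displaced_reappearance(self):
        # a confirmed track coasts through two missed frames, then the animal
        # reappears displaced so that 1 - IoU is ~0.77: only the extra, more
        # permissive IoU round re-associates it instead of spawning a new id
        streams = {}
        for f in range(1, 4):
            streams[f] = [det(f, 100, 100)]
        streams[4], streams[5] = [], []
        streams[6] = [det(6, 125, 100)]
        improved = Tracker(TrackerConfig())
        out_improved = improved.run(streams)
        recovered = out_improved[6]
        assert len(recovered) == 1 and recovered[0].track_id == 1

        baseline = Tracker(TrackerConfig.baseline())
        out_base = baseline.run(streams)
        # without the second round the track stays lost at frame 6
        assert all(r.track_id != 1 for r in out_base[6])

    def test_out_of_order_frames_rejected(self):
        tr = Tracker(TrackerConfig())
        tr.step([det(5, 100, 100)])
        with pytest.raises(ValueError, match="strictly increasing"):
            tr.step([det(4, 100, 100)])

    def test_mixed_frames_in_one_step_rejected(self):
        tr = Tracker(TrackerConfig())
        with pytest.raises(ValueError, match="multiple frames"):
            tr.step([det(1, 100, 100), det(2, 200, 200)])


class TestEndToEnd:
    def test_stationary_target_keeps_one_id(self):
        tr = Tracker(TrackerConfig())
        for f in range(1, 51):
            out = tr.step([det(f, 500, 400)])
        assert len(tr.tracks) == 1
        assert out == sorted(out, key=lambda r: r.track_id)
        assert out[0].track_id == 1 and out[0].state == "confirmed"

    def _crossing_streams(self):
        frames = {}
        for f in range(1, 61):
            x1 = 100.0 + 10 * (f - 1)
            x2 = 700.0 - 10 * (f - 1)
            frames[f] = [
                det(f, x1, 300, emb=unit([1, 0, 0, 0])),
                det(f, x2, 300, emb=unit([0, 1, 0, 0])),
            ]
        return frames

    def test_crossing_objects_with_cap_stay_within_two_ids(self):
        tr = Tracker(TrackerConfig())
        results = tr.run(self._crossing_streams())
        max_id = max(r.track_id for outs in results.values() for r in outs)
        assert max_id <= 2

    def test_crossing_objects_baseline_recorded(self):
        tr = Tracker(TrackerConfig.baseline())
        results = tr.run(self._crossing_streams())
        max_id = max(r.track_id for outs in results.values() for r in outs)
        assert max_id >= 2  # may exceed 2; not asserted exactly

    def test_deterministic_output_files(self, tmp_path, small_scene):
        from pigpen_mot.io import write_results

        paths = []
        for k in range(2):
            tr = Tracker(TrackerConfig())
            results = tr.run(small_scene.detections)
            p = tmp_path / f"run{k}.csv"
            write_results(p, results)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_cap_safety_on_simulated_run(self):
        from pigpen_mot.simulate import preset, simulate_pen

        scene = simulate_pen(preset("dense_day", n_frames=120, seed=3))
        tr = Tracker(TrackerConfig())
        for f in sorted(scene.detections):
            tr.step(scene.detections[f])  # internal assert guards every creation
            alive = sum(1 for t in tr.tracks if not t.is_deleted)
            assert alive <= max(tr._population.n, 16)

    def test_behavior_carried_to_output(self):
        tr = Tracker(TrackerConfig())
        for f in range(1, 6):
            out = tr.step([det(f, 100, 100, behavior="eat")])
        assert out[0].behavior == "eat"
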