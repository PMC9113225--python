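"""Tracker unit tests: Kalman filter, association, displacement, lifecycle."""

import itertools

import numpy as np
import pytest

from orangesort import (
    BoundingBox,
    Detection,
    DisplacementEstimate,
    SequenceMeta,
    Track,
    Tracker,
    TrackerConfig,
    associate,
    estimate_unmatched,
    filter_region,
    mean_displacement,
    outputs_to_track_boxes,
    run_sequence,
)
from orangesort.counting_eval import id_switches

from conftest import gt_track_boxes, make_scene


def det(cx, cy, w, h, frame=0, conf=1.0):
    return Detection(frame, BoundingBox(cx, cy, w, h), conf)


class TestTrackCreation:
    def test_initial_state(self):
        t = Track.create(det(100, 50, 20, 30), track_id=1, frame_index=0)
        assert t.last_box == BoundingBox(100, 50, 20, 30)
        assert t.hits == 1
        assert t.birth_scale == 600
        assert t.consecutive_estimates == 0

    def test_tracker_assigns_increasing_unique_ids(self):
        tracker = Tracker()
        out = tracker.step([det(10, 10, 5, 5), det(50, 50, 5, 5), det(90, 90, 5, 5)], 0)
        assert [o.track_id for o in out] == [1, 2, 3]


class TestKalman:
    def test_zero_velocity_prediction_is_stationary(self):
        t = Track.create(det(100, 50, 20, 30), 1, 0)
        box = t.predict()
        assert (box.cx, box.cy) == pytest.approx((100, 50))
        assert (box.w, box.h) == pytest.approx((20, 30), rel=1e-9)

    def test_velocity_shifts_prediction(self):
        t = Track.create(det(100, 50, 20, 30), 1, 0)
        t.kf.x[4] = -3.0
        box = t.predict()
        assert (box.cx, box.cy) == pytest.approx((97, 50))

    def test_covariance_inflates_without_update(self):
        t = Track.create(det(100, 50, 20, 30), 1, 0)
        traces = []
        for _ in range(5):
            t.predict()
            traces.append(np.trace(t.kf.P[:2, :2]))
        assert all(b > a for a, b in zip(traces, traces[1:]))

    def test_update_with_predicted_measurement_keeps_center(self):
        t = Track.create(det(100, 50, 20, 30), 1, 0)
        box = t.predict()
        t.update(det(box.cx, box.cy, box.w, box.h))
        assert (t.last_box.cx, t.last_box.cy) == pytest.approx((100, 50))

    def test_posterior_between_prior_and_measurement(self):
        """Scalar Kalman property on the x-center subproblem."""
        t = Track.create(det(100, 50, 20, 30), 1, 0)
        prior = t.predict()
        t.update(det(110, 50, 20, 30))
        assert prior.cx < t.last_box.cx < 110

    def test_update_resets_counters_and_increments_hits(self):
        t = Track.create(det(100, 50, 20, 30), 1, 0)
        for _ in range(3):
            t.predict()
            t.update(det(100, 50, 20, 30))
        t.frames_since_match = 2
        t.consecutive_estimates = 2
        t.predict()
        t.update(det(100, 50, 20, 30))
        assert t.hits == 5
        assert t.frames_since_match == 0
        assert t.consecutive_estimates == 0


class TestAssociate:
    def test_empty_detections(self):
        res = associate([BoundingBox(10, 10, 10, 10)], [], 0.3)
        assert res.matches == [] and res.unmatched_tracks == [0]

    def test_identical_single_pair(self):
        res = associate([BoundingBox(10, 10, 10, 10)], [det(10, 10, 10, 10)], 0.3)
        assert res.matches == [(0, 0)]
        assert res.unmatched_tracks == [] and res.unmatched_detections == []

    def test_gate_breaks_weak_matches(self):
        res = associate([BoundingBox(0, 0, 10, 10)], [det(100, 100, 10, 10)], 0.3)
        assert res.matches == []
        assert res.unmatched_tracks == [0] and res.unmatched_detections == [0]

    def test_partition_property(self, rng):
        boxes = [BoundingBox(*c, 10, 10) for c in rng.uniform(0, 100, size=(5, 2))]
        dets = [det(*c, 10, 10) for c in rng.uniform(0, 100, size=(7, 2))]
        res = associate(boxes, dets, 0.1)
        t_seen = sorted([m[0] for m in res.matches] + res.unmatched_tracks)
        d_seen = sorted([m[1] for m in res.matches] + res.unmatched_detections)
        assert t_seen == list(range(5)) and d_seen == list(range(7))

    def test_matches_brute_force_assignment(self, rng):
        """Hungarian total cost equals exhaustive search over permutations."""
        from orangesort.core import iou

        for _ in range(20):
            n = 4
            boxes = [BoundingBox(*c, 12, 12) for c in rng.uniform(0, 60, size=(n, 2))]
            dets = [det(*c, 12, 12) for c in rng.uniform(0, 60, size=(n, 2))]
            res = associate(boxes, dets, iou_threshold=0.0)
            got = sum(1 - iou(boxes[i], dets[j].box) for i, j in res.matches)
            best = min(
                sum(1 - iou(boxes[i], dets[j].box) for i, j in enumerate(perm))
                for perm in itertools.permutations(range(n))
            )
            assert got == pytest.approx(best, abs=1e-12)


class TestDisplacement:
    def test_mean_of_two(self):
        est = mean_displacement([((10, 5), (7, 5)), ((20, 5), (17, 5))])
        assert (est.dx, est.dy, est.n) == (-3, 0, 2)
        assert not est.is_fallback

    def test_single_match(self):
        est = mean_displacement([((0, 0), (2, 1))])
        assert (est.dx, est.dy) == (2, 1)

    def test_empty_sets_fallback(self):
        assert mean_displacement([]).is_fallback

    def test_estimate_shifts_and_decays(self):
        t = Track.create(det(30, 10, 20, 10), 1, 0)
        box = estimate_unmatched(t, DisplacementEstimate(-3, 0, 2), alpha=0.9)
        assert (box.cx, box.cy) == pytest.approx((27, 10))
        assert (box.w, box.h) == pytest.approx((18, 9))
        assert t.consecutive_estimates == 1

    def test_alpha_one_boundary_rejected_but_near_one_preserves_scale(self):
        t = Track.create(det(30, 10, 20, 10), 1, 0)
        box = estimate_unmatched(t, DisplacementEstimate(-3, 0, 1), alpha=1 - 1e-12)
        assert box.w == pytest.approx(20, rel=1e-9)

    def test_closed_form_decay_exact(self):
        """m consecutive estimates give width w0 * alpha**m bitwise."""
        alpha, w0 = 0.9, 20.0
        t = Track.create(det(30, 10, w0, 10), 1, 0)
        for m in range(1, 15):
            box = estimate_unmatched(t, DisplacementEstimate(-1, 0, 1), alpha)
            assert box.w == w0 * alpha**m
            assert box.h == 10.0 * alpha**m


class TestFilterRegion:
    meta = SequenceMeta(1000, 800, 10)

    def test_defaults_drop_edges(self):
        dets = [det(100, 5, 4, 4), det(500, 5, 4, 4)]
        kept = filter_region(dets, self.meta, 0.2, 0.8)
        assert [d.box.cx for d in kept] == [500]

    def test_full_region_is_identity(self):
        dets = [det(1, 5, 4, 4), det(999, 5, 4, 4)]
        assert filter_region(dets, self.meta, 0.0, 1.0) == dets

    def test_boundary_closed(self):
        dets = [det(200, 5, 4, 4), det(800, 5, 4, 4)]
        assert len(filter_region(dets, self.meta, 0.2, 0.8)) == 2


class TestStep:
    def test_out_of_order_frames_rejected(self):
        tracker = Tracker()
        tracker.step([], 0)
        with pytest.raises(ValueError, match="increasing order"):
            tracker.step([], 0)

    def test_noiseless_sequence_fully_matched(self):
        """Constant-velocity targets: every frame matched, zero estimates."""
        tracker = Tracker()
        for t in range(20):
            out = tracker.step([det(500 - 4 * t, 100, 30, 30, frame=t)], t)
            assert len(out) == 1 and out[0].track_id == 1
        assert tracker.all_tracks[0].consecutive_estimates == 0
        assert tracker.all_tracks[0].hits == 20

    def test_scale_death_deletes_track(self):
        cfg = TrackerConfig(alpha=0.5, scale_delete_ratio=0.25)
        tracker = Tracker(cfg)
        tracker.step([det(500, 100, 30, 30)], 0)
        tracker.step([det(496, 100, 30, 30)], 1)
        # then disappear: area decays by 0.25 per frame -> deleted on first estimate...
        # alpha=0.5 -> area factor 0.25 at m=1, equality is not below; second step kills it
        tracker.step([], 2)
        tracker.step([], 3)
        assert tracker.tracks == []

    def test_gap_bridging_vs_baseline_sort(self):
        """A 5-frame detection gap: displacement estimation keeps the id,
        baseline SORT with max_age=1 starts a new one."""
        def frames():
            out = []
            for t in range(40):
                dets = [det(800 - 4 * t, 100, 30, 30, frame=t),
                        det(400 - 4 * t, 300, 30, 30, frame=t)]
                if 15 <= t < 20:   # suppress the first target
                    dets = dets[1:]
                out.append(dets)
            return out

        meta = SequenceMeta(1000, 600, 40)
        _, out_disp, _ = run_sequence(frames(), meta, TrackerConfig(use_displacement=True))
        _, out_sort, _ = run_sequence(frames(), meta, TrackerConfig(use_displacement=False, max_age=1))
        ids_disp = {o.track_id for o in out_disp}
        ids_sort = {o.track_id for o in out_sort}
        assert ids_disp == {1, 2}
        assert len(ids_sort) > 2


class TestRunSequence:
    def test_empty_sequence(self):
        _, outputs, count = run_sequence([], SequenceMeta(100, 100, 1), TrackerConfig())
        assert count == 0 and outputs == []

    def test_zero_noise_counts_ground_truth(self):
        config, _, gt, frames = make_scene(seed=3, n_fruits=10)
        for use_region in (False, True):
            cfg = TrackerConfig(use_region=use_region)
            _, _, count = run_sequence(frames, config.meta, cfg)
            assert count == 10

    def test_ids_unique_per_frame_and_never_reused(self):
        config, _, _, frames = make_scene(seed=9, n_fruits=15, miss_rate=0.1)
        tracks, outputs, _ = run_sequence(frames, config.meta, TrackerConfig())
        ids = [t.track_id for t in tracks]
        assert len(ids) == len(set(ids))
        per_frame = {}
        for o in outputs:
            per_frame.setdefault(o.frame_index, []).append(o.track_id)
        for fids in per_frame.values():
            assert len(fids) == len(set(fids))

    def test_displacement_reduces_id_switches_under_misses(self):
        """Random detector misses: displacement estimation strictly fewer
        identity switches than baseline SORT."""
        config, _, gt, frames = make_scene(seed=11, n_fruits=20, miss_rate=0.15)
        gtd = gt_track_boxes(gt)
        switches = {}
        for use_disp in (True, False):
            cfg = TrackerConfig(use_displacement=use_disp, max_age=1)
            tracks, outputs, _ = run_sequence(frames, config.meta, cfg)
            pred = outputs_to_track_boxes(outputs)
            switches[use_disp] = id_switches(pred, gtd)
        assert switches[True] < switches[False]
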