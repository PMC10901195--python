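"""Sniffing classification, touching, event statistics and locomotion."""

import numpy as np
import pandas as pd
import pytest

from mousetrack.behavior import (
    Ethogram,
    classify_sniffing,
    detect_touching,
    f1_score,
    frame_benchmark,
    locomotion_metrics,
    summarize_events,
)
from mousetrack.instseg import Detection, InstanceSegmentationResult
from mousetrack.io import ArenaConfig, KeypointSet
from mousetrack.tracking import assign_identities


def _square(shape, r0, c0, size=10):
    m = np.zeros(shape, dtype=bool)
    m[r0 : r0 + size, c0 : c0 + size] = True
    return m


def _track(mask_lists):
    seg = InstanceSegmentationResult(
        detections=[[Detection(mask=m) for m in ms] for ms in mask_lists],
        failed=[False] * len(mask_lists),
    )
    return assign_identities(seg, len(mask_lists[0]))


def _kps_at(snouts, tails):
    return KeypointSet.from_arrays(
        np.asarray(snouts, dtype=float), np.asarray(tails, dtype=float)
    )


def _geometry(actor_snout, recipient_snout, recipient_tail, recipient_col=120):
    """One frame, two animals; recipient mask at a known location."""
    shape = (200, 200)
    masks = [[_square(shape, 20, 5), _square(shape, 95, recipient_col)]]
    snouts = [[actor_snout, recipient_snout]]
    tails = [[[7.0, 22.0], recipient_tail]]
    return _kps_at(snouts, tails), _track(masks)


class TestClassifySniffing:
    def test_snout_near_snout_is_head_directed(self):
        cfg = ArenaConfig(sniff_threshold_px=25.0)
        kps, track = _geometry(
            actor_snout=[115.0, 100.0],
            recipient_snout=[125.0, 100.0],  # 10 px from actor snout
            recipient_tail=[129.0, 104.0],
        )
        eth = classify_sniffing(kps, track, cfg)
        assert eth.label_series(0, 1)[0] == "head_directed"

    def test_far_from_everything_is_none(self):
        cfg = ArenaConfig(sniff_threshold_px=25.0)
        kps, track = _geometry(
            actor_snout=[15.0, 30.0],
            recipient_snout=[125.0, 100.0],
            recipient_tail=[129.0, 104.0],
        )
        eth = classify_sniffing(kps, track, cfg)
        assert eth.label_series(0, 1)[0] == "none"

    def test_precedence_anogenital_before_body(self):
        # actor snout 30 px from the recipient snout but 10 px from its
        # tail-base (and close to the mask): anogenital wins over body
        cfg = ArenaConfig(sniff_threshold_px=25.0)
        kps, track = _geometry(
            actor_snout=[120.0, 135.0],
            recipient_snout=[120.0, 165.0],
            recipient_tail=[120.0, 125.0],
        )
        eth = classify_sniffing(kps, track, cfg)
        assert np.linalg.norm(np.subtract([120, 135], [120, 165])) >= 25
        assert eth.label_series(0, 1)[0] == "anogenital_directed"

    def test_near_mask_only_is_body_directed(self):
        cfg = ArenaConfig(sniff_threshold_px=25.0)
        # recipient mask rows 95-104, cols 120-129; snout 10 px left of it
        kps, track = _geometry(
            actor_snout=[110.0, 100.0],
            recipient_snout=[160.0, 100.0],
            recipient_tail=[150.0, 104.0],
        )
        eth = classify_sniffing(kps, track, cfg)
        assert eth.label_series(0, 1)[0] == "body_directed"

    def test_labels_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        shape = (200, 200)
        masks, snouts, tails = [], [], []
        for _ in range(20):
            r0 = rng.integers(20, 120)
            masks.append([_square(shape, 20, 5), _square(shape, r0, 120)])
            snouts.append([rng.uniform(0, 199, 2), [125.0, r0 + 5.0]])
            tails.append([[7.0, 22.0], [121.0, r0 + 9.0]])
        kps = _kps_at(snouts, tails)
        track = _track(masks)
        counts = []
        for thr in (5.0, 25.0, 60.0, 120.0):
            cfg = ArenaConfig(sniff_threshold_px=thr)
            eth = classify_sniffing(kps, track, cfg)
            counts.append(int((eth.labels["label"] != "none").sum()))
        assert counts == sorted(counts)

    def test_exactly_one_label_per_frame_and_pair(self):
        cfg = ArenaConfig()
        kps, track = _geometry([115.0, 100.0], [125.0, 100.0], [129.0, 104.0])
        eth = classify_sniffing(kps, track, cfg)
        assert len(eth.labels) == 2  # ordered pairs (0,1) and (1,0)

    def test_missing_keypoint_record_rejected(self):
        cfg = ArenaConfig()
        shape = (60, 60)
        track = _track([[_square(shape, 5, 5), _square(shape, 40, 40)]])
        snouts = np.array([[[10.0, 10.0], [np.nan, np.nan]]])
        kps = KeypointSet.from_arrays(snouts, snouts + 2)
        with pytest.raises(ValueError, match="missing keypoint"):
            classify_sniffing(kps, track, cfg)


class TestDetectTouching:
    def _setup(self, gap_cols, labels=("none", "none")):
        shape = (60, 120)
        masks = [[_square(shape, 25, 10), _square(shape, 25, 20 + gap_cols)]]
        track = _track(masks)
        rows = [(0, 0, 1, labels[0]), (0, 1, 0, labels[1])]
        eth = Ethogram(
            labels=pd.DataFrame(rows, columns=["frame", "actor", "recipient", "label"])
        )
        return track, eth

    def test_overlapping_masks_touch(self):
        track, eth = self._setup(gap_cols=-5)
        cfg = ArenaConfig(touch_threshold_px=25.0)
        out = detect_touching(track, eth, cfg)
        assert out.touching["touching"].all()

    def test_sniffing_suppresses_touching(self):
        track, eth = self._setup(gap_cols=-5, labels=("head_directed", "none"))
        out = detect_touching(track, eth, ArenaConfig())
        assert not out.touching["touching"].any()

    def test_distant_masks_do_not_touch(self):
        track, eth = self._setup(gap_cols=90)
        out = detect_touching(track, eth, ArenaConfig(touch_threshold_px=25.0))
        assert not out.touching["touching"].any()

    def test_touching_is_per_unordered_pair(self):
        track, eth = self._setup(gap_cols=-5)
        out = detect_touching(track, eth, ArenaConfig())
        assert list(out.touching.columns) == ["frame", "animal_a", "animal_b", "touching"]
        assert len(out.touching) == 1


def _etho_from_labels(labels, actor=0, recipient=1):
    rows = [(f, actor, recipient, lab) for f, lab in enumerate(labels)]
    return Ethogram(
        labels=pd.DataFrame(rows, columns=["frame", "actor", "recipient", "label"])
    )


class TestSummarizeEvents:
    def test_run_length_arithmetic(self):
        labels = ["none", "body_directed", "body_directed", "none", "body_directed"]
        table = summarize_events(_etho_from_labels(labels), fps=30.0)
        assert len(table.events) == 2
        assert list(table.events["duration_s"]) == pytest.approx([2 / 30, 1 / 30])
        assert list(table.intervals["interval_s"]) == pytest.approx([1 / 30])

    def test_all_none_gives_empty_table(self):
        table = summarize_events(_etho_from_labels(["none"] * 10), fps=30.0)
        assert len(table.events) == 0 and len(table.intervals) == 0

    def test_single_event_spanning_video_has_no_interval(self):
        table = summarize_events(_etho_from_labels(["head_directed"] * 8), fps=30.0)
        assert len(table.events) == 1
        assert table.events.iloc[0]["duration_s"] == pytest.approx(8 / 30)
        assert len(table.intervals) == 0

    def test_durations_sum_to_labelled_time(self):
        rng = np.random.default_rng(3)
        labels = rng.choice(["none", "body_directed", "head_directed"], size=200)
        table = summarize_events(_etho_from_labels(list(labels)), fps=30.0)
        for behavior in ("body_directed", "head_directed"):
            total = table.events[table.events["behavior"] == behavior]["duration_s"].sum()
            assert total == pytest.approx((labels == behavior).sum() / 30.0)

    def test_touching_events_included(self):
        eth = _etho_from_labels(["none"] * 4)
        eth.touching = pd.DataFrame(
            [(f, 0, 1, f in (1, 2)) for f in range(4)],
            columns=["frame", "animal_a", "animal_b", "touching"],
        )
        table = summarize_events(eth, fps=30.0)
        touch = table.events[table.events["behavior"] == "touching"]
        assert len(touch) == 1 and touch.iloc[0]["duration_s"] == pytest.approx(2 / 30)

    def test_min_event_frames_filters_short_bouts(self):
        labels = ["body_directed", "none", "body_directed", "body_directed"]
        table = summarize_events(_etho_from_labels(labels), fps=30.0, min_event_frames=2)
        assert len(table.events) == 1


class TestLocomotion:
    def test_straight_line_distance(self):
        n = 30
        centers = np.zeros((n, 2, 2))
        centers[:, 0, 0] = 3.0 * np.arange(n)  # 3 px/frame
        centers[:, 1] = [100.0, 100.0]
        kps = KeypointSet.from_arrays(centers + 1.0, centers - 1.0)
        out = locomotion_metrics(kps, fps=30.0, cfg=ArenaConfig())
        assert out.total_distance_px[0] == pytest.approx(87.0)

    def test_stationary_animal(self):
        centers = np.full((60, 2, 2), 50.0)
        kps = KeypointSet.from_arrays(centers + 1.0, centers - 1.0)
        out = locomotion_metrics(kps, fps=30.0, cfg=ArenaConfig())
        assert out.total_distance_px[1] == 0.0
        # 59 inter-frame steps below the stationary speed -> 59/30 s
        assert out.stationary_time_s[1] == pytest.approx(59 / 30)

    def test_identical_velocity_traces_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        n = 300
        steps = rng.uniform(0, 4, size=n - 1)
        path = np.concatenate([[0], np.cumsum(steps)])
        centers = np.zeros((n, 2, 2))
        centers[:, 0, 0] = path
        centers[:, 1, 0] = path + 50.0
        kps = KeypointSet.from_arrays(centers + 1.0, centers - 1.0)
        out = locomotion_metrics(kps, fps=30.0, cfg=ArenaConfig())
        assert out.pair_r == pytest.approx(1.0)

    def test_video_shorter_than_one_bin_has_no_correlation(self):
        centers = np.zeros((10, 2, 2))
        kps = KeypointSet.from_arrays(centers + 1.0, centers - 1.0)
        out = locomotion_metrics(kps, fps=30.0, cfg=ArenaConfig())
        assert out.pair_r is None and out.velocity_bins_px_s.shape[1] == 0


class TestBenchmarkArithmetic:
    def test_f1_is_harmonic_mean(self):
        assert f1_score(0.75, 0.53) == pytest.approx(2 * 0.75 * 0.53 / 1.28)
        assert f1_score(0.0, 0.0) == 0.0
        assert f1_score(1.0, 1.0) == 1.0

    def test_frame_benchmark_counts(self):
        ref = np.array(["head_directed", "none", "body_directed", "head_directed"])
        pred = np.array(["head_directed", "head_directed", "none", "none"])
        out = frame_benchmark(pred, ref).set_index("behavior")
        head = out.loc["head_directed"]
        assert head["precision"] == pytest.approx(0.5)  # 1 TP, 1 FP
        assert head["recall"] == pytest.approx(0.5)  # 1 TP, 1 FN
        assert head["f1"] == pytest.approx(0.5)

    def test_perfect_agreement(self):
        seq = np.array(["head_directed", "anogenital_directed", "body_directed"])
        out = frame_benchmark(seq, seq)
        assert (out["f1"] == 1.0).all()
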