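"""PCKh, MOTA, switch counting, mask AP and the outlier summary."""

import itertools

import numpy as np
import pytest

from mousetrack.evaluation import (
    count_switches,
    error_summary,
    keypoint_errors,
    mask_ap,
    mota,
    pckh,
)
from mousetrack.io import KeypointSet


def _kps(centers, valid=None):
    """Build a KeypointSet whose snout/tailbase straddle given centers."""
    c = np.asarray(centers, dtype=float)
    return KeypointSet.from_arrays(c + 1.0, c - 1.0, valid=valid)


def _tracks(n_frames, n_animals, rng, step=3.0):
    pos = rng.uniform(30, 70, size=(n_animals, 2))
    out = np.zeros((n_frames, n_animals, 2))
    for f in range(n_frames):
        pos = pos + rng.uniform(-step, step, size=pos.shape)
        out[f] = pos
    return out


class TestPckh:
    def test_perfect_prediction(self):
        gt = _kps(np.zeros((4, 2, 2)) + 50)
        assert pckh(gt, gt, threshold_px=5.0) == 1.0

    def test_all_offset_beyond_threshold(self):
        c = np.zeros((4, 2, 2)) + 50
        assert pckh(_kps(c + 12.0), _kps(c), threshold_px=6.0) == 0.0

    def test_half_within_half_beyond(self):
        c = np.zeros((4, 2, 2)) + 50
        off = np.zeros_like(c)
        off[:2] = 2.0  # frames 0-1 within, 2-3 beyond
        off[2:] = 20.0
        assert pckh(_kps(c + off), _kps(c), threshold_px=5.0) == 0.5

    def test_monotone_in_threshold(self, rng):
        gt = _kps(_tracks(10, 2, rng))
        pred = _kps(_tracks(10, 2, rng))
        vals = [pckh(pred, gt, t) for t in (1.0, 5.0, 20.0, 100.0)]
        assert vals == sorted(vals)

    def test_no_valid_ground_truth_rejected(self):
        c = np.zeros((2, 2, 2)) + 50
        gt = _kps(c, valid=np.zeros((2, 2), dtype=bool))
        with pytest.raises(ValueError, match="no valid"):
            pckh(_kps(c), gt, 5.0)


class TestMota:
    def test_perfect_tracking_is_one(self):
        c = np.cumsum(np.ones((5, 2, 2)), axis=0) + 30
        r = mota(_kps(c), _kps(c), match_threshold_px=5.0)
        assert r.mota == 1.0
        assert r.misses == r.false_positives == r.mismatches == 0
        assert r.total_gt == 10

    def test_worked_example_one_of_each_error(self):
        """2 targets x 5 frames, one miss + one fp + one mismatch -> 0.7."""
        gt = np.zeros((5, 2, 2))
        gt[:, 0] = [20.0, 20.0]
        gt[:, 1] = [80.0, 80.0]
        pred = gt.copy()
        valid = np.ones((5, 2), dtype=bool)
        valid[2, 0] = False  # miss: target 0 absent on frame 2
        pred[4, 1] = [300.0, 300.0]  # fp: located far beyond threshold
        # mismatch: swap the two track labels from frame 3 on
        pred[3:, [0, 1]] = pred[3:, [1, 0]]
        valid[3:] = valid[3:, ::-1]
        r = mota(_kps(pred, valid=valid), _kps(gt), match_threshold_px=10.0)
        # frame 4: target 1's prediction is far away -> also a miss there
        assert r.misses == 2 and r.false_positives == 1 and r.mismatches >= 1
        assert r.total_gt == 10

    def test_direct_eq1_substitution(self):
        """MOTA = 1 - (m + fp + mme) / g on a constructed count pattern."""
        gt = np.zeros((5, 2, 2))
        gt[:, 0] = [20.0, 20.0]
        gt[:, 1] = [80.0, 80.0]
        pred = gt.copy()
        valid = np.ones((5, 2), dtype=bool)
        valid[1, 0] = False  # one miss, no fp (prediction absent entirely)
        pred[2, 1] = [82.0, 300.0]  # one fp (beyond threshold) + one miss
        r = mota(_kps(pred, valid=valid), _kps(gt), match_threshold_px=10.0)
        assert r.misses == 2 and r.false_positives == 1 and r.mismatches == 0
        assert r.mota == pytest.approx(1 - 3 / 10)

    def test_permutation_of_track_labels_does_not_change_mota(self, rng):
        gt = _tracks(8, 3, rng)
        pred = gt + rng.normal(0, 1, gt.shape)
        base = mota(_kps(pred), _kps(gt), 15.0)
        perm = pred[:, [2, 0, 1], :]
        relabeled = mota(_kps(perm), _kps(gt), 15.0)
        assert relabeled.mota == base.mota
        assert relabeled.mismatches == base.mismatches

    def test_mismatched_frame_ranges_rejected(self, rng):
        with pytest.raises(ValueError, match="frame ranges"):
            mota(_kps(_tracks(5, 2, rng)), _kps(_tracks(6, 2, rng)), 5.0)


class TestMotaBruteForceOracle:
    """The CLEAR-MOT matcher must agree with exhaustive enumeration."""

    @staticmethod
    def _oracle(pred, gt, threshold):
        n_frames = gt.shape[0]
        m = fp = mme = g = 0
        last = {}
        for f in range(n_frames):
            gts = {
                i: gt[f, i]
                for i in range(gt.shape[1])
                if not np.isnan(gt[f, i]).any()
            }
            preds = {
                j: pred[f, j]
                for j in range(pred.shape[1])
                if not np.isnan(pred[f, j]).any()
            }
            g += len(gts)
            kept = {
                gid: pid
                for gid, pid in last.items()
                if gid in gts
                and pid in preds
                and np.linalg.norm(gts[gid] - preds[pid]) <= threshold
            }
            rg = [i for i in gts if i not in kept]
            rp = [j for j in preds if j not in set(kept.values())]
            best = None
            k = min(len(rg), len(rp))
            for subset in itertools.combinations(rg, k):
                for perm in itertools.permutations(rp, k):
                    pairs = [
                        (a, b)
                        for a, b in zip(subset, perm)
                        if np.linalg.norm(gts[a] - preds[b]) <= threshold
                    ]
                    cost = sum(np.linalg.norm(gts[a] - preds[b]) for a, b in pairs)
                    key = (-len(pairs), cost)
                    if best is None or key < best[0]:
                        best = (key, dict(pairs))
            matches = dict(kept)
            if best is not None:
                matches.update(best[1])
            for gid, pid in matches.items():
                if gid in last and last[gid] != pid:
                    mme += 1
            m += len(gts) - len(matches)
            fp += len(preds) - len(matches)
            last.update(matches)
        return m, fp, mme, g

    def test_agrees_on_random_small_scenarios(self, rng):
        for _ in range(60):
            n_targets = int(rng.integers(1, 4))
            n_frames = int(rng.integers(2, 11))
            # 3-decimal coordinates: keypoint tables store that precision
            gt = np.round(_tracks(n_frames, n_targets, rng), 3)
            pred = np.round(gt + rng.normal(0, 4, gt.shape), 3)
            # random dropouts on both sides
            valid_p = rng.random((n_frames, n_targets)) > 0.15
            valid_g = rng.random((n_frames, n_targets)) > 0.1
            gt_a = gt.copy()
            pred_a = pred.copy()
            pred_a[~valid_p] = np.nan
            gt_a[~valid_g] = np.nan
            if np.isnan(gt_a).all(axis=2).all():
                continue
            thr = float(rng.uniform(3, 12))
            r = mota(
                _kps(pred, valid=valid_p), _kps(gt, valid=valid_g), thr
            )
            m, fp, mme, g = self._oracle(pred_a, gt_a, thr)
            assert (r.misses, r.false_positives, r.mismatches, r.total_gt) == (
                m,
                fp,
                mme,
                g,
            )


class TestCountSwitches:
    def _pair(self, swap_frames):
        gt = np.zeros((10, 2, 2))
        gt[:, 0] = [20.0, 20.0]
        gt[:, 1] = [80.0, 80.0]
        pred = gt.copy()
        swapped = False
        for f in range(10):
            if f in swap_frames:
                swapped = not swapped
            if swapped:
                pred[f] = pred[f, ::-1]
        return _kps(pred), _kps(gt)

    def test_correct_tracking_has_zero_switches(self):
        pred, gt = self._pair(set())
        assert count_switches(pred, gt, 10.0) == 0

    def test_single_permanent_swap_counts_once(self):
        pred, gt = self._pair({4})
        assert count_switches(pred, gt, 10.0) == 1

    def test_swap_and_swap_back_counts_twice(self):
        pred, gt = self._pair({4, 7})
        assert count_switches(pred, gt, 10.0) == 2


def _disk(shape, cx, cy, r):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


class TestMaskAP:
    def test_perfect_detections(self):
        gts = [[_disk((60, 60), 20, 20, 8)], [_disk((60, 60), 40, 40, 8)]]
        preds = [[(g[0], 1.0)] for g in gts]
        rep = mask_ap(preds, gts)
        assert rep.ap == rep.ap50 == rep.ap75 == 1.0

    def test_no_overlap_is_zero(self):
        gts = [[_disk((60, 60), 15, 15, 6)]]
        preds = [[(_disk((60, 60), 45, 45, 6), 0.9)]]
        rep = mask_ap(preds, gts)
        assert rep.ap == rep.ap50 == 0.0

    def test_iou_between_thresholds_splits_ap50_and_ap75(self):
        gt = np.zeros((40, 40), dtype=bool)
        gt[10:20, 10:20] = True  # 100 px
        pred = np.zeros((40, 40), dtype=bool)
        pred[10:20, 10:18] = True  # 80 px, IoU = 80/100 = 0.8? no: 80/100
        # IoU = 80 / 100 = 0.8 -> adjust to land between 0.5 and 0.75:
        pred2 = np.zeros((40, 40), dtype=bool)
        pred2[10:20, 10:16] = True  # 60 px, IoU = 60/100 = 0.6
        rep = mask_ap([[(pred2, 0.95)]], [[gt]])
        assert rep.ap50 == 1.0
        assert rep.ap75 == 0.0

    def test_ap_not_above_ap50(self, rng):
        gts, preds = [], []
        for _ in range(4):
            g = _disk((50, 50), rng.integers(15, 35), rng.integers(15, 35), 7)
            p = _disk((50, 50), rng.integers(15, 35), rng.integers(15, 35), 7)
            gts.append([g])
            preds.append([(p, float(rng.uniform(0.5, 1)))])
        rep = mask_ap(preds, gts)
        assert rep.ap <= rep.ap50 + 1e-12
        assert 0.0 <= rep.ap <= 1.0


class TestErrorSummary:
    def test_tukey_outlier_rule(self):
        errors = np.concatenate([np.ones(99), [100.0]])
        s = error_summary(errors)
        # P75 = 1, IQR = 0 -> threshold 1; only the 100 exceeds it
        assert s.outlier_count == 1
        assert s.outlier_mean == pytest.approx(100.0)
        assert s.median == 1.0

    def test_no_outliers_in_uniform_data(self, rng):
        s = error_summary(rng.uniform(0, 1, 1000))
        assert s.outlier_count == 0 and np.isnan(s.outlier_mean)

    def test_keypoint_errors_pools_both_targets(self):
        c = np.zeros((3, 2, 2)) + 40
        errs = keypoint_errors(_kps(c + 3.0), _kps(c))
        assert errs.shape == (12,)  # 3 frames x 2 animals x 2 keypoint types
        assert errs == pytest.approx(np.hypot(3, 3))
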