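"""Tracking and segmentation evaluation.

* PCKh: fraction of keypoints within a fixed pixel threshold of the
  annotated location (the threshold is calibrated externally as half the
  average head length and supplied via the config).
* MOTA: multi-object tracking accuracy, ``1 - (sum of misses, false
  positives and mismatches) / (total ground-truth targets)``, computed
  with the CLEAR-MOT matching convention: matches from the previous frame
  are kept while still within the distance threshold, remaining targets
  are matched by distance-minimising assignment, and a ground-truth
  target whose matched track changes counts as one mismatch.  The snout,
  the tail-base and the center point (midpoint of snout and tail-base)
  are evaluated as independent target types.
* Identity switches: frames at which the prediction-to-ground-truth
  correspondence of the center points changes.
* Mask AP: COCO-style average precision of instance masks over IoU
  thresholds 0.50 to 0.95 in steps of 0.05 (AP50/AP75 at the fixed
  thresholds), with all-points PR interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io import KeypointSet
from .tracking import IdentityTrack, compute_iou

__all__ = [
    "MotaResult",
    "TrackEvalReport",
    "APReport",
    "ErrorSummary",
    "pckh",
    "mota",
    "count_switches",
    "mask_ap",
    "error_summary",
    "keypoint_errors",
    "evaluate_tracking",
]

_BIG = 1e12
AP_THRESHOLDS = np.arange(0.50, 0.951, 0.05)


# ---------------------------------------------------------------------------
# PCKh


def _points(kps: KeypointSet | np.ndarray, target: str) -> np.ndarray:
    if isinstance(kps, np.ndarray):
        return kps
    if target == "center":
        return kps.centers()
    return kps.coords(target)


def pckh(
    pred: KeypointSet, gt: KeypointSet, threshold_px: float, targets=("snout", "tailbase")
) -> float:
    """Fraction of keypoints within threshold of the ground truth.

    Computed over valid ground-truth entries; an invalid prediction for a
    valid ground-truth entry counts as incorrect.
    """
    if threshold_px <= 0:
        raise ValueError("threshold_px must be positive")
    total = correct = 0
    for target in targets:
        p = _points(pred, target)
        g = _points(gt, target)
        n = min(p.shape[0], g.shape[0])
        p, g = p[:n], g[:n]
        valid_gt = ~np.isnan(g).any(axis=2)
        err = np.linalg.norm(p - g, axis=2)
        total += int(valid_gt.sum())
        correct += int(np.sum(valid_gt & (err < threshold_px)))
    if total == 0:
        raise ValueError("no valid ground-truth keypoints to evaluate")
    return correct / total


def keypoint_errors(
    pred: KeypointSet, gt: KeypointSet, targets=("snout", "tailbase")
) -> np.ndarray:
    """Pooled Euclidean errors over valid (pred, gt) pairs."""
    errs = []
    for target in targets:
        p = _points(pred, target)
        g = _points(gt, target)
        n = min(p.shape[0], g.shape[0])
        e = np.linalg.norm(p[:n] - g[:n], axis=2).ravel()
        errs.append(e[~np.isnan(e)])
    return np.concatenate(errs) if errs else np.array([])


# ---------------------------------------------------------------------------
# CLEAR-MOT


@dataclass
class MotaResult:
    mota: float
    misses: int
    false_positives: int
    mismatches: int
    total_gt: int
    per_frame: dict = field(default_factory=dict)  # m_n, fp_n, mme_n, g_n arrays


def _frame_points(arr: np.ndarray, f: int) -> dict[int, np.ndarray]:
    out = {}
    for i in range(arr.shape[1]):
        p = arr[f, i]
        if not np.isnan(p).any():
            out[i] = p
    return out


def _threshold_assignment(
    gts: dict[int, np.ndarray], preds: dict[int, np.ndarray], threshold: float
) -> dict[int, int]:
    """Distance-minimising matching; pairs beyond threshold are forbidden.

    Maximises the number of feasible matches, then minimises total
    distance (guaranteed by the large forbidden-pair cost).
    """
    if not gts or not preds:
        return {}
    g_ids, p_ids = list(gts), list(preds)
    cost = np.full((len(g_ids), len(p_ids)), _BIG)
    for a, gid in enumerate(g_ids):
        for b, pid in enumerate(p_ids):
            d = float(np.linalg.norm(gts[gid] - preds[pid]))
            if d <= threshold:
                cost[a, b] = d
    rows, cols = linear_sum_assignment(cost)
    return {
        g_ids[a]: p_ids[b] for a, b in zip(rows, cols) if cost[a, b] < _BIG
    }


def mota(
    pred: KeypointSet,
    gt: KeypointSet,
    match_threshold_px: float,
    target: str = "center",
) -> MotaResult:
    """Multi-object tracking accuracy for one target type."""
    p_arr = _points(pred, target)
    g_arr = _points(gt, target)
    if p_arr.shape[0] != g_arr.shape[0]:
        raise ValueError(
            f"frame ranges differ: pred {p_arr.shape[0]} vs gt {g_arr.shape[0]}"
        )
    n_frames = g_arr.shape[0]
    m_n = np.zeros(n_frames, dtype=int)
    fp_n = np.zeros(n_frames, dtype=int)
    mme_n = np.zeros(n_frames, dtype=int)
    g_n = np.zeros(n_frames, dtype=int)
    last_match: dict[int, int] = {}
    for f in range(n_frames):
        gts = _frame_points(g_arr, f)
        preds = _frame_points(p_arr, f)
        g_n[f] = len(gts)
        matches: dict[int, int] = {}
        # keep surviving matches from the previous frame
        for gid, pid in last_match.items():
            if gid in gts and pid in preds:
                if np.linalg.norm(gts[gid] - preds[pid]) <= match_threshold_px:
                    matches[gid] = pid
        rem_g = {k: v for k, v in gts.items() if k not in matches}
        used = set(matches.values())
        rem_p = {k: v for k, v in preds.items() if k not in used}
        matches.update(_threshold_assignment(rem_g, rem_p, match_threshold_px))
        for gid, pid in matches.items():
            if gid in last_match and last_match[gid] != pid:
                mme_n[f] += 1
        m_n[f] = len(gts) - len(matches)
        fp_n[f] = len(preds) - len(matches)
        last_match.update(matches)
    total_gt = int(g_n.sum())
    if total_gt == 0:
        raise ValueError("no ground-truth targets")
    value = 1.0 - (m_n.sum() + fp_n.sum() + mme_n.sum()) / total_gt
    return MotaResult(
        mota=float(value),
        misses=int(m_n.sum()),
        false_positives=int(fp_n.sum()),
        mismatches=int(mme_n.sum()),
        total_gt=total_gt,
        per_frame={"m_n": m_n, "fp_n": fp_n, "mme_n": mme_n, "g_n": g_n},
    )


def count_switches(
    pred: KeypointSet | IdentityTrack | np.ndarray,
    gt: KeypointSet | np.ndarray,
    match_threshold_px: float,
) -> int:
    """Frames at which the center-point identity correspondence changes."""
    if isinstance(pred, IdentityTrack):
        p_arr = pred.centroids
    else:
        p_arr = _points(pred, "center")
    g_arr = _points(gt, "center")
    n_frames = min(p_arr.shape[0], g_arr.shape[0])
    switches = 0
    prev: dict[int, int] | None = None
    for f in range(n_frames):
        gts = _frame_points(g_arr, f)
        preds = _frame_points(p_arr, f)
        corr = _threshold_assignment(gts, preds, match_threshold_px)
        if prev is not None:
            common = set(corr) & set(prev)
            if any(corr[g] != prev[g] for g in common):
                switches += 1
        if corr:
            prev = corr
    return switches


# ---------------------------------------------------------------------------
# mask AP


@dataclass
class APReport:
    ap: float
    ap50: float
    ap75: float
    per_threshold: dict = field(default_factory=dict)


def _ap_at(
    dets: list[tuple[float, int, np.ndarray]],
    gt_masks: list[list[np.ndarray]],
    tau: float,
) -> tuple[float, np.ndarray, np.ndarray]:
    n_gt = sum(len(g) for g in gt_masks)
    if n_gt == 0:
        return 0.0, np.array([]), np.array([])
    matched: list[set[int]] = [set() for _ in gt_masks]
    tp = np.zeros(len(dets))
    for k, (_, img, mask) in enumerate(dets):
        best_iou, best_j = 0.0, -1
        for j, g in enumerate(gt_masks[img]):
            if j in matched[img]:
                continue
            iou = compute_iou(mask, g)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou >= tau:
            tp[k] = 1
            matched[img].add(best_j)
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1 - tp)
    recall = cum_tp / n_gt
    precision = cum_tp / np.maximum(cum_tp + cum_fp, 1)
    # all-points interpolation: monotone precision envelope
    env = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = 0.0
    ap = 0.0
    for r, p in zip(recall, env):
        ap += (r - r_prev) * p
        r_prev = r
    return float(ap), precision, recall


def mask_ap(pred_per_image, gt_per_image) -> APReport:
    """COCO-style mask average precision.

    ``pred_per_image``: per image, a list of detections — either
    ``Detection`` objects or ``(mask, confidence)`` pairs.
    ``gt_per_image``: per image, a list of ground-truth masks.
    """
    dets: list[tuple[float, int, np.ndarray]] = []
    for img, frame_dets in enumerate(pred_per_image):
        for d in frame_dets:
            if hasattr(d, "mask"):
                dets.append((float(d.confidence), img, d.mask))
            else:
                mask, conf = d
                dets.append((float(conf), img, np.asarray(mask, dtype=bool)))
    dets.sort(key=lambda t: -t[0])
    gt_masks = [[np.asarray(m, dtype=bool) for m in g] for g in gt_per_image]
    per = {}
    aps = []
    for tau in AP_THRESHOLDS:
        ap_tau, precision, recall = _ap_at(dets, gt_masks, tau)
        per[round(float(tau), 2)] = {
            "ap": ap_tau,
            "precision": precision,
            "recall": recall,
        }
        aps.append(ap_tau)
    return APReport(
        ap=float(np.mean(aps)),
        ap50=per[0.5]["ap"],
        ap75=per[0.75]["ap"],
        per_threshold=per,
    )


# ---------------------------------------------------------------------------
# error distributions (Tukey outlier rule)


@dataclass
class ErrorSummary:
    n: int
    mean: float
    median: float
    outlier_threshold: float  # 75th percentile + 1.5 * IQR
    outlier_count: int
    outlier_mean: float  # NaN when there are no outliers


def error_summary(errors: np.ndarray) -> ErrorSummary:
    """Mean/median errors and outliers (> P75 + 1.5 * IQR)."""
    errors = np.asarray(errors, dtype=float)
    errors = errors[~np.isnan(errors)]
    if errors.size == 0:
        raise ValueError("no errors to summarise")
    q25, q75 = np.percentile(errors, [25, 75])
    thr = q75 + 1.5 * (q75 - q25)
    outliers = errors[errors > thr]
    return ErrorSummary(
        n=int(errors.size),
        mean=float(errors.mean()),
        median=float(np.median(errors)),
        outlier_threshold=float(thr),
        outlier_count=int(outliers.size),
        outlier_mean=float(outliers.mean()) if outliers.size else float("nan"),
    )


# ---------------------------------------------------------------------------
# combined report


@dataclass
class TrackEvalReport:
    per_target: dict[str, MotaResult]
    switches: int
    pckh_fraction: float
    errors: ErrorSummary

    def to_dict(self) -> dict:
        return {
            "mota": {t: r.mota for t, r in self.per_target.items()},
            "misses": {t: r.misses for t, r in self.per_target.items()},
            "false_positives": {
                t: r.false_positives for t, r in self.per_target.items()
            },
            "mismatches": {t: r.mismatches for t, r in self.per_target.items()},
            "total_gt": {t: r.total_gt for t, r in self.per_target.items()},
            "switches": self.switches,
            "pckh": self.pckh_fraction,
            "error_mean": self.errors.mean,
            "error_median": self.errors.median,
            "outlier_count": self.errors.outlier_count,
            "outlier_mean": self.errors.outlier_mean,
        }


def evaluate_tracking(
    pred: KeypointSet, gt: KeypointSet, threshold_px: float
) -> TrackEvalReport:
    """Full report: MOTA per target, switches, PCKh, error distribution."""
    per_target = {
        t: mota(pred, gt, threshold_px, target=t)
        for t in ("snout", "tailbase", "center")
    }
    return TrackEvalReport(
        per_target=per_target,
        switches=count_switches(pred, gt, threshold_px),
        pckh_fraction=pckh(pred, gt, threshold_px),
        errors=error_summary(keypoint_errors(pred, gt)),
    )
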