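"""Social-behavior quantification from masks and keypoints.

Sniffing classification is a distance-thresholding rule evaluated per
frame for every ordered (actor, recipient) pair: with threshold ``t``
(default 25 px), the frame is labelled ``head_directed`` when the
actor's snout is within ``t`` of the recipient's snout, else
``anogenital_directed`` when within ``t`` of the recipient's tail-base,
else ``body_directed`` when within ``t`` of the recipient's body mask,
else ``none``.  The precedence (head > anogenital > body) makes the
labelling single-valued: a snout close to the recipient's snout is
necessarily close to its mask too.

Touching is scored per unordered pair on frames where the shortest
distance between the two body masks is below a threshold and neither
direction of the pair carries a sniffing label — i.e. contact that is
not snout-directed investigation.

Locomotion uses the animal center (midpoint of snout and tail-base):
total path length, time stationary, per-second velocity bins, and the
Pearson correlation between the two animals' binned velocities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

from .io import ArenaConfig, KeypointSet
from .tracking import IdentityTrack

__all__ = [
    "SNIFF_LABELS",
    "Ethogram",
    "EventTable",
    "LocomotionSummary",
    "classify_sniffing",
    "detect_touching",
    "summarize_events",
    "locomotion_metrics",
    "f1_score",
    "frame_benchmark",
]

SNIFF_LABELS = ("head_directed", "anogenital_directed", "body_directed", "none")


@dataclass
class Ethogram:
    """Per-frame behavior labels.

    ``labels``: DataFrame (frame, actor, recipient, label) with exactly
    one row per frame and ordered pair.  ``touching``: DataFrame (frame,
    animal_a, animal_b, touching) per unordered pair, a < b.
    """

    labels: pd.DataFrame
    touching: pd.DataFrame | None = None

    def label_series(self, actor: int, recipient: int) -> np.ndarray:
        sel = self.labels[
            (self.labels["actor"] == actor) & (self.labels["recipient"] == recipient)
        ].sort_values("frame")
        return sel["label"].to_numpy()

    def to_csv(self, path) -> None:
        df = self.labels.copy()
        if self.touching is not None:
            touch = self.touching.rename(
                columns={"animal_a": "actor", "animal_b": "recipient"}
            )
            df = df.merge(
                touch, on=["frame", "actor", "recipient"], how="left"
            )
            df["touching"] = df["touching"].notna() & df["touching"].eq(True)
        df.to_csv(path, index=False)


@dataclass
class EventTable:
    """Behavior bouts: maximal same-label runs with onsets and durations."""

    events: pd.DataFrame  # behavior, actor, recipient, onset, offset, duration_s
    intervals: pd.DataFrame  # behavior, actor, recipient, interval_s

    def summary(self) -> pd.DataFrame:
        if len(self.events) == 0:
            return pd.DataFrame(
                columns=["behavior", "actor", "recipient", "n_events",
                         "mean_duration_s", "mean_interval_s"]
            )
        g = self.events.groupby(["behavior", "actor", "recipient"])
        out = g.agg(
            n_events=("duration_s", "size"), mean_duration_s=("duration_s", "mean")
        ).reset_index()
        if len(self.intervals):
            gi = (
                self.intervals.groupby(["behavior", "actor", "recipient"])["interval_s"]
                .mean()
                .reset_index()
                .rename(columns={"interval_s": "mean_interval_s"})
            )
            out = out.merge(gi, on=["behavior", "actor", "recipient"], how="left")
        else:
            out["mean_interval_s"] = np.nan
        return out


@dataclass
class LocomotionSummary:
    total_distance_px: np.ndarray  # per animal
    stationary_time_s: np.ndarray  # per animal
    velocity_bins_px_s: np.ndarray  # (n_animals, n_bins)
    pair_r: float | None
    pair_p: float | None


def _min_dist_to_mask(point: np.ndarray, mask: np.ndarray, tree: cKDTree) -> float:
    """Exact minimum distance from a point to the mask's pixel set."""
    x, y = point
    c, r = int(round(x)), int(round(y))
    h, w = mask.shape
    if 0 <= r < h and 0 <= c < w and mask[r, c]:
        return 0.0
    return float(tree.query(point)[0])


def _boundary_tree(mask: np.ndarray) -> cKDTree:
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3), dtype=bool))
    ys, xs = np.nonzero(mask & ~eroded)
    return cKDTree(np.column_stack([xs, ys]).astype(float))


def classify_sniffing(
    kps: KeypointSet, track: IdentityTrack, cfg: ArenaConfig
) -> Ethogram:
    """Label every (frame, actor, recipient) with a sniffing state."""
    n_frames, n_animals = track.n_frames, track.n_animals
    snout = kps.coords("snout")
    tailb = kps.coords("tailbase")
    if snout.shape[0] < n_frames:
        raise ValueError("keypoint set does not cover every tracked frame")
    if np.isnan(snout[:n_frames]).any() or np.isnan(tailb[:n_frames]).any():
        bad = np.argwhere(np.isnan(snout[:n_frames]).any(axis=2))
        raise ValueError(f"missing keypoint record at (frame, animal) {bad[0]}")
    t = cfg.sniff_threshold_px
    rows = []
    for f in range(n_frames):
        trees = [_boundary_tree(track.masks[f][i]) for i in range(n_animals)]
        for a in range(n_animals):
            for r in range(n_animals):
                if a == r:
                    continue
                s = snout[f, a]
                if np.linalg.norm(s - snout[f, r]) < t:
                    label = "head_directed"
                elif np.linalg.norm(s - tailb[f, r]) < t:
                    label = "anogenital_directed"
                elif _min_dist_to_mask(s, track.masks[f][r], trees[r]) < t:
                    label = "body_directed"
                else:
                    label = "none"
                rows.append((f, a, r, label))
    labels = pd.DataFrame(rows, columns=["frame", "actor", "recipient", "label"])
    return Ethogram(labels=labels)


def mask_pair_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Shortest distance between two masks (0 when they overlap)."""
    if np.any(a & b):
        return 0.0
    ta = _boundary_tree(a)
    eroded = ndimage.binary_erosion(b, structure=np.ones((3, 3), dtype=bool))
    ys, xs = np.nonzero(b & ~eroded)
    pts = np.column_stack([xs, ys]).astype(float)
    if len(pts) == 0 or ta.n == 0:
        return np.inf
    return float(ta.query(pts)[0].min())


def detect_touching(
    track: IdentityTrack, ethogram: Ethogram, cfg: ArenaConfig
) -> Ethogram:
    """Fill the touching flag: mask contact that is not sniffing.

    A pair touches on a frame when the shortest distance between their
    masks is below ``touch_threshold_px`` and neither animal of the pair
    carries a sniffing label toward the other on that frame.
    """
    n_frames, n_animals = track.n_frames, track.n_animals
    lab = ethogram.labels.set_index(["frame", "actor", "recipient"])["label"]
    rows = []
    for f in range(n_frames):
        for a in range(n_animals):
            for b in range(a + 1, n_animals):
                sniffing = (
                    lab.get((f, a, b), "none") != "none"
                    or lab.get((f, b, a), "none") != "none"
                )
                touch = False
                if not sniffing:
                    d = mask_pair_distance(track.masks[f][a], track.masks[f][b])
                    touch = d < cfg.touch_threshold_px
                rows.append((f, a, b, touch))
    touching = pd.DataFrame(rows, columns=["frame", "animal_a", "animal_b", "touching"])
    return Ethogram(labels=ethogram.labels, touching=touching)


def _runs(values: np.ndarray) -> list[tuple[int, int, object]]:
    """Maximal runs of equal values as (start, end_inclusive, value)."""
    out = []
    start = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[start]:
            out.append((start, i - 1, values[start]))
            start = i
    return out


def summarize_events(
    ethogram: Ethogram,
    fps: float,
    min_event_frames: int = 0,
    merge_gap_frames: int = 0,
) -> EventTable:
    """Turn per-frame labels into bouts with durations and intervals.

    An event is a maximal run of consecutive frames carrying the same
    (non-none) label; by default there is no minimum duration and no gap
    merging.  The inter-event interval is the gap, in seconds, between
    consecutive events of the same behavior for the same pair.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    ev_rows, iv_rows = [], []

    def emit(series: np.ndarray, frames: np.ndarray, behavior_of, actor, recipient):
        runs = [r for r in _runs(series) if behavior_of(r[2]) is not None]
        if merge_gap_frames > 0:
            merged = []
            for run in runs:
                if (
                    merged
                    and behavior_of(run[2]) == behavior_of(merged[-1][2])
                    and frames[run[0]] - frames[merged[-1][1]] - 1 <= merge_gap_frames
                ):
                    merged[-1] = (merged[-1][0], run[1], run[2])
                else:
                    merged.append(list(run) if isinstance(run, list) else run)
            runs = merged
        last_end: dict[str, int] = {}
        for start, end, value in runs:
            n = end - start + 1
            if n < min_event_frames:
                continue
            behavior = behavior_of(value)
            ev_rows.append(
                (
                    behavior,
                    actor,
                    recipient,
                    int(frames[start]),
                    int(frames[end]),
                    n / fps,
                )
            )
            if behavior in last_end:
                iv_rows.append(
                    (behavior, actor, recipient,
                     (frames[start] - last_end[behavior] - 1) / fps)
                )
            last_end[behavior] = frames[end]

    for (a, r), grp in ethogram.labels.groupby(["actor", "recipient"]):
        grp = grp.sort_values("frame")
        emit(
            grp["label"].to_numpy(),
            grp["frame"].to_numpy(),
            lambda v: v if v != "none" else None,
            int(a),
            int(r),
        )
    if ethogram.touching is not None:
        for (a, b), grp in ethogram.touching.groupby(["animal_a", "animal_b"]):
            grp = grp.sort_values("frame")
            emit(
                grp["touching"].to_numpy(),
                grp["frame"].to_numpy(),
                lambda v: "touching" if v else None,
                int(a),
                int(b),
            )
    events = pd.DataFrame(
        ev_rows,
        columns=["behavior", "actor", "recipient", "onset", "offset", "duration_s"],
    )
    intervals = pd.DataFrame(
        iv_rows, columns=["behavior", "actor", "recipient", "interval_s"]
    )
    return EventTable(events=events, intervals=intervals)


def locomotion_metrics(
    kps: KeypointSet, fps: float, cfg: ArenaConfig
) -> LocomotionSummary:
    """Distance traveled, stationary time, 1-s velocity bins, pair r."""
    if fps <= 0:
        raise ValueError("fps must be positive")
    centers = kps.centers()  # (n_frames, n_animals, 2)
    n_frames, n_animals = centers.shape[:2]
    disp = np.linalg.norm(np.diff(centers, axis=0), axis=2)  # (n_frames-1, n_animals)
    total = disp.sum(axis=0)
    speed = disp * fps  # instantaneous px/s between frames k and k+1
    stationary = (speed < cfg.stationary_speed_px_s).sum(axis=0) / fps
    n_bins = int(np.floor((n_frames - 1) / fps))
    vel = np.zeros((n_animals, n_bins))
    for b in range(n_bins):
        lo, hi = int(round(b * fps)), int(round((b + 1) * fps))
        vel[:, b] = disp[lo:hi].sum(axis=0)  # px per 1-s bin == px/s
    pair_r = pair_p = None
    if n_animals >= 2 and n_bins >= 2:
        with np.errstate(invalid="ignore"):
            r, p = pearsonr(vel[0], vel[1])
        if np.isfinite(r):
            pair_r, pair_p = float(r), float(p)
    return LocomotionSummary(
        total_distance_px=total,
        stationary_time_s=stationary,
        velocity_bins_px_s=vel,
        pair_r=pair_r,
        pair_p=pair_p,
    )


# ---------------------------------------------------------------------------
# benchmark arithmetic (precision / recall / F1 against a reference labeling)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def frame_benchmark(
    pred: np.ndarray, ref: np.ndarray, behaviors: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Per-behavior frame-level precision, recall and F1.

    ``pred`` and ``ref`` are aligned per-frame label sequences; the
    reference is treated as ground truth.
    """
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape:
        raise ValueError("label sequences differ in length")
    if behaviors is None:
        behaviors = tuple(
            b for b in SNIFF_LABELS if b != "none"
        )
    rows = []
    for b in behaviors:
        tp = int(np.sum((pred == b) & (ref == b)))
        fp = int(np.sum((pred == b) & (ref != b)))
        fn = int(np.sum((pred != b) & (ref == b)))
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        rows.append((b, precision, recall, f1_score(precision, recall)))
    return pd.DataFrame(rows, columns=["behavior", "precision", "recall", "f1"])
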