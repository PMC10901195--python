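"""Identity tracking by IoU mask stitching.

Individual trajectories are inferred by stitching, frame to frame, the
masks with the most overlapped area.  For two animals the decision rule
is, with ``prev_i`` the mask held by identity ``i`` on the previous frame
and ``M1, M2`` the current frame's masks::

    d1 = IoU(prev_1, M1) - IoU(prev_1, M2)
    d2 = IoU(prev_2, M1) - IoU(prev_2, M2)
    if |d1| > |d2|:
        d1 > 0  ->  ID1<-M1, ID2<-M2   else  ID1<-M2, ID2<-M1
    else:
        d2 > 0  ->  ID1<-M2, ID2<-M1   else  ID1<-M1, ID2<-M2

The else-else default (no informative overlap at all) keeps the input
order.  For more than two animals the identity permutation maximising the
total IoU against the previous frame is used (Hungarian assignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .bgseg import ForegroundResult
from .instseg import Detection, InstanceSegmentationResult

__all__ = [
    "IdentityTrack",
    "compute_iou",
    "assign_identities",
    "merge_conventional_and_backend",
]


def compute_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary masks (0 when both empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    inter = np.count_nonzero(a & b)
    union = np.count_nonzero(a) + np.count_nonzero(b) - inter
    if union == 0:
        return 0.0
    return inter / union


@dataclass
class IdentityTrack:
    """Per-frame identity -> mask assignment with centroids and areas.

    ``masks[n][i]`` is the mask of identity ``i`` at frame ``n``;
    ``centroids`` has shape (n_frames, n_animals, 2) in (x, y);
    ``sources[n][i]`` records where the mask came from.
    """

    masks: list[list[np.ndarray]] = field(default_factory=list)
    centroids: np.ndarray | None = None
    areas: np.ndarray | None = None
    sources: list[list[str]] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.masks)

    @property
    def n_animals(self) -> int:
        return len(self.masks[0]) if self.masks else 0


def _centroid(mask: np.ndarray) -> tuple[float, float]:
    ys, xs = np.nonzero(mask)
    return float(xs.mean()), float(ys.mean())


def _initial_order(dets: list[Detection]) -> list[int]:
    """First-frame identity rule: identity 0 = smallest centroid x (ties: y)."""
    cents = [_centroid(d.mask) for d in dets]
    return sorted(range(len(dets)), key=lambda i: (cents[i][0], cents[i][1]))


def _assign_two(prev: list[np.ndarray], dets: list[Detection]) -> list[int]:
    """The two-animal stitching rule; returns mask index per identity."""
    m1, m2 = dets[0].mask, dets[1].mask
    d1 = compute_iou(prev[0], m1) - compute_iou(prev[0], m2)
    d2 = compute_iou(prev[1], m1) - compute_iou(prev[1], m2)
    if abs(d1) > abs(d2):
        return [0, 1] if d1 > 0 else [1, 0]
    return [1, 0] if d2 > 0 else [0, 1]


def _assign_many(prev: list[np.ndarray], dets: list[Detection]) -> list[int]:
    """Permutation maximising total IoU with the previous frame's masks."""
    k = len(prev)
    cost = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            cost[i, j] = -compute_iou(prev[i], dets[j].mask)
    rows, cols = linear_sum_assignment(cost)
    out = [0] * k
    for i, j in zip(rows, cols):
        out[i] = int(j)
    return out


def assign_identities(
    seg: InstanceSegmentationResult, n_animals: int
) -> IdentityTrack:
    """Assign stable identities to every frame's masks.

    Requires the gap-filled stream: every frame must hold exactly
    ``n_animals`` detections.
    """
    n = seg.n_frames
    if n == 0:
        raise ValueError("empty segmentation result")
    track = IdentityTrack()
    centroids = np.zeros((n, n_animals, 2))
    areas = np.zeros((n, n_animals), dtype=int)
    prev: list[np.ndarray] | None = None
    for f in range(n):
        dets = seg.detections[f]
        if dets is None or len(dets) != n_animals:
            got = 0 if dets is None else len(dets)
            raise ValueError(
                f"frame {f} has {got} masks, expected {n_animals}"
            )
        if prev is None:
            order = _initial_order(dets)
        elif n_animals == 2:
            order = _assign_two(prev, dets)
        else:
            order = _assign_many(prev, dets)
        frame_masks = [dets[j].mask for j in order]
        track.masks.append(frame_masks)
        track.sources.append([dets[j].source for j in order])
        for i, m in enumerate(frame_masks):
            centroids[f, i] = _centroid(m)
            areas[f, i] = np.count_nonzero(m)
        prev = frame_masks
    track.centroids = centroids
    track.areas = areas
    return track


def merge_conventional_and_backend(
    fg: ForegroundResult | None, seg: InstanceSegmentationResult
) -> InstanceSegmentationResult:
    """Combine the conventional pass-through and backend streams.

    Conventional pass-through frames are injected as confidence-1.0
    detections; every other frame must be covered by the backend stream.
    The per-frame failed flags of the backend stream are preserved so the
    merged stream is ready for gap-filling.
    """
    n = seg.n_frames if fg is None or not fg.frames else len(fg.frames)
    if seg.n_frames and fg is not None and fg.frames and seg.n_frames != n:
        raise ValueError("conventional and backend streams cover different lengths")
    out = InstanceSegmentationResult(detections=[None] * n, failed=[False] * n)
    for f in range(n):
        conv = (
            fg.frames[f]
            if fg is not None and fg.enabled and f < len(fg.frames)
            else None
        )
        if conv is not None and conv.pass_through:
            out.detections[f] = [
                Detection(mask=m, confidence=1.0, source="conventional")
                for m in conv.masks
            ]
            out.failed[f] = False
        elif f < seg.n_frames and seg.detections[f] is not None:
            out.detections[f] = seg.detections[f]
            out.failed[f] = seg.failed[f]
        else:
            raise ValueError(f"frame {f} covered by neither segmentation source")
    return out
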