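"""Pluggable instance segmentation with failure filtering and gap-filling.

Frames the conventional stage could not separate are handed to a
``SegmentationBackend`` (in production a CNN instance segmenter; in tests
an oracle replaying simulated ground truth).  Each frame's detections are
then screened by the failure filter: a frame fails when fewer than
``n_animals`` detections remain, when any kept confidence is below
``conf_min`` (default 0.9), or when any kept mask area is below
``area_frac_min`` (default 0.2, i.e. 20%) of the largest kept area.
Failed frames are repaired by copying the masks of the temporally closest
successfully segmented frame (ties resolved toward the earlier frame).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ArenaConfig

__all__ = [
    "Detection",
    "InstanceSegmentationResult",
    "SegmentationBackend",
    "OracleBackend",
    "filter_detections",
    "fill_failed_frames",
]


@dataclass
class Detection:
    mask: np.ndarray  # H x W bool
    confidence: float = 1.0
    source: str = "backend"  # 'conventional' | 'backend' | 'gapfill'

    @property
    def area(self) -> int:
        return int(np.count_nonzero(self.mask))


@dataclass
class InstanceSegmentationResult:
    """Per-frame detections plus a per-frame failed flag.

    ``detections[i]`` may be ``None`` for frames not covered by this
    source (used before merging the conventional and backend streams).
    """

    detections: list[list[Detection] | None] = field(default_factory=list)
    failed: list[bool] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.detections)

    @property
    def failure_fraction(self) -> float:
        flags = np.asarray(self.failed, dtype=bool)
        return float(flags.mean()) if flags.size else 0.0


class SegmentationBackend:
    """Interface: produce candidate animal masks for one frame.

    Implementations return zero or more detections with confidences in
    [0, 1].  Backend errors must surface as an empty detection list (a
    frame-level failure handled by the filter), not as an exception.
    """

    def segment(self, frame: np.ndarray, index: int | None = None) -> list[Detection]:
        raise NotImplementedError


class OracleBackend(SegmentationBackend):
    """Replays ground-truth masks, with optional corruption for testing.

    Parameters
    ----------
    masks_per_frame:
        Sequence of per-frame mask lists (the simulation ground truth).
    dropout_rate:
        Probability of dropping each detection independently.
    confidence_noise:
        Scale of the half-normal deficit subtracted from confidence 1.0.
    seed:
        Seed for the corruption stream; identical seeds give identical
        confidences and dropouts.
    """

    def __init__(
        self,
        masks_per_frame,
        dropout_rate: float = 0.0,
        confidence_noise: float = 0.0,
        seed: int = 0,
    ):
        self.masks_per_frame = masks_per_frame
        self.dropout_rate = dropout_rate
        self.confidence_noise = confidence_noise
        self._rng = np.random.default_rng(seed)

    def segment(self, frame: np.ndarray, index: int | None = None) -> list[Detection]:
        if index is None:
            raise ValueError("OracleBackend needs the frame index")
        dets = []
        for mask in self.masks_per_frame[index]:
            if self.dropout_rate and self._rng.random() < self.dropout_rate:
                continue
            conf = 1.0
            if self.confidence_noise:
                conf = float(
                    np.clip(1.0 - abs(self._rng.normal(0.0, self.confidence_noise)), 0, 1)
                )
            dets.append(Detection(mask=np.asarray(mask, dtype=bool), confidence=conf))
        return dets


def filter_detections(
    dets: list[Detection], cfg: ArenaConfig
) -> tuple[list[Detection], bool]:
    """Apply the segmentation failure filter to one frame's detections.

    Keeps the ``n_animals`` highest-confidence detections (ties broken by
    larger area), then flags the frame failed when fewer than n_animals
    detections exist, any kept confidence < conf_min, or any kept area is
    below area_frac_min of the largest kept area.  Order-invariant in the
    input list.
    """
    ranked = sorted(
        dets, key=lambda d: (-d.confidence, -d.area)
    )
    kept = ranked[: cfg.n_animals]
    if len(kept) < cfg.n_animals:
        return kept, True
    if any(d.confidence < cfg.conf_min for d in kept):
        return kept, True
    largest = max(d.area for d in kept)
    if largest == 0 or any(d.area < cfg.area_frac_min * largest for d in kept):
        return kept, True
    return kept, False


def fill_failed_frames(seg: InstanceSegmentationResult) -> InstanceSegmentationResult:
    """Replace failed frames' masks with the closest successful frame's.

    Ties between an earlier and later successful frame at equal temporal
    distance resolve to the earlier frame.  Raises when no frame in the
    video was successfully segmented.
    """
    n = seg.n_frames
    ok = [i for i in range(n) if not seg.failed[i]]
    if not ok:
        raise ValueError("unrecoverable video: every frame failed segmentation")
    ok_arr = np.asarray(ok)
    out = InstanceSegmentationResult(
        detections=[None] * n, failed=[False] * n
    )
    for i in range(n):
        if not seg.failed[i]:
            out.detections[i] = seg.detections[i]
            continue
        dist = np.abs(ok_arr - i)
        best = int(ok_arr[int(np.argmin(dist))])  # argmin takes first == earlier
        out.detections[i] = [
            Detection(mask=d.mask, confidence=d.confidence, source="gapfill")
            for d in seg.detections[best]
        ]
    return out
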