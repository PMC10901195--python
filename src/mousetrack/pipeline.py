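"""End-to-end tracking pipeline.

Frames first pass through conventional background-subtraction
segmentation; frames whose blob count equals the number of animals skip
the instance-segmentation backend entirely.  The remaining frames are
segmented by the backend, screened by the failure filter, gap-filled
from the nearest successful frame, and identity-stitched by IoU.
Mask-based snout/tail-base detection (and optionally the conditional
ensemble with external keypoints) completes the run.
"""

from __future__ import annotations

from dataclasses import dataclass

from .bgseg import BackgroundModel, ForegroundResult, build_background, segment_video
from .ensemble import conditional_ensemble, match_external_tracks
from .instseg import (
    InstanceSegmentationResult,
    SegmentationBackend,
    filter_detections,
    fill_failed_frames,
)
from .io import ArenaConfig, KeypointSet, VideoFrames
from .keypoints import md_keypoints
from .tracking import IdentityTrack, assign_identities, merge_conventional_and_backend

__all__ = ["TrackingResult", "track_video", "detect_keypoints"]


@dataclass
class TrackingResult:
    foreground: ForegroundResult | None
    segmentation: InstanceSegmentationResult  # merged, pre gap-fill
    filled: InstanceSegmentationResult
    track: IdentityTrack

    @property
    def failure_fraction(self) -> float:
        """Fraction of frames whose segmentation failed before gap-fill."""
        return self.segmentation.failure_fraction


def track_video(
    video: VideoFrames,
    cfg: ArenaConfig,
    backend: SegmentationBackend | None = None,
    background: "BackgroundModel | None" = None,
) -> TrackingResult:
    """Run segmentation, failure filtering, gap-fill and identity stitching.

    A pre-experiment background model may be supplied; otherwise one is
    built from the video per the config (temporal median by default).
    """
    fg = None
    if cfg.use_conventional:
        if background is None:
            k = min(cfg.bg_frames, video.frame_count)
            background = build_background(video, cfg.bg_method, k_frames=k)
        fg = segment_video(video, background, cfg)
    n = video.frame_count
    backend_seg = InstanceSegmentationResult(
        detections=[None] * n, failed=[False] * n
    )
    for f in range(n):
        if fg is not None and fg.frames[f].pass_through:
            continue
        if backend is None:
            raise ValueError(
                f"frame {f} needs the instance-segmentation backend but none "
                "was supplied"
            )
        dets = backend.segment(video.frames[f], index=f)
        kept, failed = filter_detections(dets, cfg)
        backend_seg.detections[f] = kept
        backend_seg.failed[f] = failed
    merged = merge_conventional_and_backend(fg, backend_seg)
    filled = fill_failed_frames(merged)
    track = assign_identities(filled, cfg.n_animals)
    return TrackingResult(
        foreground=fg, segmentation=merged, filled=filled, track=track
    )


def detect_keypoints(
    result: TrackingResult,
    cfg: ArenaConfig,
    external: KeypointSet | None = None,
) -> KeypointSet:
    """Mask-based keypoints, optionally ensembled with external estimates."""
    md = md_keypoints(result.track, cfg)
    if external is None:
        return md
    match = match_external_tracks(external, result.track)
    return conditional_ensemble(md, external, match, result.track)
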