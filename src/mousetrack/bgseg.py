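"""Conventional foreground detection.

A background model is built either from empty-arena frames recorded
before the experiment (pixel-wise mean) or from a temporal median over
the first frames of the recording.  Foreground pixels are those darker
than half the background intensity at the same location (the animals are
dark on a bright, diffusely lit floor).  The binary image is cleaned by
morphological closing with a 9-pixel-radius circular structuring element
followed by opening with a 3-pixel-radius element, and connected
components at least ``min_component_area`` pixels large are returned.
Frames whose component count equals the number of animals "pass through"
and skip the learned instance-segmentation stage entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import ArenaConfig, VideoFrames

__all__ = [
    "BackgroundModel",
    "FrameSegmentation",
    "ForegroundResult",
    "build_background",
    "segment_frame",
    "segment_video",
    "disk_closing",
    "disk_opening",
]

CLOSING_RADIUS = 9
OPENING_RADIUS = 3


@dataclass
class BackgroundModel:
    image: np.ndarray  # H x W float intensities in [0, 255]
    method: str  # 'pre_experiment' | 'temporal_median'
    k_frames: int = 0


@dataclass
class FrameSegmentation:
    """Connected components of one frame, sorted by area descending."""

    masks: list[np.ndarray]
    pass_through: bool


@dataclass
class ForegroundResult:
    frames: list[FrameSegmentation] = field(default_factory=list)
    enabled: bool = True

    @property
    def pass_through_flags(self) -> np.ndarray:
        return np.array([f.pass_through for f in self.frames], dtype=bool)


def build_background(
    frames: VideoFrames | np.ndarray, method: str = "temporal_median", k_frames: int = 300
) -> BackgroundModel:
    """Build the per-pixel background intensity model.

    'pre_experiment' averages all supplied (empty arena) frames;
    'temporal_median' takes the pixel-wise median of the first ``k_frames``
    frames of the recording itself.
    """
    stack = frames.frames if isinstance(frames, VideoFrames) else np.asarray(frames)
    if method == "pre_experiment":
        image = stack.astype(np.float64).mean(axis=0)
    elif method == "temporal_median":
        if k_frames < 1:
            raise ValueError("k_frames must be at least 1")
        if k_frames > stack.shape[0]:
            raise ValueError(
                f"k_frames={k_frames} exceeds frame count {stack.shape[0]}"
            )
        image = np.median(stack[:k_frames].astype(np.float64), axis=0)
    else:
        raise ValueError(f"unknown background method: {method!r}")
    return BackgroundModel(image=image, method=method, k_frames=k_frames)


def _edt_dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary dilation by a Euclidean disk of the given radius.

    Equivalent to dilation with ``skimage.morphology.disk(radius)``: a
    pixel is on iff some foreground pixel lies within Euclidean distance
    ``radius``.  Implemented with a distance transform, which is much
    faster than direct convolution for large disks.
    """
    if not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask)
    return dist <= radius


def _edt_erode(mask: np.ndarray, radius: int) -> np.ndarray:
    if mask.all():
        return mask.copy()
    dist = ndimage.distance_transform_edt(mask)
    return dist > radius


def _fg_window(mask: np.ndarray, margin: int):
    """Slice covering all foreground plus a margin (None when empty)."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        return None
    r0 = max(0, rows[0] - margin)
    r1 = min(mask.shape[0], rows[-1] + margin + 1)
    c0 = max(0, cols[0] - margin)
    c1 = min(mask.shape[1], cols[-1] + margin + 1)
    return slice(r0, r1), slice(c0, c1)


def disk_closing(mask: np.ndarray, radius: int) -> np.ndarray:
    """Closing with a circular structuring element (dilate then erode).

    Border handling matches morphology with zero padding outside the
    image, i.e. the image is treated as embedded in background.  The
    distance transforms run only on the foreground bounding box (the
    closing of a set is contained in its dilation, so nothing outside
    the padded window can turn on).
    """
    win = _fg_window(mask, radius + 1)
    if win is None:
        return mask.copy()
    pad = radius + 1
    sub = np.pad(mask[win], pad, mode="constant", constant_values=False)
    closed = _edt_erode(_edt_dilate(sub, radius), radius)
    out = np.zeros_like(mask)
    out[win] = closed[pad:-pad, pad:-pad]
    return out


def disk_opening(mask: np.ndarray, radius: int) -> np.ndarray:
    """Opening with a circular structuring element (erode then dilate)."""
    win = _fg_window(mask, radius + 1)
    if win is None:
        return mask.copy()
    pad = radius + 1
    sub = np.pad(mask[win], pad, mode="constant", constant_values=False)
    opened = _edt_dilate(_edt_erode(sub, radius), radius)
    out = np.zeros_like(mask)
    out[win] = opened[pad:-pad, pad:-pad]
    return out


def segment_frame(
    frame: np.ndarray, bg: BackgroundModel, cfg: ArenaConfig
) -> FrameSegmentation:
    """Threshold one frame against the background and extract components.

    Foreground = pixels darker than half the local background intensity,
    then closing (radius 9) and opening (radius 3), then 8-connected
    components with area >= cfg.min_component_area, sorted by area
    descending (ties by centroid x then y).
    """
    frame = np.asarray(frame)
    if frame.shape != bg.image.shape:
        raise ValueError(
            f"frame shape {frame.shape} != background shape {bg.image.shape}"
        )
    fg = frame.astype(np.float64) < 0.5 * bg.image
    fg = disk_closing(fg, CLOSING_RADIUS)
    fg = disk_opening(fg, OPENING_RADIUS)
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    masks: list[np.ndarray] = []
    order = []
    for lab in range(1, n + 1):
        m = labels == lab
        area = int(m.sum())
        if area < cfg.min_component_area:
            continue
        ys, xs = np.nonzero(m)
        order.append((-area, xs.mean(), ys.mean()))
        masks.append(m)
    idx = sorted(range(len(masks)), key=lambda i: order[i])
    masks = [masks[i] for i in idx]
    return FrameSegmentation(masks=masks, pass_through=len(masks) == cfg.n_animals)


def segment_video(
    frames: VideoFrames, bg: BackgroundModel, cfg: ArenaConfig
) -> ForegroundResult:
    """Apply segment_frame to every frame.

    When the conventional stage is disabled in the config, an empty
    (disabled) result is returned and all frames are deferred to the
    instance-segmentation backend.
    """
    if not cfg.use_conventional:
        return ForegroundResult(frames=[], enabled=False)
    out = ForegroundResult(enabled=True)
    for i in range(frames.frame_count):
        out.frames.append(segment_frame(frames.frames[i], bg, cfg))
    return out
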