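"""Mask-based detection (MD) of snout and tail-base.

For each animal and frame the mask's two extremal contour points are
found (the pair of contour points at maximal Euclidean distance, via the
convex hull).  Whether those end points can be labelled directly depends
on the animal's posture: a frame is treated as "body parallel to the
floor" when the mask's principal length exceeds the animal's median
length over the whole video AND the mask lies entirely on the cage floor.
On parallel frames the snout is the end point with the narrower taper
(smaller mean mask width over the three terminal tenths of the body axis
nearest it) — the mouse rear is wider than the head.  On all other
frames (rearing, curled up, against a wall) the end points inherit their
labels from the nearest labelled points of the previous frame.  Frames
before the first parallel frame are labelled by propagating backwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import cdist

from .io import ArenaConfig, KeypointSet
from .tracking import IdentityTrack

__all__ = ["MaskGeometry", "extract_endpoints", "md_keypoints"]

N_WIDTH_BINS = 10
N_TERMINAL_BINS = 3


@dataclass
class MaskGeometry:
    """Principal-axis geometry of one body mask."""

    length: float  # max pairwise distance between contour points
    endpoints: np.ndarray  # (2, 2) array of (x, y), on the contour
    width_profile: np.ndarray  # (N_WIDTH_BINS,) widths from endpoint 0 to 1
    floor_overlap: float  # fraction of mask pixels inside the floor ROI


def _contour_points(mask: np.ndarray) -> np.ndarray:
    """Boundary pixels of the mask as (x, y) points."""
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3), dtype=bool))
    boundary = mask & ~eroded
    ys, xs = np.nonzero(boundary)
    return np.column_stack([xs, ys]).astype(float)


def _diameter(points: np.ndarray) -> tuple[float, np.ndarray]:
    """Maximal pairwise distance and the realizing pair of points."""
    if len(points) > 6:
        try:
            hull = ConvexHull(points)
            points = points[hull.vertices]
        except Exception:
            pass  # degenerate (collinear) point sets: brute force below
    d = cdist(points, points)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    return float(d[i, j]), np.array([points[i], points[j]])


def extract_endpoints(
    mask: np.ndarray, floor_mask: np.ndarray | None = None
) -> MaskGeometry:
    """Compute principal length, end points, width profile, floor overlap."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    pts = _contour_points(mask)
    if len(pts) == 1:
        length, endpoints = 0.0, np.array([pts[0], pts[0]])
    else:
        length, endpoints = _diameter(pts)
    ys, xs = np.nonzero(mask)
    pix = np.column_stack([xs, ys]).astype(float)
    width = _width_profile(pix, endpoints)
    if floor_mask is None:
        floor_overlap = 1.0
    else:
        floor_overlap = float(floor_mask[ys, xs].mean())
    return MaskGeometry(
        length=length,
        endpoints=endpoints,
        width_profile=width,
        floor_overlap=floor_overlap,
    )


def _width_profile(pix: np.ndarray, endpoints: np.ndarray) -> np.ndarray:
    """Mask extent perpendicular to the end-point axis in 10 equal bins."""
    axis = endpoints[1] - endpoints[0]
    norm = np.hypot(*axis)
    widths = np.zeros(N_WIDTH_BINS)
    if norm == 0:
        return widths
    u = axis / norm
    v = np.array([-u[1], u[0]])
    rel = pix - endpoints[0]
    t = rel @ u / norm  # in [0, 1] along the axis
    w = rel @ v
    bins = np.clip((t * N_WIDTH_BINS).astype(int), 0, N_WIDTH_BINS - 1)
    for b in range(N_WIDTH_BINS):
        sel = bins == b
        if sel.any():
            widths[b] = w[sel].max() - w[sel].min() + 1.0  # pixel extent
    return widths


def _label_by_taper(geom: MaskGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Snout = end point whose terminal bins are narrower."""
    head_w = geom.width_profile[:N_TERMINAL_BINS].mean()
    tail_w = geom.width_profile[-N_TERMINAL_BINS:].mean()
    if head_w <= tail_w:
        return geom.endpoints[0], geom.endpoints[1]
    return geom.endpoints[1], geom.endpoints[0]


def _label_by_stitching(
    geom: MaskGeometry, prev_snout: np.ndarray, prev_tail: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Assign labels by the total-distance-minimising 2x2 pairing."""
    e0, e1 = geom.endpoints
    straight = np.linalg.norm(e0 - prev_snout) + np.linalg.norm(e1 - prev_tail)
    crossed = np.linalg.norm(e1 - prev_snout) + np.linalg.norm(e0 - prev_tail)
    if straight <= crossed:
        return e0, e1
    return e1, e0


def md_keypoints(track: IdentityTrack, cfg: ArenaConfig) -> KeypointSet:
    """Two-pass mask-based snout/tail-base detection for all animals.

    Pass 1 computes every mask's geometry and each animal's median
    principal length; pass 2 labels end points on parallel frames by the
    taper rule and stitches the rest to the previous (or, before the
    first parallel frame, the next) labelled frame.
    """
    n_frames, n_animals = track.n_frames, track.n_animals
    if n_frames == 0:
        raise ValueError("empty track")
    floor = cfg.floor_mask(track.masks[0][0].shape)

    geoms: list[list[MaskGeometry]] = []
    for f in range(n_frames):
        geoms.append(
            [extract_endpoints(track.masks[f][i], floor) for i in range(n_animals)]
        )

    snout = np.zeros((n_frames, n_animals, 2))
    tail = np.zeros((n_frames, n_animals, 2))
    for i in range(n_animals):
        lengths = np.array([geoms[f][i].length for f in range(n_frames)])
        median_len = float(np.median(lengths))
        parallel = np.array(
            [
                geoms[f][i].length > median_len
                and geoms[f][i].floor_overlap >= 1.0
                for f in range(n_frames)
            ]
        )
        if not parallel.any():
            raise ValueError(
                f"labeling undetermined for animal {i}: no frame with "
                f"length > median ({median_len:.1f} px) and full floor overlap"
            )
        first_par = int(np.flatnonzero(parallel)[0])
        # forward pass from the first parallel frame
        for f in range(first_par, n_frames):
            g = geoms[f][i]
            if parallel[f]:
                snout[f, i], tail[f, i] = _label_by_taper(g)
            else:
                snout[f, i], tail[f, i] = _label_by_stitching(
                    g, snout[f - 1, i], tail[f - 1, i]
                )
        # backward propagation for frames before the first parallel frame
        for f in range(first_par - 1, -1, -1):
            snout[f, i], tail[f, i] = _label_by_stitching(
                geoms[f][i], snout[f + 1, i], tail[f + 1, i]
            )
    return KeypointSet.from_arrays(snout, tail, source="MD")
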