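"""Standardised synthetic evaluation protocol.

Runs the full pipeline (conventional segmentation + oracle instance
masks, failure filter, gap-fill, IoU identity stitching, mask-based
keypoints, conditional ensemble against a corrupted external estimator)
over a batch of seeded synthetic recordings and aggregates the tracking
metrics: identity switches, per-target MOTA, PCKh, keypoint error
distributions and snout-labelling accuracy.

The protocol videos are 500 frames at 30 fps in a 256-px arena (the
540-px reference geometry scaled down for speed, see docs/methods.md)
with scripted approach, contact and crossing episodes so that every
hard case — merged foregrounds, occlusion, path crossings — occurs in
every video.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .bgseg import build_background
from .ensemble import conditional_ensemble, match_external_tracks
from .evaluation import count_switches, error_summary, keypoint_errors, mota, pckh
from .instseg import OracleBackend
from .io import ArenaConfig
from .keypoints import md_keypoints
from .pipeline import track_video
from .simulate import (
    Episode,
    SimulationConfig,
    corrupt_keypoints,
    generate_video,
    render_empty_arena,
)

__all__ = [
    "REFERENCE_IMAGE_SIZE",
    "scaled_arena",
    "standard_episodes",
    "SuiteResult",
    "evaluate_synthetic_video",
    "run_suite",
]

REFERENCE_IMAGE_SIZE = 540

#: external-estimator corruption rates used by the ensemble comparison
EXT_DROPOUT = 0.05
EXT_SWAP = 0.02
EXT_JITTER_PX = 3.0


def scaled_arena(image_size: int = 256, **overrides) -> ArenaConfig:
    """ArenaConfig with pixel thresholds scaled from the 540-px defaults."""
    k = image_size / REFERENCE_IMAGE_SIZE
    params = dict(
        pckh_threshold_px=15.0 * k,
        sniff_threshold_px=25.0 * k,
        touch_threshold_px=25.0 * k,
        stationary_speed_px_s=15.0 * k,
        min_component_area=max(1, int(round(200 * k * k))),
        floor_margin_px=max(1, int(round(10 * k))),
    )
    params.update(overrides)
    return ArenaConfig(**params)


def standard_episodes(n_frames: int) -> list[Episode]:
    """Approach, two contacts and a crossing, spread over the video."""
    f = lambda x: int(round(x * n_frames))
    return [
        Episode("approach", f(0.10), f(0.20)),
        Episode("contact", f(0.20), f(0.32)),
        Episode("cross", f(0.50), f(0.60)),
        Episode("contact", f(0.70), f(0.82)),
    ]


def _interaction_frames(episodes: list[Episode], n_frames: int) -> np.ndarray:
    """Boolean mask of frames inside contact or crossing episodes."""
    inside = np.zeros(n_frames, dtype=bool)
    for ep in episodes:
        if ep.kind in ("contact", "cross"):
            inside[ep.start : ep.end] = True
    return inside


@dataclass
class SuiteResult:
    """Aggregated metrics over the evaluated videos."""

    n_videos: int = 0
    n_frames_per_video: int = 0
    switches_total: int = 0
    failure_fraction_mean: float = 0.0
    center_mota: float = 0.0
    snout_mota: float = 0.0
    tailbase_mota: float = 0.0
    pckh_md: float = 0.0
    md_errors: np.ndarray = field(default_factory=lambda: np.array([]))
    ensemble_errors: np.ndarray = field(default_factory=lambda: np.array([]))
    external_errors: np.ndarray = field(default_factory=lambda: np.array([]))
    snout_label_accuracy: float = 0.0
    contour_fraction: float = 0.0

    def summary(self) -> dict:
        md = error_summary(self.md_errors)
        ens = error_summary(self.ensemble_errors)
        ext_errors = self.external_errors[~np.isnan(self.external_errors)]
        ext = error_summary(ext_errors)
        # common fence: the baseline (external) distribution's Tukey rule,
        # so "outlier reduction" is measured against the same yardstick
        fence = ext.outlier_threshold
        ens_beyond = int((self.ensemble_errors > fence).sum())
        ext_beyond = int((ext_errors > fence).sum())
        return {
            "ensemble_outliers_beyond_baseline_fence": ens_beyond,
            "external_outliers_beyond_baseline_fence": ext_beyond,
            "n_videos": self.n_videos,
            "identity_switches_total": self.switches_total,
            "segmentation_failure_fraction": self.failure_fraction_mean,
            "center_mota": self.center_mota,
            "snout_mota": self.snout_mota,
            "tailbase_mota": self.tailbase_mota,
            "pckh_md": self.pckh_md,
            "md_mean_error_px": md.mean,
            "ensemble_mean_error_px": ens.mean,
            "external_mean_error_px": ext.mean,
            "ensemble_outlier_count": ens.outlier_count,
            "external_outlier_count": ext.outlier_count,
            "snout_label_accuracy": self.snout_label_accuracy,
            "keypoints_on_contour_fraction": self.contour_fraction,
        }


def _on_boundary(point: np.ndarray, mask: np.ndarray, boundary: np.ndarray) -> bool:
    x, y = int(round(point[0])), int(round(point[1]))
    h, w = mask.shape
    return 0 <= y < h and 0 <= x < w and bool(boundary[y, x])


def evaluate_synthetic_video(
    seed: int,
    n_frames: int = 500,
    image_size: int = 256,
) -> dict:
    """Run the whole pipeline on one protocol video; return raw tallies."""
    episodes = standard_episodes(n_frames)
    sim = SimulationConfig(
        n_frames=n_frames, seed=seed, episodes=episodes
    ).scaled(image_size)
    arena = scaled_arena(image_size)
    video, gt = generate_video(sim)
    backend = OracleBackend(gt.masks)
    bg = build_background(
        render_empty_arena(sim)[None].astype(np.uint8), "pre_experiment"
    )
    res = track_video(video, arena, backend, background=bg)
    md = md_keypoints(res.track, arena)
    ext = corrupt_keypoints(
        gt, EXT_DROPOUT, EXT_SWAP, EXT_JITTER_PX, seed=seed + 1_000_000
    )
    match = match_external_tracks(ext, res.track)
    ens = conditional_ensemble(md, ext, match, res.track)
    gtk = gt.keypoint_set()
    thr = arena.pckh_threshold_px

    center = mota(md, gtk, thr, target="center")
    out = {
        "switches": count_switches(md, gtk, thr),
        "center_counts": (
            center.misses,
            center.false_positives,
            center.mismatches,
            center.total_gt,
        ),
        "snout_counts": _mota_counts(md, gtk, thr, "snout"),
        "tailbase_counts": _mota_counts(md, gtk, thr, "tailbase"),
        "pckh": pckh(md, gtk, thr),
        "failure_fraction": res.failure_fraction,
        "md_errors": keypoint_errors(md, gtk),
        "ensemble_errors": keypoint_errors(ens, gtk),
        "external_errors": keypoint_errors(ext, gtk),
    }

    # snout-label accuracy outside interaction episodes, and contour check
    inside = _interaction_frames(episodes, n_frames)
    snout_pred = md.coords("snout")
    tail_pred = md.coords("tailbase")
    correct = total = 0
    on_contour = 0
    n_points = 0
    for f in range(n_frames):
        for i in range(gt.n_agents):
            mask = res.track.masks[f][i]
            eroded = ndimage.binary_erosion(
                mask, structure=np.ones((3, 3), dtype=bool)
            )
            boundary = mask & ~eroded
            n_points += 2
            on_contour += _on_boundary(snout_pred[f, i], mask, boundary)
            on_contour += _on_boundary(tail_pred[f, i], mask, boundary)
            if inside[f]:
                continue
            d_snout = np.linalg.norm(snout_pred[f, i] - gt.snout[f, i])
            d_tail = np.linalg.norm(snout_pred[f, i] - gt.tailbase[f, i])
            correct += d_snout < d_tail
            total += 1
    out["snout_correct"] = int(correct)
    out["snout_total"] = int(total)
    out["on_contour"] = int(on_contour)
    out["n_points"] = int(n_points)
    return out


def _mota_counts(pred, gt, thr, target):
    r = mota(pred, gt, thr, target=target)
    return (r.misses, r.false_positives, r.mismatches, r.total_gt)


def _pooled_mota(counts: list[tuple]) -> float:
    m = sum(c[0] for c in counts)
    fp = sum(c[1] for c in counts)
    mme = sum(c[2] for c in counts)
    g = sum(c[3] for c in counts)
    return 1.0 - (m + fp + mme) / g


def run_suite(
    n_videos: int = 50,
    n_frames: int = 500,
    image_size: int = 256,
    base_seed: int = 0,
) -> SuiteResult:
    """Evaluate ``n_videos`` seeded protocol videos and pool the metrics."""
    per_video = [
        evaluate_synthetic_video(base_seed + i, n_frames, image_size)
        for i in range(n_videos)
    ]
    result = SuiteResult(n_videos=n_videos, n_frames_per_video=n_frames)
    result.switches_total = sum(v["switches"] for v in per_video)
    result.failure_fraction_mean = float(
        np.mean([v["failure_fraction"] for v in per_video])
    )
    result.center_mota = _pooled_mota([v["center_counts"] for v in per_video])
    result.snout_mota = _pooled_mota([v["snout_counts"] for v in per_video])
    result.tailbase_mota = _pooled_mota([v["tailbase_counts"] for v in per_video])
    result.pckh_md = float(np.mean([v["pckh"] for v in per_video]))
    result.md_errors = np.concatenate([v["md_errors"] for v in per_video])
    result.ensemble_errors = np.concatenate(
        [v["ensemble_errors"] for v in per_video]
    )
    result.external_errors = np.concatenate(
        [v["external_errors"] for v in per_video]
    )
    result.snout_label_accuracy = sum(
        v["snout_correct"] for v in per_video
    ) / sum(v["snout_total"] for v in per_video)
    result.contour_fraction = sum(v["on_contour"] for v in per_video) / sum(
        v["n_points"] for v in per_video
    )
    return result
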