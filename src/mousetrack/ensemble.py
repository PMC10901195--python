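"""Conditional ensembling of external pose-estimator keypoints with MD.

An external pose estimator (e.g. a multi-animal keypoint CNN) supplies
per-frame snout/tail-base estimates under its own track labels.  Those
tracks are first matched to the internal identities by mask containment
(an external track belongs to the identity whose body masks contain the
majority of its valid points).  The ensemble rule is then binary, per
frame and identity: the external snout and tail-base are taken when both
are valid and both fall inside that identity's own body mask for that
frame; otherwise the mask-based (MD) coordinates are kept.  Containment
in the animal's *own* mask is what rejects cross-animal swaps and stray
points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import KeypointSet
from .tracking import IdentityTrack

__all__ = ["ExternalTrackMatch", "match_external_tracks", "conditional_ensemble"]


@dataclass
class ExternalTrackMatch:
    """Injective mapping external track id -> internal identity."""

    mapping: dict[int, int] = field(default_factory=dict)
    containment_counts: dict[int, dict[int, int]] = field(default_factory=dict)
    unmatched: list[int] = field(default_factory=list)


def _point_in_mask(x: float, y: float, mask: np.ndarray) -> bool:
    """Nearest-pixel containment; boundary pixels count as inside."""
    if np.isnan(x) or np.isnan(y):
        return False
    c, r = int(round(x)), int(round(y))
    h, w = mask.shape
    if not (0 <= r < h and 0 <= c < w):
        return False
    return bool(mask[r, c])


def match_external_tracks(
    ext: KeypointSet, track: IdentityTrack
) -> ExternalTrackMatch:
    """Map each external track to the identity containing most of its points."""
    counts: dict[int, dict[int, int]] = {}
    n_frames, n_animals = track.n_frames, track.n_animals
    for row in ext.df.itertuples(index=False):
        if not row.valid or not (0 <= row.frame < n_frames):
            continue
        per = counts.setdefault(int(row.animal), {i: 0 for i in range(n_animals)})
        for x, y in ((row.snout_x, row.snout_y), (row.tailbase_x, row.tailbase_y)):
            for i in range(n_animals):
                if _point_in_mask(x, y, track.masks[row.frame][i]):
                    per[i] += 1
    match = ExternalTrackMatch(containment_counts=counts)
    claimed: dict[int, int] = {}
    for ext_id in sorted(set(ext.df["animal"].astype(int))):
        per = counts.get(ext_id)
        if per is None or sum(per.values()) == 0:
            match.unmatched.append(ext_id)
            continue
        best = max(per.values())
        winners = [i for i, c in per.items() if c == best]
        if len(winners) > 1:
            raise ValueError(
                f"ambiguous match for external track {ext_id}: "
                f"containment counts {per}"
            )
        winner = winners[0]
        if winner in claimed:
            raise ValueError(
                f"external tracks {claimed[winner]} and {ext_id} both map to "
                f"identity {winner}; containment counts: {counts}"
            )
        claimed[winner] = ext_id
        match.mapping[ext_id] = winner
    return match


def conditional_ensemble(
    md: KeypointSet,
    ext: KeypointSet,
    match: ExternalTrackMatch,
    track: IdentityTrack,
) -> KeypointSet:
    """Choose external keypoints when both lie in the animal's own mask.

    MD must be total over (frame, identity); missing or rejected external
    records fall back to MD, so the output is total as well.
    """
    inv = {identity: ext_id for ext_id, identity in match.mapping.items()}
    ext_by_key = {
        (int(r.frame), int(r.animal)): r for r in ext.df.itertuples(index=False)
    }
    recs = []
    for row in md.df.itertuples(index=False):
        frame, identity = int(row.frame), int(row.animal)
        chosen = row
        source = "ensemble/MD"
        ext_id = inv.get(identity)
        if ext_id is not None and 0 <= frame < track.n_frames:
            er = ext_by_key.get((frame, ext_id))
            if er is not None and er.valid:
                mask = track.masks[frame][identity]
                if _point_in_mask(er.snout_x, er.snout_y, mask) and _point_in_mask(
                    er.tailbase_x, er.tailbase_y, mask
                ):
                    chosen = er
                    source = "ensemble/external"
        recs.append(
            {
                "frame": frame,
                "animal": identity,
                "snout_x": chosen.snout_x,
                "snout_y": chosen.snout_y,
                "tailbase_x": chosen.tailbase_x,
                "tailbase_y": chosen.tailbase_y,
                "source": source,
                "valid": bool(chosen.valid),
            }
        )
    return KeypointSet.from_records(recs)
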