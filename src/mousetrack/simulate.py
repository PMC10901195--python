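"""Synthetic two-(or N-)mouse videos with complete ground truth.

The generator emulates the imaging regime the pipeline is built for:
dark, deformable-looking mouse-shaped blobs on a bright, uniformly lit
floor seen from above.  Each agent is a tapered capsule (a wide rear
circle and a narrow front circle joined by their tangent hull) oriented
along its heading, which gives an unambiguous snout end for ground
truth.  Motion is a correlated random walk (heading diffusion at
constant speed) with reflective walls; scheduled episodes force the
inter-agent distance profile — approach (one agent steers toward the
other), contact (both steer together until their masks overlap and hold)
and crossing (paths intersect as the agents swap sides of the arena).

Optional artifacts reproduce common experimental clutter: a static
bedding speckle texture (bounded so every agent pixel stays below half
the local background intensity and conventional segmentation remains
valid), a thin bright tether line from an agent's rear to the nearest
wall, and a bright headstage disc over the head that locally destroys
the dark-on-bright contrast.

All randomness derives from a single seed; identical configurations
produce bit-identical videos and ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import ArenaConfig, KeypointSet, VideoFrames

__all__ = [
    "Episode",
    "SimulationConfig",
    "GroundTruth",
    "generate_video",
    "render_empty_arena",
    "corrupt_keypoints",
]


@dataclass
class Episode:
    kind: str  # 'approach' | 'contact' | 'cross'
    start: int
    end: int  # exclusive

    def __post_init__(self) -> None:
        if self.kind not in ("approach", "contact", "cross"):
            raise ValueError(f"unknown episode kind: {self.kind!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid episode range [{self.start}, {self.end})")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic recording.

    Defaults mirror the target imaging regime: a 540 x 540 px top-down
    arena at 30 frames/s with mouse-sized agents (body axis ~110 px) and
    a speed of 3 px/frame (~90 px/s).  ``scaled`` derives a geometrically
    proportional configuration at another arena size.
    """

    n_frames: int = 500
    fps: float = 30.0
    image_size: int = 540
    n_agents: int = 2
    background_intensity: float = 200.0
    agent_intensity: float = 40.0
    body_length: float = 70.0  # rear-to-front circle center distance
    rear_radius: float = 22.0
    front_radius: float = 9.0
    speed: float = 3.0  # px / frame
    turn_sigma: float = 0.15  # rad / frame heading diffusion
    episodes: list[Episode] = field(default_factory=list)
    tether: bool = False
    headstage: bool = False
    bedding_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.agent_intensity >= 0.5 * self.background_intensity:
            raise ValueError(
                "agent intensity must stay below half the background intensity"
            )
        for ep in self.episodes:
            if ep.end > self.n_frames:
                raise ValueError(
                    f"episode [{ep.start}, {ep.end}) exceeds n_frames={self.n_frames}"
                )

    def scaled(self, image_size: int) -> "SimulationConfig":
        """Same conditions at a different arena size (lengths rescaled)."""
        k = image_size / self.image_size
        return replace(
            self,
            image_size=image_size,
            body_length=self.body_length * k,
            rear_radius=self.rear_radius * k,
            front_radius=self.front_radius * k,
            speed=self.speed * k,
        )


@dataclass
class GroundTruth:
    """Per-frame, per-agent masks, keypoints and identity labels."""

    masks: list[list[np.ndarray]]  # [frame][agent] bool H x W
    snout: np.ndarray  # (n_frames, n_agents, 2) x, y
    tailbase: np.ndarray
    fps: float = 30.0

    @property
    def n_frames(self) -> int:
        return len(self.masks)

    @property
    def n_agents(self) -> int:
        return self.snout.shape[1]

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.snout + self.tailbase)

    def keypoint_set(self, source: str = "groundtruth") -> KeypointSet:
        return KeypointSet.from_arrays(self.snout, self.tailbase, source=source)

    def identity_track(self):
        """View the ground truth as an IdentityTrack (for behavior scoring)."""
        from .tracking import IdentityTrack

        n, k = self.n_frames, self.n_agents
        centroids = np.zeros((n, k, 2))
        areas = np.zeros((n, k), dtype=int)
        for f in range(n):
            for i in range(k):
                ys, xs = np.nonzero(self.masks[f][i])
                centroids[f, i] = xs.mean(), ys.mean()
                areas[f, i] = len(xs)
        return IdentityTrack(
            masks=self.masks,
            centroids=centroids,
            areas=areas,
            sources=[["groundtruth"] * k for _ in range(n)],
        )

    def ethogram(self, arena_cfg: ArenaConfig):
        """Ground-truth behavior labels, scored from the ground-truth
        geometry with the same classifier used for predictions."""
        from .behavior import classify_sniffing, detect_touching

        track = self.identity_track()
        eth = classify_sniffing(self.keypoint_set(), track, arena_cfg)
        return detect_touching(track, eth, arena_cfg)


# ---------------------------------------------------------------------------
# motion


def _avoid_walls(
    pos: np.ndarray, heading: float, lo: float, hi: float, zone: float, max_turn: float
) -> float:
    """Steer away from nearby walls with a limited turn rate.

    Animals turn at walls continuously rather than reflecting, so the
    body orientation (and hence the true snout position) never jumps
    between frames.
    """
    near = (
        pos[0] < lo + zone
        or pos[0] > hi - zone
        or pos[1] < lo + zone
        or pos[1] > hi - zone
    )
    if not near:
        return heading
    center = np.array([(lo + hi) / 2, (lo + hi) / 2])
    to_center = float(np.arctan2(*(center - pos)[::-1]))
    return _steer_toward(heading, to_center, max_turn)


def _steer_toward(heading: float, target_angle: float, max_turn: float) -> float:
    diff = (target_angle - heading + np.pi) % (2 * np.pi) - np.pi
    return heading + float(np.clip(diff, -max_turn, max_turn))


def _segment_distance(
    a0: np.ndarray, a1: np.ndarray, b0: np.ndarray, b1: np.ndarray
) -> float:
    """Minimum distance between two 2-D segments."""
    best = np.inf
    ts = np.linspace(0.0, 1.0, 9)
    pa = a0[None, :] + ts[:, None] * (a1 - a0)[None, :]
    for p in pa:
        best = min(best, _point_segment_distance(p, b0, b1))
    pb = b0[None, :] + ts[:, None] * (b1 - b0)[None, :]
    for p in pb:
        best = min(best, _point_segment_distance(p, a0, a1))
    return float(best)


def _point_segment_distance(p: np.ndarray, s0: np.ndarray, s1: np.ndarray) -> float:
    d = s1 - s0
    l2 = float(d @ d)
    t = 0.0 if l2 == 0 else float(np.clip((p - s0) @ d / l2, 0.0, 1.0))
    return float(np.linalg.norm(p - (s0 + t * d)))


def _resolve_collisions(
    pos: np.ndarray, heading: np.ndarray, cfg: SimulationConfig, lo: float, hi: float
) -> None:
    """Push body axes apart so agents overlap at most partially.

    Mice are solid: two bodies may press against or climb over each
    other (masks overlap) but cannot coincide.  The minimum allowed
    distance between body axes is kept below the touching distance
    (rear+front radius), so contact episodes still produce overlapping
    masks.
    """
    k = pos.shape[0]
    d_min = 0.5 * cfg.rear_radius
    half = cfg.body_length / 2
    for _ in range(4):
        moved = False
        for i in range(k):
            for j in range(i + 1, k):
                ui = np.array([np.cos(heading[i]), np.sin(heading[i])])
                uj = np.array([np.cos(heading[j]), np.sin(heading[j])])
                d = _segment_distance(
                    pos[i] - half * ui, pos[i] + half * ui,
                    pos[j] - half * uj, pos[j] + half * uj,
                )
                if d >= d_min:
                    continue
                sep = pos[i] - pos[j]
                nrm = np.linalg.norm(sep)
                direction = sep / nrm if nrm > 1e-9 else np.array([1.0, 0.0])
                push = 0.5 * (d_min - d) + 0.25
                pos[i] = np.clip(pos[i] + direction * push, lo, hi)
                pos[j] = np.clip(pos[j] - direction * push, lo, hi)
                moved = True
        if not moved:
            break


def _simulate_motion(cfg: SimulationConfig, rng: np.random.Generator):
    """Positions (body midpoints) and headings for every frame and agent."""
    n, k = cfg.n_frames, cfg.n_agents
    margin = cfg.body_length / 2 + cfg.rear_radius + 3
    lo, hi = margin, cfg.image_size - margin
    pos = np.zeros((n, k, 2))
    heading = np.zeros((n, k))
    # spread initial positions on a diagonal, well separated
    for i in range(k):
        frac = (i + 1) / (k + 1)
        pos[0, i] = [lo + frac * (hi - lo), hi - frac * (hi - lo)]
        heading[0, i] = rng.uniform(-np.pi, np.pi)
    episode_at = {}
    for ep in cfg.episodes:
        for f in range(ep.start, ep.end):
            episode_at[f] = ep
    cross_targets: dict[int, np.ndarray] = {}
    # approach until the bodies press together (the collision constraint
    # stops them from coinciding); close enough for the masks to overlap
    contact_dist = cfg.rear_radius
    for f in range(1, n):
        ep = episode_at.get(f)
        for i in range(k):
            h = heading[f - 1, i] + rng.normal(0.0, cfg.turn_sigma)
            speed = cfg.speed
            p_prev = pos[f - 1, i]
            if ep is not None and i < 2:
                other = pos[f - 1, 1 - i]
                to_other = float(np.arctan2(*(other - p_prev)[::-1]))
                if ep.kind == "approach" and i == 0:
                    h = _steer_toward(heading[f - 1, i], to_other, 0.4)
                elif ep.kind == "contact":
                    gap = float(np.linalg.norm(other - p_prev))
                    if gap > contact_dist:
                        h = _steer_toward(heading[f - 1, i], to_other, 0.5)
                    else:
                        speed = 0.0  # hold the contact
                elif ep.kind == "cross":
                    if ep.start not in cross_targets:
                        # swap sides: each agent aims past the other's position
                        perp = np.array(
                            [-(other - p_prev)[1], (other - p_prev)[0]]
                        )
                        nrm = np.linalg.norm(perp)
                        offset = perp / nrm * cfg.rear_radius if nrm else 0.0
                        cross_targets[ep.start] = np.stack(
                            [
                                pos[f - 1, 1] + offset,
                                pos[f - 1, 0] - offset,
                            ]
                        )
                    tgt = cross_targets[ep.start][i]
                    to_tgt = float(np.arctan2(*(tgt - p_prev)[::-1]))
                    h = _steer_toward(heading[f - 1, i], to_tgt, 0.5)
            h = _avoid_walls(p_prev, h, lo, hi, zone=3 * cfg.speed, max_turn=0.3)
            p = np.clip(
                p_prev + speed * np.array([np.cos(h), np.sin(h)]), lo, hi
            )
            pos[f, i] = p
            heading[f, i] = h
        _resolve_collisions(pos[f], heading[f], cfg, lo, hi)
    return pos, heading


# ---------------------------------------------------------------------------
# rendering


def _capsule_mask(
    shape: tuple[int, int],
    rear: np.ndarray,
    front: np.ndarray,
    r_rear: float,
    r_front: float,
) -> np.ndarray:
    """Tapered capsule: disks of radius r(t) swept from rear to front."""
    h, w = shape
    rmax = max(r_rear, r_front)
    x0 = int(max(0, np.floor(min(rear[0], front[0]) - rmax - 1)))
    x1 = int(min(w, np.ceil(max(rear[0], front[0]) + rmax + 2)))
    y0 = int(max(0, np.floor(min(rear[1], front[1]) - rmax - 1)))
    y1 = int(min(h, np.ceil(max(rear[1], front[1]) + rmax + 2)))
    ys, xs = np.mgrid[y0:y1, x0:x1]
    axis = front - rear
    length2 = float(axis @ axis)
    px = xs - rear[0]
    py = ys - rear[1]
    if length2 == 0:
        t = np.zeros_like(px, dtype=float)
    else:
        t = np.clip((px * axis[0] + py * axis[1]) / length2, 0.0, 1.0)
    cx = rear[0] + t * axis[0]
    cy = rear[1] + t * axis[1]
    dist = np.hypot(xs - cx, ys - cy)
    radius = r_rear + (r_front - r_rear) * t
    mask = np.zeros(shape, dtype=bool)
    mask[y0:y1, x0:x1] = dist <= radius
    return mask


def _draw_line(img: np.ndarray, p0: np.ndarray, p1: np.ndarray, value: float, thickness: int = 2) -> None:
    from skimage.draw import line

    rr, cc = line(int(round(p0[1])), int(round(p0[0])), int(round(p1[1])), int(round(p1[0])))
    h, w = img.shape
    for dr in range(thickness):
        r = np.clip(rr + dr, 0, h - 1)
        img[r, np.clip(cc, 0, w - 1)] = value


def _draw_disc(img: np.ndarray, center: np.ndarray, radius: float, value: float) -> None:
    from skimage.draw import disk

    rr, cc = disk((center[1], center[0]), radius, shape=img.shape)
    img[rr, cc] = value


def render_empty_arena(cfg: SimulationConfig) -> np.ndarray:
    """The agent-free arena floor (background + bedding texture).

    Deterministic per seed and identical to the floor rendered behind the
    agents by :func:`generate_video`; usable as a pre-experiment
    background model.
    """
    size = cfg.image_size
    background = np.full((size, size), float(cfg.background_intensity))
    if cfg.bedding_sigma > 0:
        # static speckle, bounded to keep the dark-agent contrast invariant
        bg_rng = np.random.default_rng([cfg.seed, 1])
        noise = bg_rng.normal(0.0, cfg.bedding_sigma, size=(size, size))
        background = np.clip(
            background + noise, 2.2 * cfg.agent_intensity + 10, 255
        )
    return background


def generate_video(cfg: SimulationConfig) -> tuple[VideoFrames, GroundTruth]:
    """Render the configured scene and return frames plus ground truth."""
    rng = np.random.default_rng([cfg.seed, 0])
    size = cfg.image_size
    pos, heading = _simulate_motion(cfg, rng)
    background = render_empty_arena(cfg)
    frames = np.zeros((cfg.n_frames, size, size), dtype=np.uint8)
    masks: list[list[np.ndarray]] = []
    snout = np.zeros((cfg.n_frames, cfg.n_agents, 2))
    tailbase = np.zeros((cfg.n_frames, cfg.n_agents, 2))
    half = cfg.body_length / 2
    for f in range(cfg.n_frames):
        img = background.copy()
        frame_masks = []
        for i in range(cfg.n_agents):
            u = np.array([np.cos(heading[f, i]), np.sin(heading[f, i])])
            rear = pos[f, i] - half * u
            front = pos[f, i] + half * u
            m = _capsule_mask((size, size), rear, front, cfg.rear_radius, cfg.front_radius)
            img[m] = cfg.agent_intensity
            frame_masks.append(m)
            snout[f, i] = front + u * cfg.front_radius
            tailbase[f, i] = rear - u * cfg.rear_radius
            if cfg.tether and i == 0:
                tail_tip = tailbase[f, i]
                wall = tail_tip.copy()
                # straight run to the nearest wall
                d = np.array(
                    [tail_tip[0], size - 1 - tail_tip[0], tail_tip[1], size - 1 - tail_tip[1]]
                )
                side = int(np.argmin(d))
                wall[0] = 0 if side == 0 else (size - 1 if side == 1 else wall[0])
                if side >= 2:
                    wall[1] = 0 if side == 2 else size - 1
                _draw_line(img, tail_tip, wall, 235.0, thickness=2)
            if cfg.headstage and i == 0:
                _draw_disc(img, front, cfg.front_radius + 2, 240.0)
        frames[f] = np.clip(np.round(img), 0, 255).astype(np.uint8)
        masks.append(frame_masks)
    video = VideoFrames(frames=frames, fps=cfg.fps)
    gt = GroundTruth(masks=masks, snout=snout, tailbase=tailbase, fps=cfg.fps)
    return video, gt


# ---------------------------------------------------------------------------
# external-keypoint corruption


def corrupt_keypoints(
    gt: GroundTruth,
    p_dropout: float = 0.0,
    q_swap: float = 0.0,
    jitter_sigma: float = 0.0,
    seed: int = 0,
) -> KeypointSet:
    """Emulate an external pose estimator's failure modes.

    Independently per frame and keypoint type, the two animals' points
    are exchanged with probability ``q_swap`` (for more than two agents a
    random pair is exchanged); every surviving point is jittered with
    isotropic Gaussian noise ``jitter_sigma`` and dropped (made invalid)
    with probability ``p_dropout``.
    """
    for name, v in (("p_dropout", p_dropout), ("q_swap", q_swap)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n, k = gt.n_frames, gt.n_agents
    out = {"snout": gt.snout.copy(), "tailbase": gt.tailbase.copy()}
    for f in range(n):
        for key in ("snout", "tailbase"):
            if q_swap and rng.random() < q_swap:
                if k == 2:
                    a, b = 0, 1
                else:
                    a, b = rng.choice(k, size=2, replace=False)
                out[key][f, [a, b]] = out[key][f, [b, a]]
    for key in ("snout", "tailbase"):
        if jitter_sigma:
            out[key] += rng.normal(0.0, jitter_sigma, size=out[key].shape)
        if p_dropout:
            drop = rng.random(size=(n, k)) < p_dropout
            out[key][drop] = np.nan
    return KeypointSet.from_arrays(out["snout"], out["tailbase"], source="external")
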