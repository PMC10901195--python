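"""Shared fixtures: desk-scale arenas and teardrop mask helpers.

Unit and integration tests run on 256-px arenas with agents scaled down
proportionally from the 540-px default, which keeps the full pipeline
fast while preserving every geometric relation (contrast, taper, episode
structure).  Pixel thresholds in the arena config are scaled by the same
factor.
"""

from __future__ import annotations

import numpy as np
import pytest

from mousetrack.io import ArenaConfig
from mousetrack.simulate import SimulationConfig, _capsule_mask

REFERENCE_SIZE = 540


def desk_arena(image_size: int = 256, **overrides) -> ArenaConfig:
    """ArenaConfig with pixel thresholds scaled from the 540-px defaults."""
    k = image_size / REFERENCE_SIZE
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


def desk_sim(seed: int, image_size: int = 256, **overrides) -> SimulationConfig:
    sim = SimulationConfig(seed=seed, **overrides)
    return sim.scaled(image_size)


def teardrop(
    shape=(128, 128),
    center=(64.0, 64.0),
    heading: float = 0.0,
    body_length: float = 34.0,
    rear_radius: float = 10.0,
    front_radius: float = 4.0,
) -> np.ndarray:
    """A single mouse-shaped (tapered-capsule) mask; heading in radians."""
    u = np.array([np.cos(heading), np.sin(heading)])
    c = np.asarray(center, dtype=float)
    rear = c - u * body_length / 2
    front = c + u * body_length / 2
    return _capsule_mask(shape, rear, front, rear_radius, front_radius)


@pytest.fixture
def arena() -> ArenaConfig:
    return desk_arena()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
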