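"""Input/output: videos, keypoint tables, mask archives, configuration.

Coordinate convention used throughout the package: ``x`` is the column
index, ``y`` the row index, both 0-based, with pixel centers at integer
coordinates.  Identity labels are integers ``0..n_animals-1`` assigned at
the first tracked frame (identity 0 = mask with the smallest centroid x,
ties broken by smallest centroid y).
"""

from __future__ import annotations

import dataclasses
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VideoFrames",
    "ArenaConfig",
    "KeypointSet",
    "read_video",
    "write_video",
    "read_keypoint_table",
    "write_keypoint_table",
    "encode_rle",
    "decode_rle",
    "write_mask_archive",
    "read_mask_archive",
]

#: columns of the native keypoint CSV, in order
NATIVE_COLUMNS = [
    "frame",
    "animal",
    "snout_x",
    "snout_y",
    "tailbase_x",
    "tailbase_y",
    "source",
    "valid",
]

#: decimal places used when serialising coordinates
COORD_DECIMALS = 3


@dataclass
class VideoFrames:
    """A grayscale frame stack with its frame rate.

    ``frames`` has shape ``(n_frames, H, W)`` and dtype uint8.
    """

    frames: np.ndarray
    fps: float = 30.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, H, W) stack")
        if self.frames.shape[0] < 1:
            raise ValueError("need at least one frame")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def frame_count(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class ArenaConfig:
    """Arena geometry and all tunable thresholds of the pipeline.

    Distances are in pixels; rates in pixels/second.  ``conf_min`` and
    ``area_frac_min`` parametrise the segmentation failure filter: a frame
    fails when any kept mask confidence is below ``conf_min`` or any kept
    mask area is below ``area_frac_min`` times the largest kept area.
    """

    n_animals: int = 2
    floor_roi: list[tuple[float, float]] | None = None  # polygon, (x, y)
    pckh_threshold_px: float = 15.0
    sniff_threshold_px: float = 25.0
    touch_threshold_px: float = 25.0
    stationary_speed_px_s: float = 15.0
    conf_min: float = 0.9
    area_frac_min: float = 0.2
    min_component_area: int = 200
    use_conventional: bool = True
    bg_method: str = "temporal_median"
    bg_frames: int = 300
    floor_margin_px: int = 10  # used when floor_roi is None

    def __post_init__(self) -> None:
        if self.n_animals < 2:
            raise ValueError("n_animals must be at least 2")
        for name in (
            "pckh_threshold_px",
            "sniff_threshold_px",
            "touch_threshold_px",
            "stationary_speed_px_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.conf_min <= 1:
            raise ValueError("conf_min must be in (0, 1]")
        if not 0 < self.area_frac_min < 1:
            raise ValueError("area_frac_min must be in (0, 1)")

    def floor_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean floor mask for an ``(H, W)`` image.

        When no polygon is configured, the floor defaults to the full frame
        eroded by ``floor_margin_px`` on each side.
        """
        h, w = shape
        if self.floor_roi is None:
            m = np.zeros((h, w), dtype=bool)
            k = self.floor_margin_px
            m[k : h - k, k : w - k] = True
            return m
        from skimage.draw import polygon

        xs = [p[0] for p in self.floor_roi]
        ys = [p[1] for p in self.floor_roi]
        rr, cc = polygon(ys, xs, shape=(h, w))
        m = np.zeros((h, w), dtype=bool)
        m[rr, cc] = True
        return m

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ArenaConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if data.get("floor_roi") is not None:
            data["floor_roi"] = [tuple(p) for p in data["floor_roi"]]
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        if data["floor_roi"] is not None:
            data["floor_roi"] = [list(p) for p in data["floor_roi"]]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


class KeypointSet:
    """Per-frame, per-identity snout and tail-base coordinates.

    Backed by a DataFrame with the native columns (``frame``, ``animal``,
    ``snout_x``, ``snout_y``, ``tailbase_x``, ``tailbase_y``, ``source``,
    ``valid``).  Exactly one record exists per (frame, animal); missing
    data is represented by ``valid=False`` records, never by absent rows.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = [c for c in NATIVE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"keypoint table missing columns: {missing}")
        df = df[NATIVE_COLUMNS]
        df["frame"] = df["frame"].astype(int)
        df["animal"] = df["animal"].astype(int)
        df["valid"] = df["valid"].astype(bool)
        if df.duplicated(subset=["frame", "animal"]).any():
            dup = df[df.duplicated(subset=["frame", "animal"], keep=False)]
            pairs = sorted(set(zip(dup["frame"], dup["animal"])))
            raise ValueError(f"duplicate (frame, animal) records: {pairs[:5]}")
        self.df = df.sort_values(["frame", "animal"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KeypointSet):
            return NotImplemented
        return self.df.equals(other.df)

    @property
    def frames(self) -> np.ndarray:
        return np.unique(self.df["frame"].to_numpy())

    @property
    def animals(self) -> np.ndarray:
        return np.unique(self.df["animal"].to_numpy())

    def record(self, frame: int, animal: int) -> pd.Series:
        sel = self.df[(self.df["frame"] == frame) & (self.df["animal"] == animal)]
        if len(sel) == 0:
            raise KeyError(f"no record for frame={frame}, animal={animal}")
        return sel.iloc[0]

    def coords(self, keypoint: str) -> np.ndarray:
        """(n_frames, n_animals, 2) array of x, y for 'snout' or 'tailbase'.

        Invalid records yield NaN.  Frames and animals are taken from the
        sorted unique values present in the table.
        """
        key = {"snout": ("snout_x", "snout_y"), "tailbase": ("tailbase_x", "tailbase_y")}[
            keypoint
        ]
        frames = self.frames
        animals = self.animals
        out = np.full((len(frames), len(animals), 2), np.nan)
        fidx = {f: i for i, f in enumerate(frames)}
        aidx = {a: i for i, a in enumerate(animals)}
        for row in self.df.itertuples(index=False):
            i, j = fidx[row.frame], aidx[row.animal]
            if row.valid:
                out[i, j, 0] = getattr(row, key[0])
                out[i, j, 1] = getattr(row, key[1])
        return out

    def centers(self) -> np.ndarray:
        """Midpoint between snout and tail-base, (n_frames, n_animals, 2)."""
        return 0.5 * (self.coords("snout") + self.coords("tailbase"))

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "KeypointSet":
        if len(records) == 0:
            return cls(pd.DataFrame(columns=NATIVE_COLUMNS))
        return cls(pd.DataFrame.from_records(list(records)))

    @classmethod
    def from_arrays(
        cls,
        snout: np.ndarray,
        tailbase: np.ndarray,
        source: str = "MD",
        valid: np.ndarray | None = None,
        frames: np.ndarray | None = None,
    ) -> "KeypointSet":
        """Build from (n_frames, n_animals, 2) snout/tailbase arrays."""
        n_frames, n_animals = snout.shape[:2]
        if frames is None:
            frames = np.arange(n_frames)
        if valid is None:
            valid = ~(
                np.isnan(snout).any(axis=2) | np.isnan(tailbase).any(axis=2)
            )
        recs = []
        for i in range(n_frames):
            for a in range(n_animals):
                recs.append(
                    {
                        "frame": int(frames[i]),
                        "animal": a,
                        "snout_x": round(float(snout[i, a, 0]), COORD_DECIMALS),
                        "snout_y": round(float(snout[i, a, 1]), COORD_DECIMALS),
                        "tailbase_x": round(float(tailbase[i, a, 0]), COORD_DECIMALS),
                        "tailbase_y": round(float(tailbase[i, a, 1]), COORD_DECIMALS),
                        "source": source,
                        "valid": bool(valid[i, a]),
                    }
                )
        return cls.from_records(recs)


# ---------------------------------------------------------------------------
# video I/O


def read_video(path: str | Path, fps: float | None = None) -> VideoFrames:
    """Read a video into a grayscale frame stack.

    Multi-page TIFF stacks are read via tifffile (frame rate from a JSON
    sidecar ``<path>.meta.json`` when present, else the ``fps`` argument,
    else 30).  Other containers (AVI/MP4/...) are read through imageio when
    a decoding plugin is available.  Color frames are converted to
    luminance (ITU-R 601).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"video file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        try:
            frames = tifffile.imread(path)
        except Exception as exc:  # pragma: no cover - corrupt-file path
            raise IOError(f"could not decode video {path}: {exc}") from exc
        if frames.ndim == 2:
            frames = frames[None]
        meta = path.with_name(path.name + ".meta.json")
        if fps is None and meta.exists():
            fps = float(json.loads(meta.read_text()).get("fps", 30.0))
    else:
        import imageio.v3 as iio

        try:
            frames = iio.imread(path, index=None)
        except Exception as exc:
            raise IOError(f"could not decode video {path}: {exc}") from exc
        if fps is None:
            try:
                meta = iio.immeta(path)
                fps = float(meta.get("fps", 30.0))
            except Exception:
                fps = 30.0
    frames = np.asarray(frames)
    if frames.size == 0:
        raise IOError(f"video {path} contains no frames")
    if frames.ndim == 4:  # color -> luminance
        rgb = frames[..., :3].astype(np.float64)
        frames = (
            0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
        )
    frames = np.clip(np.round(frames), 0, 255).astype(np.uint8)
    return VideoFrames(frames=frames, fps=float(fps if fps else 30.0))


def write_video(video: VideoFrames, path: str | Path) -> None:
    """Write a frame stack as a multi-page TIFF with an fps sidecar."""
    path = Path(path)
    if path.suffix.lower() not in (".tif", ".tiff"):
        raise ValueError("write_video writes TIFF stacks; use a .tif path")
    import tifffile

    tifffile.imwrite(path, video.frames)
    meta = path.with_name(path.name + ".meta.json")
    meta.write_text(json.dumps({"fps": video.fps}))


# ---------------------------------------------------------------------------
# keypoint tables


def write_keypoint_table(kps: KeypointSet, path: str | Path) -> None:
    """Write the native CSV; read_keypoint_table() reproduces it exactly.

    Coordinates are written as decimal text with 3 places, so round-trip
    identity holds for values already at that precision.
    """
    df = kps.df.copy()
    fmt = f"%.{COORD_DECIMALS}f"
    df.to_csv(path, index=False, float_format=fmt)


def read_keypoint_table(path: str | Path, dialect: str = "native") -> KeypointSet:
    """Read a keypoint table.

    dialect='native': the package's own CSV schema.
    dialect='pose-table': the multi-row-header CSV emitted by common
    multi-animal pose estimators (scorer / individuals / bodyparts / coords
    header rows); only the snout and tail-base body parts are consumed,
    extra body parts are ignored.  Missing cells become ``valid=False``
    records, never dropped rows.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"keypoint table not found: {path}")
    if dialect == "native":
        df = pd.read_csv(path)
        if len(df) == 0:
            return KeypointSet(pd.DataFrame(columns=NATIVE_COLUMNS))
        return KeypointSet(df)
    if dialect == "pose-table":
        return _read_pose_table(path)
    raise ValueError(f"unknown keypoint table dialect: {dialect!r}")


_SNOUT_NAMES = {"snout", "nose"}
_TAIL_NAMES = {"tailbase", "tail_base", "tail-base"}


def _read_pose_table(path: Path) -> KeypointSet:
    raw = pd.read_csv(path, header=[0, 1, 2, 3], index_col=0)
    # columns: (scorer, individual, bodypart, coord)
    individuals = sorted({c[1] for c in raw.columns})
    track_ids = {name: i for i, name in enumerate(individuals)}
    recs = []
    seen = set()
    for frame, row in raw.iterrows():
        frame = int(frame)
        for name, animal in track_ids.items():
            if (frame, animal) in seen:
                raise ValueError(
                    f"duplicate (frame, track) row: frame={frame}, track={name}"
                )
            seen.add((frame, animal))
            vals = {}
            ok = True
            for part, keys in (("snout", _SNOUT_NAMES), ("tailbase", _TAIL_NAMES)):
                hit = [
                    c
                    for c in raw.columns
                    if c[1] == name
                    and c[2].lower().replace(" ", "") in keys
                    and c[3] in ("x", "y")
                ]
                xs = [c for c in hit if c[3] == "x"]
                ys = [c for c in hit if c[3] == "y"]
                if not xs or not ys:
                    ok = False
                    vals[f"{part}_x"] = np.nan
                    vals[f"{part}_y"] = np.nan
                    continue
                x, y = row[xs[0]], row[ys[0]]
                if pd.isna(x) or pd.isna(y):
                    ok = False
                vals[f"{part}_x"] = float(x) if not pd.isna(x) else np.nan
                vals[f"{part}_y"] = float(y) if not pd.isna(y) else np.nan
            recs.append(
                {
                    "frame": frame,
                    "animal": animal,
                    "snout_x": vals["snout_x"],
                    "snout_y": vals["snout_y"],
                    "tailbase_x": vals["tailbase_x"],
                    "tailbase_y": vals["tailbase_y"],
                    "source": "external",
                    "valid": ok,
                }
            )
    return KeypointSet.from_records(recs)


# ---------------------------------------------------------------------------
# RLE mask archives


def encode_rle(mask: np.ndarray) -> dict:
    """Run-length encode a binary mask (row-major runs of foreground)."""
    flat = np.asarray(mask, dtype=bool).ravel()
    # run starts/ends over the padded difference signal
    diff = np.diff(np.concatenate(([0], flat.view(np.uint8), [0])))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    runs = np.column_stack([starts, ends - starts])
    return {"shape": list(mask.shape), "runs": runs.astype(int).tolist()}


def decode_rle(rle: dict) -> np.ndarray:
    shape = tuple(rle["shape"])
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    for start, length in rle["runs"]:
        flat[start : start + length] = True
    return flat.reshape(shape)


def write_mask_archive(path: str | Path, entries: Sequence[dict]) -> None:
    """Write per-frame masks to a zip with a JSON index.

    Each entry: {frame, identity, mask, confidence, source}; the mask is
    RLE-encoded into the index.
    """
    index = []
    for e in entries:
        index.append(
            {
                "frame": int(e["frame"]),
                "identity": int(e["identity"]),
                "rle": encode_rle(e["mask"]),
                "confidence": float(e.get("confidence", 1.0)),
                "source": str(e.get("source", "unknown")),
            }
        )
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("index.json", json.dumps({"masks": index}))


def read_mask_archive(path: str | Path) -> list[dict]:
    with zipfile.ZipFile(path) as zf:
        index = json.loads(zf.read("index.json"))
    out = []
    for e in index["masks"]:
        out.append(
            {
                "frame": e["frame"],
                "identity": e["identity"],
                "mask": decode_rle(e["rle"]),
                "confidence": e["confidence"],
                "source": e["source"],
            }
        )
    return out
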