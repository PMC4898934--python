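"""Movie/table input-output and run configuration.

A :class:`Movie` is a two-channel time-lapse stack (kinetochore marker +
geminin/chromatin) with spatial and temporal calibration.  Movies travel as
multi-page TIFF with axis order T-C-Y-X and a YAML sidecar holding the
calibration; tables are plain UTF-8 CSV with '.' decimals.

Coordinates are 0-based and pixel-centered; frame k is at time
``k * frame_interval`` minutes from frame 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

log = logging.getLogger(__name__)

#: Calibration applied when no sidecar is found.
DEFAULT_PIXEL_SIZE_UM = 0.2
DEFAULT_FRAME_INTERVAL_MIN = 2.0

DEFAULT_CHANNEL_ROLES = {"kinetochore": 0, "geminin": 1}


@dataclass
class Movie:
    """Two-channel time-lapse stack with calibration.

    Parameters
    ----------
    pixels
        Non-negative intensities, shape (T, C, Y, X).
    pixel_size
        Lateral calibration in µm per pixel.
    frame_interval
        Time between frames in minutes.
    channel_roles
        Mapping from role name ("kinetochore", "geminin") to channel index.
    """

    pixels: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval: float = DEFAULT_FRAME_INTERVAL_MIN
    channel_roles: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_ROLES))

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ValueError(f"movie pixels must be T x C x Y x X, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 2:
            raise ValueError("T >= 2 required")
        if not np.issubdtype(self.pixels.dtype, np.number):
            raise ValueError("non-numeric pixels")
        if np.any(self.pixels < 0):
            raise ValueError("negative intensities")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("calibration must be positive")
        for role in ("kinetochore", "geminin"):
            if role not in self.channel_roles:
                raise ValueError(f"channel role {role!r} not assigned")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame times in minutes from frame 0."""
        return np.arange(self.n_frames) * self.frame_interval

    def channel(self, role: str) -> np.ndarray:
        """All frames of one channel, shape (T, Y, X)."""
        return self.pixels[:, self.channel_roles[role]]

    def frame(self, role: str, k: int) -> np.ndarray:
        return self.pixels[k, self.channel_roles[role]]


@dataclass
class RunConfig:
    """Detector parameters and batch paths shared across pipeline stages."""

    input_dir: str | None = None
    output_dir: str = "results"
    seed: int = 0
    threshold_method: str = "otsu"
    min_focus_area: int = 4
    profile_bins: int = 100
    bridge_offset_min: float = 4.0
    presets: list = field(default_factory=list)

    def __post_init__(self):
        if self.min_focus_area < 1:
            raise ValueError("min_focus_area must be >= 1")
        if self.profile_bins < 2:
            raise ValueError("profile_bins must be >= 2")
        if self.bridge_offset_min <= 0:
            raise ValueError("bridge_offset_min must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def sidecar_path(movie_path) -> Path:
    return Path(movie_path).with_suffix(".yaml")


def write_movie(movie: Movie, path) -> None:
    """Write a movie as multi-page TIFF (T-C-Y-X) plus a YAML sidecar."""
    path = Path(path)
    tifffile.imwrite(path, movie.pixels.astype(np.float32), imagej=False)
    meta = {
        "pixel_size_um": float(movie.pixel_size),
        "frame_interval_min": float(movie.frame_interval),
        "channel_roles": {k: int(v) for k, v in movie.channel_roles.items()},
        "axes": "TCYX",
    }
    with open(sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_movie(path, sidecar=None) -> Movie:
    """Read a TIFF movie and attach calibration from its YAML sidecar.

    When the sidecar is absent, documented defaults (0.2 µm px, 2 min
    frames) are applied and a warning is logged.
    """
    path = Path(path)
    pixels = tifffile.imread(path)
    if pixels.ndim == 3:  # single-channel stack: no role mapping possible
        raise ValueError("axis mismatch: expected T x C x Y x X (2-channel stack)")
    if pixels.ndim != 4:
        raise ValueError(f"axis mismatch: expected 4 axes, got {pixels.ndim}")
    sidecar = Path(sidecar) if sidecar is not None else sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
        pixel_size = float(meta.get("pixel_size_um", DEFAULT_PIXEL_SIZE_UM))
        frame_interval = float(meta.get("frame_interval_min", DEFAULT_FRAME_INTERVAL_MIN))
        roles = meta.get("channel_roles", dict(DEFAULT_CHANNEL_ROLES))
    else:
        log.warning(
            "no sidecar for %s; using defaults pixel_size=%.3g um, frame_interval=%.3g min",
            path, DEFAULT_PIXEL_SIZE_UM, DEFAULT_FRAME_INTERVAL_MIN,
        )
        warnings.warn(f"no calibration sidecar for {path}; defaults applied")
        pixel_size = DEFAULT_PIXEL_SIZE_UM
        frame_interval = DEFAULT_FRAME_INTERVAL_MIN
        roles = dict(DEFAULT_CHANNEL_ROLES)
    return Movie(pixels=pixels, pixel_size=pixel_size, frame_interval=frame_interval,
                 channel_roles=roles)


def write_table(records, path) -> pd.DataFrame:
    """Write records (list of dicts or DataFrame) as a UTF-8 CSV with header.

    An empty record list yields a header-only CSV when the columns are
    known (DataFrame input) or an empty file with no rows otherwise.
    Columns mixing numeric and non-numeric values are rejected.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    for col in df.columns:
        if df[col].dtype == object:
            kinds = {type(v) for v in df[col].dropna()}
            has_num = any(issubclass(k, (int, float, np.number)) and not issubclass(k, bool)
                          for k in kinds)
            has_str = any(issubclass(k, str) for k in kinds)
            if has_num and has_str:
                raise ValueError(f"mixed-type column {col!r}")
    df.to_csv(path, index=False, encoding="utf-8")
    return df


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
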