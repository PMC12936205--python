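"""Image-stack container and disk formats.

Movies are exchanged as multi-page TIFF (ImageJ-style metadata), feature and
track tables as CSV, geometry and summaries as JSON.  All intermediate
coordinates are in pixels; physical units enter only through the stack
metadata (``pixel_size`` in nm/px, ``frame_interval`` in s).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


@dataclasses.dataclass
class ImageStack:
    """A single-channel time-lapse movie.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Intensity data, non-negative.
    pixel_size : float
        Lateral pixel size in nm/px.
    frame_interval : float
        Time between frames in seconds.
    channel : str
        Free-form channel label (e.g. ``"tcr"`` or ``"actin"``).
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    channel: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.frames.shape[0] < 2:
            raise ValueError("a movie needs at least 2 frames")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")
        if np.min(self.frames) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self):
        return self.frames.shape

    def save_tiff(self, path) -> None:
        """Write as ImageJ-style multi-page TIFF with physical metadata."""
        px_um = self.pixel_size / 1000.0
        frames = np.asarray(self.frames)
        if frames.dtype not in (np.uint8, np.uint16, np.float32):
            frames = frames.astype(np.float32)  # ImageJ TIFF compatibility
        tifffile.imwrite(
            path,
            frames,
            imagej=True,
            resolution=(1.0 / px_um, 1.0 / px_um),
            metadata={
                "axes": "TYX",
                "finterval": self.frame_interval,
                "unit": "um",
                "channel": self.channel,
            },
        )

    @classmethod
    def load_tiff(cls, path, channel: str = "") -> "ImageStack":
        with tifffile.TiffFile(path) as tf:
            frames = tf.asarray()
            meta = tf.imagej_metadata or {}
            page = tf.pages[0]
            # XResolution is stored as pixels per unit (um)
            try:
                xres = page.tags["XResolution"].value
                pixel_size = 1000.0 * xres[1] / xres[0]
            except (KeyError, ZeroDivisionError):
                pixel_size = 1.0
            frame_interval = float(meta.get("finterval", 1.0))
            channel = channel or str(meta.get("channel", ""))
        return cls(frames, pixel_size, frame_interval, channel)


def write_features_csv(features: pd.DataFrame, path) -> None:
    cols = [c for c in ("frame", "x", "y", "intensity", "size") if c in features]
    features.to_csv(path, index=False, columns=cols)


def read_features_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
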