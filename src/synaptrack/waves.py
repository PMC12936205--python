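"""Actin wavefront detection and TCR--wavefront colocalization.

Wavefronts are delineated per frame by band-pass Sobel edge detection: the
8-bit actin frame is smoothed with a 5x5 Gaussian kernel, the Sobel
gradient magnitude is computed, and pixels whose gradient lies between a
minimum (10 AU) and maximum (40 AU) bound are kept as edge pixels.  The
lower bound suppresses speckle noise; the upper bound rejects saturated
boundaries such as the cell edge.

A TCR is colocalized with a wavefront at a time point when any edge pixel
lies within the 8 nearest pixel neighbors of its rounded position
(a 3x3 Chebyshev neighborhood; one pixel is ~42 nm, so the diagonal
neighbor distance is ~59 nm, i.e. a ~60 nm capture radius).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .geometry import CellGeometry
from .io import ImageStack
from .detection import to_8bit

__all__ = ["WavefrontSet", "detect_wavefront", "detect_wavefronts", "tcr_wave_colocalization"]


@dataclasses.dataclass
class WavefrontSet:
    """Edge-pixel coordinates of actin wavefronts in one frame."""

    frame: int
    edges: np.ndarray  # (N, 2) int array of (x, y); may be empty
    gradient_bounds: tuple[float, float] = (10.0, 40.0)

    def edge_image(self, shape) -> np.ndarray:
        img = np.zeros(shape, dtype=bool)
        if len(self.edges):
            img[self.edges[:, 1], self.edges[:, 0]] = True
        return img


def _smooth_5x5(frame: np.ndarray) -> np.ndarray:
    # 5x5 Gaussian kernel: sigma 1 px truncated at radius 2
    return ndimage.gaussian_filter(np.asarray(frame, dtype=np.float64), sigma=1.0, truncate=2.0)


def detect_wavefront(
    actin_frame: np.ndarray,
    gmin: float = 10.0,
    gmax: float = 40.0,
    mask: np.ndarray | None = None,
    frame_index: int = 0,
) -> WavefrontSet:
    """Band-pass Sobel edge detection on one 8-bit actin frame.

    Pixels with 5x5-smoothed Sobel gradient magnitude in [gmin, gmax]
    (arbitrary units on the 8-bit intensity scale) are returned as edge
    coordinates, optionally restricted to the cell mask.
    """
    if gmin >= gmax:
        raise ValueError("gmin must be smaller than gmax")
    sm = _smooth_5x5(actin_frame)
    gx = ndimage.sobel(sm, axis=1)
    gy = ndimage.sobel(sm, axis=0)
    g = np.hypot(gx, gy)
    sel = (g >= gmin) & (g <= gmax)
    if mask is not None:
        sel &= mask
    ys, xs = np.nonzero(sel)
    return WavefrontSet(frame_index, np.column_stack([xs, ys]).astype(int), (gmin, gmax))


def detect_wavefronts(
    actin: ImageStack,
    geometry: CellGeometry | None = None,
    gmin: float = 10.0,
    gmax: float = 40.0,
) -> list[WavefrontSet]:
    """Per-frame wavefront detection over a whole actin movie."""
    eight = to_8bit(actin)
    mask = geometry.mask if geometry is not None else None
    return [
        detect_wavefront(eight.frames[t], gmin, gmax, mask=mask, frame_index=t)
        for t in range(eight.n_frames)
    ]


def tcr_wave_colocalization(
    tracks,
    wavefronts: list[WavefrontSet],
    shape=None,
    neighborhood_radius: int = 1,
) -> float:
    """Average per-timepoint TCR--wavefront colocalization fraction.

    For every (track, frame) point, the point counts as colocalized iff any
    edge pixel lies within Chebyshev distance ``neighborhood_radius`` (the
    default 1 is the 3x3 / 8-neighbor rule) of the rounded TCR position.
    The returned value pools all time points of all tracks.
    """
    if not tracks:
        raise ValueError("no track points")
    if shape is None:
        n = 0
        for w in wavefronts:
            if len(w.edges):
                n = max(n, w.edges[:, 0].max() + 2, w.edges[:, 1].max() + 2)
        for t in tracks:
            n = int(max(n, np.max(t.x) + 2, np.max(t.y) + 2))
        shape = (n, n)
    by_frame = {w.frame: w for w in wavefronts}
    footprint = np.ones((2 * neighborhood_radius + 1,) * 2, dtype=bool)
    dilated = {}
    hits = 0
    total = 0
    for t in tracks:
        for f, x, y in zip(t.frame, t.x, t.y):
            f = int(f)
            total += 1
            w = by_frame.get(f)
            if w is None or not len(w.edges):
                continue
            if f not in dilated:
                dilated[f] = ndimage.binary_dilation(w.edge_image(shape), structure=footprint)
            xi = int(np.clip(round(x), 0, shape[1] - 1))
            yi = int(np.clip(round(y), 0, shape[0] - 1))
            if dilated[f][yi, xi]:
                hits += 1
    if total == 0:
        raise ValueError("no track points")
    return hits / total
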