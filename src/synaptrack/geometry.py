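"""Cell geometry: synapse footprint, cSMAC, and the analyzable annulus."""

from __future__ import annotations

import dataclasses

import numpy as np


@dataclasses.dataclass
class CellGeometry:
    """Circular synapse footprint with a central actin-depleted cSMAC.

    The analyzable region (``mask``) is the annulus between the cSMAC
    boundary and the cell edge; analysis of receptor transport is restricted
    to it because clusters accumulate and stall inside the cSMAC.

    All lengths are pixels; ``center`` is (x, y) with x = column, y = row,
    origin at the top-left pixel.
    """

    center: tuple[float, float]
    cell_radius: float
    csmac_radius: float
    mask: np.ndarray  # (H, W) bool, True inside the analyzable annulus

    def __post_init__(self) -> None:
        if not self.csmac_radius < self.cell_radius:
            raise ValueError("csmac_radius must be smaller than cell_radius")

    @property
    def shape(self):
        return self.mask.shape

    def radii(self, x, y):
        """Distance of point(s) from the cell center, px."""
        return np.hypot(np.asarray(x) - self.center[0], np.asarray(y) - self.center[1])

    def outward_unit(self, x, y):
        """Outward radial unit vector(s) at the given point(s)."""
        dx = np.asarray(x, dtype=float) - self.center[0]
        dy = np.asarray(y, dtype=float) - self.center[1]
        r = np.hypot(dx, dy)
        r = np.where(r == 0, 1.0, r)
        return dx / r, dy / r

    def contains(self, x, y) -> np.ndarray:
        """True where the point lies inside the analyzable annulus mask."""
        xi = np.clip(np.round(x).astype(int), 0, self.mask.shape[1] - 1)
        yi = np.clip(np.round(y).astype(int), 0, self.mask.shape[0] - 1)
        return self.mask[yi, xi]

    @classmethod
    def disc(cls, shape, center, cell_radius, csmac_radius) -> "CellGeometry":
        """Analytic geometry: perfect annulus mask on a pixel grid."""
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        r = np.hypot(xx - center[0], yy - center[1])
        mask = (r <= cell_radius) & (r > csmac_radius)
        return cls(tuple(center), float(cell_radius), float(csmac_radius), mask)


def radial_normalize(point, geometry: CellGeometry):
    """Map a point to normalized radius r in [0, 1].

    0 corresponds to the cSMAC boundary and 1 to the cell periphery; values
    are clipped into [0, 1].  Raises on degenerate geometry.
    """
    span = geometry.cell_radius - geometry.csmac_radius
    if span <= 0:
        raise ValueError("degenerate geometry: cell_radius <= csmac_radius")
    x, y = point
    r = geometry.radii(x, y)
    return np.clip((r - geometry.csmac_radius) / span, 0.0, 1.0)
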