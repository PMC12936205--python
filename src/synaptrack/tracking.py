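"""Predictive particle linking, track filtering and directional statistics.

Linking uses velocity extrapolation: a track whose last two observed
positions are x(t_-1) and x(t_0) is expected near

    P(t_1) = x(t_0) + v(t_0) (t_1 - t_0),   v(t_0) = (x(t_0) - x(t_-1)) / (t_0 - t_-1)

and candidate features in the next frame are assigned by minimizing total
distance to the predicted positions (optimal bipartite assignment, gated at
``search_range``).  A track with a single observed point predicts zero
velocity.  Tracks survive up to ``memory`` consecutive missed frames.

Downstream statistics follow the experimental conventions: tracks with
end-to-end displacement below 3.5 px (146 nm, ~5% of the cell radius) are
discarded as non-motile debris; direction is classified by comparing first
and last radial distance from the cell center; speed is the mean
frame-to-frame step speed in nm/s.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .geometry import CellGeometry

__all__ = [
    "Track",
    "DirectionalSummary",
    "IntensityHistogram",
    "link",
    "link_nearest_neighbor",
    "filter_motile",
    "classify_direction",
    "track_speed",
    "directional_fraction",
    "intensity_density",
    "tracks_to_dataframe",
]

MOTILE_MIN_DISPLACEMENT_PX = 3.5  # 146 nm at 41.6 nm/px


@dataclasses.dataclass
class Track:
    """One linked trajectory."""

    id: int
    frame: np.ndarray  # int, strictly increasing
    x: np.ndarray
    y: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.frame) and np.any(np.diff(self.frame) <= 0):
            raise ValueError("track frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def end_to_end_px(self) -> float:
        return float(np.hypot(self.x[-1] - self.x[0], self.y[-1] - self.y[0]))

    @property
    def mean_intensity(self) -> float:
        return float(np.mean(self.intensity))


@dataclasses.dataclass
class DirectionalSummary:
    """Anterograde/retrograde composition and speed of a track population."""

    n_tracks: int
    n_anterograde: int
    n_retrograde: int
    n_tie: int
    anterograde_fraction: float
    mean_speed: float  # nm/s over all non-tie tracks
    mean_speed_anterograde: float
    mean_speed_retrograde: float


@dataclasses.dataclass
class IntensityHistogram:
    """Probability density of feature intensities.

    density = frequency / (sum of frequencies * bin width), so that
    sum(density * width) == 1.
    """

    bin_edges: np.ndarray
    densities: np.ndarray


class _Active:
    __slots__ = ("id", "frames", "xs", "ys", "ints", "misses")

    def __init__(self, tid, frame, x, y, inten):
        self.id = tid
        self.frames = [frame]
        self.xs = [x]
        self.ys = [y]
        self.ints = [inten]
        self.misses = 0

    def predict(self, t_next, predictive=True):
        if predictive and len(self.frames) >= 2:
            dt = self.frames[-1] - self.frames[-2]
            vx = (self.xs[-1] - self.xs[-2]) / dt
            vy = (self.ys[-1] - self.ys[-2]) / dt
            lead = t_next - self.frames[-1]
            return self.xs[-1] + vx * lead, self.ys[-1] + vy * lead
        return self.xs[-1], self.ys[-1]


def link(
    features: pd.DataFrame,
    search_range: float = 5.0,
    memory: int = 2,
    min_length: int = 2,
    predictive: bool = True,
) -> list[Track]:
    """Link per-frame features into trajectories.

    Parameters
    ----------
    features : DataFrame with columns frame, x, y and optionally intensity.
    search_range : float
        Maximum distance (px) between a predicted position and an accepted
        feature.
    memory : int
        Number of consecutive frames a track may go undetected.
    min_length : int
        Minimum number of points for a returned track.
    predictive : bool
        If False, predictions use the last position only (nearest-neighbor
        linking); used as a degraded baseline for validation.
    """
    if search_range <= 0:
        raise ValueError("search_range must be > 0")
    if "intensity" not in features:
        features = features.assign(intensity=0.0)
    frames = sorted(features["frame"].unique())
    active: list[_Active] = []
    done: list[_Active] = []
    next_id = 0
    by_frame = dict(tuple(features.groupby("frame")))
    for t in frames:
        det = by_frame[t]
        fx = det["x"].to_numpy()
        fy = det["y"].to_numpy()
        fi = det["intensity"].to_numpy()
        assigned_feat = np.zeros(len(fx), dtype=bool)
        assigned_trk = np.zeros(len(active), dtype=bool)
        if active and len(fx):
            preds = np.array([a.predict(t, predictive) for a in active])
            cost = np.hypot(preds[:, 0, None] - fx[None, :], preds[:, 1, None] - fy[None, :])
            big = 1e9
            gated = np.where(cost <= search_range, cost, big)
            rows, cols = linear_sum_assignment(gated)
            for r, c in zip(rows, cols):
                if gated[r, c] >= big:
                    continue
                a = active[r]
                a.frames.append(int(t))
                a.xs.append(float(fx[c]))
                a.ys.append(float(fy[c]))
                a.ints.append(float(fi[c]))
                a.misses = 0
                assigned_feat[c] = True
                assigned_trk[r] = True
        still = []
        for k, a in enumerate(active):
            if assigned_trk[k]:
                still.append(a)
            else:
                a.misses += 1
                if a.misses > memory:
                    done.append(a)
                else:
                    still.append(a)
        active = still
        for c in np.nonzero(~assigned_feat)[0]:
            active.append(_Active(next_id, int(t), float(fx[c]), float(fy[c]), float(fi[c])))
            next_id += 1
    done.extend(active)
    done.sort(key=lambda a: a.id)
    return [
        Track(a.id, a.frames, a.xs, a.ys, a.ints)
        for a in done
        if len(a.frames) >= min_length
    ]


def link_nearest_neighbor(features: pd.DataFrame, search_range: float = 5.0, memory: int = 2) -> list[Track]:
    """Zero-velocity-prediction baseline linker (for cross-validation)."""
    return link(features, search_range, memory, predictive=False)


def filter_motile(tracks: list[Track], min_displacement_px: float = MOTILE_MIN_DISPLACEMENT_PX) -> list[Track]:
    """Drop tracks whose end-to-end displacement is below the cutoff.

    A displacement exactly at the cutoff is kept (only strictly smaller
    displacements are treated as immotile debris).
    """
    return [t for t in tracks if t.end_to_end_px >= min_displacement_px]


def classify_direction(track: Track, geometry: CellGeometry) -> str:
    """'anterograde' if the final radial distance exceeds the initial one,
    'retrograde' if smaller, 'tie' if exactly equal."""
    r0 = geometry.radii(track.x[0], track.y[0])
    r1 = geometry.radii(track.x[-1], track.y[-1])
    if r1 > r0:
        return "anterograde"
    if r1 < r0:
        return "retrograde"
    return "tie"


def track_speed(track: Track, pixel_size: float, frame_interval: float) -> float:
    """Mean frame-to-frame step speed in nm/s (gap-aware)."""
    if len(track) < 2:
        raise ValueError("speed needs at least 2 points")
    steps = np.hypot(np.diff(track.x), np.diff(track.y))  # px
    dts = np.diff(track.frame) * frame_interval  # s
    return float(np.mean(steps * pixel_size / dts))


def directional_fraction(
    tracks: list[Track],
    geometry: CellGeometry,
    pixel_size: float,
    frame_interval: float,
) -> DirectionalSummary:
    """Summarize direction composition and speeds of motile tracks.

    The anterograde fraction is anterograde / (anterograde + retrograde);
    ties are counted but excluded from the fraction.
    """
    if not tracks:
        raise ValueError("no motile tracks")
    labels = [classify_direction(t, geometry) for t in tracks]
    speeds = np.array([track_speed(t, pixel_size, frame_interval) for t in tracks])
    labels = np.array(labels)
    n_a = int(np.sum(labels == "anterograde"))
    n_r = int(np.sum(labels == "retrograde"))
    n_t = int(np.sum(labels == "tie"))
    if n_a + n_r == 0:
        raise ValueError("no directional (non-tie) tracks")
    sel = labels != "tie"
    return DirectionalSummary(
        n_tracks=len(tracks),
        n_anterograde=n_a,
        n_retrograde=n_r,
        n_tie=n_t,
        anterograde_fraction=n_a / (n_a + n_r),
        mean_speed=float(speeds[sel].mean()),
        mean_speed_anterograde=float(speeds[labels == "anterograde"].mean()) if n_a else float("nan"),
        mean_speed_retrograde=float(speeds[labels == "retrograde"].mean()) if n_r else float("nan"),
    )


def intensity_density(
    tracks: list[Track],
    geometry: CellGeometry,
    bins: int = 20,
) -> dict[str, IntensityHistogram]:
    """Per-direction probability density of track mean intensities.

    Bin edges are shared: ``bins`` equal-width bins over the pooled
    intensity range.  Each direction's densities integrate to 1.
    """
    if not tracks:
        raise ValueError("no tracks")
    values = np.array([t.mean_intensity for t in tracks])
    labels = np.array([classify_direction(t, geometry) for t in tracks])
    edges = np.histogram_bin_edges(values, bins=bins)
    out = {}
    for lab in ("anterograde", "retrograde"):
        v = values[labels == lab]
        if len(v) == 0:
            continue
        counts, _ = np.histogram(v, bins=edges)
        width = np.diff(edges)
        dens = counts / (counts.sum() * width)
        out[lab] = IntensityHistogram(edges, dens)
    return out


def tracks_to_dataframe(tracks: list[Track], frame_interval: float = 1.0) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for f, x, y, i in zip(t.frame, t.x, t.y, t.intensity):
            rows.append((t.id, int(f), f * frame_interval, x, y, i))
    return pd.DataFrame(rows, columns=["track_id", "frame", "t_s", "x", "y", "intensity"])
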