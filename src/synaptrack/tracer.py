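"""Phenomenological tracer model of TCR transport at the synapse.

Tracers are featureless particles confined to the synapse plane with a
constitutive retrograde drift (default 50 nm/s, the TCR speed measured in
cells lacking anterograde flow).  At every step a tracer scans a disc of
radius 300 nm around itself and can be carried outward by the actin
machinery in one of two modes:

* **mode 1 (wavefront-coupled)** -- if any wavefront edge coordinate lies
  inside the scan disc, the tracer follows the expanding front outward at
  the front speed; otherwise it moves inward at the default speed.
* **mode 2 (flow-coupled)** -- the PIV vectors whose grid points lie inside
  the scan disc are averaged; if the mean speed exceeds a threshold the
  tracer moves with that mean velocity, otherwise it falls back to the
  default retrograde drift.

Tracers reaching the cSMAC boundary stop moving inward (they may still be
captured and carried outward); they never leave the cell disc.

Model output is compared against reference trajectories through the
outward/inward time distribution: the probability density of the durations
of maximal contiguous outward (inward) runs, histogram-normalized and
smoothed by sampling a Gaussian KDE at the bin points.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import gaussian_kde

from .geometry import CellGeometry

__all__ = [
    "Tracer",
    "DurationDistribution",
    "init_tracers",
    "step_mode1",
    "step_mode2",
    "run_simulation",
    "outward_time_distribution",
    "distribution_mse",
    "estimate_front_speed",
    "mode2_threshold_sweep",
]

DEFAULT_SPEED = 50.0  # nm/s
SCAN_RADIUS = 300.0  # nm


@dataclasses.dataclass
class Tracer:
    x: float  # px
    y: float  # px
    state: str = "free"  # free | wave_coupled | flow_coupled


def init_tracers(n: int, geometry: CellGeometry, seed: int) -> list[Tracer]:
    """n tracers uniformly distributed over the analyzable annulus."""
    if n < 1:
        raise ValueError("need at least one tracer")
    if geometry.cell_radius <= geometry.csmac_radius:
        raise ValueError("degenerate geometry")
    rng = np.random.default_rng(seed)
    r = np.sqrt(rng.uniform(geometry.csmac_radius**2, geometry.cell_radius**2, n))
    th = rng.uniform(0, 2 * np.pi, n)
    cx, cy = geometry.center
    return [Tracer(cx + ri * np.cos(ti), cy + ri * np.sin(ti)) for ri, ti in zip(r, th)]


def _move_radial(tr: Tracer, dr_px: float, geometry: CellGeometry) -> None:
    cx, cy = geometry.center
    r = np.hypot(tr.x - cx, tr.y - cy)
    if r == 0:
        return
    new_r = np.clip(r + dr_px, geometry.csmac_radius, geometry.cell_radius)
    tr.x = cx + (tr.x - cx) * new_r / r
    tr.y = cy + (tr.y - cy) * new_r / r


def step_mode1(
    tracers: list[Tracer],
    wavefront_edges: np.ndarray,
    geometry: CellGeometry,
    dt: float,
    pixel_size: float,
    wave_speed: float,
    default_speed: float = DEFAULT_SPEED,
    scan_radius: float = SCAN_RADIUS,
) -> list[Tracer]:
    """Advance tracers one step against a frame's wavefront edge set.

    ``wavefront_edges`` is an (N, 2) array of (x, y) edge coordinates (px);
    speeds are nm/s, ``scan_radius`` nm.
    """
    scan_px = scan_radius / pixel_size
    tree = cKDTree(wavefront_edges) if len(wavefront_edges) else None
    for tr in tracers:
        coupled = False
        if tree is not None:
            d, _ = tree.query([tr.x, tr.y], k=1)
            coupled = d <= scan_px
        if coupled:
            tr.state = "wave_coupled"
            _move_radial(tr, wave_speed * dt / pixel_size, geometry)
        else:
            tr.state = "free"
            _move_radial(tr, -default_speed * dt / pixel_size, geometry)
    return tracers


def step_mode2(
    tracers: list[Tracer],
    flow_field,
    speed_threshold: float,
    geometry: CellGeometry,
    dt: float,
    pixel_size: float,
    default_speed: float = DEFAULT_SPEED,
    scan_radius: float = SCAN_RADIUS,
) -> list[Tracer]:
    """Advance tracers one step against a frame's PIV flow field.

    The PIV vectors (nm/s) whose grid points fall inside the tracer's scan
    disc are averaged; the tracer moves with the mean velocity when its
    magnitude exceeds ``speed_threshold`` (nm/s), else it drifts inward.
    """
    scan_px = scan_radius / pixel_size
    pts = np.column_stack([flow_field.x, flow_field.y])
    tree = cKDTree(pts) if len(pts) else None
    for tr in tracers:
        vel = None
        if tree is not None:
            idx = tree.query_ball_point([tr.x, tr.y], scan_px)
            if idx:
                mu = float(np.mean(flow_field.u[idx]))
                mv = float(np.mean(flow_field.v[idx]))
                if np.hypot(mu, mv) > speed_threshold:
                    vel = (mu, mv)
        if vel is not None:
            tr.state = "flow_coupled"
            tr.x += vel[0] * dt / pixel_size
            tr.y += vel[1] * dt / pixel_size
            _clamp(tr, geometry)
        else:
            tr.state = "free"
            _move_radial(tr, -default_speed * dt / pixel_size, geometry)
    return tracers


def _clamp(tr: Tracer, geometry: CellGeometry) -> None:
    cx, cy = geometry.center
    r = np.hypot(tr.x - cx, tr.y - cy)
    if r == 0:
        return
    new_r = np.clip(r, geometry.csmac_radius, geometry.cell_radius)
    if new_r != r:
        tr.x = cx + (tr.x - cx) * new_r / r
        tr.y = cy + (tr.y - cy) * new_r / r


def run_simulation(
    mode: int,
    inputs,
    geometry: CellGeometry,
    n_steps: int,
    seed: int,
    pixel_size: float,
    frame_interval: float,
    n_tracers: int = 100,
    default_speed: float = DEFAULT_SPEED,
    scan_radius: float = SCAN_RADIUS,
    wave_speed: float | None = None,
    speed_threshold: float = 0.0,
) -> np.ndarray:
    """Run a tracer simulation and return trajectories.

    Parameters
    ----------
    mode : {1, 2}
    inputs : per-step wavefront edge arrays (mode 1) or FlowFields (mode 2).
        A shorter input list is an error; ``inputs[t]`` drives step t.
    wave_speed : float, optional (mode 1)
        Outward speed followed while wave-coupled (nm/s).  When None it is
        estimated per step from consecutive edge sets
        (:func:`estimate_front_speed`), falling back to ``default_speed``.

    Returns
    -------
    ndarray, shape (n_tracers, n_steps + 1, 2) of (x, y) px positions.
    """
    if len(inputs) < n_steps:
        raise ValueError("inputs shorter than n_steps")
    tracers = init_tracers(n_tracers, geometry, seed)
    traj = np.empty((n_tracers, n_steps + 1, 2))
    traj[:, 0, 0] = [t.x for t in tracers]
    traj[:, 0, 1] = [t.y for t in tracers]
    if mode == 1 and wave_speed is None:
        speeds = estimate_front_speed(inputs, geometry)
    for s in range(n_steps):
        if mode == 1:
            ws = wave_speed if wave_speed is not None else (
                speeds[s] * pixel_size / frame_interval if np.isfinite(speeds[s]) else default_speed
            )
            step_mode1(
                tracers, inputs[s], geometry, frame_interval, pixel_size,
                wave_speed=ws, default_speed=default_speed, scan_radius=scan_radius,
            )
        elif mode == 2:
            step_mode2(
                tracers, inputs[s], speed_threshold, geometry, frame_interval,
                pixel_size, default_speed=default_speed, scan_radius=scan_radius,
            )
        else:
            raise ValueError("mode must be 1 or 2")
        traj[:, s + 1, 0] = [t.x for t in tracers]
        traj[:, s + 1, 1] = [t.y for t in tracers]
    return traj


def estimate_front_speed(edge_sets, geometry: CellGeometry) -> np.ndarray:
    """Per-step outward front speed (px/frame) from consecutive edge sets.

    Each edge pixel at step t is matched to its nearest edge pixel at step
    t+1; the median radial displacement of matches within 3 px estimates the
    expansion speed.  NaN where either set is empty.
    """
    out = np.full(len(edge_sets), np.nan)
    for t in range(len(edge_sets) - 1):
        a, b = np.asarray(edge_sets[t]), np.asarray(edge_sets[t + 1])
        if len(a) == 0 or len(b) == 0:
            continue
        tree = cKDTree(b)
        d, j = tree.query(a, k=1)
        ok = d <= 3.0
        if not ok.any():
            continue
        ra = geometry.radii(a[ok, 0], a[ok, 1])
        rb = geometry.radii(b[j[ok], 0], b[j[ok], 1])
        out[t] = float(np.median(rb - ra))
    return out


# ---------------------------------------------------------------------------
# run-duration distributions
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DurationDistribution:
    """Histogram + KDE-smoothed density of run durations (s)."""

    durations: np.ndarray
    bin_edges: np.ndarray
    densities: np.ndarray
    kde_curve: np.ndarray  # KDE sampled at bin centers

    @classmethod
    def from_durations(cls, durations, bins: int = 15) -> "DurationDistribution":
        durations = np.asarray(durations, dtype=float)
        if len(durations) == 0:
            raise ValueError("no runs found")
        edges = np.histogram_bin_edges(durations, bins=bins)
        if edges[0] == edges[-1]:
            edges = np.array([edges[0] - 0.5, edges[0] + 0.5])
        counts, edges = np.histogram(durations, bins=edges)
        widths = np.diff(edges)
        densities = counts / (counts.sum() * widths)
        centers = 0.5 * (edges[:-1] + edges[1:])
        curve = cls._kde(durations, centers)
        return cls(durations, edges, densities, curve)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @staticmethod
    def _kde(durations, grid):
        durations = np.asarray(durations, dtype=float)
        grid = np.asarray(grid, dtype=float)
        if len(np.unique(durations)) < 2:
            # degenerate sample: narrow Gaussian bump at the single value
            mu = durations[0]
            sigma = max(0.5, 0.05 * max(abs(mu), 1.0))
            return np.exp(-((grid - mu) ** 2) / (2 * sigma**2)) / (sigma * np.sqrt(2 * np.pi))
        kde = gaussian_kde(durations)  # Scott's rule bandwidth
        return kde(grid)

    def kde_at(self, grid) -> np.ndarray:
        """Smoothed density interpolated/evaluated on an arbitrary grid."""
        return self._kde(self.durations, grid)


def _run_lengths(increments: np.ndarray) -> tuple[list[int], list[int]]:
    """Maximal runs of consecutive positive / negative increments.

    Zero increments terminate the current run without starting a new one.
    """
    out_runs, in_runs = [], []
    sign = 0
    length = 0
    for d in increments:
        s = 1 if d > 0 else (-1 if d < 0 else 0)
        if s == sign and s != 0:
            length += 1
        else:
            if sign > 0:
                out_runs.append(length)
            elif sign < 0:
                in_runs.append(length)
            sign = s
            length = 1 if s != 0 else 0
    if sign > 0:
        out_runs.append(length)
    elif sign < 0:
        in_runs.append(length)
    return out_runs, in_runs


def outward_time_distribution(
    trajectories: np.ndarray,
    geometry: CellGeometry,
    dt: float,
    bins: int = 15,
) -> tuple[DurationDistribution, DurationDistribution]:
    """Outward and inward run-duration distributions of trajectories.

    ``trajectories`` has shape (n, T, 2) in px.  Runs are maximal stretches
    of consecutive steps with positive (outward) or negative (inward) radial
    increments; run lengths are multiplied by ``dt`` and pooled over all
    trajectories.

    Returns
    -------
    (outward, inward) : DurationDistribution pair.  Raises if a direction
    has no runs at all.
    """
    trajectories = np.asarray(trajectories, dtype=float)
    if trajectories.ndim != 3 or trajectories.shape[1] < 2:
        raise ValueError("need trajectories of at least 2 points")
    out_all, in_all = [], []
    for traj in trajectories:
        r = geometry.radii(traj[:, 0], traj[:, 1])
        o, i = _run_lengths(np.diff(r))
        out_all.extend(o)
        in_all.extend(i)
    outward = DurationDistribution.from_durations(np.asarray(out_all) * dt, bins) if out_all else None
    inward = DurationDistribution.from_durations(np.asarray(in_all) * dt, bins) if in_all else None
    if outward is None and inward is None:
        raise ValueError("no runs found")
    return outward, inward


def distribution_mse(d1: DurationDistribution, d2: DurationDistribution) -> float:
    """Mean squared difference of two KDE curves on their common grid.

    The grid is the sorted union of both distributions' bin centers.
    """
    if d1 is None or d2 is None:
        raise ValueError("both distributions must be non-empty")
    grid = np.union1d(d1.bin_centers, d2.bin_centers)
    if len(grid) == 0:
        raise ValueError("no overlap grid")
    return float(np.mean((d1.kde_at(grid) - d2.kde_at(grid)) ** 2))


def mode2_threshold_sweep(
    fields,
    geometry: CellGeometry,
    reference: DurationDistribution,
    thresholds,
    n_steps: int,
    seed: int,
    pixel_size: float,
    frame_interval: float,
    n_tracers: int = 100,
) -> dict[float, float]:
    """Outward-time MSE against a reference for a range of speed thresholds.

    Thresholds whose simulation yields no outward runs at all are scored by
    comparing the reference against a zero density curve (no outward motion
    is maximally distant from any observed outward-time distribution).
    """
    results = {}
    for thr in thresholds:
        traj = run_simulation(
            2, fields, geometry, n_steps, seed, pixel_size, frame_interval,
            n_tracers=n_tracers, speed_threshold=float(thr),
        )
        try:
            outward, _ = outward_time_distribution(traj, geometry, frame_interval)
        except ValueError:
            outward = None
        if outward is None:
            grid = reference.bin_centers
            results[float(thr)] = float(np.mean(reference.kde_at(grid) ** 2))
        else:
            results[float(thr)] = distribution_mse(outward, reference)
    return results
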