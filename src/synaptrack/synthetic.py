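"""Synthetic two-channel synapse movies with known ground truth.

The generator realizes the schematic picture of receptor transport at the
immunological synapse: a circular synapse footprint with an actin-depleted
cSMAC at its center, cortical actin flowing inward (retrograde) through the
surrounding annulus, annular actin wavefronts nucleating at random positions
and expanding outward, and diffraction-limited TCR microclusters that drift
inward by default but can couple to a passing wavefront and ride it outward.

Two products are made from one random draw:

* :class:`GroundTruth` -- exact cluster trajectories, wavefront arcs, the
  analytic flow field, and per-cluster direction labels.  Used as the oracle
  for every downstream stage (detection, linking, PIV, wave detection).
* a rendered movie pair (TCR channel, actin channel) with realistic PSF,
  Poisson photon noise and Gaussian read noise, returned as
  :class:`~synaptrack.io.ImageStack`.

Rendering the actin channel advects a frozen speckle texture with the true
flow so that PIV has matchable image structure.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.ndimage import gaussian_filter as _ndi_gaussian
from scipy.ndimage import map_coordinates
from scipy.special import expit

from .geometry import CellGeometry
from .io import ImageStack
from .profiles import GeneratorProfile

__all__ = ["GroundTruth", "simulate_ground_truth", "render_movie"]

_MIN_SPAWN_SEPARATION_PX = 10.0
_EDGE_MARGIN_PX = 2.0
_CONTACT_DISTANCE_PX = 6.5  # microclusters exclude each other below this
_SPECKLE_SIGMA = (6.0, 10.0)  # (radial, angular) speckle correlation scale
_RIDER_LEAD_PX = 1.0   # coupled clusters sit just ahead of the front crest
_RIDER_RELAX = 0.5     # per-frame relaxation toward the leading edge
_RIDER_MAX_PULL_PX = 1.5  # cap on the per-frame relaxation step
_FRONT_DEATH_FRACTION = 0.92  # fronts dissipate before reaching the membrane
_WAVE_NUCLEATION_MAX_FRACTION = 0.5  # fronts are born in the inner lamella
_RIDGE_SIGMA_PX = 1.2   # sharp polymerization ridge at the wave crest
_RIDGE_AMPLITUDE_RATIO = 0.5  # ridge peak relative to wave_amplitude


@dataclasses.dataclass
class ClusterPath:
    """Realized trajectory of one simulated microcluster."""

    id: int
    frames: np.ndarray  # int, strictly increasing
    x: np.ndarray
    y: np.ndarray
    coupled: np.ndarray  # bool, True while riding a wavefront
    brightness: float = 1.0

    def label(self, center) -> str:
        r0 = math.hypot(self.x[0] - center[0], self.y[0] - center[1])
        r1 = math.hypot(self.x[-1] - center[0], self.y[-1] - center[1])
        if r1 > r0:
            return "anterograde"
        if r1 < r0:
            return "retrograde"
        return "tie"


@dataclasses.dataclass
class WavePath:
    """One expanding wavefront arc: radius grows monotonically until the
    front reaches the cell edge and dies."""

    id: int
    frames: np.ndarray
    radius: np.ndarray  # px, non-decreasing
    theta0: float       # arc center angle, rad
    arc: float          # angular extent, rad

    def edge_coords(self, frame: int, center, spacing_px: float = 1.0):
        """Integer pixel coordinates along the arc at the given frame."""
        idx = np.searchsorted(self.frames, frame)
        if idx >= len(self.frames) or self.frames[idx] != frame:
            return np.empty((0, 2), dtype=int)
        r = self.radius[idx]
        n = max(3, int(self.arc * r / spacing_px))
        th = self.theta0 + np.linspace(-self.arc / 2, self.arc / 2, n)
        pts = np.column_stack(
            [np.round(center[0] + r * np.cos(th)), np.round(center[1] + r * np.sin(th))]
        ).astype(int)
        return np.unique(pts, axis=0)


@dataclasses.dataclass
class GroundTruth:
    """Exact scenario state underlying one rendered movie."""

    profile: GeneratorProfile
    geometry: CellGeometry
    cluster_paths: list
    wavefront_paths: list
    labels: dict  # cluster id -> 'anterograde' | 'retrograde' | 'tie'

    @property
    def n_frames(self) -> int:
        return self.profile.n_frames

    def positions_at(self, frame: int):
        """(id, x, y) arrays of clusters alive in the given frame."""
        ids, xs, ys = [], [], []
        for c in self.cluster_paths:
            idx = np.searchsorted(c.frames, frame)
            if idx < len(c.frames) and c.frames[idx] == frame:
                ids.append(c.id)
                xs.append(c.x[idx])
                ys.append(c.y[idx])
        return np.array(ids), np.array(xs), np.array(ys)

    def true_velocity(self, x, y):
        """Analytic cortical flow (u, v) in nm/s at the given point(s).

        Purely radial, inward at ``profile.retro_speed`` inside the annulus,
        zero elsewhere.
        """
        ux, uy = self.geometry.outward_unit(x, y)
        r = self.geometry.radii(x, y)
        inside = (r > self.geometry.csmac_radius) & (r <= self.geometry.cell_radius)
        s = np.where(inside, -self.profile.retro_speed, 0.0)
        return s * ux, s * uy

    def wavefront_edges_at(self, frame: int) -> np.ndarray:
        """(N, 2) integer (x, y) edge coordinates of all fronts in a frame."""
        parts = [w.edge_coords(frame, self.geometry.center) for w in self.wavefront_paths]
        parts = [p for p in parts if len(p)]
        if not parts:
            return np.empty((0, 2), dtype=int)
        return np.concatenate(parts, axis=0)

    def label_fraction(self) -> float:
        """Anterograde fraction of realized (non-tie) cluster labels."""
        n_a = sum(1 for v in self.labels.values() if v == "anterograde")
        n_r = sum(1 for v in self.labels.values() if v == "retrograde")
        if n_a + n_r == 0:
            raise ValueError("no directional labels")
        return n_a / (n_a + n_r)

    def radial_increments(self):
        """Per-cluster arrays of frame-to-frame radial increments (px)."""
        out = []
        cx, cy = self.geometry.center
        for c in self.cluster_paths:
            if len(c.frames) < 2:
                continue
            r = np.hypot(c.x - cx, c.y - cy)
            out.append(np.diff(r))
        return out


# ---------------------------------------------------------------------------
# ground-truth simulation
# ---------------------------------------------------------------------------

class _Front:
    __slots__ = ("id", "theta0", "arc", "radius", "frames", "radii")

    def __init__(self, fid, theta0, arc, radius):
        self.id = fid
        self.theta0 = theta0
        self.arc = arc
        self.radius = radius
        self.frames = []
        self.radii = []


def _spawn_position(rng, existing_xy, center, r_lo, r_hi, max_tries=60):
    """Area-uniform position in [r_lo, r_hi] keeping clusters separated."""
    for _ in range(max_tries):
        r = math.sqrt(rng.uniform(r_lo**2, r_hi**2))
        th = rng.uniform(0, 2 * math.pi)
        x = center[0] + r * math.cos(th)
        y = center[1] + r * math.sin(th)
        if not existing_xy:
            return x, y
        d2 = min((x - ex) ** 2 + (y - ey) ** 2 for ex, ey in existing_xy)
        if d2 >= _MIN_SPAWN_SEPARATION_PX**2:
            return x, y
    return x, y  # crowded: accept the last draw


def simulate_ground_truth(profile: GeneratorProfile) -> GroundTruth:
    """Realize one cell scenario: cluster paths, wavefronts, labels.

    Clusters drift inward with a per-cluster radial speed drawn from
    ``N(retro_speed, retro_speed_sd)`` plus Brownian positional jitter.  A
    cluster within ``capture_radius`` of an active front couples to it with
    per-frame probability ``coupling_prob`` and then expands outward with the
    front until the front dies at the cell edge.  Clusters reaching the cSMAC
    boundary leave the analyzable annulus and are replaced by a new cluster
    nucleating in the outer annulus, keeping the population steady.
    """
    rng = np.random.default_rng([int(profile.seed) % (2**31), 17])
    px = profile.pixel_size
    dt = profile.frame_interval
    size = profile.image_size
    center = (size / 2.0, size / 2.0)
    R = profile.cell_radius_px
    Rc = profile.csmac_radius_px
    geometry = CellGeometry.disc((size, size), center, R, Rc)

    wave_px = profile.wave_speed * dt / px
    jitter_px = profile.jitter_sd / px
    cap_px = profile.capture_radius / px

    # live cluster state
    paths: list[ClusterPath] = []
    fronts_done: list[_Front] = []
    live = []  # dicts
    next_cid = 0

    def new_cluster(r_lo, r_hi):
        nonlocal next_cid
        x, y = _spawn_position(
            rng, [(c["x"], c["y"]) for c in live], center, r_lo, r_hi
        )
        c = {
            "id": next_cid,
            "x": x,
            "y": y,
            "drift": rng.normal(profile.retro_speed, profile.retro_speed_sd),
            "front": None,
            "brightness": float(rng.lognormal(0.0, 0.2)),
            "frames": [],
            "xs": [],
            "ys": [],
            "coupled": [],
        }
        next_cid += 1
        live.append(c)
        return c

    for _ in range(profile.n_clusters):
        new_cluster(Rc + 4.0, 0.95 * R)

    fronts: list[_Front] = []
    next_fid = 0

    for t in range(profile.n_frames):
        # record state at frame t
        for c in live:
            c["frames"].append(t)
            c["xs"].append(c["x"])
            c["ys"].append(c["y"])
            c["coupled"].append(c["front"] is not None)
        for f in fronts:
            f.frames.append(t)
            f.radii.append(f.radius)

        # nucleate new fronts (visible from the next frame)
        n_new = rng.poisson(profile.wave_nucleation_rate * dt)
        for _ in range(n_new):
            fronts.append(
                _Front(
                    next_fid,
                    rng.uniform(0, 2 * math.pi),
                    profile.wave_arc,
                    rng.uniform(Rc, _WAVE_NUCLEATION_MAX_FRACTION * R),
                )
            )
            next_fid += 1

        # coupling decisions for free clusters
        if profile.coupling_prob > 0 and fronts:
            for c in live:
                if c["front"] is not None:
                    continue
                rc = math.hypot(c["x"] - center[0], c["y"] - center[1])
                thc = math.atan2(c["y"] - center[1], c["x"] - center[0])
                best = None
                for f in fronts:
                    # contact capture: the linkage forms when the front's
                    # leading edge reaches the cluster; clusters ahead of
                    # the crest keep drifting until the crest arrives
                    if not (-cap_px <= rc - f.radius <= _RIDER_LEAD_PX + 1.5):
                        continue
                    dth = (thc - f.theta0 + math.pi) % (2 * math.pi) - math.pi
                    if abs(dth) > f.arc / 2 + cap_px / max(f.radius, 1.0):
                        continue
                    if best is None or abs(rc - f.radius) < abs(rc - best.radius):
                        best = f
                if best is not None and rng.random() < profile.coupling_prob:
                    c["front"] = best

        # advance fronts
        dead_front_objs = set()
        for f in fronts:
            f.radius += wave_px
            if f.radius >= _FRONT_DEATH_FRACTION * R:
                dead_front_objs.add(id(f))
        fronts_next = []
        for f in fronts:
            if id(f) in dead_front_objs:
                fronts_done.append(f)
            else:
                fronts_next.append(f)
        fronts = fronts_next

        # advance clusters
        n_respawn = 0
        survivors = []
        for c in live:
            rc = math.hypot(c["x"] - center[0], c["y"] - center[1])
            ux = (c["x"] - center[0]) / max(rc, 1e-9)
            uy = (c["y"] - center[1]) / max(rc, 1e-9)
            if c["front"] is not None and id(c["front"]) in dead_front_objs:
                c["front"] = None
            if c["front"] is not None:
                # ride the front: advance with it while relaxing toward its
                # leading edge (a pushed cluster sits just ahead of the
                # density crest, not wherever it happened to be captured)
                target = c["front"].radius + _RIDER_LEAD_PX  # radius is already advanced
                pull = _RIDER_RELAX * (target - (rc + wave_px))
                # cap the per-frame pull so the approach to the crest stays
                # a smooth, trackable motion rather than a jump
                dr = wave_px + float(np.clip(pull, -_RIDER_MAX_PULL_PX, _RIDER_MAX_PULL_PX))
            else:
                dr = -c["drift"] * dt / px
            nx = c["x"] + dr * ux + rng.normal(0, jitter_px)
            ny = c["y"] + dr * uy + rng.normal(0, jitter_px)
            nr = math.hypot(nx - center[0], ny - center[1])
            if nr <= Rc + 1.0:
                # absorbed into the cSMAC: leaves the annulus
                n_respawn += 1
                _finalize(paths, c)
                continue
            if nr >= R - _EDGE_MARGIN_PX:
                scale = (R - _EDGE_MARGIN_PX) / nr
                nx = center[0] + (nx - center[0]) * scale
                ny = center[1] + (ny - center[1]) * scale
            c["x"], c["y"] = nx, ny
            survivors.append(c)
        live = survivors
        _resolve_contacts(live, center, R, Rc)
        for _ in range(n_respawn):
            new_cluster(0.55 * R, 0.95 * R)

    for c in live:
        _finalize(paths, c)
    fronts_done.extend(fronts)

    wave_paths = [
        WavePath(f.id, np.asarray(f.frames), np.asarray(f.radii), f.theta0, f.arc)
        for f in fronts_done
        if f.frames
    ]
    wave_paths.sort(key=lambda w: w.id)
    paths.sort(key=lambda p: p.id)
    labels = {
        p.id: p.label(center) for p in paths if len(p.frames) >= 2
    }
    return GroundTruth(profile, geometry, paths, wave_paths, labels)


def _resolve_contacts(live, center, R, Rc, passes: int = 2) -> None:
    """Contact exclusion: clusters closer than the contact distance are
    pushed apart symmetrically (microclusters are extended objects and do
    not interpenetrate at the imaging resolution)."""
    d_min = _CONTACT_DISTANCE_PX
    for _ in range(passes):
        moved = False
        for i in range(len(live)):
            for j in range(i + 1, len(live)):
                a, b = live[i], live[j]
                dx = b["x"] - a["x"]
                dy = b["y"] - a["y"]
                d = math.hypot(dx, dy)
                if d >= d_min or d == 0:
                    continue
                push = (d_min - d) / 2.0
                ux, uy = dx / d, dy / d
                for c, s in ((a, -1.0), (b, 1.0)):
                    nx = c["x"] + s * push * ux
                    ny = c["y"] + s * push * uy
                    r = math.hypot(nx - center[0], ny - center[1])
                    r_clip = min(max(r, Rc + 1.0), R - _EDGE_MARGIN_PX)
                    if r > 0 and r_clip != r:
                        nx = center[0] + (nx - center[0]) * r_clip / r
                        ny = center[1] + (ny - center[1]) * r_clip / r
                    c["x"], c["y"] = nx, ny
                moved = True
        if not moved:
            break


def _finalize(paths, c):
    if not c["frames"]:
        return
    paths.append(
        ClusterPath(
            c["id"],
            np.asarray(c["frames"]),
            np.asarray(c["xs"]),
            np.asarray(c["ys"]),
            np.asarray(c["coupled"], dtype=bool),
            c["brightness"],
        )
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_movie(gt: GroundTruth, profile: GeneratorProfile | None = None):
    """Render a (TCR, actin) ImageStack pair from a ground-truth scenario.

    TCR channel: Gaussian PSF spots at cluster positions over a flat
    background.  Actin channel: cortical intensity (dimmed in the cSMAC)
    carrying an inward-advected frozen speckle texture, plus bright expanding
    wave arcs.  Both channels receive Poisson photon noise and additive
    Gaussian read noise.
    """
    profile = profile or gt.profile
    size = profile.image_size
    if size < 2 * profile.cell_radius_px + 2:
        raise ValueError("image too small to contain the cell disc")
    if gt.geometry.shape != (size, size):
        raise ValueError("ground truth does not match profile dimensions")
    rng = np.random.default_rng([int(profile.seed) % (2**31), 29])
    T = profile.n_frames

    tcr = _render_tcr(gt, profile, rng)
    actin = _render_actin(gt, profile, rng)
    meta = dict(pixel_size=profile.pixel_size, frame_interval=profile.frame_interval)
    return (
        ImageStack(tcr, channel="tcr", **meta),
        ImageStack(actin, channel="actin", **meta),
    )


def _render_tcr(gt, profile, rng):
    size = profile.image_size
    T = profile.n_frames
    expected = np.full((T, size, size), float(profile.background_rate), dtype=np.float64)
    sig = profile.psf_sigma / profile.pixel_size
    half = int(math.ceil(3 * sig))
    ax = np.arange(-half, half + 1)
    for c in gt.cluster_paths:
        amp = profile.cluster_photon_rate * c.brightness
        for f, x, y in zip(c.frames, c.x, c.y):
            ix, iy = int(round(x)), int(round(y))
            gx = np.exp(-((ax + ix - x) ** 2) / (2 * sig**2))
            gy = np.exp(-((ax + iy - y) ** 2) / (2 * sig**2))
            patch = amp / (2 * math.pi * sig**2) * np.outer(gy, gx)
            y0, y1 = max(0, iy - half), min(size, iy + half + 1)
            x0, x1 = max(0, ix - half), min(size, ix + half + 1)
            expected[f, y0:y1, x0:x1] += patch[
                y0 - (iy - half) : y1 - (iy - half), x0 - (ix - half) : x1 - (ix - half)
            ]
    noisy = rng.poisson(expected).astype(np.float64)
    if profile.read_noise_sd > 0:
        noisy += rng.normal(0, profile.read_noise_sd, noisy.shape)
    return np.clip(noisy, 0, None)


def _render_actin(gt, profile, rng):
    size = profile.image_size
    T = profile.n_frames
    cx, cy = gt.geometry.center
    R, Rc = gt.geometry.cell_radius, gt.geometry.csmac_radius
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    rr = np.hypot(xx - cx, yy - cy)
    theta = np.arctan2(yy - cy, xx - cx)

    rate = profile.actin_background_rate
    inner = expit((rr - Rc) / 1.5)          # 0 inside cSMAC -> 1 outside
    outer = expit((R - rr) / 1.5)           # 1 inside cell  -> 0 outside
    base_level = rate * (profile.csmac_dimming + (1 - profile.csmac_dimming) * inner) * outer
    ambient = 2.0

    # frozen speckle texture in polar (radius, angle) coordinates, periodic
    # in the radial direction so inward advection is exact for all t
    period = 96
    n_th = 720
    tex = rng.standard_normal((period, n_th))
    tex = _ndi_gaussian(tex, sigma=_SPECKLE_SIGMA, mode="wrap")
    tex /= tex.std()
    flow_px = profile.retro_speed * profile.frame_interval / profile.pixel_size
    th_idx = (theta % (2 * math.pi)) / (2 * math.pi) * n_th

    # active wavefront (radius, theta0, arc) per frame
    sig_w = profile.wave_width / profile.pixel_size
    fronts_by_frame = [[] for _ in range(T)]
    for w in gt.wavefront_paths:
        for f, r in zip(w.frames, w.radius):
            fronts_by_frame[f].append((r, w.theta0, w.arc))

    expected = np.empty((T, size, size), dtype=np.float64)
    contrast = profile.actin_speckle_contrast
    for t in range(T):
        u_idx = (rr + flow_px * t) % period
        sp = map_coordinates(tex, [u_idx, th_idx], order=1, mode="grid-wrap")
        frame = base_level * (1.0 + contrast * sp) + ambient
        for r_f, th0, arc in fronts_by_frame[t]:
            dth = (theta - th0 + math.pi) % (2 * math.pi) - math.pi
            # Gaussian angular envelope (arc = FWHM): the arc ends fade
            # gently instead of forming steep tangential walls
            sig_th = arc / 2.355
            env = np.exp(-(dth**2) / (2 * sig_th**2))
            if not env.any():
                continue
            body = np.exp(-((rr - r_f) ** 2) / (2 * sig_w**2))
            ridge = _RIDGE_AMPLITUDE_RATIO * np.exp(
                -((rr - r_f) ** 2) / (2 * _RIDGE_SIGMA_PX**2)
            )
            frame += profile.wave_amplitude * rate * (body + ridge) * env * outer
        expected[t] = frame
    noisy = rng.poisson(np.clip(expected, 0, None)).astype(np.float64)
    if profile.read_noise_sd > 0:
        noisy += rng.normal(0, profile.read_noise_sd, noisy.shape)
    return np.clip(noisy, 0, None)
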