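"""Ground-truth scenario profiles for the synthetic movie generator.

A :class:`GeneratorProfile` holds every tunable parameter of one simulated
synapse: geometry, cortical-flow kinematics, actin-wave kinematics,
cluster--wave coupling, and camera/rendering settings.  The named profiles
encode the cell types studied experimentally:

``primary``
    Primary CD8+ T cell: retrograde cortical flow plus outward-expanding
    actin wavefronts; clusters near a front can couple to it and move
    outward, producing an anterograde track fraction of about 0.43.
``jurkat``
    Jurkat T-cell line: no actin waves (``wave_nucleation_rate = 0``); the
    residual anterograde fraction of about 0.11 arises from heterogeneity in
    per-cluster radial drift.
``wasp_ko``
    WASP-deficient primary cell: waves are present but the cluster--wave
    coupling probability is strongly reduced (anterograde fraction ~0.19).
``ck666``
    Arp2/3-inhibited primary cell: wave coupling essentially unchanged
    (anterograde fraction ~0.45).

Coupling probabilities were calibrated once by simulation sweep against the
target anterograde fractions and are frozen here; see ``docs/methods.md``.
"""

from __future__ import annotations

import dataclasses
import math

__all__ = ["GeneratorProfile", "make_profile", "PROFILE_NAMES"]


@dataclasses.dataclass
class GeneratorProfile:
    """All ground-truth parameters of one simulated cell scenario.

    Lengths are nm, times s, speeds nm/s, rates events/s unless noted.
    """

    name: str = "custom"
    # --- acquisition geometry ---
    pixel_size: float = 41.6          # nm/px
    frame_interval: float = 1.0       # s
    n_frames: int = 200
    cell_radius: float = 3000.0       # nm
    csmac_radius: float = 750.0       # nm
    # --- cluster kinematics ---
    retro_speed: float = 45.0         # nm/s, mean inward drift
    retro_speed_sd: float = 8.0       # nm/s, per-cluster drift spread
    jitter_sd: float = 8.0            # nm per step, Brownian positional jitter
    # --- wave kinematics ---
    wave_speed: float = 40.0          # nm/s outward front expansion
    wave_nucleation_rate: float = 0.10   # fronts/s
    wave_arc: float = 1.8             # rad, angular extent of a front
    wave_width: float = 330.0         # nm, Gaussian front thickness
    # --- coupling ---
    coupling_prob: float = 0.0        # per-frame P(couple | within capture range)
    capture_radius: float = 300.0     # nm
    # --- rendering ---
    n_clusters: int = 25
    cluster_photon_rate: float = 1500.0   # photons/frame/cluster
    psf_sigma: float = 60.0           # nm (TIRF-SIM scale resolution)
    background_rate: float = 30.0     # photons/px/frame (TCR channel)
    read_noise_sd: float = 2.0        # intensity units
    actin_background_rate: float = 6000.0  # photons/px/frame, lamellar cortex
    actin_speckle_contrast: float = 0.06  # relative speckle amplitude
    csmac_dimming: float = 0.30       # cSMAC actin level / lamellar level
    wave_amplitude: float = 0.15      # wave-body brightness / lamellar level
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = (
            "pixel_size frame_interval cell_radius csmac_radius retro_speed "
            "wave_speed wave_width capture_radius cluster_photon_rate psf_sigma"
        ).split()
        for f in positive:
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be > 0")
        nonneg = (
            "retro_speed_sd jitter_sd wave_nucleation_rate wave_arc n_clusters "
            "background_rate read_noise_sd actin_background_rate "
            "actin_speckle_contrast wave_amplitude"
        ).split()
        for f in nonneg:
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if not self.csmac_radius < self.cell_radius:
            raise ValueError("csmac_radius must be smaller than cell_radius")
        if not 0.0 <= self.coupling_prob <= 1.0:
            raise ValueError("coupling_prob must lie in [0, 1]")
        if not 0.0 < self.csmac_dimming < 1.0:
            raise ValueError("csmac_dimming must lie in (0, 1)")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not 0.0 < self.wave_arc <= 2 * math.pi:
            if self.wave_nucleation_rate > 0:
                raise ValueError("wave_arc must lie in (0, 2*pi]")

    # convenience conversions -------------------------------------------------
    @property
    def cell_radius_px(self) -> float:
        return self.cell_radius / self.pixel_size

    @property
    def csmac_radius_px(self) -> float:
        return self.csmac_radius / self.pixel_size

    @property
    def image_size(self) -> int:
        return 2 * (math.ceil(self.cell_radius_px) + 8)

    def replace(self, **overrides) -> "GeneratorProfile":
        return dataclasses.replace(self, **overrides)


# Calibrated per-profile parameters.  coupling_prob values were fixed by a
# one-off simulation sweep against the target anterograde track fractions
# (0.43 primary, 0.11 jurkat, 0.19 wasp_ko, 0.45 ck666).
_PRIMARY_WAVES = dict(
    wave_nucleation_rate=0.15,
    wave_arc=0.9,
    capture_radius=600.0,
)

_PROFILES = {
    "primary": dict(
        retro_speed=43.0,
        retro_speed_sd=30.0,
        coupling_prob=1.0,
        **_PRIMARY_WAVES,
    ),
    "jurkat": dict(
        retro_speed=46.0,
        retro_speed_sd=37.5,
        wave_nucleation_rate=0.0,
        coupling_prob=0.0,
    ),
    "wasp_ko": dict(
        retro_speed=43.0,
        retro_speed_sd=39.0,
        coupling_prob=0.02,
        **_PRIMARY_WAVES,
    ),
    "ck666": dict(
        retro_speed=43.0,
        retro_speed_sd=30.0,
        coupling_prob=1.0,
        **_PRIMARY_WAVES,
    ),
}

PROFILE_NAMES = tuple(_PROFILES) + ("custom",)


def make_profile(name: str, overrides: dict | None = None) -> GeneratorProfile:
    """Build a validated generator profile.

    Parameters
    ----------
    name : str
        One of ``primary``, ``jurkat``, ``wasp_ko``, ``ck666`` or ``custom``.
    overrides : dict, optional
        Field overrides applied on top of the named profile's defaults.

    Returns
    -------
    GeneratorProfile
    """
    overrides = dict(overrides or {})
    if name in _PROFILES:
        fields = dict(_PROFILES[name])
        fields.update(overrides)
        return GeneratorProfile(name=name, **fields)
    if name == "custom":
        return GeneratorProfile(name="custom", **overrides)
    raise ValueError(f"unknown profile {name!r}; known: {PROFILE_NAMES}")
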