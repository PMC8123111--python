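"""Synthetic multibeam water-column surveys with per-sample ground truth.

Emulates a dual-transducer hydrographic multibeam echosounder running a
lawnmower survey over a flat, muddy-sand seabed: two 75.1° fans of 256
equiangular beams each, combined into a 130.1° swath of 512 beams, pinging at
2.6 Hz with 0.64 m range bins.  Four target classes with distinct shape and
kinematics can be injected into the water column:

* ``FISH`` — compact anisotropic ellipsoidal schools drifting horizontally at
  less than 5 m/s;
* ``GAS`` — narrow bubble clusters released at the seabed that rise (often
  faster than 10 m/s) and re-spawn at the bottom, so that over time the seep
  spans the water column from seabed to surface;
* ``PLATFORM`` — static rectangular pillars spanning near-surface to seafloor,
  with backscatter increasing towards the bottom (stronger returns and
  sidelobe contamination at long range push the apparent mass centre deep);
* ``NOISE`` — diffuse static patches (e.g. entrained air), in addition to the
  sidelobe arcs and near-surface bubble layer added by :func:`inject_noise`.

Conventions used throughout the package: depth is positive-down metres; world
coordinates are local east/north metres about a survey origin; beam angles are
degrees off nadir, negative to port; ``Sv`` values are uncalibrated volume
backscattering strengths in dB (relative values only).  Ground-truth codes:
0 background, 1 FISH, 2 GAS, 3 NOISE, 4 PLATFORM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "CLASS_CODES",
    "CLASS_NAMES",
    "FanGeometry",
    "NoiseConfig",
    "PingFan",
    "SurveyConfig",
    "TargetSpec",
    "generate_survey",
    "inject_noise",
    "inject_target",
]

CLASS_CODES = {"FISH": 1, "GAS": 2, "NOISE": 3, "PLATFORM": 4}
CLASS_NAMES = {0: "BACKGROUND", 1: "FISH", 2: "GAS", 3: "NOISE", 4: "PLATFORM"}

#: metres of slant range beyond the detected seafloor kept before no-data
NODATA_BEYOND_SEAFLOOR_M = 10.0


class ConfigError(ValueError):
    """Invalid survey configuration or target specification."""


@dataclass(frozen=True)
class SurveyConfig:
    """Acquisition geometry and survey layout.

    Defaults reproduce the EM2040CD-style geometry: 256 equiangular beams per
    transducer over 75.1°, two fans combined into a 130.1° swath (512 beams),
    2.6 Hz ping rate and 0.64 m range bins.
    """

    water_depth: float = 77.0
    area_side: float = 200.0
    n_transects: int = 5
    transect_spacing: float = 40.0
    vessel_speed: float = 2.0
    ping_rate: float = 2.6
    n_beams_per_transducer: int = 256
    fan_width: float = 75.1
    combined_swath: float = 130.1
    range_bin: float = 0.64
    background_sv: float = -85.0
    seed: int = 0
    # implementation knobs (the printed geometry above is fixed by the system;
    # these control the synthetic scene itself)
    speckle_std: float = 2.0
    seafloor_sv_offset: float = 45.0
    seafloor_roughness: float = 0.3
    transect_length: Optional[float] = None
    pings_per_transect: Optional[int] = None
    origin_lat: float = 43.6
    origin_lon: float = 14.4

    def __post_init__(self) -> None:
        if self.combined_swath > 2 * self.fan_width + 1e-9:
            raise ConfigError("combined_swath must be <= 2 * fan_width")
        if self.ping_rate <= 0 or self.vessel_speed <= 0:
            raise ConfigError("ping_rate and vessel_speed must be positive")
        if self.range_bin <= 0:
            raise ConfigError("range_bin must be positive")
        if self.area_side < (self.n_transects - 1) * self.transect_spacing:
            raise ConfigError(
                "area_side must cover (n_transects - 1) * transect_spacing"
            )

    @property
    def beam_spacing(self) -> float:
        """Angular spacing between adjacent beams of one fan, degrees."""
        return self.fan_width / self.n_beams_per_transducer

    @property
    def ping_advance(self) -> float:
        """Along-track distance travelled between consecutive pings, metres."""
        return self.vessel_speed / self.ping_rate

    @property
    def max_range(self) -> float:
        half = math.radians(self.combined_swath / 2.0)
        return self.water_depth / math.cos(half) + NODATA_BEYOND_SEAFLOOR_M + 5.0

    @property
    def n_range_bins(self) -> int:
        return int(math.ceil(self.max_range / self.range_bin))


@dataclass(frozen=True)
class TargetSpec:
    """One injected water-column target.

    ``velocity`` components are (east, north, depth-rate) in m/s with depth
    positive down, so a *rising* target has negative ``vz``.  ``dims`` are the
    full extents (along-track, across-track, vertical) in metres.  ``anchor``
    is the target centre at ``t_start`` (for GAS: the release point whose
    depth sets the seabed end of the seep).
    """

    klass: str
    anchor: tuple[float, float, float]
    dims: tuple[float, float, float]
    sv_offset: float = 15.0
    velocity: tuple[float, float, float] = (0.0, 0.0, 0.0)
    persistence: Optional[float] = None
    t_start: float = 0.0

    def __post_init__(self) -> None:
        if self.klass not in CLASS_CODES:
            raise ConfigError(f"unknown target class {self.klass!r}")
        if min(self.dims) <= 0:
            raise ConfigError("target dims must all be positive")
        vx, vy, vz = self.velocity
        if self.klass == "FISH" and math.hypot(vx, vy) >= 5.0:
            raise ConfigError("FISH horizontal speed must be < 5 m/s")
        if self.klass == "GAS" and vz >= 0:
            raise ConfigError("GAS must rise: vz (depth-rate) must be negative")
        if self.klass == "PLATFORM" and any(v != 0 for v in self.velocity):
            raise ConfigError("PLATFORM targets are static")

    @property
    def code(self) -> int:
        return CLASS_CODES[self.klass]


@dataclass(frozen=True)
class NoiseConfig:
    """Structured noise added on top of the seeded background speckle."""

    surface_layer_depth: float = 3.0
    surface_layer_sv: float = 12.0
    sidelobe: bool = True
    sidelobe_source_db: float = 30.0  # above background
    sidelobe_extent_beams: int = 4
    sidelobe_sv: float = 7.0
    bad_ping_fraction: float = 0.0
    bad_ping_sv: float = 20.0


@dataclass(frozen=True)
class FanGeometry:
    """Per-survey sampling lattice shared by every ping.

    ``across`` and ``depth`` are (transducer, beam, range_bin) arrays of the
    across-track offset r·sinθ and depth r·cosθ of each sample centre.
    """

    beam_angles: np.ndarray  # (2, n_beams) degrees, off-nadir
    ranges: np.ndarray  # (n_range_bins,) bin-centre slant ranges, m
    range_bin: float
    across: np.ndarray = field(repr=False, default=None)
    depth: np.ndarray = field(repr=False, default=None)

    @classmethod
    def from_config(cls, config: SurveyConfig) -> "FanGeometry":
        nb, step = config.n_beams_per_transducer, config.beam_spacing
        half = config.combined_swath / 2.0
        port_left = -half
        stbd_left = half - config.fan_width
        angles = np.stack(
            [
                port_left + (np.arange(nb) + 0.5) * step,
                stbd_left + (np.arange(nb) + 0.5) * step,
            ]
        )
        ranges = (np.arange(config.n_range_bins) + 0.5) * config.range_bin
        theta = np.radians(angles)[:, :, None]
        return cls(
            beam_angles=angles,
            ranges=ranges,
            range_bin=config.range_bin,
            across=np.sin(theta) * ranges[None, None, :],
            depth=np.cos(theta) * ranges[None, None, :],
        )

    @property
    def flat_angles(self) -> np.ndarray:
        """All 2·n_beams beam angles sorted across the combined swath."""
        return np.sort(self.beam_angles.ravel())


@dataclass
class PingFan:
    """One transmit-receive cycle: the two-transducer fan of Sv samples."""

    ping_id: int
    time: float
    nav: tuple[float, float, float]  # (x east m, y north m, heading deg)
    geometry: FanGeometry
    sv: np.ndarray  # (2, n_beams, n_range_bins) float32 dB, NaN = no data
    ground_truth: np.ndarray  # same shape, uint8 class codes
    seafloor_depth: np.ndarray  # (2, n_beams) true seabed depth per beam, m

    @property
    def along_unit(self) -> np.ndarray:
        h = math.radians(self.nav[2])
        return np.array([math.sin(h), math.cos(h)])

    @property
    def across_unit(self) -> np.ndarray:
        h = math.radians(self.nav[2])
        return np.array([math.cos(h), -math.sin(h)])

    def sample_world_xy(self) -> tuple[np.ndarray, np.ndarray]:
        """World (east, north) of every sample centre, (2, beams, bins)."""
        ax, ay = self.across_unit
        x = self.nav[0] + ax * self.geometry.across
        y = self.nav[1] + ay * self.geometry.across
        return x, y


def _transect_navigation(config: SurveyConfig) -> list[tuple[float, float, float]]:
    """Lawnmower track: parallel transects, alternating direction."""
    length = config.transect_length or config.area_side
    if config.pings_per_transect is not None:
        n_pings = config.pings_per_transect
    else:
        n_pings = max(1, int(length / config.ping_advance))
    y0 = (config.area_side - (config.n_transects - 1) * config.transect_spacing) / 2.0
    navs = []
    for t in range(config.n_transects):
        y = y0 + t * config.transect_spacing
        for p in range(n_pings):
            s = p * config.ping_advance
            if t % 2 == 0:
                navs.append((s, y, 90.0))  # eastbound
            else:
                navs.append((length - s, y, 270.0))  # westbound
    return navs


def _seafloor_profile(config: SurveyConfig, rng: np.random.Generator, n_beams: int) -> np.ndarray:
    """Per-beam seabed depth for one ping: flat + smoothed seeded roughness."""
    rough = rng.standard_normal((2, n_beams))
    rough = gaussian_filter1d(rough, sigma=8.0, axis=1, mode="nearest")
    return config.water_depth + config.seafloor_roughness * rough


def _blank_fan(
    config: SurveyConfig,
    geometry: FanGeometry,
    ping_id: int,
    time: float,
    nav: tuple[float, float, float],
    rng: np.random.Generator,
) -> PingFan:
    shape = (2, config.n_beams_per_transducer, config.n_range_bins)
    sv = np.full(shape, config.background_sv, dtype=np.float32)
    sv += rng.standard_normal(shape).astype(np.float32) * config.speckle_std
    truth = np.zeros(shape, dtype=np.uint8)
    sf_depth = _seafloor_profile(config, rng, config.n_beams_per_transducer)

    # seafloor echo: strong return at the slant range of the seabed per beam,
    # then no-data beyond seafloor + 10 m of slant range
    cos_t = np.cos(np.radians(geometry.beam_angles))
    r_sf = sf_depth / cos_t  # (2, n_beams)
    bin_sf = np.clip((r_sf / config.range_bin).astype(int), 0, shape[2] - 1)
    ti, bi = np.meshgrid(np.arange(2), np.arange(shape[1]), indexing="ij")
    for db in (0, 1):  # echo spread over two bins
        idx = np.clip(bin_sf + db, 0, shape[2] - 1)
        sv[ti, bi, idx] = config.background_sv + config.seafloor_sv_offset
    nodata = geometry.ranges[None, None, :] > (r_sf + NODATA_BEYOND_SEAFLOOR_M)[:, :, None]
    sv[nodata] = np.nan
    return PingFan(ping_id, time, nav, geometry, sv, truth, sf_depth)


#: nominal along-track beam width (1° fans), radians of half-width
ALONG_TRACK_HALFWIDTH = math.radians(0.5)


def inject_target(
    fan: PingFan,
    target: TargetSpec,
    water_depth: float,
    rng: Optional[np.random.Generator] = None,
) -> PingFan:
    """Raise the samples inside the target's instantaneous footprint.

    The target centre is advanced by ``velocity * (t - t_start)``; GAS
    clusters wrap back to the release depth once they break the surface.
    The 1° along-track beam opening widens every footprint by
    ``r·tan(0.5°)`` on each side, so targets persist over several pings.
    Ground truth is set only where currently background, so every truth
    sample stays attributable to exactly one component.  Mutates ``fan`` in
    place and returns it; out-of-swath targets are silently absent.
    """
    dt = fan.time - target.t_start
    if dt < 0 or (target.persistence is not None and dt > target.persistence):
        return fan
    dx, dy, dz = target.dims
    vx, vy, vz = target.velocity
    cx = target.anchor[0] + vx * dt
    cy = target.anchor[1] + vy * dt
    if target.klass == "GAS":
        # rising bubble cluster released at the seabed; wraps so the seep
        # spans seabed to surface over time
        travel_span = max(target.anchor[2] - dz / 2.0, dz)
        risen = (-vz * dt) % travel_span
        cz = target.anchor[2] - dz / 2.0 - risen
    else:
        cz = target.anchor[2] + vz * dt

    rel = np.array([cx, cy]) - np.array(fan.nav[:2])
    u = float(rel @ fan.along_unit)  # along-track offset of centre from ping plane
    yc = float(rel @ fan.across_unit)

    geom = fan.geometry
    Y, D = geom.across, geom.depth
    # per-sample along-track half-extent: target size + beam opening
    half_along = dx / 2.0 + geom.ranges[None, None, :] * math.tan(ALONG_TRACK_HALFWIDTH)
    if abs(u) > dx / 2.0 + float(geom.ranges[-1]) * math.tan(ALONG_TRACK_HALFWIDTH):
        return fan
    inson = np.abs(u) <= half_along
    if target.klass == "FISH":
        s = np.clip(1.0 - (u / half_along) ** 2, 0.0, None)
        mask = ((Y - yc) / (dy / 2.0)) ** 2 + ((D - cz) / (dz / 2.0)) ** 2 <= s
        raise_db = np.float32(target.sv_offset)
    elif target.klass == "GAS":
        radius = np.full(D.shape[-1], dy / 2.0)
        if rng is not None:  # per-depth radius jitter
            radius = radius * (1.0 + 0.3 * np.clip(rng.standard_normal(D.shape[-1]), -1, 1))
        mask = (np.abs(Y - yc) <= radius[None, None, :]) & (np.abs(D - cz) <= dz / 2.0)
        mask &= inson
        raise_db = np.float32(target.sv_offset)
    else:  # PLATFORM or NOISE: rectangular pillar / patch
        top, bot = cz - dz / 2.0, cz + dz / 2.0
        mask = (np.abs(Y - yc) <= dy / 2.0) & (D >= top) & (D <= bot)
        mask &= inson
        if target.klass == "PLATFORM":
            # backscatter grows towards the bottom of the pillar
            frac = np.clip((D - top) / max(bot - top, 1e-9), 0.0, 1.0)
            raise_db = (target.sv_offset + 8.0 * frac).astype(np.float32)
        else:
            raise_db = np.float32(target.sv_offset)
    mask &= D <= water_depth  # nothing below the seabed
    valid = mask & ~np.isnan(fan.sv)
    if np.isscalar(raise_db) or raise_db.ndim == 0:
        fan.sv[valid] += raise_db
    else:
        fan.sv[valid] += raise_db[valid]
    fan.ground_truth[valid & (fan.ground_truth == 0)] = target.code
    return fan


def inject_noise(
    fan: PingFan,
    noise: NoiseConfig,
    background_sv: float,
    rng: Optional[np.random.Generator] = None,
    bad_ping: bool = False,
) -> PingFan:
    """Add sidelobe arcs, a near-surface bubble layer, and bad-ping glare.

    Sidelobe arcs replicate strong water-column targets across neighbouring
    beams at constant range; the near-surface layer elevates every sample
    shallower than ``surface_layer_depth``.  Both are ground-truthed NOISE
    (where background).  Speckle itself is part of the blank fan.
    """
    geom = fan.geometry
    if noise.surface_layer_depth > 0:
        shallow = geom.depth < noise.surface_layer_depth
        shallow &= ~np.isnan(fan.sv)
        fan.sv[shallow] += np.float32(noise.surface_layer_sv)
        fan.ground_truth[shallow & (fan.ground_truth == 0)] = CLASS_CODES["NOISE"]
    if noise.sidelobe:
        # sources: strong *water-column* samples (above the seabed echo range)
        strong = fan.sv > background_sv + noise.sidelobe_source_db
        above_bottom = geom.depth < (fan.seafloor_depth[:, :, None] - 1.0)
        strong &= above_bottom
        arc = np.zeros_like(strong)
        for shift in range(1, noise.sidelobe_extent_beams + 1):
            arc[:, shift:, :] |= strong[:, :-shift, :]
            arc[:, :-shift, :] |= strong[:, shift:, :]
        arc &= ~strong & ~np.isnan(fan.sv)
        fan.sv[arc] += np.float32(noise.sidelobe_sv)
        fan.ground_truth[arc & (fan.ground_truth == 0)] = CLASS_CODES["NOISE"]
    if bad_ping:
        ok = ~np.isnan(fan.sv)
        fan.sv[ok] += np.float32(noise.bad_ping_sv)
        fan.ground_truth[ok & (fan.ground_truth == 0)] = CLASS_CODES["NOISE"]
    return fan


def generate_survey(
    config: SurveyConfig,
    targets: Sequence[TargetSpec] = (),
    noise: Optional[NoiseConfig] = None,
) -> list[PingFan]:
    """Run the lawnmower survey and return the labelled ping sequence.

    Deterministic for a fixed ``(config, targets, seed)``.  Targets must lie
    inside the survey volume; ping positions advance by
    ``vessel_speed / ping_rate`` along each transect.
    """
    margin = 2.0 * config.water_depth  # swath reaches well beyond the track
    for t in targets:
        x, y, z = t.anchor
        if not (-margin <= x <= config.area_side + margin and -margin <= y <= config.area_side + margin):
            raise ConfigError(f"target anchor {t.anchor} outside the survey area")
        if not (0 <= z <= config.water_depth + 1e-9):
            raise ConfigError(f"target depth {z} outside [0, water_depth]")

    geometry = FanGeometry.from_config(config)
    rng = np.random.default_rng(config.seed)
    target_rngs = [
        np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 1000 + i]))
        for i in range(len(targets))
    ]
    navs = _transect_navigation(config)
    bad_ids: set[int] = set()
    if noise is not None and noise.bad_ping_fraction > 0:
        n_bad = int(round(noise.bad_ping_fraction * len(navs)))
        bad_ids = set(rng.choice(len(navs), size=n_bad, replace=False).tolist())

    fans = []
    for pid, nav in enumerate(navs):
        fan = _blank_fan(config, geometry, pid, pid / config.ping_rate, nav, rng)
        for i, t in enumerate(targets):
            inject_target(fan, t, config.water_depth, rng=target_rngs[i])
        if noise is not None:
            inject_noise(fan, noise, config.background_sv, rng=rng, bad_ping=pid in bad_ids)
        fans.append(fan)
    return fans
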