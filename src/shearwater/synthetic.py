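"""Synthetic shearwater cohorts: GPS tracks, logger streams, annual cycles.

The generator emulates the two deployment types the analysis needs:

* **Foraging trips** — breeding-season GPS tracks at 5-min fixes with three
  latent behavioural modes (rest, flight, forage) following a first-order
  Markov chain, realised as a correlated random walk on the sphere, plus a
  coupled 10-min salt/light logger stream.
* **Annual cycles** — year-round logger-only records spanning breeding,
  southbound migration, wintering and northbound migration, with known
  stage boundaries (the ground truth for stage segmentation) and
  transit-flight days at the start and end of each migration leg.

Behavioural modes are parameterised so that the kinematic labelling rules
separate them by construction: rest well below the 2.5 m/s speed cut,
flight fast and near-straight (tortuosity > 0.98), forage fast and
tortuous.  Per-state wet fractions give salt counts (binomial over the 200
wet/dry checks per 10-min block) that differ strongly between states, so a
classifier trained on salt windows has learnable signal.

All randomness flows from explicit integer seeds through
:class:`numpy.random.Generator`; regeneration with the same config and
seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from shearwater.labelling import LABELS, great_circle_distance
from shearwater.solar import solar_elevation

SALT_MAX = 200
LIGHT_MAX = 64
_LIGHT_RAMP_DEG = 8.0  # solar-elevation span of the dark->saturated light ramp


def _default_transitions() -> np.ndarray:
    # sticky chain: mean dwell ~33 fixes (~2.8 h at 5-min fixes)
    p = 0.97
    off = (1.0 - p) / 2.0
    return np.full((3, 3), off) + np.eye(3) * (p - off)


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Speed/turn/immersion parameters are per-state dictionaries keyed by
    ``rest``/``flight``/``forage``.  Speeds are segment speeds in m/s
    (mean, sd of a truncated normal); turning-angle concentrations are von
    Mises kappas (large = straight); immersion parameters are mean wet
    fractions per 10-min block in [0, 1].
    """

    seed: int = 0
    n_individuals: int = 20
    fix_interval: float = 300.0
    logger_interval: float = 600.0
    state_transition_matrix: np.ndarray = field(default_factory=_default_transitions)
    speed_params: dict = field(
        default_factory=lambda: {
            "rest": (0.15, 0.08),
            "flight": (10.0, 1.2),
            "forage": (6.0, 1.5),
        }
    )
    turn_params: dict = field(
        default_factory=lambda: {"rest": 0.3, "flight": 2000.0, "forage": 0.6}
    )
    immersion_params: dict = field(
        default_factory=lambda: {"rest": 0.95, "flight": 0.02, "forage": 0.50}
    )
    colony: tuple = (54.67, -5.52)
    winter_centroid: tuple = (-40.0, -52.0)
    #: solar elevation (deg) at which simulated light crosses the 4/64 threshold
    twilight_angle: float = -3.5
    light_threshold: int = 4
    #: day counts of the annual-cycle stage plan
    breeding_days: int = 90
    migration_days: int = 28
    winter_days: int = 153
    #: flight-dominated transit days at each end of a migration leg
    transit_days: int = 2
    deployment_start: str = "2007-06-15"

    def __post_init__(self) -> None:
        m = np.asarray(self.state_transition_matrix, dtype=float)
        if m.shape != (3, 3) or np.any(m < 0) or np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("state_transition_matrix must be 3x3 row-stochastic")
        self.state_transition_matrix = m
        for k, w in self.immersion_params.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"wet fraction for {k} must be in [0,1], got {w}")
        if not (
            self.speed_params["rest"][0] < 2.5 < self.speed_params["flight"][0]
            and 2.5 < self.speed_params["forage"][0]
        ):
            raise ValueError("rest mean speed must be < 2.5 m/s < flight and forage means")


@dataclass
class SimulatedBird:
    """One simulated deployment with full ground truth."""

    track: pd.DataFrame  # time, lat, lon
    true_states: np.ndarray  # one label per fix
    logger: pd.DataFrame  # time, salt, light
    stage_truth: pd.DataFrame | None = None  # kind, start, end (annual cycles only)
    bird_id: int = 0
    trip_id: int = 0

    def __post_init__(self) -> None:
        assert len(self.track) == len(self.true_states)


# ---------------------------------------------------------------------------
# latent states and movement


def simulate_state_sequence(config: SimConfig, n: int, seed: int) -> np.ndarray:
    """Sample a length-``n`` Markov chain over the three behaviour labels.

    The initial state is drawn from the stationary distribution of the
    transition matrix.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    m = config.state_transition_matrix
    rng = np.random.default_rng(seed)
    # stationary distribution = left eigenvector for eigenvalue 1
    w, v = np.linalg.eig(m.T)
    pi = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    pi = np.abs(pi) / np.abs(pi).sum()
    states = np.empty(n, dtype=np.int64)
    states[0] = rng.choice(3, p=pi)
    # row-wise inverse-CDF sampling
    cum = np.cumsum(m, axis=1)
    u = rng.random(n)
    for i in range(1, n):
        states[i] = np.searchsorted(cum[states[i - 1]], u[i])
    return np.asarray(LABELS, dtype=object)[states]


def _destination(lat, lon, bearing_rad, dist_m):
    """Great-circle destination point (degrees in, degrees out)."""
    R = 6_371_000.0
    phi1 = np.radians(lat)
    lam1 = np.radians(lon)
    d = dist_m / R
    phi2 = np.arcsin(
        np.sin(phi1) * np.cos(d) + np.cos(phi1) * np.sin(d) * np.cos(bearing_rad)
    )
    lam2 = lam1 + np.arctan2(
        np.sin(bearing_rad) * np.sin(d) * np.cos(phi1),
        np.cos(d) - np.sin(phi1) * np.sin(phi2),
    )
    lon2 = (np.degrees(lam2) + 180.0) % 360.0 - 180.0
    return np.degrees(phi2), lon2


def simulate_track(
    states: np.ndarray,
    config: SimConfig,
    seed: int,
    start: tuple | None = None,
    start_time: str | pd.Timestamp = "2008-06-01T00:00:00Z",
) -> pd.DataFrame:
    """Realise a state sequence as a correlated random walk on the sphere.

    The segment from fix *i* to fix *i+1* is governed by state *i*: its
    speed is a truncated normal and its heading change a von Mises draw
    with the state's concentration.  Returns one fix per state.
    """
    states = np.asarray(states)
    if len(states) == 0:
        raise ValueError("states must be non-empty")
    rng = np.random.default_rng(seed)
    lat0, lon0 = start if start is not None else config.colony
    t0 = pd.Timestamp(start_time)
    times = t0 + pd.to_timedelta(np.arange(len(states)) * config.fix_interval, unit="s")
    lat = np.empty(len(states))
    lon = np.empty(len(states))
    lat[0], lon[0] = lat0, lon0
    heading = rng.uniform(0.0, 2.0 * np.pi)
    for i in range(len(states) - 1):
        mu, sd = config.speed_params[states[i]]
        speed = max(rng.normal(mu, sd), 0.0)
        heading = heading + rng.vonmises(0.0, config.turn_params[states[i]])
        lat[i + 1], lon[i + 1] = _destination(
            lat[i], lon[i], heading, speed * config.fix_interval
        )
    return pd.DataFrame({"time": times, "lat": lat, "lon": lon})


# ---------------------------------------------------------------------------
# logger streams


def _light_from_elevation(elev_deg: np.ndarray, config: SimConfig) -> np.ndarray:
    """Quantize solar elevation to the logger's 0-64 light scale.

    A linear ramp spanning 8 degrees of solar elevation, placed so that the
    configured ``light_threshold`` is crossed exactly when the sun sits at
    ``twilight_angle`` — the geometry the elevation-angle calibration of
    the geolocation module assumes.
    """
    a0 = config.twilight_angle - _LIGHT_RAMP_DEG * config.light_threshold / LIGHT_MAX
    frac = np.clip((np.asarray(elev_deg, float) - a0) / _LIGHT_RAMP_DEG, 0.0, 1.0)
    return np.rint(LIGHT_MAX * frac).astype(np.int64)


def simulate_logger_series(
    states: np.ndarray,
    fix_times: pd.Series | pd.DatetimeIndex,
    config: SimConfig,
    seed: int,
    positions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Generate the 10-min salt/light stream coupled to a state sequence.

    One sample per ``logger_interval`` block covering the fix span.  Salt is
    Binomial(200, wet fraction of the block's dominant state) — the logger
    performs 200 wet/dry checks per block.  Light comes from the solar
    elevation at the block midpoint, at ``positions`` (time, lat, lon) if
    given, else at the colony.
    """
    states = np.asarray(states)
    times = pd.DatetimeIndex(fix_times)
    if len(states) != len(times):
        raise ValueError("states must align with fix_times")
    rng = np.random.default_rng(seed)
    step = pd.Timedelta(seconds=config.logger_interval)
    t0 = times[0].floor(f"{int(config.logger_interval)}s")
    n_blocks = int(np.ceil((times[-1] - t0) / step)) + 1
    block_mid = t0 + pd.to_timedelta(
        np.arange(n_blocks) * config.logger_interval + config.logger_interval / 2.0,
        unit="s",
    )

    # dominant state per block
    idx = np.clip(((times - t0) / step).astype(int), 0, n_blocks - 1)
    wet = np.empty(n_blocks)
    order = {s: i for i, s in enumerate(LABELS)}
    codes = np.array([order[s] for s in states])
    for b in range(n_blocks):
        in_block = codes[idx == b]
        if len(in_block) == 0:
            in_block = codes[np.argmin(np.abs(times - block_mid[b]))][None]
        dominant = np.bincount(in_block, minlength=3).argmax()
        wet[b] = config.immersion_params[LABELS[dominant]]
    salt = rng.binomial(SALT_MAX, wet)

    if positions is not None:
        lat = np.interp(
            block_mid.astype("int64"),
            pd.DatetimeIndex(positions["time"]).astype("int64"),
            positions["lat"],
        )
        lon = np.interp(
            block_mid.astype("int64"),
            pd.DatetimeIndex(positions["time"]).astype("int64"),
            positions["lon"],
        )
    else:
        lat = np.full(n_blocks, config.colony[0])
        lon = np.full(n_blocks, config.colony[1])
    light = _light_from_elevation(solar_elevation(block_mid, lat, lon), config)
    return pd.DataFrame({"time": block_mid, "salt": salt, "light": light})


def simulate_light_series(
    times: pd.DatetimeIndex, lat, lon, config: SimConfig
) -> pd.DataFrame:
    """Noise-free light trace at a (possibly moving) position; salt set to 0."""
    light = _light_from_elevation(solar_elevation(times, lat, lon), config)
    return pd.DataFrame({"time": times, "salt": 0, "light": light})


# ---------------------------------------------------------------------------
# foraging-trip cohort


def simulate_foraging_trip(
    config: SimConfig, seed: int, n_fixes: int = 500, start_time="2008-06-01T06:00:00Z"
) -> SimulatedBird:
    """One breeding-season GPS foraging trip with coupled logger stream."""
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=3)
    states = simulate_state_sequence(config, n_fixes, int(sub[0]))
    track = simulate_track(states, config, int(sub[1]), start_time=start_time)
    logger = simulate_logger_series(
        states, track["time"], config, int(sub[2]), positions=track
    )
    return SimulatedBird(track=track, true_states=states, logger=logger)


def simulate_foraging_cohort(config: SimConfig, seed: int | None = None) -> list[SimulatedBird]:
    """The GPS cohort: ``n_individuals`` birds with 1-3 foraging trips each.

    Trips are ~40 h of 5-min fixes (about 480 fixes), starting on
    consecutive days from the colony.
    """
    root = np.random.default_rng(config.seed if seed is None else seed)
    birds: list[SimulatedBird] = []
    for b in range(config.n_individuals):
        n_trips = int(root.integers(1, 4))
        for trip in range(n_trips):
            n_fixes = int(root.integers(420, 540))
            t0 = pd.Timestamp("2008-06-01T06:00:00Z") + pd.Timedelta(days=b * 4 + trip)
            bird = simulate_foraging_trip(
                config, int(root.integers(0, 2**31 - 1)), n_fixes, start_time=t0
            )
            bird.bird_id, bird.trip_id = b, trip
            birds.append(bird)
    return birds


# ---------------------------------------------------------------------------
# annual cycle

# stationary behaviour mixes per day regime (rest, flight, forage);
# migration days come in three types: ordinary travel, rest stopovers and
# foraging stopovers, the two stopover flavours seen in migrating shearwaters
_STAGE_MIX = {
    "breeding": (0.75, 0.08, 0.17),
    "migration": (0.60, 0.24, 0.16),
    "rest_stopover": (0.82, 0.05, 0.13),
    "forage_stopover": (0.33, 0.14, 0.53),
    "flight_day": (0.25, 0.60, 0.15),
    "transit": (0.08, 0.88, 0.04),
    "winter": (0.90, 0.01, 0.09),
}
#: probabilities of (travel, rest_stopover, forage_stopover, flight_day)
#: for a non-transit migration day — flight periods, foraging stopovers and
#: rest stopovers are interspersed along the whole migratory journey
_MIGRATION_DAY_TYPES = (0.35, 0.22, 0.25, 0.18)
_STAGE_PERSISTENCE = 0.8


def _stage_states(regime: str, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sticky chain with the regime's stationary mix."""
    pi = np.asarray(_STAGE_MIX[regime])
    k = _STAGE_PERSISTENCE
    m = k * np.eye(3) + (1.0 - k) * np.tile(pi, (3, 1))
    cum = np.cumsum(m, axis=1)
    s = np.empty(n, dtype=np.int64)
    s[0] = rng.choice(3, p=pi)
    u = rng.random(n)
    for i in range(1, n):
        s[i] = np.searchsorted(cum[s[i - 1]], u[i])
    return s


def _migration_day_fractions(n_days: int, transit_days: int) -> np.ndarray:
    """Cumulative route fraction at midday of each migration day.

    Transit days at either end cover 10% of the route per day (fast,
    flight-dominated travel); the remaining fraction is spread evenly over
    the middle days (stopover-paced drift).
    """
    fast = 0.10
    per_day = np.full(n_days, fast)
    mid = n_days - 2 * transit_days
    if mid > 0:
        per_day[transit_days : n_days - transit_days] = (
            1.0 - 2 * transit_days * fast
        ) / mid
    per_day = per_day / per_day.sum()
    cum = np.cumsum(per_day)
    return cum - per_day / 2.0  # midday = halfway through the day's travel


def _great_circle_interp(p0: tuple, p1: tuple, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Points at fractions ``f`` along the great circle from p0 to p1 (slerp)."""
    to_xyz = lambda lat, lon: np.array(
        [
            np.cos(np.radians(lat)) * np.cos(np.radians(lon)),
            np.cos(np.radians(lat)) * np.sin(np.radians(lon)),
            np.sin(np.radians(lat)),
        ]
    )
    a, b = to_xyz(*p0), to_xyz(*p1)
    omega = np.arccos(np.clip(a @ b, -1.0, 1.0))
    f = np.atleast_1d(np.asarray(f, float))
    xyz = (
        np.outer(np.sin((1 - f) * omega), a) + np.outer(np.sin(f * omega), b)
    ) / np.sin(omega)
    xyz /= np.linalg.norm(xyz, axis=1, keepdims=True)
    return np.degrees(np.arcsin(xyz[:, 2])), np.degrees(np.arctan2(xyz[:, 1], xyz[:, 0]))


def simulate_annual_cycle(config: SimConfig, seed: int) -> SimulatedBird:
    """One year-round logger deployment with known stage boundaries.

    The year tiles into breeding -> southbound migration -> winter ->
    northbound migration -> breeding.  Daily positions sit near the colony
    during breeding, near the winter centroid during wintering, and step
    along the great-circle route during migration, covering > 1200 km of
    the route within the first two (transit) days of each leg.  States,
    salt and light are generated at the logger cadence.
    """
    if config.migration_days < 1:
        raise ValueError("migration_days must be >= 1")
    if np.sign(config.colony[0]) == np.sign(config.winter_centroid[0]):
        raise ValueError("colony and winter_centroid must lie in opposite hemispheres")
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(config.deployment_start, tz="UTC")
    plan = [
        ("breeding", config.breeding_days),
        ("migration_south", config.migration_days),
        ("winter", config.winter_days),
        ("migration_north", config.migration_days),
    ]
    total_so_far = sum(d for _, d in plan)
    plan.append(("breeding", 365 - total_so_far))

    stage_rows = []
    day_lat, day_lon, day_regime = [], [], []
    offset = 0
    for kind, n_days in plan:
        if n_days < 1:
            raise ValueError(f"stage {kind} has non-positive length")
        stage_rows.append(
            {
                "kind": kind,
                "start": (start + pd.Timedelta(days=offset)).date(),
                "end": (start + pd.Timedelta(days=offset + n_days - 1)).date(),
            }
        )
        if kind == "breeding":
            lat = config.colony[0] + rng.normal(0.0, 0.8, n_days)
            lon = config.colony[1] + rng.normal(0.0, 1.2, n_days)
            regime = ["breeding"] * n_days
        elif kind == "winter":
            lat = config.winter_centroid[0] + rng.normal(0.0, 0.8, n_days)
            lon = config.winter_centroid[1] + rng.normal(0.0, 1.2, n_days)
            regime = ["winter"] * n_days
        else:
            f = _migration_day_fractions(n_days, config.transit_days)
            if kind == "migration_north":
                f = 1.0 - f
            lat, lon = _great_circle_interp(config.colony, config.winter_centroid, f)
            regime = []
            for d in range(n_days):
                if d < config.transit_days or d >= n_days - config.transit_days:
                    regime.append("transit")
                else:
                    regime.append(
                        ["migration", "rest_stopover", "forage_stopover", "flight_day"][
                            rng.choice(4, p=_MIGRATION_DAY_TYPES)
                        ]
                    )
        day_lat.append(lat)
        day_lon.append(lon)
        day_regime.extend(regime)
        offset += n_days
    day_lat = np.concatenate(day_lat)
    day_lon = np.concatenate(day_lon)
    n_days_total = len(day_lat)

    per_day = int(86400 // config.logger_interval)
    times = start + pd.to_timedelta(
        np.arange(n_days_total * per_day) * config.logger_interval
        + config.logger_interval / 2.0,
        unit="s",
    )
    # piecewise-linear position through midday waypoints
    day_mid = (
        start + pd.to_timedelta(np.arange(n_days_total) + 0.5, unit="D")
    ).astype("int64")
    lat = np.interp(times.astype("int64"), day_mid, day_lat)
    lon = np.interp(times.astype("int64"), day_mid, day_lon)

    codes = np.concatenate(
        [_stage_states(day_regime[d], per_day, rng) for d in range(n_days_total)]
    )
    states = np.asarray(LABELS, dtype=object)[codes]
    wet = np.array([config.immersion_params[s] for s in states])
    salt = rng.binomial(SALT_MAX, wet)
    light = _light_from_elevation(solar_elevation(times, lat, lon), config)

    track = pd.DataFrame({"time": times, "lat": lat, "lon": lon})
    logger = pd.DataFrame({"time": times, "salt": salt, "light": light})
    return SimulatedBird(
        track=track,
        true_states=states,
        logger=logger,
        stage_truth=pd.DataFrame(stage_rows),
    )


# ---------------------------------------------------------------------------
# environmental rasters


@dataclass
class EnvRaster:
    """A lat/lon gridded environmental field.

    ``values`` is indexed [lat, lon]; ``lats``/``lons`` are cell-centre
    coordinates in degrees, ascending.
    """

    variable: str
    lats: np.ndarray
    lons: np.ndarray
    values: np.ndarray
    cell: float

    def __post_init__(self) -> None:
        assert self.values.shape == (len(self.lats), len(self.lons))


def simulate_env_raster(
    extent: tuple,
    config: SimConfig,
    seed: int,
    cell: float = 1.0,
    constant: bool = False,
) -> dict[str, EnvRaster]:
    """NPP, CHL and SST rasters over ``extent`` = (lat_min, lat_max, lon_min, lon_max).

    SST follows a meridional gradient (warm tropics) plus a smooth random
    field; NPP and CHL are decreasing functions of SST plus smooth noise,
    so productivity is highest in colder waters (negative SST correlation
    by construction).  ``constant=True`` yields flat fields for tests.
    """
    lat_min, lat_max, lon_min, lon_max = extent
    if lat_min > lat_max or lon_min > lon_max:
        raise ValueError("degenerate extent")
    lats = np.arange(lat_min + cell / 2.0, lat_max + cell / 2.0 - 1e-9, cell)
    lons = np.arange(lon_min + cell / 2.0, lon_max + cell / 2.0 - 1e-9, cell)
    if len(lats) == 0:
        lats = np.array([(lat_min + lat_max) / 2.0])
    if len(lons) == 0:
        lons = np.array([(lon_min + lon_max) / 2.0])
    shape = (len(lats), len(lons))
    rng = np.random.default_rng(seed)

    def smooth_field(scale: float) -> np.ndarray:
        noise = rng.normal(0.0, 1.0, shape)
        sigma = max(min(shape) / 8.0, 1.0)
        f = ndimage.gaussian_filter(noise, sigma, mode="nearest")
        sd = f.std()
        return scale * f / sd if sd > 0 else np.zeros(shape)

    if constant:
        sst = np.full(shape, 18.0)
        npp = np.full(shape, 600.0)
        chl = np.full(shape, 0.4)
    else:
        lat_grid = np.tile(lats[:, None], (1, len(lons)))
        sst = 28.0 - 0.35 * np.abs(lat_grid) + smooth_field(1.5)
        npp = np.clip(1800.0 - 45.0 * sst + smooth_field(120.0), 10.0, None)
        chl = np.clip(2.5 - 0.07 * sst + smooth_field(0.15), 0.01, None)
    return {
        "SST": EnvRaster("SST", lats, lons, sst, cell),
        "NPP": EnvRaster("NPP", lats, lons, npp, cell),
        "CHL": EnvRaster("CHL", lats, lons, chl, cell),
    }
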