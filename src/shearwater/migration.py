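"""Annual-cycle segmentation and behaviour-specific occupancy mapping.

Stage boundaries follow a proximity rule: the breeding stage runs through
the last day the bird is recorded within 1200 km of the colony, the winter
stage between the first and last days within 1200 km of the median
wintering location (the component-wise median of Southern-Hemisphere daily
positions), and the migration legs fill the gaps.  Migratory flight bouts
are the first run of days with daily wet proportion below 0.25 after
departure (and the last before arrival) on each leg.

Occupancy is mapped by Gaussian kernel density estimation on a lon/lat
grid (default cell 0.1 deg, bandwidth 10 deg for geolocation-scale data),
with isopleths extracted as the highest-density region containing a target
probability mass.  The "top-quartile" comparison ranks location-days by
each behaviour's daily proportion and reports how the per-behaviour
top-25% sets overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely.geometry as sgeom
from skimage import measure

from shearwater.labelling import LABELS, great_circle_distance


@dataclass
class AnalysisConfig:
    proximity_radius_km: float = 1200.0
    flight_bout_threshold: float = 0.25  # daily wet proportion
    substage_days: int = 30
    top_fraction: float = 0.25
    kde_cell: float = 0.1  # degrees (use 0.01 for GPS-scale data)
    kde_bandwidth: float = 10.0  # degrees (use 1 for GPS-scale data)
    isopleths: tuple = (0.5, 0.95)


@dataclass
class Stage:
    kind: str  # breeding | migration_south | winter | migration_north
    start: object  # datetime.date, inclusive
    end: object  # datetime.date, inclusive

    @property
    def n_days(self) -> int:
        return (pd.Timestamp(self.end) - pd.Timestamp(self.start)).days + 1


# ---------------------------------------------------------------------------
# stage segmentation


def median_wintering_location(daily_positions: pd.DataFrame) -> tuple:
    """Component-wise median of Southern-Hemisphere daily positions."""
    south = daily_positions[daily_positions["lat"] < 0]
    if len(south) == 0:
        raise ValueError("no Southern-Hemisphere positions; winter not detectable")
    return float(south["lat"].median()), float(south["lon"].median())


def segment_stages(
    daily_positions: pd.DataFrame,
    colony: tuple,
    config: AnalysisConfig | None = None,
) -> list[Stage]:
    """Tile the deployment period into breeding/migration/winter stages.

    ``daily_positions`` needs columns ``date``, ``lat``, ``lon`` (one row
    per day; days missing positions are interpolated by the caller or
    simply absent — boundaries are decided on the days present).  Requires
    the bird to reach the Southern Hemisphere; a deployment that never
    leaves the colony radius collapses to a single breeding stage.
    """
    cfg = config or AnalysisConfig()
    pos = daily_positions.dropna(subset=["lat", "lon"]).sort_values("date")
    pos = pos.reset_index(drop=True)
    dates = pd.DatetimeIndex(pd.to_datetime(pos["date"]))
    first_day, last_day = dates[0].date(), dates[-1].date()
    d_colony = great_circle_distance(pos["lat"], pos["lon"], colony[0], colony[1]) / 1000.0
    near_colony = np.asarray(d_colony <= cfg.proximity_radius_km)
    if near_colony.all():
        return [Stage("breeding", first_day, last_day)]
    winter_loc = median_wintering_location(pos)
    d_winter = (
        great_circle_distance(pos["lat"], pos["lon"], winter_loc[0], winter_loc[1]) / 1000.0
    )
    near_winter = np.asarray(d_winter <= cfg.proximity_radius_km)
    if not near_winter.any():
        raise ValueError("no positions within radius of the median wintering location")

    w_first, w_last = np.flatnonzero(near_winter)[[0, -1]]
    # breeding ends at the last colony-proximal day before the bird reaches
    # the wintering grounds; resumes at the first one after it leaves
    pre = np.flatnonzero(near_colony[:w_first])
    post = w_last + 1 + np.flatnonzero(near_colony[w_last + 1 :])
    stages: list[Stage] = []

    def day(i):
        return dates[i].date()

    def day_after(i):
        return (dates[i] + pd.Timedelta(days=1)).date()

    def day_before(i):
        return (dates[i] - pd.Timedelta(days=1)).date()

    if len(pre):
        b_end = pre[-1]
        stages.append(Stage("breeding", first_day, day(b_end)))
        if b_end + 1 <= w_first - 1:
            stages.append(Stage("migration_south", day_after(b_end), day_before(w_first)))
        elif day_after(b_end) <= day_before(w_first):
            stages.append(Stage("migration_south", day_after(b_end), day_before(w_first)))
    elif w_first > 0:
        stages.append(Stage("migration_south", first_day, day_before(w_first)))
    stages.append(Stage("winter", day(w_first), day(w_last)))
    if len(post):
        b2_start = post[0]
        if day_after(w_last) <= day_before(b2_start):
            stages.append(Stage("migration_north", day_after(w_last), day_before(b2_start)))
        stages.append(Stage("breeding", day(b2_start), last_day))
    elif day(w_last) < last_day:
        stages.append(Stage("migration_north", day_after(w_last), last_day))
    return stages


def split_substages(stage: Stage, config: AnalysisConfig | None = None) -> list[Stage]:
    """First / middle / last sub-stages (default 30-day ends).

    Stages of 2x``substage_days`` or shorter get an empty middle (with a
    warning) — the first and last blocks then meet or overlap is avoided
    by clipping the last block to start after the first.
    """
    cfg = config or AnalysisConfig()
    k = cfg.substage_days
    start = pd.Timestamp(stage.start)
    end = pd.Timestamp(stage.end)
    n = (end - start).days + 1
    first_end = start + pd.Timedelta(days=k - 1)
    last_start = end - pd.Timedelta(days=k - 1)
    out = [Stage(f"{stage.kind}_first", stage.start, min(first_end, end).date())]
    if n > 2 * k:
        out.append(
            Stage(
                f"{stage.kind}_middle",
                (first_end + pd.Timedelta(days=1)).date(),
                (last_start - pd.Timedelta(days=1)).date(),
            )
        )
    else:
        warnings.warn(
            f"stage {stage.kind} has {n} days (<= {2 * k}); middle sub-stage is empty"
        )
    if last_start > first_end:
        out.append(Stage(f"{stage.kind}_last", last_start.date(), stage.end))
    return out


# ---------------------------------------------------------------------------
# flight bouts


@dataclass
class FlightBout:
    stage_kind: str
    start: object
    end: object
    position: str  # "departure" or "arrival"


def detect_flight_bouts(
    daily_wet: pd.DataFrame,
    stages: list[Stage],
    config: AnalysisConfig | None = None,
) -> list[FlightBout]:
    """Sustained-flight bouts on each migration leg.

    ``daily_wet`` needs columns ``date`` and ``wet`` (daily proportion of
    salt-water immersion).  For each migration stage, the first run of
    days with wet < threshold after departure and the last run before
    arrival are returned (a single run serving both ends is reported
    once).
    """
    cfg = config or AnalysisConfig()
    dw = daily_wet.sort_values("date").reset_index(drop=True)
    dd = pd.DatetimeIndex(pd.to_datetime(dw["date"]))
    wet = dw["wet"].to_numpy(float)
    bouts: list[FlightBout] = []
    for st in stages:
        if not st.kind.startswith("migration"):
            continue
        mask = (dd >= pd.Timestamp(st.start)) & (dd <= pd.Timestamp(st.end))
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            continue
        below = wet[idx] < cfg.flight_bout_threshold
        runs = _runs(below)
        if not runs:
            continue
        first = runs[0]
        bouts.append(
            FlightBout(
                st.kind,
                dd[idx[first[0]]].date(),
                dd[idx[first[1]]].date(),
                "departure",
            )
        )
        last = runs[-1]
        if last != first:
            bouts.append(
                FlightBout(
                    st.kind,
                    dd[idx[last[0]]].date(),
                    dd[idx[last[1]]].date(),
                    "arrival",
                )
            )
    return bouts


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, end) index pairs of True runs."""
    out = []
    i = 0
    while i < len(mask):
        if mask[i]:
            j = i
            while j + 1 < len(mask) and mask[j + 1]:
                j += 1
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


# ---------------------------------------------------------------------------
# kernel density occupancy


@dataclass
class OccupancyContour:
    level: float  # probability mass enclosed
    polygons: list  # shapely Polygons (lon/lat)
    density_threshold: float

    @property
    def area(self) -> float:
        return float(sum(p.area for p in self.polygons))

    def contains(self, lon: float, lat: float) -> bool:
        pt = sgeom.Point(lon, lat)
        return any(p.contains(pt) for p in self.polygons)


@dataclass
class OccupancyGrid:
    lons: np.ndarray  # cell centres, ascending
    lats: np.ndarray
    density: np.ndarray  # [lat, lon], integrates to 1 over the grid
    cell: float
    contours: dict = field(default_factory=dict)  # level -> OccupancyContour


def kde_occupancy(
    locations: pd.DataFrame, config: AnalysisConfig | None = None
) -> OccupancyGrid:
    """Gaussian KDE of lon/lat locations with fixed degree bandwidth.

    The kernel is isotropic in degrees (matching how tracking studies
    usually parameterise smoothing for geolocation data); the grid extends
    6 bandwidths beyond the data so that the discretised density
    integrates to 1 to well below 1e-6.  Isopleths are highest-density
    regions: the contour of level q encloses the smallest-area region
    containing fraction q of the probability mass.
    """
    cfg = config or AnalysisConfig()
    lon = locations["lon"].to_numpy(float)
    lat = locations["lat"].to_numpy(float)
    if len(lon) < 1:
        raise ValueError("no locations given")
    if len(lon) < 10:
        warnings.warn(f"only {len(lon)} locations; density estimate will be crude")
    h, cell = cfg.kde_bandwidth, cfg.kde_cell
    pad = 6.0 * h
    lons = np.arange(lon.min() - pad, lon.max() + pad + cell, cell)
    lats = np.arange(lat.min() - pad, lat.max() + pad + cell, cell)
    if np.ptp(lon) == 0 and np.ptp(lat) == 0:
        warnings.warn("all locations identical; contour collapses to a point")
    # separable Gaussian kernel: density = (1/n) sum_i g(lon-x_i) g(lat-y_i)
    glon = np.exp(-0.5 * ((lons[None, :] - lon[:, None]) / h) ** 2)
    glat = np.exp(-0.5 * ((lats[None, :] - lat[:, None]) / h) ** 2)
    norm = 1.0 / (2.0 * np.pi * h * h * len(lon))
    density = norm * (glat.T @ glon)  # [lat, lon]

    grid = OccupancyGrid(lons=lons, lats=lats, density=density, cell=cell)
    mass = density.ravel() * cell * cell
    order = np.argsort(mass)[::-1]
    cum = np.cumsum(mass[order])
    for level in cfg.isopleths:
        k = int(np.searchsorted(cum, level))
        k = min(k, len(cum) - 1)
        thr = float(density.ravel()[order[k]])
        polys = _density_polygons(grid, thr)
        grid.contours[level] = OccupancyContour(
            level=level, polygons=polys, density_threshold=thr
        )
    return grid


def _density_polygons(grid: OccupancyGrid, threshold: float) -> list:
    """Marching-squares polygons of the density >= threshold region."""
    polys = []
    for c in measure.find_contours(grid.density, threshold):
        lat_pts = np.interp(c[:, 0], np.arange(len(grid.lats)), grid.lats)
        lon_pts = np.interp(c[:, 1], np.arange(len(grid.lons)), grid.lons)
        ring = np.column_stack([lon_pts, lat_pts])
        if len(ring) >= 4:
            poly = sgeom.Polygon(ring).buffer(0)
            if not poly.is_empty:
                polys.append(poly)
    # drop holes/nested rings: keep outer shells only, subtracting holes
    shells = []
    for p in polys:
        if isinstance(p, sgeom.MultiPolygon):
            shells.extend(list(p.geoms))
        else:
            shells.append(p)
    outer = [
        p
        for p in shells
        if not any(q is not p and q.contains(p) for q in shells)
    ]
    inner = [p for p in shells if p not in outer]
    result = []
    for p in outer:
        for q in inner:
            if p.contains(q):
                p = p.difference(q)
        if isinstance(p, sgeom.MultiPolygon):
            result.extend(list(p.geoms))
        elif not p.is_empty:
            result.append(p)
    return result


def contours_to_geojson(
    grid: OccupancyGrid, properties: dict | None = None
) -> dict:
    """GeoJSON FeatureCollection with one feature per isopleth polygon."""
    features = []
    for level, contour in sorted(grid.contours.items()):
        for poly in contour.polygons:
            features.append(
                {
                    "type": "Feature",
                    "geometry": sgeom.mapping(poly),
                    "properties": {**(properties or {}), "level": level},
                }
            )
    return {"type": "FeatureCollection", "features": features}


# ---------------------------------------------------------------------------
# top-quartile behaviour subsets


def top_quartile_overlap(
    daily: pd.DataFrame, config: AnalysisConfig | None = None
) -> dict:
    """Per-behaviour top-25% location-day subsets and their overlap table.

    ``daily`` needs one row per location-day with columns ``date``,
    ``lat``, ``lon`` and ``p_rest``/``p_flight``/``p_forage``.  Days
    already excluded (colony/winter-proximal) must be removed by the
    caller.  Ranking ties break toward the earlier date.  Returns a dict
    with the per-behaviour subsets, the percentage of days in exactly
    zero/one/two/three top-sets, and the composition of two-set overlaps.
    """
    cfg = config or AnalysisConfig()
    n = len(daily)
    if n < 4:
        raise ValueError(f"need at least 4 location-days, got {n}")
    df = daily.sort_values("date").reset_index(drop=True)
    k = int(np.ceil(cfg.top_fraction * n))
    top_sets = {}
    for lab in LABELS:
        order = df.sort_values(
            ["date"], kind="stable"
        ).sort_values(f"p_{lab}", ascending=False, kind="stable")
        top_sets[lab] = set(order.index[:k])
    counts = np.zeros(n, dtype=int)
    for s in top_sets.values():
        for i in s:
            counts[i] += 1
    pct = {
        "zero": 100.0 * np.mean(counts == 0),
        "one": 100.0 * np.mean(counts == 1),
        "two": 100.0 * np.mean(counts == 2),
        "three": 100.0 * np.mean(counts == 3),
    }
    pair_names = [("rest", "flight"), ("rest", "forage"), ("flight", "forage")]
    two_idx = set(np.flatnonzero(counts == 2))
    pair_comp = {}
    for a, b in pair_names:
        both = top_sets[a] & top_sets[b] & two_idx
        pair_comp[f"{a}+{b}"] = (
            100.0 * len(both) / len(two_idx) if two_idx else 0.0
        )
    return {
        "top_sets": top_sets,
        "set_size": k,
        "percent": pct,
        "two_set_composition": pair_comp,
    }
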