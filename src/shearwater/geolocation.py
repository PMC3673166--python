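"""Threshold light-level geolocation with quality filters.

Positions are estimated twice-daily from the 0-64 light trace of the
logger: twilights are the times the light crosses a threshold, longitude
comes from the midpoint of sunrise and sunset (local apparent noon), and
latitude from the day length given the sun at a calibrated elevation angle
below the horizon.  Quality control follows standard practice for pelagic
geolocation:

* noisy light-dark transitions are suppressed by requiring threshold
  crossings to persist at least two samples;
* dark periods shorter than 4 h (a bird shading the sensor, not night)
  drop their bounding twilights;
* twilights within +/-10 days of the equinoxes are dropped — day length
  carries no latitude information there;
* positions implying sustained travel above 30 m/s (the maximum plausible
  flight speed) for 3 days are removed, as are residual positions at
  extreme latitudes (|lat| > 75 deg, outside the species' range).

The elevation angle is calibrated per deployment year by minimising
positional error against a known site (the colony during breeding).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from shearwater.labelling import great_circle_distance
from shearwater.solar import equation_of_time, solar_declination


@dataclass
class GeolocationConfig:
    light_threshold: int = 4
    min_dark_hours: float = 4.0
    equinox_window_days: int = 10
    max_speed: float = 30.0  # m/s
    speed_window_days: int = 3
    elevation_angle: float = -3.5  # degrees; calibrated per year
    max_abs_lat: float = 75.0


# ---------------------------------------------------------------------------
# twilight detection


def _despike(bright: np.ndarray, min_run: int = 2) -> np.ndarray:
    """Merge runs shorter than ``min_run`` into the preceding state."""
    out = bright.copy()
    i = 0
    n = len(out)
    while i < n:
        j = i
        while j < n and out[j] == out[i]:
            j += 1
        if j - i < min_run and i > 0:
            out[i:j] = out[i - 1]
            # re-scan from the start of the merged run
            i = i - 1
            while i > 0 and out[i - 1] == out[i]:
                i -= 1
            continue
        i = j
    return out


def detect_twilights(light: pd.DataFrame, config: GeolocationConfig | None = None) -> pd.DataFrame:
    """Find sunrise/sunset threshold crossings of a light trace.

    ``light`` needs columns ``time`` and ``light``.  A crossing must
    persist at least two samples; the crossing time is linearly
    interpolated between the bracketing samples.  Returns a frame with
    columns ``time`` and ``kind`` (``sunrise``/``sunset``).
    """
    cfg = config or GeolocationConfig()
    t = pd.DatetimeIndex(light["time"])
    lv = light["light"].to_numpy(float)
    bright = _despike(lv >= cfg.light_threshold)
    if bright.all() or (~bright).all():
        warnings.warn("light trace never crosses the threshold; no twilights")
        return pd.DataFrame({"time": pd.DatetimeIndex([]), "kind": []})
    rows = []
    secs = t.astype("int64").to_numpy() / 1e9
    lo, hi = 0, lv.max()
    for i in np.flatnonzero(bright[1:] != bright[:-1]) + 1:
        # refine the crossing with a line through nearby on-ramp samples;
        # samples clipped at the dark/saturated ends would bias a naive
        # two-point interpolation because the threshold sits near the ramp foot
        sl = slice(max(i - 3, 0), min(i + 3, len(lv)))
        j = np.arange(sl.start, sl.stop)
        on_ramp = (lv[j] > lo) & (lv[j] < hi)
        ts = None
        if on_ramp.sum() >= 2:
            jj = j[on_ramp]
            m, b = np.polyfit(secs[jj], lv[jj], 1)
            if m != 0.0:
                t_cross = (cfg.light_threshold - b) / m
                if secs[sl.start] - 1800.0 <= t_cross <= secs[sl.stop - 1] + 1800.0:
                    ts = pd.Timestamp(t_cross, unit="s", tz="UTC")
        if ts is None:
            l0, l1 = lv[i - 1], lv[i]
            frac = (
                0.5 if l1 == l0 else np.clip((cfg.light_threshold - l0) / (l1 - l0), 0.0, 1.0)
            )
            ts = pd.Timestamp(secs[i - 1] + frac * (secs[i] - secs[i - 1]), unit="s", tz="UTC")
        rows.append({"time": ts, "kind": "sunrise" if bright[i] else "sunset"})
    return pd.DataFrame(rows)


def _near_equinox(times: pd.DatetimeIndex, window_days: int) -> np.ndarray:
    """Mask of twilights within ``window_days`` of Mar 20 / Sep 22 (UTC)."""
    mask = np.zeros(len(times), dtype=bool)
    if len(times) == 0:
        return mask
    for year in range(times.min().year - 1, times.max().year + 2):
        for month, day in ((3, 20), (9, 22)):
            eq = pd.Timestamp(year=year, month=month, day=day, tz="UTC")
            mask |= np.asarray(abs(times - eq) <= pd.Timedelta(days=window_days))
    return mask


def filter_twilights(
    twilights: pd.DataFrame, config: GeolocationConfig | None = None
) -> pd.DataFrame:
    """Drop twilights bounding short dark periods and near-equinox twilights."""
    cfg = config or GeolocationConfig()
    if len(twilights) == 0:
        return twilights
    tw = twilights.sort_values("time").reset_index(drop=True)
    keep = np.ones(len(tw), dtype=bool)
    times = pd.DatetimeIndex(tw["time"])
    kinds = tw["kind"].to_numpy()
    for i in range(len(tw) - 1):
        if kinds[i] == "sunset" and kinds[i + 1] == "sunrise":
            dark_h = (times[i + 1] - times[i]).total_seconds() / 3600.0
            if dark_h < cfg.min_dark_hours:
                keep[i] = keep[i + 1] = False
    keep &= ~_near_equinox(times, cfg.equinox_window_days)
    return tw[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# position estimation


def _latitude_from_day_length(
    half_day_deg: float, decl_deg: float, elev_deg: float, prev_lat: float | None
) -> float:
    """Solve sin(e) = sin(lat)sin(d) + cos(lat)cos(d)cos(H) for lat.

    Two closed-form branches exist; feasible roots (|lat| <= 89.5) are
    kept, and ambiguity is resolved toward the previous day's latitude,
    else toward the equator.  NaN when no root exists (day length
    impossible at this declination).
    """
    e = np.radians(elev_deg)
    d = np.radians(decl_deg)
    H = np.radians(half_day_deg)
    A, B, C = np.sin(d), np.cos(d) * np.cos(H), np.sin(e)
    R = np.hypot(A, B)
    if R < abs(C):
        return float("nan")
    alpha = np.arctan2(B, A)
    base = np.arcsin(C / R)
    cands = []
    for phi in (base - alpha, np.pi - base - alpha):
        phi = (phi + np.pi) % (2.0 * np.pi) - np.pi
        if abs(phi) <= np.radians(89.5):
            # guard against the spurious branch
            resid = A * np.sin(phi) + B * np.cos(phi) - C
            if abs(resid) < 1e-9:
                cands.append(np.degrees(phi))
    if not cands:
        return float("nan")
    if len(cands) == 1:
        return cands[0]
    key = (lambda x: abs(x - prev_lat)) if prev_lat is not None else abs
    return min(cands, key=key)


def positions_from_twilights(
    twilights: pd.DataFrame, elevation_angle: float
) -> pd.DataFrame:
    """One position per sunrise-sunset pair.

    Longitude places local apparent noon at the sunrise/sunset midpoint;
    latitude solves the day-length geometry with the sun at
    ``elevation_angle``.  Days whose day length is incompatible with any
    latitude are flagged (lat = NaN).
    """
    tw = twilights.sort_values("time").reset_index(drop=True)
    rows = []
    prev_lat: float | None = None
    kinds = tw["kind"].to_numpy()
    times = pd.DatetimeIndex(tw["time"])
    for i in range(len(tw) - 1):
        if not (kinds[i] == "sunrise" and kinds[i + 1] == "sunset"):
            continue
        rise, set_ = times[i], times[i + 1]
        if (set_ - rise) > pd.Timedelta(hours=24):
            continue
        noon = rise + (set_ - rise) / 2
        noon_hours = noon.hour + noon.minute / 60.0 + noon.second / 3600.0 + noon.microsecond / 3.6e9
        eot_min = float(equation_of_time(pd.DatetimeIndex([noon]))[0])
        lon = (12.0 - noon_hours - eot_min / 60.0) * 15.0
        lon = (lon + 180.0) % 360.0 - 180.0
        half_day_deg = (set_ - rise).total_seconds() / 3600.0 / 2.0 * 15.0
        decl = float(solar_declination(pd.DatetimeIndex([noon]))[0])
        lat = _latitude_from_day_length(half_day_deg, decl, elevation_angle, prev_lat)
        flagged = bool(np.isnan(lat))
        if not flagged:
            prev_lat = lat
        rows.append(
            {"date": noon.date(), "time": noon, "lat": lat, "lon": lon, "flagged": flagged}
        )
    return pd.DataFrame(rows, columns=["date", "time", "lat", "lon", "flagged"])


def estimate_positions(
    light: pd.DataFrame, config: GeolocationConfig | None = None
) -> pd.DataFrame:
    """Detect, filter and invert twilights in one call."""
    cfg = config or GeolocationConfig()
    tw = filter_twilights(detect_twilights(light, cfg), cfg)
    pos = positions_from_twilights(tw, cfg.elevation_angle)
    return speed_filter(pos, cfg)


def calibrate_elevation(
    light: pd.DataFrame,
    true_position: tuple,
    candidate_angles,
    config: GeolocationConfig | None = None,
) -> float:
    """Pick the elevation angle minimising mean error against a known site.

    Ties go to the smaller-magnitude angle.
    """
    candidates = list(candidate_angles)
    if not candidates:
        raise ValueError("candidate angle set is empty")
    cfg = config or GeolocationConfig()
    tw = filter_twilights(detect_twilights(light, cfg), cfg)
    best, best_err = None, np.inf
    for angle in sorted(candidates, key=abs):
        pos = positions_from_twilights(tw, angle)
        ok = pos[~pos["flagged"]]
        if len(ok) == 0:
            continue
        err = float(
            np.mean(
                great_circle_distance(
                    ok["lat"], ok["lon"], true_position[0], true_position[1]
                )
            )
        )
        if err < best_err - 1e-9:
            best, best_err = angle, err
    if best is None:
        raise ValueError("no candidate angle produced any unflagged positions")
    return best


# ---------------------------------------------------------------------------
# speed filter


def speed_filter(
    positions: pd.DataFrame, config: GeolocationConfig | None = None
) -> pd.DataFrame:
    """Remove sustained-implausible-speed windows and extreme latitudes.

    A position is removed when it lies in a window of
    ``speed_window_days`` days in which every implied inter-position
    travel speed exceeds ``max_speed``.  Residual positions with
    |lat| > ``max_abs_lat`` are also removed.  Flagged (NaN-latitude)
    positions pass through untouched by the speed rule.
    """
    cfg = config or GeolocationConfig()
    if len(positions) == 0:
        return positions
    pos = positions.sort_values("time").reset_index(drop=True)
    ok = (~pos["flagged"]).to_numpy()
    idx = np.flatnonzero(ok)
    lat = pos["lat"].to_numpy(float)
    lon = pos["lon"].to_numpy(float)
    secs = pd.DatetimeIndex(pos["time"]).astype("int64").to_numpy() / 1e9
    # implied speed of each segment between consecutive usable positions
    seg_speed = np.array(
        [
            float(
                great_circle_distance(lat[a], lon[a], lat[b], lon[b])
                / max(secs[b] - secs[a], 1.0)
            )
            for a, b in zip(idx[:-1], idx[1:])
        ]
    )
    remove = np.zeros(len(pos), dtype=bool)
    window_s = cfg.speed_window_days * 86400.0
    for s in range(len(idx)):
        # grow the window of consecutive fast segments starting at position s
        e = s
        while e < len(seg_speed) and seg_speed[e] > cfg.max_speed:
            e += 1
        if e == s:
            continue
        span = secs[idx[e]] - secs[idx[s]]
        if span >= window_s:
            remove[idx[s] : idx[e] + 1] = True
    keep = ~remove
    keep &= ~(np.abs(np.nan_to_num(lat)) > cfg.max_abs_lat)
    return pos[keep].reset_index(drop=True)
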