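"""Kinematic behaviour labelling of GPS tracks.

Each fix is classified into one of three behavioural states from two
window statistics:

* speed *s* — the median of the five segment speeds within a window of six
  consecutive fixes (m/s);
* tortuosity *t* — the arc-chord ratio over five consecutive fixes: the
  beeline (chord) distance from the first to the last fix divided by the
  summed segment (arc) distance, in [0, 1] with 1 a straight line.

The decision rule is::

    s <= s_cut            -> rest      (birds sitting on the water)
    s >  s_cut, t >= t_cut -> flight   (fast, directed commuting)
    s >  s_cut, t <  t_cut -> forage   (fast, tortuous search)

with defaults s_cut = 2.5 m/s and t_cut = 0.98.  Windows are centred:
fix *i* uses fixes i-2 .. i+3 for speed and i-2 .. i+2 for tortuosity, so
behaviour is attributed to the location where it occurred; fixes whose
windows cannot be formed are labelled ``undefined`` and excluded from
classifier training downstream.

Tracks are plain :class:`pandas.DataFrame` objects with columns
``time`` (tz-aware UTC timestamps), ``lat`` and ``lon`` (degrees).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EARTH_RADIUS_M = 6_371_000.0

#: Behaviour labels, in canonical order.
LABELS = ("rest", "flight", "forage")
UNDEFINED = "undefined"

# window geometry: fix i -> speed window of 6 fixes starting at i-2,
# tortuosity window of 5 fixes starting at i-2
_SPEED_BACK, _SPEED_FWD = 2, 3
_TORT_BACK, _TORT_FWD = 2, 2


@dataclass(frozen=True)
class ClassifierThresholds:
    """Cut points of the rule-based behaviour classifier.

    Parameters
    ----------
    s_cut:
        Speed separating rest from active behaviour, m/s.  The speed
        distribution of shearwater fixes is bimodal with a trough near
        2.5 m/s.
    t_cut:
        Arc-chord ratio separating directed flight from tortuous
        foraging movement.
    """

    s_cut: float = 2.5
    t_cut: float = 0.98

    def __post_init__(self) -> None:
        if not self.s_cut > 0:
            raise ValueError(f"s_cut must be positive, got {self.s_cut}")
        if not 0 < self.t_cut <= 1:
            raise ValueError(f"t_cut must be in (0, 1], got {self.t_cut}")


def great_circle_distance(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Haversine distance in metres on a sphere of radius 6371 km.

    Accepts scalars or broadcastable arrays of degrees.
    """
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    if any(np.any(np.isnan(x)) for x in (lat1, lon1, lat2, lon2)):
        raise ValueError("NaN coordinate passed to great_circle_distance")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return EARTH_RADIUS_M * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _validate_track(track: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = track["time"]
    secs = t.astype("int64").to_numpy() / 1e9
    if np.any(np.diff(secs) <= 0):
        raise ValueError("track timestamps must be strictly increasing")
    return secs, track["lat"].to_numpy(float), track["lon"].to_numpy(float)


def _segment_speeds(track: pd.DataFrame) -> np.ndarray:
    """Speed of each inter-fix segment (length n-1), m/s."""
    secs, lat, lon = _validate_track(track)
    d = great_circle_distance(lat[:-1], lon[:-1], lat[1:], lon[1:])
    return d / np.diff(secs)


def median_speed(track: pd.DataFrame, i: int) -> float:
    """Median of the 5 segment speeds in the 6-fix window centred on fix ``i``.

    Returns NaN when the window does not fit inside the track.
    """
    n = len(track)
    if not (_SPEED_BACK <= i <= n - 1 - _SPEED_FWD):
        return float("nan")
    seg = _segment_speeds(track.iloc[i - _SPEED_BACK : i + _SPEED_FWD + 1])
    return float(np.median(seg))


def arc_chord_tortuosity(track: pd.DataFrame, i: int) -> float:
    """Arc-chord ratio of the 5-fix window centred on fix ``i``.

    The chord is the beeline distance from the first to the last fix of
    the window; the arc is the sum of the four segment distances.  Equals
    1 for a straight path and approaches 0 for a path returning to its
    start.  NaN when the window does not fit or the arc length is zero
    (all five fixes coincident).
    """
    n = len(track)
    if not (_TORT_BACK <= i <= n - 1 - _TORT_FWD):
        return float("nan")
    w = track.iloc[i - _TORT_BACK : i + _TORT_FWD + 1]
    lat, lon = w["lat"].to_numpy(float), w["lon"].to_numpy(float)
    arc = float(np.sum(great_circle_distance(lat[:-1], lon[:-1], lat[1:], lon[1:])))
    if arc == 0.0:
        return float("nan")
    chord = float(great_circle_distance(lat[0], lon[0], lat[-1], lon[-1]))
    return min(chord / arc, 1.0)


def classify_point(s: float, t: float, thresholds: ClassifierThresholds | None = None) -> str:
    """Assign a behaviour label to a single (s, t) pair.

    Ties are deterministic: s exactly at the cut is rest; t exactly at the
    cut (with s above the speed cut) is flight.  Undefined tortuosity
    (zero arc, i.e. no movement) maps to rest.  NaN speed marks an
    unformable window and yields ``undefined``.
    """
    th = thresholds or ClassifierThresholds()
    if np.isnan(s):
        return UNDEFINED
    if s < 0:
        raise ValueError(f"speed must be non-negative, got {s}")
    if s <= th.s_cut:
        return "rest"
    if np.isnan(t):  # zero arc with s > cut cannot arise from one track; be total anyway
        return "rest"
    return "flight" if t >= th.t_cut else "forage"


def label_track(
    track: pd.DataFrame, thresholds: ClassifierThresholds | None = None
) -> pd.DataFrame:
    """Label every fix of a track; returns the track with s, t and label columns.

    Boundary fixes whose 6-fix speed window or 5-fix tortuosity window
    does not fit are labelled ``undefined``.  Requires at least 6 fixes.
    """
    th = thresholds or ClassifierThresholds()
    n = len(track)
    if n < 6:
        raise ValueError(f"track must have at least 6 fixes, got {n}")
    secs, lat, lon = _validate_track(track)
    seg_d = great_circle_distance(lat[:-1], lon[:-1], lat[1:], lon[1:])
    seg_v = seg_d / np.diff(secs)

    s = np.full(n, np.nan)
    t = np.full(n, np.nan)
    # sliding windows over segments: fix i -> segments [i-2, i+3) for speed,
    # [i-2, i+2) for tortuosity
    windows_v = np.lib.stride_tricks.sliding_window_view(seg_v, 5)
    s[2 : 2 + len(windows_v)] = np.median(windows_v, axis=1)
    for i in range(_TORT_BACK, n - _TORT_FWD):
        arc = float(np.sum(seg_d[i - 2 : i + 2]))
        if arc > 0.0:
            chord = float(great_circle_distance(lat[i - 2], lon[i - 2], lat[i + 2], lon[i + 2]))
            t[i] = min(chord / arc, 1.0)

    labels = np.array([classify_point(si, ti, th) for si, ti in zip(s, t)], dtype=object)
    # a fix needs *both* windows; speed's forward reach is the binding one
    labels[: _SPEED_BACK] = UNDEFINED
    labels[n - _SPEED_FWD :] = UNDEFINED

    out = track.copy()
    out["s"] = s
    out["t"] = t
    out["label"] = labels
    return out


def attach_logger_values(labelled: pd.DataFrame, logger: pd.DataFrame) -> pd.DataFrame:
    """Attach to each fix the salt and light of the nearest-in-time logger sample.

    Ties (a fix exactly equidistant between two samples) go to the earlier
    sample.  ``logger`` must be a non-empty frame with columns ``time``,
    ``salt``, ``light`` sorted by time.
    """
    if len(logger) == 0:
        raise ValueError("logger series is empty")
    fix_s = labelled["time"].astype("int64").to_numpy() / 1e9
    log_s = logger["time"].astype("int64").to_numpy() / 1e9
    # candidate = last sample at-or-before the fix; compare with the next one,
    # keeping the earlier sample on exact ties
    idx = np.searchsorted(log_s, fix_s, side="right") - 1
    idx = np.clip(idx, 0, len(log_s) - 1)
    nxt = np.clip(idx + 1, 0, len(log_s) - 1)
    take_next = np.abs(log_s[nxt] - fix_s) < np.abs(fix_s - log_s[idx])
    nearest = np.where(take_next, nxt, idx)
    out = labelled.copy()
    out["salt"] = logger["salt"].to_numpy()[nearest]
    out["light"] = logger["light"].to_numpy()[nearest]
    return out
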