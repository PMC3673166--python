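"""Low-precision solar position: declination, equation of time, elevation.

Uses the Spencer (1971) Fourier series in the fractional year.  Accuracy is
a few hundredths of a degree in declination and well under a minute in the
equation of time — far below the ~200 km error scale of threshold
light-level geolocation, which is what these routines serve.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SECONDS_PER_DAY = 86_400.0


def fractional_year(times: pd.DatetimeIndex | pd.Series) -> np.ndarray:
    """Fractional year gamma in radians (0 at Jan 1 00:00 UTC)."""
    t = pd.DatetimeIndex(times)
    doy = t.dayofyear.to_numpy(float)
    hour = (
        t.hour.to_numpy(float)
        + t.minute.to_numpy(float) / 60.0
        + t.second.to_numpy(float) / 3600.0
    )
    return 2.0 * np.pi / 365.0 * (doy - 1.0 + (hour - 12.0) / 24.0)


def solar_declination(times) -> np.ndarray:
    """Solar declination in degrees."""
    g = fractional_year(times)
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    return np.degrees(decl)


def equation_of_time(times) -> np.ndarray:
    """Equation of time in minutes (apparent minus mean solar time)."""
    g = fractional_year(times)
    return 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )


def hour_angle(times, lon) -> np.ndarray:
    """Solar hour angle in degrees (0 at local apparent noon, +ve afternoon)."""
    t = pd.DatetimeIndex(times)
    utc_hours = (
        t.hour.to_numpy(float)
        + t.minute.to_numpy(float) / 60.0
        + t.second.to_numpy(float) / 3600.0
    )
    tst_hours = utc_hours + np.asarray(lon, float) / 15.0 + equation_of_time(times) / 60.0
    return (tst_hours - 12.0) * 15.0


def solar_elevation(times, lat, lon) -> np.ndarray:
    """Solar elevation angle in degrees at given UTC times and positions."""
    decl = np.radians(solar_declination(times))
    ha = np.radians(hour_angle(times, lon))
    phi = np.radians(np.asarray(lat, float))
    sin_e = np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.cos(ha)
    return np.degrees(np.arcsin(np.clip(sin_e, -1.0, 1.0)))
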