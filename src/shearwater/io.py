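"""Plain-text readers and writers for tracks, loggers, rasters and configs.

All on-disk formats are flat CSV (ISO-8601 UTC timestamps) or key=value
text, deliberately avoiding binary container formats so runs remain
diffable and portable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from shearwater.synthetic import EnvRaster

SALT_RANGE = (0, 200)
LIGHT_RANGE = (0, 64)


def write_track(track: pd.DataFrame, path) -> None:
    out = track.copy()
    out["time"] = pd.DatetimeIndex(out["time"]).strftime("%Y-%m-%dT%H:%M:%S%z")
    out.to_csv(path, index=False)


def read_track(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["time"] = pd.to_datetime(df["time"], utc=True)
    return df


# logger CSVs share the track layout (time, salt, light)
write_logger = write_track
read_logger = read_track
write_labelled = write_track
read_labelled = read_track
write_predictions = write_track
read_predictions = read_track


def write_positions(positions: pd.DataFrame, path) -> None:
    cols = ["date", "lat", "lon", "flagged"]
    positions[cols].to_csv(path, index=False)


def read_positions(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def write_raster(raster: EnvRaster, path) -> None:
    """Long-format grid CSV: lat, lon, value."""
    lat, lon = np.meshgrid(raster.lats, raster.lons, indexing="ij")
    pd.DataFrame(
        {"lat": lat.ravel(), "lon": lon.ravel(), "value": raster.values.ravel()}
    ).to_csv(path, index=False)


def read_raster(path, variable: str) -> EnvRaster:
    df = pd.read_csv(path)
    lats = np.unique(df["lat"].to_numpy())
    lons = np.unique(df["lon"].to_numpy())
    values = (
        df.pivot_table(index="lat", columns="lon", values="value")
        .reindex(index=lats, columns=lons)
        .to_numpy()
    )
    cell = float(np.median(np.diff(lats))) if len(lats) > 1 else 1.0
    return EnvRaster(variable, lats, lons, values, cell)


def write_flat_config(values: dict, path) -> None:
    """Flat dotted-key=value text file; round-trips via read_flat_config."""
    with open(path, "w") as fh:
        for k in sorted(values):
            fh.write(f"{k}={values[k]!r}\n")


def read_flat_config(path) -> dict:
    import ast

    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        k, _, v = line.partition("=")
        out[k.strip()] = ast.literal_eval(v.strip())
    return out


def validate_table(path, kind: str) -> list[str]:
    """Format diagnostics for a track or logger CSV; empty list = clean."""
    issues: list[str] = []
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - diagnostics, not control flow
        return [f"unreadable: {exc}"]
    required = {
        "track": ["time", "lat", "lon"],
        "logger": ["time", "salt", "light"],
    }[kind]
    missing = [c for c in required if c not in df.columns]
    if missing:
        return [f"missing columns: {missing}"]
    try:
        times = pd.to_datetime(df["time"], utc=True)
        if not times.is_monotonic_increasing or times.duplicated().any():
            issues.append("timestamps not strictly increasing")
    except Exception:
        issues.append("unparseable timestamps")
    if kind == "track":
        if (df["lat"].abs() > 90).any():
            issues.append("latitude outside [-90, 90]")
        if (df["lon"].abs() > 180).any():
            issues.append("longitude outside [-180, 180]")
    else:
        if ((df["salt"] < SALT_RANGE[0]) | (df["salt"] > SALT_RANGE[1])).any():
            issues.append(f"salt outside {SALT_RANGE}")
        if ((df["light"] < LIGHT_RANGE[0]) | (df["light"] > LIGHT_RANGE[1])).any():
            issues.append(f"light outside {LIGHT_RANGE}")
    return issues
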