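#!/usr/bin/env python
"""Map behaviour-specific occupancy during migration.

Takes the daily summaries cached by script 05, drops days within 1200 km
of the colony or the median wintering location, extracts the per-behaviour
top-25% location-day subsets, and computes 50%/95% kernel-density
occupancy contours for each.  Finding: most location-days fall in the top
quarter of exactly one behaviour, the two-set overlaps are dominated by
flight+forage, and no day tops all three — echoing how distinct the three
behavioural distributions are.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from shearwater.labelling import LABELS, great_circle_distance
from shearwater.migration import (
    contours_to_geojson,
    kde_occupancy,
    median_wintering_location,
    top_quartile_overlap,
)
from shearwater.pipeline import PipelineConfig

SEED = 20070615
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = PipelineConfig(seed=SEED)
    days = pd.read_csv(ROOT / "scratch" / "daily_summaries.csv")
    mig = days[days["stage"].isin(["migration_south", "migration_north"])].copy()
    winter_loc = median_wintering_location(days)
    d_col = great_circle_distance(mig["lat"], mig["lon"], *cfg.sim.colony) / 1000.0
    d_win = great_circle_distance(mig["lat"], mig["lon"], *winter_loc) / 1000.0
    mig = mig[
        (np.asarray(d_col) > cfg.analysis.proximity_radius_km)
        & (np.asarray(d_win) > cfg.analysis.proximity_radius_km)
    ].reset_index(drop=True)

    overlap = top_quartile_overlap(mig, cfg.analysis)
    features = []
    areas = {}
    for lab in LABELS:
        subset = mig.loc[sorted(overlap["top_sets"][lab])]
        grid = kde_occupancy(subset, cfg.analysis)
        gj = contours_to_geojson(grid, {"behaviour": lab, "period": "migration"})
        features.extend(gj["features"])
        areas[lab] = {
            "area_50_deg2": grid.contours[0.5].area,
            "area_95_deg2": grid.contours[0.95].area,
        }
    (ROOT / "scratch" / "contours.geojson").write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )
    mig.to_csv(ROOT / "scratch" / "migration_days.csv", index=False)
    summary = {
        "n_location_days": int(len(mig)),
        "top_set_size": overlap["set_size"],
        "percent": overlap["percent"],
        "two_set_composition": overlap["two_set_composition"],
        "contour_areas": areas,
    }
    (ROOT / "results" / "06_overlap_summary.json").write_text(json.dumps(summary, indent=1))
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
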