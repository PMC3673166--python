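#!/usr/bin/env python
"""Relate migration behaviour to environmental covariates.

Samples NPP, CHL and SST rasters at migration location-days (from script
06), fits per-direction multinomial models of dominant daily behaviour on
each covariate, and runs use-vs-availability KS tests against random
points inside each behaviour's 95% occupancy contour.  Finding: the
generator couples behaviour to position but not to the environmental
fields, so covariate effects are weak, while the KS tests flag the strong
mismatch between route-concentrated use and uniform availability.
"""

import json
from pathlib import Path

import pandas as pd
import shapely.geometry as sgeom

from shearwater.environment import fit_behaviour_env_model, sample_raster, use_vs_availability_ks
from shearwater.labelling import LABELS
from shearwater.migration import OccupancyContour
from shearwater.pipeline import PipelineConfig, _dominant_behaviour, stage_seed
from shearwater.synthetic import simulate_env_raster

SEED = 20070615
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = PipelineConfig(seed=SEED)
    mig = pd.read_csv(ROOT / "scratch" / "migration_days.csv")
    rasters = simulate_env_raster(
        cfg.env_extent, cfg.sim, stage_seed(SEED, "env"), cell=cfg.env_cell
    )
    mig["behaviour"] = mig.apply(_dominant_behaviour, axis=1)
    for name, r in rasters.items():
        mig[name] = sample_raster(r, mig["lat"], mig["lon"])

    report: dict = {"models": {}, "ks": {}}
    coef_rows = []
    for name in rasters:
        for direction in ("migration_south", "migration_north"):
            sub = mig[mig["stage"] == direction]
            counts = sub["behaviour"].value_counts()
            if any(counts.get(lab, 0) < 30 for lab in LABELS):
                report["models"][f"{name}:{direction}"] = "insufficient samples"
                continue
            fit = fit_behaviour_env_model(sub, name)
            report["models"][f"{name}:{direction}"] = {"n": fit.n, "converged": fit.converged}
            tbl = fit.coef.reset_index()
            tbl.insert(0, "direction", direction)
            tbl.insert(0, "variable", name)
            coef_rows.append(tbl)
    pd.concat(coef_rows, ignore_index=True).to_csv(
        ROOT / "results" / "07_multinomial_coefficients.csv", index=False
    )

    contours = json.loads((ROOT / "scratch" / "contours.geojson").read_text())
    for lab in LABELS:
        polys = [
            sgeom.shape(f["geometry"])
            for f in contours["features"]
            if f["properties"]["behaviour"] == lab and f["properties"]["level"] == 0.95
        ]
        used = mig[mig["behaviour"] == lab]
        if len(used) < 10 or not polys:
            continue
        contour = OccupancyContour(level=0.95, polygons=polys, density_threshold=float("nan"))
        ks = use_vs_availability_ks(
            used, contour, rasters["NPP"], n_random=200, seed=stage_seed(SEED, f"ks{lab}")
        )
        report["ks"][lab] = {
            "statistic": round(ks["statistic"], 4),
            "p_value": ks["p_value"],
            "n_used": int(len(used)),
        }
    (ROOT / "results" / "07_environment_summary.json").write_text(
        json.dumps(report, indent=1, default=str)
    )
    print(json.dumps(report, indent=1, default=str))


if __name__ == "__main__":
    main()
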