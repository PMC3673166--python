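#!/usr/bin/env python
"""Predict year-round behaviour, segment stages, and detect flight bouts.

Uses the trained model (results/model.json, from script 03) and the
geolocated positions (scratch/positions, from script 04).  Finding:
stage-median behaviour budgets show the expected annual pattern — rest
dominating the winter, flight and foraging elevated on migration — stage
boundaries land within a couple of days of the simulated truth, and the
immersion-defined flight bouts sit at the migration ends.  Daily
summaries are cached under scratch/ for the mapping scripts.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from shearwater import io as sio
from shearwater.migration import detect_flight_bouts, segment_stages
from shearwater.model import ClassifierModel, daily_proportions, predict_series
from shearwater.pipeline import PipelineConfig, daily_position_series, stage_seed
from shearwater.synthetic import simulate_annual_cycle
from shearwater.labelling import LABELS

SEED = 20070615
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = PipelineConfig(seed=SEED)
    model = ClassifierModel.from_json((ROOT / "results" / "model.json").read_text())
    day_rows, stage_rows, bout_rows, boundary_errors = [], [], [], []
    for i in range(cfg.n_annual):
        bird = simulate_annual_cycle(cfg.sim, stage_seed(SEED, f"annual{i}"))
        pos = sio.read_positions(ROOT / "scratch" / "positions" / f"annual{i:02d}_positions.csv")
        daily_pos = daily_position_series(pos)
        preds = predict_series(model, bird.logger, cfg.model)
        budget = daily_proportions(preds)
        stages = segment_stages(daily_pos, cfg.sim.colony, cfg.analysis)
        wet = bird.logger.copy()
        wet["date"] = pd.DatetimeIndex(wet["time"]).date
        dw = (wet.groupby("date")["salt"].mean() / 200.0).reset_index()
        dw.columns = ["date", "wet"]
        for b in detect_flight_bouts(dw, stages, cfg.analysis):
            bout_rows.append(
                {"bird": i, "stage": b.stage_kind, "position": b.position, "start": b.start, "end": b.end}
            )
        truth = bird.stage_truth
        for s in stages:
            stage_rows.append({"bird": i, "kind": s.kind, "start": s.start, "end": s.end})
            t = truth[truth["kind"] == s.kind]
            if len(t) == 1 and s.kind != "breeding":
                boundary_errors.append(
                    abs((pd.Timestamp(s.start) - pd.Timestamp(t.iloc[0]["start"])).days)
                )
                boundary_errors.append(
                    abs((pd.Timestamp(s.end) - pd.Timestamp(t.iloc[0]["end"])).days)
                )
        merged = budget.merge(daily_pos, on="date", how="inner")
        merged["bird"] = i
        stage_of = {}
        for s in stages:
            for d in pd.date_range(str(s.start), str(s.end), freq="D"):
                stage_of[d.date()] = s.kind
        merged["stage"] = merged["date"].map(stage_of)
        day_rows.append(merged)

    days = pd.concat(day_rows, ignore_index=True)
    (ROOT / "scratch").mkdir(exist_ok=True)
    days.to_csv(ROOT / "scratch" / "daily_summaries.csv", index=False)
    pd.DataFrame(stage_rows).to_csv(ROOT / "results" / "05_stages.csv", index=False)
    pd.DataFrame(bout_rows).to_csv(ROOT / "results" / "05_flight_bouts.csv", index=False)
    medians = (
        days.groupby("stage")[[f"p_{lab}" for lab in LABELS]].median().round(3)
    )
    medians.to_csv(ROOT / "results" / "05_stage_behaviour_medians.csv")
    summary = {
        "n_location_days": int(len(days)),
        "n_flight_bouts": len(bout_rows),
        "stage_boundary_error_days_max": int(np.max(boundary_errors)),
        "stage_boundary_error_days_mean": float(np.mean(boundary_errors)),
    }
    (ROOT / "results" / "05_summary.json").write_text(json.dumps(summary, indent=1))
    print(medians)
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
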