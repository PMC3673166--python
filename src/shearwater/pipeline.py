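"""End-to-end orchestration: simulate -> label -> train -> geolocate ->
predict -> stages -> contours -> environment.

Each stage draws its seed from the single pipeline seed by stable hashing
of the stage name, so stages are reproducible and statistically
independent; a manifest with SHA-256 checksums records every artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from shearwater import io as sio
from shearwater.environment import (
    fit_behaviour_env_model,
    sample_raster,
    use_vs_availability_ks,
)
from shearwater.geolocation import GeolocationConfig, calibrate_elevation, estimate_positions
from shearwater.labelling import (
    LABELS,
    ClassifierThresholds,
    attach_logger_values,
    great_circle_distance,
    label_track,
)
from shearwater.migration import (
    AnalysisConfig,
    detect_flight_bouts,
    kde_occupancy,
    contours_to_geojson,
    segment_stages,
    top_quartile_overlap,
)
from shearwater.model import (
    FeatureWindows,
    ModelConfig,
    balance_and_split,
    daily_proportions,
    evaluate_classifier,
    make_windows,
    predict_series,
    train_classifier,
)
from shearwater.synthetic import (
    SimConfig,
    simulate_annual_cycle,
    simulate_env_raster,
    simulate_foraging_cohort,
)

log = logging.getLogger("shearwater")


@dataclass
class PipelineConfig:
    seed: int = 0
    n_annual: int = 31
    env_extent: tuple = (-60.0, 65.0, -90.0, 30.0)
    env_cell: float = 1.0
    sim: SimConfig = field(default_factory=SimConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    geo: GeolocationConfig = field(default_factory=GeolocationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)

    # -- flat key/value round-trip ------------------------------------------
    def to_flat(self) -> dict:
        out: dict = {}

        def put(prefix, obj):
            for f in dataclasses.fields(obj):
                v = getattr(obj, f.name)
                if isinstance(v, np.ndarray):
                    v = v.tolist()
                out[f"{prefix}{f.name}"] = v

        for k in ("seed", "n_annual", "env_extent", "env_cell"):
            out[k] = getattr(self, k)
        put("sim.", self.sim)
        put("model.", self.model)
        put("geo.", self.geo)
        put("analysis.", self.analysis)
        put("thresholds.", self.thresholds)
        return out

    @classmethod
    def from_flat(cls, flat: dict) -> "PipelineConfig":
        groups: dict[str, dict] = {"sim": {}, "model": {}, "geo": {}, "analysis": {}, "thresholds": {}}
        top: dict = {}
        known = {
            "sim": SimConfig,
            "model": ModelConfig,
            "geo": GeolocationConfig,
            "analysis": AnalysisConfig,
            "thresholds": ClassifierThresholds,
        }
        valid_top = {"seed", "n_annual", "env_extent", "env_cell"}
        for k, v in flat.items():
            if "." in k:
                g, _, name = k.partition(".")
                if g not in groups:
                    raise KeyError(f"unknown config group in key '{k}'")
                names = {f.name for f in dataclasses.fields(known[g])}
                if name not in names:
                    raise KeyError(f"unknown config key '{k}'")
                groups[g][name] = v
            else:
                if k not in valid_top:
                    raise KeyError(f"unknown config key '{k}'")
                top[k] = v
        if "state_transition_matrix" in groups["sim"]:
            groups["sim"]["state_transition_matrix"] = np.asarray(
                groups["sim"]["state_transition_matrix"], float
            )
        for tup_key in ("split",):
            if tup_key in groups["model"]:
                groups["model"][tup_key] = tuple(groups["model"][tup_key])
        for tup_key in ("colony", "winter_centroid"):
            if tup_key in groups["sim"]:
                groups["sim"][tup_key] = tuple(groups["sim"][tup_key])
        for tup_key in ("isopleths",):
            if tup_key in groups["analysis"]:
                groups["analysis"][tup_key] = tuple(groups["analysis"][tup_key])
        if "env_extent" in top:
            top["env_extent"] = tuple(top["env_extent"])
        return cls(
            **top,
            sim=SimConfig(**groups["sim"]),
            model=ModelConfig(**groups["model"]),
            geo=GeolocationConfig(**groups["geo"]),
            analysis=AnalysisConfig(**groups["analysis"]),
            thresholds=ClassifierThresholds(**groups["thresholds"]),
        )

    def save(self, path) -> None:
        sio.write_flat_config(self.to_flat(), path)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_flat(sio.read_flat_config(path))


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2**31) by stable hashing of the stage name."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _prepare_run_dir(run_dir, force: bool) -> Path:
    run_dir = Path(run_dir)
    if run_dir.exists() and any(run_dir.iterdir()) and not force:
        raise FileExistsError(f"run directory {run_dir} is not empty (use force)")
    run_dir.mkdir(parents=True, exist_ok=True)
    return run_dir


def _write_manifest(run_dir: Path) -> Path:
    entries = []
    for p in sorted(run_dir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            entries.append(
                {
                    "path": str(p.relative_to(run_dir)),
                    "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
                    "bytes": p.stat().st_size,
                }
            )
    manifest = run_dir / "manifest.json"
    manifest.write_text(json.dumps({"files": entries}, indent=1))
    return manifest


# ---------------------------------------------------------------------------
# simulate


def run_simulate(config: PipelineConfig, run_dir, force: bool = False) -> Path:
    """Write the synthetic cohort (GPS trips, annual loggers, rasters, truth)."""
    run_dir = _prepare_run_dir(run_dir, force)
    trips = simulate_foraging_cohort(config.sim, stage_seed(config.seed, "trips"))
    gps_dir = run_dir / "gps"
    gps_dir.mkdir(exist_ok=True)
    for t in trips:
        stem = f"bird{t.bird_id:02d}_trip{t.trip_id}"
        sio.write_track(t.track, gps_dir / f"{stem}_track.csv")
        sio.write_logger(t.logger, gps_dir / f"{stem}_logger.csv")
        truth = t.track.copy()
        truth["state"] = t.true_states
        sio.write_track(truth, gps_dir / f"{stem}_truth.csv")
    ann_dir = run_dir / "annual"
    ann_dir.mkdir(exist_ok=True)
    for i in range(config.n_annual):
        bird = simulate_annual_cycle(config.sim, stage_seed(config.seed, f"annual{i}"))
        sio.write_logger(bird.logger, ann_dir / f"annual{i:02d}_logger.csv")
        sio.write_track(bird.track, ann_dir / f"annual{i:02d}_track.csv")
        bird.stage_truth.to_csv(ann_dir / f"annual{i:02d}_stages.csv", index=False)
    rasters = simulate_env_raster(
        config.env_extent, config.sim, stage_seed(config.seed, "env"), cell=config.env_cell
    )
    for name, r in rasters.items():
        sio.write_raster(r, run_dir / f"raster_{name.lower()}.csv")
    config.save(run_dir / "config.txt")
    _write_manifest(run_dir)
    return run_dir


# ---------------------------------------------------------------------------
# stage helpers (importable pieces of run_full)


def label_cohort(trips, thresholds=None) -> list[pd.DataFrame]:
    """Label every trip and attach its logger values."""
    out = []
    for t in trips:
        lab = label_track(t.track, thresholds)
        out.append(attach_logger_values(lab, t.logger))
    return out


def build_training_windows(trips, labelled, model_cfg: ModelConfig) -> FeatureWindows:
    parts = [make_windows(t.logger, lab, model_cfg) for t, lab in zip(trips, labelled)]
    return FeatureWindows(
        X=np.vstack([p.X for p in parts]),
        center_time=pd.DatetimeIndex(np.concatenate([p.center_time for p in parts])),
        labels=np.concatenate([p.labels for p in parts]),
    )


def daily_position_series(positions: pd.DataFrame) -> pd.DataFrame:
    """Daily mean position, gap-filled by linear interpolation (flagged).

    Geolocation yields at most two positions per day with equinox-window
    gaps; mapping and stage segmentation want one position per calendar
    day.
    """
    ok = positions.dropna(subset=["lat"])
    if len(ok) == 0:
        raise ValueError("no usable positions")
    daily = ok.groupby("date")[["lat", "lon"]].mean()
    daily.index = pd.to_datetime(daily.index)
    full = pd.date_range(daily.index.min(), daily.index.max(), freq="D")
    out = daily.reindex(full)
    filled = out["lat"].isna()
    out = out.interpolate(method="time")
    out["interpolated"] = filled
    out = out.reset_index().rename(columns={"index": "date"})
    out["date"] = out["date"].dt.date
    return out


def _dominant_behaviour(row) -> str:
    probs = [row[f"p_{lab}"] for lab in LABELS]
    return LABELS[int(np.argmax(probs))]


# ---------------------------------------------------------------------------
# full pipeline


def run_full(
    config: PipelineConfig,
    run_dir,
    force: bool = False,
    skip: set | None = None,
) -> dict:
    """Execute every stage on a synthetic cohort and write a summary report.

    Returns the report dict (also written as ``report.json``).  ``skip``
    may contain ``"environment"`` to omit the covariate analyses.
    """
    skip = skip or set()
    run_dir = _prepare_run_dir(run_dir, force)
    report: dict = {"seed": config.seed}

    log.info("simulating cohort")
    trips = simulate_foraging_cohort(config.sim, stage_seed(config.seed, "trips"))
    annual = [
        simulate_annual_cycle(config.sim, stage_seed(config.seed, f"annual{i}"))
        for i in range(config.n_annual)
    ]

    log.info("labelling GPS tracks")
    labelled = label_cohort(trips, config.thresholds)
    lab_all = pd.concat(labelled, ignore_index=True)
    truth_all = np.concatenate([t.true_states for t in trips])
    defined = lab_all["label"].isin(LABELS).to_numpy()
    report["labelling"] = {
        "n_fixes": int(len(lab_all)),
        "n_defined": int(defined.sum()),
        "state_recovery_accuracy": float(
            np.mean(lab_all["label"].to_numpy()[defined] == truth_all[defined])
        ),
    }

    log.info("training classifier")
    windows = build_training_windows(trips, labelled, config.model)
    train, test, validation = balance_and_split(
        windows, config.model, stage_seed(config.seed, "split")
    )
    model = train_classifier(train, test, config.model, stage_seed(config.seed, "train"))
    result = evaluate_classifier(model, validation, seed=stage_seed(config.seed, "eval"))
    (run_dir / "model.json").write_text(model.to_json())
    report["classifier"] = {
        "validation_accuracy": result.accuracy,
        "balanced_accuracy": result.balanced_accuracy,
        "permutation_p": result.permutation_p,
        "confusion": result.matrix.tolist(),
        "best_epoch": model.best_epoch,
    }

    log.info("geolocating annual birds")
    breeding_end = annual[0].stage_truth.iloc[0]["end"]
    calib_light = annual[0].logger[
        pd.DatetimeIndex(annual[0].logger["time"]).date <= breeding_end
    ]
    angle = calibrate_elevation(
        calib_light, config.sim.colony, np.arange(-6.0, 0.01, 0.5), config.geo
    )
    geo_cfg = dataclasses.replace(config.geo, elevation_angle=angle)
    report["geolocation"] = {"calibrated_elevation_angle": float(angle)}

    log.info("predicting behaviour and segmenting stages")
    stage_rows, bout_rows, day_rows = [], [], []
    for i, bird in enumerate(annual):
        positions = estimate_positions(bird.logger, geo_cfg)
        daily_pos = daily_position_series(positions)
        preds = predict_series(model, bird.logger, config.model)
        budget = daily_proportions(preds)
        stages = segment_stages(daily_pos, config.sim.colony, config.analysis)
        wet = bird.logger.copy()
        wet["date"] = pd.DatetimeIndex(wet["time"]).date
        dw = (wet.groupby("date")["salt"].mean() / 200.0).reset_index()
        dw.columns = ["date", "wet"]
        bouts = detect_flight_bouts(dw, stages, config.analysis)
        for s in stages:
            stage_rows.append(
                {"bird": i, "kind": s.kind, "start": s.start, "end": s.end}
            )
        for b in bouts:
            bout_rows.append(
                {
                    "bird": i,
                    "stage": b.stage_kind,
                    "position": b.position,
                    "start": b.start,
                    "end": b.end,
                }
            )
        merged = budget.merge(daily_pos, on="date", how="inner")
        merged["bird"] = i
        stage_of = {}
        for s in stages:
            for d in pd.date_range(str(s.start), str(s.end), freq="D"):
                stage_of[d.date()] = s.kind
        merged["stage"] = merged["date"].map(stage_of)
        day_rows.append(merged)
    stage_table = pd.DataFrame(stage_rows)
    bout_table = pd.DataFrame(bout_rows)
    days = pd.concat(day_rows, ignore_index=True)
    stage_table.to_csv(run_dir / "stages.csv", index=False)
    bout_table.to_csv(run_dir / "flight_bouts.csv", index=False)
    days.to_csv(run_dir / "daily_summaries.csv", index=False)
    behaviour_by_stage = {}
    for kind in ("breeding", "migration_south", "winter", "migration_north"):
        sub = days[days["stage"] == kind]
        if len(sub):
            behaviour_by_stage[kind] = {
                f"median_p_{lab}": float(sub[f"p_{lab}"].median()) for lab in LABELS
            }
    report["stages"] = {
        "n_stage_rows": int(len(stage_table)),
        "n_flight_bouts": int(len(bout_table)),
        "behaviour_by_stage": behaviour_by_stage,
    }

    log.info("occupancy contours and top-quartile subsets")
    mig = days[days["stage"].isin(["migration_south", "migration_north"])].copy()
    # exclude colony/winter-proximal days from the behaviour mapping
    from shearwater.migration import median_wintering_location

    winter_loc = median_wintering_location(days)
    d_col = great_circle_distance(
        mig["lat"], mig["lon"], config.sim.colony[0], config.sim.colony[1]
    ) / 1000.0
    d_win = great_circle_distance(mig["lat"], mig["lon"], winter_loc[0], winter_loc[1]) / 1000.0
    mig = mig[
        (np.asarray(d_col) > config.analysis.proximity_radius_km)
        & (np.asarray(d_win) > config.analysis.proximity_radius_km)
    ].reset_index(drop=True)
    overlap = top_quartile_overlap(mig, config.analysis)
    report["top_quartile"] = {
        "n_location_days": int(len(mig)),
        "percent": overlap["percent"],
        "two_set_composition": overlap["two_set_composition"],
    }
    contours = {}
    geo_features = []
    for lab in LABELS:
        subset = mig.loc[sorted(overlap["top_sets"][lab])]
        grid = kde_occupancy(subset, config.analysis)
        contours[lab] = grid
        gj = contours_to_geojson(grid, {"behaviour": lab, "period": "migration"})
        geo_features.extend(gj["features"])
    (run_dir / "contours.geojson").write_text(
        json.dumps({"type": "FeatureCollection", "features": geo_features})
    )

    if "environment" not in skip:
        log.info("environmental analyses")
        rasters = simulate_env_raster(
            config.env_extent, config.sim, stage_seed(config.seed, "env"), cell=config.env_cell
        )
        env = mig.copy()
        env["behaviour"] = env.apply(_dominant_behaviour, axis=1)
        for name, r in rasters.items():
            env[name] = sample_raster(r, env["lat"], env["lon"])
        env.to_csv(run_dir / "env_samples.csv", index=False)
        env_report: dict = {"models": {}, "ks": {}}
        for name in rasters:
            for direction in ("migration_south", "migration_north"):
                sub = env[env["stage"] == direction]
                counts = sub["behaviour"].value_counts()
                if any(counts.get(lab, 0) < 30 for lab in LABELS):
                    env_report["models"][f"{name}:{direction}"] = "insufficient samples"
                    continue
                fit = fit_behaviour_env_model(sub, name)
                env_report["models"][f"{name}:{direction}"] = {
                    "n": fit.n,
                    "converged": fit.converged,
                    "coef": {
                        f"{c}:{t}": round(fit.coef.loc[(c, t), "coef"], 4)
                        for c, t in fit.coef.index
                    },
                }
                fit.coef.to_csv(run_dir / f"env_coef_{name}_{direction}.csv")
                fit.curves.to_csv(
                    run_dir / f"env_curves_{name}_{direction}.csv", index=False
                )
        for lab in LABELS:
            used = env[env["behaviour"] == lab]
            contour = contours[lab].contours[0.95]
            if len(used) < 10 or not contour.polygons:
                continue
            ks = use_vs_availability_ks(
                used,
                contour,
                rasters["NPP"],
                n_random=200,
                seed=stage_seed(config.seed, f"ks{lab}"),
            )
            env_report["ks"][lab] = {
                "statistic": ks["statistic"],
                "p_value": ks["p_value"],
                "n_used": int(len(used)),
            }
        report["environment"] = env_report

    config.save(run_dir / "config.txt")
    (run_dir / "report.json").write_text(json.dumps(report, indent=1, default=str))
    _write_manifest(run_dir)
    return report


def validate_inputs(paths) -> dict:
    """Format diagnostics for a collection of track/logger CSVs."""
    out = {}
    for p in paths:
        head = pd.read_csv(p, nrows=1)
        kind = "logger" if "salt" in head.columns else "track"
        out[str(p)] = sio.validate_table(p, kind)
    return out
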