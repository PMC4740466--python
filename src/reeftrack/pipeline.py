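"""End-to-end pipeline: from input CSVs to the full set of output tables.

A run is governed by one config (YAML file or dict).  Outputs are written
as CSV plus a ``run_manifest.json`` recording the config hash, package
version and row counts, so that a rerun on identical inputs is verifiably
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, covariates, io, migration, residency, space
from .errors import ReeftrackError
from .simulate import SimulationConfig, simulate_dataset, write_bundle

DEFAULT_RUN_CONFIG = {
    "detections": "detections.csv",
    "receivers": "receivers.csv",
    "tags": "tags.csv",
    "environment": "environment.csv",
    "sites": None,                  # optional site registry with reef areas
    "home_array": "TSV",
    "study_end": None,              # default: last detection's local day
    "utc_offset_hours": 10.0,
    "hour_window_s": 3600.0,
    "min_detections_home": 2,
    "min_detections_away": 1,
    "min_detection_days": 2,
    "group_cutpoints": [0.09, 0.20, 0.50],
    "coa_interval": "1h",
    "matrix_mode": "individuals",
    "utm_zone": 55,
    "output_dir": "outputs",
}

OUTPUT_FILES = [
    "residency_summary.csv", "monthly_residency.csv", "coa.csv", "dispersal.csv",
    "movement_matrix.csv", "migration_events.csv", "array_summary.csv",
    "occupancy.csv", "daily_model_table.csv", "coverage.csv",
]


def load_config(path) -> dict:
    """Read a YAML run config, filling unspecified keys with defaults."""
    cfg = dict(DEFAULT_RUN_CONFIG)
    loaded = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(loaded) - set(cfg)
    if unknown:
        raise ReeftrackError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(loaded)
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, float_format="%.6f") -> int:
    df.to_csv(path, index=False, float_format=float_format)
    return len(df)


def run_pipeline(config: dict, *, log=None) -> dict:
    """Execute every analysis stage and write the output bundle.

    Returns the manifest dict.  Raises on missing inputs before any stage
    runs; per-stage timings go to ``log`` (a writable stream) if given.
    """
    cfg = dict(DEFAULT_RUN_CONFIG)
    cfg.update(config)
    log = log or sys.stderr

    for key in ("detections", "receivers", "tags", "environment"):
        if not Path(cfg[key]).exists():
            raise ReeftrackError(f"input file missing: {key} -> {cfg[key]}")

    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "config": {k: str(v) for k, v in cfg.items()},
        "config_hash": _config_hash(cfg),
        "row_counts": {},
        "stages_completed": [],
    }

    def stage(name):
        t0 = time.perf_counter()
        print(f"[reeftrack] stage {name} ...", file=log)
        return t0

    def done(name, t0):
        manifest["stages_completed"].append(name)
        print(f"[reeftrack] stage {name} done in {time.perf_counter() - t0:.1f}s", file=log)

    t0 = stage("read")
    detections = io.read_detections(cfg["detections"])
    receivers = io.read_receivers(cfg["receivers"])
    tags = io.read_tags(cfg["tags"])
    environment = io.read_environment(cfg["environment"])
    joined, rejects = io.join_detections_to_deployments(detections, receivers)
    joined, tag_rejects = io.attach_tags(joined, tags)
    rejects = pd.concat([rejects, tag_rejects], ignore_index=True)
    _write_csv(rejects, outdir / "rejects.csv")
    done("read", t0)

    home = cfg["home_array"]
    off = cfg["utc_offset_hours"]
    if cfg["study_end"] is not None:
        study_end = pd.Timestamp(cfg["study_end"])
    else:
        study_end = io.local_day(joined["timestamp"], off).max()

    t0 = stage("presence")
    pres_home = residency.daily_presence(
        joined.loc[joined["array_id"] == home],
        hour_window_s=cfg["hour_window_s"],
        min_detections=cfg["min_detections_home"],
        utc_offset_hours=off,
    )
    pres_away = residency.daily_presence(
        joined.loc[joined["array_id"] != home],
        min_detections=cfg["min_detections_away"],
        utc_offset_hours=off,
    )
    parts = [p for p in (pres_home, pres_away) if not p.empty]
    presence = pd.concat(parts, ignore_index=True) if parts else pres_home
    done("presence", t0)

    t0 = stage("residency")
    summary = residency.residency_summary(
        presence, tags, home_array=home, study_end=study_end,
        cutpoints=tuple(cfg["group_cutpoints"]),
    )
    visited = space.sites_visited(joined, array_id=home)
    n_sites = receivers.loc[receivers["array_id"] == home, "site_id"].nunique()
    summary["sites_visited"] = summary["tag_id"].map(visited).fillna(0).astype(int)
    summary["roaming_index"] = summary["sites_visited"] / max(n_sites, 1)
    kept, excluded = residency.exclude_transients(summary, cfg["min_detection_days"])
    summary["excluded_transient"] = summary["tag_id"].isin(excluded["tag_id"])
    manifest["row_counts"]["residency_summary.csv"] = _write_csv(
        summary, outdir / "residency_summary.csv"
    )
    monthly = residency.monthly_residency_table(
        presence, tags, home_array=home, study_end=study_end
    )
    manifest["row_counts"]["monthly_residency.csv"] = _write_csv(
        monthly, outdir / "monthly_residency.csv"
    )
    done("residency", t0)

    t0 = stage("space_use")
    coa = space.center_of_activity(
        joined.loc[joined["array_id"] == home],
        interval=cfg["coa_interval"], utc_offset_hours=off, zone=cfg["utm_zone"],
    )
    manifest["row_counts"]["coa.csv"] = _write_csv(coa, outdir / "coa.csv")
    disp = space.dispersal_steps(coa)
    manifest["row_counts"]["dispersal.csv"] = _write_csv(disp, outdir / "dispersal.csv")

    matrix = space.movement_matrix(
        joined.loc[joined["array_id"] == home], level="site", mode=cfg["matrix_mode"]
    )
    long = space.matrix_to_long(matrix)
    long["stratum"] = "all"
    strata = [long]
    for sex in ("F", "M"):
        m = space.movement_matrix(
            joined.loc[joined["array_id"] == home], level="site",
            mode=cfg["matrix_mode"], sex=sex,
        )
        ml = space.matrix_to_long(m)
        ml["stratum"] = sex
        strata.append(ml)
    manifest["row_counts"]["movement_matrix.csv"] = _write_csv(
        pd.concat(strata, ignore_index=True), outdir / "movement_matrix.csv"
    )

    if cfg["sites"] and Path(cfg["sites"]).exists():
        sites = pd.read_csv(cfg["sites"])
        cov_rows = []
        for _, s in sites.iterrows():
            radii = receivers.loc[
                receivers["site_id"] == s["site_id"], "detection_radius_m"
            ]
            if len(radii) and s.get("reef_area_km2", 0) > 0:
                cov_rows.append(
                    {
                        "array_id": s["array_id"],
                        "site_id": s["site_id"],
                        "reef_area_km2": s["reef_area_km2"],
                        "n_receivers": len(radii),
                        "coverage_fraction": space.acoustic_coverage(
                            s["reef_area_km2"], radii
                        ),
                    }
                )
        coverage = pd.DataFrame(cov_rows)
    else:
        coverage = pd.DataFrame(
            columns=["array_id", "site_id", "reef_area_km2", "n_receivers",
                     "coverage_fraction"]
        )
    manifest["row_counts"]["coverage.csv"] = _write_csv(coverage, outdir / "coverage.csv")
    done("space_use", t0)

    t0 = stage("migration")
    events = migration.detect_migration_events(joined, home_array=home)
    ev = events.copy()
    manifest["row_counts"]["migration_events.csv"] = _write_csv(
        ev, outdir / "migration_events.csv"
    )
    transitions = migration.array_transitions(joined)
    arr_summary = migration.array_presence_summary(
        presence, transitions, home_array=home
    )
    manifest["row_counts"]["array_summary.csv"] = _write_csv(
        arr_summary, outdir / "array_summary.csv"
    )
    occupancy = migration.monthly_array_occupancy(presence, tags)
    manifest["row_counts"]["occupancy.csv"] = _write_csv(
        occupancy, outdir / "occupancy.csv"
    )
    classification = migration.classify_population(events, tags)
    manifest["classification"] = {
        k: v for k, v in classification.items() if k != "per_tag"
    }
    done("migration", t0)

    t0 = stage("covariates")
    daily_env = covariates.aggregate_environment(environment)
    model_table = covariates.build_daily_count_table(
        presence, tags, daily_env, home_array=home
    )
    manifest["row_counts"]["daily_model_table.csv"] = _write_csv(
        model_table, outdir / "daily_model_table.csv"
    )
    done("covariates", t0)

    manifest["n_detections"] = len(detections)
    manifest["n_rejects"] = len(rejects)
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def simulate_to_dir(sim_config: SimulationConfig, outdir) -> dict:
    """Generate a synthetic input bundle and write it under ``outdir``."""
    bundle = simulate_dataset(sim_config)
    paths = write_bundle(bundle, outdir)
    meta = dataclasses.asdict(sim_config)
    (Path(outdir) / "simulation_config.json").write_text(
        json.dumps(meta, indent=1, default=str)
    )
    return paths
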