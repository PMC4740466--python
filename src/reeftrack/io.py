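"""Reading, validation and normalisation of telemetry input tables.

Four CSV inputs drive the pipeline:

* detections — one row per decoded transmitter ping at a receiver
  (timestamp, receiver, transmitter, optional depth-sensor value);
* receivers — deployment metadata (array, reef/site, position, active
  interval, detection radius);
* tags — tagged animals (sex, fork length, tagging date/site, home array);
* environment — daily weather records per station (temperature, wind, rain).

All tables are plain pandas DataFrames with normalised column names;
timestamps are stored tz-aware UTC and converted to local calendar days
only where a day-level statistic requires it (default offset UTC+10,
Queensland, which observes no daylight saving).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MalformedDataError, SchemaError, ValidationError

#: vendor-export column convention accepted without a schema mapping
DEFAULT_DETECTION_SCHEMA = {
    "timestamp": "Date and Time (UTC)",
    "receiver_id": "Receiver",
    "transmitter_id": "Transmitter",
    "depth_m": "Sensor.Value",
}

DETECTION_COLUMNS = ["timestamp", "receiver_id", "transmitter_id", "depth_m"]
RECEIVER_COLUMNS = [
    "receiver_id", "array_id", "site_id", "latitude", "longitude",
    "active_from", "active_to", "detection_radius_m",
]
TAG_COLUMNS = [
    "tag_id", "transmitter_id", "sex", "fork_length_cm",
    "tagging_date", "tagging_site", "home_array",
]
ENV_COLUMNS = ["date", "station_id", "temperature_c", "wind_kmh", "rain_mm"]

#: pressure-sensor transmitters used on large coastal sharks are rated to 68 m
DEFAULT_MAX_DEPTH_M = 68.0

#: local civil time of the study region (Queensland, UTC+10, no DST)
DEFAULT_UTC_OFFSET_HOURS = 10.0


def local_day(timestamps: pd.Series, utc_offset_hours: float = DEFAULT_UTC_OFFSET_HOURS):
    """Local calendar day of tz-aware UTC timestamps, as datetime64[ns] dates."""
    ts = pd.to_datetime(timestamps, utc=True)
    return (ts + pd.Timedelta(hours=utc_offset_hours)).dt.tz_localize(None).dt.normalize()


def _resolve_schema(columns, schema):
    """Map internal names to file columns, falling back to either the vendor
    convention or already-normalised names."""
    mapping = {}
    for internal in ("timestamp", "receiver_id", "transmitter_id"):
        if schema and internal in schema:
            mapping[internal] = schema[internal]
        elif internal in columns:
            mapping[internal] = internal
        elif DEFAULT_DETECTION_SCHEMA[internal] in columns:
            mapping[internal] = DEFAULT_DETECTION_SCHEMA[internal]
        else:
            raise SchemaError(
                f"no column found for '{internal}'; available: {list(columns)}"
            )
        if mapping[internal] not in columns:
            raise SchemaError(
                f"schema maps '{internal}' to '{mapping[internal]}' which is absent"
            )
    # depth is optional
    depth_col = (schema or {}).get("depth_m")
    if depth_col is None:
        for cand in ("depth_m", DEFAULT_DETECTION_SCHEMA["depth_m"]):
            if cand in columns:
                depth_col = cand
                break
    elif depth_col not in columns:
        raise SchemaError(f"schema maps 'depth_m' to '{depth_col}' which is absent")
    if depth_col is not None:
        mapping["depth_m"] = depth_col
    return mapping


def read_detections(
    path,
    schema: dict | None = None,
    *,
    max_malformed_frac: float = 0.01,
    max_depth_m: float = DEFAULT_MAX_DEPTH_M,
) -> pd.DataFrame:
    """Read a detections CSV into the normalised detection table.

    Rows with unparseable timestamps are dropped and counted; the read fails
    with :class:`MalformedDataError` if more than ``max_malformed_frac`` of
    rows are malformed.  Exact duplicates on (timestamp, receiver,
    transmitter) — the signature of overlapping receiver downloads — are
    collapsed to the first occurrence.  Depth values outside
    [0, ``max_depth_m``] are sensor glitches and are blanked to NaN.

    The result is sorted by timestamp (then receiver, transmitter for a
    deterministic total order) and carries counts in ``df.attrs``:
    ``n_input``, ``n_malformed``, ``n_duplicates``, ``n_depth_blanked``.
    """
    raw = pd.read_csv(path, dtype=str)
    mapping = _resolve_schema(raw.columns, schema)
    df = pd.DataFrame({k: raw[v] for k, v in mapping.items()})
    n_input = len(df)

    ts = pd.to_datetime(df["timestamp"], utc=True, errors="coerce", format="mixed")
    n_malformed = int(ts.isna().sum())
    if n_input and n_malformed / n_input > max_malformed_frac:
        raise MalformedDataError(
            f"{n_malformed}/{n_input} rows have unparseable timestamps "
            f"(> {max_malformed_frac:.1%} allowed)"
        )
    df = df.assign(timestamp=ts).loc[ts.notna()].copy()

    if "depth_m" in df.columns:
        depth = pd.to_numeric(df["depth_m"], errors="coerce")
        bad = depth.notna() & ((depth < 0) | (depth > max_depth_m))
        df["depth_m"] = depth.mask(bad)
        n_depth_blanked = int(bad.sum())
    else:
        df["depth_m"] = np.nan
        n_depth_blanked = 0

    before = len(df)
    df = df.drop_duplicates(subset=["timestamp", "receiver_id", "transmitter_id"], keep="first")
    n_duplicates = before - len(df)

    df = df.sort_values(["timestamp", "receiver_id", "transmitter_id"], kind="mergesort")
    df = df[DETECTION_COLUMNS].reset_index(drop=True)
    df.attrs.update(
        n_input=n_input,
        n_malformed=n_malformed,
        n_duplicates=n_duplicates,
        n_depth_blanked=n_depth_blanked,
    )
    return df


def write_detections(df: pd.DataFrame, path) -> None:
    """Write a normalised detection table; round-trips through read_detections."""
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    out.to_csv(path, index=False)


def read_receivers(path) -> pd.DataFrame:
    """Read receiver deployment metadata and validate its invariants.

    Raises :class:`ValidationError` on inverted active intervals,
    out-of-range coordinates, non-positive detection radii, or overlapping
    deployments of the same receiver id.
    """
    df = pd.read_csv(path)
    missing = [c for c in RECEIVER_COLUMNS if c not in df.columns and c != "detection_radius_m"]
    if missing:
        raise SchemaError(f"receivers file missing columns: {missing}")
    if df.empty:
        warnings.warn("receivers file is empty", stacklevel=2)
        for c in RECEIVER_COLUMNS:
            if c not in df.columns:
                df[c] = pd.Series(dtype=float)
        return df[RECEIVER_COLUMNS]

    df["active_from"] = pd.to_datetime(df["active_from"])
    df["active_to"] = pd.to_datetime(df["active_to"])
    if "detection_radius_m" not in df.columns:
        df["detection_radius_m"] = 250.0
    df["detection_radius_m"] = df["detection_radius_m"].fillna(250.0)

    if (df["active_to"] < df["active_from"]).any():
        bad = df.loc[df["active_to"] < df["active_from"], "receiver_id"].tolist()
        raise ValidationError(f"active_to < active_from for receivers {bad}")
    if ((df["latitude"].abs() > 90) | (df["longitude"].abs() > 180)).any():
        raise ValidationError("coordinates outside [-90,90] x [-180,180]")
    if (df["detection_radius_m"] <= 0).any():
        raise ValidationError("detection_radius_m must be positive")

    for rid, grp in df.groupby("receiver_id"):
        if len(grp) < 2:
            continue
        g = grp.sort_values("active_from")
        if (g["active_from"].values[1:] <= g["active_to"].values[:-1]).any():
            raise ValidationError(f"overlapping deployments for receiver {rid}")

    return df[RECEIVER_COLUMNS].reset_index(drop=True)


def site_registry(receivers: pd.DataFrame) -> pd.DataFrame:
    """One row per (array, site): receiver count and mean position."""
    if receivers.empty:
        return pd.DataFrame(
            columns=["array_id", "site_id", "n_receivers", "latitude", "longitude"]
        )
    reg = (
        receivers.groupby(["array_id", "site_id"], as_index=False)
        .agg(
            n_receivers=("receiver_id", "nunique"),
            latitude=("latitude", "mean"),
            longitude=("longitude", "mean"),
        )
    )
    return reg


def read_tags(path) -> pd.DataFrame:
    """Read animal tagging metadata."""
    df = pd.read_csv(path)
    missing = [c for c in TAG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"tags file missing columns: {missing}")
    df["tagging_date"] = pd.to_datetime(df["tagging_date"])
    if not df["sex"].isin(["M", "F"]).all():
        raise ValidationError("sex must be 'M' or 'F'")
    if (pd.to_numeric(df["fork_length_cm"]) <= 0).any():
        raise ValidationError("fork_length_cm must be positive")
    if df["tag_id"].duplicated().any():
        raise ValidationError("duplicate tag_id")
    return df[TAG_COLUMNS].reset_index(drop=True)


def read_environment(path) -> pd.DataFrame:
    """Read the daily per-station environmental series."""
    df = pd.read_csv(path)
    missing = [c for c in ENV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"environment file missing columns: {missing}")
    df["date"] = pd.to_datetime(df["date"])
    if df.duplicated(subset=["date", "station_id"]).any():
        raise ValidationError("more than one environment record per (date, station)")
    if (pd.to_numeric(df["wind_kmh"], errors="coerce") < 0).any():
        raise ValidationError("wind_kmh must be non-negative")
    if (pd.to_numeric(df["rain_mm"], errors="coerce") < 0).any():
        raise ValidationError("rain_mm must be non-negative")
    return df[ENV_COLUMNS].reset_index(drop=True)


def join_detections_to_deployments(
    detections: pd.DataFrame, receivers: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join each detection to the deployment active at its time.

    Returns ``(joined, rejects)``.  Detections at unknown receivers or
    outside any active interval go to ``rejects`` with a ``reason`` column;
    they are data, not failures.  Conservation: ``len(joined) +
    len(rejects) == len(detections)``.
    """
    det = detections.reset_index(drop=True)
    if det.empty:
        joined = det.copy()
        for c in ("array_id", "site_id", "latitude", "longitude", "detection_radius_m"):
            joined[c] = pd.Series(dtype=float)
        rejects = det.copy()
        rejects["reason"] = pd.Series(dtype=str)
        return joined, rejects

    merged = det.reset_index(names="_orig").merge(receivers, on="receiver_id", how="left")
    # deployment intervals are dates; a detection belongs to a deployment if
    # its UTC day falls within [active_from, active_to] inclusive
    day = pd.to_datetime(merged["timestamp"], utc=True).dt.tz_localize(None).dt.normalize()
    known = merged["array_id"].notna()
    merged["_ok"] = known & (day >= merged["active_from"]) & (day <= merged["active_to"])

    # a receiver may have several deployment rows; keep the in-window one,
    # and keep each original detection exactly once
    best = merged.sort_values("_ok", ascending=False, kind="mergesort").drop_duplicates(
        subset="_orig", keep="first"
    ).sort_values("_orig", kind="mergesort")

    ok = best["_ok"].to_numpy()
    joined = best.loc[ok].drop(columns=["_ok", "_orig"]).reset_index(drop=True)
    rej = best.loc[~ok, det.columns.tolist() + ["array_id"]].copy()
    rej["reason"] = np.where(rej["array_id"].isna(), "unknown_receiver", "outside_deployment")
    rejects = rej.drop(columns="array_id").reset_index(drop=True)
    return joined, rejects


def attach_tags(joined: pd.DataFrame, tags: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map transmitter ids to tag ids; detections of unknown transmitters
    (other projects' animals drifting through the array) become rejects."""
    merged = joined.merge(
        tags[["tag_id", "transmitter_id", "sex", "home_array", "tagging_date"]],
        on="transmitter_id",
        how="left",
    )
    known = merged["tag_id"].notna()
    rejects = merged.loc[~known, joined.columns].copy()
    rejects["reason"] = "unknown_transmitter"
    return merged.loc[known].reset_index(drop=True), rejects.reset_index(drop=True)
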