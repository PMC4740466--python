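"""Space-use metrics within a receiver array.

Positions of free-ranging animals in passive telemetry are approximated by
short-interval centres of activity (COA): within each clock hour the
animal's position is estimated as the mean of the logging receivers'
positions weighted by their detection counts.  Consecutive COAs give
minimum linear dispersal (straight-line distance, a lower bound on the
path actually swum) and minimum dispersal time.  Site-level movement is
summarised by a roaming index (fraction of monitored reefs visited), a
directed site-by-site movement matrix suitable for circular connectivity
plots, and cross-shelf move frequencies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import geo
from .errors import NoEventsError, UndefinedMetricError
from .io import DEFAULT_UTC_OFFSET_HOURS

DEFAULT_COA_INTERVAL = "1h"


def center_of_activity(
    joined: pd.DataFrame,
    *,
    interval: str = DEFAULT_COA_INTERVAL,
    utc_offset_hours: float = DEFAULT_UTC_OFFSET_HOURS,
    zone: int = geo.DEFAULT_ZONE,
    tag_col: str = "tag_id",
) -> pd.DataFrame:
    """Detection-count-weighted mean position per animal per time bin.

    The weighted mean is computed on projected (UTM) coordinates, then
    inverted to latitude/longitude, so each COA lies inside the convex hull
    of its contributing receivers.  Bins are clock-aligned local-time
    intervals (default one hour).

    Columns: tag, bin_start (local naive time), latitude, longitude,
    easting, northing, n_detections.
    """
    cols = [tag_col, "bin_start", "latitude", "longitude", "easting", "northing",
            "n_detections"]
    if joined.empty:
        return pd.DataFrame(columns=cols)
    df = joined[[tag_col, "timestamp", "latitude", "longitude"]].copy()
    local = (
        pd.to_datetime(df["timestamp"], utc=True)
        + pd.Timedelta(hours=utc_offset_hours)
    ).dt.tz_localize(None)
    df["bin_start"] = local.dt.floor(interval)
    e, n = geo.project_to_utm(df["latitude"].to_numpy(), df["longitude"].to_numpy(), zone=zone)
    df["easting"], df["northing"] = e, n

    agg = (
        df.groupby([tag_col, "bin_start"], sort=True)
        .agg(
            easting=("easting", "mean"),
            northing=("northing", "mean"),
            n_detections=("easting", "size"),
        )
        .reset_index()
    )
    lat, lon = geo.utm_to_latlon(agg["easting"].to_numpy(), agg["northing"].to_numpy(), zone=zone)
    agg["latitude"], agg["longitude"] = lat, lon
    return agg[cols]


def dispersal_steps(
    coa: pd.DataFrame,
    *,
    geodesic: bool = False,
    tag_col: str = "tag_id",
) -> pd.DataFrame:
    """Minimum linear dispersal between consecutive COAs of each animal.

    Distance is straight-line on the projected plane (km); with
    ``geodesic=True`` a great-circle distance is used instead, preferable
    for spans of hundreds of km where projection distortion accumulates.
    Elapsed time is in hours and always positive.
    """
    cols = [tag_col, "bin_start", "to_bin_start", "distance_km", "elapsed_h"]
    if coa.empty:
        return pd.DataFrame(columns=cols)
    parts = []
    for tag, grp in coa.sort_values([tag_col, "bin_start"]).groupby(tag_col, sort=True):
        if len(grp) < 2:
            continue
        g = grp.reset_index(drop=True)
        if geodesic:
            dist = geo.geodesic_distance_m(
                g["latitude"].to_numpy()[:-1], g["longitude"].to_numpy()[:-1],
                g["latitude"].to_numpy()[1:], g["longitude"].to_numpy()[1:],
            )
        else:
            dist = geo.planar_distance_m(
                g["easting"].to_numpy()[:-1], g["northing"].to_numpy()[:-1],
                g["easting"].to_numpy()[1:], g["northing"].to_numpy()[1:],
            )
        dt = (
            g["bin_start"].to_numpy()[1:] - g["bin_start"].to_numpy()[:-1]
        ) / np.timedelta64(1, "h")
        parts.append(
            pd.DataFrame(
                {
                    tag_col: tag,
                    "bin_start": g["bin_start"].to_numpy()[:-1],
                    "to_bin_start": g["bin_start"].to_numpy()[1:],
                    "distance_km": dist / 1000.0,
                    "elapsed_h": dt,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=cols)
    return pd.concat(parts, ignore_index=True)


def roaming_index(sites_visited: int, sites_monitored: int) -> float:
    """RoI = reefs visited / reefs monitored, in [0, 1].

    A reef counts as visited on any detection there; the two-detection
    presence rule applies to day-level residency, not to roaming.
    """
    if sites_monitored < 1:
        raise UndefinedMetricError("sites_monitored must be >= 1")
    if not 0 <= sites_visited <= sites_monitored:
        raise UndefinedMetricError("need 0 <= sites_visited <= sites_monitored")
    return sites_visited / sites_monitored


def sites_visited(
    joined: pd.DataFrame, *, array_id: str | None = None, tag_col: str = "tag_id"
) -> pd.Series:
    """Distinct sites with at least one detection, per animal."""
    df = joined if array_id is None else joined.loc[joined["array_id"] == array_id]
    return df.groupby(tag_col)["site_id"].nunique()


def movement_matrix(
    joined: pd.DataFrame,
    *,
    level: str = "site",
    mode: str = "individuals",
    include_self: bool = False,
    sex: str | None = None,
    tag_col: str = "tag_id",
) -> pd.DataFrame:
    """Directed site-to-site (or array-to-array) movement matrix.

    For each animal, consecutive detections at different locations
    contribute a directed transition.  ``mode="individuals"`` counts the
    number of distinct animals observed moving between each ordered pair
    (the convention of connectivity plots pooled over a whole monitoring
    period); ``mode="moves"`` counts raw transitions.  Self-transitions are
    excluded unless ``include_self`` — the flag is recorded in
    ``df.attrs["include_self"]`` so matrix consumers know the diagonal's
    meaning.
    """
    if level not in ("site", "array"):
        raise ValueError("level must be 'site' or 'array'")
    if mode not in ("individuals", "moves"):
        raise ValueError("mode must be 'individuals' or 'moves'")
    loc = "site_id" if level == "site" else "array_id"
    df = joined
    if sex is not None:
        if "sex" not in df.columns:
            raise ValueError("stratifying by sex requires a 'sex' column (attach_tags)")
        df = df.loc[df["sex"] == sex]
    df = df.sort_values([tag_col, "timestamp"], kind="mergesort")

    frm = df.groupby(tag_col)[loc].shift()
    moves = pd.DataFrame(
        {tag_col: df[tag_col], "from": frm, "to": df[loc]}
    ).dropna(subset=["from"])
    moves = moves.loc[(moves["from"] != moves["to"]) | include_self]

    labels = sorted(joined[loc].dropna().unique())
    if mode == "individuals":
        moves = moves.drop_duplicates(subset=[tag_col, "from", "to"])
    counts = (
        moves.groupby(["from", "to"]).size().unstack(fill_value=0)
        .reindex(index=labels, columns=labels, fill_value=0)
    )
    counts.index.name = "from"
    counts.columns.name = "to"
    counts.attrs.update(level=level, mode=mode, include_self=include_self, sex=sex)
    return counts


def matrix_to_long(matrix: pd.DataFrame) -> pd.DataFrame:
    """Long-format (from, to, count) export of a movement matrix, the layout
    circular-plot tools ingest directly."""
    long = matrix.stack().rename("count").reset_index()
    return long.loc[long["count"] > 0].reset_index(drop=True)


def shelf_position_frequencies(
    matrix: pd.DataFrame, shelf_labels: dict
) -> pd.DataFrame:
    """Percentage of moves within and between inner and outer shelf reefs.

    ``shelf_labels`` maps every site in the matrix to ``"inner"`` or
    ``"outer"``.  Returns a 2x2 table of percentages summing to 100 over
    all moves counted in the input matrix.
    """
    unlabelled = [s for s in set(matrix.index) | set(matrix.columns) if s not in shelf_labels]
    if unlabelled:
        raise UndefinedMetricError(f"sites without shelf label: {sorted(unlabelled)}")
    bad = {v for v in shelf_labels.values()} - {"inner", "outer"}
    if bad:
        raise UndefinedMetricError(f"shelf labels must be inner/outer, got {bad}")

    long = matrix.stack().rename("count").reset_index()
    if not matrix.attrs.get("include_self", False):
        long = long.loc[long["from"] != long["to"]]
    total = long["count"].sum()
    if total == 0:
        raise NoEventsError("movement matrix contains no moves")
    long["from_shelf"] = long["from"].map(shelf_labels)
    long["to_shelf"] = long["to"].map(shelf_labels)
    pct = (
        long.groupby(["from_shelf", "to_shelf"])["count"].sum() / total * 100.0
    ).unstack(fill_value=0.0).reindex(
        index=["inner", "outer"], columns=["inner", "outer"], fill_value=0.0
    )
    pct.index.name = "from_shelf"
    pct.columns.name = "to_shelf"
    return pct


def acoustic_coverage(reef_area_km2: float, detection_radii_m) -> float:
    """Fraction of a reef's area inside nominal receiver detection range.

    Computed as min(1, sum of detection-range circle areas / reef area).
    No overlap correction is applied — receivers are spaced to tile reef
    slopes, and the nominal radius is itself an approximation — so this is
    an upper bound, capped at full coverage.
    """
    radii = np.asarray(detection_radii_m, dtype=float)
    if reef_area_km2 <= 0:
        raise UndefinedMetricError("reef area must be positive")
    if radii.size == 0 or np.any(radii <= 0):
        raise UndefinedMetricError("detection radii must be positive")
    covered_km2 = float(np.sum(np.pi * (radii / 1000.0) ** 2))
    return min(1.0, covered_km2 / reef_area_km2)
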