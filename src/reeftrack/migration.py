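"""Broad-scale movement: migration events across receiver arrays.

A tagged animal's detections across the coastal network of arrays form a
time-ordered sequence of array visits.  A migration event (away-episode)
opens at the first detection in a non-home array following a detection in
the home array (or following tagging, for animals that left on day one)
and closes at the next home-array detection, which marks a return.  Travel
time between arrays is the span from the last detection at the previous
array to the first detection at the next one — a minimum estimate, as the
animal may have departed later or arrived earlier than it was last/first
heard.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import NoEventsError
from .io import DEFAULT_UTC_OFFSET_HOURS, local_day

EVENT_COLUMNS = [
    "tag_id", "origin_array", "destination_array", "depart", "arrive",
    "travel_days", "arrays_visited", "return_time", "returned",
]

TRANSITION_COLUMNS = [
    "tag_id", "from_array", "to_array", "depart", "arrive", "travel_days",
]


def _array_runs(det: pd.DataFrame, tag_col: str) -> pd.DataFrame:
    """Compress a time-sorted detection sequence into runs of equal array."""
    df = det.sort_values([tag_col, "timestamp"], kind="mergesort")
    changed = (df["array_id"] != df.groupby(tag_col)["array_id"].shift()) | (
        df[tag_col] != df[tag_col].shift()
    )
    df = df.assign(_run=changed.cumsum())
    runs = df.groupby([tag_col, "_run"], sort=True).agg(
        array_id=("array_id", "first"),
        first=("timestamp", "min"),
        last=("timestamp", "max"),
    ).reset_index()
    return runs


def array_transitions(joined: pd.DataFrame, *, tag_col: str = "tag_id") -> pd.DataFrame:
    """Per-animal array-to-array legs: each change of array in the detection
    sequence yields one leg with minimum travel time in days."""
    if joined.empty:
        return pd.DataFrame(columns=TRANSITION_COLUMNS)
    runs = _array_runs(joined[[tag_col, "timestamp", "array_id"]], tag_col)
    prev = runs.groupby(tag_col).shift()
    legs = pd.DataFrame(
        {
            "tag_id": runs[tag_col],
            "from_array": prev["array_id"],
            "to_array": runs["array_id"],
            "depart": prev["last"],
            "arrive": runs["first"],
        }
    ).dropna(subset=["from_array"])
    legs["travel_days"] = (
        pd.to_datetime(legs["arrive"], utc=True) - pd.to_datetime(legs["depart"], utc=True)
    ).dt.total_seconds() / 86400.0
    return legs.reset_index(drop=True)


def detect_migration_events(
    joined: pd.DataFrame, *, home_array: str, tag_col: str = "tag_id"
) -> pd.DataFrame:
    """Find contiguous away-episodes per animal.

    Each maximal block of consecutive non-home array runs is one event:
    ``depart`` is the last home-array detection before the block (NaT when
    the animal was never detected at home first — it left on tagging),
    ``arrive`` the first detection of the block, ``destination_array`` the
    first away array visited, ``arrays_visited`` the full itinerary
    (';'-joined, in order of first visit), and ``returned`` whether a later
    home detection closed the episode.
    """
    if joined.empty:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    runs = _array_runs(joined[[tag_col, "timestamp", "array_id"]], tag_col)
    events = []
    for tag, grp in runs.groupby(tag_col, sort=True):
        g = grp.reset_index(drop=True)
        i = 0
        last_home_time = pd.NaT
        while i < len(g):
            if g.loc[i, "array_id"] == home_array:
                last_home_time = g.loc[i, "last"]
                i += 1
                continue
            # open an away block
            j = i
            itinerary = []
            while j < len(g) and g.loc[j, "array_id"] != home_array:
                if g.loc[j, "array_id"] not in itinerary:
                    itinerary.append(g.loc[j, "array_id"])
                j += 1
            returned = j < len(g)
            depart = last_home_time
            arrive = g.loc[i, "first"]
            travel = (
                (pd.Timestamp(arrive) - pd.Timestamp(depart)).total_seconds() / 86400.0
                if pd.notna(depart)
                else np.nan
            )
            events.append(
                {
                    "tag_id": tag,
                    "origin_array": home_array if pd.notna(depart) else None,
                    "destination_array": g.loc[i, "array_id"],
                    "depart": depart,
                    "arrive": arrive,
                    "travel_days": travel,
                    "arrays_visited": ";".join(itinerary),
                    "return_time": g.loc[j, "first"] if returned else pd.NaT,
                    "returned": returned,
                }
            )
            i = j
    return pd.DataFrame(events, columns=EVENT_COLUMNS)


def classify_population(
    events: pd.DataFrame, tags: pd.DataFrame, *, tag_col: str = "tag_id"
) -> dict:
    """Population-level partial-migration classification.

    Per animal: ``moved`` if it has at least one away-episode, ``stayed``
    otherwise; a mover is ``returned`` when every episode it opened also
    closed with a home-array detection.  Returns proportions over all
    tagged animals plus the per-animal table.
    """
    per_tag = pd.DataFrame({tag_col: tags[tag_col]})
    if events.empty:
        per_tag["moved"] = False
        per_tag["returned"] = False
    else:
        moved = events.groupby(tag_col).size()
        all_closed = events.groupby(tag_col)["returned"].all()
        per_tag["moved"] = per_tag[tag_col].map(moved).fillna(0).astype(int) > 0
        closed = per_tag[tag_col].map(all_closed)
        per_tag["returned"] = (
            closed.where(closed.notna(), False).astype(bool) & per_tag["moved"]
        )
    n = len(per_tag)
    n_moved = int(per_tag["moved"].sum())
    n_returned = int(per_tag["returned"].sum())
    return {
        "per_tag": per_tag,
        "n_tags": n,
        "n_moved": n_moved,
        "n_returned": n_returned,
        "prop_moved": n_moved / n if n else np.nan,
        "prop_stayed": (n - n_moved) / n if n else np.nan,
        "prop_returned_given_moved": n_returned / n_moved if n_moved else np.nan,
    }


def travel_time_summary(
    transitions: pd.DataFrame, *, destination_array: str, home_array: str
) -> dict:
    """Range and mean +/- SD of travel days for legs from the home array to
    one destination array.

    Legs arriving at the destination from anywhere other than the home
    array are excluded: a travel time "from home" is only meaningful for
    direct departures.  Raises :class:`NoEventsError` when no qualifying
    leg exists (e.g. every arrival was staged through intermediate arrays).
    """
    legs = transitions.loc[
        (transitions["to_array"] == destination_array)
        & (transitions["from_array"] == home_array)
    ]
    if legs.empty:
        raise NoEventsError(
            f"no direct legs from {home_array} to {destination_array}"
        )
    days = legs["travel_days"].astype(float)
    return {
        "destination_array": destination_array,
        "n": int(len(days)),
        "min_days": float(days.min()),
        "max_days": float(days.max()),
        "mean_days": float(days.mean()),
        "sd_days": float(days.std(ddof=1)) if len(days) > 1 else np.nan,
    }


def array_presence_summary(
    presence: pd.DataFrame,
    transitions: pd.DataFrame,
    *,
    home_array: str,
    tag_col: str = "tag_id",
) -> pd.DataFrame:
    """Per-array summary: number of animals detected, mean +/- SD of days
    detected per animal, and min/max/mean travel time from the home array
    (NaN where no direct leg from home exists)."""
    days = presence.groupby(["array_id", tag_col])["date"].nunique().rename("days")
    per_array = days.reset_index().groupby("array_id").agg(
        n_sharks=(tag_col, "nunique"),
        mean_days_detected=("days", "mean"),
        sd_days_detected=("days", lambda d: d.std(ddof=1)),
    )
    rows = []
    for array_id, row in per_array.iterrows():
        rec = {
            "array_id": array_id,
            "n_sharks": int(row["n_sharks"]),
            "mean_days_detected": float(row["mean_days_detected"]),
            "sd_days_detected": float(row["sd_days_detected"])
            if pd.notna(row["sd_days_detected"]) else np.nan,
        }
        if array_id != home_array:
            try:
                tt = travel_time_summary(
                    transitions, destination_array=array_id, home_array=home_array
                )
                rec.update(
                    travel_min_days=tt["min_days"],
                    travel_max_days=tt["max_days"],
                    travel_mean_days=tt["mean_days"],
                    travel_sd_days=tt["sd_days"],
                )
            except NoEventsError:
                rec.update(
                    travel_min_days=np.nan, travel_max_days=np.nan,
                    travel_mean_days=np.nan, travel_sd_days=np.nan,
                )
        else:
            rec.update(
                travel_min_days=np.nan, travel_max_days=np.nan,
                travel_mean_days=np.nan, travel_sd_days=np.nan,
            )
        rows.append(rec)
    return pd.DataFrame(rows)


def monthly_array_occupancy(
    presence: pd.DataFrame, tags: pd.DataFrame, *, tag_col: str = "tag_id"
) -> pd.DataFrame:
    """Distinct animals with at least one presence day, per array x month x
    sex.  An animal present in two arrays in one month counts in both."""
    if presence.empty:
        return pd.DataFrame(columns=["array_id", "month", "sex", "n_individuals"])
    df = presence.merge(tags[[tag_col, "sex"]], on=tag_col, how="left")
    df["month"] = df["date"].dt.to_period("M").astype(str)
    out = (
        df.groupby(["array_id", "month", "sex"])[tag_col]
        .nunique()
        .rename("n_individuals")
        .reset_index()
    )
    return out


def monthly_depth_summary(
    joined: pd.DataFrame,
    *,
    utc_offset_hours: float = DEFAULT_UTC_OFFSET_HOURS,
    tag_col: str = "tag_id",
) -> pd.DataFrame:
    """Monthly mean and SD of transmitter depth per animal x array.

    Depth comes from the transmitters' pressure sensors; detections without
    a depth value are ignored.  Returns an empty frame (with a warning)
    when no detection carries depth.
    """
    cols = [tag_col, "array_id", "month", "mean_depth_m", "sd_depth_m", "n"]
    df = joined.loc[joined["depth_m"].notna()] if "depth_m" in joined.columns else joined.iloc[0:0]
    if df.empty:
        warnings.warn("no depth values present; depth summary is empty", stacklevel=2)
        return pd.DataFrame(columns=cols)
    month = local_day(df["timestamp"], utc_offset_hours).dt.to_period("M").astype(str)
    out = (
        df.assign(month=month)
        .groupby([tag_col, "array_id", "month"])["depth_m"]
        .agg(mean_depth_m="mean", sd_depth_m=lambda d: d.std(ddof=1), n="size")
        .reset_index()
    )
    return out[cols]
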