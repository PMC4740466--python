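"""Daily presence and residency metrics.

The presence rule follows standard practice for reef-scale acoustic arrays:
an animal is considered present in an array on a local calendar day when two
or more detections, no more than an hour apart, were logged on any receivers
of that array on that day.  The single-detection case is treated as a
possible false positive (code collision / reflection) and does not confer
presence.  A pair spanning midnight confers presence on neither day, because
the rule anchors the pair to one calendar day.

From the presence ledger the module derives the per-animal residency
metrics used throughout coastal shark telemetry:

* days monitored (DM) — days from tagging to the end of the study;
* days detected (DD) — presence days in the home array;
* residency index (RI) — DD / DM, in [0, 1];
* maximum consecutive detection days;
* residency groups — banded RI classes I (high) through IV (very low).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .errors import UndefinedMetricError
from .io import DEFAULT_UTC_OFFSET_HOURS, local_day

DEFAULT_HOUR_WINDOW_S = 3600.0
DEFAULT_GROUP_CUTPOINTS = (0.09, 0.20, 0.50)
GROUP_LABELS = ("I", "II", "III", "IV")


def round_half_up(x, ndigits: int = 2):
    """Round with ties away from zero, the convention of printed report
    tables (numpy/python bankers' rounding would turn 0.645 into 0.64).

    Works on the decimal representation so that a value entered as 0.645
    is treated as the tie it looks like, not as its binary neighbour.
    """
    from decimal import ROUND_HALF_UP, Decimal

    quantum = Decimal(1).scaleb(-ndigits)

    def _one(v: float) -> float:
        if not math.isfinite(v):
            return v
        return float(Decimal(repr(v)).quantize(quantum, rounding=ROUND_HALF_UP))

    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        return _one(float(arr))
    return np.array([_one(float(v)) for v in arr.ravel()]).reshape(arr.shape)


def daily_presence(
    joined: pd.DataFrame,
    *,
    hour_window_s: float = DEFAULT_HOUR_WINDOW_S,
    min_detections: int = 2,
    utc_offset_hours: float = DEFAULT_UTC_OFFSET_HOURS,
    tag_col: str = "tag_id",
) -> pd.DataFrame:
    """Build the presence ledger: one row per (tag, local day, array) that
    satisfies the presence rule.

    With ``min_detections=2`` (default) a day qualifies iff some pair of
    detections on that day, pooled across the array's receivers, are at most
    ``hour_window_s`` apart.  ``min_detections=1`` accepts any detection —
    the appropriate threshold for sparse satellite arrays where pairs are
    unlikely.

    Columns: tag, date, array_id, n_detections, n_sites, sites (sorted,
    ';'-joined).
    """
    if joined.empty:
        return pd.DataFrame(
            columns=[tag_col, "date", "array_id", "n_detections", "n_sites", "sites"]
        )
    df = joined[[tag_col, "timestamp", "array_id", "site_id"]].copy()
    df["date"] = local_day(df["timestamp"], utc_offset_hours)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    df = df.sort_values([tag_col, "array_id", "date", "timestamp"], kind="mergesort")

    grp = df.groupby([tag_col, "date", "array_id"], sort=True)
    ledger = grp.agg(
        n_detections=("timestamp", "size"),
        n_sites=("site_id", "nunique"),
        sites=("site_id", lambda s: ";".join(sorted(set(s.astype(str))))),
    ).reset_index()

    if min_detections >= 2:
        # min gap between consecutive detections within the (tag, day, array)
        gaps = grp["timestamp"].agg(
            lambda t: t.diff().dt.total_seconds().min() if len(t) > 1 else np.inf
        )
        ledger["_min_gap"] = gaps.to_numpy()
        ok = (ledger["n_detections"] >= min_detections) & (
            ledger["_min_gap"] <= hour_window_s
        )
        ledger = ledger.loc[ok].drop(columns="_min_gap")
    return ledger.reset_index(drop=True)


def days_monitored(tagging_date, study_end, *, inclusive: bool = True) -> int:
    """Days from tagging to the last day of the study.

    ``study_end`` is the final monitored calendar day; with the default
    inclusive convention both endpoints count, so tagging on the last day
    gives DM = 1.
    """
    t0 = pd.Timestamp(tagging_date).normalize()
    t1 = pd.Timestamp(study_end).normalize()
    if t1 < t0:
        raise UndefinedMetricError("study_end precedes tagging_date")
    return int((t1 - t0).days) + (1 if inclusive else 0)


def residency_index(days_detected, days_monitored):
    """RI = DD / DM; proportion of monitored days with confirmed presence."""
    dd = np.asarray(days_detected, dtype=float)
    dm = np.asarray(days_monitored, dtype=float)
    if np.any(dm < 1):
        raise UndefinedMetricError("days_monitored must be >= 1")
    if np.any((dd < 0) | (dd > dm)):
        raise UndefinedMetricError("need 0 <= days_detected <= days_monitored")
    out = dd / dm
    return float(out) if out.ndim == 0 else out


def max_consecutive_days(dates) -> int:
    """Length of the longest run of strictly consecutive calendar days."""
    days = pd.to_datetime(pd.Series(sorted(set(pd.to_datetime(list(dates)))))) if len(
        list(dates)
    ) else pd.Series(dtype="datetime64[ns]")
    if days.empty:
        return 0
    deltas = days.diff().dt.days.to_numpy()
    best = run = 1
    for d in deltas[1:]:
        run = run + 1 if d == 1 else 1
        best = max(best, run)
    return int(best)


def assign_residency_groups(ri, cutpoints=DEFAULT_GROUP_CUTPOINTS):
    """Band RI values into groups I-IV.

    I: RI > high cut (default 0.50); II: mid <= RI <= high; III:
    low <= RI < mid; IV: RI < low.  The band between the top of the
    published group-II range (0.40) and the group-I floor is assigned to II,
    i.e. group I strictly requires RI above the high cut.
    """
    low, mid, high = cutpoints
    arr = np.asarray(ri, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise UndefinedMetricError("RI values must lie in [0, 1]")
    labels = np.where(
        arr > high, "I", np.where(arr >= mid, "II", np.where(arr >= low, "III", "IV"))
    )
    if arr.ndim == 0:
        return str(labels)
    return pd.Series(labels, index=ri.index if isinstance(ri, pd.Series) else None)


def single_linkage_groups(ri, n_groups: int = 4):
    """Generic 1-D single-linkage hierarchical clustering of RI values.

    Returns ``(labels, linkage_matrix)`` where labels are relabelled in
    descending order of cluster mean RI (so label "I" is the most resident
    cluster), mirroring the dendrogram-based grouping used in residency
    studies.  The linkage matrix is scipy-format and can be drawn with
    ``scipy.cluster.hierarchy.dendrogram``.
    """
    arr = np.asarray(ri, dtype=float).reshape(-1, 1)
    if len(arr) < n_groups:
        raise UndefinedMetricError("fewer observations than requested groups")
    lm = linkage(arr, method="single")
    raw = fcluster(lm, t=n_groups, criterion="maxclust")
    order = (
        pd.DataFrame({"cluster": raw, "ri": arr.ravel()})
        .groupby("cluster")["ri"]
        .mean()
        .sort_values(ascending=False)
        .index
    )
    rename = {c: GROUP_LABELS[i] if i < len(GROUP_LABELS) else str(i + 1)
              for i, c in enumerate(order)}
    labels = pd.Series([rename[c] for c in raw],
                       index=ri.index if isinstance(ri, pd.Series) else None)
    return labels, lm


def residency_summary(
    presence: pd.DataFrame,
    tags: pd.DataFrame,
    *,
    home_array: str,
    study_end,
    cutpoints=DEFAULT_GROUP_CUTPOINTS,
    tag_col: str = "tag_id",
) -> pd.DataFrame:
    """Per-animal residency summary table: DM, DD, max consecutive days, RI,
    and group label, for every tagged animal (zero rows detected included)."""
    home = presence.loc[presence["array_id"] == home_array]
    per_tag = home.groupby(tag_col)["date"]
    dd = per_tag.nunique()
    maxc = per_tag.apply(lambda d: max_consecutive_days(d))

    out = tags[[tag_col, "sex", "fork_length_cm", "tagging_date"]].copy()
    out["days_monitored"] = [
        days_monitored(t, study_end) for t in out["tagging_date"]
    ]
    out["days_detected"] = out[tag_col].map(dd).fillna(0).astype(int)
    out["max_consecutive_days"] = out[tag_col].map(maxc).fillna(0).astype(int)
    out["residency_index"] = residency_index(
        out["days_detected"], out["days_monitored"]
    )
    out["group"] = assign_residency_groups(out["residency_index"], cutpoints)
    return out


def exclude_transients(
    summaries: pd.DataFrame, min_detection_days: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a residency-summary table into (kept, excluded).

    Animals detected in the home array on fewer than ``min_detection_days``
    days likely left the array at tagging; they are excluded from
    population residency statistics but retained for migration analysis.
    """
    if summaries.empty:
        return summaries.copy(), summaries.copy()
    mask = summaries["days_detected"] >= min_detection_days
    return (
        summaries.loc[mask].reset_index(drop=True),
        summaries.loc[~mask].reset_index(drop=True),
    )


def monthly_residency_table(
    presence: pd.DataFrame,
    tags: pd.DataFrame,
    *,
    home_array: str,
    study_end,
    tag_col: str = "tag_id",
) -> pd.DataFrame:
    """Month-level residency response: for each animal and each month from
    its tagging month to the end of the study, the number of presence days
    and the number of days at liberty (prorated in the tagging and final
    months).  This is the response table for binomial residency models.
    """
    end = pd.Timestamp(study_end).normalize()
    home = presence.loc[presence["array_id"] == home_array]
    det_by_month = (
        home.assign(month=home["date"].dt.to_period("M"))
        .groupby([tag_col, "month"])["date"]
        .nunique()
    )
    rows = []
    for _, tag in tags.iterrows():
        t0 = pd.Timestamp(tag["tagging_date"]).normalize()
        for month in pd.period_range(t0.to_period("M"), end.to_period("M"), freq="M"):
            first = max(t0, month.start_time.normalize())
            last = min(end, month.end_time.normalize())
            liberty = int((last - first).days) + 1
            detected = int(det_by_month.get((tag[tag_col], month), 0))
            rows.append(
                {
                    tag_col: tag[tag_col],
                    "month": str(month),
                    "days_detected": detected,
                    "days_at_liberty": liberty,
                    "proportion": detected / liberty if liberty else np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SummaryStat:
    mean: float
    sd: float          # sample SD (n-1); NaN when n == 1
    min: float
    max: float
    n: int


def _stat(values) -> SummaryStat:
    v = pd.to_numeric(pd.Series(values), errors="coerce").dropna()
    n = len(v)
    return SummaryStat(
        mean=float(v.mean()) if n else math.nan,
        sd=float(v.std(ddof=1)) if n > 1 else math.nan,
        min=float(v.min()) if n else math.nan,
        max=float(v.max()) if n else math.nan,
        n=n,
    )


def population_summary(
    summaries: pd.DataFrame,
    metrics: tuple[str, ...] = (
        "residency_index",
        "roaming_index",
        "fork_length_cm",
        "max_consecutive_days",
        "days_detected",
    ),
) -> pd.DataFrame:
    """Mean/SD/min/max of each metric, overall and by sex.

    SD uses the n-1 denominator and is NaN for single-animal strata (the
    ``n`` column makes that unambiguous in output).
    """
    if summaries.empty:
        raise UndefinedMetricError("population_summary needs at least one animal")
    rows = []
    strata = [("all", summaries)] + [
        (sex, grp) for sex, grp in summaries.groupby("sex")
    ]
    for name, grp in strata:
        for metric in metrics:
            if metric not in grp.columns:
                continue
            s = _stat(grp[metric])
            rows.append(
                {"stratum": name, "metric": metric, "mean": s.mean, "sd": s.sd,
                 "min": s.min, "max": s.max, "n": s.n}
            )
    return pd.DataFrame(rows)
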