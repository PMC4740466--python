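"""Environmental covariate series and model-ready tables.

The pipeline does not fit presence or residency models itself — those are
ordinary GLM/GLMM fits best done in a statistics environment — but it
assembles their input tables: a daily environmental series averaged across
weather stations, and a daily count-of-animals response table joined to
those covariates.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .errors import ValidationError


def aggregate_environment(env: pd.DataFrame) -> pd.DataFrame:
    """Daily mean of temperature, wind and rain across reporting stations.

    Stations are weighted equally; dates with no reporting station are
    omitted rather than interpolated.  ``n_stations_reporting`` records how
    many stations contributed to each day.
    """
    cols = ["date", "temperature_c", "wind_kmh", "rain_mm", "n_stations_reporting"]
    if env.empty:
        return pd.DataFrame(columns=cols)
    if env.duplicated(subset=["date", "station_id"]).any():
        raise ValidationError("duplicate (date, station) environment records")
    out = (
        env.groupby("date")
        .agg(
            temperature_c=("temperature_c", "mean"),
            wind_kmh=("wind_kmh", "mean"),
            rain_mm=("rain_mm", "mean"),
            n_stations_reporting=("station_id", "nunique"),
        )
        .reset_index()
    )
    return out[cols]


def build_daily_count_table(
    presence: pd.DataFrame,
    tags: pd.DataFrame,
    daily_env: pd.DataFrame,
    *,
    home_array: str,
    tag_col: str = "tag_id",
) -> pd.DataFrame:
    """Daily number of animals present in the home array, by sex, joined to
    environmental covariates — the response table for a Gaussian/Poisson
    presence GLM with month, sex and weather as predictors.

    One row per covariate-covered date x sex, zero counts included.  Dates
    with presence but no covariates are dropped with a warning (the model
    cannot use them).
    """
    home = presence.loc[presence["array_id"] == home_array]
    df = home.merge(tags[[tag_col, "sex"]], on=tag_col, how="left")
    counts = (
        df.groupby(["date", "sex"])[tag_col].nunique().rename("n_sharks").reset_index()
    )

    env_dates = pd.to_datetime(daily_env["date"]).unique()
    uncovered = set(counts["date"]) - set(env_dates)
    if uncovered:
        warnings.warn(
            f"{len(uncovered)} presence date(s) lack environmental covariates "
            "and were dropped from the model table",
            stacklevel=2,
        )

    grid = pd.MultiIndex.from_product(
        [sorted(env_dates), ["F", "M"]], names=["date", "sex"]
    ).to_frame(index=False)
    out = grid.merge(counts, on=["date", "sex"], how="left")
    out["n_sharks"] = out["n_sharks"].fillna(0).astype(int)
    out = out.merge(
        daily_env[["date", "temperature_c", "wind_kmh", "rain_mm"]], on="date", how="left"
    )
    out["month"] = pd.to_datetime(out["date"]).dt.strftime("%b")
    return out[["date", "sex", "n_sharks", "month", "temperature_c", "wind_kmh", "rain_mm"]]
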