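"""Synthetic telemetry datasets with known ground truth.

The generator emulates the design of a reef-scale passive acoustic study:
a focal array of midshelf reefs (default 17, spaced 5-15 km apart, 3-4
receivers each) plus satellite arrays strung along a coastline hundreds to
1,400 km away; depth-sensing transmitters pinging at pseudo-random 50-100 s
intervals; individually heterogeneous residency; and a female-biased subset
of animals undertaking summer excursions to distant arrays with
near-certain return.

Movement is a daily-resolution Markov process: each animal-day is spent at
one focal reef, at one satellite array (during a scheduled excursion), or
off-array in unmonitored space.  Within a day the animal is acoustically
available for a configurable block of hours, sitting at one receiver per
hour.  This is deliberately the simplest process that exercises every
pipeline metric — presence, residency, roaming, centres of activity,
movement matrices, and migration events — with an exactly known truth.

Everything is driven by one :class:`numpy.random.Generator`; a fixed seed
reproduces the output byte-for-byte.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geo

HOME_ARRAY = "TSV"
OFF_ARRAY = "off"

#: satellite arrays: name -> (coastal distance from the focal array in km,
#: bearing in degrees clockwise from north, number of receivers)
DEFAULT_SATELLITES = {
    "LOI": (310.0, 325.0, 3),
    "ORI": (78.0, 325.0, 4),
    "CB": (79.0, 250.0, 4),
    "HI": (730.0, 155.0, 4),
    "LEI": (833.0, 155.0, 2),
    "FI": (912.0, 160.0, 3),
    "SC": (1038.0, 165.0, 3),
    "MB": (1161.0, 168.0, 4),
    "CR": (1400.0, 170.0, 3),
}


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults mirror the reference study design: 17 focal reefs monitored
    Oct 2012 onwards for 734 days, 33 animals at a 25:8 female:male ratio,
    fork length ~ N(201.8, 25.2) cm, transmitters rated to 68 m pinging at
    uniform 50-100 s intervals, receivers with a 250 m nominal detection
    radius.
    """

    seed: int = 0
    # array geometry
    n_sites_focal: int = 17
    receivers_per_site: int = 4
    site_spacing_km: tuple[float, float] = (5.0, 15.0)
    shelf_row_separation_km: float = 10.0
    receiver_spacing_m: float = 600.0
    detection_radius_m: float = 250.0
    array_center: tuple[float, float] = (-18.7, 147.2)  # lat, lon
    satellites: dict = field(default_factory=lambda: dict(DEFAULT_SATELLITES))
    # study window and animals
    study_start: str = "2012-10-08"
    study_days: int = 734
    n_animals: int = 33
    female_fraction: float = 25.0 / 33.0
    fork_length_mean_cm: float = 201.8
    fork_length_sd_cm: float = 25.2
    tag_window_days: int = 480
    # daily movement
    residency_beta: tuple[float, float] = (0.8, 3.4)  # per-animal target occupancy
    leave_prob_range: tuple[float, float] = (0.05, 0.40)
    site_switch_prob: float = 0.30
    # migration
    migration_probability: dict = field(default_factory=lambda: {"F": 0.55, "M": 0.45})
    migration_months: tuple[int, ...] = (12, 1, 2)
    swim_speed_km_per_day: float = 40.0
    away_dwell_mean_days: float = 4.0
    return_probability: float = 0.94
    # detection process
    ping_interval_s: tuple[float, float] = (50.0, 100.0)
    hours_in_range_per_day: int = 6
    detection_probability: float = 0.8
    transmitter_depth_rating_m: float = 68.0
    # environment
    n_weather_stations: int = 3

    def validate(self) -> None:
        if self.n_sites_focal < 1:
            raise ValueError("n_sites_focal must be >= 1")
        if self.receivers_per_site < 1:
            raise ValueError("receivers_per_site must be >= 1")
        if self.n_animals < 0:
            raise ValueError("n_animals must be >= 0")
        for p in (
            self.detection_probability,
            self.return_probability,
            self.site_switch_prob,
            self.female_fraction,
            *self.migration_probability.values(),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        lo, hi = self.ping_interval_s
        if not 0 < lo <= hi:
            raise ValueError("ping_interval_s must be 0 < lo <= hi")
        if not 1 <= self.hours_in_range_per_day <= 24:
            raise ValueError("hours_in_range_per_day must be in 1..24")
        if self.study_days < 1:
            raise ValueError("study_days must be >= 1")


@dataclass
class GroundTruth:
    """Per-animal truth of the simulated movement process."""

    occupancy: pd.DataFrame  # tag_id, date, array_id, site_id
    excursions: pd.DataFrame  # tag_id, destination_array, dates, returned
    residency: pd.DataFrame  # tag_id, days_monitored, focal_days, true_residency

    def to_json(self, path) -> None:
        payload = {
            "occupancy": _frame_records(self.occupancy),
            "excursions": _frame_records(self.excursions),
            "residency": _frame_records(self.residency),
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=str))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        occ = pd.DataFrame(payload["occupancy"])
        exc = pd.DataFrame(payload["excursions"])
        res = pd.DataFrame(payload["residency"])
        for col in ("date",):
            if col in occ.columns:
                occ[col] = pd.to_datetime(occ[col])
        for col in ("depart_date", "arrive_date", "leave_date", "return_date"):
            if col in exc.columns:
                exc[col] = pd.to_datetime(exc[col])
        return cls(occupancy=occ, excursions=exc, residency=res)


def _frame_records(df: pd.DataFrame) -> list:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    return out.where(pd.notna(out), None).to_dict(orient="records")


def _focal_site_ids(n: int) -> list[str]:
    return [f"Reef{i + 1:02d}" for i in range(n)]


def simulate_array(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Lay out the focal and satellite arrays.

    Returns ``(receivers, sites)``: a receiver deployment table in the
    format :func:`reeftrack.io.read_receivers` produces, and a site registry
    with positions, shelf labels (focal sites only, inner/outer rows) and a
    notional reef area for coverage estimates.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    e0, n0 = geo.project_to_utm(*config.array_center)
    start = pd.Timestamp(config.study_start)
    end = start + pd.Timedelta(days=config.study_days - 1)

    site_rows = []
    n_inner = int(np.ceil(config.n_sites_focal / 2))
    along = 0.0
    lo, hi = config.site_spacing_km
    for i in range(config.n_sites_focal):
        row = 0 if i < n_inner else 1
        if i in (0, n_inner):
            along = 0.0
        else:
            along += rng.uniform(lo, hi)
        e = e0 + along * 1000.0
        n = n0 - row * config.shelf_row_separation_km * 1000.0
        site_rows.append(
            {
                "array_id": HOME_ARRAY,
                "site_id": _focal_site_ids(config.n_sites_focal)[i],
                "easting": e,
                "northing": n,
                "shelf": "inner" if row == 1 else "outer",
                "reef_area_km2": float(np.round(rng.uniform(1.0, 30.0), 3)),
                "n_receivers": config.receivers_per_site,
            }
        )
    for name, (dist_km, bearing_deg, n_rec) in config.satellites.items():
        b = np.radians(bearing_deg)
        site_rows.append(
            {
                "array_id": name,
                "site_id": f"{name}-S1",
                "easting": e0 + dist_km * 1000.0 * np.sin(b),
                "northing": n0 + dist_km * 1000.0 * np.cos(b),
                "shelf": None,
                "reef_area_km2": float(np.round(rng.uniform(1.0, 30.0), 3)),
                "n_receivers": n_rec,
            }
        )
    sites = pd.DataFrame(site_rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # distant satellites are off-zone by design
        lat, lon = geo.utm_to_latlon(sites["easting"].to_numpy(), sites["northing"].to_numpy())
    sites["latitude"], sites["longitude"] = lat, lon

    # receivers on a small square around each site centre
    rec_rows = []
    serial = 100001
    offsets = [(-0.5, -0.5), (0.5, -0.5), (-0.5, 0.5), (0.5, 0.5)]
    for _, site in sites.iterrows():
        for k in range(int(site["n_receivers"])):
            ox, oy = offsets[k % 4]
            ring = 1 + k // 4  # extra receivers spiral outwards
            e = site["easting"] + ox * ring * config.receiver_spacing_m
            n = site["northing"] + oy * ring * config.receiver_spacing_m
            rec_rows.append(
                {
                    "receiver_id": f"VR2W-{serial}",
                    "array_id": site["array_id"],
                    "site_id": site["site_id"],
                    "easting": e,
                    "northing": n,
                    "active_from": start,
                    "active_to": end,
                    "detection_radius_m": config.detection_radius_m,
                }
            )
            serial += 1
    receivers = pd.DataFrame(rec_rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lat, lon = geo.utm_to_latlon(
            receivers["easting"].to_numpy(), receivers["northing"].to_numpy()
        )
    receivers["latitude"], receivers["longitude"] = lat, lon
    receivers = receivers[
        ["receiver_id", "array_id", "site_id", "latitude", "longitude",
         "active_from", "active_to", "detection_radius_m", "easting", "northing"]
    ]
    return receivers, sites


def simulate_tags(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the tagged animals: ids, sex, length, tagging date and site."""
    n = config.n_animals
    site_ids = _focal_site_ids(config.n_sites_focal)
    n_f = int(round(n * config.female_fraction))
    sexes = np.array(["F"] * n_f + ["M"] * (n - n_f))
    rng.shuffle(sexes)
    fl = np.clip(
        rng.normal(config.fork_length_mean_cm, config.fork_length_sd_cm, size=n),
        120.0, 300.0,
    ).round(0)
    start = pd.Timestamp(config.study_start)
    # every animal must be tagged inside the monitored window
    window = min(config.tag_window_days, config.study_days - 1)
    offsets = np.sort(rng.integers(0, window + 1, size=n)) if n else []
    rows = []
    for i in range(n):
        rows.append(
            {
                "tag_id": f"S{i + 1}",
                "transmitter_id": f"A69-1601-{60001 + i}",
                "sex": sexes[i],
                "fork_length_cm": fl[i],
                "tagging_date": start + pd.Timedelta(days=int(offsets[i])),
                "tagging_site": site_ids[int(rng.integers(0, len(site_ids)))],
                "home_array": HOME_ARRAY,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["tag_id", "transmitter_id", "sex", "fork_length_cm",
                 "tagging_date", "tagging_site", "home_array"],
    )


def _schedule_excursion(config, rng, tagging_day: int):
    """Pick a departure day (within a migration-window month after tagging),
    destination, travel and dwell durations.  Returns None if no summer
    window remains in the animal's monitored span."""
    start = pd.Timestamp(config.study_start)
    days = np.arange(tagging_day + 1, config.study_days)
    if days.size == 0:
        return None
    months = (start + pd.to_timedelta(days, unit="D")).month
    candidates = days[np.isin(months, config.migration_months)]
    if candidates.size == 0:
        return None
    depart = int(candidates[int(rng.integers(0, candidates.size))])
    names = list(config.satellites)
    dest = names[int(rng.integers(0, len(names)))]
    dist_km = config.satellites[dest][0]
    travel = max(1, int(round(dist_km / config.swim_speed_km_per_day
                              + rng.exponential(2.0))))
    dwell = 1 + int(rng.poisson(max(config.away_dwell_mean_days - 1, 0.0)))
    return depart, dest, travel, dwell


def simulate_movement(
    config: SimulationConfig,
    tags: pd.DataFrame,
    rng: np.random.Generator,
) -> GroundTruth:
    """Run the daily-state movement process for every animal.

    Each animal gets a target focal-array occupancy drawn from a beta
    distribution (individual heterogeneity) realised through leave/return
    probabilities of a two-state chain, a site-switch probability within
    the focal array, and at most one scheduled migration excursion
    (sex-biased probability, summer departure, distance-dependent travel
    time, near-certain return).
    """
    start = pd.Timestamp(config.study_start)
    site_ids = _focal_site_ids(config.n_sites_focal)
    occ_rows, exc_rows, res_rows = [], [], []

    for _, tag in tags.iterrows():
        tagging_day = int((pd.Timestamp(tag["tagging_date"]) - start).days)
        n_days = config.study_days - tagging_day

        pi = rng.beta(*config.residency_beta)
        p_leave = rng.uniform(*config.leave_prob_range)
        p_return = min(1.0, pi * p_leave / max(1.0 - pi, 1e-9))

        excursion = None
        if rng.uniform() < config.migration_probability.get(tag["sex"], 0.0):
            excursion = _schedule_excursion(config, rng, tagging_day)
        if excursion is not None:
            depart, dest, travel, dwell = excursion
            returns = rng.uniform() < config.return_probability
            away_start = depart + travel
            away_end = away_start + dwell  # exclusive
            back = away_end + travel if returns else None

        state_site = tag["tagging_site"]
        in_array = True
        day_states = []
        for d in range(tagging_day, config.study_days):
            if excursion is not None and d >= depart:
                if d < away_start:
                    day_states.append((d, OFF_ARRAY, None)); continue
                if d < away_end:
                    day_states.append((d, dest, f"{dest}-S1")); continue
                if back is None or d < back:
                    day_states.append((d, OFF_ARRAY, None)); continue
                if d == back:
                    in_array = True
                    state_site = site_ids[int(rng.integers(0, len(site_ids)))]
            if in_array:
                day_states.append((d, HOME_ARRAY, state_site))
                if rng.uniform() < p_leave:
                    in_array = False
                elif rng.uniform() < config.site_switch_prob:
                    state_site = site_ids[int(rng.integers(0, len(site_ids)))]
            else:
                day_states.append((d, OFF_ARRAY, None))
                if rng.uniform() < p_return:
                    in_array = True
                    state_site = site_ids[int(rng.integers(0, len(site_ids)))]

        focal_days = sum(1 for _, a, _s in day_states if a == HOME_ARRAY)
        for d, a, s in day_states:
            occ_rows.append(
                {"tag_id": tag["tag_id"], "date": start + pd.Timedelta(days=d),
                 "array_id": a, "site_id": s}
            )
        res_rows.append(
            {
                "tag_id": tag["tag_id"],
                "days_monitored": n_days,
                "focal_days": focal_days,
                "true_residency": focal_days / n_days if n_days else np.nan,
            }
        )
        if excursion is not None:
            exc_rows.append(
                {
                    "tag_id": tag["tag_id"],
                    "destination_array": dest,
                    "depart_date": start + pd.Timedelta(days=depart),
                    "arrive_date": start + pd.Timedelta(days=away_start),
                    "leave_date": start + pd.Timedelta(days=away_end - 1),
                    "return_date": (start + pd.Timedelta(days=back))
                    if back is not None and back < config.study_days else pd.NaT,
                    "returned": bool(back is not None and back < config.study_days),
                    "away_days": int(dwell),
                }
            )

    occupancy = pd.DataFrame(
        occ_rows, columns=["tag_id", "date", "array_id", "site_id"]
    )
    excursions = pd.DataFrame(
        exc_rows,
        columns=["tag_id", "destination_array", "depart_date", "arrive_date",
                 "leave_date", "return_date", "returned", "away_days"],
    )
    residency = pd.DataFrame(
        res_rows, columns=["tag_id", "days_monitored", "focal_days", "true_residency"]
    )
    return GroundTruth(occupancy=occupancy, excursions=excursions, residency=residency)


def simulate_detections(
    truth: GroundTruth,
    receivers: pd.DataFrame,
    tags: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Generate the detection table implied by the movement truth.

    For every monitored animal-day the animal is acoustically available for
    a contiguous block of ``hours_in_range_per_day`` local hours, sitting at
    one receiver of its day's site per hour.  Ping times advance by uniform
    draws from ``ping_interval_s``; each ping is logged by that receiver
    with probability ``detection_probability`` (a step detection-range
    model: in range or not).  Depth values are drawn around a per-site mean
    and clipped to the transmitter's rating.
    """
    lo, hi = config.ping_interval_s
    mean_gap = (lo + hi) / 2.0
    tz = pd.Timedelta(hours=10)  # local (UTC+10) -> UTC

    rec_by_site: dict[str, list[str]] = {
        site: grp["receiver_id"].tolist() for site, grp in receivers.groupby("site_id")
    }
    site_depth = {
        site: (rng.uniform(12.0, 20.0) if grp["array_id"].iloc[0] == HOME_ARRAY
               else rng.uniform(4.0, 15.0))
        for site, grp in receivers.groupby("site_id")
    }
    tx_of = dict(zip(tags["tag_id"], tags["transmitter_id"]))

    frames = []
    occ = truth.occupancy
    occ = occ.loc[occ["site_id"].notna()].sort_values(["tag_id", "date"], kind="mergesort")
    for row in occ.itertuples(index=False):
        recs = rec_by_site.get(row.site_id)
        if not recs:
            continue
        h0 = int(rng.integers(0, 25 - config.hours_in_range_per_day))
        block_s = config.hours_in_range_per_day * 3600.0
        n_max = int(block_s / lo) + 2
        gaps = rng.uniform(lo, hi, size=n_max)
        t = np.cumsum(gaps)
        t = t[t < block_s]
        if t.size == 0:
            continue
        detected = rng.uniform(size=t.size) < config.detection_probability
        t = t[detected]
        if t.size == 0:
            continue
        hour_idx = np.minimum((t // 3600.0).astype(int), config.hours_in_range_per_day - 1)
        rec_choice = rng.integers(0, len(recs), size=config.hours_in_range_per_day)
        rec_ids = [recs[rec_choice[h]] for h in hour_idx]
        depth = np.clip(
            rng.normal(site_depth[row.site_id], 2.0, size=t.size),
            0.0, config.transmitter_depth_rating_m,
        ).round(1)
        ts = (
            pd.Timestamp(row.date)
            + pd.to_timedelta(h0 * 3600.0 + t, unit="s")
            - tz
        )
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": ts,
                    "receiver_id": rec_ids,
                    "transmitter_id": tx_of[row.tag_id],
                    "depth_m": depth,
                }
            )
        )
    if not frames:
        det = pd.DataFrame(columns=["timestamp", "receiver_id", "transmitter_id", "depth_m"])
        det["timestamp"] = pd.to_datetime(det["timestamp"], utc=True)
        return det
    det = pd.concat(frames, ignore_index=True)
    # receivers log at second precision; gaps >= 50 s keep order strict
    det["timestamp"] = pd.to_datetime(det["timestamp"]).dt.floor("s").dt.tz_localize("UTC")
    det = det.sort_values(
        ["timestamp", "receiver_id", "transmitter_id"], kind="mergesort"
    ).reset_index(drop=True)
    return det


def simulate_environment(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Daily temperature/wind/rain series for a few weather stations.

    Temperature follows a seasonal sinusoid peaking in late January
    (austral summer, 24-29 degC band typical of the central GBR); wind is a
    truncated normal; rain is zero-inflated gamma."""
    start = pd.Timestamp(config.study_start)
    dates = pd.date_range(start, periods=config.study_days, freq="D")
    doy = dates.dayofyear.to_numpy()
    rows = []
    for s in range(config.n_weather_stations):
        base = 26.5 + rng.normal(0.0, 0.3)
        temp = base + 2.5 * np.cos(2 * np.pi * (doy - 25) / 365.25) + rng.normal(0, 0.4, len(dates))
        wind = np.clip(rng.normal(15.0, 6.0, len(dates)), 0.0, None)
        rain = np.where(
            rng.uniform(size=len(dates)) < 0.3, rng.gamma(1.5, 6.0, len(dates)), 0.0
        )
        rows.append(
            pd.DataFrame(
                {
                    "date": dates,
                    "station_id": f"WS{s + 1}",
                    "temperature_c": np.round(temp, 2),
                    "wind_kmh": np.round(wind, 2),
                    "rain_mm": np.round(rain, 2),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_dataset(config: SimulationConfig) -> dict:
    """Generate a full input bundle: receivers, sites, tags, detections,
    environment, and the ground truth.  Deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    receivers, sites = simulate_array(config, rng)
    tags = simulate_tags(config, rng)
    truth = simulate_movement(config, tags, rng)
    detections = simulate_detections(truth, receivers, tags, config, rng)
    environment = simulate_environment(config, rng)
    return {
        "receivers": receivers,
        "sites": sites,
        "tags": tags,
        "detections": detections,
        "environment": environment,
        "truth": truth,
        "config": config,
    }


def write_bundle(bundle: dict, outdir) -> dict:
    """Write a simulated bundle to CSV files in the dialect the readers
    accept, plus ground_truth.json.  Returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    det = bundle["detections"].copy()
    det["timestamp"] = det["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    paths["detections"] = outdir / "detections.csv"
    det.to_csv(paths["detections"], index=False)

    rec = bundle["receivers"].drop(columns=["easting", "northing"], errors="ignore").copy()
    for c in ("active_from", "active_to"):
        rec[c] = pd.to_datetime(rec[c]).dt.strftime("%Y-%m-%d")
    paths["receivers"] = outdir / "receivers.csv"
    rec.to_csv(paths["receivers"], index=False)

    tags = bundle["tags"].copy()
    tags["tagging_date"] = pd.to_datetime(tags["tagging_date"]).dt.strftime("%Y-%m-%d")
    paths["tags"] = outdir / "tags.csv"
    tags.to_csv(paths["tags"], index=False)

    env = bundle["environment"].copy()
    env["date"] = pd.to_datetime(env["date"]).dt.strftime("%Y-%m-%d")
    paths["environment"] = outdir / "environment.csv"
    env.to_csv(paths["environment"], index=False)

    paths["sites"] = outdir / "sites.csv"
    bundle["sites"].to_csv(paths["sites"], index=False)

    paths["ground_truth"] = outdir / "ground_truth.json"
    bundle["truth"].to_json(paths["ground_truth"])
    return paths
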