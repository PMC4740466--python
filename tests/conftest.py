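"""Shared fixtures: the published per-shark reference table and a small
simulated study used across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from reeftrack import io
from reeftrack.datasets import load_shark_summaries
from reeftrack.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def shark_table() -> pd.DataFrame:
    return load_shark_summaries()


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=7, n_animals=8, study_days=200, tag_window_days=60)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_joined(small_bundle) -> pd.DataFrame:
    joined, rejects = io.join_detections_to_deployments(
        small_bundle["detections"], small_bundle["receivers"].drop(columns=["easting", "northing"])
    )
    assert rejects.empty
    joined, tag_rejects = io.attach_tags(joined, small_bundle["tags"])
    assert tag_rejects.empty
    return joined


def make_detections(rows) -> pd.DataFrame:
    """Build a normalised detection frame from (iso_ts, receiver, transmitter)
    triples (optionally + depth)."""
    recs = []
    for row in rows:
        ts, rid, tid = row[:3]
        depth = row[3] if len(row) > 3 else np.nan
        recs.append(
            {"timestamp": pd.Timestamp(ts, tz="UTC"), "receiver_id": rid,
             "transmitter_id": tid, "depth_m": depth}
        )
    return pd.DataFrame(recs, columns=io.DETECTION_COLUMNS)


def make_receivers(rows) -> pd.DataFrame:
    """Build a deployment frame from (receiver, array, site, lat, lon) tuples;
    active over 2012-2015 unless the tuple appends (from, to)."""
    recs = []
    for row in rows:
        rid, arr, site, lat, lon = row[:5]
        frm = pd.Timestamp(row[5]) if len(row) > 5 else pd.Timestamp("2012-01-01")
        to = pd.Timestamp(row[6]) if len(row) > 6 else pd.Timestamp("2015-12-31")
        recs.append(
            {"receiver_id": rid, "array_id": arr, "site_id": site,
             "latitude": lat, "longitude": lon, "active_from": frm,
             "active_to": to, "detection_radius_m": 250.0}
        )
    return pd.DataFrame(recs, columns=io.RECEIVER_COLUMNS)
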