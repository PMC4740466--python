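"""Packaged reference data.

``townsville_bull_sharks.csv`` is the published per-shark residency summary
for 33 adult bull sharks (*Carcharhinus leucas*) acoustically monitored on
17 midshelf reefs off Townsville, central Great Barrier Reef, October
2012 - October 2014.  It carries, per animal: tagging reef and date, sex,
fork length, days monitored (DM), days detected (DD), maximum consecutive
detection days, reefs visited (of 17 monitored), a migration flag
("M" — detected at another receiver array; "M-R" — migrated and returned)
and the printed roaming and residency indices (rounded to 2 decimals;
values below 0.01 were printed as "<0.01" and load as NaN in the
``*_printed`` columns).

This is a desk-scale ground truth for the metric layer: the index columns
are recomputable exactly from the count columns.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: last monitored calendar day of the reference study (DM is counted
#: inclusively from the tagging date through this day)
STUDY_LAST_DAY = pd.Timestamp("2014-10-14")

#: reefs monitored in the focal (home) array
N_MONITORED_REEFS = 17

HOME_ARRAY = "TSV"


def load_shark_summaries() -> pd.DataFrame:
    """Load the packaged per-shark residency summary table.

    Adds numeric ``roaming_index_printed`` / ``residency_index_printed``
    columns (NaN where the table printed "<0.01").
    """
    with resources.files("reeftrack.data").joinpath(
        "townsville_bull_sharks.csv"
    ).open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)
    df["tagging_date"] = pd.to_datetime(df["tagging_date"])
    for col in ("roaming_index_printed", "residency_index_printed"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df
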