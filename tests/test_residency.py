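"""Presence rule, residency metrics, grouping, and population summaries."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reeftrack import residency
from reeftrack.datasets import N_MONITORED_REEFS, STUDY_LAST_DAY
from reeftrack.errors import UndefinedMetricError

from conftest import make_detections


def _joined(rows):
    """Detection rows (ts, receiver, site) in one array for one animal."""
    det = make_detections([(ts, rid, "TX1") for ts, rid, _ in rows])
    det["array_id"] = "TSV"
    det["site_id"] = [site for _, _, site in rows]
    det["tag_id"] = "S1"
    return det


class TestDailyPresence:
    # timestamps below are UTC; local day (UTC+10) is the date shown + 10 h
    def test_pair_within_hour_confers_presence(self):
        led = residency.daily_presence(
            _joined([("2013-03-04 01:00:00", "R1", "A"),
                     ("2013-03-04 01:30:00", "R2", "B")])
        )
        assert len(led) == 1
        assert led.loc[0, "n_detections"] == 2 and led.loc[0, "sites"] == "A;B"

    def test_single_detection_is_not_presence(self):
        led = residency.daily_presence(_joined([("2013-03-04 01:00:00", "R1", "A")]))
        assert led.empty

    def test_pair_wider_than_hour_is_not_presence(self):
        led = residency.daily_presence(
            _joined([("2013-03-04 01:00:00", "R1", "A"),
                     ("2013-03-04 02:30:00", "R1", "A")])
        )
        assert led.empty

    def test_pair_spanning_local_midnight_confers_nothing(self):
        # 13:45 and 14:15 UTC straddle midnight at UTC+10
        led = residency.daily_presence(
            _joined([("2013-03-04 13:45:00", "R1", "A"),
                     ("2013-03-04 14:15:00", "R1", "A")])
        )
        assert led.empty

    def test_single_detection_threshold_for_sparse_arrays(self):
        led = residency.daily_presence(
            _joined([("2013-03-04 01:00:00", "R1", "A")]), min_detections=1
        )
        assert len(led) == 1

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.data())
    def test_presence_is_monotone_in_detections(self, data):
        base_rows = data.draw(
            st.lists(
                st.tuples(
                    st.integers(0, 3),      # day
                    st.integers(0, 86399),  # second of day
                ),
                min_size=0, max_size=12,
            )
        )
        extra_rows = data.draw(
            st.lists(st.tuples(st.integers(0, 3), st.integers(0, 86399)),
                     min_size=1, max_size=6)
        )

        def build(rows):
            return _joined(
                [
                    (
                        (pd.Timestamp("2013-03-01") + pd.Timedelta(days=d, seconds=s))
                        .strftime("%Y-%m-%d %H:%M:%S"),
                        "R1", "A",
                    )
                    for d, s in rows
                ]
            )

        before = residency.daily_presence(build(base_rows))
        after = residency.daily_presence(build(base_rows + extra_rows))
        days_before = set(before["date"]) if not before.empty else set()
        days_after = set(after["date"]) if not after.empty else set()
        assert days_before <= days_after


class TestResidencyIndex:
    @pytest.mark.parametrize(
        "dd,dm,expected", [(473, 734, 0.64), (0, 100, 0.0), (100, 100, 1.0)]
    )
    def test_values(self, dd, dm, expected):
        assert residency.round_half_up(residency.residency_index(dd, dm), 2) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(UndefinedMetricError):
            residency.residency_index(0, 0)

    def test_bounds_hold_for_random_inputs(self):
        rng = np.random.default_rng(3)
        dm = rng.integers(1, 1000, 200)
        dd = (rng.uniform(size=200) * dm).astype(int)
        ri = residency.residency_index(dd, dm)
        assert np.all((ri >= 0) & (ri <= 1))


class TestDaysMonitored:
    def test_reproduces_published_dm_for_all_sharks(self, shark_table):
        dm = [
            residency.days_monitored(t, STUDY_LAST_DAY)
            for t in shark_table["tagging_date"]
        ]
        assert dm == shark_table["days_monitored"].tolist()

    def test_tagging_on_last_day_gives_one(self):
        assert residency.days_monitored("2014-10-14", STUDY_LAST_DAY) == 1

    def test_end_before_tagging_rejected(self):
        with pytest.raises(UndefinedMetricError):
            residency.days_monitored("2014-10-15", STUDY_LAST_DAY)


class TestMaxConsecutiveDays:
    d0 = dt.date(2013, 5, 1)

    @pytest.mark.parametrize(
        "offsets,expected",
        [([], 0), ([0], 1), ([0, 1, 2, 10], 3), ([0, 2, 4], 1), ([5, 1, 0, 4, 3], 3)],
    )
    def test_examples(self, offsets, expected):
        dates = {self.d0 + dt.timedelta(days=o) for o in offsets}
        assert residency.max_consecutive_days(dates) == expected

    def test_agrees_with_set_walk_oracle(self):
        # independent oracle: start a walk at every run head
        def oracle(dates):
            s = set(dates)
            best = 0
            for d in s:
                if d - dt.timedelta(days=1) not in s:
                    run = 1
                    while d + dt.timedelta(days=run) in s:
                        run += 1
                    best = max(best, run)
            return best

        rng = np.random.default_rng(11)
        for _ in range(200):
            offs = rng.choice(200, size=rng.integers(0, 60), replace=False)
            dates = {self.d0 + dt.timedelta(days=int(o)) for o in offs}
            assert residency.max_consecutive_days(dates) == oracle(dates)


class TestResidencyGroups:
    def test_published_table_partitions_4_8_8_12(self, shark_table):
        kept = shark_table.loc[shark_table["days_detected"] >= 2]
        ri = kept["days_detected"] / kept["days_monitored"]
        groups = residency.assign_residency_groups(ri)
        assert groups.value_counts().to_dict() == {"IV": 12, "II": 8, "III": 8, "I": 4}

    def test_scalar_and_edge_labels(self):
        assert residency.assign_residency_groups(0.64) == "I"
        assert residency.assign_residency_groups(0.0) == "IV"
        assert residency.assign_residency_groups(0.45) == "II"  # unassigned band -> II
        with pytest.raises(UndefinedMetricError):
            residency.assign_residency_groups(1.2)

    def test_single_linkage_matches_thresholds_on_separated_data(self):
        # four tight, well-separated bands: the dendrogram cut and the
        # threshold rule must agree
        rng = np.random.default_rng(5)
        ri = np.concatenate(
            [
                rng.uniform(0.00, 0.05, 8),
                rng.uniform(0.12, 0.17, 6),
                rng.uniform(0.27, 0.32, 5),
                rng.uniform(0.60, 0.65, 4),
            ]
        )
        labels, lm = residency.single_linkage_groups(pd.Series(ri), n_groups=4)
        expected = residency.assign_residency_groups(pd.Series(ri))
        assert (labels == expected).all()
        assert lm.shape == (len(ri) - 1, 4)


class TestTransientsAndMonthly:
    def test_exclusion_rule(self):
        df = pd.DataFrame(
            {"tag_id": ["A", "B", "C"], "days_detected": [1, 3, 0], "sex": "F"}
        )
        kept, excl = residency.exclude_transients(df)
        assert kept["tag_id"].tolist() == ["B"]
        assert sorted(excl["tag_id"]) == ["A", "C"]
        k2, e2 = residency.exclude_transients(df.iloc[0:0])
        assert k2.empty and e2.empty

    def _presence(self, dates):
        return pd.DataFrame(
            {
                "tag_id": "S1",
                "date": pd.to_datetime(list(dates)),
                "array_id": "TSV",
                "n_detections": 10,
                "n_sites": 1,
                "sites": "A",
            }
        )

    def _tags(self, tagging):
        return pd.DataFrame(
            {"tag_id": ["S1"], "sex": ["F"], "fork_length_cm": [200.0],
             "tagging_date": [pd.Timestamp(tagging)]}
        )

    def test_full_month_present_is_one(self):
        dates = pd.date_range("2013-06-01", "2013-06-30")
        tbl = residency.monthly_residency_table(
            self._presence(dates), self._tags("2013-06-01"),
            home_array="TSV", study_end="2013-06-30",
        )
        assert len(tbl) == 1 and tbl.loc[0, "proportion"] == 1.0

    def test_tagging_month_is_prorated(self):
        dates = pd.date_range("2013-06-16", "2013-06-30")
        tbl = residency.monthly_residency_table(
            self._presence(dates), self._tags("2013-06-16"),
            home_array="TSV", study_end="2013-06-30",
        )
        assert tbl.loc[0, "days_at_liberty"] == 15
        assert tbl.loc[0, "proportion"] == 1.0

    def test_absent_month_is_zero_row(self):
        tbl = residency.monthly_residency_table(
            self._presence(pd.date_range("2013-06-01", "2013-06-03")),
            self._tags("2013-06-01"),
            home_array="TSV", study_end="2013-07-31",
        )
        july = tbl.loc[tbl["month"] == "2013-07"]
        assert july["proportion"].eq(0.0).all()
        # liberty days never exceed the month length
        assert (tbl["days_at_liberty"] <= 31).all()


class TestPopulationSummary:
    def test_single_animal_sd_is_nan(self):
        df = pd.DataFrame(
            {"tag_id": ["A"], "sex": ["F"], "residency_index": [0.3]}
        )
        out = residency.population_summary(df, metrics=("residency_index",))
        row = out.loc[(out["stratum"] == "all")].iloc[0]
        assert row["mean"] == 0.3 and np.isnan(row["sd"]) and row["n"] == 1

    def test_round_half_up_ties(self):
        assert residency.round_half_up(0.645, 2) == 0.65
        assert residency.round_half_up(0.115, 2) == 0.12
        assert residency.round_half_up(-0.645, 2) == -0.65
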