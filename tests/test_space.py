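"""Centre-of-activity positioning, dispersal, roaming, movement matrices
and acoustic coverage."""

import numpy as np
import pandas as pd
import pytest

from reeftrack import geo, space
from reeftrack.datasets import N_MONITORED_REEFS
from reeftrack.errors import NoEventsError, UndefinedMetricError
from reeftrack.residency import round_half_up

from conftest import make_detections


def _joined_at(points):
    """Detections at given projected offsets (m) from a reference origin.

    points: list of (iso_ts, easting_offset, northing_offset, site).
    """
    e0, n0 = geo.project_to_utm(-18.7, 147.2)
    rows, lats, lons, sites = [], [], [], []
    for i, (ts, de, dn, site) in enumerate(points):
        lat, lon = geo.utm_to_latlon(e0 + de, n0 + dn)
        rows.append((ts, f"R{de}_{dn}", "TX1"))
        lats.append(lat)
        lons.append(lon)
        sites.append(site)
    det = make_detections(rows)
    det["latitude"] = lats
    det["longitude"] = lons
    det["array_id"] = "TSV"
    det["site_id"] = sites
    det["tag_id"] = "S1"
    return det, (e0, n0)


class TestCenterOfActivity:
    def test_single_receiver_coa_is_receiver_position(self):
        det, (e0, n0) = _joined_at(
            [("2013-03-04 01:10:00", 0, 0, "A"), ("2013-03-04 01:20:00", 0, 0, "A")]
        )
        coa = space.center_of_activity(det)
        assert len(coa) == 1
        assert coa.loc[0, "easting"] == pytest.approx(e0, abs=0.01)
        assert coa.loc[0, "northing"] == pytest.approx(n0, abs=0.01)
        assert coa.loc[0, "n_detections"] == 2

    def test_equal_counts_give_midpoint(self):
        det, (e0, n0) = _joined_at(
            [("2013-03-04 01:10:00", 0, 0, "A"), ("2013-03-04 01:20:00", 0, 4000, "A")]
        )
        coa = space.center_of_activity(det)
        assert coa.loc[0, "northing"] == pytest.approx(n0 + 2000, abs=0.01)

    def test_three_to_one_weighting(self):
        det, (e0, n0) = _joined_at(
            [
                ("2013-03-04 01:05:00", 0, 0, "A"),
                ("2013-03-04 01:15:00", 0, 0, "A"),
                ("2013-03-04 01:25:00", 0, 0, "A"),
                ("2013-03-04 01:35:00", 0, 4000, "A"),
            ]
        )
        coa = space.center_of_activity(det)
        assert coa.loc[0, "northing"] == pytest.approx(n0 + 1000, abs=0.01)

    def test_hour_bins_are_clock_aligned(self):
        det, _ = _joined_at(
            [("2013-03-04 01:59:00", 0, 0, "A"), ("2013-03-04 02:01:00", 0, 0, "A")]
        )
        coa = space.center_of_activity(det)
        assert len(coa) == 2

    def test_hull_property_on_simulated_tracks(self, small_joined, small_bundle):
        rec = small_bundle["receivers"]
        home = small_joined.loc[small_joined["array_id"] == "TSV"]
        coa = space.center_of_activity(home)
        hr = rec.loc[rec["array_id"] == "TSV"]
        eps = 0.01
        assert (coa["easting"] >= hr["easting"].min() - eps).all()
        assert (coa["easting"] <= hr["easting"].max() + eps).all()
        assert (coa["northing"] >= hr["northing"].min() - eps).all()
        assert (coa["northing"] <= hr["northing"].max() + eps).all()


class TestDispersal:
    def _coa(self, rows):
        return pd.DataFrame(
            rows,
            columns=["tag_id", "bin_start", "latitude", "longitude", "easting",
                     "northing", "n_detections"],
        )

    def test_three_four_five_triangle(self):
        t = pd.Timestamp("2013-03-04 01:00:00")
        coa = self._coa(
            [
                ("S1", t, -18.7, 147.2, 0.0, 0.0, 3),
                ("S1", t + pd.Timedelta(hours=2), -18.7, 147.2, 3000.0, 4000.0, 1),
            ]
        )
        steps = space.dispersal_steps(coa)
        assert steps.loc[0, "distance_km"] == pytest.approx(5.0)
        assert steps.loc[0, "elapsed_h"] == pytest.approx(2.0)

    def test_single_coa_yields_no_steps(self):
        t = pd.Timestamp("2013-03-04 01:00:00")
        assert space.dispersal_steps(
            self._coa([("S1", t, -18.7, 147.2, 0.0, 0.0, 1)])
        ).empty

    def test_stationary_track(self):
        t = pd.Timestamp("2013-03-04 01:00:00")
        coa = self._coa(
            [("S1", t + pd.Timedelta(hours=h), -18.7, 147.2, 10.0, 20.0, 1)
             for h in range(4)]
        )
        steps = space.dispersal_steps(coa)
        assert (steps["distance_km"] == 0).all() and (steps["elapsed_h"] > 0).all()

    def test_triangle_inequality_on_simulated_tracks(self, small_joined):
        home = small_joined.loc[small_joined["array_id"] == "TSV"]
        coa = space.center_of_activity(home)
        steps = space.dispersal_steps(coa)
        for tag, grp in steps.groupby("tag_id"):
            d = grp["distance_km"].to_numpy()
            if len(d) < 2:
                continue
            g = coa.loc[coa["tag_id"] == tag].reset_index(drop=True)
            d13 = np.hypot(
                g["easting"].to_numpy()[2:] - g["easting"].to_numpy()[:-2],
                g["northing"].to_numpy()[2:] - g["northing"].to_numpy()[:-2],
            ) / 1000.0
            assert np.all(d13 <= d[:-1] + d[1:] + 1e-9)


class TestRoamingIndex:
    @pytest.mark.parametrize(
        "visited,expected2dp", [(11, 0.65), (17, 1.0), (2, 0.12)]
    )
    def test_printed_values(self, visited, expected2dp):
        roi = space.roaming_index(visited, N_MONITORED_REEFS)
        assert round_half_up(roi, 2) == expected2dp

    def test_preconditions(self):
        with pytest.raises(UndefinedMetricError):
            space.roaming_index(1, 0)
        with pytest.raises(UndefinedMetricError):
            space.roaming_index(18, 17)


class TestMovementMatrix:
    def _joined_moves(self, seq, tag="S1"):
        rows = []
        t = pd.Timestamp("2013-03-04 01:00:00", tz="UTC")
        for i, site in enumerate(seq):
            rows.append(
                {"tag_id": tag, "timestamp": t + pd.Timedelta(minutes=10 * i),
                 "receiver_id": f"R-{site}", "site_id": site, "array_id": "TSV"}
            )
        return pd.DataFrame(rows)

    def test_individuals_mode_counts_each_animal_once_per_pair(self):
        j = self._joined_moves(["A", "B", "A", "B"])
        m = space.movement_matrix(j)
        assert m.loc["A", "B"] == 1 and m.loc["B", "A"] == 1

    def test_moves_mode_counts_transitions(self):
        j = self._joined_moves(["A", "B", "A", "B"])
        m = space.movement_matrix(j, mode="moves")
        assert m.loc["A", "B"] == 2 and m.loc["B", "A"] == 1

    def test_no_site_change_gives_empty_matrix(self):
        m = space.movement_matrix(self._joined_moves(["A", "A", "A"]))
        assert m.to_numpy().sum() == 0

    def test_two_animals_sum(self):
        j = pd.concat(
            [self._joined_moves(["A", "B"], "S1"), self._joined_moves(["A", "B"], "S2")],
            ignore_index=True,
        )
        m = space.movement_matrix(j)
        assert m.loc["A", "B"] == 2


class TestShelfFrequencies:
    labels = {"A": "inner", "B": "inner", "C": "outer"}

    def _matrix(self, entries):
        sites = ["A", "B", "C"]
        m = pd.DataFrame(0, index=sites, columns=sites)
        for (f, t), c in entries.items():
            m.loc[f, t] = c
        m.index.name, m.columns.name = "from", "to"
        m.attrs["include_self"] = False
        return m

    def test_all_inner_moves(self):
        pct = space.shelf_position_frequencies(
            self._matrix({("A", "B"): 4, ("B", "A"): 1}), self.labels
        )
        assert pct.loc["inner", "inner"] == 100.0

    def test_uniform_cells(self):
        pct = space.shelf_position_frequencies(
            self._matrix({("A", "B"): 2, ("A", "C"): 2, ("C", "B"): 2, ("C", "C"): 0}),
            self.labels,
        )
        assert pct.to_numpy().sum() == pytest.approx(100.0)
        assert pct.loc["inner", "inner"] == pytest.approx(100 / 3)

    def test_empty_matrix_flags_no_moves(self):
        with pytest.raises(NoEventsError):
            space.shelf_position_frequencies(self._matrix({}), self.labels)

    def test_unlabelled_site_rejected(self):
        with pytest.raises(UndefinedMetricError):
            space.shelf_position_frequencies(self._matrix({("A", "B"): 1}), {"A": "inner"})

    def test_percentages_conserve_total_moves(self, small_joined):
        home = small_joined.loc[small_joined["array_id"] == "TSV"]
        m = space.movement_matrix(home, mode="moves")
        labels = {s: ("inner" if int(s[-2:]) % 2 else "outer") for s in m.index}
        pct = space.shelf_position_frequencies(m, labels)
        off_diag = m.to_numpy().sum() - np.trace(m.to_numpy())
        assert pct.to_numpy().sum() == pytest.approx(100.0)
        # recover absolute counts from percentages
        assert (pct.to_numpy() / 100.0 * off_diag).sum() == pytest.approx(off_diag)


class TestAcousticCoverage:
    def test_exact_full_coverage(self):
        area = np.pi * 0.25**2
        assert space.acoustic_coverage(area, [250.0]) == 1.0

    def test_two_receivers_small_fraction(self):
        # 2 * pi * (0.25 km)^2 over 19.635 km^2 = 0.02
        cov = space.acoustic_coverage(19.635, [250.0, 250.0])
        assert cov == pytest.approx(0.02, abs=5e-5)

    def test_caps_at_one(self):
        assert space.acoustic_coverage(0.01, [250.0, 250.0]) == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(UndefinedMetricError):
            space.acoustic_coverage(0.0, [250.0])
        with pytest.raises(UndefinedMetricError):
            space.acoustic_coverage(1.0, [0.0])
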