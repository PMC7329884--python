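import datetime as dt

import numpy as np
import pandas as pd
import pytest

import geopheno as gp
from geopheno.phenotypes import DIURNAL_ENERGY_FLOOR

from conftest import MIN
from oracles import sinusoid_fit_power

HOUR = 60 * MIN
DAY = 24 * HOUR


def sp_frame(rows):
    """Rows of (arrival_ms, departure_ms, lat, lon)."""
    return pd.DataFrame(
        {
            "arrival_ms": [r[0] for r in rows],
            "departure_ms": [r[1] for r in rows],
            "centroid_lat": [r[2] for r in rows],
            "centroid_lon": [r[3] for r in rows],
            "duration_min": [(r[1] - r[0]) / MIN for r in rows],
        }
    )


class TestNormalizedEntropy:
    def test_uniform_four_places_is_one(self):
        assert gp.normalized_entropy(np.full(4, 0.25)) == pytest.approx(1.0)

    def test_single_place_is_zero(self):
        assert gp.normalized_entropy(np.array([1.0])) == 0.0

    def test_closed_form_80_20(self):
        expected = -(0.8 * np.log(0.8) + 0.2 * np.log(0.2)) / np.log(2)
        val = gp.normalized_entropy(np.array([0.8, 0.2]))
        assert val == pytest.approx(expected)
        assert val == pytest.approx(0.7219, abs=1e-4)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(rng.integers(2, 9)))
        assert 0.0 <= gp.normalized_entropy(p) <= 1.0

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            gp.normalized_entropy(np.array([0.7, 0.2]))


class TestCountPhenotypes:
    def test_single_day_counts(self):
        sps = sp_frame(
            [
                (8 * HOUR, 10 * HOUR, 52.0, 5.0),
                (11 * HOUR, 13 * HOUR, 52.01, 5.0),
                (14 * HOUR, 16 * HOUR, 52.0, 5.0),
            ]
        )
        trs = pd.DataFrame({"start_ms": [10 * HOUR, 13 * HOUR], "end_ms": [11 * HOUR, 14 * HOUR]})
        counts = gp.count_phenotypes(sps, trs, np.array([0, 1, 0]))
        assert len(counts) == 1
        row = counts.iloc[0]
        assert (row["places_visited"], row["unique_places"], row["trajectories"]) == (3, 2, 2)

    def test_empty_inputs_give_empty_table(self):
        counts = gp.count_phenotypes(
            sp_frame([]), pd.DataFrame({"start_ms": [], "end_ms": []}), np.array([])
        )
        assert counts.empty

    def test_midnight_spanning_staypoint_counted_on_arrival_day(self):
        sps = sp_frame([(23 * HOUR + 50 * MIN, DAY + 2 * HOUR, 52.0, 5.0)])
        trs = pd.DataFrame({"start_ms": [], "end_ms": []})
        counts = gp.count_phenotypes(sps, trs, np.array([0]))
        assert len(counts) == 1
        assert counts["date"].iloc[0] == dt.date(1970, 1, 1)
        assert counts["places_visited"].iloc[0] == 1


class TestInferHome:
    def test_nightly_place_wins(self):
        rows = []
        for d in range(3):  # nights at A (cluster 0), days at B (cluster 1)
            rows.append((d * DAY, d * DAY + 7 * HOUR, 52.0, 5.0))
            rows.append((d * DAY + 9 * HOUR, d * DAY + 18 * HOUR, 52.05, 5.0))
        sps = sp_frame(rows)
        home = gp.infer_home(sps, np.array([0, 1] * 3))
        assert home.determined and home.home_cluster_id == 0

    def test_tie_broken_by_total_dwell(self):
        # equal nighttime dwell (2 h each), cluster 1 has more total dwell
        sps = sp_frame(
            [
                (2 * HOUR, 4 * HOUR, 52.0, 5.0),
                (DAY + 2 * HOUR, DAY + 4 * HOUR, 52.05, 5.0),
                (DAY + 10 * HOUR, DAY + 20 * HOUR, 52.05, 5.0),
            ]
        )
        home = gp.infer_home(sps, np.array([0, 1, 1]))
        assert home.home_cluster_id == 1

    def test_no_night_dwell_leaves_home_undetermined(self):
        sps = sp_frame([(10 * HOUR, 14 * HOUR, 52.0, 5.0)])
        home = gp.infer_home(sps, np.array([0]))
        assert not home.determined
        hs = gp.home_stay(sps, np.array([0]), home)
        assert hs["home_stay_pct"].isna().all()


class TestHomeStay:
    def test_all_dwell_at_home(self):
        sps = sp_frame([(0, 6 * HOUR, 52.0, 5.0), (8 * HOUR, 20 * HOUR, 52.0, 5.0)])
        assign = np.array([0, 0])
        home = gp.infer_home(sps, assign)
        hs = gp.home_stay(sps, assign, home)
        assert hs["home_stay_pct"].iloc[0] == pytest.approx(100.0)

    def test_18h_home_6h_elsewhere(self):
        sps = sp_frame(
            [(0, 18 * HOUR, 52.0, 5.0), (18 * HOUR, 24 * HOUR, 52.05, 5.0)]
        )
        assign = np.array([0, 1])
        home = gp.infer_home(sps, assign)
        hs = gp.home_stay(sps, assign, home)
        row = hs.iloc[0]
        assert row["home_stay_hours"] == pytest.approx(18.0)
        assert row["home_stay_pct"] == pytest.approx(75.0)

    def test_midnight_spanning_hours_conserve_time(self):
        sps = sp_frame([(20 * HOUR, DAY + 8 * HOUR, 52.0, 5.0)])
        assign = np.array([0])
        home = gp.infer_home(sps, assign)
        hs = gp.home_stay(sps, assign, home)
        assert len(hs) == 2
        assert hs["home_stay_hours"].tolist() == pytest.approx([4.0, 8.0])
        assert hs["home_stay_hours"].sum() == pytest.approx(12.0)
        assert (hs["home_stay_hours"] <= 24.0).all()

    def test_elapsed_denominator(self):
        sps = sp_frame([(0, 12 * HOUR, 52.0, 5.0)])
        assign = np.array([0])
        home = gp.infer_home(sps, assign)
        hs = gp.home_stay(sps, assign, home, denominator="elapsed")
        assert hs["home_stay_pct"].iloc[0] == pytest.approx(50.0)


class TestDiurnalMovement:
    def routine(self, n_days, jitter_h=0.0, rng=None):
        """Home nights / work days at fixed (or jittered) clock times."""
        rows, labels = [], []
        for d in range(n_days):
            j = 0.0 if rng is None else rng.uniform(-jitter_h, jitter_h)
            rows.append((d * DAY, int(d * DAY + (8 + j) * HOUR), 52.0, 5.0))
            rows.append(
                (int(d * DAY + (9 + j) * HOUR), int(d * DAY + (17 + j) * HOUR), 52.1, 5.1)
            )
            rows.append((int(d * DAY + 18 * HOUR), (d + 1) * DAY, 52.0, 5.0))
        return sp_frame(rows)

    def test_periodic_beats_shuffled(self):
        periodic = self.routine(10)
        rng = np.random.default_rng(0)
        # destroy the 24-h phase by jittering dwell clock times day to day
        irregular = self.routine(10, jitter_h=6.0, rng=np.random.default_rng(1))
        assert gp.diurnal_movement(periodic) > gp.diurnal_movement(irregular)

    def test_constant_location_hits_floor(self):
        sps = sp_frame([(0, 4 * DAY, 52.0, 5.0)])
        assert gp.diurnal_movement(sps) == pytest.approx(np.log(DIURNAL_ENERGY_FLOOR))

    def test_too_few_days_is_missing(self):
        assert np.isnan(gp.diurnal_movement(self.routine(2)))

    def test_single_frequency_matches_least_squares_oracle(self):
        sps = self.routine(14)
        score = gp.diurnal_movement(sps, period_band_h=(24.0, 24.0))
        # rebuild the same sampled series the phenotype uses
        from geopheno.phenotypes import diurnal_movement  # noqa: F401
        step = 10 * MIN
        grid = np.arange(sps["arrival_ms"].min(), sps["departure_ms"].max() + 1, step)
        arr = sps["arrival_ms"].to_numpy(float)
        dep = sps["departure_ms"].to_numpy(float)
        idx = np.clip(np.searchsorted(arr, grid, side="right") - 1, 0, len(sps) - 1)
        known = (grid >= arr[idx]) & (grid - dep[idx] <= 60 * MIN)
        t_sec = (grid[known] - grid[0]) / 1000.0
        lat = sps["centroid_lat"].to_numpy()[idx[known]]
        lon = sps["centroid_lon"].to_numpy()[idx[known]]
        expected = sinusoid_fit_power(t_sec, lat, 24.0) + sinusoid_fit_power(
            t_sec, lon, 24.0
        )
        assert np.exp(score) == pytest.approx(expected, rel=1e-6)


class TestAdjustCounts:
    def cohort(self, counts, ndays):
        return pd.DataFrame({"places_visited": counts, "n_days_observed": ndays})

    def test_proportional_counts_become_constant(self):
        ndays = np.array([7.0, 14.0, 21.0, 28.0])
        df = self.cohort(3.0 * ndays, ndays)
        out = gp.adjust_counts_for_duration(df, ["places_visited"])
        assert np.allclose(out["places_visited_adj"], out["places_visited_adj"].iloc[0])

    def test_constant_duration_is_identity(self):
        df = self.cohort([5.0, 9.0, 7.0], [14.0, 14.0, 14.0])
        with pytest.warns(UserWarning):
            out = gp.adjust_counts_for_duration(df, ["places_visited"])
        assert np.allclose(out["places_visited_adj"], df["places_visited"])

    def test_residuals_orthogonal_to_duration(self):
        rng = np.random.default_rng(5)
        ndays = rng.uniform(5, 30, 40)
        counts = 2.0 * ndays + rng.normal(0, 3, 40)
        df = self.cohort(counts, ndays)
        out = gp.adjust_counts_for_duration(df, ["places_visited"])
        resid = out["places_visited_adj"] - counts.mean()
        r = np.corrcoef(resid, ndays)[0, 1]
        assert abs(r) < 1e-10


class TestPhenotypeTable:
    def test_summary_row_consistency(self, sim_result):
        result, _ = sim_result
        table = result.phenotypes
        summary = table[table["date"] == "all"].iloc[0]
        days = table[table["date"] != "all"]
        assert summary["places_visited"] == days["places_visited"].sum()
        assert summary["trajectories"] == days["trajectories"].sum()
        assert summary["unique_places"] <= summary["places_visited"]
        assert 0.0 <= summary["normalized_entropy"] <= 1.0
        assert 0.0 <= summary["home_stay_pct"] <= 100.0
        assert (days["home_stay_hours"].dropna() <= 24.0 + 1e-9).all()
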