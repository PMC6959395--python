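"""Mobility metrics: per-feature oracles, invariants and the daily table."""

import numpy as np
import pandas as pd
import pytest
from helpers import (
    brute_diversity,
    brute_gyration,
    brute_sd,
    brute_total_distance,
    hav_km,
)
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import DEG_PER_KM, points_frame, stops_frame
from mobisym.features import (
    BASE_FEATURES,
    MobilityFeatureExtractor,
    daily_features,
    displacement_features,
    distance_stats,
    diversity,
    interval_features,
    max_displacement_from_home,
    radius_of_gyration,
    rolling_aggregates,
    significant_places,
    split_stops_at_midnight,
    total_distance,
    visit_counts,
)
from mobisym.places import StopDetector


def equator_lons(*km):
    """Longitudes (deg) of points at the given east offsets in km on the equator."""
    return [k * DEG_PER_KM for k in km]


class TestTotalDistance:
    def test_single_point_is_zero(self):
        assert total_distance([0.0], [0.0]) == 0.0

    def test_two_half_degree_legs(self):
        lats = [0.0, 0.0, 0.0]
        lons = [0.0, 0.5, 1.0]
        assert total_distance(lats, lons) == pytest.approx(111.195, abs=1e-3)

    def test_matches_brute_force_on_random_traces(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 15))
            lat = rng.uniform(44, 46, n)
            lon = rng.uniform(10, 12, n)
            expected = brute_total_distance(list(zip(lat, lon)))
            assert total_distance(lat, lon) == pytest.approx(expected, rel=1e-9)


class TestDistanceStats:
    def test_equal_legs(self):
        lons = equator_lons(0, 1, 2, 3)
        avg, sd = distance_stats([0.0] * 4, lons)
        assert avg == pytest.approx(1.0, rel=1e-6)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_unequal_legs(self):
        # legs 0 km and 2 km
        lons = equator_lons(0, 0, 2)
        avg, sd = distance_stats([0.0] * 3, lons)
        assert avg == pytest.approx(1.0, rel=1e-6)
        assert sd == pytest.approx(np.sqrt(2.0), rel=1e-6)

    def test_single_point_is_missing(self):
        avg, sd = distance_stats([0.0], [0.0])
        assert np.isnan(avg) and np.isnan(sd)


class TestDisplacements:
    def test_single_stop(self):
        dis_t, sd, dis_m = displacement_features([0.0], [0.0])
        assert dis_t == 0.0
        assert np.isnan(dis_m) and np.isnan(sd)

    def test_out_and_back(self):
        lons = equator_lons(0, 2, 0)
        dis_t, _, dis_m = displacement_features([0.0] * 3, lons)
        assert dis_t == pytest.approx(4.0, rel=1e-5)
        assert dis_m == pytest.approx(2.0, rel=1e-5)

    def test_max_leg_never_exceeds_total(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 10))
            lat, lon = rng.uniform(44, 46, n), rng.uniform(10, 12, n)
            dis_t, _, dis_m = displacement_features(lat, lon)
            assert dis_m <= dis_t + 1e-12


class TestGyration:
    def test_single_place_is_zero(self):
        assert radius_of_gyration([45.0], [11.0], [3600.0]) == pytest.approx(0.0, abs=1e-12)

    def test_two_places_equal_dwell_half_separation(self):
        lons = equator_lons(0, 1)
        g = radius_of_gyration([0.0, 0.0], lons, [3600.0, 3600.0])
        assert g == pytest.approx(0.5, abs=1e-3)

    def test_degenerate_weight_is_zero(self):
        lons = equator_lons(0, 5)
        assert radius_of_gyration([0.0, 0.0], lons, [3600.0, 0.0]) == pytest.approx(0.0, abs=1e-9)

    def test_zero_total_dwell_is_missing(self):
        assert np.isnan(radius_of_gyration([0.0], [0.0], [0.0]))

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 10))
            lat, lon = rng.uniform(44, 46, n), rng.uniform(10, 12, n)
            w = rng.uniform(0.5, 5.0, n) * 3600
            expected = brute_gyration(list(zip(lat, lon)), list(w))
            assert radius_of_gyration(lat, lon, w) == pytest.approx(expected, rel=1e-9)

    def test_planar_two_point_limit_under_5km(self, rng):
        # closed form: equal dwell at separation d gives G = d/2 on the plane
        for d in rng.uniform(0.1, 5.0, 10):
            g = radius_of_gyration([0.0, 0.0], equator_lons(0, d), [1.0, 1.0])
            assert g == pytest.approx(d / 2, rel=1e-3)


class TestHomeDisplacement:
    def test_only_home_visited(self):
        assert max_displacement_from_home([45.0], [11.0], 45.0, 11.0) == pytest.approx(0.0)

    def test_farthest_stop_wins(self):
        lons = equator_lons(1, 5)
        assert max_displacement_from_home([0.0, 0.0], lons, 0.0, 0.0) == pytest.approx(
            5.0, rel=1e-5
        )

    def test_unknown_home_is_missing(self):
        assert np.isnan(max_displacement_from_home([0.0], [0.0], np.nan, np.nan))


class TestVisitCounts:
    def test_worked_example_one_and_two_visits(self):
        # Pl1 visited once and Pl2 twice => 3 visits over 2 distinct places
        n_dif, _, n_unq = visit_counts([1, 2, 2], set())
        assert n_dif == 3
        assert n_unq == 2

    def test_no_stops(self):
        assert visit_counts([], {1}) == (0, 0, 0)

    def test_all_visits_significant(self):
        assert visit_counts([7] * 5, {7}) == (5, 5, 1)


class TestSignificantPlaces:
    def test_few_places_all_significant(self):
        stops = stops_frame(
            [(p, "2023-01-01 0%d:00" % p, "2023-01-01 0%d:30" % p, 0.0, 0.0) for p in (1, 2, 3)]
        )
        assert significant_places(stops)["u0"] == {1, 2, 3}

    def test_top_ten_of_twelve(self):
        rows = []
        t = pd.Timestamp("2023-01-01 00:00")
        for p in range(1, 13):
            for _ in range(p):  # place p visited p times
                rows.append((p, t, t + pd.Timedelta(minutes=20), 0.0, 0.0))
                t += pd.Timedelta(hours=1)
        sig = significant_places(stops_frame(rows))["u0"]
        assert sig == set(range(3, 13))

    def test_boundary_tie_broken_by_first_visit(self):
        rows = []
        t = pd.Timestamp("2023-01-01 00:00")
        # places 1..9 visited 5x; places 10 and 11 visited 2x each — only one fits
        for p in list(range(1, 10)) * 5 + [11, 10, 11, 10]:
            rows.append((p, t, t + pd.Timedelta(minutes=20), 0.0, 0.0))
            t += pd.Timedelta(hours=1)
        sig = significant_places(stops_frame(rows))["u0"]
        assert len(sig) == 10
        assert 11 in sig and 10 not in sig  # 11 was visited first


class TestDiversity:
    def test_even_split_is_one(self):
        assert diversity([1] * 5 + [2] * 5) == pytest.approx(1.0, abs=1e-12)

    def test_single_place_is_zero(self):
        assert diversity([1, 1, 1]) == 0.0

    def test_worked_value(self):
        assert diversity([1, 1, 2, 3]) == pytest.approx(0.946, abs=1e-3)

    @given(st.lists(st.integers(min_value=1, max_value=6), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=200)
    def test_bounds_and_equality_condition(self, ids):
        d = diversity(ids)
        assert 0.0 <= d <= 1.0 + 1e-12
        counts = pd.Series(ids).value_counts()
        if len(counts) >= 2 and counts.nunique() == 1:
            assert d == pytest.approx(1.0, abs=1e-9)
        elif len(counts) >= 2 and counts.nunique() > 1:
            assert d < 1.0
        assert d == pytest.approx(brute_diversity(ids), abs=1e-12)


class TestRollingAggregates:
    def _daily(self, values, start="2023-01-01"):
        dates = pd.date_range(start, periods=len(values)).date
        df = pd.DataFrame({"user_id": "u0", "date": dates})
        for f in BASE_FEATURES:
            df[f] = values
        return df

    def test_zero_history_window(self):
        daily = self._daily([3.0])
        agg = rolling_aggregates(daily, "2023-01-01", 0)
        assert agg["d_t__mean"] == agg["d_t__max"] == agg["d_t__min"] == 3.0
        assert agg["d_t__diff"] == 0.0
        assert np.isnan(agg["d_t__std"])

    def test_constant_window(self):
        agg = rolling_aggregates(self._daily([2.0, 2.0, 2.0]), "2023-01-03", 2)
        assert agg["g__std"] == 0.0 and agg["g__diff"] == 0.0

    def test_arithmetic(self):
        agg = rolling_aggregates(self._daily([1.0, 2.0, 4.0]), "2023-01-03", 2)
        assert agg["dis_t__mean"] == pytest.approx(7 / 3)
        assert agg["dis_t__diff"] == 3.0
        assert agg["dis_t__max"] == 4.0 and agg["dis_t__min"] == 1.0
        assert agg["dis_t__std"] == pytest.approx(brute_sd([1.0, 2.0, 4.0]))

    def test_missing_day_refused(self):
        daily = self._daily([1.0, 2.0]).drop(index=0)
        with pytest.raises(ValueError):
            rolling_aggregates(daily, "2023-01-02", 1)


class TestDailyTable:
    def _toy_day(self):
        """Handcrafted itinerary: home (2 h) -> 2 moving points -> work 2 km
        away (1 h) -> moving -> home (2 h)."""
        home, work = (0.0, 0.0), (0.0, 2 * DEG_PER_KM)
        stops = stops_frame(
            [
                (1, "2023-01-05 06:00", "2023-01-05 08:00", *home),
                (2, "2023-01-05 08:12", "2023-01-05 09:12", *work),
                (1, "2023-01-05 09:24", "2023-01-05 11:24", *home),
            ]
        )
        moves = points_frame(
            [
                ("2023-01-05 08:04", 0.0, 2 / 3 * 2 * DEG_PER_KM),
                ("2023-01-05 08:08", 0.0, 1 / 3 * 2 * DEG_PER_KM),  # deliberate zigzag
                ("2023-01-05 09:18", 0.0, 1 * DEG_PER_KM),
            ]
        )
        return stops, moves

    def test_toy_day_against_hand_computation(self):
        stops, moves = self._toy_day()
        stops["dwell_s"] = (stops["t_departure"] - stops["t_arrival"]).dt.total_seconds()
        feats = interval_features(stops, moves, home=(0.0, 0.0), significant_set={1, 2})
        # merged x-offsets in km: 0, 4/3, 2/3, 2, 1, 0
        seq = [0.0, 4 / 3, 2 / 3, 2.0, 1.0, 0.0]
        assert feats["d_t"] == pytest.approx(
            sum(abs(b - a) * 111.19492664 / 111.19492664 for a, b in zip(seq, seq[1:])),
            rel=1e-4,
        )
        assert feats["dis_t"] == pytest.approx(4.0, rel=1e-5)
        assert feats["dis_m"] == pytest.approx(2.0, rel=1e-5)
        assert feats["n_dif"] == 3 and feats["n_unq"] == 2 and feats["n_sig"] == 3
        assert feats["n_moves"] == 3
        assert feats["div"] == pytest.approx(brute_diversity([1, 2, 1]), abs=1e-9)
        assert feats["dis_h"] == pytest.approx(2.0, rel=1e-5)
        # dwell-weighted gyration: home 4 h at 0 km, work 1 h at 2 km
        assert feats["g"] == pytest.approx(
            brute_gyration([(0.0, 0.0), (0.0, 2 * DEG_PER_KM), (0.0, 0.0)], [2.0, 1.0, 2.0]),
            rel=1e-6,
        )

    def test_midnight_split_attributes_dwell_per_day(self):
        stops = stops_frame([(1, "2023-01-05 20:00", "2023-01-06 06:00", 0.0, 0.0)])
        split = split_stops_at_midnight(stops)
        assert len(split) == 2
        by_date = split.set_index("date")["dwell_s"]
        assert by_date[pd.Timestamp("2023-01-05").date()] == 4 * 3600
        assert by_date[pd.Timestamp("2023-01-06").date()] == 6 * 3600

    def test_counts_invariants_on_simulated_days(self, small_signal_daily):
        daily = small_signal_daily
        assert (daily["n_unq"] <= daily["n_dif"]).all()
        assert (daily["n_sig"] <= daily["n_dif"]).all()
        assert daily["div"].between(0, 1).all()
        for f in ("d_t", "dis_t", "g"):
            assert (daily[f].dropna() >= 0).all()
        valid = ~daily["dis_m"].isna()
        assert (daily.loc[valid, "dis_m"] <= daily.loc[valid, "dis_t"] + 1e-9).all()

    def test_day_without_any_data_emits_no_row(self, small_signal_cohort, small_signal_daily):
        config, locations, _, _ = small_signal_cohort
        observed = set(zip(small_signal_daily["user_id"], small_signal_daily["date"]))
        with_points = set(
            zip(locations["user_id"], locations["timestamp"].dt.date)
        )
        assert set(observed) <= with_points

    def test_translation_invariance(self, rng):
        lat, lon = rng.uniform(45, 45.05, 8), rng.uniform(11, 11.05, 8)
        base = displacement_features(lat, lon)[0]
        shifted = displacement_features(lat + 0.01, lon + 0.01)[0]
        assert shifted == pytest.approx(base, rel=1e-3)

    def test_doubling_legs_doubles_distances(self):
        lons = np.array(equator_lons(0, 1, 3, 2))
        d1 = displacement_features([0.0] * 4, lons)
        d2 = displacement_features([0.0] * 4, 2 * lons)
        assert d2[0] == pytest.approx(2 * d1[0], rel=1e-4)
        assert d2[2] == pytest.approx(2 * d1[2], rel=1e-4)
        g1 = radius_of_gyration([0.0] * 4, lons, [1.0] * 4)
        g2 = radius_of_gyration([0.0] * 4, 2 * lons, [1.0] * 4)
        assert g2 == pytest.approx(2 * g1, rel=1e-4)


class TestExtractor:
    def test_fit_transform_matches_manual_chain(self, small_signal_cohort):
        _, locations, _, _ = small_signal_cohort
        ext = MobilityFeatureExtractor()
        daily = ext.fit_transform(locations)
        det = StopDetector().fit(locations)
        manual = daily_features(det.stops_, det.places_, det.annotated_points_)
        pd.testing.assert_frame_equal(daily, manual)
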