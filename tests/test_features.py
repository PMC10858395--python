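"""Exposure-feature construction: time-weighted AQI, smoke proportions,
HMS index, distance and its categories."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Polygon

import exposure_weave as ew
from exposure_weave.geo import destination_point, haversine_miles
from exposure_weave.synthetic import TIMEZONE

from conftest import make_fixes
from oracles import (exhaustive_nearest, per_second_smoke_proportions,
                     per_second_weighted_aqi)


def monitor_day_rows(specs, date):
    return pd.DataFrame([
        {"monitor_id": mid, "latitude": lat, "longitude": lon, "date": pd.Timestamp(date).date(), "aqi": aqi}
        for mid, lat, lon, aqi in specs
    ])


class TestDailyAverage:
    def test_single_and_mean(self):
        raw = pd.DataFrame({
            "monitor_id": ["A", "B", "B"], "latitude": [45.0] * 3, "longitude": [-123.0] * 3,
            "date": [pd.Timestamp("2017-08-14").date()] * 3, "aqi": [40.0, 40.0, 60.0],
        })
        out = ew.daily_average_monitors(raw)
        assert out.set_index("monitor_id")["aqi"].to_dict() == {"A": 40.0, "B": 50.0}

    def test_matches_group_mean_oracle(self):
        rng = np.random.default_rng(0)
        n = 60
        raw = pd.DataFrame({
            "monitor_id": rng.choice(["A", "B", "C"], n),
            "latitude": 45.0, "longitude": -123.0,
            "date": [pd.Timestamp("2017-08-14").date()] * n,
            "aqi": rng.uniform(0, 200, n),
        })
        out = ew.daily_average_monitors(raw).set_index("monitor_id")["aqi"]
        for mid in ("A", "B", "C"):
            expected = raw.loc[raw["monitor_id"] == mid, "aqi"].sum() / (raw["monitor_id"] == mid).sum()
            assert out[mid] == pytest.approx(expected)

    def test_negative_aqi_rejected(self):
        raw = monitor_day_rows([("A", 45.0, -123.0, -1.0)], "2017-08-14")
        with pytest.raises(ValueError, match="negative AQI"):
            ew.daily_average_monitors(raw)


class TestNearestMonitor:
    def test_exact_coordinates_and_ordering(self):
        monitors = monitor_day_rows([("A", 45.0, -123.0, 50), ("B", 45.5, -123.0, 60)], "2017-08-14")
        mid, dist = ew.nearest_monitor(45.0, -123.0, monitors)
        assert mid == "A" and dist == 0.0

    def test_agrees_with_exhaustive_search(self):
        rng = np.random.default_rng(1)
        monitors = monitor_day_rows(
            [(f"M{i}", rng.uniform(44, 46), rng.uniform(-124, -122), 50) for i in range(10)],
            "2017-08-14")
        for _ in range(20):
            lat, lon = rng.uniform(44, 46), rng.uniform(-124, -122)
            assert ew.nearest_monitor(lat, lon, monitors) == exhaustive_nearest(lat, lon, monitors)

    def test_no_data_errors(self):
        with pytest.raises(ValueError, match="no monitor"):
            ew.nearest_monitor(45.0, -123.0, monitor_day_rows([], "2017-08-14").iloc[:0])


class TestWeightedAqi:
    def test_single_monitor_weight_one(self):
        monitors = monitor_day_rows([("A", 45.0, -123.0, 80.0)], "2017-08-14")
        fixes = make_fixes(["2017-08-14 08:00", "2017-08-14 20:00"], [45.0, 45.01], [-123.0, -123.0])
        on = pd.Timestamp("2017-08-14 08:00", tz=TIMEZONE)
        off = pd.Timestamp("2017-08-14 23:00", tz=TIMEZONE)
        assert ew.weighted_aqi(fixes, on, off, monitors) == pytest.approx(80.0)

    def test_half_half_split(self):
        monitors = monitor_day_rows([("A", 45.0, -123.0, 100.0), ("B", 45.5, -123.0, 50.0)], "2017-08-14")
        # 8:00-14:00 at A's location, 14:00-20:00 at B's
        fixes = make_fixes(["2017-08-14 08:00", "2017-08-14 14:00"], [45.0, 45.5], [-123.0, -123.0])
        on = pd.Timestamp("2017-08-14 08:00", tz=TIMEZONE)
        off = pd.Timestamp("2017-08-14 20:00", tz=TIMEZONE)
        assert ew.weighted_aqi(fixes, on, off, monitors) == pytest.approx(75.0)

    def test_matches_per_second_oracle_on_random_trajectories(self):
        rng = np.random.default_rng(2)
        date = pd.Timestamp("2017-08-14").date()
        monitors = pd.DataFrame([
            {"monitor_id": f"M{i}", "latitude": rng.uniform(44.5, 45.5),
             "longitude": rng.uniform(-123.5, -122.5), "date": date,
             "aqi": rng.uniform(10, 250)} for i in range(10)
        ])
        for trial in range(10):
            n_fix = int(rng.integers(3, 12))
            offsets = np.sort(rng.integers(0, 4 * 3600, n_fix))
            on = pd.Timestamp("2017-08-14 08:00", tz=TIMEZONE)
            off = on + pd.Timedelta(hours=4)
            fixes = make_fixes([on + pd.Timedelta(seconds=int(s)) for s in offsets],
                               rng.uniform(44.5, 45.5, n_fix), rng.uniform(-123.5, -122.5, n_fix))
            got = ew.weighted_aqi(fixes, on, off, monitors)
            want = per_second_weighted_aqi(fixes, on, off, monitors)
            assert got == pytest.approx(want, abs=1e-6)

    def test_convexity_bound(self, small_features, small_study):
        """Each period's weighted AQI lies within the range of its days' monitor AQIs."""
        monitor_days = small_features["monitor_days"]
        feats = small_features["features"]
        for _, p in small_features["paired"].head(10).iterrows():
            days = {p["on_time"].date(), p["off_time"].date()}
            day_vals = monitor_days[monitor_days["date"].isin(days)]["aqi"]
            w = feats.loc[feats["wristband_id"] == p["wristband_id"], "weighted_aqi"].iloc[0]
            assert day_vals.min() - 1e-9 <= w <= day_vals.max() + 1e-9

    def test_zero_length_wear_errors(self):
        monitors = monitor_day_rows([("A", 45.0, -123.0, 80.0)], "2017-08-14")
        fixes = make_fixes(["2017-08-14 08:00"], [45.0], [-123.0])
        on = pd.Timestamp("2017-08-14 08:00", tz=TIMEZONE)
        with pytest.raises(ValueError, match="zero-length"):
            ew.weighted_aqi(fixes, on, on, monitors)


def square(lat0, lat1, lon0, lon1):
    return Polygon([(lon0, lat0), (lon1, lat0), (lon1, lat1), (lon0, lat1)])


class TestSmokeProportions:
    def setup_method(self):
        self.on = pd.Timestamp("2017-08-14 08:00", tz=TIMEZONE)
        self.off = self.on + pd.Timedelta(hours=12)
        self.fixes = make_fixes(["2017-08-14 08:00", "2017-08-14 14:00"],
                                [45.0, 45.0], [-123.0, -123.0])

    def test_no_polygons_all_none(self):
        props = ew.smoke_proportions(self.fixes, self.on, self.off, pd.DataFrame(columns=["date", "density", "geometry"]))
        assert props == {"none": 1.0, "light": 0.0, "medium": 0.0, "heavy": 0.0}

    def test_whole_bbox_heavy(self):
        polys = pd.DataFrame([{"date": self.on.date(), "density": "heavy",
                               "geometry": square(44, 46, -124, -122)}])
        props = ew.smoke_proportions(self.fixes, self.on, self.off, polys)
        assert props["heavy"] == pytest.approx(1.0)

    def test_overlap_resolves_to_highest_density(self):
        polys = pd.DataFrame([
            {"date": self.on.date(), "density": "light", "geometry": square(44, 46, -124, -122)},
            {"date": self.on.date(), "density": "medium", "geometry": square(44, 46, -124, -122)},
        ])
        props = ew.smoke_proportions(self.fixes, self.on, self.off, polys)
        assert props["medium"] == pytest.approx(1.0) and props["light"] == 0.0

    def test_straddling_polygon_matches_oracle(self):
        # second fix (from 14:00, half the wear time) sits inside a light polygon
        fixes = make_fixes(["2017-08-14 08:00", "2017-08-14 14:00"],
                           [45.0, 45.5], [-123.0, -123.0])
        polys = pd.DataFrame([{"date": self.on.date(), "density": "light",
                               "geometry": square(45.25, 46, -124, -122)}])
        props = ew.smoke_proportions(fixes, self.on, self.off, polys)
        assert props["light"] == pytest.approx(0.5)
        oracle = per_second_smoke_proportions(fixes, self.on, self.off, polys)
        for k in props:
            assert props[k] == pytest.approx(oracle[k], abs=1e-6)

    def test_invalid_geometry_rejected(self):
        bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        polys = pd.DataFrame([{"date": self.on.date(), "density": "light", "geometry": bowtie}])
        with pytest.raises(ValueError, match="invalid smoke polygon"):
            ew.smoke_proportions(self.fixes, self.on, self.off, polys)

    def test_proportions_sum_to_one_across_study(self, small_features):
        f = small_features["features"]
        totals = f[["prop_none", "prop_light", "prop_medium", "prop_heavy"]].sum(axis=1)
        assert np.allclose(totals, 1.0, atol=1e-9)


class TestHmsIndex:
    @pytest.mark.parametrize("props,expected", [
        ({"none": 1.0, "light": 0.0, "medium": 0.0, "heavy": 0.0}, 0.0),
        ({"none": 0.0, "light": 0.0, "medium": 0.0, "heavy": 1.0}, 1.0),
        ({"none": 0.0, "light": 0.5, "medium": 0.0, "heavy": 0.5}, 2.0 / 3.0),
    ])
    def test_formula(self, props, expected):
        assert ew.hms_index(props) == pytest.approx(expected)

    def test_invalid_sum_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            ew.hms_index({"none": 0.5, "light": 0.0, "medium": 0.0, "heavy": 0.0})

    @given(st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4),
           st.integers(0, 2), st.data())
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_density(self, raw, low_idx, data):
        """Moving mass from a lower to a higher density never decreases the index."""
        total = sum(raw)
        props = dict(zip(("none", "light", "medium", "heavy"), (x / total for x in raw)))
        keys = ["none", "light", "medium", "heavy"]
        hi_idx = data.draw(st.integers(low_idx + 1, 3))
        shift = props[keys[low_idx]] / 2
        bumped = dict(props)
        bumped[keys[low_idx]] -= shift
        bumped[keys[hi_idx]] += shift
        assert ew.hms_index(bumped) >= ew.hms_index(props) - 1e-12


class TestDistance:
    def test_repeated_fixes_zero(self):
        fixes = make_fixes(["2017-08-14 08:00", "2017-08-14 09:00"], [45.0, 45.0], [-123.0, -123.0])
        assert ew.distance_traveled(fixes) == 0.0

    def test_one_degree_longitude_at_equator(self):
        # closed form: pi * R / 180 with R = 3958.8 mi
        fixes = make_fixes(["2017-08-14 08:00", "2017-08-14 09:00"], [0.0, 0.0], [0.0, 1.0])
        assert ew.distance_traveled(fixes) == pytest.approx(np.pi * 3958.8 / 180.0, rel=1e-9)

    def test_out_and_back_doubles_one_way(self):
        lat0, lon0 = 45.0, -123.0
        lat1, lon1 = destination_point(lat0, lon0, 70.0, 10.0)
        one_way = float(haversine_miles(lat0, lon0, lat1, lon1))
        fixes = make_fixes(["2017-08-14 08:00", "2017-08-14 09:00", "2017-08-14 10:00"],
                           [lat0, lat1, lat0], [lon0, lon1, lon0])
        assert ew.distance_traveled(fixes) == pytest.approx(2 * one_way, rel=1e-9)
        assert one_way == pytest.approx(10.0, rel=1e-6)


class TestCategorizeDistance:
    def test_balanced_quartiles(self):
        cats = ew.categorize_distance(np.arange(1.0, 9.0))
        assert list(cats.value_counts()) == [2, 2, 2, 2]

    def test_cutpoint_tie_goes_low_and_pinned(self):
        cats = ew.categorize_distance([4.0, 20.0, 36.0], cutpoints=(4.0, 15.0, 35.0))
        assert list(cats) == ["Q1", "Q3", "Q4"]

    def test_non_monotone_cutpoints_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            ew.categorize_distance([1.0], cutpoints=(10.0, 5.0, 20.0))


class TestBuildFeatures:
    def test_interaction_columns_zero_off_season(self, small_features):
        f = small_features["features"]
        w18 = f[f["season"] == "W18"]
        assert (w18["aqi_S17"] == 0).all() and (w18["aqi_S18"] == 0).all()
        assert np.allclose(w18["aqi_W18"], w18["weighted_aqi"])

    def test_feature_column_count(self, small_features):
        f = small_features["features"]
        standard = ["weighted_aqi", "hms_index", "prop_light", "prop_medium", "prop_heavy",
                    "season", "distance_category", "time_indoors", "prop_none",
                    "distance_traveled_mi"]
        interactions = [c for c in f.columns if c.startswith(("aqi_", "hms_"))
                        and c not in ("hms_index",)]
        assert all(c in f.columns for c in standard)
        assert len(interactions) == 6  # two families x three seasons

    def test_csv_round_trip_preserves_values(self, small_features, tmp_path):
        f = small_features["features"]
        path = tmp_path / "features.csv"
        ew.io.write_features_csv(f, path)
        back = ew.io.read_features_csv(path)
        for col in ("weighted_aqi", "hms_index", "distance_traveled_mi"):
            assert np.array_equal(back[col].to_numpy(), f[col].to_numpy())
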