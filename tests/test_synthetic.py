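"""Seeded study generator: determinism, degenerate settings, planted structure."""
import datetime as dt

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal
from shapely.geometry import Point

import exposure_weave as ew
from exposure_weave.synthetic import (ChemicalEffect, SeasonSpec, SimConfig,
                                      TIMEZONE, generate_smoke)


def degenerate_config(**over):
    base = dict(
        n_participants=2, days_per_season=2, n_monitors=3,
        seasons=(SeasonSpec("S17", dt.date(2017, 8, 14), aqi_baseline=20.0,
                            smoke_event_prob=0.0),),
        aqi_noise_sd=0.0, monitor_missing_rate=0.0, seed=5,
    )
    base.update(over)
    return SimConfig(**base)


class TestConfigValidation:
    def test_bad_interference_rate(self):
        with pytest.raises(ValueError, match="interference_rate"):
            SimConfig(interference_rate=1.5)

    def test_empty_date_range(self):
        with pytest.raises(ValueError, match="empty date range"):
            SimConfig(days_per_season=0)

    def test_negative_sd(self):
        with pytest.raises(ValueError, match="SDs"):
            ChemicalEffect("c", "x", 100.0, "PAH", 1.0, residual_sd=-1.0)


class TestMonitors:
    def test_degenerate_generator_constant(self):
        m = ew.generate_monitors(degenerate_config())
        assert (m["aqi"] == 20.0).all()

    def test_seeded_determinism(self):
        cfg = ew.default_config(seed=3, n_participants=2, days_per_season=2)
        assert_frame_equal(ew.generate_monitors(cfg), ew.generate_monitors(cfg))

    def test_smoke_spike_applied_to_covered_monitors(self):
        cfg = degenerate_config(seasons=(
            SeasonSpec("S17", dt.date(2017, 8, 14), aqi_baseline=40.0,
                       smoke_event_prob=1.0, max_polygons=1,
                       density_weights=(0.0, 0.0, 1.0), aqi_spike=150.0),))
        monitors = ew.generate_monitors(cfg)
        smoke = generate_smoke(cfg)
        pos = monitors.groupby("monitor_id")[["latitude", "longitude"]].first()
        for _, row in monitors.iterrows():
            day_polys = smoke[smoke["date"] == row["date"]]
            lat, lon = pos.loc[row["monitor_id"]]
            covered = any(g.covers(Point(lon, lat)) for g in day_polys["geometry"])
            assert row["aqi"] == pytest.approx(190.0 if covered else 40.0)

    def test_missing_rate_thins_rows(self):
        cfg = degenerate_config(monitor_missing_rate=0.5, n_monitors=40, days_per_season=5)
        m = ew.generate_monitors(cfg)
        full = 40 * (5 + 1)
        assert 0.3 * full < len(m) < 0.7 * full


class TestSmoke:
    def test_zero_event_probability_empty(self):
        assert generate_smoke(degenerate_config()).empty

    def test_winter_default_has_no_smoke(self):
        cfg = ew.default_config(seed=9, n_participants=2, days_per_season=4)
        smoke = generate_smoke(cfg)
        w18 = next(s for s in cfg.seasons if s.label == "W18")
        w18_dates = set(cfg.season_dates(w18))
        assert not smoke["date"].isin(w18_dates).any()

    def test_polygons_simple_and_deterministic(self):
        cfg = ew.default_config(seed=4, n_participants=2, days_per_season=3)
        s1, s2 = generate_smoke(cfg), generate_smoke(cfg)
        assert all(g.is_valid and g.is_simple for g in s1["geometry"])
        assert all(a.equals_exact(b, 0) for a, b in zip(s1["geometry"], s2["geometry"]))
        assert s1["density"].isin(["light", "medium", "heavy"]).all()


class TestTrajectories:
    def test_stay_home_day_path_zero(self):
        cfg = degenerate_config(stay_home_prob=1.0)
        fixes = ew.generate_trajectories(cfg)
        for _, g in fixes.groupby("participant_id"):
            assert g["lat"].nunique() == 1 and g["lon"].nunique() == 1
            assert ew.distance_traveled(g) == 0.0

    def test_fixes_inside_bbox_and_deterministic(self):
        cfg = ew.default_config(seed=6, n_participants=3, days_per_season=2)
        f1 = ew.generate_trajectories(cfg)
        assert_frame_equal(f1, ew.generate_trajectories(cfg))
        lat_min, lat_max, lon_min, lon_max = cfg.bbox
        assert f1["lat"].between(lat_min, lat_max).all()
        assert f1["lon"].between(lon_min, lon_max).all()

    def test_median_daily_distance_near_target(self):
        cfg = ew.default_config(seed=8, n_participants=20, days_per_season=3)
        fixes = ew.generate_trajectories(cfg)
        fixes["date"] = fixes["timestamp"].dt.date
        daily = fixes.groupby(["participant_id", "date"]).apply(
            lambda g: ew.distance_traveled(g), include_groups=False)
        # log-normal with median 15.4 mi; wide tolerance for sampling noise
        assert 8.0 < daily.median() < 30.0


class TestQuestionnaires:
    def test_no_failures_all_valid(self, small_study):
        cfg = degenerate_config(questionnaire_missing_rate=0.0,
                                questionnaire_window_violation_rate=0.0,
                                no_carry_rate=0.0)
        periods = ew.generate_periods(cfg)
        q = ew.generate_questionnaires(cfg, periods)
        assert len(q) == len(periods)
        assert q["carried_phone"].all()
        assert len(ew.filter_questionnaires(q)) == len(q)

    def test_total_window_violation_filtered_downstream(self):
        cfg = degenerate_config(questionnaire_missing_rate=0.0,
                                questionnaire_window_violation_rate=1.0)
        q = ew.generate_questionnaires(cfg, ew.generate_periods(cfg))
        assert ew.filter_questionnaires(q).empty

    def test_category_frequencies_converge(self):
        probs = (0.1, 0.2, 0.3, 0.25, 0.15)
        cfg = degenerate_config(time_indoors_probs=probs,
                                questionnaire_missing_rate=0.0)
        n = 10_000
        periods = pd.DataFrame({
            "wristband_id": [f"w{i}" for i in range(n)],
            "participant_id": "P00", "season": "S17",
            "on_time": pd.Timestamp("2017-08-14 08:00", tz=TIMEZONE),
            "off_time": pd.Timestamp("2017-08-15 08:00", tz=TIMEZONE),
            "bagged": True, "times_recorded": True,
        })
        q = ew.generate_questionnaires(cfg, periods)
        freq = q["time_indoors"].value_counts(normalize=True)
        for lvl, p in zip(("0h", "<1h", "1-8h", "9-12h", "12-24h"), probs):
            assert freq.get(lvl, 0.0) == pytest.approx(p, abs=0.02)


def flat_features(n, aqi=None, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "wristband_id": [f"w{i}" for i in range(n)],
        "participant_id": [f"P{i % 10:02d}" for i in range(n)],
        "season": "S17",
        "weighted_aqi": rng.uniform(10, 150, n) if aqi is None else aqi,
        "hms_index": rng.uniform(0, 1, n),
        "time_indoors": "1-8h",
        "distance_category": "Q2",
    })


class TestChemistry:
    def test_degenerate_all_constant(self):
        chem = ChemicalEffect("c0", "x", 100.0, "PAH", intercept=10.0,
                              season_offsets={"S17": 0.0},
                              indoors_offsets={"1-8h": 0.0}, distance_offsets={"Q2": 0.0},
                              participant_sd=0.0, residual_sd=0.0)
        cfg = degenerate_config(chemicals=(chem,), interference_rate=0.0)
        feats = flat_features(50)
        feats["weighted_aqi"] = 0.0
        feats["hms_index"] = 0.0
        meas, truth = ew.generate_chemistry(cfg, feats)
        log2 = ew.to_log2_pmol_per_g(meas["raw_conc"].to_numpy(), 100.0)
        assert np.allclose(log2, 10.0)
        assert np.allclose(truth.true_log2["true_log2"], 10.0)

    def test_interference_rate_binomial(self):
        chems = tuple(
            ChemicalEffect(f"c{i}", "x", 100.0, "PAH", intercept=10.0,
                           season_offsets={"S17": 0.0}, indoors_offsets={"1-8h": 0.0},
                           distance_offsets={"Q2": 0.0})
            for i in range(25))
        cfg = degenerate_config(chemicals=chems, interference_rate=0.013)
        meas, _ = ew.generate_chemistry(cfg, flat_features(1600))
        n_missing = int(meas["interference"].sum())
        # 40,000 Bernoulli(0.013) draws: mean 520, 4 SD ~ 91
        assert 520 - 91 <= n_missing <= 520 + 91

    def test_positive_aqi_slope_gives_positive_correlation(self):
        chem = ChemicalEffect("c0", "x", 100.0, "PAH", intercept=8.0, slope_aqi=0.02,
                              season_offsets={"S17": 0.0}, indoors_offsets={"1-8h": 0.0},
                              distance_offsets={"Q2": 0.0}, participant_sd=0.0, residual_sd=0.5)
        cfg = degenerate_config(chemicals=(chem,), interference_rate=0.0)
        feats = flat_features(300, seed=1)
        meas, truth = ew.generate_chemistry(cfg, feats)
        r = np.corrcoef(feats["weighted_aqi"], truth.true_log2["true_log2"])[0, 1]
        assert r > 0.5

    def test_missing_category_level_errors(self):
        chem = ChemicalEffect("c0", "x", 100.0, "PAH", intercept=8.0,
                              season_offsets={}, indoors_offsets={}, distance_offsets={})
        cfg = degenerate_config(chemicals=(chem,))
        with pytest.raises(KeyError, match="season offset"):
            ew.generate_chemistry(cfg, flat_features(10))

    def test_ols_recovery_of_generating_coefficients(self):
        """With censoring off and no participant effect, OLS on the true
        design recovers every generating coefficient within 3 SE."""
        import statsmodels.api as sm

        chem = ChemicalEffect("c0", "x", 100.0, "PAH", intercept=8.0, slope_aqi=0.015,
                              slope_hms=1.5, season_offsets={"S17": 0.0},
                              indoors_offsets={"1-8h": 0.0}, distance_offsets={"Q2": 0.0},
                              participant_sd=0.0, residual_sd=1.0)
        cfg = degenerate_config(chemicals=(chem,), interference_rate=0.0)
        feats = flat_features(600, seed=2)
        _, truth = ew.generate_chemistry(cfg, feats)
        X = sm.add_constant(feats[["weighted_aqi", "hms_index"]].to_numpy())
        fit = sm.OLS(truth.true_log2["true_log2"].to_numpy(), X).fit()
        for est, se, true in zip(fit.params, fit.bse, (8.0, 0.015, 1.5)):
            assert abs(est - true) < 3 * se

    def test_seeded_determinism(self):
        cfg = degenerate_config(chemicals=ew.default_chemicals(3))
        feats = flat_features(40)
        m1, _ = ew.generate_chemistry(cfg, feats)
        m2, _ = ew.generate_chemistry(cfg, feats)
        assert_frame_equal(m1, m2)


class TestModelingTable:
    def test_deterministic_and_balanced(self):
        df1 = ew.simulate_modeling_table(n=364, seed=5)
        df2 = ew.simulate_modeling_table(n=364, seed=5)
        assert_frame_equal(df1, df2)
        counts = df1["outcome"].value_counts()
        assert counts.max() - counts.min() <= 2

    def test_winter_has_no_smoke(self):
        df = ew.simulate_modeling_table(n=500, seed=6)
        assert (df.loc[df["season"] == "W18", "hms_index"] == 0).all()

    def test_interaction_columns_match_indicators(self):
        df = ew.simulate_modeling_table(n=200, seed=7)
        s17 = df["season"] == "S17"
        assert np.allclose(df.loc[s17, "aqi_S17"], df.loc[s17, "weighted_aqi"])
        assert (df.loc[~s17, "aqi_S17"] == 0).all()
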