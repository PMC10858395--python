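import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import exposure_weave as ew

settings.register_profile("stable", derandomize=True, deadline=None)
settings.load_profile("stable")
from exposure_weave.synthetic import TIMEZONE


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study: 6 participants x 3 seasons x 3 days."""
    return ew.default_config(seed=11, n_participants=6, days_per_season=3)


@pytest.fixture(scope="session")
def small_study(small_config):
    cfg = small_config
    periods = ew.generate_periods(cfg)
    fixes = ew.generate_trajectories(cfg)
    questionnaires = ew.generate_questionnaires(cfg, periods)
    monitors = ew.generate_monitors(cfg)
    smoke = ew.synthetic.generate_smoke(cfg)
    return {"config": cfg, "periods": periods, "fixes": fixes,
            "questionnaires": questionnaires, "monitors": monitors, "smoke": smoke}


@pytest.fixture(scope="session")
def small_features(small_study):
    cfg = small_study["config"]
    kept, _ = ew.filter_wristbands(small_study["periods"])
    responses = ew.filter_questionnaires(small_study["questionnaires"])
    paired, fix_map = ew.pair_gps(kept, small_study["fixes"], responses)
    monitor_days = ew.daily_average_monitors(small_study["monitors"])
    feats = ew.build_features(paired, fix_map, responses, monitor_days, small_study["smoke"])
    return {"features": feats, "paired": paired, "fix_map": fix_map,
            "responses": responses, "monitor_days": monitor_days}


def make_period(on="2017-08-14 08:00", hours=24.0, wid="wb1", pid="P00",
                season="S17", bagged=True, times_recorded=True):
    on_ts = pd.Timestamp(on, tz=TIMEZONE) if times_recorded else pd.NaT
    off_ts = on_ts + pd.Timedelta(hours=hours) if times_recorded else pd.NaT
    return {"wristband_id": wid, "participant_id": pid, "season": season,
            "on_time": on_ts, "off_time": off_ts, "bagged": bagged,
            "times_recorded": times_recorded}


def make_fixes(times, lats, lons, pid="P00"):
    return pd.DataFrame({
        "participant_id": pid,
        "timestamp": [t if isinstance(t, pd.Timestamp) and t.tz is not None
                      else pd.Timestamp(t, tz=TIMEZONE) for t in times],
        "lat": np.asarray(lats, dtype=float),
        "lon": np.asarray(lons, dtype=float),
    })
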