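"""Seeded synthetic study generator.

Emulates a multi-season personal-exposure study: ~35 participants wearing
daily silicone wristbands for 7 days in each of three seasons (two summers
with wildfire-smoke episodes, one smoke-free winter), while carrying a GPS
phone and answering evening questionnaires; a network of stationary PM2.5
AQI monitors and daily satellite smoke-density polygons provide the
environmental context.

Every generator is a pure function of (config, seed): identical seeds give
byte-identical tables.  Chemical concentrations are generated from an
explicit linear model on the log2 pmol/g scale, so the generating
coefficients double as ground truth for recovery tests.
"""
from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .geo import destination_point, path_length_miles

TIMEZONE = "US/Pacific"

SEASON_LABELS = ("S17", "W18", "S18")
TIME_INDOORS_LEVELS = ("0h", "<1h", "1-8h", "9-12h", "12-24h")
NO_CARRY_REASONS = ("forgot", "inconvenient", "left_in_general_location", "device_malfunction", "other")
DENSITY_LEVELS = {"light": 1, "medium": 2, "heavy": 3}


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SeasonSpec:
    """One study season: a date window plus its air-quality and smoke regime."""

    label: str
    start: dt.date
    aqi_baseline: float
    smoke_event_prob: float        # per-day probability of any smoke coverage
    max_polygons: int = 3
    density_weights: tuple[float, float, float] = (0.5, 0.3, 0.2)  # light/medium/heavy
    aqi_spike: float = 120.0       # added to covered monitors on event days, scaled by density/3


@dataclass(frozen=True)
class ChemicalEffect:
    """Generating model for one chemical's log2 pmol/g concentration.

    true log2 value = intercept + season_offset + slope_aqi * weighted_aqi
                      + slope_hms * hms_index + indoors_offset + distance_offset
                      + participant effect (SD ``participant_sd``)
                      + residual noise (SD ``residual_sd``);
    the reported value is left-censored at ``lod_log2``.
    """

    chemical_id: str
    name: str
    molecular_weight: float
    class_label: str
    intercept: float
    season_offsets: dict = field(default_factory=dict)      # label -> offset
    slope_aqi: float = 0.0
    slope_hms: float = 0.0
    indoors_offsets: dict = field(default_factory=dict)     # time-indoors level -> offset
    distance_offsets: dict = field(default_factory=dict)    # Q1..Q4 -> offset
    participant_sd: float = 0.8
    residual_sd: float = 1.2
    lod_log2: float = -math.inf
    loq_log2: float = -math.inf

    def __post_init__(self):
        if self.participant_sd < 0 or self.residual_sd < 0:
            raise ValueError("effect SDs must be nonnegative")
        if self.molecular_weight <= 0:
            raise ValueError("molecular weight must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Full study-simulation configuration; defaults mirror the emulated design."""

    n_participants: int = 35
    seasons: tuple[SeasonSpec, ...] = (
        SeasonSpec("S17", dt.date(2017, 8, 14), aqi_baseline=55.0, smoke_event_prob=0.45, aqi_spike=150.0),
        SeasonSpec("W18", dt.date(2018, 1, 15), aqi_baseline=21.0, smoke_event_prob=0.0),
        SeasonSpec("S18", dt.date(2018, 7, 30), aqi_baseline=38.0, smoke_event_prob=0.25, aqi_spike=90.0),
    )
    days_per_season: int = 7
    n_monitors: int = 10
    bbox: tuple[float, float, float, float] = (44.0, 46.0, -124.0, -122.0)  # lat_min, lat_max, lon_min, lon_max
    fix_interval_min: int = 5
    gps_noise_deg: float = 0.0
    monitor_missing_rate: float = 0.08
    aqi_noise_sd: float = 6.0
    aqi_rho: float = 0.6           # AR(1) day-to-day correlation of monitor noise
    stay_home_prob: float = 0.05
    trip_median_mi: float = 15.4   # median daily round-trip distance
    trip_log_sd: float = 1.15
    trip_max_mi: float = 260.0
    travel_speed_mph: float = 30.0
    # wristband QC violation rates (each period draws at most one violation)
    rate_bag_violation: float = 0.015
    rate_times_missing: float = 0.015
    rate_duration_violation: float = 0.01
    rate_ontime_violation: float = 0.01
    # questionnaire behaviour
    questionnaire_missing_rate: float = 0.03
    questionnaire_window_violation_rate: float = 0.05
    no_carry_rate: float = 0.03
    time_indoors_probs: tuple[float, ...] = (0.01, 0.04, 0.46, 0.30, 0.19)
    chemicals: tuple[ChemicalEffect, ...] = ()
    interference_rate: float = 0.013
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.interference_rate <= 1.0:
            raise ValueError("interference_rate must lie in [0, 1]")
        lat_min, lat_max, lon_min, lon_max = self.bbox
        if not (lat_min < lat_max and lon_min < lon_max):
            raise ValueError("bbox must be a valid lat/lon rectangle")
        if self.n_monitors < 1:
            raise ValueError("need at least one monitor")
        if self.days_per_season < 1:
            raise ValueError("empty date range")
        labels = [s.label for s in self.seasons]
        if len(set(labels)) != len(labels):
            raise ValueError("season labels must be unique")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic child stream of the master seed."""
        return np.random.default_rng([int(self.seed) % (2**31), stream])

    def season_dates(self, season: SeasonSpec, extra_days: int = 1) -> list[dt.date]:
        return [season.start + dt.timedelta(days=d) for d in range(self.days_per_season + extra_days)]


_DEFAULT_PANEL = [
    # (name, molecular weight g/mol, class)
    ("naphthalene", 128.17, "PAH"), ("2-methylnaphthalene", 142.20, "PAH"),
    ("1,6-dimethylnaphthalene", 156.22, "PAH"), ("acenaphthylene", 152.19, "PAH"),
    ("fluorene", 166.22, "PAH"), ("phenanthrene", 178.23, "PAH"),
    ("anthracene", 178.23, "PAH"), ("fluoranthene", 202.25, "PAH"),
    ("pyrene", 202.25, "PAH"), ("retene", 234.38, "PAH"),
    ("9-fluorenone", 180.20, "OPAH"), ("9,10-anthraquinone", 208.21, "OPAH"),
    ("n-nonane", 128.26, "alkane"), ("n-decane", 142.28, "alkane"),
    ("n-dodecane", 170.33, "alkane"), ("n-tetradecane", 198.39, "alkane"),
    ("n-hexadecane", 226.44, "alkane"), ("n-heptadecane", 240.47, "alkane"),
    ("n-octadecane", 254.49, "alkane"), ("n-eicosane", 282.55, "alkane"),
    ("ethylbenzene", 106.17, "VOC"), ("o-xylene", 106.17, "VOC"),
    ("m,p-xylene", 106.17, "VOC"), ("1,2,4-trimethylbenzene", 120.19, "VOC"),
    ("tributyl phosphate", 266.32, "OPE"),
]


def default_chemicals(n: int = 25) -> tuple[ChemicalEffect, ...]:
    """A representative panel of ``n`` chemicals (n <= 25).

    Effects vary deterministically across the panel: AQI and smoke slopes,
    seasonal offsets, behavioural offsets, and censoring that spans roughly
    0-80% below the LOD across chemicals.
    """
    from scipy.stats import norm

    chems = []
    for i, (name, mw, cls) in enumerate(_DEFAULT_PANEL[:n]):
        intercept = 8.0 + (i % 7)
        slope_aqi = 0.004 * (i % 4)            # per AQI unit, log2 scale
        slope_hms = 0.8 * ((i + 1) % 3)
        season_offsets = {"S17": 0.4 * (i % 3), "W18": -0.3 * (i % 2), "S18": 0.0}
        indoors = {lvl: 0.15 * j * ((i + j) % 2) for j, lvl in enumerate(TIME_INDOORS_LEVELS)}
        distance = {q: 0.1 * j * (i % 2) for j, q in enumerate(("Q1", "Q2", "Q3", "Q4"))}
        target_censor = (i / max(n - 1, 1)) * 0.8   # 0 .. 0.8 across the panel
        marginal_sd = math.sqrt(0.8**2 + 1.2**2) * 1.25
        lod = -math.inf if target_censor == 0 else intercept + norm.ppf(target_censor) * marginal_sd
        chems.append(ChemicalEffect(
            chemical_id=f"chem{i:02d}", name=name, molecular_weight=mw, class_label=cls,
            intercept=intercept, season_offsets=season_offsets, slope_aqi=slope_aqi,
            slope_hms=slope_hms, indoors_offsets=indoors, distance_offsets=distance,
            lod_log2=lod, loq_log2=lod if lod == -math.inf else lod + 1.0,
        ))
    return tuple(chems)


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The study-scale default configuration with the representative panel."""
    cfg = SimConfig(chemicals=default_chemicals(), seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


@dataclass(frozen=True)
class GroundTruth:
    """Uncensored generating quantities retained for recovery tests."""

    true_log2: pd.DataFrame          # wristband_id, chemical_id, true_log2
    effects: tuple[ChemicalEffect, ...]
    participant_effects: pd.DataFrame  # participant_id, chemical_id, effect


# --------------------------------------------------------------------------
# shared smoke-event schedule (drives both polygons and monitor spikes)
# --------------------------------------------------------------------------

def _ellipse_polygon(center_lat, center_lon, r_lat, r_lon, angle_rad, n_vertices=12) -> Polygon:
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    x = r_lon * np.cos(t)
    y = r_lat * np.sin(t)
    xr = x * np.cos(angle_rad) - y * np.sin(angle_rad)
    yr = x * np.sin(angle_rad) + y * np.cos(angle_rad)
    return Polygon(zip(center_lon + xr, center_lat + yr))


def _event_schedule(config: SimConfig) -> pd.DataFrame:
    """Daily smoke polygons, deterministic in the seed; shared by the smoke
    and monitor generators so AQI spikes co-occur with plume coverage."""
    rng = config.rng(11)
    lat_min, lat_max, lon_min, lon_max = config.bbox
    lat_span, lon_span = lat_max - lat_min, lon_max - lon_min
    rows = []
    for season in config.seasons:
        for date in config.season_dates(season):
            if rng.random() >= season.smoke_event_prob:
                continue
            n_poly = int(rng.integers(1, season.max_polygons + 1))
            for _ in range(n_poly):
                clat = rng.uniform(lat_min, lat_max)
                clon = rng.uniform(lon_min, lon_max)
                r_lat = rng.uniform(0.15, 0.45) * lat_span
                r_lon = rng.uniform(0.15, 0.45) * lon_span
                angle = rng.uniform(0, np.pi)
                density = rng.choice(("light", "medium", "heavy"), p=np.asarray(season.density_weights) / sum(season.density_weights))
                rows.append({
                    "date": date, "season": season.label, "density": str(density),
                    "geometry": _ellipse_polygon(clat, clon, r_lat, r_lon, angle),
                })
    return pd.DataFrame(rows, columns=["date", "season", "density", "geometry"])


def generate_smoke(config: SimConfig) -> pd.DataFrame:
    """Daily smoke-density polygons: columns (date, density, geometry).

    Zero or more simple polygons per day; none on days without an event
    (a season with ``smoke_event_prob`` 0, e.g. the winter default, has no
    smoke coverage at all).
    """
    return _event_schedule(config).drop(columns="season").reset_index(drop=True)


# --------------------------------------------------------------------------
# monitors
# --------------------------------------------------------------------------

def generate_monitors(config: SimConfig) -> pd.DataFrame:
    """Daily stationary-monitor AQI table: (monitor_id, latitude, longitude, date, aqi).

    Each monitor sits at a fixed random location; its daily series is a
    seasonal baseline plus AR(1) noise, plus an additive spike (scaled by
    smoke density / 3) on days a smoke polygon covers it.  A configurable
    fraction of monitor-days is missing (row absent).
    """
    rng = config.rng(12)
    lat_min, lat_max, lon_min, lon_max = config.bbox
    ids = [f"M{i:02d}" for i in range(config.n_monitors)]
    lats = rng.uniform(lat_min, lat_max, config.n_monitors)
    lons = rng.uniform(lon_min, lon_max, config.n_monitors)
    events = _event_schedule(config)

    rows = []
    for season in config.seasons:
        dates = config.season_dates(season)
        noise = np.zeros(config.n_monitors)
        for d_idx, date in enumerate(dates):
            innov = rng.normal(0.0, config.aqi_noise_sd, config.n_monitors)
            if d_idx == 0:
                noise = innov
            else:
                noise = config.aqi_rho * noise + math.sqrt(1.0 - config.aqi_rho**2) * innov
            spike = np.zeros(config.n_monitors)
            day_polys = events[events["date"] == date]
            for _, poly in day_polys.iterrows():
                level = DENSITY_LEVELS[poly["density"]]
                covered = np.array([poly["geometry"].covers(Point(lon, lat)) for lat, lon in zip(lats, lons)])
                spike = np.maximum(spike, covered * season.aqi_spike * level / 3.0)
            aqi = np.maximum(season.aqi_baseline + noise + spike, 0.0)
            keep = rng.random(config.n_monitors) >= config.monitor_missing_rate
            for m in np.flatnonzero(keep):
                rows.append({"monitor_id": ids[m], "latitude": lats[m], "longitude": lons[m],
                             "date": date, "aqi": float(aqi[m])})
    return pd.DataFrame(rows, columns=["monitor_id", "latitude", "longitude", "date", "aqi"])


# --------------------------------------------------------------------------
# sampling periods, trajectories, questionnaires
# --------------------------------------------------------------------------

def _participant_ids(config: SimConfig) -> list[str]:
    return [f"P{i:02d}" for i in range(config.n_participants)]


def generate_periods(config: SimConfig) -> pd.DataFrame:
    """Wristband sampling periods, one per participant-season-day.

    Columns: wristband_id, participant_id, season, on_time, off_time,
    bagged, times_recorded.  A small configurable fraction carries a planted
    QC violation (bad duration, missing times, unbagged, or an afternoon
    on-time) so downstream filters have work to do.
    """
    rng = config.rng(13)
    rows = []
    for pid in _participant_ids(config):
        for season in config.seasons:
            for day in range(config.days_per_season):
                date = season.start + dt.timedelta(days=day)
                on = pd.Timestamp(date, tz=TIMEZONE) + pd.Timedelta(hours=7.5 + rng.uniform(0, 1.5))
                duration = pd.Timedelta(hours=float(np.clip(24.0 + rng.normal(0, 2.0), 17.0, 31.0)))
                bagged, times_recorded = True, True
                u = rng.random()
                if u < config.rate_bag_violation:
                    bagged = False
                elif u < config.rate_bag_violation + config.rate_times_missing:
                    times_recorded = False
                elif u < config.rate_bag_violation + config.rate_times_missing + config.rate_duration_violation:
                    duration = pd.Timedelta(hours=40.0)
                elif u < (config.rate_bag_violation + config.rate_times_missing
                          + config.rate_duration_violation + config.rate_ontime_violation):
                    on = pd.Timestamp(date, tz=TIMEZONE) + pd.Timedelta(hours=13.0 + rng.uniform(0, 3))
                rows.append({
                    "wristband_id": f"{pid}-{season.label}-{day + 1}",
                    "participant_id": pid, "season": season.label,
                    "on_time": on if times_recorded else pd.NaT,
                    "off_time": (on + duration) if times_recorded else pd.NaT,
                    "bagged": bagged, "times_recorded": times_recorded,
                })
    return pd.DataFrame(rows)


def generate_trajectories(config: SimConfig) -> pd.DataFrame:
    """GPS fixes at a fixed cadence: (participant_id, timestamp, lat, lon).

    Movement is piecewise: dwell at a fixed home, with on travel days a
    constant-speed out-and-back trip whose round-trip length is log-normal
    (median ``trip_median_mi``); a ``stay_home_prob`` fraction of days has
    zero travel.  Fixes are generated for every study day plus one trailing
    day so 24-h wear windows that cross midnight stay covered.
    """
    rng = config.rng(14)
    lat_min, lat_max, lon_min, lon_max = config.bbox
    # homes in the central half of the bbox so trips stay inside
    homes = {
        pid: (rng.uniform(lat_min + 0.25 * (lat_max - lat_min), lat_max - 0.25 * (lat_max - lat_min)),
              rng.uniform(lon_min + 0.25 * (lon_max - lon_min), lon_max - 0.25 * (lon_max - lon_min)))
        for pid in _participant_ids(config)
    }
    step = pd.Timedelta(minutes=config.fix_interval_min)
    n_per_day = int(round(24 * 60 / config.fix_interval_min))
    hours = np.arange(n_per_day) * config.fix_interval_min / 60.0

    frames = []
    for pid, (hlat, hlon) in homes.items():
        for season in config.seasons:
            for date in config.season_dates(season):
                day_start = pd.Timestamp(date, tz=TIMEZONE)
                times = day_start + step * np.arange(n_per_day)
                if rng.random() < config.stay_home_prob:
                    lats = np.full(n_per_day, hlat)
                    lons = np.full(n_per_day, hlon)
                else:
                    total = min(float(rng.lognormal(math.log(config.trip_median_mi), config.trip_log_sd)),
                                config.trip_max_mi)
                    one_way = total / 2.0
                    bearing = rng.uniform(0, 360)
                    dlat, dlon = destination_point(hlat, hlon, bearing, one_way)
                    dlat = float(np.clip(dlat, lat_min, lat_max))
                    dlon = float(np.clip(dlon, lon_min, lon_max))
                    t_travel = one_way / config.travel_speed_mph
                    depart, dwell = 9.0, 4.0
                    t_arrive = depart + t_travel
                    t_back = t_arrive + dwell
                    t_home = t_back + t_travel
                    frac = np.zeros(n_per_day)
                    going = (hours >= depart) & (hours < t_arrive)
                    frac[going] = (hours[going] - depart) / max(t_travel, 1e-9)
                    frac[(hours >= t_arrive) & (hours < t_back)] = 1.0
                    returning = (hours >= t_back) & (hours < t_home)
                    frac[returning] = 1.0 - (hours[returning] - t_back) / max(t_travel, 1e-9)
                    lats = hlat + frac * (dlat - hlat)
                    lons = hlon + frac * (dlon - hlon)
                if config.gps_noise_deg > 0:
                    lats = lats + rng.normal(0, config.gps_noise_deg, n_per_day)
                    lons = lons + rng.normal(0, config.gps_noise_deg, n_per_day)
                frames.append(pd.DataFrame({
                    "participant_id": pid, "timestamp": times,
                    "lat": np.clip(lats, lat_min, lat_max),
                    "lon": np.clip(lons, lon_min, lon_max),
                }))
    return pd.concat(frames, ignore_index=True)


def generate_questionnaires(config: SimConfig, periods: pd.DataFrame) -> pd.DataFrame:
    """One evening questionnaire per sampling period.

    Columns: participant_id, date, answered_at, carried_phone,
    no_carry_reason, time_indoors.  A configurable fraction is missing
    entirely, another fraction is answered outside the 4 p.m.-4 a.m. window
    (to exercise the downstream time filter), and a ``no_carry_rate``
    fraction reports not carrying the phone with a sampled reason.
    """
    rng = config.rng(15)
    probs = np.asarray(config.time_indoors_probs, dtype=float)
    probs = probs / probs.sum()
    rows = []
    for _, p in periods.iterrows():
        if rng.random() < config.questionnaire_missing_rate:
            continue
        if pd.notna(p["on_time"]):
            wear_date = p["on_time"].date()
        else:  # times unrecorded: reconstruct the nominal wear day from the id
            _, label, day = p["wristband_id"].rsplit("-", 2)
            start = next(s.start for s in config.seasons if s.label == label)
            wear_date = start + dt.timedelta(days=int(day) - 1)
        day_start = pd.Timestamp(wear_date, tz=TIMEZONE)
        if rng.random() < config.questionnaire_window_violation_rate:
            answered = day_start + pd.Timedelta(hours=rng.uniform(9.0, 15.9))
        else:
            answered = day_start + pd.Timedelta(hours=rng.uniform(17.0, 23.5))
        carried = rng.random() >= config.no_carry_rate
        reason = None if carried else str(rng.choice(NO_CARRY_REASONS, p=(0.35, 0.15, 0.3, 0.1, 0.1)))
        rows.append({
            "participant_id": p["participant_id"], "date": wear_date, "answered_at": answered,
            "carried_phone": carried, "no_carry_reason": reason,
            "time_indoors": str(rng.choice(TIME_INDOORS_LEVELS, p=probs)),
        })
    return pd.DataFrame(rows, columns=["participant_id", "date", "answered_at",
                                       "carried_phone", "no_carry_reason", "time_indoors"])


# --------------------------------------------------------------------------
# chemistry
# --------------------------------------------------------------------------

def generate_chemistry(config: SimConfig, features: pd.DataFrame,
                       participants: pd.Series | None = None) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-chemical wristband measurements from the generating linear model.

    ``features`` must carry one row per sampling period with columns
    wristband_id, participant_id, season, weighted_aqi, hms_index,
    time_indoors, distance_category.  Returns the measurement table
    (concentrations in ng/g, left-censored at the LOD, matrix interference
    set missing at ``interference_rate``) together with the uncensored
    ground truth.
    """
    if not config.chemicals:
        raise ValueError("config.chemicals is empty")
    required = {"wristband_id", "participant_id", "season", "weighted_aqi",
                "hms_index", "time_indoors", "distance_category"}
    missing = required - set(features.columns)
    if missing:
        raise ValueError(f"features table is missing columns: {sorted(missing)}")
    rng = config.rng(16)
    pids = sorted(features["participant_id"].unique()) if participants is None else sorted(set(participants))
    n = len(features)

    meas_rows, truth_rows, pe_rows = [], [], []
    for chem in config.chemicals:
        for lvl in features["season"].unique():
            if lvl not in chem.season_offsets:
                raise KeyError(f"{chem.chemical_id}: no season offset for level {lvl!r}")
        for lvl in features["time_indoors"].dropna().unique():
            if lvl not in chem.indoors_offsets:
                raise KeyError(f"{chem.chemical_id}: no indoors offset for level {lvl!r}")
        pe = dict(zip(pids, rng.normal(0.0, chem.participant_sd, len(pids))))
        for pid, eff in pe.items():
            pe_rows.append({"participant_id": pid, "chemical_id": chem.chemical_id, "effect": eff})
        season_off = features["season"].map(chem.season_offsets).to_numpy(float)
        indoors_off = features["time_indoors"].map(chem.indoors_offsets).fillna(0.0).to_numpy(float)
        dist_off = features["distance_category"].map(chem.distance_offsets).fillna(0.0).to_numpy(float)
        true_log2 = (chem.intercept + season_off
                     + chem.slope_aqi * features["weighted_aqi"].to_numpy(float)
                     + chem.slope_hms * features["hms_index"].to_numpy(float)
                     + indoors_off + dist_off
                     + features["participant_id"].map(pe).to_numpy(float)
                     + rng.normal(0.0, chem.residual_sd, n))
        nondetect = true_log2 < chem.lod_log2
        interference = rng.random(n) < config.interference_rate
        # pmol/g = 2**log2 ; ng/g = pmol/g * MW / 1000
        raw_ng = np.where(nondetect | interference, np.nan,
                          np.exp2(true_log2) * chem.molecular_weight / 1000.0)
        lod_ng = (np.exp2(chem.lod_log2) * chem.molecular_weight / 1000.0
                  if np.isfinite(chem.lod_log2) else 0.0)
        loq_ng = (np.exp2(chem.loq_log2) * chem.molecular_weight / 1000.0
                  if np.isfinite(chem.loq_log2) else 0.0)
        for i, wb in enumerate(features["wristband_id"].to_numpy()):
            meas_rows.append({
                "wristband_id": wb, "chemical_id": chem.chemical_id,
                "raw_conc": raw_ng[i],
                "nondetect": bool(nondetect[i]) and not bool(interference[i]),
                "interference": bool(interference[i]),
                "lod": lod_ng, "loq": loq_ng,
            })
            truth_rows.append({"wristband_id": wb, "chemical_id": chem.chemical_id,
                               "true_log2": float(true_log2[i])})
    measurements = pd.DataFrame(meas_rows)
    truth = GroundTruth(true_log2=pd.DataFrame(truth_rows), effects=config.chemicals,
                        participant_effects=pd.DataFrame(pe_rows))
    return measurements, truth


def chemical_info(config: SimConfig) -> pd.DataFrame:
    """Panel metadata table: chemical_id, name, molecular_weight, class_label."""
    return pd.DataFrame([
        {"chemical_id": c.chemical_id, "name": c.name,
         "molecular_weight": c.molecular_weight, "class_label": c.class_label}
        for c in config.chemicals
    ])


# --------------------------------------------------------------------------
# direct modeling-table simulator (for model-framework studies)
# --------------------------------------------------------------------------

def simulate_modeling_table(
    n: int = 364,
    seed: int = 0,
    n_participants: int = 35,
    beta_aqi: float = 0.0,
    beta_hms: float = 0.0,
    season_offsets: dict | None = None,
    indoors_slope: float = 0.0,
    distance_slope: float = 0.0,
    interaction_aqi: dict | None = None,
    participant_sd: float = 0.0,
    noise_sd: float = 1.0,
    season_aqi_regimes: bool = True,
) -> pd.DataFrame:
    """Feature table + tertile outcome drawn directly at the modeling scale.

    Features mimic the marginal structure of the merged study table (seasonal
    AQI regimes, zero-inflated smoke proportions sharing a latent driver with
    AQI, log-normal travel distance, categorical time indoors).  The outcome
    is the empirical-tertile category of a latent variable

        latent = beta_aqi*AQI + beta_hms*HMS + season offset
                 + indoors_slope*indoors_rank + distance_slope*distance_rank
                 + interaction_aqi[season]*(AQI - season median AQI)
                 + participant effect + noise

    The interaction term is season-centred, so a pure sign-flip
    specification carries no marginal AQI effect — the regime greedy trees
    cannot discover without explicit per-season columns.

    so null (all coefficients 0) and planted-effect studies share one code
    path.  Returns a DataFrame with feature columns, ``participant_id`` and
    an ordered categorical ``outcome`` in {Low, Medium, High}.
    """
    rng = np.random.default_rng([int(seed) % (2**31), 99])
    # per-season AQI regimes (two smoky summers, one clean winter); a shared
    # regime isolates pure interactions: no season is identifiable from AQI
    season_specs = ({"S17": (60.0, 0.8), "W18": (21.0, 0.45), "S18": (40.0, 0.6)}
                    if season_aqi_regimes
                    else {"S17": (40.0, 0.7), "W18": (40.0, 0.7), "S18": (40.0, 0.7)})
    season = np.asarray(SEASON_LABELS)[rng.integers(0, 3, n)]
    mu = np.array([season_specs[s][0] for s in season])
    sig = np.array([season_specs[s][1] for s in season])
    aqi = np.exp(np.log(mu) + sig * rng.normal(0, 1, n) - sig**2 / 2)
    aqi = np.clip(aqi, 0.0, 500.0)

    # smoke driven by the same latent severity as AQI (winter has none)
    sev = (np.log(aqi + 1) - np.log(mu)) / sig
    p_smoke = np.where(season == "W18", 0.0, 1 / (1 + np.exp(-(sev - 0.3) * 1.5)))
    has_smoke = rng.random(n) < p_smoke
    mass = np.where(has_smoke, rng.beta(2, 2, n), 0.0)
    split = rng.dirichlet((2.0, 1.2, 0.8), n)
    light, medium, heavy = (mass * split[:, k] for k in range(3))
    hms = (light + 2 * medium + 3 * heavy) / 3.0

    distance = np.where(rng.random(n) < 0.04, 0.0,
                        np.exp(np.log(15.4) + 1.1 * rng.normal(0, 1, n)))
    dist_rank = np.searchsorted([4.0, 15.0, 35.0], distance, side="left")
    indoors_rank = rng.choice(5, n, p=(0.01, 0.04, 0.46, 0.30, 0.19))

    pids = np.array([f"P{i:02d}" for i in rng.integers(0, n_participants, n)])
    pe = {f"P{i:02d}": rng.normal(0, participant_sd) for i in range(n_participants)}
    soff = season_offsets or {}
    iaq = interaction_aqi or {}
    latent = (beta_aqi * aqi + beta_hms * hms
              + np.array([soff.get(s, 0.0) for s in season])
              + indoors_slope * indoors_rank + distance_slope * dist_rank
              + np.array([iaq.get(s, 0.0) for s in season]) * (aqi - mu)
              + np.array([pe[p] for p in pids])
              + noise_sd * rng.normal(0, 1, n))
    cuts = np.quantile(latent, [1 / 3, 2 / 3])
    outcome = pd.Categorical.from_codes(np.searchsorted(cuts, latent, side="right"),
                                        categories=["Low", "Medium", "High"], ordered=True)

    df = pd.DataFrame({
        "wristband_id": [f"wb{i:04d}" for i in range(n)],
        "participant_id": pids, "season": season,
        "weighted_aqi": aqi, "hms_index": hms,
        "prop_light": light, "prop_medium": medium, "prop_heavy": heavy,
        "distance_traveled_mi": distance,
        "distance_category": pd.Categorical.from_codes(dist_rank, ["Q1", "Q2", "Q3", "Q4"], ordered=True),
        "time_indoors": pd.Categorical.from_codes(indoors_rank, list(TIME_INDOORS_LEVELS), ordered=True),
        "outcome": outcome,
    })
    for s in SEASON_LABELS:
        ind = (df["season"] == s).to_numpy(float)
        df[f"aqi_{s}"] = df["weighted_aqi"] * ind
        df[f"hms_{s}"] = df["hms_index"] * ind
    return df


def simulate_crossing_interaction_table(n: int = 364, seed: int = 0,
                                        label_noise: float = 0.15) -> pd.DataFrame:
    """Feature table with a pure Season x AQI crossing interaction.

    The outcome is the within-season AQI tertile *rotated* by season
    (S17: low->Low..., S18 and W18 rotated by one and two positions), with
    ``label_noise`` random relabelling.  Seasons share one AQI regime, so
    neither season nor AQI carries any marginal signal — class given AQI
    alone, or season alone, is uniform.  Only season-specific AQI splits
    (the explicit interaction columns) expose the structure; a greedy tree
    on the standard features has no first split to find.
    """
    df = simulate_modeling_table(n=n, seed=seed, season_aqi_regimes=False)
    rng = np.random.default_rng([int(seed) % (2**31), 98])
    codes = np.empty(n, dtype=int)
    rotation = {"S17": 0, "S18": 1, "W18": 2}
    for s, rot in rotation.items():
        m = (df["season"] == s).to_numpy()
        aqi = df.loc[m, "weighted_aqi"].to_numpy()
        cuts = np.quantile(aqi, [1 / 3, 2 / 3])
        codes[m] = (np.searchsorted(cuts, aqi, side="right") + rot) % 3
    flip = rng.random(n) < label_noise
    codes[flip] = rng.integers(0, 3, int(flip.sum()))
    df["outcome"] = pd.Categorical.from_codes(codes, categories=["Low", "Medium", "High"],
                                              ordered=True)
    return df
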