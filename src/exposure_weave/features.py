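"""Per-period environmental and behavioural exposure features.

The central quantity is the time-weighted daily PM2.5 AQI: wear time is
partitioned into inter-fix intervals, each interval is attributed to the
stationary monitor nearest its *starting* fix (leading/trailing slack goes
to the first/last fix), and the period's AQI is the time-weight-averaged
AQI of those monitors.  Smoke exposure works the same way with a
point-in-polygon test against the day's plume polygons (overlaps resolve
to the highest density), summarised by the HMS Index

    (0*None + 1*Light + 2*Medium + 3*Heavy) / 3

which is 0 with no smoke and 1 for a period spent entirely in heavy smoke.
Intervals that cross local midnight are split so each piece uses its own
calendar day's monitor values and polygons.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .geo import haversine_miles, path_length_miles

DENSITY_ORDER = ("none", "light", "medium", "heavy")
_DENSITY_LEVEL = {"none": 0, "light": 1, "medium": 2, "heavy": 3}
DISTANCE_LABELS = ("Q1", "Q2", "Q3", "Q4")
PINNED_DISTANCE_CUTPOINTS = (4.0, 15.0, 35.0)


def daily_average_monitors(raw: pd.DataFrame) -> pd.DataFrame:
    """Collapse repeated same-day readings to one arithmetic mean per monitor-day."""
    if (raw["aqi"] < 0).any():
        bad = raw.loc[raw["aqi"] < 0].iloc[0]
        raise ValueError(f"negative AQI for monitor {bad['monitor_id']} on {bad['date']}")
    out = (raw.groupby(["monitor_id", "date"], as_index=False)
              .agg(latitude=("latitude", "first"), longitude=("longitude", "first"),
                   aqi=("aqi", "mean")))
    return out[["monitor_id", "latitude", "longitude", "date", "aqi"]]


def nearest_monitor(lat: float, lon: float, monitors_for_day: pd.DataFrame) -> tuple[str, float]:
    """Nearest monitor (great-circle, statute miles) among those with data that day.

    Ties break by lexicographic monitor id for determinism.
    """
    if monitors_for_day.empty:
        raise ValueError("no monitor has data for this day")
    d = haversine_miles(lat, lon, monitors_for_day["latitude"].to_numpy(),
                        monitors_for_day["longitude"].to_numpy())
    ids = monitors_for_day["monitor_id"].to_numpy()
    order = np.lexsort((ids, d))
    best = order[0]
    return str(ids[best]), float(d[best])


def _intervals(fixes: pd.DataFrame, on_time: pd.Timestamp, off_time: pd.Timestamp):
    """Wear-time partition: (start, end, fix_lat, fix_lon) per interval, with
    leading/trailing slack attributed to the first/last fix, then split at
    local midnight so each piece has a single calendar day."""
    if off_time <= on_time:
        raise ValueError("zero-length wear time")
    if fixes.empty:
        raise ValueError("period has no fixes")
    f = fixes.sort_values("timestamp").reset_index(drop=True)
    times = list(f["timestamp"])
    n = len(times)
    raw = []
    for i in range(n):
        start = on_time if i == 0 else times[i]          # leading slack -> first fix
        end = off_time if i == n - 1 else times[i + 1]   # trailing slack -> last fix
        if end <= start:
            continue
        raw.append((start, end, float(f.loc[i, "lat"]), float(f.loc[i, "lon"])))
    # split at midnight boundaries
    out = []
    for start, end, lat, lon in raw:
        cur = start
        while cur < end:
            next_midnight = (cur + pd.Timedelta(days=1)).normalize()
            piece_end = min(end, next_midnight)
            out.append((cur, piece_end, lat, lon))
            cur = piece_end
    return out


def weighted_aqi(fixes: pd.DataFrame, on_time: pd.Timestamp, off_time: pd.Timestamp,
                 monitor_days: pd.DataFrame) -> float:
    """Time-weighted mean AQI over the wear interval.

    Each interval contributes weight (interval seconds / total wear seconds)
    to the AQI of the monitor nearest its starting fix on the interval's own
    calendar day; monitors without data that day are excluded from the
    search.  Weights sum to 1 by construction.
    """
    total = (off_time - on_time).total_seconds()
    by_day = {d: g for d, g in monitor_days.groupby("date")}
    aqi_lookup = monitor_days.set_index(["monitor_id", "date"])["aqi"]
    acc = 0.0
    for start, end, lat, lon in _intervals(fixes, on_time, off_time):
        day = start.date()
        if day not in by_day:
            raise ValueError(f"no monitor has data on {day}")
        mid, _ = nearest_monitor(lat, lon, by_day[day])
        acc += ((end - start).total_seconds() / total) * float(aqi_lookup[(mid, day)])
    return acc


def smoke_proportions(fixes: pd.DataFrame, on_time: pd.Timestamp, off_time: pd.Timestamp,
                      polygons: pd.DataFrame) -> dict:
    """Proportion of wear time in none/light/medium/heavy smoke density.

    Each interval's starting fix is tested against the interval-day's
    polygons; overlapping polygons resolve to the highest density.  The four
    proportions sum to 1.
    """
    for i, geom in enumerate(polygons["geometry"] if len(polygons) else []):
        if not geom.is_valid:
            raise ValueError(f"invalid smoke polygon at row {i}")
    from shapely.geometry import Point

    total = (off_time - on_time).total_seconds()
    by_day = {d: g for d, g in polygons.groupby("date")} if len(polygons) else {}
    acc = dict.fromkeys(DENSITY_ORDER, 0.0)
    for start, end, lat, lon in _intervals(fixes, on_time, off_time):
        day_polys = by_day.get(start.date())
        level = 0
        if day_polys is not None:
            pt = Point(lon, lat)
            for _, row in day_polys.iterrows():
                if row["geometry"].covers(pt):
                    level = max(level, _DENSITY_LEVEL[row["density"]])
        acc[DENSITY_ORDER[level]] += (end - start).total_seconds() / total
    s = sum(acc.values())   # remove float accumulation drift
    return {k: v / s for k, v in acc.items()}


def hms_index(props: dict) -> float:
    """(0*None + 1*Light + 2*Medium + 3*Heavy)/3 of the wear-time proportions."""
    total = sum(props[k] for k in DENSITY_ORDER)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"smoke proportions sum to {total}, not 1")
    return (props["light"] + 2.0 * props["medium"] + 3.0 * props["heavy"]) / 3.0


def distance_traveled(fixes: pd.DataFrame) -> float:
    """Summed consecutive-fix great-circle distance over the period, in miles."""
    return path_length_miles(fixes["lat"].to_numpy(), fixes["lon"].to_numpy())


def categorize_distance(distances, cutpoints=None) -> pd.Categorical:
    """Quartile-style distance categories Q1<Q2<Q3<Q4.

    With ``cutpoints=None`` the three cutpoints are the empirical 25/50/75th
    percentiles of the input; pass explicit cutpoints (e.g. the pinned
    4/15/35 mi) to reproduce a fixed categorisation.  A value exactly at a
    cutpoint goes to the lower category.
    """
    d = np.asarray(distances, dtype=float)
    if cutpoints is None:
        cuts = np.quantile(d, [0.25, 0.5, 0.75])
    else:
        cuts = np.asarray(cutpoints, dtype=float)
        if cuts.shape != (3,) or np.any(np.diff(cuts) < 0):
            raise ValueError("cutpoints must be three non-decreasing values")
    codes = np.searchsorted(cuts, d, side="left")
    return pd.Categorical.from_codes(codes, categories=list(DISTANCE_LABELS), ordered=True)


def build_features(periods: pd.DataFrame, fix_map: dict, responses: pd.DataFrame,
                   monitor_days: pd.DataFrame, polygons: pd.DataFrame,
                   distance_cutpoints=None) -> pd.DataFrame:
    """One feature row per surviving period.

    Columns: wristband_id, participant_id, season, weighted_aqi, the four
    smoke proportions, hms_index, distance_traveled_mi, distance_category,
    time_indoors, plus per-season interaction copies aqi_<season> and
    hms_<season> that are zero off-season.
    """
    resp = responses.set_index(["participant_id", "date"])
    rows = []
    for _, p in periods.iterrows():
        wid = p["wristband_id"]
        fixes = fix_map[wid]
        try:
            waqi = weighted_aqi(fixes, p["on_time"], p["off_time"], monitor_days)
            props = smoke_proportions(fixes, p["on_time"], p["off_time"], polygons)
        except ValueError as exc:
            raise ValueError(f"feature construction failed for {wid}: {exc}") from exc
        key = (p["participant_id"], p["on_time"].date())
        indoors = None
        if key in resp.index:
            r = resp.loc[key]
            indoors = (r.iloc[0] if isinstance(r, pd.DataFrame) else r)["time_indoors"]
        rows.append({
            "wristband_id": wid, "participant_id": p["participant_id"], "season": p["season"],
            "weighted_aqi": waqi,
            "prop_none": props["none"], "prop_light": props["light"],
            "prop_medium": props["medium"], "prop_heavy": props["heavy"],
            "hms_index": hms_index(props),
            "distance_traveled_mi": distance_traveled(fixes),
            "time_indoors": indoors,
        })
    from .synthetic import TIME_INDOORS_LEVELS

    feats = pd.DataFrame(rows)
    feats["time_indoors"] = pd.Categorical(feats["time_indoors"],
                                           categories=list(TIME_INDOORS_LEVELS), ordered=True)
    feats["distance_category"] = categorize_distance(feats["distance_traveled_mi"],
                                                     cutpoints=distance_cutpoints)
    for season in sorted(feats["season"].unique()):
        ind = (feats["season"] == season).to_numpy(float)
        feats[f"aqi_{season}"] = feats["weighted_aqi"] * ind
        feats[f"hms_{season}"] = feats["hms_index"] * ind
    return feats
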