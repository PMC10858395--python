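"""Independent brute-force oracles used only by the tests.

These re-derive the feature quantities by per-second time integration and
exhaustive search, deliberately sharing no code with the interval-based
implementations they check.
"""
import numpy as np
import pandas as pd
from shapely.geometry import Point

from exposure_weave.geo import haversine_miles

DENSITY_LEVEL = {"light": 1, "medium": 2, "heavy": 3}


def _governing_fix(fix_times_ns, t_ns):
    """Left-constant attribution: last fix at/before t, first fix before any."""
    idx = np.searchsorted(fix_times_ns, t_ns, side="right") - 1
    return np.clip(idx, 0, len(fix_times_ns) - 1)


def per_second_weighted_aqi(fixes, on_time, off_time, monitor_days):
    """Mean over whole seconds of the nearest-monitor AQI at that second."""
    f = fixes.sort_values("timestamp")
    fix_ns = f["timestamp"].astype("int64").to_numpy()
    lats, lons = f["lat"].to_numpy(), f["lon"].to_numpy()
    seconds = np.arange(on_time.value, off_time.value, 10**9)
    idx = _governing_fix(fix_ns, seconds)
    days = pd.to_datetime(seconds, utc=True).tz_convert(on_time.tz).date
    by_day = {d: g for d, g in monitor_days.groupby("date")}
    cache = {}
    total = 0.0
    for i, d in zip(idx, days):
        key = (i, d)
        if key not in cache:
            g = by_day[d]
            dist = haversine_miles(lats[i], lons[i], g["latitude"].to_numpy(),
                                   g["longitude"].to_numpy())
            order = np.lexsort((g["monitor_id"].to_numpy(), dist))
            cache[key] = float(g["aqi"].to_numpy()[order[0]])
        total += cache[key]
    return total / len(seconds)


def per_second_smoke_proportions(fixes, on_time, off_time, polygons):
    f = fixes.sort_values("timestamp")
    fix_ns = f["timestamp"].astype("int64").to_numpy()
    lats, lons = f["lat"].to_numpy(), f["lon"].to_numpy()
    seconds = np.arange(on_time.value, off_time.value, 10**9)
    idx = _governing_fix(fix_ns, seconds)
    days = pd.to_datetime(seconds, utc=True).tz_convert(on_time.tz).date
    by_day = {d: g for d, g in polygons.groupby("date")} if len(polygons) else {}
    cache = {}
    counts = np.zeros(4)
    for i, d in zip(idx, days):
        key = (i, d)
        if key not in cache:
            level = 0
            g = by_day.get(d)
            if g is not None:
                pt = Point(lons[i], lats[i])
                for _, row in g.iterrows():
                    if row["geometry"].covers(pt):
                        level = max(level, DENSITY_LEVEL[row["density"]])
            cache[key] = level
        counts[cache[key]] += 1
    props = counts / len(seconds)
    return {"none": props[0], "light": props[1], "medium": props[2], "heavy": props[3]}


def exhaustive_nearest(lat, lon, monitors):
    best = None
    for _, m in monitors.iterrows():
        d = float(haversine_miles(lat, lon, m["latitude"], m["longitude"]))
        if best is None or d < best[1] - 1e-12 or (abs(d - best[1]) <= 1e-12 and m["monitor_id"] < best[0]):
            best = (m["monitor_id"], d)
    return best
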