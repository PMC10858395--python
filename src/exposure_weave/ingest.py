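"""Inclusion/exclusion rules and the merge into one analysis table.

A wristband sampling period survives only if it was (a) worn within +-8 h of
the nominal 24-h window (16-32 h), (b) has recorded on/off times, (c) arrived
bagged, (d) was put on between 00:01 and 11:59 local, and (e) falls inside
the participant-season's 7-day study window.  Questionnaires count only when
answered between 4 p.m. and 4 a.m. local.  GPS pairing drops periods where
the phone was neither carried nor left in the participant's general
location, and periods with no fix inside the wear interval.

Every filter returns its survivors together with an exhaustive exclusion
log; reasons are assigned by the first failing rule in the documented order
so counts are reproducible.
"""
from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from .geo import haversine_miles

MIN_WEAR_HOURS = 16.0
MAX_WEAR_HOURS = 32.0
ON_TIME_EARLIEST = dt.time(0, 1)
ON_TIME_LATEST = dt.time(11, 59)
QUESTIONNAIRE_OPEN = dt.time(16, 0)
QUESTIONNAIRE_CLOSE = dt.time(4, 0)
STUDY_WINDOW_DAYS = 7
SPEED_LIMIT_MPH = 120.0

REASON_DURATION = "wear-duration"
REASON_TIMES = "times-not-recorded"
REASON_BAG = "not-bagged"
REASON_ON_TIME = "on-time-window"
REASON_STUDY_WINDOW = "outside-study-window"


def filter_wristbands(periods: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the wristband inclusion rules.

    Returns ``(kept, exclusion_log)``; the log has one row per dropped
    period with columns (wristband_id, reason).  The wear-duration rule is
    only assessable when both times are recorded, so unrecorded times are
    reported as ``times-not-recorded``.
    """
    for col in ("on_time", "off_time"):
        if not (pd.api.types.is_datetime64_any_dtype(periods[col]) or periods[col].isna().all()):
            bad = periods.loc[~periods[col].map(lambda v: isinstance(v, pd.Timestamp) or pd.isna(v)), "wristband_id"]
            raise ValueError(f"malformed timestamps in {col} for records {list(bad)[:5]}")

    anchors = _study_anchors(periods)
    reasons = {}
    for _, p in periods.iterrows():
        wid = p["wristband_id"]
        times_ok = bool(p["times_recorded"]) and pd.notna(p["on_time"]) and pd.notna(p["off_time"])
        if times_ok:
            hours = (p["off_time"] - p["on_time"]).total_seconds() / 3600.0
            if not (MIN_WEAR_HOURS <= hours <= MAX_WEAR_HOURS):
                reasons[wid] = REASON_DURATION
                continue
        if not times_ok:
            reasons[wid] = REASON_TIMES
            continue
        if not bool(p["bagged"]):
            reasons[wid] = REASON_BAG
            continue
        clock = p["on_time"].time()
        if not (ON_TIME_EARLIEST <= clock <= ON_TIME_LATEST):
            reasons[wid] = REASON_ON_TIME
            continue
        anchor = anchors[(p["participant_id"], p["season"])]
        if not (anchor <= p["on_time"].date() <= anchor + dt.timedelta(days=STUDY_WINDOW_DAYS - 1)):
            reasons[wid] = REASON_STUDY_WINDOW
    kept = periods[~periods["wristband_id"].isin(reasons)].reset_index(drop=True)
    log = pd.DataFrame(
        [{"wristband_id": w, "reason": r} for w, r in reasons.items()],
        columns=["wristband_id", "reason"],
    )
    return kept, log


def _study_anchors(periods: pd.DataFrame) -> dict:
    """First recorded on-date per participant-season anchors its 7-day window."""
    anchors = {}
    with_times = periods[periods["on_time"].notna()]
    for (pid, season), grp in with_times.groupby(["participant_id", "season"]):
        anchors[(pid, season)] = grp["on_time"].min().date()
    for key in periods.groupby(["participant_id", "season"]).groups:
        anchors.setdefault(key, dt.date.min)
    return anchors


def filter_questionnaires(responses: pd.DataFrame) -> pd.DataFrame:
    """Keep responses answered between 16:00 and 04:00 local (both ends closed).

    The window spans midnight; responses with a missing timestamp are dropped.
    """
    present = responses[responses["answered_at"].notna()]
    if present.empty:
        return present.reset_index(drop=True)
    clock = present["answered_at"].map(lambda t: t.time())
    in_window = (clock >= QUESTIONNAIRE_OPEN) | (clock <= QUESTIONNAIRE_CLOSE)
    return present[in_window].reset_index(drop=True)


def default_fix_qc(fixes: pd.DataFrame) -> pd.DataFrame:
    """Fix-level QC hook: drop fixes implying speed above 120 mph.

    A stand-in for device-level GPS quality control; replaceable via the
    ``fix_qc`` argument of :func:`pair_gps`.
    """
    parts = []
    for _, g in fixes.groupby("participant_id", sort=False):
        g = g.sort_values("timestamp")
        if len(g) >= 2:
            lats, lons = g["lat"].to_numpy(), g["lon"].to_numpy()
            t = g["timestamp"].astype("int64").to_numpy() / 1e9
            dd = haversine_miles(lats[:-1], lons[:-1], lats[1:], lons[1:])
            hh = np.maximum(np.diff(t) / 3600.0, 1e-9)
            if np.all(dd / hh <= SPEED_LIMIT_MPH):   # fast path: clean track
                parts.append(g)
                continue
            keep = np.ones(len(g), dtype=bool)
            last = 0  # speed measured against the last kept fix
            for i in range(1, len(g)):
                d = float(haversine_miles(lats[last], lons[last], lats[i], lons[i]))
                hours = max((t[i] - t[last]) / 3600.0, 1e-9)
                if d / hours > SPEED_LIMIT_MPH:
                    keep[i] = False
                else:
                    last = i
            g = g[keep]
        parts.append(g)
    return pd.concat(parts).reset_index(drop=True) if parts else fixes


def pair_gps(periods: pd.DataFrame, fixes: pd.DataFrame, responses: pd.DataFrame,
             fix_qc=default_fix_qc) -> tuple[pd.DataFrame, dict]:
    """Attach in-window GPS fixes to each period and drop unmatched periods.

    Dropped: periods whose questionnaire reports the phone neither carried
    nor left in the participant's general location, and periods with zero
    fixes inside [on_time, off_time].  Returns ``(periods_with_fixes,
    fix_map)`` where ``fix_map[wristband_id]`` is that period's fix table.
    """
    if fix_qc is not None:
        fixes = fix_qc(fixes)
    resp = responses.set_index(["participant_id", "date"])

    kept_rows, fix_map = [], {}
    for _, p in periods.iterrows():
        key = (p["participant_id"], p["on_time"].date())
        if key in resp.index:
            r = resp.loc[key]
            if isinstance(r, pd.DataFrame):
                r = r.iloc[0]
            if not bool(r["carried_phone"]) and r["no_carry_reason"] != "left_in_general_location":
                continue
        pf = fixes[(fixes["participant_id"] == p["participant_id"])
                   & (fixes["timestamp"] >= p["on_time"])
                   & (fixes["timestamp"] <= p["off_time"])]
        if pf.empty:
            continue
        kept_rows.append(p)
        fix_map[p["wristband_id"]] = pf.sort_values("timestamp").reset_index(drop=True)
    kept = pd.DataFrame(kept_rows).reset_index(drop=True)
    return kept, fix_map


def merge(periods: pd.DataFrame, chemistry: pd.DataFrame,
          responses: pd.DataFrame) -> pd.DataFrame:
    """Inner-join surviving periods with questionnaires and chemistry.

    One row per (wristband_id, chemical_id); interference measurements keep
    their missing flag rather than a substituted value.  Duplicate
    wristband ids are an error.
    """
    if periods["wristband_id"].duplicated().any():
        dup = periods.loc[periods["wristband_id"].duplicated(), "wristband_id"].iloc[0]
        raise ValueError(f"duplicate wristband_id {dup!r}")
    pp = periods.copy()
    pp["date"] = pp["on_time"].map(lambda t: t.date())
    merged = pp.merge(responses, on=["participant_id", "date"], how="inner")
    merged = merged.merge(chemistry, on="wristband_id", how="inner")
    return merged.reset_index(drop=True)
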