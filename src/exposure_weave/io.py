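"""Readers and writers for the study's interchange formats.

GPS fixes travel as GPX 1.1 (one ``<trk>`` per participant) or CSV with
columns (participant_id, timestamp, lat, lon); monitors as CSV in a daily
AQI dialect with columns (monitor_id, latitude, longitude, date, aqi);
smoke polygons as a GeoJSON FeatureCollection in CRS84 lon/lat order with
"date" (ISO-8601) and "density" ({light, medium, heavy}) properties;
periods, questionnaires and chemistry as plain CSV.  Timestamps are written
in ISO-8601 with offsets and read back timezone-aware.
"""
from __future__ import annotations

import datetime as dt
import json
import xml.etree.ElementTree as ET
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape

from .synthetic import TIMEZONE

GPX_NS = "http://www.topografix.com/GPX/1/1"

_PERIOD_TIME_COLS = ("on_time", "off_time")


def write_gps_csv(fixes: pd.DataFrame, path) -> None:
    out = fixes.copy()
    out["timestamp"] = out["timestamp"].map(lambda t: t.isoformat())
    out.to_csv(path, index=False)


def read_gps_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True).dt.tz_convert(TIMEZONE)
    return df


def write_gpx(fixes: pd.DataFrame, path) -> None:
    """Write fixes as GPX 1.1, one track per participant, one segment per track."""
    gpx = ET.Element("gpx", {"version": "1.1", "creator": "exposure-weave", "xmlns": GPX_NS})
    for pid, group in fixes.groupby("participant_id", sort=True):
        trk = ET.SubElement(gpx, "trk")
        ET.SubElement(trk, "name").text = str(pid)
        seg = ET.SubElement(trk, "trkseg")
        for _, row in group.sort_values("timestamp").iterrows():
            pt = ET.SubElement(seg, "trkpt", {"lat": f"{row['lat']:.7f}", "lon": f"{row['lon']:.7f}"})
            ET.SubElement(pt, "time").text = row["timestamp"].tz_convert("UTC").strftime("%Y-%m-%dT%H:%M:%SZ")
    ET.ElementTree(gpx).write(path, encoding="unicode", xml_declaration=True)


def read_gpx(path) -> pd.DataFrame:
    """Read a GPX 1.1 file into the fixes table (track name = participant id)."""
    ns = {"g": GPX_NS}
    root = ET.parse(path).getroot()
    rows = []
    for trk in root.findall("g:trk", ns):
        name_el = trk.find("g:name", ns)
        pid = name_el.text if name_el is not None else "unknown"
        for pt in trk.iterfind(".//g:trkpt", ns):
            t_el = pt.find("g:time", ns)
            if t_el is None:
                continue
            rows.append({
                "participant_id": pid,
                "timestamp": pd.Timestamp(t_el.text).tz_convert(TIMEZONE),
                "lat": float(pt.get("lat")), "lon": float(pt.get("lon")),
            })
    return pd.DataFrame(rows, columns=["participant_id", "timestamp", "lat", "lon"])


def write_monitors_csv(monitor_days: pd.DataFrame, path) -> None:
    out = monitor_days.copy()
    out["date"] = out["date"].map(lambda d: d.isoformat())
    out.to_csv(path, index=False)


def read_monitors_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"monitor_id", "latitude", "longitude", "date", "aqi"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"monitor CSV {path} is missing columns {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def write_smoke_geojson(smoke: pd.DataFrame, path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"date": row["date"].isoformat(), "density": row["density"]},
            "geometry": mapping(row["geometry"]),
        }
        for _, row in smoke.iterrows()
    ]
    collection = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": "urn:ogc:def:crs:OGC:1.3:CRS84"}},
        "features": features,
    }
    Path(path).write_text(json.dumps(collection))


def read_smoke_geojson(path) -> pd.DataFrame:
    data = json.loads(Path(path).read_text())
    rows = []
    for feat in data.get("features", []):
        props = feat.get("properties", {})
        density = props.get("density")
        if density not in ("light", "medium", "heavy"):
            raise ValueError(f"smoke feature with invalid density {density!r}")
        rows.append({
            "date": dt.date.fromisoformat(props["date"]),
            "density": density,
            "geometry": shape(feat["geometry"]),
        })
    return pd.DataFrame(rows, columns=["date", "density", "geometry"])


def write_periods_csv(periods: pd.DataFrame, path) -> None:
    out = periods.copy()
    for col in _PERIOD_TIME_COLS:
        out[col] = out[col].map(lambda t: t.isoformat() if pd.notna(t) else "")
    out.to_csv(path, index=False)


def read_periods_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in _PERIOD_TIME_COLS:
        try:
            df[col] = pd.to_datetime(df[col], utc=True, format="ISO8601").dt.tz_convert(TIMEZONE)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed timestamps in column {col} of {path}: {exc}") from exc
    return df


def write_questionnaires_csv(responses: pd.DataFrame, path) -> None:
    out = responses.copy()
    out["answered_at"] = out["answered_at"].map(lambda t: t.isoformat() if pd.notna(t) else "")
    out["date"] = out["date"].map(lambda d: d.isoformat())
    out.to_csv(path, index=False)


def read_questionnaires_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["answered_at"] = pd.to_datetime(df["answered_at"], utc=True, format="ISO8601").dt.tz_convert(TIMEZONE)
    df["date"] = pd.to_datetime(df["date"]).dt.date
    df["no_carry_reason"] = df["no_carry_reason"].where(df["no_carry_reason"].notna(), None)
    return df


def write_features_csv(features: pd.DataFrame, path) -> None:
    """Feature table as CSV; floats at 17 significant digits so a read-back
    reproduces every value bit-exactly."""
    features.to_csv(path, index=False, float_format="%.17g")


def read_features_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("distance_category", "time_indoors"):
        if col in df.columns:
            df[col] = df[col].astype("category")
    return df


def write_chemistry_csv(measurements: pd.DataFrame, path) -> None:
    measurements.to_csv(path, index=False)


def read_chemistry_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["nondetect"] = df["nondetect"].astype(bool)
    df["interference"] = df["interference"].astype(bool)
    return df


def read_chemical_info_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"chemical_id", "name", "molecular_weight"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"chemical info CSV missing columns {sorted(missing)}")
    return df
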