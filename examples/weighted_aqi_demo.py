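"""Time-weighted PM2.5 AQI for one wristband sampling period.

A participant spends the morning near a clean monitor and the afternoon
near a smoky one; the period's AQI is the wear-time-weighted average of
the nearest monitor's daily value.
"""
import pandas as pd

import exposure_weave as ew
from exposure_weave.synthetic import TIMEZONE

day = pd.Timestamp("2017-08-14").date()
monitors = pd.DataFrame([
    {"monitor_id": "clean", "latitude": 45.0, "longitude": -123.0, "date": day, "aqi": 30.0},
    {"monitor_id": "smoky", "latitude": 45.6, "longitude": -123.0, "date": day, "aqi": 160.0},
])

on = pd.Timestamp("2017-08-14 08:00", tz=TIMEZONE)
off = on + pd.Timedelta(hours=12)
fixes = pd.DataFrame({
    "participant_id": "P00",
    # 8:00-17:00 near the clean monitor (9 h), 17:00-20:00 near the smoky one (3 h)
    "timestamp": [on, on + pd.Timedelta(hours=9)],
    "lat": [45.0, 45.6], "lon": [-123.0, -123.0],
})

waqi = ew.weighted_aqi(fixes, on, off, monitors)
print(f"time-weighted AQI = {waqi:.1f}")
print("check: 0.75*30 + 0.25*160 =", 0.75 * 30 + 0.25 * 160)
# The value sits between the two monitors' readings, weighted by the share
# of wear time the participant was closest to each monitor.
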