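"""Censoring-aware tertile outcome for a heavily left-censored chemical.

Half the observations sit below the limit of detection (LOD).  With
X = 50% nondetect, every nondetect becomes Low and the detects split
Medium/High at the [X + (100 - X)/2] = 75th percentile of all
observations.
"""
import numpy as np

import exposure_weave as ew

rng = np.random.default_rng(0)
n = 40
nondetect = np.zeros(n, bool)
nondetect[:20] = True                       # 50% below LOD
values = np.where(nondetect, np.nan, rng.normal(12.0, 2.0, n))  # log2 pmol/g

thresholds, categories = ew.build_tertiles(values, nondetect)
counts = {c: int((categories == c).sum()) for c in ("Low", "Medium", "High")}

print(f"censoring branch     : {thresholds['branch']}")
print(f"percent below LOD    : {thresholds['x_percent']:.1f}%")
print(f"split percentile     : {thresholds['split_percentile']:.1f}")
print(f"Medium/High threshold: {thresholds['medium_high']:.2f} log2 pmol/g")
print(f"category sizes       : {counts}")
# All 20 nondetects are Low; the 20 detects split 10/10 around the 75th
# percentile, keeping the largest:smallest class ratio at 2:1.
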