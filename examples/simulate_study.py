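"""Generate a complete synthetic exposure study and run the QC filters.

Builds three seasons of wristband sampling periods for 35 participants,
GPS trajectories at a 5-minute cadence, monitor AQI series, smoke
polygons and evening questionnaires, then applies the inclusion rules.
"""
import exposure_weave as ew

config = ew.default_config(seed=7, n_participants=10, days_per_season=4)
periods = ew.generate_periods(config)
fixes = ew.generate_trajectories(config)
questionnaires = ew.generate_questionnaires(config, periods)

kept, exclusion_log = ew.filter_wristbands(periods)
responses = ew.filter_questionnaires(questionnaires)
paired, fix_map = ew.pair_gps(kept, fixes, responses)

print(f"sampling periods generated : {len(periods)}")
print(f"periods passing wristband QC: {len(kept)}")
print("exclusions by reason        :", exclusion_log["reason"].value_counts().to_dict())
print(f"questionnaires in window    : {len(responses)} / {len(questionnaires)}")
print(f"periods with paired GPS     : {len(paired)}")
# Each surviving period carries its in-window fixes; everything downstream
# (weighted AQI, smoke proportions, distance) is computed from fix_map.
wid = paired["wristband_id"].iloc[0]
print(f"example period {wid}: {len(fix_map[wid])} fixes attached")
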