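"""End-to-end orchestration: simulate -> ingest -> features -> chemistry ->
univariate stats -> model comparison -> report.

Every stage is a pure function of (inputs, config, seed); the run writes a
JSON manifest with per-stage row counts, exclusion tallies and seeds so a
rerun with the same seed reproduces identical bookkeeping.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemistry as chem_mod
from . import features as feat_mod
from . import ingest, io, models, stats, synthetic

logger = logging.getLogger("exposure_weave")


@dataclass
class PipelineConfig:
    out_dir: str = "results"
    seed: int = 0
    folds: int = 10
    reps: int = 100
    alpha: float = 0.05
    distance_cutpoints: str = "empirical"    # "empirical" | "pinned"
    n_effective: str = "records"             # "records" | explicit int via n_effective_value
    n_effective_value: int | None = None
    simulate: bool = True
    max_model_chemicals: int | None = None   # cap the modelling stage for quick runs
    # input paths (used when simulate=False)
    gps_path: str | None = None
    periods_path: str | None = None
    questionnaires_path: str | None = None
    monitors_path: str | None = None
    smoke_path: str | None = None
    chemistry_path: str | None = None
    chem_info_path: str | None = None
    sim_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.folds < 2 or self.reps < 1:
            raise ValueError("need folds >= 2 and reps >= 1")


def _load_inputs(config: PipelineConfig):
    for name in ("gps_path", "periods_path", "questionnaires_path",
                 "monitors_path", "smoke_path", "chemistry_path", "chem_info_path"):
        path = getattr(config, name)
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"missing input for {name}: {path}")
    gps = (io.read_gpx(config.gps_path) if str(config.gps_path).endswith(".gpx")
           else io.read_gps_csv(config.gps_path))
    return {
        "fixes": gps,
        "periods": io.read_periods_csv(config.periods_path),
        "questionnaires": io.read_questionnaires_csv(config.questionnaires_path),
        "monitors": io.read_monitors_csv(config.monitors_path),
        "smoke": io.read_smoke_geojson(config.smoke_path),
        "chemistry": io.read_chemistry_csv(config.chemistry_path),
        "chem_info": io.read_chemical_info_csv(config.chem_info_path),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": {}}

    # ---- stage: simulate or load -----------------------------------------
    if config.simulate:
        sim = synthetic.default_config(seed=config.seed, **config.sim_overrides)
        periods = synthetic.generate_periods(sim)
        fixes = synthetic.generate_trajectories(sim)
        questionnaires = synthetic.generate_questionnaires(sim, periods)
        monitors = synthetic.generate_monitors(sim)
        smoke = synthetic.generate_smoke(sim)
        chem_info = synthetic.chemical_info(sim)
        measurements = None      # generated after features exist
        stage_name = "simulate"
    else:
        data = _load_inputs(config)
        periods, fixes = data["periods"], data["fixes"]
        questionnaires, monitors = data["questionnaires"], data["monitors"]
        smoke, measurements, chem_info = data["smoke"], data["chemistry"], data["chem_info"]
        sim = None
        stage_name = "load"
    manifest["stages"][stage_name] = {
        "periods": len(periods), "fixes": len(fixes),
        "questionnaires": len(questionnaires), "monitor_days": len(monitors),
        "smoke_polygons": len(smoke),
    }
    logger.info("%s: %s", stage_name, manifest["stages"][stage_name])

    # ---- stage: ingest / QC ----------------------------------------------
    kept, exclusion_log = ingest.filter_wristbands(periods)
    responses = ingest.filter_questionnaires(questionnaires)
    paired, fix_map = ingest.pair_gps(kept, fixes, responses)
    manifest["stages"]["ingest"] = {
        "periods_in": len(periods), "periods_kept": len(paired),
        "wristband_exclusions": exclusion_log["reason"].value_counts().to_dict(),
        "questionnaires_kept": len(responses),
    }
    exclusion_log.to_csv(out / "exclusion_log.csv", index=False)

    # ---- stage: features --------------------------------------------------
    monitor_days = feat_mod.daily_average_monitors(monitors)
    cutpoints = feat_mod.PINNED_DISTANCE_CUTPOINTS if config.distance_cutpoints == "pinned" else None
    features = feat_mod.build_features(paired, fix_map, responses, monitor_days, smoke,
                                       distance_cutpoints=cutpoints)
    io.write_features_csv(features, out / "features.csv")
    manifest["stages"]["features"] = {"rows": len(features)}

    # ---- stage: chemistry -------------------------------------------------
    if config.simulate:
        measurements, truth = synthetic.generate_chemistry(sim, features)
        io.write_chemistry_csv(measurements, out / "chemistry.csv")
    measurements = measurements[measurements["wristband_id"].isin(features["wristband_id"])]
    merged = ingest.merge(paired, measurements, responses)
    seasons = features.set_index("wristband_id")["season"]
    elig = chem_mod.eligibility(measurements, seasons)
    tertiles = chem_mod.tertile_table(measurements, chem_info)
    tertiles.to_csv(out / "tertiles.csv", index=False)
    manifest["stages"]["chemistry"] = {
        "analysis_records": int(merged["wristband_id"].nunique()),
        "chemicals": int(elig.shape[0]),
        "ml_eligible": int(elig["correlation_and_ml"].sum()),
        "detection_eligible": int(elig["detection_test"].sum()),
    }

    # ---- stage: univariate stats ------------------------------------------
    mw = chem_info.set_index("chemical_id")["molecular_weight"]
    feats_idx = features.set_index("wristband_id")
    stat_rows = []
    for chem_id in elig.loc[elig["detection_test"], "chemical_id"]:
        grp = measurements[measurements["chemical_id"] == chem_id]
        grp = grp[~grp["interference"] & grp["wristband_id"].isin(feats_idx.index)]
        det = (~grp["nondetect"]).astype(float)
        season = grp["wristband_id"].map(feats_idx["season"])
        pid = grp["wristband_id"].map(feats_idx["participant_id"])
        try:
            stat_rows.append(stats.detection_mixed_model(det, season, pid, variable=chem_id))
        except ValueError as exc:
            logger.warning("detection model skipped for %s: %s", chem_id, exc)
    behaviour = stats.seasonal_behavior_tests(
        features["distance_traveled_mi"], features["weighted_aqi"],
        features["hms_index"], features["season"])
    stat_rows.append(behaviour)
    contrasts = pd.concat(stat_rows, ignore_index=True) if stat_rows else pd.DataFrame()
    contrasts.to_csv(out / "univariate_contrasts.csv", index=False)

    ml_ids = list(elig.loc[elig["correlation_and_ml"], "chemical_id"])
    wide = {}
    nd_wide = {}
    for chem_id in ml_ids:
        grp = measurements[measurements["chemical_id"] == chem_id].set_index("wristband_id")
        grp = grp.reindex(features["wristband_id"])
        vals = np.full(len(grp), np.nan)
        det_mask = (~grp["nondetect"].fillna(True) & ~grp["interference"].fillna(True)).to_numpy()
        vals[det_mask] = chem_mod.to_log2_pmol_per_g(
            grp.loc[det_mask, "raw_conc"].to_numpy(), float(mw[chem_id]))
        wide[chem_id] = vals
        nd_wide[chem_id] = grp["nondetect"].fillna(True).to_numpy()
    spearman = stats.spearman_matrix(features["weighted_aqi"], features["hms_index"],
                                     pd.DataFrame(wide), pd.DataFrame(nd_wide))
    spearman.to_csv(out / "spearman.csv", index=False)
    manifest["stages"]["stats"] = {"contrast_rows": len(contrasts),
                                   "spearman_rows": len(spearman)}

    # ---- stage: model comparison ------------------------------------------
    model_ids = ml_ids[:config.max_model_chemicals] if config.max_model_chemicals else ml_ids
    tert_idx = tertiles.set_index(["chemical_id", "wristband_id"])["category"]
    n_eff_cfg = config.n_effective_value if config.n_effective == "explicit" else None
    summary = {}
    for chem_id in model_ids:
        cats = tert_idx.loc[chem_id].reindex(features["wristband_id"])
        mask = cats.notna().to_numpy()
        sub_feats = features[mask].reset_index(drop=True)
        sub_out = pd.Categorical(cats[mask], categories=["Low", "Medium", "High"], ordered=True)
        res = models.run_model_comparison(sub_feats, sub_out, chemical_id=chem_id,
                                          folds=config.folds, reps=config.reps,
                                          seed=config.seed, n_effective=n_eff_cfg)
        summary[chem_id] = {
            "chosen_model": res["selection"].chosen,
            "selection_p": res["selection"].p_value,
            "mean_accuracy": {k: v.mean_accuracy for k, v in res["results"].items()},
            "ci": res["ci"],
            "importances": (models.scaled_importance(res["multivariate"])
                            .set_index("feature")["importance"].to_dict()
                            if res["multivariate"].importances else None),
        }
    (out / "model_summary.json").write_text(json.dumps(summary, indent=2))
    manifest["stages"]["model"] = {"chemicals_modeled": len(summary)}

    # ---- stage: report ----------------------------------------------------
    if summary:
        try:
            report_accuracy_chart(summary, out / "model_accuracy.png")
            report_importance_heatmap(summary, out / "importance_heatmap.png")
            manifest["stages"]["report"] = {"figures": 2}
        except Exception as exc:  # plotting must never sink a run
            logger.warning("report stage failed: %s", exc)
            manifest["stages"]["report"] = {"figures": 0}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def report_accuracy_chart(summary: dict, path) -> None:
    """Dot-and-interval chart of per-chemical model accuracies."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chems = sorted(summary, key=lambda c: -max(summary[c]["mean_accuracy"].values()))
    fig, ax = plt.subplots(figsize=(7, max(3, 0.35 * len(chems))))
    colors = {"AQI_only": "tab:orange", "HMS_only": "tab:green",
              "Standard": "tab:blue", "Interaction": "tab:purple"}
    for i, c in enumerate(chems):
        for name, acc in summary[c]["mean_accuracy"].items():
            ax.plot(acc, i, "o", color=colors.get(name, "k"),
                    label=name if i == 0 else None, ms=4)
        lo, hi = summary[c]["ci"]
        ax.plot([lo, hi], [i, i], "-", color="gray", lw=1)
    ax.axvline(1 / 3, ls=":", color="k", label="random (1/3)")
    ax.set_yticks(range(len(chems)), chems)
    ax.set_xlabel("mean CV accuracy")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def report_importance_heatmap(summary: dict, path) -> None:
    """Heat map of scaled variable importances for the chosen models."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = {c: s["importances"] for c, s in summary.items() if s.get("importances")}
    if not rows:
        return
    table = pd.DataFrame(rows).T.fillna(0.0)
    fig, ax = plt.subplots(figsize=(0.6 * len(table.columns) + 2, 0.35 * len(table) + 2))
    im = ax.imshow(table.to_numpy(), aspect="auto", cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks(range(len(table.columns)), table.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(table)), table.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="scaled importance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
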