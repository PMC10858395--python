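"""Concentration-scale conversion and censoring-aware tertile outcomes.

Wristband concentrations arrive in ng chemical per g wristband and are
analysed as log2 pmol/g:  log2(ng_per_g / MW * 1000).  For each chemical the
Low/Medium/High outcome is built with explicit handling of left-censoring:
with X = percent of observations below the LOD,

* X <= 33.33:  thresholds at the empirical 33.33rd and 66.67th percentiles
  of all observations (nondetects ranking below every detect);
* X  > 33.33:  every nondetect is Low and detects split Medium/High at the
  [X + (100 - X)/2]th percentile of all observations.

Matrix-interference observations are excluded throughout (missing, not
zero) and never enter X's denominator.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

TERTILE_LABELS = ("Low", "Medium", "High")


def load_packaged_chemical_info() -> pd.DataFrame:
    """Representative chemical panel shipped with the package.

    Synthetic fixture: names, classes and molecular weights describe real
    PAH/OPAH/alkane/VOC analytes, but the LOD/LOQ columns are invented
    representative values, not any laboratory's reported limits.
    """
    from importlib.resources import files

    path = files("exposure_weave").joinpath("data/chemical_info_synthetic.csv")
    with path.open() as fh:
        return pd.read_csv(fh)


CENSOR_BRANCH_CUTOFF = 100.0 / 3.0   # percent nondetect at/below which both percentile thresholds are used


def to_log2_pmol_per_g(raw_conc, molecular_weight):
    """Convert ng/g wristband to log2 pmol/g wristband.

    log2(raw_conc / MW * 1000); strictly increasing in ``raw_conc``.
    Accepts scalars or arrays; nonpositive concentrations or weights are an
    error (censored values have no numeric concentration and must not be
    passed here).
    """
    raw = np.asarray(raw_conc, dtype=float)
    mw = np.asarray(molecular_weight, dtype=float)
    if np.any(raw <= 0) or np.any(mw <= 0):
        raise ValueError("raw concentration and molecular weight must be positive")
    result = np.log2(raw / mw * 1000.0)
    return float(result) if result.ndim == 0 else result


def build_tertiles(values, nondetect, interference=None):
    """Censoring-aware Low/Medium/High categories for one chemical.

    ``values`` are log2 pmol/g (NaN where censored or interfering),
    ``nondetect`` and ``interference`` boolean masks.  Returns
    ``(thresholds, categories)`` where ``categories`` is an ordered
    pandas.Categorical aligned with the input (NaN category for
    interference rows) and ``thresholds`` is a dict with the split values
    and the branch taken.  Ties at a threshold go to the lower category.
    """
    values = np.asarray(values, dtype=float)
    nondetect = np.asarray(nondetect, dtype=bool)
    interference = (np.zeros(len(values), dtype=bool) if interference is None
                    else np.asarray(interference, dtype=bool))
    obs = ~interference
    n_obs = int(obs.sum())
    if n_obs == 0:
        raise ValueError("all observations are matrix interference")
    if n_obs < 3:
        raise ValueError("need at least three non-interference observations")

    nd = nondetect & obs
    x_pct = 100.0 * nd.sum() / n_obs

    detect_vals = values[obs & ~nd]
    # sentinel ranks nondetects below every detect; categories are invariant
    # to its exact value, thresholds are reported with this convention
    sentinel = (np.nanmin(detect_vals) if detect_vals.size else 0.0) - 1.0
    combined = np.where(nd[obs], sentinel, values[obs])

    codes = np.full(len(values), -1, dtype=int)
    if x_pct <= CENSOR_BRANCH_CUTOFF + 1e-9:
        t1, t2 = np.quantile(combined, [1.0 / 3.0, 2.0 / 3.0])
        c = np.where(combined <= t1, 0, np.where(combined <= t2, 1, 2))
        thresholds = {"branch": "percentile", "x_percent": x_pct, "low_medium": float(t1),
                      "medium_high": float(t2)}
    else:
        split_pct = x_pct + (100.0 - x_pct) / 2.0
        t2 = np.quantile(combined, split_pct / 100.0)
        c = np.where(nd[obs], 0, np.where(combined <= t2, 1, 2))
        thresholds = {"branch": "censored", "x_percent": x_pct,
                      "split_percentile": split_pct, "medium_high": float(t2)}
    codes[np.flatnonzero(obs)] = c
    categories = pd.Categorical.from_codes(codes, categories=list(TERTILE_LABELS), ordered=True)
    return thresholds, categories


def tertile_table(measurements: pd.DataFrame, chem_info: pd.DataFrame) -> pd.DataFrame:
    """Per-chemical tertile outcomes for a full measurement table.

    Expects the ChemicalMeasurement columns (wristband_id, chemical_id,
    raw_conc, nondetect, interference); returns rows (wristband_id,
    chemical_id, category) for non-interference observations.
    """
    mw = chem_info.set_index("chemical_id")["molecular_weight"]
    out = []
    for chem_id, grp in measurements.groupby("chemical_id", sort=True):
        vals = np.full(len(grp), np.nan)
        detected = (~grp["nondetect"] & ~grp["interference"]).to_numpy()
        vals[detected] = to_log2_pmol_per_g(grp.loc[detected, "raw_conc"].to_numpy(), float(mw[chem_id]))
        _, cats = build_tertiles(vals, grp["nondetect"].to_numpy(), grp["interference"].to_numpy())
        keep = ~grp["interference"].to_numpy()
        out.append(pd.DataFrame({
            "wristband_id": grp["wristband_id"].to_numpy()[keep],
            "chemical_id": chem_id,
            "category": cats[keep],
        }))
    return pd.concat(out, ignore_index=True)


def eligibility(measurements: pd.DataFrame, seasons: pd.Series) -> pd.DataFrame:
    """Analysis-eligibility flags per chemical.

    * ``detection_test``:  detected above LOD in >= 3 wristbands in at least
      one season;
    * ``concentration_test``:  >= 2 seasons each with >= 2 values above LOD;
    * ``correlation_and_ml``:  <= 50% of (non-interference) observations
      below LOD, which also bounds the tertile class-size ratio at 2:1.

    ``seasons`` maps wristband_id -> season label.
    """
    m = measurements.merge(seasons.rename("season"), left_on="wristband_id", right_index=True)
    rows = []
    for chem_id, grp in m.groupby("chemical_id", sort=True):
        obs = grp[~grp["interference"]]
        detected = obs[~obs["nondetect"]]
        per_season = detected.groupby("season").size()
        detection_test = bool((per_season >= 3).any())
        concentration_test = int((per_season >= 2).sum()) >= 2
        frac_nd = obs["nondetect"].mean() if len(obs) else 1.0
        rows.append({
            "chemical_id": chem_id,
            "detection_test": detection_test,
            "concentration_test": concentration_test,
            "correlation_and_ml": bool(frac_nd <= 0.5),
        })
    return pd.DataFrame(rows)
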