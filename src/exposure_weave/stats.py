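"""Univariate and correlative analyses.

Seasonal differences in chemical detection are tested with a logistic
mixed model (participant random intercept) fitted by Gauss-Hermite
quadrature maximum likelihood; seasonal concentration differences (above
the LOD) with a Gaussian mixed model (statsmodels MixedLM).  Season
contrasts use a Tukey (studentized-range) multiplicity adjustment.
Behavioural/environmental comparisons follow the variable's scale:
ANOVA + Tukey HSD on log distance, pairwise Welch t-tests + Holm on
weighted AQI, pairwise Wilcoxon rank-sum + Holm on the HMS Index.
Shared information between variables is summarised by Spearman rank
correlation.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.numdiff import approx_hess1

LOG_DISTANCE_OFFSET_MI = 0.1   # admits zero-travel days
SEASON_PAIRS = lambda labels: list(itertools.combinations(sorted(labels), 2))  # noqa: E731
_TUKEY_DF = 1e6   # normal-approximation studentized range


def _tukey_p(t_stat: float, k: int, df: float = _TUKEY_DF) -> float:
    return float(sps.studentized_range.sf(abs(t_stat) * np.sqrt(2.0), k, df))


# --------------------------------------------------------------------------
# logistic mixed model (random intercept) via Gauss-Hermite quadrature
# --------------------------------------------------------------------------

@dataclass
class LogisticRandomInterceptFit:
    params: np.ndarray          # fixed effects
    cov: np.ndarray             # fixed-effect covariance block
    sigma: float                # random-intercept SD
    converged: bool
    loglike: float
    exog_names: list


def fit_logistic_random_intercept(y, X, groups, exog_names=None, n_quad=25,
                                  grad_tol=1e-4) -> LogisticRandomInterceptFit:
    """ML fit of logit P(y=1) = X b + u_group, u ~ N(0, sigma^2).

    The marginal likelihood integrates the random intercept with
    ``n_quad``-node Gauss-Hermite quadrature; convergence requires a small
    projected gradient and a positive-definite observed information.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    codes, _ = pd.factorize(np.asarray(groups))
    n_groups = codes.max() + 1
    # probabilists' Hermite: int f(b) phi(b) db ~= sum_k [w_k / sqrt(2pi)] f(z_k)
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    log_w = np.log(weights) - 0.5 * np.log(2.0 * np.pi)

    def negll(theta):
        beta, log_sigma = theta[:-1], theta[-1]
        sigma = np.exp(log_sigma)
        eta0 = X @ beta
        total = 0.0
        for g in range(n_groups):
            m = codes == g
            eta = eta0[m][:, None] + sigma * nodes[None, :]
            ll = np.sum(y[m][:, None] * eta - np.logaddexp(0.0, eta), axis=0)
            total += _lse(ll + log_w)
        return -total

    p = X.shape[1]
    theta0 = np.zeros(p + 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(negll, theta0, method="BFGS",
                                options={"gtol": grad_tol, "maxiter": 500})
        hess = approx_hess1(res.x, negll)
    converged = bool(res.success or np.linalg.norm(res.jac, np.inf) < 10 * grad_tol)
    try:
        cov_all = np.linalg.inv(hess)
        converged = converged and bool(np.all(np.linalg.eigvalsh(hess) > 0))
    except np.linalg.LinAlgError:
        cov_all = np.full((p + 1, p + 1), np.nan)
        converged = False
    return LogisticRandomInterceptFit(
        params=res.x[:p], cov=cov_all[:p, :p], sigma=float(np.exp(res.x[-1])),
        converged=converged, loglike=-res.fun,
        exog_names=list(exog_names) if exog_names is not None else [f"x{i}" for i in range(p)],
    )


def _lse(v):
    m = np.max(v)
    return m + np.log(np.sum(np.exp(v - m)))


# --------------------------------------------------------------------------
# mixed-model contrast machinery
# --------------------------------------------------------------------------

def _season_design(seasons: pd.Series):
    levels = sorted(pd.unique(seasons))
    if len(levels) < 2:
        raise ValueError("need at least two seasons to estimate a contrast")
    X = np.column_stack([np.ones(len(seasons))]
                        + [(seasons == lvl).to_numpy(float) for lvl in levels[1:]])
    names = ["intercept"] + [f"season[{lvl}]" for lvl in levels[1:]]
    return X, names, levels


def _season_contrasts(levels):
    """Contrast vectors over (intercept, season[l2], season[l3], ...) coefficients."""
    k = len(levels)
    coef_of = {lvl: i for i, lvl in enumerate(levels[1:], start=1)}
    out = []
    for a, b in itertools.combinations(levels, 2):
        c = np.zeros(k)
        if a in coef_of:
            c[coef_of[a]] += 1.0
        if b in coef_of:
            c[coef_of[b]] -= 1.0
        out.append((f"{a} vs {b}", c))
    return out


def _contrast_rows(variable, params, cov, levels, k_family, method_label, converged):
    rows = []
    for label, c in _season_contrasts(levels):
        est = float(c @ params)
        var = float(c @ cov @ c)
        se = float(np.sqrt(var)) if var > 0 else np.nan
        t = est / se if se > 0 else np.nan
        p = 2.0 * sps.norm.sf(abs(t)) if np.isfinite(t) else np.nan
        rows.append({
            "variable": variable, "comparison": label, "estimate": est, "se": se,
            "p_value": p,
            "p_adjusted": min(_tukey_p(t, k_family), 1.0) if np.isfinite(t) else np.nan,
            "method": method_label, "converged": converged,
        })
    return rows


def detection_mixed_model(detect, fixed, participant, variable="chemical",
                          fixed_name="season") -> pd.DataFrame:
    """Seasonal / AQI / HMS effects on detection probability.

    ``fixed`` is either a Series of season labels (all pairwise contrasts,
    Tukey-adjusted) or a numeric exposure (slope direction + Wald p).
    Returns a tidy contrast table; non-convergent fits are flagged.
    """
    detect = pd.Series(detect).astype(float)
    participant = pd.Series(participant)
    fixed = pd.Series(fixed)
    if fixed.dtype == object or isinstance(fixed.dtype, pd.CategoricalDtype):
        X, names, levels = _season_design(fixed)
        fit = fit_logistic_random_intercept(detect, X, participant, exog_names=names)
        rows = _contrast_rows(variable, fit.params, fit.cov, levels, len(levels),
                              "logistic-mixed/Tukey", fit.converged)
    else:
        X = np.column_stack([np.ones(len(fixed)), fixed.to_numpy(float)])
        fit = fit_logistic_random_intercept(detect, X, participant,
                                            exog_names=["intercept", fixed_name])
        est = float(fit.params[1])
        se = float(np.sqrt(fit.cov[1, 1]))
        p = 2.0 * sps.norm.sf(abs(est / se)) if se > 0 else np.nan
        rows = [{"variable": variable, "comparison": f"slope[{fixed_name}]",
                 "estimate": est, "se": se, "p_value": p, "p_adjusted": p,
                 "method": "logistic-mixed/Wald", "converged": fit.converged}]
    return pd.DataFrame(rows)


def concentration_mixed_model(log2_values, seasons, participant,
                              variable="chemical") -> pd.DataFrame:
    """Seasonal contrasts of mean log2 concentration among detects.

    Gaussian mixed model with participant random intercept (REML via
    statsmodels MixedLM); all pairwise season contrasts, Tukey-adjusted.
    """
    import statsmodels.api as sm

    vals = np.asarray(log2_values, dtype=float)
    seasons = pd.Series(seasons).reset_index(drop=True)
    participant = pd.Series(participant).reset_index(drop=True)
    X, names, levels = _season_design(seasons)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(vals, X, groups=participant)
        fit = model.fit(reml=True)
    converged = bool(getattr(fit, "converged", True))
    params = np.asarray(fit.fe_params)
    cov = np.asarray(fit.cov_params())[:len(params), :len(params)]
    return pd.DataFrame(_contrast_rows(variable, params, cov, levels, len(levels),
                                       "gaussian-mixed/Tukey", converged))


# --------------------------------------------------------------------------
# seasonal behaviour / environment comparisons
# --------------------------------------------------------------------------

def seasonal_behavior_tests(distances, weighted_aqi, hms_index, seasons) -> pd.DataFrame:
    """Seasonal comparisons of travel distance, weighted AQI and HMS Index.

    Distance: one-way ANOVA on log(d + 0.1 mi) with Tukey HSD pairwise;
    AQI: pairwise Welch t-tests with Holm adjustment; HMS: pairwise
    Wilcoxon rank-sum with Holm adjustment.  Seasons with fewer than two
    observations are skipped with a warning.
    """
    seasons = pd.Series(seasons).reset_index(drop=True)
    frame = pd.DataFrame({
        "distance": np.log(np.asarray(distances, dtype=float) + LOG_DISTANCE_OFFSET_MI),
        "aqi": np.asarray(weighted_aqi, dtype=float),
        "hms": np.asarray(hms_index, dtype=float),
        "season": seasons,
    })
    counts = frame.groupby("season").size()
    usable = sorted(counts[counts >= 2].index)
    skipped = sorted(set(counts.index) - set(usable))
    if skipped:
        warnings.warn(f"seasons skipped with <2 observations: {skipped}")
    rows = []

    groups = {s: frame[frame["season"] == s] for s in usable}
    if len(usable) >= 2:
        if frame["distance"].nunique() == 1:   # zero variance: nothing to test
            pvals = np.ones((len(usable), len(usable)))
        else:
            pvals = sps.tukey_hsd(*[groups[s]["distance"].to_numpy() for s in usable]).pvalue
        for i, j in itertools.combinations(range(len(usable)), 2):
            rows.append({
                "variable": "distance_traveled", "comparison": f"{usable[i]} vs {usable[j]}",
                "estimate": float(groups[usable[i]]["distance"].mean()
                                  - groups[usable[j]]["distance"].mean()),
                "p_value": float(pvals[i, j]), "p_adjusted": float(pvals[i, j]),
                "method": "anova-log/TukeyHSD", "converged": True,
            })

        welch, wilcox = [], []
        for a, b in itertools.combinations(usable, 2):
            t = sps.ttest_ind(groups[a]["aqi"], groups[b]["aqi"], equal_var=False)
            welch.append(("weighted_aqi", f"{a} vs {b}",
                          float(groups[a]["aqi"].mean() - groups[b]["aqi"].mean()),
                          float(t.pvalue), "welch-t/Holm"))
            if groups[a]["hms"].nunique() == 1 and groups[b]["hms"].nunique() == 1 \
                    and groups[a]["hms"].iloc[0] == groups[b]["hms"].iloc[0]:
                pw = 1.0
            else:
                pw = float(sps.mannwhitneyu(groups[a]["hms"], groups[b]["hms"],
                                            alternative="two-sided").pvalue)
            wilcox.append(("hms_index", f"{a} vs {b}",
                           float(groups[a]["hms"].median() - groups[b]["hms"].median()),
                           pw, "wilcoxon/Holm"))
        for batch in (welch, wilcox):
            raw_p = [r[3] for r in batch]
            adj = multipletests(raw_p, method="holm")[1]
            for (var, comp, est, p, method), pa in zip(batch, adj):
                rows.append({"variable": var, "comparison": comp, "estimate": est,
                             "p_value": p, "p_adjusted": float(pa), "method": method,
                             "converged": True})
    return pd.DataFrame(rows, columns=["variable", "comparison", "estimate",
                                       "p_value", "p_adjusted", "method", "converged"])


# --------------------------------------------------------------------------
# Spearman correlations
# --------------------------------------------------------------------------

def spearman_matrix(weighted_aqi, hms_index, chemical_log2: pd.DataFrame | None = None,
                    nondetect: pd.DataFrame | None = None) -> pd.DataFrame:
    """Spearman correlations: AQI x HMS, and each chemical x {AQI, HMS}.

    ``chemical_log2`` is a wide table (rows aligned with the exposure
    vectors, one column per eligible chemical); ``nondetect`` an aligned
    boolean table — nondetect rows are excluded per chemical.  A constant
    vector yields an NaN correlation flagged ``undefined``, never silently 0.
    """
    aqi = np.asarray(weighted_aqi, dtype=float)
    hms = np.asarray(hms_index, dtype=float)
    rows = [_spearman_row("weighted_aqi", "hms_index", aqi, hms)]
    if chemical_log2 is not None:
        for chem in chemical_log2.columns:
            vals = chemical_log2[chem].to_numpy(float)
            keep = np.isfinite(vals)
            if nondetect is not None:
                keep &= ~nondetect[chem].to_numpy(bool)
            rows.append(_spearman_row(str(chem), "weighted_aqi", vals[keep], aqi[keep]))
            rows.append(_spearman_row(str(chem), "hms_index", vals[keep], hms[keep]))
    return pd.DataFrame(rows)


def _spearman_row(a_name, b_name, a, b):
    undefined = (len(a) < 2 or np.all(a == a[0]) or np.all(b == b[0]))
    if undefined:
        rho, p = np.nan, np.nan
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho, p = sps.spearmanr(a, b)
    return {"variable_a": a_name, "variable_b": b_name, "rho": float(rho) if rho == rho else np.nan,
            "p_value": p, "n": len(a), "undefined": bool(undefined)}
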