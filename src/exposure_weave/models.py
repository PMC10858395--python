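"""Predictive model comparison for per-chemical exposure tertiles.

Four models per chemical: two single-feature quadratic-discriminant
baselines (weighted AQI only; HMS Index only) and two classification
trees — a Standard tree on the eight environmental/behavioural features
and an Interaction tree that adds explicit per-season copies of AQI and
HMS.  Every model is scored by 10-fold cross-validated accuracy inside
each of ``reps`` bootstrap resamples of the records; trees are
cost-complexity pruned at the alpha minimising internal 10-fold CV error
on the resample.  The Interaction tree replaces the Standard tree as the
final "Multivariate Model" only when a one-sided two-proportion z-test
says its mean accuracy is significantly higher; variable importance is
mean Gini impurity decrease, rescaled per chemical so the top feature
equals 1.  A non-informative three-class random baseline sits at 1/3.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

STANDARD_FEATURES = ("weighted_aqi", "hms_index", "prop_light", "prop_medium",
                     "prop_heavy", "season", "distance_category", "time_indoors")
DEFAULT_ALPHA = 0.05
MIN_LEAF = 7


@dataclass(frozen=True)
class ModelSpec:
    name: str
    features: tuple
    learner: str    # "quadratic_discriminant" | "classification_tree"

    def __post_init__(self):
        if self.learner == "quadratic_discriminant" and len(self.features) != 1:
            raise ValueError(f"{self.name}: discriminant baselines take exactly one feature")


def model_specs(feature_columns) -> dict:
    """The four comparison models, with interaction columns discovered from
    the available ``aqi_<season>`` / ``hms_<season>`` feature columns."""
    interaction_cols = tuple(c for c in feature_columns
                             if c.startswith("aqi_") or c.startswith("hms_"))
    return {
        "AQI_only": ModelSpec("AQI_only", ("weighted_aqi",), "quadratic_discriminant"),
        "HMS_only": ModelSpec("HMS_only", ("hms_index",), "quadratic_discriminant"),
        "Standard": ModelSpec("Standard", STANDARD_FEATURES, "classification_tree"),
        "Interaction": ModelSpec("Interaction", STANDARD_FEATURES + interaction_cols,
                                 "classification_tree"),
    }


@dataclass
class CvResult:
    chemical_id: str
    model_name: str
    accuracies: np.ndarray
    importances: dict | None = None    # feature -> mean Gini importance (trees only)
    n_records: int = 0

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))


@dataclass
class SelectionResult:
    chemical_id: str
    chosen: str          # "Standard" | "Interaction"
    z: float
    p_value: float


# --------------------------------------------------------------------------
# design-matrix encoding
# --------------------------------------------------------------------------

def _encode(df: pd.DataFrame, features) -> tuple[np.ndarray, list]:
    """Numeric design matrix; ordered categoricals as codes, season one-hot.

    Returns (X, source_feature_per_column) so encoded columns can be folded
    back to their source feature for importance reporting.  Features are
    encoded in sorted-name order, making results invariant to the order the
    feature list was written in.
    """
    cols, sources = [], []
    for f in sorted(features):
        s = df[f]
        if f == "season":
            for lvl in sorted(s.unique()):
                cols.append((s == lvl).to_numpy(float))
                sources.append(f)
        elif isinstance(s.dtype, pd.CategoricalDtype):
            cols.append(s.cat.codes.to_numpy(float))
            sources.append(f)
        else:
            cols.append(s.to_numpy(float))
            sources.append(f)
    return np.column_stack(cols), sources


def _fit_predict_qda(X_tr, y_tr, X_te):
    """QDA with a majority-class fallback when a within-class variance is singular."""
    classes, counts = np.unique(y_tr, return_counts=True)
    degenerate = any(np.all(X_tr[y_tr == c] == X_tr[y_tr == c][0]) for c in classes)
    if not degenerate and len(classes) >= 2:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                qda = QuadraticDiscriminantAnalysis(reg_param=1e-9)
                qda.fit(X_tr, y_tr)
                return qda.predict(X_te)
        except np.linalg.LinAlgError:
            pass
    log = logging.getLogger(__name__)
    if not getattr(_fit_predict_qda, "_warned", False):
        log.warning("singular within-class variance; falling back to majority class "
                    "(further occurrences logged at DEBUG)")
        _fit_predict_qda._warned = True
    else:
        log.debug("singular within-class variance; majority-class fallback")
    return np.full(len(X_te), classes[np.argmax(counts)])


def _group_strat_folds(resample_idx, y_orig, folds, random_state):
    """Stratified folds over *original* records.

    Inside a bootstrap resample the same record can appear several times;
    assigning folds by original record keeps every copy on one side of the
    train/test split, so duplicated rows never leak across folds.
    Yields (train_positions, test_positions) into the resample.
    """
    u = np.unique(resample_idx)
    yu = y_orig[u]
    n_splits = min(folds, int(np.min(np.bincount(yu))))
    if n_splits < 2:
        raise ValueError("a fold would contain a single class even after stratification")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=random_state)
    for _, te_u in skf.split(u.reshape(-1, 1), yu):
        in_test = np.zeros(len(y_orig), dtype=bool)
        in_test[u[te_u]] = True
        te_pos = np.flatnonzero(in_test[resample_idx])
        tr_pos = np.flatnonzero(~in_test[resample_idx])
        yield tr_pos, te_pos


def _select_alpha(X, y, resample_idx, y_orig, rng, folds=10, max_alphas=8):
    """Cost-complexity alpha minimising internal (group-aware) CV error."""
    base = DecisionTreeClassifier(min_samples_leaf=MIN_LEAF,
                                  random_state=int(rng.integers(2**31)))
    path = base.cost_complexity_pruning_path(X, y)
    alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
    if len(alphas) > max_alphas:
        idx = np.unique(np.linspace(0, len(alphas) - 1, max_alphas).astype(int))
        alphas = alphas[idx]
    if len(alphas) == 1:
        return float(alphas[0])
    scores = np.zeros(len(alphas))
    rs = int(rng.integers(2**31))
    for tr, te in _group_strat_folds(resample_idx, y_orig, folds, rs):
        for i, a in enumerate(alphas):
            t = DecisionTreeClassifier(min_samples_leaf=MIN_LEAF, ccp_alpha=float(a),
                                       random_state=0)
            t.fit(X[tr], y[tr])
            scores[i] += np.mean(t.predict(X[te]) == y[te])
    best = np.flatnonzero(scores == scores.max())[-1]   # ties -> simplest tree
    return float(alphas[best])


def run_cv(spec: ModelSpec, features: pd.DataFrame, outcome, folds: int = 10,
           reps: int = 100, seed: int = 0, bootstrap: bool = True,
           bootstrap_unit: str = "record", chemical_id: str = "",
           internal_folds: int = 10) -> CvResult:
    """Bootstrap-repeated stratified k-fold CV accuracy for one model.

    Per repetition: resample records (or participants) with replacement,
    select the pruning alpha by internal CV on the resample (trees), run
    stratified ``folds``-fold CV within the resample and pool held-out
    accuracy.  Identical seeds give identical results.
    """
    y_all = np.asarray(pd.Categorical(outcome).codes)
    if (y_all < 0).any():
        raise ValueError("outcome contains missing categories; drop interference rows first")
    X_all, sources = _encode(features, spec.features)
    n = len(y_all)
    groups = features["participant_id"].to_numpy() if "participant_id" in features else None

    accuracies = np.zeros(reps)
    imp_sum = np.zeros(X_all.shape[1])
    for rep in range(reps):
        rng = np.random.default_rng([int(seed) % (2**31), rep])
        if bootstrap:
            if bootstrap_unit == "participant":
                if groups is None:
                    raise ValueError("participant bootstrap needs a participant_id column")
                uniq = np.unique(groups)
                chosen = rng.choice(uniq, size=len(uniq), replace=True)
                idx = np.concatenate([np.flatnonzero(groups == g) for g in chosen])
            else:
                idx = rng.integers(0, n, n)
        else:
            idx = np.arange(n)
        X, y = X_all[idx], y_all[idx]
        if spec.learner == "classification_tree":
            alpha = _select_alpha(X, y, idx, y_all, rng, folds=internal_folds)
        correct = 0
        rs = int(rng.integers(2**31))
        for tr, te in _group_strat_folds(idx, y_all, folds, rs):
            if spec.learner == "classification_tree":
                t = DecisionTreeClassifier(min_samples_leaf=MIN_LEAF, ccp_alpha=alpha,
                                           random_state=int(rng.integers(2**31)))
                t.fit(X[tr], y[tr])
                pred = t.predict(X[te])
            else:
                pred = _fit_predict_qda(X[tr], y[tr], X[te])
            correct += int(np.sum(pred == y[te]))
        accuracies[rep] = correct / len(y)
        if spec.learner == "classification_tree":
            full = DecisionTreeClassifier(min_samples_leaf=MIN_LEAF, ccp_alpha=alpha,
                                          random_state=int(rng.integers(2**31)))
            full.fit(X, y)
            imp_sum += full.feature_importances_
    importances = None
    if spec.learner == "classification_tree":
        per_col = imp_sum / reps
        importances = {}
        for src, v in zip(sources, per_col):
            importances[src] = importances.get(src, 0.0) + float(v)
    return CvResult(chemical_id=chemical_id, model_name=spec.name,
                    accuracies=accuracies, importances=importances, n_records=n)


# --------------------------------------------------------------------------
# comparison, selection, reporting helpers
# --------------------------------------------------------------------------

def random_baseline() -> float:
    """Expected accuracy of uniform random prediction over three classes."""
    return 1.0 / 3.0


def simulate_random_baseline(n: int = 100_000, seed: int = 0, n_classes: int = 3) -> float:
    """Monte-Carlo check of the non-informative baseline: uniform random
    predictions against (any) labels; converges to 1/n_classes."""
    rng = np.random.default_rng(int(seed) % (2**31))
    labels = rng.integers(0, n_classes, n)
    preds = rng.integers(0, n_classes, n)
    return float(np.mean(labels == preds))


def compare_accuracies(acc_a, acc_b, n_effective: int,
                       alternative: str = "greater", alpha: float = DEFAULT_ALPHA):
    """Pooled two-proportion z-test on mean CV accuracies.

    ``acc_a``/``acc_b`` may be CvResults or floats; ``n_effective`` is the
    trial count per arm (by default the number of analysis records).
    Returns (z, p, significant).
    """
    if n_effective < 1:
        raise ValueError("n_effective must be >= 1")
    p1 = acc_a.mean_accuracy if isinstance(acc_a, CvResult) else float(acc_a)
    p2 = acc_b.mean_accuracy if isinstance(acc_b, CvResult) else float(acc_b)
    pooled = (p1 + p2) / 2.0
    se = np.sqrt(pooled * (1.0 - pooled) * 2.0 / n_effective)
    z = 0.0 if se == 0 else (p1 - p2) / se
    if alternative == "greater":
        p = float(sps.norm.sf(z))
    elif alternative == "two-sided":
        p = float(2.0 * sps.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(z), p, bool(p < alpha)


def select_multivariate(standard: CvResult, interaction: CvResult,
                        n_effective: int | None = None,
                        alpha: float = DEFAULT_ALPHA) -> SelectionResult:
    """Choose the final Multivariate Model: the Interaction tree only if its
    mean accuracy is significantly higher (one-sided); otherwise Standard."""
    n_eff = n_effective if n_effective is not None else standard.n_records
    z, p, significant = compare_accuracies(interaction, standard, n_eff,
                                           alternative="greater", alpha=alpha)
    return SelectionResult(chemical_id=standard.chemical_id,
                           chosen="Interaction" if significant else "Standard",
                           z=z, p_value=p)


def accuracy_ci(result: CvResult, n_effective: int | None = None,
                level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation proportion CI for the mean accuracy, clipped to [0,1]."""
    n_eff = n_effective if n_effective is not None else result.n_records
    p = result.mean_accuracy
    zcrit = sps.norm.ppf(0.5 + level / 2.0)
    half = zcrit * np.sqrt(p * (1.0 - p) / n_eff)
    return float(max(p - half, 0.0)), float(min(p + half, 1.0))


def scaled_importance(result: CvResult) -> pd.DataFrame:
    """Per-feature importance scaled so the top feature equals 1."""
    if result.importances is None:
        raise ValueError("importances are only available for tree models")
    vals = np.array(list(result.importances.values()))
    if np.all(vals == 0):
        raise ValueError("degenerate tree: all importances are zero")
    top = vals.max()
    return pd.DataFrame({
        "feature": list(result.importances.keys()),
        "importance": vals / top,
    }).sort_values("importance", ascending=False).reset_index(drop=True)


def run_model_comparison(features: pd.DataFrame, outcome, chemical_id: str = "",
                         folds: int = 10, reps: int = 100, seed: int = 0,
                         n_effective: int | None = None,
                         bootstrap_unit: str = "record") -> dict:
    """Fit all four models for one chemical and select the Multivariate Model.

    Returns a dict with the four CvResults, the SelectionResult, the chosen
    model's CI, and z-tests of the Multivariate Model against each baseline.
    """
    specs = model_specs(features.columns)
    results = {name: run_cv(spec, features, outcome, folds=folds, reps=reps,
                            seed=seed, chemical_id=chemical_id,
                            bootstrap_unit=bootstrap_unit)
               for name, spec in specs.items()}
    selection = select_multivariate(results["Standard"], results["Interaction"],
                                    n_effective=n_effective)
    multivariate = results[selection.chosen]
    n_eff = n_effective if n_effective is not None else multivariate.n_records
    comparisons = {
        f"Multivariate_vs_{b}": compare_accuracies(multivariate, results[b], n_eff,
                                                   alternative="two-sided")
        for b in ("AQI_only", "HMS_only")
    }
    return {
        "results": results,
        "selection": selection,
        "multivariate": multivariate,
        "ci": accuracy_ci(multivariate, n_eff),
        "baseline_comparisons": comparisons,
        "random_baseline": random_baseline(),
    }
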