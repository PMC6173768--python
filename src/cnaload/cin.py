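"""Chromosomal-instability (CIN) scoring and the cluster-assignment classifier.

The CIN score of a sample is the fraction of recurrent regions (focal plus
whole-arm features) carrying a non-diploid call.  Samples are dichotomized
into CIN-high vs CIN-low at a threshold on that fraction (default 0.25, with
the boundary inclusive: a sample with exactly 25% of regions altered is
CIN-high).  The threshold can be re-derived from survival data by scanning a
grid and picking the dichotomy under which the treatment effect within the
CIN-high stratum is strongest.

Cluster assignment for replication cohorts uses a random-forest classifier
over the region call codes, with out-of-bag permutation importance
(per-predictor error-rate increase averaged over trees and normalized by its
standard deviation) and stratified 10-fold cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold

from .recurrence import CallMatrix

__all__ = ["CinScore", "ClusterClassifier", "cin_score", "cin_scores",
           "optimize_cin_threshold", "train_classifier",
           "crossvalidate_classifier", "classify_cohort"]

CIN_THRESHOLD = 0.25


class CinError(ValueError):
    pass


@dataclass(frozen=True)
class CinScore:
    sample_id: str
    fraction_regions_altered: float
    cin_class: str  # 'high' | 'low'
    threshold_used: float


def cin_score(sample_calls, threshold: float = CIN_THRESHOLD,
              sample_id: str = "sample") -> CinScore:
    """CIN score of one sample from its per-region five-level codes.

    ``fraction = #(non-diploid regions) / #(regions)``; class is 'high' iff
    the fraction is greater than or equal to ``threshold``.
    """
    calls = np.asarray(sample_calls)
    if calls.size == 0:
        raise CinError("empty region universe")
    frac = float((calls != 0).mean())
    cls = "high" if frac >= threshold else "low"
    return CinScore(sample_id=sample_id, fraction_regions_altered=frac,
                    cin_class=cls, threshold_used=threshold)


def cin_scores(call_matrix: CallMatrix, threshold: float = CIN_THRESHOLD) -> pd.DataFrame:
    """Vectorized CIN scores for a whole call matrix (one row per sample)."""
    frac = call_matrix.altered_fraction()
    return pd.DataFrame({
        "fraction_regions_altered": frac,
        "cin_class": np.where(frac >= threshold, "high", "low"),
        "threshold_used": threshold,
    })


def optimize_cin_threshold(fractions: pd.Series, survival: pd.DataFrame,
                           grid, duration_col: str = "time",
                           event_col: str = "event", arm_col: str = "bvz",
                           min_events: int = 10) -> tuple[float, pd.DataFrame]:
    """Scan candidate CIN thresholds for the strongest within-CIN-high
    treatment effect.

    For each grid point the cohort is dichotomized at that fraction and a Cox
    model of the treatment arm is fitted within the CIN-high stratum; the
    winning threshold is the one with the strongest protective treatment
    effect, measured by the Wald z of the treatment log-HR (most negative z),
    ties broken toward the smaller threshold.  The z criterion, rather than
    the raw log-HR, keeps the scan from drifting to small high-threshold
    strata whose noisy estimates can be extreme.  Grid points whose stratum
    has fewer than ``min_events`` events or a missing arm are skipped with a
    warning.  Returns ``(best_threshold, trace)``.
    """
    from .survival import cox_fit

    grid = sorted(grid)
    if len(grid) == 0:
        raise CinError("empty threshold grid")
    if survival[arm_col].nunique() < 2:
        raise CinError("both treatment arms must be present")
    rows = []
    for t in grid:
        high = fractions.loc[survival.index] >= t
        sub = survival.loc[high.values]
        if sub[event_col].sum() < min_events or sub[arm_col].nunique() < 2:
            warnings.warn(f"threshold {t}: CIN-high stratum too small, skipped")
            continue
        try:
            est = cox_fit(sub, duration_col=duration_col, event_col=event_col,
                          covariates=[arm_col])[0]
        except Exception as exc:  # noqa: BLE001 - degenerate grid point
            warnings.warn(f"threshold {t}: Cox fit failed ({exc}); skipped")
            continue
        log_hr = np.log(est.hazard_ratio)
        se = (np.log(est.ci_high) - np.log(est.ci_low)) / (2 * 1.959963984540054)
        z = log_hr / se if se > 0 else 0.0
        rows.append({"threshold": t, "log_hr": log_hr, "z": z,
                     "hazard_ratio": est.hazard_ratio, "p_value": est.p_value,
                     "n_high": int(high.sum())})
    trace = pd.DataFrame(rows)
    if trace.empty:
        raise CinError("no usable grid point")
    minval = trace["z"].min()
    best = float(trace.loc[np.isclose(trace["z"], minval), "threshold"].min())
    return best, trace


@dataclass
class ClusterClassifier:
    """Random-forest cluster classifier with portable feature bookkeeping."""

    feature_ids: list[str]
    model: RandomForestClassifier
    training_medians: pd.Series
    seed: int | None
    classes: list[int]
    importance: pd.DataFrame | None = field(default=None)


def _oob_permutation_importance(model: RandomForestClassifier, X: np.ndarray,
                                y: np.ndarray, seed: int | None) -> pd.DataFrame | None:
    """randomForest-style importance: per tree, the out-of-bag error increase
    after permuting each predictor, averaged over trees and normalized by the
    standard deviation of the per-tree differences."""
    try:
        from sklearn.ensemble._forest import (_generate_unsampled_indices,
                                              _get_n_samples_bootstrap)
    except ImportError:  # pragma: no cover - sklearn internals moved
        return None
    n = X.shape[0]
    try:
        n_boot = _get_n_samples_bootstrap(n, model.max_samples, None)

        def unsampled(rs):
            return _generate_unsampled_indices(rs, n, n_boot, None)
    except TypeError:  # older signature without sample_weight
        n_boot = _get_n_samples_bootstrap(n, model.max_samples)

        def unsampled(rs):
            return _generate_unsampled_indices(rs, n, n_boot)
    rng = np.random.default_rng(seed)
    diffs = np.zeros((len(model.estimators_), X.shape[1]))
    for t, tree in enumerate(model.estimators_):
        oob = unsampled(tree.random_state)
        if oob.size == 0:
            continue
        Xo, yo = X[oob], y[oob]
        base_err = np.mean(tree.predict(Xo) != yo)
        for j in range(X.shape[1]):
            Xp = Xo.copy()
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
            diffs[t, j] = np.mean(tree.predict(Xp) != yo) - base_err
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, mean / sd, 0.0)
    return pd.DataFrame({"mean_decrease_accuracy": mean, "z": z})


def train_classifier(call_matrix: CallMatrix | pd.DataFrame, labels: pd.Series,
                     n_trees: int = 500, seed: int | None = None,
                     compute_importance: bool = True,
                     min_per_class: int = 10) -> ClusterClassifier:
    """Fit the cluster-assignment random forest on region call codes.

    Standard forest defaults: ``n_trees`` bootstrap-aggregated trees,
    ``sqrt(p)`` candidate features per split, Gini impurity.  Identical seeds
    reproduce identical trees, predictions and importances.
    """
    codes = call_matrix.codes if isinstance(call_matrix, CallMatrix) else call_matrix
    labels = labels.loc[codes.index]
    counts = labels.value_counts()
    if (counts < min_per_class).any():
        raise CinError(f"need at least {min_per_class} samples per class; got "
                       f"{counts.to_dict()}")
    X = codes.to_numpy(dtype=float)
    y = labels.to_numpy()
    model = RandomForestClassifier(n_estimators=n_trees, max_features="sqrt",
                                   criterion="gini", random_state=seed,
                                   oob_score=True)
    model.fit(X, y)
    importance = None
    if compute_importance:
        imp = _oob_permutation_importance(model, X, y, seed)
        if imp is not None:
            imp.index = list(codes.columns)
            importance = imp
    return ClusterClassifier(feature_ids=list(codes.columns), model=model,
                             training_medians=codes.median(),
                             seed=seed, classes=sorted(np.unique(y).tolist()),
                             importance=importance)


def crossvalidate_classifier(call_matrix: CallMatrix | pd.DataFrame,
                             labels: pd.Series, folds: int = 10,
                             seed: int | None = None,
                             n_trees: int = 500) -> dict:
    """Stratified k-fold cross-validated accuracy of the cluster classifier.

    The cohort is split into ``folds`` disjoint validation sets covering every
    sample exactly once; each fold trains on the remainder and scores on the
    held-out set.  When stratification is impossible (folds exceeding the
    smallest class) a plain shuffled split is used; ``folds == n`` gives
    leave-one-out.
    """
    codes = call_matrix.codes if isinstance(call_matrix, CallMatrix) else call_matrix
    labels = labels.loc[codes.index]
    n = len(codes)
    if folds > n:
        raise CinError(f"folds={folds} exceeds n={n}")
    X = codes.to_numpy(dtype=float)
    y = labels.to_numpy()
    min_class = pd.Series(y).value_counts().min()
    if folds <= min_class:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split = splitter.split(X, y)
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        split = splitter.split(X)
    accs, fold_sizes = [], []
    for i, (tr, va) in enumerate(split):
        model = RandomForestClassifier(n_estimators=n_trees, max_features="sqrt",
                                       random_state=None if seed is None else seed + i)
        model.fit(X[tr], y[tr])
        accs.append(float(np.mean(model.predict(X[va]) == y[va])))
        fold_sizes.append(len(va))
    return {"fold_accuracies": accs, "mean_accuracy": float(np.mean(accs)),
            "fold_sizes": fold_sizes}


def classify_cohort(classifier: ClusterClassifier,
                    new_calls: CallMatrix | pd.DataFrame,
                    max_missing: float = 0.20) -> pd.Series:
    """Assign cluster labels to a new cohort.

    Features are aligned by region id; features absent from the new cohort are
    imputed with the training-set median code (with a warning).  More than
    ``max_missing`` of features missing is an error.  Predictions are the
    forest majority vote; probability ties resolve to the lower label.
    """
    codes = new_calls.codes if isinstance(new_calls, CallMatrix) else new_calls
    if len(codes) == 0:
        return pd.Series([], dtype=int, name="cluster")
    missing = [f for f in classifier.feature_ids if f not in codes.columns]
    if len(missing) / len(classifier.feature_ids) > max_missing:
        raise CinError(f"{len(missing)}/{len(classifier.feature_ids)} features "
                       "missing from the new cohort")
    if missing:
        warnings.warn(f"{len(missing)} features missing; imputing training medians")
    aligned = codes.reindex(columns=classifier.feature_ids)
    for f in missing:
        aligned[f] = classifier.training_medians[f]
    pred = classifier.model.predict(aligned.to_numpy(dtype=float))
    return pd.Series(pred, index=codes.index, name="cluster")
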