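"""Random-forest regression of pathway enrichment scores from radiomics.

The target is a pathway's per-patient GSVA enrichment score (on the [-1, 1]
scale); predictors are the radiomic features.  Five preprocessing toggles
are supported, mirroring a bespoke optimization protocol:

1. z-score feature normalization (fit on training folds only);
2. oversampling of the training set to balance a 10-bin discretization of
   the target;
3. restricting the final model to the 15 most important features found by
   5-fold cross-validated forests;
4. per-sample weights inversely proportional to target-bin occupancy;
5. grid-search hyperparameter tuning (5-fold CV, mean absolute error).

Everything fit on data (scalers, oversampling, weights, feature selection)
derives from training folds only; validation folds and test sets are never
touched.  MAE is reported in percentage points of enrichment score
(mean |y - yhat| * 100).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from itertools import product

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold


@dataclass(frozen=True)
class PreprocessPlan:
    """The five independent preprocessing toggles."""

    zscore: bool = False
    oversample_bins: bool = False
    top15_only: bool = False
    sample_weights: bool = False
    tune_hyperparams: bool = False


@dataclass(frozen=True)
class RfGrid:
    """Hyperparameter grid for random-forest tuning."""

    n_estimators: tuple = (30, 50, 100, 250, 500, 1000, 2000)
    criterion: tuple = ("absolute_error", "squared_error", "poisson")
    max_depth: tuple = (2, 4, 6, 8, 10, None)
    max_samples: tuple = (0.2, 0.4, 0.6, 0.8, None)
    max_features: tuple = (0.2, 0.4, 0.6, 0.8, 1.0)

    def combinations(self):
        for combo in product(
            self.n_estimators, self.criterion, self.max_depth,
            self.max_samples, self.max_features,
        ):
            yield dict(
                zip(("n_estimators", "criterion", "max_depth",
                     "max_samples", "max_features"), combo)
            )


#: small grid for quick runs; a subset of the full grid above
REDUCED_GRID = RfGrid(
    n_estimators=(50, 100),
    criterion=("squared_error",),
    max_depth=(4, None),
    max_samples=(0.6, None),
    max_features=(0.6, 1.0),
)

#: untuned defaults used when tune_hyperparams is off
DEFAULT_PARAMS = {
    "n_estimators": 500,
    "criterion": "squared_error",
    "max_depth": None,
    "max_samples": None,
    "max_features": 1.0,
}


def split_cohort(sample_ids, train_frac: float = 0.8, seed: int = 0):
    """Seeded disjoint train/test split; train gets floor(train_frac * n).

    The floor convention reproduces the reference 80/20 partition of a
    174-patient cohort into 139 training and 35 test samples.
    """
    ids = list(sample_ids)
    n = len(ids)
    if n < 10:
        raise ValueError("need >= 10 samples to split")
    n_train = int(np.floor(train_frac * n))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train = [ids[i] for i in sorted(order[:n_train])]
    test = [ids[i] for i in sorted(order[n_train:])]
    return train, test


def _bin_targets(targets: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = targets.min(), targets.max()
    if hi == lo:
        raise ValueError("need >= 2 distinct target values")
    width = (hi - lo) / n_bins
    bins = np.minimum(np.floor((targets - lo) / width).astype(int), n_bins - 1)
    return bins


def oversample_bins(targets, n_bins: int = 10, seed: int = 0) -> np.ndarray:
    """Index multiset balancing equal-width target bins by oversampling.

    Every original index is retained; each non-empty bin is upsampled with
    replacement to the largest non-empty bin's count.
    """
    targets = np.asarray(targets, dtype=float)
    bins = _bin_targets(targets, n_bins)
    rng = np.random.default_rng(seed)
    counts = np.bincount(bins, minlength=n_bins)
    target_count = counts.max()
    out = []
    for b in range(n_bins):
        members = np.flatnonzero(bins == b)
        if members.size == 0:
            continue
        out.append(members)
        deficit = target_count - members.size
        if deficit > 0:
            out.append(rng.choice(members, size=deficit, replace=True))
    return np.sort(np.concatenate(out))


def compute_sample_weights(targets, n_bins: int = 10) -> np.ndarray:
    """Positive per-sample weights ∝ 1 / target-bin count, normalized to mean 1."""
    targets = np.asarray(targets, dtype=float)
    bins = _bin_targets(targets, n_bins)
    counts = np.bincount(bins, minlength=n_bins).astype(float)
    w = 1.0 / counts[bins]
    return w / w.mean()


def select_top_features(cv_importances: pd.DataFrame, k: int = 15) -> list[str]:
    """Top-k features by mean importance across folds (ties alphabetical)."""
    means = cv_importances.mean(axis=0)
    if not np.all(np.isfinite(means)):
        raise ValueError("importances must be finite")
    order = sorted(means.index, key=lambda f: (-means[f], f))
    return order[: min(k, len(order))]


def report_mae(y_true, y_pred, scale: float = 100.0) -> float:
    """MAE in percentage points of enrichment score: mean |y - yhat| * scale."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    return float(np.mean(np.abs(y_true - y_pred)) * scale)


@dataclass
class PredictionReport:
    """Outcome of training/evaluating one pathway's regressor."""

    pathway: str
    plan: PreprocessPlan
    params: dict
    cv_mae_mean: float
    cv_mae_ci: tuple[float, float]
    cv_fold_maes: list[float]
    internal_test_mae: float
    external_test_mae: float | None
    top_features: list[tuple[str, float]]
    baseline_cv_mae: float
    baseline_test_mae: float

    def as_dict(self) -> dict:
        d = asdict(self)
        d["plan"] = asdict(self.plan)
        return d


class _FoldPipeline:
    """Per-fold preprocessing that never sees validation/test data."""

    def __init__(self, plan: PreprocessPlan, seed: int):
        self.plan = plan
        self.seed = seed
        self.mu: np.ndarray | None = None
        self.sd: np.ndarray | None = None

    def fit_transform(self, X: np.ndarray, y: np.ndarray):
        if self.plan.zscore:
            self.mu = X.mean(axis=0)
            sd = X.std(axis=0, ddof=0)
            self.sd = np.where(sd > 0, sd, 1.0)
            X = (X - self.mu) / self.sd
        weights = None
        if self.plan.sample_weights:
            weights = compute_sample_weights(y)
        if self.plan.oversample_bins:
            idx = oversample_bins(y, seed=self.seed)
            X, y = X[idx], y[idx]
            weights = weights[idx] if weights is not None else None
        return X, y, weights

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.plan.zscore:
            if self.mu is None:
                raise RuntimeError("transform called before fit")
            return (X - self.mu) / self.sd
        return X


def _fit_rf(X, y, params, seed, weights=None) -> RandomForestRegressor:
    rf = RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    rf.fit(X, y, sample_weight=weights)
    return rf


def _cv_mae(X, y, params, plan, seed, n_splits=5):
    """Fold MAEs and per-fold importances under the plan's preprocessing."""
    kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    maes, importances = [], []
    for fold, (tr, va) in enumerate(kf.split(X)):
        pipe = _FoldPipeline(plan, seed=seed + fold)
        Xtr, ytr, wtr = pipe.fit_transform(X[tr], y[tr])
        rf = _fit_rf(Xtr, ytr, params, seed, wtr)
        pred = rf.predict(pipe.transform(X[va]))
        maes.append(report_mae(y[va], pred))
        importances.append(rf.feature_importances_)
    return maes, np.array(importances)


def train_and_evaluate(
    features: pd.DataFrame,
    es_row: pd.Series,
    plan: PreprocessPlan = PreprocessPlan(),
    grid: RfGrid | None = None,
    seed: int = 0,
    test_features: pd.DataFrame | None = None,
    test_es: pd.Series | None = None,
    external_features: pd.DataFrame | None = None,
    external_es: pd.Series | None = None,
    pathway: str = "",
) -> PredictionReport:
    """Train one pathway's RF regressor under a preprocessing plan.

    ``features``/``es_row`` are the training cohort (patients x features and
    the matching target scores).  When no internal test set is passed, an
    80/20 split of the training cohort is made first.  Returns CV MAE with a
    normal-approximation 95% CI over the 5 fold MAEs, internal/external test
    MAEs, the chosen hyperparameters and the top-15 impurity importances.
    """
    if not features.index.equals(es_row.index):
        es_row = es_row.loc[features.index]
    if test_features is None:
        train_ids, test_ids = split_cohort(features.index, seed=seed)
        test_features = features.loc[test_ids]
        test_es = es_row.loc[test_ids]
        features = features.loc[train_ids]
        es_row = es_row.loc[train_ids]
    if len(features) < 30:
        raise ValueError("need >= 30 training samples")

    feature_names = list(features.columns)
    X = features.to_numpy(dtype=float)
    y = es_row.to_numpy(dtype=float)

    # optional top-15 restriction from a preliminary CV pass
    if plan.top15_only:
        _, imp = _cv_mae(X, y, DEFAULT_PARAMS, plan, seed)
        keep = select_top_features(pd.DataFrame(imp, columns=feature_names))
        feature_names = keep
        X = features[keep].to_numpy(dtype=float)

    # hyperparameter search by 5-fold CV mean MAE
    if plan.tune_hyperparams:
        grid = grid or RfGrid()
        best_params, best_mae = None, np.inf
        for params in grid.combinations():
            maes, _ = _cv_mae(X, y, params, plan, seed)
            mean_mae = float(np.mean(maes))
            if mean_mae < best_mae:
                best_mae, best_params = mean_mae, params
        params = best_params
    else:
        params = dict(DEFAULT_PARAMS)

    fold_maes, imp = _cv_mae(X, y, params, plan, seed)
    cv_mean = float(np.mean(fold_maes))
    sd = float(np.std(fold_maes, ddof=1))
    ci = (cv_mean - 1.96 * sd, cv_mean + 1.96 * sd)

    # mean-only baseline under the same CV folds
    kf = KFold(n_splits=5, shuffle=True, random_state=seed)
    base_maes = [
        report_mae(y[va], np.full(va.size, y[tr].mean())) for tr, va in kf.split(X)
    ]

    # final model on the full training set
    pipe = _FoldPipeline(plan, seed=seed)
    Xtr, ytr, wtr = pipe.fit_transform(X, y)
    rf = _fit_rf(Xtr, ytr, params, seed, wtr)

    def _evaluate(feats: pd.DataFrame, target: pd.Series) -> float:
        Xt = pipe.transform(feats[feature_names].to_numpy(dtype=float))
        return report_mae(target.to_numpy(dtype=float), rf.predict(Xt))

    internal_mae = _evaluate(test_features, test_es)
    external_mae = (
        _evaluate(external_features, external_es)
        if external_features is not None
        else None
    )
    baseline_test = report_mae(
        test_es.to_numpy(dtype=float), np.full(len(test_es), y.mean())
    )

    mean_imp = pd.Series(rf.feature_importances_, index=feature_names)
    top = sorted(mean_imp.items(), key=lambda kv: (-kv[1], kv[0]))[:15]

    return PredictionReport(
        pathway=pathway,
        plan=plan,
        params=params,
        cv_mae_mean=cv_mean,
        cv_mae_ci=ci,
        cv_fold_maes=[float(m) for m in fold_maes],
        internal_test_mae=internal_mae,
        external_test_mae=external_mae,
        top_features=[(n, float(v)) for n, v in top],
        baseline_cv_mae=float(np.mean(base_maes)),
        baseline_test_mae=baseline_test,
    )
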