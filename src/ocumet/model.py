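"""Risk classifiers with a leakage-safe split / CV / SMOTE / z-score protocol.

The pipeline inside every cross-validation fold is: fit z-score statistics
on the fold-training rows, oversample the fold-training minority class
with SMOTE until the classes balance, fit the classifier, then score the
untouched fold-validation rows.  The held-out test split never enters any
training step.

The boosted-tree family is backed by scikit-learn's gradient boosting;
``"xgboost"`` is accepted as an alias for that family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    balanced_accuracy_score,
    f1_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

POSITIVE_LABEL = "deteriorated"
N_FOLDS = 5

FAMILIES = ("svm_rbf_pca", "decision_tree", "random_forest", "gradient_boosting")
_FAMILY_ALIASES = {"xgboost": "gradient_boosting"}

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "svm_rbf_pca": {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.1, 1.0]},
    "decision_tree": {"max_depth": [3, 5, 7, None], "min_samples_leaf": [1, 2, 4]},
    "random_forest": {"n_estimators": [100, 300], "max_depth": [None, 5, 10]},
    "gradient_boosting": {
        "n_estimators": [100, 300],
        "max_depth": [3, 5],
        "learning_rate": [0.05, 0.1],
    },
}


@dataclass
class ModelSpec:
    family: str
    hyperparameter_grid: dict[str, list] | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.family = _FAMILY_ALIASES.get(self.family, self.family)
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.hyperparameter_grid is None:
            self.hyperparameter_grid = DEFAULT_GRIDS[self.family]

    def grid_points(self) -> list[dict]:
        keys = list(self.hyperparameter_grid)
        return [
            dict(zip(keys, combo))
            for combo in product(*(self.hyperparameter_grid[k] for k in keys))
        ]


@dataclass
class ModelEvaluation:
    family: str
    best_params: dict
    fold_metrics: list[dict] = field(default_factory=list)
    aggregates: dict = field(default_factory=dict)
    holdout: dict = field(default_factory=dict)
    importance: list[tuple[str, float]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)


def build_estimator(family: str, params: dict, seed: int):
    """Instantiate the classifier for one family and grid point."""
    family = _FAMILY_ALIASES.get(family, family)
    if family == "svm_rbf_pca":
        # the PCA step always retains 95% variance before the RBF machine
        return Pipeline(
            [
                ("pca", PCA(n_components=0.95, random_state=seed)),
                ("svc", SVC(kernel="rbf", probability=True, random_state=seed, **params)),
            ]
        )
    if family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if family == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **params)
    raise ValueError(f"unknown model family {family!r}")


# ---------------------------------------------------------------------------
# resampling and normalization primitives
# ---------------------------------------------------------------------------


def stratified_holdout_split(
    X: np.ndarray, y: np.ndarray, test_fraction: float = 0.2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Return (train_idx, test_idx) preserving class proportions."""
    X = np.asarray(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if test_fraction > 0 and np.any(counts < 2):
        raise ValueError("every class needs at least 2 samples to stratify")
    if test_fraction == 0:
        return np.arange(len(y)), np.array([], dtype=int)
    rng = np.random.default_rng(seed)
    test_idx = []
    for cls in classes:
        idx = np.nonzero(y == cls)[0]
        rng.shuffle(idx)
        n_test = int(round(test_fraction * len(idx)))
        n_test = min(max(n_test, 1), len(idx) - 1)
        test_idx.extend(idx[:n_test])
    test_idx = np.sort(np.asarray(test_idx))
    train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
    return train_idx, test_idx


def smote_balance(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE: interpolate synthetic minority samples until classes balance.

    Each synthetic point lies on the segment between a minority sample
    and one of its k nearest minority neighbours.  Originals are kept
    unchanged and the majority class is untouched.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("SMOTE requires at least two classes")
    if len(classes) > 2:
        raise ValueError("only binary problems are supported")
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min < 2:
        raise ValueError("minority class needs at least 2 samples")
    Xmin = X[y == minority]
    k = min(k_neighbors, n_min - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xmin)
    _, neighbors = nn.kneighbors(Xmin)  # column 0 is the point itself
    n_new = int(n_maj - n_min)
    base = rng.integers(0, n_min, n_new)
    pick = rng.integers(1, k + 1, n_new)
    gap = rng.uniform(0, 1, n_new)[:, None]
    partners = neighbors[base, pick]
    synthetic = Xmin[base] + gap * (Xmin[partners] - Xmin[base])
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out


def zscore_transform(
    train_features: np.ndarray, apply_to: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Standardize ``apply_to`` with mean/SD estimated on training rows only.

    Zero-SD features are passed through centered, with a warning.
    """
    train = np.asarray(train_features, dtype=float)
    target = np.asarray(apply_to, dtype=float)
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    if np.any(sd == 0):
        warnings.warn("constant feature(s) passed through centered", UserWarning, stacklevel=2)
    safe_sd = np.where(sd == 0, 1.0, sd)
    return (target - mean) / safe_sd, {"mean": mean, "sd": sd}


# ---------------------------------------------------------------------------
# cross-validated training
# ---------------------------------------------------------------------------


def _fit_fold(family, params, seed, X_tr, y_tr, smote_seed, k_neighbors=5):
    Xz, stats = zscore_transform(X_tr, X_tr)
    Xb, yb = smote_balance(Xz, y_tr, k_neighbors=k_neighbors, rng=smote_seed)
    est = build_estimator(family, params, seed)
    est.fit(Xb, yb)
    return est, stats


def _positive_proba(est, X):
    idx = list(est.classes_).index(POSITIVE_LABEL)
    return est.predict_proba(X)[:, idx]


def _fold_scores(est, stats, X_val, y_val):
    Xz = (np.asarray(X_val, dtype=float) - stats["mean"]) / np.where(
        stats["sd"] == 0, 1.0, stats["sd"]
    )
    pred = est.predict(Xz)
    out = {
        "accuracy": float(accuracy_score(y_val, pred)),
        "f1": float(f1_score(y_val, pred, pos_label=POSITIVE_LABEL, zero_division=0)),
        "balanced_accuracy": float(balanced_accuracy_score(y_val, pred)),
    }
    if len(np.unique(y_val)) < 2:
        out["auroc"] = float("nan")
    else:
        out["auroc"] = float(
            roc_auc_score((np.asarray(y_val) == POSITIVE_LABEL).astype(int), _positive_proba(est, Xz))
        )
    return out


def _cv_folds(X, y, seed):
    skf = StratifiedKFold(n_splits=N_FOLDS, shuffle=True, random_state=seed)
    return list(skf.split(X, y))


def grid_search_cv(spec: ModelSpec, X: np.ndarray, y: np.ndarray) -> dict:
    """Pick the grid point with the best mean fold AUROC.

    Ties break on higher mean balanced accuracy, then grid order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    folds = _cv_folds(X, y, spec.rng_seed)
    best = None
    for gi, params in enumerate(spec.grid_points()):
        aurocs, bals = [], []
        for fi, (tr, va) in enumerate(folds):
            est, stats = _fit_fold(
                spec.family, params, spec.rng_seed, X[tr], y[tr], smote_seed=spec.rng_seed + fi
            )
            scores = _fold_scores(est, stats, X[va], y[va])
            if np.isfinite(scores["auroc"]):
                aurocs.append(scores["auroc"])
            bals.append(scores["balanced_accuracy"])
        key = (np.mean(aurocs) if aurocs else 0.0, np.mean(bals), -gi)
        if best is None or key > best[0]:
            best = (key, params)
    return best[1]


def evaluate_cv(spec: ModelSpec, params: dict, X: np.ndarray, y: np.ndarray) -> ModelEvaluation:
    """Stratified 5-fold evaluation of one configuration on the training set."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    fold_metrics = []
    excluded = 0
    for fi, (tr, va) in enumerate(_cv_folds(X, y, spec.rng_seed)):
        est, stats = _fit_fold(
            spec.family, params, spec.rng_seed, X[tr], y[tr], smote_seed=spec.rng_seed + fi
        )
        scores = _fold_scores(est, stats, X[va], y[va])
        if not np.isfinite(scores["auroc"]):
            excluded += 1
            warnings.warn("single-class fold validation set; AUROC excluded", stacklevel=2)
        fold_metrics.append(scores)
    aggregates = {}
    for metric in ("accuracy", "f1", "balanced_accuracy", "auroc"):
        vals = np.array([m[metric] for m in fold_metrics])
        vals = vals[np.isfinite(vals)]
        mean = float(vals.mean()) if vals.size else float("nan")
        sd = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
        aggregates[metric] = {"mean": mean, "sd": sd}
        if metric == "auroc" and vals.size:
            half = 1.96 * sd / np.sqrt(len(vals)) if vals.size > 1 else float("nan")
            aggregates[metric]["ci_low"] = mean - half
            aggregates[metric]["ci_high"] = mean + half
    return ModelEvaluation(
        family=spec.family,
        best_params=params,
        fold_metrics=fold_metrics,
        aggregates=aggregates,
        metadata={"excluded_auroc_folds": excluded, "seed": spec.rng_seed},
    )


def fit_final(spec: ModelSpec, params: dict, X_train: np.ndarray, y_train: np.ndarray):
    """Refit on the full training set (z-score + SMOTE on train only)."""
    return _fit_fold(
        spec.family, params, spec.rng_seed, np.asarray(X_train, float), np.asarray(y_train),
        smote_seed=spec.rng_seed,
    )


def evaluate_holdout(
    spec: ModelSpec,
    params: dict,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
) -> dict:
    """One-time scoring of the held-out test split."""
    if len(np.asarray(X_test)) == 0:
        raise ValueError("test set is empty")
    est, stats = fit_final(spec, params, X_train, y_train)
    return _fold_scores(est, stats, X_test, y_test)


def rank_feature_importance(fitted_model, feature_names: list[str]) -> list[tuple[str, float]]:
    """Normalized impurity-based importances of a tree ensemble, descending."""
    if not hasattr(fitted_model, "feature_importances_"):
        raise TypeError("feature importance requires a tree-ensemble model")
    raw = np.asarray(fitted_model.feature_importances_, dtype=float)
    total = raw.sum()
    if total > 0:
        raw = raw / total
    order = np.argsort(-raw)
    return [(feature_names[i], float(raw[i])) for i in order]
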