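"""Dataset assembly (D1-D6), SMOTE + stratified 10-fold cross-validated
model comparison, and the statistical tests between datasets.

Dataset design (feature domains included):

====  ===========  =======  ===========  ==================
id    demographic  cardiac  respiratory  causal_information
====  ===========  =======  ===========  ==================
D1        +           +
D2        +           +         +
D3        +           +         +              +
D4                    +         +              +
D5/D6: 35-feature subsets of the D3/D4 feature spaces selected by pooled
Shapley magnitude (see :mod:`cardioresp.explain`).
====  ===========  =======  ===========  ==================

Inside every fold the median imputer, SMOTE upsampler, and standardizer
are fit on the training part only — synthetic rows never reach a test
fold, and no test statistics leak into preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.base import clone
from sklearn.preprocessing import StandardScaler
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .manifest import FeatureManifest, default_manifest
from .metrics import MetricSet, compute_metrics
from .smote import smote_resample

__all__ = [
    "DatasetSpec",
    "DATASET_SPECS",
    "reduced_spec",
    "assemble_dataset",
    "default_model_zoo",
    "run_cv",
    "CVReport",
    "ModelCVResult",
    "compare_datasets",
    "demographic_tests",
    "GROUP_ORDER",
]

GROUP_ORDER = ["Cardiac", "Healthy", "Sport"]

_ALL_DOMAINS = ("demographic", "cardiac", "respiratory", "causal_information")


@dataclass(frozen=True)
class DatasetSpec:
    id: str
    included_domains: Tuple[str, ...]
    feature_subset: Optional[Tuple[str, ...]] = None


DATASET_SPECS: Dict[str, DatasetSpec] = {
    "D1": DatasetSpec("D1", ("demographic", "cardiac")),
    "D2": DatasetSpec("D2", ("demographic", "cardiac", "respiratory")),
    "D3": DatasetSpec("D3", _ALL_DOMAINS),
    "D4": DatasetSpec("D4", ("cardiac", "respiratory", "causal_information")),
}


def reduced_spec(
    spec_id: str, source: str, feature_names: Sequence[str]
) -> DatasetSpec:
    """D5/D6-style spec: an explicit feature subset of a source dataset."""
    base = DATASET_SPECS[source]
    return DatasetSpec(spec_id, base.included_domains, tuple(feature_names))


def assemble_dataset(
    feature_table: pd.DataFrame,
    spec: DatasetSpec,
    manifest: Optional[FeatureManifest] = None,
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Design matrix and integer label vector for one dataset spec.

    ``feature_table`` is the extractor output (one row per subject, a
    ``group`` column plus one column per manifest feature). Missing values
    stay NaN here; imputation happens inside the CV folds.
    """
    manifest = manifest or default_manifest()
    cols = manifest.names_for(*spec.included_domains)
    if spec.feature_subset is not None:
        unknown = set(spec.feature_subset) - set(cols)
        if unknown:
            raise ValueError(f"unknown features in subset: {sorted(unknown)}")
        cols = [c for c in cols if c in set(spec.feature_subset)]
    missing = set(cols) - set(feature_table.columns)
    if missing:
        raise ValueError(f"feature table lacks columns: {sorted(missing)}")
    X = feature_table[cols].copy()
    groups = feature_table["group"].astype(str)
    unknown_groups = set(groups) - set(GROUP_ORDER)
    if unknown_groups:
        raise ValueError(f"unknown group labels: {sorted(unknown_groups)}")
    y = np.array([GROUP_ORDER.index(g) for g in groups], dtype=int)
    return X, y


def default_model_zoo(
    seed: int = 0, include: Optional[Sequence[str]] = None
) -> Dict[str, Callable[[], object]]:
    """Factories for the model comparison zoo.

    Includes plain/ridge/lasso logistic regression, decision tree, SVM,
    random forest, gradient boosting, naive Bayes, k-NN, AdaBoost, an
    XGBoost-style boosted-tree classifier, and a multilayer perceptron.
    """
    from xgboost import XGBClassifier

    zoo: Dict[str, Callable[[], object]] = {
        "logreg": lambda: LogisticRegression(C=np.inf, max_iter=2000),
        "logreg_l2": lambda: LogisticRegression(C=1.0, max_iter=2000),
        "logreg_l1": lambda: LogisticRegression(
            l1_ratio=1.0, C=1.0, solver="saga", max_iter=2000
        ),
        "tree": lambda: DecisionTreeClassifier(random_state=seed),
        "svm": lambda: SVC(probability=True, random_state=seed),
        "rf": lambda: RandomForestClassifier(n_estimators=200, random_state=seed),
        "gb": lambda: GradientBoostingClassifier(random_state=seed),
        "nb": lambda: GaussianNB(),
        "knn": lambda: KNeighborsClassifier(n_neighbors=5),
        "adaboost": lambda: AdaBoostClassifier(random_state=seed),
        "xgboost": lambda: XGBClassifier(
            n_estimators=200, max_depth=4, learning_rate=0.1,
            eval_metric="logloss", random_state=seed, verbosity=0,
        ),
        "mlp": lambda: MLPClassifier(
            hidden_layer_sizes=(32,), max_iter=500, random_state=seed
        ),
    }
    if include is not None:
        zoo = {k: zoo[k] for k in include}
    return zoo


#: small random-search spaces for the optional per-fold hyperparameter tuning
DEFAULT_PARAM_SPACES: Dict[str, Dict[str, list]] = {
    "logreg_l2": {"C": [0.1, 1.0, 10.0]},
    "logreg_l1": {"C": [0.1, 1.0, 10.0]},
    "tree": {"max_depth": [3, 5, None]},
    "svm": {"C": [0.5, 1.0, 5.0]},
    "rf": {"max_depth": [None, 8], "n_estimators": [100, 200]},
    "gb": {"max_depth": [2, 3], "learning_rate": [0.05, 0.1]},
    "knn": {"n_neighbors": [3, 5, 9]},
    "xgboost": {"max_depth": [3, 4, 6]},
    "mlp": {"alpha": [1e-4, 1e-2]},
}


@dataclass
class ModelCVResult:
    fold_metrics: List[MetricSet]
    pooled_confusion: np.ndarray
    oof_true: np.ndarray
    oof_pred: np.ndarray
    oof_prob: np.ndarray
    failed_folds: List[int] = field(default_factory=list)

    def mean_metric(self, name: str) -> float:
        vals = [getattr(m, name) for m in self.fold_metrics]
        return float(np.nanmean(vals)) if vals else np.nan

    def metric_values(self, name: str) -> List[float]:
        return [getattr(m, name) for m in self.fold_metrics]


@dataclass
class CVReport:
    per_model: Dict[str, ModelCVResult]
    folds: List[np.ndarray]
    seed: int
    best_model: str

    def summary(self) -> pd.DataFrame:
        rows = {}
        for name, res in self.per_model.items():
            rows[name] = {
                m: res.mean_metric(m)
                for m in ("accuracy", "precision", "recall", "f1", "mcc", "auc")
            }
        return pd.DataFrame(rows).T.sort_values("accuracy", ascending=False)


def _impute_median(train: np.ndarray, test: np.ndarray):
    med = np.nanmedian(train, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    tr = np.where(np.isfinite(train), train, med)
    te = np.where(np.isfinite(test), test, med)
    return tr, te


def run_cv(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    models: Optional[Mapping[str, Callable[[], object]]] = None,
    k: int = 10,
    seed: int = 0,
    smote_strategy: Optional[Mapping[int, int] | Mapping[str, int]] = None,
    k_neighbors: int = 5,
    tune: bool = False,
    param_spaces: Optional[Mapping[str, Mapping[str, list]]] = None,
    n_tune_iter: int = 4,
) -> CVReport:
    """Stratified k-fold CV with per-fold SMOTE, imputation and scaling.

    ``smote_strategy`` maps class (integer code or group name) to the
    per-fold training count; None upsamples every class to the majority
    count. Model failures in a fold are recorded and the fold skipped for
    that model. Final model performance is the average over folds; the
    best model is the one with the highest mean accuracy.
    """
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n_classes = int(y.max()) + 1
    models = dict(models or default_model_zoo(seed))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [test for _, test in skf.split(Xa, y)]

    strategy_codes: Optional[Dict[int, int]] = None
    if smote_strategy is not None:
        strategy_codes = {}
        for key, val in smote_strategy.items():
            code = GROUP_ORDER.index(key) if isinstance(key, str) else int(key)
            strategy_codes[code] = int(val)

    results: Dict[str, ModelCVResult] = {
        name: ModelCVResult([], np.zeros((n_classes, n_classes), dtype=int),
                            np.empty(0, int), np.empty(0, int),
                            np.empty((0, n_classes)))
        for name in models
    }
    rng = np.random.default_rng(seed)

    for fold_id, (train_idx, test_idx) in enumerate(skf.split(Xa, y)):
        X_tr, X_te = Xa[train_idx], Xa[test_idx]
        y_tr, y_te = y[train_idx], y[test_idx]
        X_tr, X_te = _impute_median(X_tr, X_te)

        if strategy_codes is not None:
            strat = dict(strategy_codes)
        else:
            counts = np.bincount(y_tr, minlength=n_classes)
            strat = {c: int(counts.max()) for c in range(n_classes)}
        # targets may not fall below the realized fold counts
        fold_counts = np.bincount(y_tr, minlength=n_classes)
        for c in range(n_classes):
            strat[c] = max(strat.get(c, int(fold_counts[c])), int(fold_counts[c]))
        X_res, y_res = smote_resample(
            X_tr, y_tr, strat, k_neighbors=k_neighbors,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        scaler = StandardScaler().fit(X_res)
        X_res_s = scaler.transform(X_res)
        X_te_s = scaler.transform(X_te)

        for name, factory in models.items():
            try:
                model = factory()
                if tune:
                    model = _tune_model(
                        name, model, X_res_s, y_res,
                        dict(param_spaces or DEFAULT_PARAM_SPACES),
                        n_tune_iter, seed + fold_id,
                    )
                model.fit(X_res_s, y_res)
                prob = _predict_proba(model, X_te_s, n_classes)
                pred = np.argmax(prob, axis=1)
            except Exception:
                results[name].failed_folds.append(fold_id)
                continue
            ms = compute_metrics(y_te, pred, prob, k=n_classes)
            res = results[name]
            res.fold_metrics.append(ms)
            res.pooled_confusion += ms.confusion
            res.oof_true = np.concatenate([res.oof_true, y_te])
            res.oof_pred = np.concatenate([res.oof_pred, pred])
            res.oof_prob = np.vstack([res.oof_prob, prob])

    best = max(results, key=lambda m: results[m].mean_metric("accuracy")
               if results[m].fold_metrics else -np.inf)
    return CVReport(per_model=results, folds=folds, seed=seed, best_model=best)


def _predict_proba(model, X: np.ndarray, n_classes: int) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        prob = np.asarray(model.predict_proba(X), dtype=float)
    else:  # decision scores -> softmax
        scores = np.asarray(model.decision_function(X), dtype=float)
        if scores.ndim == 1:
            scores = np.column_stack([-scores, scores])
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        prob = e / e.sum(axis=1, keepdims=True)
    classes = getattr(model, "classes_", np.arange(prob.shape[1]))
    full = np.zeros((len(X), n_classes))
    for j, c in enumerate(classes):
        full[:, int(c)] = prob[:, j]
    rows = full.sum(axis=1, keepdims=True)
    rows[rows == 0] = 1.0
    return full / rows


def _tune_model(name, model, X, y, spaces, n_iter, seed):
    space = spaces.get(name)
    if not space:
        return model
    rng = np.random.default_rng(seed)
    keys = list(space)
    candidates = [dict(zip(keys, combo)) for combo in _grid(space, keys)]
    if len(candidates) > n_iter:
        pick = rng.choice(len(candidates), size=n_iter, replace=False)
        candidates = [candidates[i] for i in pick]
    best_params, best_score = None, -np.inf
    skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    for params in candidates:
        try:
            scores = []
            for tr, te in skf.split(X, y):
                m = clone(model).set_params(**params)
                m.fit(X[tr], y[tr])
                scores.append(np.mean(m.predict(X[te]) == y[te]))
            score = float(np.mean(scores))
        except Exception:
            continue
        if score > best_score:
            best_score, best_params = score, params
    if best_params is not None:
        model = clone(model).set_params(**best_params)
    return model


def _grid(space, keys):
    if not keys:
        yield ()
        return
    for val in space[keys[0]]:
        for rest in _grid(space, keys[1:]):
            yield (val,) + rest


def compare_datasets(
    fold_values: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon signed-rank matrix over fold-paired values.

    ``fold_values`` maps dataset id -> the per-fold values of one metric,
    paired by fold index (same folds and seed across datasets). Diagonal
    and all-tied comparisons yield p = 1.
    """
    ids = list(fold_values)
    mat = pd.DataFrame(np.ones((len(ids), len(ids))), index=ids, columns=ids)
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if j <= i:
                continue
            va = np.asarray(fold_values[a], dtype=float)
            vb = np.asarray(fold_values[b], dtype=float)
            if len(va) != len(vb):
                raise ValueError("fold vectors must be paired")
            diff = va - vb
            if np.allclose(diff, 0.0):
                p = 1.0
            else:
                p = float(sp_stats.wilcoxon(va, vb).pvalue)
            mat.loc[a, b] = p
            mat.loc[b, a] = p
    return mat


def demographic_tests(cohort: pd.DataFrame) -> pd.DataFrame:
    """Kruskal-Wallis comparison of age, mass, height and BMI across groups.

    ``cohort`` needs columns ``group``, ``age``, ``weight_kg``,
    ``height_cm``, ``bmi``. Requires all three groups with n >= 2 each.
    """
    groups = [g for g in GROUP_ORDER if g in set(cohort["group"])]
    if len(groups) < 3:
        raise ValueError("need all three groups for the comparison")
    rows = {}
    for var in ("age", "weight_kg", "height_cm", "bmi"):
        samples = [cohort.loc[cohort["group"] == g, var].to_numpy() for g in groups]
        if any(len(s) < 2 for s in samples):
            raise ValueError("each group needs at least 2 subjects")
        h, p = sp_stats.kruskal(*samples)
        rows[var] = {"H": float(h), "p": float(p)}
    return pd.DataFrame(rows).T
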