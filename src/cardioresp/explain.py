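"""Model explanation: Monte-Carlo permutation Shapley attributions,
permutation variable importance with a 1-AUC dropout loss, and the
Shapley-magnitude ranking that defines the reduced 35-feature datasets.

The Shapley estimator follows the sampling scheme of Strumbelj &
Kononenko: for each explained sample, feature-order permutations are
drawn and features are switched one at a time from a background draw to
the explained value; the marginal output changes telescope, so local
additivity (sum of attributions + baseline = model output) holds exactly
with respect to the sampled background.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "shapley_attributions",
    "permutation_importance",
    "select_top_features",
]


def _probability_fn(model) -> Tuple[Callable[[np.ndarray], np.ndarray], bool]:
    if hasattr(model, "predict_proba"):
        return (lambda Z: np.asarray(model.predict_proba(Z), dtype=float)), True
    def scores(Z):
        s = np.asarray(model.decision_function(Z), dtype=float)
        return s[:, None] if s.ndim == 1 else s
    return scores, False


def shapley_attributions(
    model,
    X_test: np.ndarray,
    X_background: np.ndarray,
    n_permutations: int = 10,
    seed: int = 0,
    max_background: int = 100,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-sample, per-feature, per-class Shapley attribution estimates.

    Returns ``(phi, baseline)`` with ``phi`` of shape
    ``(n_test, n_features, n_classes)`` and ``baseline`` the mean model
    output over the sampled background rows; models without probability
    output are explained through their decision scores.
    """
    X_test = np.asarray(X_test, dtype=float)
    X_background = np.asarray(X_background, dtype=float)
    if len(X_background) == 0:
        raise ValueError("background set must be non-empty")
    rng = np.random.default_rng(seed)
    if len(X_background) > max_background:
        keep = rng.choice(len(X_background), size=max_background, replace=False)
        X_background = X_background[keep]
    predict, _has_proba = _probability_fn(model)
    n_test, n_feat = X_test.shape
    n_out = predict(X_test[:1]).shape[1]
    phi = np.zeros((n_test, n_feat, n_out))
    baselines = np.zeros((n_test, n_out))

    for i in range(n_test):
        bg_idx = rng.integers(0, len(X_background), size=n_permutations)
        phi[i], baselines[i] = _accumulate(
            predict, X_test[i], X_background, bg_idx,
            n_permutations, n_feat, n_out, rng,
        )
    return phi, baselines


def _accumulate(predict, x, background, bg_idx, n_perm, n_feat, n_out, rng):
    """One sample's attribution estimate (orders drawn from ``rng``)."""
    phi = np.zeros((n_feat, n_out))
    base = np.zeros(n_out)
    rows = []
    orders = []
    for t in range(n_perm):
        order = rng.permutation(n_feat)
        orders.append(order)
        z = background[bg_idx[t]].copy()
        rows.append(z.copy())
        for j in order:
            z[j] = x[j]
            rows.append(z.copy())
    out = predict(np.asarray(rows))
    per_perm = n_feat + 1
    for t, order in enumerate(orders):
        block = out[t * per_perm: (t + 1) * per_perm]
        base += block[0]
        for step, j in enumerate(order):
            phi[j] += block[step + 1] - block[step]
    return phi / n_perm, base / n_perm


def permutation_importance(
    model,
    X_test: np.ndarray,
    y_test: np.ndarray,
    rounds: int = 30,
    seed: int = 0,
    class_labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-class permutation importance with a 1-AUC dropout loss.

    For every feature column: the column is shuffled ``rounds`` times and
    the increase of the one-vs-rest (per class) 1-AUC loss over the
    baseline is averaged. Returns a DataFrame indexed by feature with
    ``{class}_mean`` and ``{class}_sd`` columns. Classes with undefined
    AUC (absent from ``y_test`` or constant predictions) come back NaN.
    """
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test, dtype=int)
    predict, _ = _probability_fn(model)
    prob = predict(X_test)
    n_classes = prob.shape[1]
    labels = list(class_labels) if class_labels else [str(c) for c in range(n_classes)]

    def ovr_losses(p: np.ndarray) -> np.ndarray:
        out = np.full(n_classes, np.nan)
        for c in range(n_classes):
            mask = (y_test == c).astype(int)
            if mask.min() == mask.max():
                continue
            col = p[:, c]
            if np.ptp(col) == 0.0:
                out[c] = 0.5
                continue
            out[c] = 1.0 - roc_auc_score(mask, col)
        return out

    baseline = ovr_losses(prob)
    rng = np.random.default_rng(seed)
    n_feat = X_test.shape[1]
    means = np.zeros((n_feat, n_classes))
    sds = np.zeros((n_feat, n_classes))
    for j in range(n_feat):
        deltas = np.empty((rounds, n_classes))
        for r in range(rounds):
            Xp = X_test.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            deltas[r] = ovr_losses(predict(Xp)) - baseline
        means[j] = np.nanmean(deltas, axis=0)
        sds[j] = np.nanstd(deltas, axis=0)
    data = {}
    for c, lab in enumerate(labels):
        data[f"{lab}_mean"] = means[:, c]
        data[f"{lab}_sd"] = sds[:, c]
    return pd.DataFrame(data)


def select_top_features(
    attributions: Sequence[np.ndarray] | np.ndarray,
    feature_names: Sequence[str],
    k: int = 35,
) -> List[str]:
    """Top-k features by mean |Shapley| pooled over samples, folds, classes.

    ``attributions`` is one array or a list of arrays (one per CV fold),
    each of shape (n_samples, n_features, n_classes). Ties are broken by
    feature name for determinism.
    """
    if isinstance(attributions, np.ndarray):
        attributions = [attributions]
    feature_names = list(feature_names)
    if k > len(feature_names):
        raise ValueError("k exceeds the number of features")
    pooled = np.concatenate(
        [np.abs(np.asarray(a)).mean(axis=2) for a in attributions], axis=0
    )
    scores = pooled.mean(axis=0)
    ranked = sorted(
        zip(feature_names, scores), key=lambda kv: (-kv[1], kv[0])
    )
    return [name for name, _ in ranked[:k]]
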