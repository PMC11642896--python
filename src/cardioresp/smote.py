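"""Synthetic minority oversampling (SMOTE) for the training folds.

Each synthetic point is a convex combination of a class member and one of
its k nearest same-class neighbors, with a Uniform(0, 1) mixing
coefficient, so every synthetic row lies on the segment between its two
parents. Original rows are always preserved and come first in the output.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = ["smote_resample"]


def smote_resample(
    X: np.ndarray,
    y: np.ndarray,
    strategy: Dict[int, int] | Dict[str, int],
    k_neighbors: int = 5,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Upsample every class to the count requested in ``strategy``.

    ``strategy`` maps class label -> target count; targets must be at least
    the existing counts. When a class has fewer than ``k_neighbors + 1``
    members, k is reduced to the largest feasible value. A singleton class
    is replicated (it has no neighbor to interpolate with).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) != len(y):
        raise ValueError("X and y must align")
    classes, counts = np.unique(y, return_counts=True)
    count_of = dict(zip(classes.tolist(), counts.tolist()))
    for cls in strategy:
        if cls not in count_of:
            raise ValueError(f"class {cls!r} absent from the training data")
        if strategy[cls] < count_of[cls]:
            raise ValueError(
                f"strategy for class {cls!r} ({strategy[cls]}) is below the "
                f"existing count ({count_of[cls]})"
            )
    rng = np.random.default_rng(seed)
    new_rows, new_labels = [], []
    for cls in classes:
        target = strategy.get(cls, count_of[cls])
        need = int(target) - count_of[cls]
        if need <= 0:
            continue
        Xc = X[y == cls]
        if len(Xc) == 1:
            new_rows.append(np.repeat(Xc, need, axis=0))
            new_labels.extend([cls] * need)
            continue
        k = min(k_neighbors, len(Xc) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        _, idx = nn.kneighbors(Xc)  # first neighbor is the point itself
        base = rng.integers(0, len(Xc), size=need)
        pick = rng.integers(1, k + 1, size=need)
        mates = idx[base, pick]
        u = rng.uniform(0.0, 1.0, size=need)[:, None]
        synth = Xc[base] + u * (Xc[mates] - Xc[base])
        new_rows.append(synth)
        new_labels.extend([cls] * need)
    if not new_rows:
        return X.copy(), y.copy()
    X_out = np.vstack([X] + new_rows)
    y_out = np.concatenate([y, np.asarray(new_labels, dtype=y.dtype)])
    return X_out, y_out
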