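"""Synthetic minority oversampling (SMOTE) with a follow-up row shuffle.

New minority samples are interpolated uniformly on the segment between a
minority instance and one of its k nearest minority neighbours until the
class counts are equal; the balanced table is then shuffled with the same
seed (the 'randomize' step).
"""

from __future__ import annotations

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = ["smote_balance"]


def smote_balance(X, y, k: int = 5, seed: int = 1):
    """Balance a two-class feature matrix by minority oversampling.

    Returns ``(X_bal, y_bal)`` with equal class counts, rows shuffled.  An
    already balanced input is only shuffled.  The minority class must have at
    least ``k + 1`` members.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("SMOTE balancing expects exactly two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    need = n_maj - n_min
    if need > 0:
        if n_min < k + 1:
            raise ValueError(f"minority class needs at least {k + 1} members for k={k}")
        Xm = X[y == minority]
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
        _, idx = nn.kneighbors(Xm)
        neighbours = idx[:, 1:]  # drop self
        parents = rng.integers(0, n_min, size=need)
        mates = neighbours[parents, rng.integers(0, k, size=need)]
        lam = rng.random((need, 1))
        synth = Xm[parents] + lam * (Xm[mates] - Xm[parents])
        X = np.vstack([X, synth])
        y = np.concatenate([y, np.full(need, minority, dtype=y.dtype)])
    perm = rng.permutation(len(y))
    return X[perm], y[perm]
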