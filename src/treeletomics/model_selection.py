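"""Data-driven choice of the treelet cut-level and component count.

The cut-level trades variance explained (deep cuts) against sparsity
(shallow cuts).  For a fixed number of retained components K, the
optimal cut is chosen by K-fold cross-validation: fit the tree on the
training folds, select K components at each candidate cut, and score the
cut by the fraction of held-out variance the component scores capture.
Ties go to the lowest cut-level, favouring sparser patterns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .treelet import (
    _as_matrix,
    compute_scores,
    fit_treelet,
    select_components,
    variance_explained,
)

__all__ = ["cross_validate_cut", "scree_table"]


def _heldout_fraction(comps, X_test: np.ndarray) -> float:
    scores = X_test @ comps.loadings.T
    total = X_test.var(axis=0, ddof=1).sum()
    if total <= 0:
        return 0.0
    return float(scores.var(axis=0, ddof=1).sum() / total)


def cross_validate_cut(
    X,
    K: int,
    folds: int = 5,
    candidates=None,
    seed: int | None = None,
) -> tuple[int, pd.DataFrame]:
    """Cross-validated cut-level selection for K retained components.

    Returns ``(optimal_cut, table)`` where the table has one row per
    candidate cut-level with its mean held-out variance-explained
    fraction.  The optimum is the lowest cut-level attaining the maximal
    mean score.  Fold assignment is a seeded permutation of rows, so
    results are reproducible for a fixed seed.
    """
    arr, _ = _as_matrix(X)
    n, p = arr.shape
    if folds < 2:
        raise ValueError("cross-validation needs at least 2 folds")
    if n < 2 * folds:
        raise ValueError(f"{n} participants cannot populate {folds} folds of >=2")
    if candidates is None:
        candidates = np.arange(1, p)
    candidates = np.asarray(sorted(set(int(c) for c in candidates)))
    if candidates.min() < 1 or candidates.max() > p - 1:
        raise ValueError(f"candidate cut-levels must lie in [1, {p - 1}]")
    # a cut deeper than p-K leaves fewer than K active sum variables
    candidates = candidates[candidates <= p - K]
    if candidates.size == 0:
        raise ValueError(f"no candidate cut-level admits K={K} components")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, folds)):
        fold_of[chunk] = f

    cv = np.zeros((folds, candidates.size))
    for f in range(folds):
        train, test = arr[fold_of != f], arr[fold_of == f]
        tree = fit_treelet(train)
        for j, c in enumerate(candidates):
            comps = select_components(tree, int(c), K)
            cv[f, j] = _heldout_fraction(comps, test)
    mean_cv = cv.mean(axis=0)
    best = int(candidates[np.flatnonzero(mean_cv == mean_cv.max())[0]])
    table = pd.DataFrame({"cut_level": candidates, "cv_variance_explained": mean_cv})
    return best, table


def scree_table(
    X,
    K_range=range(1, 11),
    folds: int = 5,
    candidates=None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Optimal cut and variance explained for each candidate K.

    One row per K: the cross-validated optimal cut-level and the total
    variance-explained fraction of the K components refitted on the full
    data at that cut.  Used to inspect the scree and pick K at the elbow.
    """
    arr, _ = _as_matrix(X)
    rows = []
    tree_full = fit_treelet(X)
    C = tree_full.covariance
    for K in K_range:
        opt, _ = cross_validate_cut(X, K, folds=folds, candidates=candidates, seed=seed)
        comps = select_components(tree_full, opt, K)
        _, total = variance_explained(comps, C)
        rows.append({"K": K, "optimal_cut": opt, "variance_explained": total})
    return pd.DataFrame(rows)
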