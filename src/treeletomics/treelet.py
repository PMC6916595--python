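"""Treelet transform: hierarchical local PCA with sparse orthonormal components.

The treelet transform repeatedly merges the two most correlated of the
currently active variables by a 2x2 principal-component (Jacobi) rotation.
The higher-variance rotated coordinate (the *sum* variable) stays active;
the other (the *difference* variable) is retired.  After ``p - 1`` merges
all variables are joined into a single cluster tree.  Cutting the tree at
level ``c`` and keeping the ``K`` highest-variance active sum variables
yields components whose loadings are exactly zero outside the leaf set of
their subtree -- a sparse alternative to PCA that is easier to interpret
on grouped variables such as metabolite classes.

The estimator is fitted on a covariance matrix of (log) concentrations,
conventionally computed in the control population of a matched study so
that the basis is independent of case status.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "MergeStep",
    "TreeletTree",
    "ComponentSet",
    "TreeletTransform",
    "fit_treelet",
    "basis_at_level",
    "select_components",
    "compute_scores",
    "variance_explained",
]

_ORTHO_TOL = 1e-10


@dataclass(frozen=True)
class MergeStep:
    """One level of the cluster tree: a single local PCA rotation."""

    level: int            # 1 .. p-1
    alpha: int            # first merged variable (lower index)
    beta: int             # second merged variable
    theta: float          # rotation angle, |theta| <= pi/4
    sum_index: int        # higher-variance rotated coordinate (stays active)
    diff_index: int       # retired coordinate
    sum_variance: float
    diff_variance: float


@dataclass
class TreeletTree:
    """Full merge history of a treelet fit.

    Stores the ordered rotations, the per-level variable variances in the
    rotated coordinates, and which variables are still active (sum
    variables) at each level.  Bases are reconstructed on demand by
    replaying the rotations, which keeps the object light for large p.
    """

    steps: list[MergeStep]
    variable_names: list[str]
    covariance: np.ndarray          # input covariance, never mutated
    n_obs: int
    # row L of each array describes the state *after* merge step L+1
    _diag_history: np.ndarray = field(repr=False)
    _active_history: np.ndarray = field(repr=False)

    @property
    def n_variables(self) -> int:
        return len(self.variable_names)

    @property
    def n_levels(self) -> int:
        return len(self.steps)

    def basis_at_level(self, c: int) -> np.ndarray:
        """Orthonormal basis after the first ``c`` rotations (p x p).

        Column ``j`` is the loading vector of rotated coordinate ``j``.
        """
        p = self.n_variables
        if not 1 <= c <= p - 1:
            raise ValueError(f"cut-level must be in [1, {p - 1}], got {c}")
        basis = np.eye(p)
        for step in self.steps[:c]:
            _rotate_columns(basis, step.alpha, step.beta, step.theta)
        return basis

    def active_at_level(self, c: int) -> np.ndarray:
        """Boolean mask of sum variables still active after level ``c``."""
        if not 1 <= c <= self.n_levels:
            raise ValueError(f"cut-level must be in [1, {self.n_levels}], got {c}")
        return self._active_history[c - 1].copy()

    def variances_at_level(self, c: int) -> np.ndarray:
        """Variable variances in the rotated coordinates after level ``c``."""
        if not 1 <= c <= self.n_levels:
            raise ValueError(f"cut-level must be in [1, {self.n_levels}], got {c}")
        return self._diag_history[c - 1].copy()

    def merge_table(self) -> pd.DataFrame:
        """Merge history as a table (one row per level)."""
        names = self.variable_names
        return pd.DataFrame(
            {
                "level": [s.level for s in self.steps],
                "var_a": [names[s.alpha] for s in self.steps],
                "var_b": [names[s.beta] for s in self.steps],
                "theta": [s.theta for s in self.steps],
                "sum_var": [names[s.sum_index] for s in self.steps],
                "sum_variance": [s.sum_variance for s in self.steps],
                "diff_variance": [s.diff_variance for s in self.steps],
            }
        )


@dataclass
class ComponentSet:
    """K sparse unit-norm loading vectors selected at a cut-level."""

    cut_level: int
    loadings: np.ndarray            # K x p, rows unit norm with exact zeros
    variances: np.ndarray           # w' C w, descending
    variable_names: list[str]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def support(self, k: int) -> np.ndarray:
        """Indices of variables with nonzero loading in component ``k``."""
        return np.flatnonzero(self.loadings[k] != 0.0)

    def to_frame(self) -> pd.DataFrame:
        cols = {f"TC{k + 1}": self.loadings[k] for k in range(self.n_components)}
        return pd.DataFrame(cols, index=pd.Index(self.variable_names, name="variable"))


def _rotate_columns(mat: np.ndarray, a: int, b: int, theta: float) -> None:
    """In-place Givens rotation of columns a, b."""
    c, s = np.cos(theta), np.sin(theta)
    col_a = mat[:, a].copy()
    col_b = mat[:, b].copy()
    mat[:, a] = c * col_a + s * col_b
    mat[:, b] = -s * col_a + c * col_b


def _jacobi_angle(caa: float, cbb: float, cab: float) -> float:
    """Rotation angle zeroing the (a, b) covariance, reduced to |theta| <= pi/4."""
    theta = 0.5 * np.arctan2(2.0 * cab, caa - cbb)
    if theta > np.pi / 4:
        theta -= np.pi / 2
    elif theta < -np.pi / 4:
        theta += np.pi / 2
    return theta


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return np.asarray(X, dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    return arr, [f"x{j}" for j in range(arr.shape[1])]


def fit_treelet(X, *, covariance: np.ndarray | None = None) -> TreeletTree:
    """Fit the full cluster tree from a data matrix (rows = participants).

    Pair selection maximises the absolute correlation implied by the
    current rotated covariance; the rotation itself operates on the
    covariance, so high-variance variables keep their weight in the sum
    coordinate.  Ties are broken towards the lexicographically smallest
    index pair, making the tree fully deterministic.
    """
    arr, names = _as_matrix(X)
    if covariance is None:
        n, p = arr.shape
        if n < 2 or p < 2:
            raise ValueError("need at least 2 participants and 2 variables")
        if not np.all(np.isfinite(arr)):
            raise ValueError("input matrix contains non-finite values")
        C = np.cov(arr, rowvar=False, ddof=1)
        n_obs = n
    else:
        C = np.array(covariance, dtype=float)
        n_obs = arr.shape[0] if arr.size else 0
        p = C.shape[0]
        if p < 2:
            raise ValueError("need at least 2 variables")

    diag = np.diag(C)
    if np.any(diag <= 0):
        bad = [names[j] for j in np.flatnonzero(diag <= 0)]
        raise ValueError(
            f"constant (zero-variance) variables cannot be merged: {bad}; "
            "drop or jitter them before fitting"
        )

    C = C.copy()
    C_input = C.copy()
    active = np.ones(p, dtype=bool)
    steps: list[MergeStep] = []
    diag_hist = np.empty((p - 1, p))
    active_hist = np.empty((p - 1, p), dtype=bool)

    for level in range(1, p):
        idx = np.flatnonzero(active)
        sub = C[np.ix_(idx, idx)]
        d = np.diag(sub)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.abs(sub) / np.sqrt(np.outer(d, d))
        corr[~np.isfinite(corr)] = 0.0
        iu = np.triu_indices(len(idx), k=1)
        flat = corr[iu]
        best = int(np.argmax(flat))  # first max in row-major order = lexicographic
        a, b = int(idx[iu[0][best]]), int(idx[iu[1][best]])

        theta = _jacobi_angle(C[a, a], C[b, b], C[a, b])
        ct, st = np.cos(theta), np.sin(theta)
        # Givens update of the covariance (rows and columns a, b)
        row_a = C[a, :].copy()
        row_b = C[b, :].copy()
        C[a, :] = ct * row_a + st * row_b
        C[b, :] = -st * row_a + ct * row_b
        col_a = C[:, a].copy()
        col_b = C[:, b].copy()
        C[:, a] = ct * col_a + st * col_b
        C[:, b] = -st * col_a + ct * col_b
        C[a, b] = C[b, a] = 0.0  # zero by construction; kill rounding residue

        var_a, var_b = C[a, a], C[b, b]
        if var_a >= var_b:
            sum_i, diff_i = a, b
            sum_v, diff_v = var_a, var_b
        else:
            sum_i, diff_i = b, a
            sum_v, diff_v = var_b, var_a
        active[diff_i] = False
        steps.append(
            MergeStep(level, a, b, float(theta), sum_i, diff_i, float(sum_v), float(diff_v))
        )
        diag_hist[level - 1] = np.diag(C)
        active_hist[level - 1] = active

    return TreeletTree(
        steps=steps,
        variable_names=names,
        covariance=C_input,
        n_obs=n_obs,
        _diag_history=diag_hist,
        _active_history=active_hist,
    )


def basis_at_level(tree: TreeletTree, c: int) -> np.ndarray:
    """Orthonormal basis (p x p) after the first ``c`` rotations."""
    return tree.basis_at_level(c)


def select_components(tree: TreeletTree, c: int, K: int) -> ComponentSet:
    """The K highest-variance active sum variables at cut-level ``c``.

    Loadings are signed so that the largest-magnitude entry is positive
    and sorted by decreasing component variance.  Entries outside the
    subtree leaf set are exactly zero (never rotated), so the sparsity
    pattern is structural, not numerical.
    """
    p = tree.n_variables
    active = tree.active_at_level(c)
    n_active = int(active.sum())
    if K > n_active:
        raise ValueError(
            f"K={K} exceeds the {n_active} active sum variables at cut-level {c}"
        )
    if K == 0:
        return ComponentSet(c, np.empty((0, p)), np.empty(0), tree.variable_names)

    variances = tree.variances_at_level(c)
    idx = np.flatnonzero(active)
    # descending variance; np.argsort on -var is stable -> ties keep low index
    order = idx[np.argsort(-variances[idx], kind="stable")][:K]
    basis = tree.basis_at_level(c)
    loadings = basis[:, order].T.copy()
    for k in range(K):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] = -loadings[k]
        loadings[k][loadings[k] == 0.0] = 0.0  # normalise -0.0
    return ComponentSet(c, loadings, variances[order].copy(), tree.variable_names)


def compute_scores(X, comps: ComponentSet, *, reference: np.ndarray | None = None):
    """Component scores: weighted sums of (log) concentrations.

    Returns ``(scores, reference_sds)`` where the reference SDs are the
    score standard deviations in ``reference`` (default: ``X`` itself),
    used downstream for per-1-SD effect scaling.
    """
    arr, names = _as_matrix(X)
    if arr.shape[1] != comps.loadings.shape[1]:
        raise ValueError(
            f"matrix has {arr.shape[1]} variables, loadings expect "
            f"{comps.loadings.shape[1]}"
        )
    if isinstance(X, pd.DataFrame) and names != comps.variable_names:
        raise ValueError("variable names do not match the fitted components")
    scores = arr @ comps.loadings.T
    ref = scores if reference is None else np.asarray(reference) @ comps.loadings.T
    sds = ref.std(axis=0, ddof=1) if ref.shape[0] > 1 else np.ones(comps.n_components)
    if isinstance(X, pd.DataFrame):
        scores = pd.DataFrame(
            scores, index=X.index, columns=[f"TC{k+1}" for k in range(comps.n_components)]
        )
    return scores, sds


def variance_explained(comps: ComponentSet, C: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-component and total fractions of total variance, w'Cw / tr(C)."""
    C = np.asarray(C, dtype=float)
    total = np.trace(C)
    if total <= 0:
        raise ValueError("total variance is zero")
    if comps.n_components == 0:
        return np.empty(0), 0.0
    fracs = np.einsum("kp,pq,kq->k", comps.loadings, C, comps.loadings) / total
    return fracs, float(fracs.sum())


class TreeletTransform(TransformerMixin, BaseEstimator):
    """Sparse hierarchical-PCA decomposition via the treelet transform.

    Parameters
    ----------
    n_components : int, default 3
        Number of components to retain at the cut-level.
    cut_level : int or None, default None
        Tree level at which components are selected.  ``None`` uses the
        deepest level admitting ``n_components`` active sum variables
        (``p - n_components``); pass an integer to fix it, typically the
        optimum from :func:`~treeletomics.model_selection.cross_validate_cut`.

    Attributes
    ----------
    tree_ : TreeletTree
        Full merge history fitted on the training data.
    components_ : ndarray of shape (n_components, n_features)
        Sparse unit-norm loading vectors, descending variance.
    component_variances_ : ndarray
        w' C w per component on the training covariance.
    reference_sds_ : ndarray
        Training-population score SDs, used for per-1-SD scaling.
    cut_level_ : int
        The cut-level actually used.

    Examples
    --------
    >>> tt = TreeletTransform(n_components=2).fit(X_controls)
    >>> scores = tt.transform(X_all)      # participants x 2
    """

    def __init__(self, n_components: int = 3, cut_level: int | None = None):
        self.n_components = n_components
        self.cut_level = cut_level

    def fit(self, X, y=None):
        arr, names = _as_matrix(X)
        self.tree_ = fit_treelet(X)
        p = self.tree_.n_variables
        c = self.cut_level if self.cut_level is not None else p - self.n_components
        comps = select_components(self.tree_, c, self.n_components)
        self.cut_level_ = c
        self.components_ = comps.loadings
        self.component_variances_ = comps.variances
        self.component_set_ = comps
        _, self.reference_sds_ = compute_scores(X, comps)
        self.n_features_in_ = p
        self.feature_names_in_ = np.asarray(names, dtype=object)
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        scores, _ = compute_scores(X, self.component_set_)
        return np.asarray(scores) if not isinstance(X, pd.DataFrame) else scores

    def variance_explained(self) -> tuple[np.ndarray, float]:
        check_is_fitted(self, "components_")
        return variance_explained(self.component_set_, self.tree_.covariance)


def stability_bootstrap(
    X,
    c: int,
    K: int,
    B: int,
    seed: int | None = None,
    *,
    replace: bool = True,
) -> pd.DataFrame:
    """Bootstrap stability of treelet components via Tucker congruence.

    Refits the tree on ``B`` participant resamples and matches each
    original component to the most similar refitted one by absolute
    Tucker congruence ``|w . w'|`` (a cosine, both vectors unit norm).
    Returns per-component median and interquartile range of the
    congruence, plus the number of degenerate resamples skipped.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap resamples")
    arr, _ = _as_matrix(X)
    rng = np.random.default_rng(seed)
    base = select_components(fit_treelet(X), c, K)
    cong = np.full((B, K), np.nan)
    skipped = 0
    for b in range(B):
        rows = rng.integers(0, arr.shape[0], arr.shape[0]) if replace else np.arange(arr.shape[0])
        sample = arr[rows]
        if np.any(sample.std(axis=0) == 0):
            warnings.warn("degenerate bootstrap resample (constant variable); skipped")
            skipped += 1
            continue
        comps_b = select_components(fit_treelet(sample), c, K)
        sim = np.abs(base.loadings @ comps_b.loadings.T)  # K x K cosines
        cong[b] = sim.max(axis=1)
    valid = cong[~np.isnan(cong).any(axis=1)]
    out = pd.DataFrame(
        {
            "component": [f"TC{k+1}" for k in range(K)],
            "median_congruence": np.median(valid, axis=0),
            "iqr_low": np.percentile(valid, 25, axis=0),
            "iqr_high": np.percentile(valid, 75, axis=0),
        }
    )
    out.attrs["n_skipped"] = skipped
    return out
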