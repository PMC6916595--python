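"""Comparator analyses: PCA patterns and the per-metabolite screen.

PCA provides the dense-loading benchmark for the sparse treelet
patterns: it is conventionally fitted on the *entire* study population
(cases and controls), unlike the treelet basis which uses controls
only.  The univariate screen fits one conditional-logistic model per
metabolite (per 1 SD of log concentration) with multiplicity control
across the panel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .clogit import NoInformationError, SeparationError
from .risk import AdjustmentSet, ExposureSpec, clogit_fit
from .synthetic import MatchedCohort
from .treelet import _as_matrix

__all__ = ["MetabolitePCA", "fit_pca", "correlate_scores", "screen_metabolites"]


class MetabolitePCA(TransformerMixin, BaseEstimator):
    """PCA of the log-concentration covariance with a fixed sign convention.

    Eigendecomposition of the sample covariance; each loading vector is
    signed so its largest-magnitude entry is positive (matching the
    treelet convention, so score correlations are comparable across
    methods).

    Attributes
    ----------
    components_ : ndarray (n_components, p), orthonormal rows.
    explained_variance_ : eigenvalues, non-increasing.
    explained_variance_ratio_ : eigenvalue fractions of the trace.
    mean_ : training column means (scores are computed on centred data).
    """

    def __init__(self, n_components: int = 9):
        self.n_components = n_components

    def fit(self, X, y=None):
        arr, names = _as_matrix(X)
        n, p = arr.shape
        if self.n_components > p:
            raise ValueError(f"n_components={self.n_components} exceeds p={p}")
        C = np.cov(arr, rowvar=False, ddof=1)
        vals, vecs = np.linalg.eigh(C)
        order = np.argsort(vals)[::-1][: self.n_components]
        comps = vecs[:, order].T.copy()
        for k in range(comps.shape[0]):
            j = int(np.argmax(np.abs(comps[k])))
            if comps[k, j] < 0:
                comps[k] = -comps[k]
        self.components_ = comps
        self.explained_variance_ = vals[order].copy()
        self.explained_variance_ratio_ = self.explained_variance_ / np.trace(C)
        self.mean_ = arr.mean(axis=0)
        self.n_features_in_ = p
        self.feature_names_in_ = np.asarray(names, dtype=object)
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        arr, _ = _as_matrix(X)
        scores = (arr - self.mean_) @ self.components_.T
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(
                scores, index=X.index,
                columns=[f"PC{k+1}" for k in range(scores.shape[1])])
        return scores


def fit_pca(X, n_components: int = 9) -> MetabolitePCA:
    """Fit the PCA comparator (entire study population by convention)."""
    return MetabolitePCA(n_components=n_components).fit(X)


def correlate_scores(tt_scores: pd.DataFrame, pc_scores: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between treelet and PCA scores (same rows)."""
    if len(tt_scores) != len(pc_scores):
        raise ValueError("score matrices must cover the same participants")
    t = np.asarray(tt_scores, dtype=float)
    p = np.asarray(pc_scores, dtype=float)
    tz = (t - t.mean(0)) / t.std(0, ddof=1)
    pz = (p - p.mean(0)) / p.std(0, ddof=1)
    corr = tz.T @ pz / (len(t) - 1)
    tt_names = (list(tt_scores.columns) if isinstance(tt_scores, pd.DataFrame)
                else [f"TC{k+1}" for k in range(t.shape[1])])
    pc_names = (list(pc_scores.columns) if isinstance(pc_scores, pd.DataFrame)
                else [f"PC{k+1}" for k in range(p.shape[1])])
    return pd.DataFrame(corr, index=tt_names, columns=pc_names)


def screen_metabolites(
    cohort: MatchedCohort,
    X: pd.DataFrame,
    adjust: AdjustmentSet | None = None,
    outcome: str = "overall",
    method: str = "bh",
    alpha: float = 0.05,
    set_ids=None,
) -> pd.DataFrame:
    """Per-metabolite conditional-logistic screen with multiplicity control.

    One row per metabolite: OR per 1 SD of log concentration, 95% CI,
    raw and adjusted p (Benjamini-Hochberg by default, ``"bonferroni"``
    optional).  Fit failures are recorded per row, never fatal.
    """
    if method not in ("bh", "bonferroni"):
        raise ValueError("method must be 'bh' or 'bonferroni'")
    adjust = adjust or AdjustmentSet()
    rows = []
    for m in X.columns:
        row = {"metabolite": m, "outcome": outcome}
        try:
            fit = clogit_fit(cohort, ExposureSpec(X[m], name="expo"),
                             adjust, set_ids=set_ids)
            lo, hi = fit.or_ci
            row.update(odds_ratio=fit.odds_ratio, ci_low=lo, ci_high=hi,
                       p_value=fit.p_value, error="")
        except (NoInformationError, SeparationError, ValueError) as err:
            row.update(odds_ratio=np.nan, ci_low=np.nan, ci_high=np.nan,
                       p_value=np.nan, error=str(err))
        rows.append(row)
    out = pd.DataFrame(rows)
    ok = out["p_value"].notna()
    adj = np.full(len(out), np.nan)
    if ok.any():
        sm_method = "fdr_bh" if method == "bh" else "bonferroni"
        adj[ok.to_numpy()] = multipletests(
            out.loc[ok, "p_value"], alpha=alpha, method=sm_method)[1]
    out["p_adjusted"] = adj
    return out
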