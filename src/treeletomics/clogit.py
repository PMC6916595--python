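"""Conditional logistic regression for 1:1 matched case-control sets.

For one case and one control per set, conditioning on the set removes
the per-set nuisance intercepts and the conditional likelihood reduces
to

    L(beta) = prod_i  exp(x_case' beta) / (exp(x_case' beta) + exp(x_control' beta))
            = prod_i  sigma(d_i' beta),     d_i = x_case - x_control,

i.e. an intercept-free logistic regression on within-pair covariate
differences with all outcomes equal to one.  Sets with d_i = 0
contribute a constant and carry no information.  The model is fitted by
Newton-Raphson on this exact likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = ["ConditionalLogit", "CLogitFit", "SeparationError", "NoInformationError"]


class SeparationError(RuntimeError):
    """The conditional likelihood has no finite maximiser (complete separation)."""


class NoInformationError(ValueError):
    """No matched set shows within-pair variation in the design."""


@dataclass(frozen=True)
class CLogitFit:
    """Summary of one exposure coefficient from a conditional-logistic fit."""

    beta: float                 # log odds per exposure unit
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    loglik: float
    n_sets: int
    n_informative: int
    converged: bool

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        with np.errstate(over="ignore"):
            return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


class ConditionalLogit(BaseEstimator):
    """1:1 matched conditional logistic regression estimator.

    Parameters
    ----------
    tol : float, default 1e-10
        Convergence tolerance on the infinity norm of the score
        (gradient) vector.
    max_iter : int, default 100
        Maximum Newton iterations.
    drop_invariant : bool, default True
        Drop design columns with no within-pair variation in any set
        (they are not identified) with a warning instead of failing.

    Attributes
    ----------
    coef_ : ndarray of shape (n_kept_features,)
        Log odds ratios.
    bse_ : ndarray
        Standard errors from the inverse observed information.
    loglik_ : float
        Maximised conditional log-likelihood (informative sets only).
    n_sets_, n_informative_ : int
    converged_ : bool
    feature_names_ : list of str
        Names of the kept columns; ``dropped_features_`` lists the rest.

    Notes
    -----
    ``fit`` accepts either per-participant data (``X``, case indicator
    ``y`` and ``groups`` of set ids) or precomputed case-minus-control
    difference rows via :meth:`fit_differences`.
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 100,
                 drop_invariant: bool = True):
        self.tol = tol
        self.max_iter = max_iter
        self.drop_invariant = drop_invariant

    # ------------------------------------------------------------------
    def fit(self, X, y, groups):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        groups = np.asarray(groups)
        if X.ndim == 1:
            X = X[:, None]
        order = np.lexsort((1 - y, groups))  # within set: case first
        Xs, ys, gs = X[order], y[order], groups[order]
        uniq, start, counts = np.unique(gs, return_index=True, return_counts=True)
        if np.any(counts != 2):
            raise ValueError("every set must have exactly two participants")
        case_rows = Xs[start]
        ctrl_rows = Xs[start + 1]
        case_y = ys[start]
        ctrl_y = ys[start + 1]
        if not (np.all(case_y == 1) and np.all(ctrl_y == 0)):
            raise ValueError("every set must have exactly one case and one control")
        return self.fit_differences(case_rows - ctrl_rows)

    def fit_differences(self, D, feature_names=None):
        """Fit from case-minus-control difference rows (one per set)."""
        if isinstance(D, pd.DataFrame):
            feature_names = feature_names or [str(c) for c in D.columns]
        D = np.asarray(D, dtype=float)
        if D.ndim == 1:
            D = D[:, None]
        n_sets, p = D.shape
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(p)]

        varying = np.any(D != 0.0, axis=0)
        dropped = [feature_names[j] for j in np.flatnonzero(~varying)]
        if dropped:
            if not self.drop_invariant:
                raise ValueError(f"no within-pair variation for: {dropped}")
            warnings.warn(
                f"dropping design columns with no within-pair variation: {dropped}"
            )
        kept = np.flatnonzero(varying)
        informative = np.any(D != 0.0, axis=1)
        n_informative = int(informative.sum())
        if n_informative == 0 or kept.size == 0:
            raise NoInformationError(
                "no informative sets: exposure and covariates are identical "
                "within every matched pair"
            )
        Dk = D[informative][:, kept]

        beta = np.zeros(kept.size)
        converged = False
        ll = self._loglik(Dk, beta)
        for _ in range(self.max_iter):
            eta = Dk @ beta
            mu = expit(eta)
            grad = Dk.T @ (1.0 - mu)
            if np.linalg.norm(grad, np.inf) <= self.tol:
                converged = True
                break
            w = mu * (1.0 - mu)
            H = (Dk * w[:, None]).T @ Dk
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step, *_ = np.linalg.lstsq(H, grad, rcond=None)
            # damped Newton: halve until the likelihood does not decrease
            # (tolerance scales with |loglik| to absorb rounding at large n)
            slack = 1e-12 * (1.0 + abs(ll))
            t = 1.0
            while t > 1e-8:
                new_beta = beta + t * step
                new_ll = self._loglik(Dk, new_beta)
                if new_ll >= ll - slack:
                    break
                t /= 2.0
            beta, ll = new_beta, new_ll
            if np.abs(beta).max() > 40.0:
                raise SeparationError(
                    "coefficients diverging: complete or quasi-complete "
                    "separation of the within-pair differences"
                )
        if not converged:
            eta = Dk @ beta
            mu = expit(eta)
            grad = Dk.T @ (1.0 - mu)
            converged = bool(np.linalg.norm(grad, np.inf) <= self.tol)
            if not converged:
                raise SeparationError(
                    "Newton iterations did not converge; the likelihood may "
                    "be monotone (separation) or ill-conditioned"
                )

        mu = expit(Dk @ beta)
        w = mu * (1.0 - mu)
        H = (Dk * w[:, None]).T @ Dk
        cov = np.linalg.pinv(H)
        self.coef_ = beta
        self.cov_params_ = cov
        self.bse_ = np.sqrt(np.diag(cov))
        self.loglik_ = float(ll)
        self.n_sets_ = n_sets
        self.n_informative_ = n_informative
        self.converged_ = converged
        self.feature_names_ = [feature_names[j] for j in kept]
        self.dropped_features_ = dropped
        self.n_features_in_ = p
        return self

    @staticmethod
    def _loglik(D: np.ndarray, beta: np.ndarray) -> float:
        eta = D @ beta
        # log sigma(eta), numerically stable
        return float(-np.logaddexp(0.0, -eta).sum())

    # ------------------------------------------------------------------
    def predict_proba(self, D):
        """Probability that the first member of each difference row is the case."""
        check_is_fitted(self, "coef_")
        D = np.asarray(D, dtype=float)
        if D.ndim == 1:
            D = D[:, None]
        return expit(D @ self.coef_)

    def summary_for(self, name_or_index=0) -> CLogitFit:
        """CLogitFit summary (Wald CI, z = 1.96) for one coefficient."""
        check_is_fitted(self, "coef_")
        j = (self.feature_names_.index(name_or_index)
             if isinstance(name_or_index, str) else int(name_or_index))
        b, se = float(self.coef_[j]), float(self.bse_[j])
        z = b / se if se > 0 else np.inf
        return CLogitFit(
            beta=b,
            se=se,
            ci_low=b - 1.96 * se,
            ci_high=b + 1.96 * se,
            p_value=float(2 * norm.sf(abs(z))),
            loglik=self.loglik_,
            n_sets=self.n_sets_,
            n_informative=self.n_informative_,
            converged=self.converged_,
        )
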