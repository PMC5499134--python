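"""Survival-guided feature selection.

Two pieces feed the network stages:

* :class:`CoxElasticNetSelector` — elastic-net penalized Cox regression with
  the (lambda, l1-ratio) pair chosen by event-stratified 10-fold
  cross-validated partial-likelihood deviance. Selected features are those
  with nonzero coefficients at the chosen point.
* :func:`univariate_cox_prizes` — per-feature single-covariate Cox fits whose
  absolute coefficients become node prizes for the Steiner-tree refinement.

The penalty follows the glmnet parameterization
``alpha * (r * |b| + (1 - r)/2 * b^2)`` with ``r`` the L1 ratio; ``r = 1`` is
the lasso, small ``r`` approaches ridge.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted
from sksurv.linear_model import CoxnetSurvivalAnalysis

from .io import SurvivalTable

logger = logging.getLogger(__name__)

DEFAULT_L1_RATIO_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1))


def _as_structured(y) -> np.ndarray:
    if isinstance(y, SurvivalTable):
        return y.to_structured()
    y = np.asarray(y)
    if y.dtype.names and {"event", "time"} <= set(y.dtype.names):
        return y
    raise TypeError("y must be a SurvivalTable or structured (event, time) array")


def breslow_neg_log_partial_likelihood(
    eta: np.ndarray, time: np.ndarray, event: np.ndarray
):
    """Negative log partial likelihood with Breslow tie handling.

    ``eta`` is the linear predictor X @ beta; a 2-D ``eta`` (samples x
    models) is scored column-wise. Used as the CV deviance loss.
    """
    eta = np.asarray(eta, dtype=float)
    squeeze = eta.ndim == 1
    if squeeze:
        eta = eta[:, None]
    order = np.argsort(-time, kind="stable")
    eta = eta[order]
    time_s = np.asarray(time, dtype=float)[order]
    event_s = np.asarray(event, dtype=bool)[order]
    # risk-set sums: with descending time, the risk set of subject i is
    # everyone sorted before (and tied with) i; ties share the later index
    last_idx = np.empty(len(time_s), dtype=int)
    i = 0
    while i < len(time_s):
        j = i
        while j + 1 < len(time_s) and time_s[j + 1] == time_s[i]:
            j += 1
        last_idx[i : j + 1] = j
        i = j + 1
    m = eta.max(axis=0, keepdims=True)
    cum = np.cumsum(np.exp(eta - m), axis=0)
    log_risk = np.log(cum[last_idx]) + m
    nll = -np.sum(eta[event_s] - log_risk[event_s], axis=0)
    return float(nll[0]) if squeeze else nll


def stratified_folds(event: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Fold labels balanced on the event indicator (no event-free folds when
    there are at least ``n_folds`` events)."""
    rng = np.random.default_rng(seed)
    event = np.asarray(event, dtype=bool)
    folds = np.empty(len(event), dtype=int)
    for grp in (np.flatnonzero(event), np.flatnonzero(~event)):
        perm = rng.permutation(grp)
        folds[perm] = np.arange(len(perm)) % n_folds
    return folds


class CoxElasticNetSelector(SelectorMixin, BaseEstimator):
    """Elastic-net Cox feature selector with CV over a (lambda, l1-ratio) grid.

    Parameters
    ----------
    l1_ratio_grid : sequence of float in (0, 1]
        Candidate L1/L2 mixes; 1.0 is the lasso.
    n_alphas : int
        Length of the lambda path, log-spaced from the data-derived maximum
        down to ``alpha_min_ratio`` times it.
    alpha_min_ratio : float
    cv : int
        Number of event-stratified folds.
    random_state : int
        Seeds the fold assignment; identical seeds give identical folds and
        hence an identical chosen grid point.
    alphas : sequence of float, optional
        Fixed lambda path overriding the data-derived one (single values
        allowed, e.g. for oracle comparisons).

    Attributes
    ----------
    coef_ : ndarray (n_features,)
        Coefficients at the chosen grid point.
    alpha_ : float
        Chosen lambda.
    l1_ratio_ : float
        Chosen L1 ratio.
    cv_results_ : pandas.DataFrame
        Mean CV deviance per grid point.
    folds_ : ndarray
        Fold label per sample.
    """

    def __init__(
        self,
        l1_ratio_grid: Sequence[float] = DEFAULT_L1_RATIO_GRID,
        n_alphas: int = 100,
        alpha_min_ratio: float = 0.01,
        cv: int = 10,
        random_state: int = 0,
        alphas: Sequence[float] | None = None,
        max_iter: int = 100000,
        tol: float = 1e-7,
    ):
        self.l1_ratio_grid = l1_ratio_grid
        self.n_alphas = n_alphas
        self.alpha_min_ratio = alpha_min_ratio
        self.cv = cv
        self.random_state = random_state
        self.alphas = alphas
        self.max_iter = max_iter
        self.tol = tol

    def _coxnet(self, l1_ratio: float, alphas=None) -> CoxnetSurvivalAnalysis:
        kw = dict(
            l1_ratio=l1_ratio,
            max_iter=self.max_iter,
            tol=self.tol,
            fit_baseline_model=False,
        )
        if alphas is not None:
            kw["alphas"] = list(alphas)
        else:
            kw["n_alphas"] = self.n_alphas
            kw["alpha_min_ratio"] = self.alpha_min_ratio
        return CoxnetSurvivalAnalysis(**kw)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = _as_structured(y)
        if X.shape[0] != len(y):
            raise ValueError("X and y have different numbers of samples")
        time, event = y["time"], y["event"]
        if event.sum() < self.cv:
            raise ValueError(
                f"need at least cv={self.cv} events, got {int(event.sum())}"
            )
        self.n_features_in_ = X.shape[1]
        self.folds_ = stratified_folds(event, self.cv, self.random_state)

        records = []
        best = None  # (mean deviance, -alpha, -l1_ratio) minimized
        for l1_ratio in self.l1_ratio_grid:
            if self.alphas is not None:
                path = np.asarray(self.alphas, dtype=float)
            else:
                probe = self._coxnet(l1_ratio).fit(X, y)
                path = probe.alphas_
            dev = np.zeros((self.cv, len(path)))
            for k in range(self.cv):
                tr = self.folds_ != k
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = self._coxnet(l1_ratio, alphas=path).fit(X[tr], y[tr])
                coefs = model.coef_  # (n_features, n_alphas_fit)
                fit_alphas = np.asarray(model.alphas_)
                cols = [int(np.argmin(np.abs(fit_alphas - a))) for a in path]
                eta_full = X @ coefs[:, cols]
                # van Houwelingen CV deviance: full-data minus training-fold
                # partial likelihood at the training-fold solution (stabler
                # than scoring the small test fold alone)
                dev[k, :] = breslow_neg_log_partial_likelihood(
                    eta_full, time, event
                ) - breslow_neg_log_partial_likelihood(
                    eta_full[tr], time[tr], event[tr]
                )
            mean_dev = dev.mean(axis=0)
            for alpha, d in zip(path, mean_dev):
                records.append(
                    {"l1_ratio": l1_ratio, "alpha": alpha, "mean_cv_deviance": d}
                )
                key = (d, -alpha, -l1_ratio)  # ties -> larger alpha, larger l1
                if best is None or key < best[0]:
                    best = (key, alpha, l1_ratio)

        self.cv_results_ = pd.DataFrame.from_records(records)
        _, self.alpha_, self.l1_ratio_ = best
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            final = self._coxnet(self.l1_ratio_, alphas=[self.alpha_]).fit(X, y)
        self.coef_ = final.coef_[:, 0]
        if not np.any(self.coef_):
            logger.warning("all coefficients zero at the chosen grid point; empty selection")
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "coef_")
        return self.coef_ != 0

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags


def fit_elastic_net_cox(
    X: pd.DataFrame,
    surv: SurvivalTable,
    l1_ratio_grid: Sequence[float] = DEFAULT_L1_RATIO_GRID,
    n_folds: int = 10,
    seed: int = 0,
    **kwargs,
) -> CoxElasticNetSelector:
    """Thin functional wrapper: fit the selector on samples x features ``X``."""
    sel = CoxElasticNetSelector(
        l1_ratio_grid=l1_ratio_grid, cv=n_folds, random_state=seed, **kwargs
    )
    return sel.fit(X.to_numpy(dtype=float), surv)


def select_nonzero(fit: CoxElasticNetSelector, feature_ids: Sequence[str]) -> list[str]:
    """Feature IDs with nonzero coefficients at the chosen grid point,
    in the input order (stable)."""
    mask = fit._get_support_mask()
    return [f for f, m in zip(feature_ids, mask) if m]


def _univariate_cox_beta(
    x: np.ndarray, time: np.ndarray, event: np.ndarray, max_iter: int = 50
) -> float:
    """Newton's method on the scalar Cox partial likelihood (Breslow ties)."""
    order = np.argsort(-time, kind="stable")
    x_s = np.asarray(x, dtype=float)[order]
    time_s = np.asarray(time, dtype=float)[order]
    event_s = np.asarray(event, dtype=bool)[order]
    last_idx = np.empty(len(time_s), dtype=int)
    i = 0
    while i < len(time_s):
        j = i
        while j + 1 < len(time_s) and time_s[j + 1] == time_s[i]:
            j += 1
        last_idx[i : j + 1] = j
        i = j + 1
    d_idx = np.flatnonzero(event_s)
    if d_idx.size == 0:
        raise ValueError("no events")
    beta = 0.0
    for _ in range(max_iter):
        w = np.exp(beta * x_s - (beta * x_s).max())
        s0 = np.cumsum(w)[last_idx[d_idx]]
        s1 = np.cumsum(w * x_s)[last_idx[d_idx]]
        s2 = np.cumsum(w * x_s**2)[last_idx[d_idx]]
        mu = s1 / s0
        grad = float(np.sum(x_s[d_idx] - mu))
        hess = float(np.sum(s2 / s0 - mu**2))
        if hess <= 0 or not np.isfinite(hess):
            raise FloatingPointError("non-positive curvature")
        step = grad / hess
        beta += step
        if not np.isfinite(beta) or abs(beta) > 50:
            raise FloatingPointError("divergence")
        if abs(step) < 1e-10:
            break
    return beta


def univariate_cox_prizes(X: pd.DataFrame, surv: SurvivalTable) -> pd.Series:
    """Absolute univariate Cox coefficient per feature (node prizes).

    ``X`` is samples x features, standardized, aligned with ``surv``.
    Non-convergent fits get prize 0 with a warning.
    """
    time, event = surv.time, surv.event
    prizes = {}
    for col in X.columns:
        try:
            beta = _univariate_cox_beta(X[col].to_numpy(dtype=float), time, event)
        except (FloatingPointError, ValueError) as exc:
            logger.warning("univariate Cox failed for %s (%s); prize set to 0", col, exc)
            beta = 0.0
        prizes[col] = abs(beta)
    return pd.Series(prizes, name="prize")
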