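"""Sparse partial least squares coupling of regulators to module expression.

Regulators (methylation sites and miRNAs that survive elastic-net Cox
screening) form D (samples x q); module expression forms Y (samples x p).
Each component seeks unit-norm directions maximizing cov(Y a, D b), with an
L1-style soft threshold on the regulator-side direction to zero out
irrelevant regulators (the Chun-Keles surrogate: threshold the leading
singular vector of the cross-covariance at a fraction eta of its largest
absolute entry, renormalize, deflate, repeat). eta and the number of
components K are picked by cross-validated prediction error of Y from the
latent scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold

from .io import OmicsMatrix, SurvivalTable, align_samples
from .selection import CoxElasticNetSelector, DEFAULT_L1_RATIO_GRID

logger = logging.getLogger(__name__)

DEFAULT_ETA_GRID = tuple(np.round(np.arange(0.1, 0.91, 0.1), 1))
DEFAULT_K_GRID = (1, 2, 3, 4, 5)


@dataclass
class RegulatorCandidates:
    """Trait-associated regulators pooled across omics layers.

    ``matrix`` is samples x regulators; ``types`` maps each regulator ID to
    ``"methylation"`` or ``"miRNA"``.
    """

    matrix: pd.DataFrame
    types: pd.Series

    def __post_init__(self) -> None:
        if self.matrix.shape[1] < 1:
            raise ValueError("need at least one regulator")
        missing = set(self.matrix.columns) - set(self.types.index)
        if missing:
            raise ValueError(f"regulator(s) without a type tag: {sorted(missing)[:5]}")

    @property
    def regulator_ids(self) -> list[str]:
        return list(self.matrix.columns)


def screen_regulators(
    methylation: OmicsMatrix | None,
    mirna: OmicsMatrix | None,
    surv: SurvivalTable,
    cv_seed: int = 0,
    l1_ratio_grid=DEFAULT_L1_RATIO_GRID,
    n_folds: int = 10,
) -> RegulatorCandidates:
    """Elastic-net Cox screening per omics layer; union forms D.

    Either layer may be None/empty; both empty selections is an error
    ("no trait-associated regulators").
    """
    layers = []
    for m, tag in ((methylation, "methylation"), (mirna, "miRNA")):
        if m is None or m.shape[0] == 0:
            continue
        layers.append((m, tag))
    if not layers:
        raise ValueError("no regulator omics layers supplied")
    common = align_samples(*(m for m, _ in layers), surv)
    blocks, types = [], {}
    for m, tag in layers:
        sub = m.subset_samples(common)
        X = sub.samples_by_features()
        sel = CoxElasticNetSelector(
            l1_ratio_grid=l1_ratio_grid, cv=n_folds, random_state=cv_seed
        ).fit(X.to_numpy(dtype=float), surv.subset_samples(common))
        chosen = [f for f, keep in zip(X.columns, sel.get_support()) if keep]
        if chosen:
            blocks.append(X[chosen])
            types.update({f: tag for f in chosen})
    if not blocks:
        raise ValueError("no trait-associated regulators selected in any omics layer")
    D = pd.concat(blocks, axis=1)
    return RegulatorCandidates(matrix=D, types=pd.Series(types))


def _soft_threshold_direction(w: np.ndarray, eta: float) -> np.ndarray:
    """Zero entries below eta * max|w|, soft-shrink the rest, renormalize."""
    thr = eta * np.max(np.abs(w))
    out = np.sign(w) * np.maximum(np.abs(w) - thr, 0.0)
    nrm = np.linalg.norm(out)
    if nrm == 0:  # keep at least the largest entry
        out = np.zeros_like(w)
        out[np.argmax(np.abs(w))] = np.sign(w[np.argmax(np.abs(w))])
        nrm = 1.0
    return out / nrm


class SPLSRegression(RegressorMixin, BaseEstimator):
    """Sparse PLS regression of Y (module genes) on D (regulators).

    Parameters
    ----------
    n_components : int
        Number of latent components K.
    eta : float in [0, 1)
        Sparsity fraction on the regulator-side direction; 0 recovers plain
        PLS-SVD directions.
    scale : bool
        Standardize columns of both blocks before fitting.

    Attributes
    ----------
    x_weights_ : ndarray (q, K)
        Unit-norm regulator-side directions (beta per component).
    y_weights_ : ndarray (p, K)
        Unit-norm gene-side directions (alpha per component).
    x_scores_ : ndarray (n, K)
        Latent scores Gamma = D beta.
    selected_ : ndarray of int
        Regulator column indices with nonzero weight in >= 1 component.
    coef_ : ndarray (q, p)
        Regression matrix mapping (scaled) D to (scaled) Y predictions.
    """

    def __init__(self, n_components: int = 1, eta: float = 0.5, scale: bool = True):
        self.n_components = n_components
        self.eta = eta
        self.scale = scale

    def _center_scale(self, A: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        mu = A.mean(axis=0)
        if self.scale:
            sd = A.std(axis=0, ddof=1)
            sd[sd < 1e-12] = 1.0
        else:
            sd = np.ones(A.shape[1])
        return (A - mu) / sd, mu, sd

    def fit(self, X, Y):
        D = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if D.shape[0] != Y.shape[0]:
            raise ValueError("D and Y must have the same number of samples")
        n, q = D.shape
        p = Y.shape[1]
        Dc, self.x_mean_, self.x_std_ = self._center_scale(D)
        Yc, self.y_mean_, self.y_std_ = self._center_scale(Y)

        K = self.n_components
        max_K = int(np.linalg.matrix_rank(Dc.T @ Yc))
        if K > max_K:
            logger.warning("K=%d exceeds cross-covariance rank %d; truncating", K, max_K)
            K = max(max_K, 1)
        self.n_components_ = K

        Dd = Dc.copy()
        Yd = Yc.copy()
        W = np.zeros((q, K))
        C = np.zeros((p, K))
        T = np.zeros((n, K))
        for k in range(K):
            M = Dd.T @ Yd  # q x p cross-covariance (up to 1/(n-1))
            U, s, Vt = np.linalg.svd(M, full_matrices=False)
            w = U[:, 0]
            c = Vt[0, :]
            # deterministic sign: largest-|entry| component positive
            if w[np.argmax(np.abs(w))] < 0:
                w, c = -w, -c
            if self.eta > 0:
                w = _soft_threshold_direction(w, self.eta)
            t = Dd @ w
            W[:, k] = w
            C[:, k] = c / np.linalg.norm(c)
            T[:, k] = t
            tt = float(t @ t)
            if tt < 1e-12:
                break
            # deflate both blocks on the score
            Dd = Dd - np.outer(t, (t @ Dd) / tt)
            Yd = Yd - np.outer(t, (t @ Yd) / tt)

        self.x_weights_ = W
        self.y_weights_ = C
        self.x_scores_ = T
        self.selected_ = np.flatnonzero(np.any(W != 0, axis=1))
        # OLS of Yc on the scores gives the prediction map
        G = np.linalg.lstsq(T, Yc, rcond=None)[0]  # K x p
        # scores are linear in Dc through the deflation chain; recover the map
        R = np.linalg.lstsq(Dc, T, rcond=None)[0]  # q x K
        self.coef_ = R @ G
        return self

    def predict(self, X):
        D = (np.asarray(X, dtype=float) - self.x_mean_) / self.x_std_
        Yhat = D @ self.coef_
        return Yhat * self.y_std_ + self.y_mean_


def fit_spls(
    Y: pd.DataFrame,
    D: RegulatorCandidates | pd.DataFrame,
    K_grid=DEFAULT_K_GRID,
    eta_grid=DEFAULT_ETA_GRID,
    n_folds: int = 10,
    seed: int = 0,
) -> tuple[SPLSRegression, pd.DataFrame]:
    """Grid-search (K, eta) by K-fold mean squared prediction error.

    Ties prefer the sparser model (largest eta, then smallest K). Returns the
    refit model on all samples and the CV table.
    """
    Dm = D.matrix if isinstance(D, RegulatorCandidates) else D
    Dv = Dm.to_numpy(dtype=float)
    Yv = Y.to_numpy(dtype=float)
    n = Dv.shape[0]
    folds = KFold(n_splits=min(n_folds, n), shuffle=True, random_state=seed)
    # cap the component grid at the attainable rank up front
    max_K = min(Dv.shape[1], Yv.shape[1])
    K_grid = [K for K in K_grid if K <= max_K] or [max_K]
    records = []
    best = None
    for K in K_grid:
        for eta in eta_grid:
            errs = []
            for tr, te in folds.split(Dv):
                model = SPLSRegression(n_components=K, eta=eta).fit(Dv[tr], Yv[tr])
                resid = Yv[te] - model.predict(Dv[te])
                errs.append(float(np.mean(resid**2)))
            mse = float(np.mean(errs))
            records.append({"K": K, "eta": eta, "cv_mse": mse})
            key = (mse, -eta, K)
            if best is None or key < best[0]:
                best = (key, K, eta)
    _, K_best, eta_best = best
    model = SPLSRegression(n_components=K_best, eta=eta_best).fit(Dv, Yv)
    return model, pd.DataFrame.from_records(records)


def selected_regulators(model: SPLSRegression, regulator_ids) -> list[str]:
    """Regulator IDs with nonzero loading in at least one component."""
    return [regulator_ids[i] for i in model.selected_]
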