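"""Gaussian-graphical-model trimming of indirect within-module interactions.

Partial correlations come from the inverse sample covariance,
gamma_ij = -omega_ij / sqrt(omega_ii * omega_jj); pairs whose partial
correlation is not significantly nonzero (Benjamini-Hochberg FDR 0.05 over
all within-module pairs) are trimmed as indirect. Significance uses the
Fisher z transform: z = atanh(gamma) * sqrt(n - k - 3), where k is the
conditioning-set size (module size minus the pair itself).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.covariance import LedoitWolf
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_FDR = 0.05
COND_THRESHOLD = 1e10


@dataclass
class TrimmingSummary:
    """Bookkeeping of how many candidate pairs a module's GGM step removed."""

    module_size: int
    candidate_pairs: int
    kept_pairs: int
    trimmed_percent: float


def estimate_partial_correlations(
    expr_module: np.ndarray | pd.DataFrame,
    shrinkage: str = "auto",
) -> tuple[np.ndarray, float | None]:
    """Partial-correlation matrix of the module genes.

    ``expr_module`` is samples x genes. The sample covariance is inverted
    directly; if it is ill-conditioned (condition number above 1e10, or
    more genes than samples) and ``shrinkage`` is ``"auto"``, a Ledoit-Wolf
    analytically shrunk covariance is used instead and the intensity is
    returned (None when no shrinkage was applied).
    """
    X = np.asarray(expr_module, dtype=float)
    n, m = X.shape
    if n <= 3:
        raise ValueError("need more than 3 samples")
    S = np.cov(X, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    intensity: float | None = None
    cond = np.linalg.cond(S)
    if (cond > COND_THRESHOLD or m >= n) and shrinkage == "auto":
        lw = LedoitWolf(assume_centered=False).fit(X)
        S = lw.covariance_
        intensity = float(lw.shrinkage_)
        logger.info("covariance shrinkage applied (intensity %.4f)", intensity)
        cond = np.linalg.cond(S)
    if cond > 1e14:
        raise np.linalg.LinAlgError(
            f"covariance is singular even after shrinkage (condition number {cond:.3g})"
        )
    omega = np.linalg.inv(S)
    d = np.sqrt(np.diag(omega))
    gamma = -omega / np.outer(d, d)
    np.fill_diagonal(gamma, 1.0)
    gamma = np.clip((gamma + gamma.T) / 2.0, -1.0, 1.0)
    return gamma, intensity


def test_partial_correlations(
    gamma: np.ndarray, n: int, conditioning_size: int
) -> np.ndarray:
    """Two-sided p-values for each off-diagonal partial correlation.

    Fisher z asymptotics: z = atanh(gamma) * sqrt(n - k - 3) with k the
    conditioning-set size; |gamma| = 1 gives p = 0 (with a warning).
    """
    if n <= conditioning_size + 3:
        raise ValueError("need n > conditioning_size + 3")
    g = np.asarray(gamma, dtype=float)
    dof_scale = np.sqrt(n - conditioning_size - 3)
    p = np.ones_like(g)
    off = ~np.eye(g.shape[0], dtype=bool)
    sat = off & (np.abs(g) >= 1.0)
    if sat.any():
        logger.warning("|partial correlation| = 1 encountered; p set to 0")
    reg = off & ~sat
    z = np.arctanh(g[reg]) * dof_scale
    p[reg] = 2.0 * stats.norm.sf(np.abs(z))
    p[sat] = 0.0
    return p


def fdr_filter(p_values: np.ndarray, q: float = DEFAULT_FDR) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg over a flat vector of p-values.

    Returns (keep mask, q-values); kept = q-value <= ``q``. The kept set is
    invariant to the order the p-values are supplied in.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    _, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals <= q, qvals


def trimming_summary(module_size: int, kept_count: int) -> TrimmingSummary:
    """Fraction of candidate pairs trimmed, reported to two decimals."""
    candidates = module_size * (module_size - 1) // 2
    if kept_count > candidates:
        raise ValueError(f"kept {kept_count} exceeds candidate pairs {candidates}")
    pct = round(100.0 * (candidates - kept_count) / candidates, 2)
    return TrimmingSummary(module_size, candidates, kept_count, pct)


class GGMTrimmer(BaseEstimator):
    """Estimate within-module partial correlations and keep FDR-significant pairs.

    Parameters
    ----------
    fdr : float
        Benjamini-Hochberg threshold on the within-module pair universe.
    shrinkage : {"auto", "never"}
        Whether ill-conditioned covariances may be analytically shrunk.

    Attributes
    ----------
    partial_corr_ : ndarray (genes x genes)
    pvalues_, qvalues_ : ndarray (genes x genes), symmetric, diag NaN
    kept_edges_ : list[tuple[int, int]]
        Index pairs (i < j) surviving the FDR filter.
    shrinkage_ : float or None
    summary_ : TrimmingSummary
    """

    def __init__(self, fdr: float = DEFAULT_FDR, shrinkage: str = "auto"):
        self.fdr = fdr
        self.shrinkage = shrinkage

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, m = X.shape
        self.partial_corr_, self.shrinkage_ = estimate_partial_correlations(
            X, shrinkage=self.shrinkage
        )
        pmat = test_partial_correlations(self.partial_corr_, n, conditioning_size=m - 2)
        iu = np.triu_indices(m, k=1)
        keep, qflat = fdr_filter(pmat[iu], self.fdr)
        self.pvalues_ = np.full((m, m), np.nan)
        self.qvalues_ = np.full((m, m), np.nan)
        self.pvalues_[iu] = pmat[iu]
        self.qvalues_[iu] = qflat
        self.pvalues_ = np.fmin(self.pvalues_, self.pvalues_.T)
        self.qvalues_ = np.fmin(self.qvalues_, self.qvalues_.T)
        self.kept_edges_ = [
            (int(i), int(j)) for i, j, k in zip(iu[0], iu[1], keep) if k
        ]
        self.summary_ = trimming_summary(m, len(self.kept_edges_))
        return self

    def edge_table(self, gene_ids) -> pd.DataFrame:
        """Tidy per-pair table (gene_a, gene_b, partial_cor, p, q, kept)."""
        m = self.partial_corr_.shape[0]
        iu = np.triu_indices(m, k=1)
        kept = set(self.kept_edges_)
        return pd.DataFrame(
            {
                "gene_a": [gene_ids[i] for i in iu[0]],
                "gene_b": [gene_ids[j] for j in iu[1]],
                "partial_cor": self.partial_corr_[iu],
                "p": self.pvalues_[iu],
                "q": self.qvalues_[iu],
                "kept": [(i, j) in kept for i, j in zip(iu[0], iu[1])],
            }
        )
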