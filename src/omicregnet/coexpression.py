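"""Weighted coexpression module detection.

The classic weighted-network recipe: soft-threshold the absolute Pearson
correlation with a power chosen for approximate scale-free topology, convert
to topological overlap, cluster 1 - TOM with average linkage, and cut the
dendrogram into modules with a minimum size (default 15). Genes on branches
below the minimum form the unassigned ("grey") pool, labelled 0.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

logger = logging.getLogger(__name__)

GREY = 0  #: module label of the unassigned pool

DEFAULT_POWERS = tuple(range(1, 21))
DEFAULT_MIN_MODULE_SIZE = 15
DEFAULT_CUT_HEIGHT_FRAC = 0.99


def adjacency(expr: np.ndarray | pd.DataFrame, power: float) -> np.ndarray:
    """Unsigned soft-threshold adjacency a_ij = |cor(g_i, g_j)|**power.

    ``expr`` is samples x genes; diagonal is set to 1.
    """
    if power < 1:
        raise ValueError("power must be >= 1")
    X = np.asarray(expr, dtype=float)
    cor = np.corrcoef(X, rowvar=False)
    if np.isnan(cor).any():
        raise ValueError("degenerate correlations (constant gene?)")
    adj = np.abs(cor) ** power
    np.fill_diagonal(adj, 1.0)
    return adj


def scale_free_fit(adj: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution regression.

    Follows the usual scale-free-topology index: bin the connectivities,
    regress log10 frequency on log10 mean connectivity, and sign the R^2 by
    the slope so only decreasing distributions score high.
    """
    k = adj.sum(axis=0) - 1.0  # exclude self
    k = k[k > 0]
    if k.size < 2:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-9, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        return 0.0
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = ys - (slope * xs + intercept)
    ss_tot = float(np.sum((ys - ys.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return -np.sign(slope) * r2


def pick_soft_power(
    expr: np.ndarray | pd.DataFrame,
    candidate_powers: Sequence[int] = DEFAULT_POWERS,
    r2_cut: float = 0.8,
) -> int:
    """Smallest candidate power whose scale-free fit reaches ``r2_cut``;
    otherwise the power with maximal fit (with a warning)."""
    X = np.asarray(expr, dtype=float)
    if X.shape[1] < 3 or X.shape[0] < 4:
        raise ValueError("need at least 3 genes and 4 samples")
    fits = {}
    for p in candidate_powers:
        fits[p] = scale_free_fit(adjacency(X, p))
        if fits[p] >= r2_cut:
            return p
    best = max(fits, key=lambda p: fits[p])
    logger.warning(
        "no candidate power reached scale-free R^2 >= %.2f; using power %d (R^2=%.3f)",
        r2_cut, best, fits[best],
    )
    return best


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with k_i = sum_{u != i} a_iu; diagonal 1. Entries lie in [0, 1] and the
    matrix is symmetric.
    """
    A = np.asarray(adj, dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=0)
    shared = A @ A  # includes u = i or j only via zeroed diagonal, so it's sum over u != i and u != j plus terms where u==i/j vanish
    numer = shared + A
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, numer / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip((tom + tom.T) / 2.0, 0.0, 1.0)


def detect_modules(
    tom: np.ndarray,
    min_size: int = DEFAULT_MIN_MODULE_SIZE,
    cut_height_frac: float = DEFAULT_CUT_HEIGHT_FRAC,
) -> np.ndarray:
    """Cut average-linkage clustering of 1 - TOM into modules.

    Deterministic tree-based cut: the dendrogram is cut at
    ``cut_height_frac`` times the final merge height and branches smaller
    than ``min_size`` are routed to the grey pool. Returns integer labels
    (0 = grey; modules numbered 1.. by decreasing size, ties by smallest
    member index).
    """
    n = tom.shape[0]
    if n < min_size:
        logger.warning("fewer genes (%d) than min module size (%d): all grey", n, min_size)
        return np.zeros(n, dtype=int)
    diss = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(diss, 0.0)
    condensed = squareform((diss + diss.T) / 2.0, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    cut = cut_height_frac * Z[-1, 2]
    raw = hierarchy.fcluster(Z, t=cut, criterion="distance")
    labels = np.zeros(n, dtype=int)
    clusters = []
    for lab in np.unique(raw):
        members = np.flatnonzero(raw == lab)
        if members.size >= min_size:
            clusters.append(members)
    clusters.sort(key=lambda m: (-m.size, m.min()))
    for i, members in enumerate(clusters, start=1):
        labels[members] = i
    return labels


def grey_percentage(n_grey: int, n_total: int) -> float:
    """Percentage of selected genes left unassigned, to two decimals."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_grey / n_total, 2)


class CoexpressionModules(ClusterMixin, BaseEstimator):
    """Detect coexpression modules among the columns (genes) of X.

    Unlike sample-clustering estimators, ``labels_`` here has one entry per
    *feature*: the expression profile of each gene over samples is the object
    being clustered.

    Parameters
    ----------
    power : int or None
        Soft-threshold power; None picks the smallest power with scale-free
        fit >= ``r2_cut``.
    min_module_size : int
    cut_height_frac : float
        Fraction of the final merge height at which the dendrogram is cut.

    Attributes
    ----------
    power_ : int
    adjacency_, tom_ : ndarray (genes x genes)
    labels_ : ndarray (genes,), 0 = unassigned
    modules_ : dict[int, list[int]]
        Column indices per non-grey module.
    """

    def __init__(
        self,
        power: int | None = None,
        candidate_powers: Sequence[int] = DEFAULT_POWERS,
        r2_cut: float = 0.8,
        min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
        cut_height_frac: float = DEFAULT_CUT_HEIGHT_FRAC,
    ):
        self.power = power
        self.candidate_powers = candidate_powers
        self.r2_cut = r2_cut
        self.min_module_size = min_module_size
        self.cut_height_frac = cut_height_frac

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.power_ = (
            self.power
            if self.power is not None
            else pick_soft_power(X, self.candidate_powers, self.r2_cut)
        )
        self.adjacency_ = adjacency(X, self.power_)
        self.tom_ = tom_similarity(self.adjacency_)
        self.labels_ = detect_modules(
            self.tom_, self.min_module_size, self.cut_height_frac
        )
        self.modules_ = {
            int(lab): np.flatnonzero(self.labels_ == lab).tolist()
            for lab in np.unique(self.labels_)
            if lab != GREY
        }
        return self


def linkage_to_newick(Z: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Export a scipy linkage matrix as a Newick string (for inspection)."""
    tree = hierarchy.to_tree(Z)

    def rec(node):
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{node.dist:.6g}"
        return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

    return f"({rec(tree.left)},{rec(tree.right)});"
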