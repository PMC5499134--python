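"""Interaction-evidence combination and prize-collecting Steiner refinement.

Channel subscores (database evidence plus the local absolute correlation)
are combined into a confidence score with a naive-Bayes rule corrected for
the prior probability p that any two genes interact (0.063 against the KEGG
benchmark):

    S = [1 - prod_j (1 - (S_j - p)/(1 - p))] * (1 - p) + p

with each prior-corrected term clamped to [0, 1]. Edge cost is c_e = 1 - S;
node prizes b_i are absolute univariate Cox coefficients. The refined
subnetwork minimizes  sum_{e in E'} c_e - sum_{i in V'} b_i  over connected
subgraphs (the unrooted prize-collecting Steiner problem). Small instances
are solved exactly by node-subset enumeration (the optimal edge set for a
fixed node set is a minimum spanning tree); larger instances use a
deterministic MST + strong-pruning heuristic evaluated from every root.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_PRIOR = 0.063
EXACT_MAX_NODES = 14

STRING_CHANNELS = (
    "neighborhood",
    "fusion",
    "cooccurence",
    "coexpression",
    "experimental",
    "database",
    "textmining",
)


def prior_correct(sub_score: float, p: float = DEFAULT_PRIOR) -> float:
    """Remove the prior from a channel subscore, clamped to [0, 1]."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"prior must be in (0, 1), got {p}")
    if not 0.0 <= sub_score <= 1.0:
        raise ValueError(f"sub_score must be in [0, 1], got {sub_score}")
    return min(1.0, max(0.0, (sub_score - p) / (1.0 - p)))


def combine_evidence(sub_scores, p: float = DEFAULT_PRIOR) -> float:
    """Naive-Bayes combination of channel subscores into a confidence S.

    Single channel: S(s) = s for s >= p. Floor: S = p when every channel
    equals p. Adding a channel never decreases S.
    """
    scores = list(sub_scores)
    if not scores:
        raise ValueError("an edge must carry at least one evidence channel")
    prod = 1.0
    for s in scores:
        prod *= 1.0 - prior_correct(s, p)
    return (1.0 - prod) * (1.0 - p) + p


def read_string_scores(path: str | Path) -> pd.DataFrame:
    """Parse a STRING-links style flat file (tab or space separated).

    The header is autodetected; the first two columns are the protein/gene
    pair and every recognized channel column is kept. Integer 0-1000 scores
    are rescaled to [0, 1].
    """
    df = pd.read_csv(path, sep=r"\s+")
    cols = list(df.columns)
    if len(cols) < 3:
        raise ValueError(f"{path}: expected pair columns plus at least one score")
    pair_cols = cols[:2]
    channel_cols = [c for c in cols[2:] if c in STRING_CHANNELS]
    if not channel_cols:  # fall back: every numeric column except combined_score
        channel_cols = [c for c in cols[2:] if c != "combined_score"]
    out = df[pair_cols + channel_cols].copy()
    out.columns = ["node_a", "node_b"] + channel_cols
    for c in channel_cols:
        vals = out[c].astype(float)
        if vals.max() > 1.0:  # 0-1000 integer convention
            vals = vals / 1000.0
        out[c] = vals.clip(0.0, 1.0)
    out["node_a"] = out["node_a"].astype(str)
    out["node_b"] = out["node_b"].astype(str)
    return out


@dataclass
class Subnetwork:
    """A connected prize-collecting solution with its objective value."""

    nodes: list
    edges: list[tuple]
    objective: float


def build_evidence_graph(
    ggm_edges: list[tuple[str, str]],
    local_correlations: dict[tuple[str, str], float],
    prizes: pd.Series | dict,
    string_scores: pd.DataFrame | None = None,
    p: float = DEFAULT_PRIOR,
) -> nx.Graph:
    """Assemble the per-module evidence graph.

    Nodes are the module genes with attribute ``prize``; edges are exactly
    the GGM-kept pairs, each carrying the list of available channel
    subscores (database channels plus the local |Pearson correlation|),
    the combined score ``score`` and cost ``cost = 1 - score``. Database
    evidence for trimmed pairs is ignored. A gene missing from the prize
    vector is an error.
    """
    prizes = pd.Series(prizes)
    genes = sorted({g for e in ggm_edges for g in e} | set(prizes.index))
    missing = [g for g in genes if g not in prizes.index]
    if missing:
        raise ValueError(f"gene(s) absent from prize vector: {missing[:5]}")

    lookup: dict[frozenset, dict[str, float]] = {}
    if string_scores is not None:
        channel_cols = [c for c in string_scores.columns if c not in ("node_a", "node_b")]
        for row in string_scores.itertuples(index=False):
            key = frozenset((row.node_a, row.node_b))
            lookup[key] = {
                c: getattr(row, c) for c in channel_cols if getattr(row, c) > 0
            }

    G = nx.Graph(prior=p)
    for g in prizes.index:
        G.add_node(g, prize=float(prizes[g]))
    for a, b in ggm_edges:
        channels = dict(lookup.get(frozenset((a, b)), {}))
        if not channels:
            logger.info("edge (%s, %s) has no database entry; local channel only", a, b)
        key = (a, b) if (a, b) in local_correlations else (b, a)
        if key in local_correlations:
            channels["local_correlation"] = abs(float(local_correlations[key]))
        if not channels:
            raise ValueError(f"edge ({a}, {b}) carries no evidence channel")
        S = combine_evidence(channels.values(), p)
        G.add_edge(a, b, channels=channels, score=S, cost=1.0 - S)
    return G


def _mst_cost(G: nx.Graph, nodes: tuple) -> float | None:
    """Cost of the cheapest spanning tree of the induced subgraph, or None
    if the subgraph is disconnected."""
    sub = G.subgraph(nodes)
    if not nx.is_connected(sub):
        return None
    return sum(d["cost"] for _, _, d in nx.minimum_spanning_edges(sub, weight="cost"))


def _solve_exact(G: nx.Graph) -> Subnetwork:
    nodes = sorted(G.nodes)
    best_obj = np.inf
    best_set: tuple | None = None
    # singletons first (always feasible), then growing subsets
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            if r == 1:
                cost = 0.0
            else:
                cost = _mst_cost(G, subset)
                if cost is None:
                    continue
            obj = cost - sum(G.nodes[v]["prize"] for v in subset)
            # deterministic tie-break: lexicographically smallest node set
            if obj < best_obj - 1e-12 or (
                abs(obj - best_obj) <= 1e-12 and (best_set is None or subset < best_set)
            ):
                best_obj = obj
                best_set = subset
    assert best_set is not None
    edges = (
        [
            (u, v)
            for u, v, _ in nx.minimum_spanning_edges(G.subgraph(best_set), weight="cost")
        ]
        if len(best_set) > 1
        else []
    )
    return Subnetwork(list(best_set), [tuple(sorted(e)) for e in edges], float(best_obj))


def _strong_prune(tree: nx.Graph, root) -> tuple[float, set]:
    """Optimal prize-collecting subtree of ``tree`` containing ``root``.

    Dynamic program over the rooted tree: a child subtree is kept iff its
    net value exceeds the cost of the connecting edge.
    """
    value = {}
    keep_nodes = {}
    for v in reversed(list(nx.dfs_preorder_nodes(tree, root))):
        val = tree.nodes[v]["prize"]
        kept = {v}
        for c in tree.neighbors(v):
            if c in value:  # child (already processed in reverse preorder)
                gain = value[c] - tree.edges[v, c]["cost"]
                if gain > 0:
                    val += gain
                    kept |= keep_nodes[c]
        value[v] = val
        keep_nodes[v] = kept
    return value[root], keep_nodes[root]


def _solve_heuristic(G: nx.Graph) -> Subnetwork:
    best_obj = np.inf
    best_nodes: set = set()
    for comp in nx.connected_components(G):
        sub = G.subgraph(comp)
        mst = nx.minimum_spanning_tree(sub, weight="cost")
        for root in sorted(mst.nodes):
            net, nodes = _strong_prune(mst, root)
            if -net < best_obj - 1e-12:
                best_obj = -net
                best_nodes = nodes
    # singleton fallback (also covers isolated nodes)
    top = max(sorted(G.nodes), key=lambda v: G.nodes[v]["prize"])
    if -G.nodes[top]["prize"] < best_obj - 1e-12:
        best_obj = -G.nodes[top]["prize"]
        best_nodes = {top}
    if len(best_nodes) > 1:
        edges = [
            tuple(sorted((u, v)))
            for u, v, _ in nx.minimum_spanning_edges(
                G.subgraph(best_nodes), weight="cost"
            )
        ]
    else:
        edges = []
    return Subnetwork(sorted(best_nodes), edges, float(best_obj))


def solve_pcst(G: nx.Graph, exact_max_nodes: int = EXACT_MAX_NODES) -> Subnetwork:
    """Minimize  sum cost(E') - sum prize(V')  over connected subgraphs.

    Exact (subset enumeration + MST) up to ``exact_max_nodes`` nodes;
    MST + strong pruning from every root beyond that. The solution is
    verified connected before returning.
    """
    if G.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if G.number_of_nodes() <= exact_max_nodes:
        sol = _solve_exact(G)
    else:
        sol = _solve_heuristic(G)
    sub = nx.Graph()
    sub.add_nodes_from(sol.nodes)
    sub.add_edges_from(sol.edges)
    if not nx.is_connected(sub):
        raise AssertionError("PCST solution is not connected")
    return sol


def write_sif(G: nx.Graph, path: str | Path, interaction: str = "pp") -> None:
    with open(path, "w") as fh:
        isolated = [n for n in G.nodes if G.degree(n) == 0]
        for u, v in sorted(tuple(sorted(e)) for e in G.edges):
            fh.write(f"{u}\t{interaction}\t{v}\n")
        for n in sorted(isolated):
            fh.write(f"{n}\n")


def write_graphml(G: nx.Graph, path: str | Path) -> None:
    out = nx.Graph(**{k: v for k, v in G.graph.items()})
    for n, d in G.nodes(data=True):
        out.add_node(n, **{k: v for k, v in d.items() if np.isscalar(v)})
    for u, v, d in G.edges(data=True):
        out.add_edge(u, v, **{k: val for k, val in d.items() if np.isscalar(val)})
    nx.write_graphml(out, path)
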