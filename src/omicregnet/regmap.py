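"""Regulator-to-gene edge resolution and module merging.

SPLS-selected regulators are linked to individual module genes by Pearson
correlation (two-sided t-test, raw p <= 0.05 — no multiplicity correction at
this stage, matching the pipeline's design). miRNA edges must additionally
be negative and annotated in a miRNA-target database; methylation edges must
be cis (the site is annotated to the very gene it is tested against). Module
networks plus their regulator edges are merged into one global regulatory
network with shared-regulator bookkeeping.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_P_CUTOFF = 0.05


def correlate_pairs(
    regulators: pd.DataFrame, module_expr: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r and two-sided p for every regulator x module-gene pair.

    Both inputs are samples x features with identical sample order, n >= 4.
    p comes from t = r * sqrt((n - 2)/(1 - r^2)) on n - 2 df. Zero-variance
    vectors are skipped with a warning.
    """
    if len(regulators) != len(module_expr):
        raise ValueError("sample counts differ")
    n = len(regulators)
    if n < 4:
        raise ValueError("need at least 4 samples")
    R = regulators.to_numpy(dtype=float)
    Y = module_expr.to_numpy(dtype=float)
    r_sd = R.std(axis=0, ddof=1)
    y_sd = Y.std(axis=0, ddof=1)
    ok_r = r_sd > 1e-12
    ok_y = y_sd > 1e-12
    if not ok_r.all() or not ok_y.all():
        logger.warning(
            "skipping %d zero-variance regulator(s) and %d gene(s)",
            int((~ok_r).sum()), int((~ok_y).sum()),
        )
    Rc = (R - R.mean(axis=0)) / np.where(ok_r, r_sd, 1.0)
    Yc = (Y - Y.mean(axis=0)) / np.where(ok_y, y_sd, 1.0)
    cor = (Rc.T @ Yc) / (n - 1)
    cor = np.clip(cor, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cor * np.sqrt((n - 2) / (1.0 - cor**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(cor) >= 1.0, 0.0, p)
    rows = []
    for i, reg in enumerate(regulators.columns):
        if not ok_r[i]:
            continue
        for j, gene in enumerate(module_expr.columns):
            if not ok_y[j]:
                continue
            rows.append((reg, gene, cor[i, j], p[i, j]))
    return pd.DataFrame(rows, columns=["regulator", "gene", "r", "p"])


def read_target_list(path: str | Path) -> pd.DataFrame:
    """TSV of (mirna_id, gene_symbol, source); any single database hit counts."""
    df = pd.read_csv(path, sep="\t")
    df = df.rename(
        columns=dict(zip(df.columns[:2], ["mirna_id", "gene_symbol"]))
    )
    return df


def read_site_map(path: str | Path) -> pd.Series:
    """TSV of (site_id, gene_symbol[, chrom, pos]); returns site -> gene."""
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns=dict(zip(df.columns[:2], ["site_id", "gene_symbol"])))
    return df.set_index("site_id")["gene_symbol"]


def filter_mirna_edges(
    pairs: pd.DataFrame,
    target_list: pd.DataFrame,
    p_cutoff: float = DEFAULT_P_CUTOFF,
) -> pd.DataFrame:
    """Keep (miRNA, gene) pairs with p <= cutoff AND r < 0 AND a database hit."""
    annotated = {
        (m, g)
        for m, g in zip(target_list["mirna_id"], target_list["gene_symbol"])
    }
    hit = np.array(
        [(m, g) in annotated for m, g in zip(pairs["regulator"], pairs["gene"])],
        dtype=bool,
    )
    mask = (pairs["p"] <= p_cutoff) & (pairs["r"] < 0) & hit
    out = pairs.loc[mask].copy()
    out["edge_type"] = "miRNA"
    out["annotated"] = True
    return out.reset_index(drop=True)


def annotate_cis(
    pairs: pd.DataFrame,
    site_gene_map: pd.Series,
    p_cutoff: float = DEFAULT_P_CUTOFF,
) -> pd.DataFrame:
    """Keep (site, gene) pairs that are significant AND cis (site maps to the
    same gene). The correlation sign is reported, not filtered. Unmapped
    sites are excluded with a log message."""
    unmapped = sorted(set(pairs["regulator"]) - set(site_gene_map.index))
    if unmapped:
        logger.info("excluding %d unmapped site(s): %s", len(unmapped), unmapped[:5])
    mapped = pairs["regulator"].map(site_gene_map)
    mask = (pairs["p"] <= p_cutoff) & (mapped == pairs["gene"]) & mapped.notna()
    out = pairs.loc[mask].copy()
    out["edge_type"] = "methylation"
    out["annotated"] = True
    return out.reset_index(drop=True)


def merge_modules(
    module_subnetworks: dict[object, nx.Graph],
    regulation_edges: dict[object, pd.DataFrame] | None = None,
) -> tuple[nx.Graph, pd.DataFrame]:
    """Union of module gene-gene subnetworks and their regulator edges.

    Returns the merged graph (node attribute ``modules`` = sorted module
    label list; ``node_type`` in {gene, miRNA, methylation}) and the
    regulator degree table sorted by descending degree, ties lexicographic.
    Idempotent and invariant to module ordering.
    """
    G = nx.Graph()
    for label in sorted(module_subnetworks, key=str):
        sub = module_subnetworks[label]
        for node in sub.nodes:
            _touch(G, node, label, "gene")
        for u, v in sub.edges:
            G.add_edge(u, v, edge_type="gene-gene")
    if regulation_edges:
        for label in sorted(regulation_edges, key=str):
            df = regulation_edges[label]
            for row in df.itertuples(index=False):
                _touch(G, row.regulator, label, row.edge_type)
                _touch(G, row.gene, label, "gene")
                G.add_edge(
                    row.regulator, row.gene, edge_type=row.edge_type, r=float(row.r)
                )
    for n in G.nodes:
        G.nodes[n]["modules"] = sorted(G.nodes[n]["modules"], key=str)
    regs = [
        n for n, d in G.nodes(data=True) if d["node_type"] in ("miRNA", "methylation")
    ]
    table = pd.DataFrame(
        {
            "regulator": regs,
            "type": [G.nodes[n]["node_type"] for n in regs],
            "degree": [G.degree(n) for n in regs],
            "modules": [",".join(map(str, G.nodes[n]["modules"])) for n in regs],
        }
    ).sort_values(["degree", "regulator"], ascending=[False, True], ignore_index=True)
    return G, table


def _touch(G: nx.Graph, node, module_label, node_type: str) -> None:
    if node not in G:
        G.add_node(node, modules=set(), node_type=node_type)
    G.nodes[node]["modules"] = set(G.nodes[node]["modules"]) | {module_label}
    if node_type != "gene":  # regulator typing wins over default
        G.nodes[node]["node_type"] = node_type


def write_regulation_map(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def write_merged_graphml(G: nx.Graph, path: str | Path) -> None:
    out = nx.Graph()
    for n, d in G.nodes(data=True):
        out.add_node(
            n,
            node_type=d.get("node_type", "gene"),
            modules=",".join(map(str, d.get("modules", []))),
        )
    for u, v, d in G.edges(data=True):
        out.add_edge(u, v, **{k: val for k, val in d.items() if np.isscalar(val)})
    nx.write_graphml(out, path)


def write_merged_sif(G: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v, d in sorted(G.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            fh.write(f"{u}\t{d.get('edge_type', 'pp')}\t{v}\n")
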