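"""In-memory end-to-end runs on synthetic data, with recovery metrics.

Shared by the test suite and the results-reproduction script: simulate one
dataset, run both pipeline stages against the planted ground truth, and
report what was recovered at each step.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import io as oio
from . import selection as sel
from . import coexpression as coex
from . import ggm
from . import evidence as ev
from . import spls as spls_mod
from . import regmap
from .simulate import SimulationConfig, simulate_dataset


def synthetic_end_to_end(
    seed: int,
    config: SimulationConfig | None = None,
    l1_ratio_grid=sel.DEFAULT_L1_RATIO_GRID,
    n_folds: int = 10,
    spls_K_grid=(1, 2, 3),
    spls_eta_grid=(0.3, 0.5, 0.7, 0.9),
    min_module_size: int = 15,
) -> dict:
    """Full two-stage run on one simulated dataset; returns recovery metrics.

    The SPLS grids are the pipeline defaults thinned to the resolution the
    synthetic problem sizes warrant; the selection grid is the full default
    (the ridge-leaning mixes matter for pulling whole correlated modules in).
    """
    cfg = config or SimulationConfig(seed=seed)
    cfg.seed = seed
    ds = simulate_dataset(cfg)
    truth = ds.truth

    # ---- stage 1 -----------------------------------------------------------
    surv = oio.filter_survival(ds.survival)
    common = oio.align_samples(ds.mrna, surv)
    mrna, surv = oio.apply_alignment(common, ds.mrna, surv)
    X = oio.standardize(mrna).samples_by_features()
    fit = sel.CoxElasticNetSelector(
        l1_ratio_grid=l1_ratio_grid, cv=n_folds, random_state=seed
    ).fit(X.to_numpy(dtype=float), surv)
    selected = sel.select_nonzero(fit, list(X.columns))

    metrics: dict = {
        "seed": seed,
        "n_selected_genes": len(selected),
        "gene_recovery": _recall(selected, [g for g, l in truth.module_labels.items() if l > 0]),
    }
    if len(selected) < min_module_size:
        metrics.update(module_ari=0.0, regulator_recovery=0.0)
        return metrics

    est = coex.CoexpressionModules(min_module_size=min_module_size).fit(
        X[selected].to_numpy(dtype=float)
    )
    true_labels = truth.module_labels.reindex(selected).fillna(0).to_numpy()
    metrics["module_ari"] = float(adjusted_rand_score(true_labels, est.labels_))
    metrics["n_modules"] = len(est.modules_)
    metrics["soft_power"] = int(est.power_)

    prizes = sel.univariate_cox_prizes(X[selected], surv)
    string_scores = _string_frame(ds)

    subnets = {}
    trims = {}
    for lab, idx in est.modules_.items():
        genes = [selected[i] for i in idx]
        trimmer = ggm.GGMTrimmer().fit(X[genes].to_numpy(dtype=float))
        trims[lab] = trimmer.summary_.trimmed_percent
        kept = [(genes[i], genes[j]) for i, j in trimmer.kept_edges_]
        cors = X[genes].corr()
        local = {(a, b): float(cors.loc[a, b]) for a, b in kept}
        G = ev.build_evidence_graph(kept, local, prizes.loc[genes], string_scores)
        solution = ev.solve_pcst(G)
        subnets[lab] = solution
    metrics["trimmed_percent"] = trims
    metrics["pcst_nodes"] = {lab: len(s.nodes) for lab, s in subnets.items()}
    metrics["pcst_objective"] = {lab: s.objective for lab, s in subnets.items()}

    # ---- stage 2 -----------------------------------------------------------
    s2_common = oio.align_samples(ds.mrna, ds.mirna, ds.methylation, surv)
    meth2 = oio.standardize(ds.methylation.subset_samples(s2_common))
    mir2 = oio.standardize(ds.mirna.subset_samples(s2_common))
    surv2 = surv.subset_samples(s2_common)
    try:
        cands = spls_mod.screen_regulators(
            meth2, mir2, surv2, cv_seed=seed,
            l1_ratio_grid=l1_ratio_grid, n_folds=n_folds,
        )
    except ValueError:
        metrics["regulator_recovery"] = 0.0
        return metrics

    planted = sorted(truth.mirna_targets) + sorted(truth.meth_sites)
    metrics["screen_recovery"] = _recall(cands.regulator_ids, planted)

    selected_union: set[str] = set()
    mirna_edges = []
    cis_edges = []
    targets = ds.target_list
    site_map = ds.site_map
    for lab, solution in subnets.items():
        genes = [g for g in solution.nodes]
        Y = X.loc[s2_common, genes]
        model, _ = spls_mod.fit_spls(
            Y, cands, K_grid=spls_K_grid, eta_grid=spls_eta_grid,
            n_folds=n_folds, seed=seed,
        )
        chosen = spls_mod.selected_regulators(model, cands.regulator_ids)
        selected_union |= set(chosen)
        if not chosen:
            continue
        pairs = regmap.correlate_pairs(cands.matrix.loc[s2_common, chosen], Y)
        mir_pairs = pairs[pairs["regulator"].map(cands.types) == "miRNA"]
        meth_pairs = pairs[pairs["regulator"].map(cands.types) == "methylation"]
        mirna_edges.append(regmap.filter_mirna_edges(mir_pairs, targets))
        cis_edges.append(regmap.annotate_cis(meth_pairs, site_map))

    metrics["regulator_recovery"] = _recall(selected_union, planted)
    metrics["n_mirna_edges"] = int(sum(len(df) for df in mirna_edges))
    metrics["n_cis_edges"] = int(sum(len(df) for df in cis_edges))
    return metrics


def _recall(found, truth_items) -> float:
    truth_items = list(truth_items)
    if not truth_items:
        return float("nan")
    found = set(found)
    return float(sum(t in found for t in truth_items)) / len(truth_items)


def _string_frame(ds) -> pd.DataFrame:
    df = ds.string_scores.copy()
    out = df.rename(columns={"protein1": "node_a", "protein2": "node_b"})
    for c in out.columns:
        if c not in ("node_a", "node_b"):
            out[c] = out[c].astype(float) / 1000.0
    return out


def median_metrics(per_seed: list[dict], keys: tuple[str, ...]) -> dict:
    """Median of scalar metrics across seeds (NaN-safe)."""
    out = {}
    for k in keys:
        vals = [m[k] for m in per_seed if k in m and np.isscalar(m[k])]
        out[k] = float(np.median(vals)) if vals else float("nan")
    return out
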