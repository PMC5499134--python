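"""Synthetic multi-omics data with planted ground truth.

The generator mirrors the statistical structure the pipeline assumes:

* gene expression from latent per-module factors (block-correlated within
  modules, independent between), plus independent null genes;
* right-censored survival from an exponential-baseline Cox model whose
  log-hazard is linear in the module factors; all times are shifted so the
  minimum is 30 days (the short-survival filter is a no-op unless
  contamination is requested explicitly);
* planted miRNAs anti-correlated with their target module (hence both
  hazard-linked and negatively correlated with their annotated targets),
  among independent null miRNAs;
* planted cis methylation sites anti-correlated with their own gene;
* database-style channel subscores drawn Beta-high on true within-module
  edges and Beta-low on false pairs.

Effect-size fields are expressed directly as target correlation magnitudes
so the generator's invariants are checkable on its output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import OmicsMatrix, SurvivalTable, write_omics_matrix, write_survival


@dataclass
class SimulationConfig:
    """Knobs of the generator; the defaults define the standard test regime.

    ``mirna_effect`` and ``meth_effect`` are the intended |Pearson r| between
    a planted regulator and its target gene(s); ``within_cor`` the pairwise
    correlation of genes sharing a module.
    """

    n_samples: int = 300
    module_sizes: tuple[int, ...] = (20, 20)
    within_cor: float = 0.8
    n_null_genes: int = 100
    module_hazard_effects: tuple[float, ...] = (1.0, -1.0)
    censoring_frac: float = 0.3
    baseline_scale_days: float = 600.0
    min_day_shift: float = 30.0
    contaminate_sub30: int = 0  # samples given times < 30 d, for filter tests
    n_mirna: int = 60
    n_planted_mirna: int = 5
    mirna_targets_each: int = 3
    mirna_effect: float = 0.5
    n_meth: int = 80
    n_planted_meth: int = 5
    meth_effect: float = 0.5
    string_true_beta: tuple[float, float] = (8.0, 2.0)
    string_false_beta: tuple[float, float] = (2.0, 8.0)
    string_channels: tuple[str, ...] = ("experimental", "database")
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.within_cor < 1.0:
            raise ValueError("within_cor must be in (0, 1)")
        for name in ("censoring_frac",):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        for name in ("mirna_effect", "meth_effect"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.mirna_effect**2 > self.within_cor:
            # regulator-factor loading = effect / sqrt(within_cor) must be <= 1
            raise ValueError("mirna_effect^2 must not exceed within_cor")
        if len(self.module_hazard_effects) != len(self.module_sizes):
            raise ValueError("one hazard effect per module required")


@dataclass
class GroundTruth:
    """What was planted: used by recovery tests, never by the pipeline."""

    module_labels: pd.Series  # gene -> module index (0 = null gene)
    mirna_targets: dict[str, list[str]]
    meth_sites: dict[str, str]  # site -> its cis gene
    hazard_linked: list[str]
    true_edges: list[tuple[str, str]]


@dataclass
class SyntheticDataset:
    mrna: OmicsMatrix
    mirna: OmicsMatrix
    methylation: OmicsMatrix
    survival: SurvivalTable
    string_scores: pd.DataFrame
    target_list: pd.DataFrame
    site_map: pd.Series
    truth: GroundTruth
    config: SimulationConfig


def _censor_scale(t_uncens: np.ndarray, u: np.ndarray, frac: float) -> float:
    """Bisection for the exponential censoring scale giving the target
    censoring fraction on this sample (C = -scale * log(u))."""
    if frac <= 0:
        return np.inf
    lo, hi = 1e-3, 1e6
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        achieved = float(np.mean(-mid * np.log(u) < t_uncens))
        if achieved > frac:
            lo = mid  # too much censoring -> larger scale
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw one complete multi-omics dataset; the seed fully determines it."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"S{i:04d}" for i in range(n)]
    w = config.within_cor
    n_mod = len(config.module_sizes)

    factors = rng.standard_normal((n, n_mod))

    # --- mRNA ---------------------------------------------------------------
    gene_cols = {}
    labels = {}
    gid = 0
    for m, size in enumerate(config.module_sizes):
        for _ in range(size):
            name = f"g{gid:04d}"
            gid += 1
            eps = rng.standard_normal(n)
            gene_cols[name] = np.sqrt(w) * factors[:, m] + np.sqrt(1 - w) * eps
            labels[name] = m + 1
    for _ in range(config.n_null_genes):
        name = f"g{gid:04d}"
        gid += 1
        gene_cols[name] = rng.standard_normal(n)
        labels[name] = 0
    genes = pd.DataFrame(gene_cols, index=samples)
    module_labels = pd.Series(labels, name="module")

    # --- miRNA (planted ones anti-load on a module factor) ------------------
    mir_cols = {}
    mirna_targets: dict[str, list[str]] = {}
    rho_r = config.mirna_effect / np.sqrt(w)
    module_members = {
        m + 1: [g for g, lab in labels.items() if lab == m + 1] for m in range(n_mod)
    }
    for j in range(config.n_mirna):
        name = f"mir{j:03d}"
        if j < config.n_planted_mirna and n_mod > 0:
            m = (j % n_mod) + 1
            eps = rng.standard_normal(n)
            mir_cols[name] = -rho_r * factors[:, m - 1] + np.sqrt(1 - rho_r**2) * eps
            k = min(config.mirna_targets_each, len(module_members[m]))
            start = (j * config.mirna_targets_each) % max(len(module_members[m]) - k + 1, 1)
            mirna_targets[name] = module_members[m][start : start + k]
        else:
            mir_cols[name] = rng.standard_normal(n)
    mirnas = pd.DataFrame(mir_cols, index=samples)

    # --- methylation (planted cis sites anti-correlated with their gene) ----
    meth_cols = {}
    meth_sites: dict[str, str] = {}
    module_genes_flat = [g for g, lab in labels.items() if lab > 0]
    for j in range(config.n_meth):
        name = f"cg{j:04d}"
        if j < config.n_planted_meth and module_genes_flat:
            # alternate target modules so cis sites are not mutually redundant
            m = (j % n_mod) + 1
            members = module_members[m]
            gene = members[(2 * (j // n_mod) + 1) % len(members)]
            eps = rng.standard_normal(n)
            c = config.meth_effect
            meth_cols[name] = -c * gene_cols[gene] + np.sqrt(1 - c**2) * eps
            meth_sites[name] = gene
        else:
            meth_cols[name] = rng.standard_normal(n)
    meth = pd.DataFrame(meth_cols, index=samples)

    # --- survival ------------------------------------------------------------
    eta = factors @ np.asarray(config.module_hazard_effects, dtype=float)
    hazard = np.exp(eta)
    t_uncens = rng.exponential(1.0, n) * config.baseline_scale_days / hazard
    u = rng.uniform(size=n)
    scale_c = _censor_scale(t_uncens, u, config.censoring_frac)
    c_times = -scale_c * np.log(u) if np.isfinite(scale_c) else np.full(n, np.inf)
    time = np.minimum(t_uncens, c_times) + config.min_day_shift
    event = (t_uncens <= c_times).astype(int)
    if config.contaminate_sub30 > 0:
        idx = rng.choice(n, size=config.contaminate_sub30, replace=False)
        time[idx] = rng.uniform(1.0, 29.0, size=config.contaminate_sub30)
        event[idx] = 1
    survival = SurvivalTable(
        pd.DataFrame({"time": time, "event": event}, index=pd.Index(samples))
    )

    # --- database-style evidence ---------------------------------------------
    true_edges = []
    for members in module_members.values():
        for a_i in range(len(members)):
            for b_i in range(a_i + 1, len(members)):
                true_edges.append((members[a_i], members[b_i]))
    all_genes = list(genes.columns)
    false_edges = set()
    attempts = 0
    while len(false_edges) < len(true_edges) and attempts < 20 * len(true_edges) + 100:
        a, b = rng.choice(len(all_genes), size=2, replace=False)
        pair = (all_genes[min(a, b)], all_genes[max(a, b)])
        if module_labels[pair[0]] == 0 or module_labels[pair[0]] != module_labels[pair[1]]:
            false_edges.add(pair)
        attempts += 1
    rows = []
    at, bt = config.string_true_beta
    af, bf = config.string_false_beta
    for pair_list, (alpha, beta) in ((true_edges, (at, bt)), (sorted(false_edges), (af, bf))):
        for a, b in pair_list:
            rec = {"protein1": a, "protein2": b}
            for ch in config.string_channels:
                rec[ch] = int(round(1000 * rng.beta(alpha, beta)))
            rows.append(rec)
    string_scores = pd.DataFrame(rows)

    target_rows = [
        {"mirna_id": m, "gene_symbol": g, "source": "synthesisDB"}
        for m, targets in mirna_targets.items()
        for g in targets
    ]
    target_list = pd.DataFrame(
        target_rows, columns=["mirna_id", "gene_symbol", "source"]
    )
    site_rows = {s: g for s, g in meth_sites.items()}
    # null sites map to arbitrary genes so the annotation file covers them
    for j in range(config.n_planted_meth, config.n_meth):
        site_rows[f"cg{j:04d}"] = all_genes[j % len(all_genes)]
    site_map = pd.Series(site_rows, name="gene_symbol")

    hazard_linked = (
        module_genes_flat
        + sorted(mirna_targets)
        + sorted(meth_sites)
    )
    truth = GroundTruth(
        module_labels=module_labels,
        mirna_targets=mirna_targets,
        meth_sites=meth_sites,
        hazard_linked=hazard_linked,
        true_edges=true_edges,
    )
    return SyntheticDataset(
        mrna=OmicsMatrix(genes.T, "mRNA"),
        mirna=OmicsMatrix(mirnas.T, "miRNA"),
        methylation=OmicsMatrix(meth.T, "methylation"),
        survival=survival,
        string_scores=string_scores,
        target_list=target_list,
        site_map=site_map,
        truth=truth,
        config=config,
    )


def export_fixture(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write every pipeline input format into ``directory``; returns the paths."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "mrna": d / "mrna.tsv",
        "mirna": d / "mirna.tsv",
        "methylation": d / "methylation.tsv",
        "survival": d / "survival.tsv",
        "string": d / "string_links.txt",
        "targets": d / "mirna_targets.tsv",
        "site_map": d / "site_map.tsv",
        "truth": d / "ground_truth.json",
    }
    write_omics_matrix(dataset.mrna, paths["mrna"])
    write_omics_matrix(dataset.mirna, paths["mirna"])
    write_omics_matrix(dataset.methylation, paths["methylation"])
    write_survival(dataset.survival, paths["survival"])
    dataset.string_scores.to_csv(paths["string"], sep="\t", index=False)
    dataset.target_list.to_csv(paths["targets"], sep="\t", index=False)
    site_df = dataset.site_map.rename_axis("site_id").reset_index()
    site_df.to_csv(paths["site_map"], sep="\t", index=False)
    import json

    truth = dataset.truth
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "module_labels": truth.module_labels.to_dict(),
                "mirna_targets": truth.mirna_targets,
                "meth_sites": truth.meth_sites,
                "hazard_linked": truth.hazard_linked,
                "true_edges": [list(e) for e in truth.true_edges],
                "config": {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in asdict(dataset.config).items()
                },
            },
            fh,
            indent=1,
        )
    return paths
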