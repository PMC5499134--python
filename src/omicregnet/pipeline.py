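"""Two-stage pipeline orchestration.

Stage 1: elastic-net Cox gene selection -> coexpression modules -> GGM
trimming -> evidence-weighted prize-collecting Steiner refinement.
Stage 2: regulator screening (methylation + miRNA) -> per-module SPLS ->
correlation/sign/annotation filtering -> merged global regulatory network.

Every step reads its inputs from and writes its artifacts to a run
directory, so the CLI subcommands can execute steps independently; a
manifest records completed steps with input checksums, making re-runs
no-ops unless inputs changed or ``force`` is set.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
import yaml

from . import io as oio
from . import selection as sel
from . import coexpression as coex
from . import ggm
from . import evidence as ev
from . import spls as spls_mod
from . import regmap

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths and tunables. Defaults follow the method's stated values:
    30-day survival filter, minimum module size 15, FDR 0.05 for partial
    correlations, raw p <= 0.05 for regulator-gene correlations, interaction
    prior 0.063, 10 CV folds."""

    mrna: str = ""
    mirna: str = ""
    methylation: str = ""
    survival: str = ""
    string_links: str = ""
    mirna_targets: str = ""
    site_map: str = ""

    min_survival_days: float = 30.0
    min_module_size: int = 15
    fdr: float = 0.05
    p_cutoff: float = 0.05
    prior: float = 0.063
    n_folds: int = 10
    l1_ratio_grid: tuple = sel.DEFAULT_L1_RATIO_GRID
    soft_power: int | None = None
    spls_K_grid: tuple = spls_mod.DEFAULT_K_GRID
    spls_eta_grid: tuple = spls_mod.DEFAULT_ETA_GRID
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("l1_ratio_grid", "spls_K_grid", "spls_eta_grid"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for k, v in data.items():
            if isinstance(v, tuple):
                data[k] = [float(x) if isinstance(x, (np.floating, float)) else x for x in v]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def seed_for(self, stage: str) -> int:
        """Named substream: stable per-stage seed derived from the top seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    """Step-completion record with input checksums."""

    def __init__(self, outdir: Path):
        self.path = Path(outdir) / "manifest.json"
        self.data = {"steps": {}}
        if self.path.exists():
            self.data = json.loads(self.path.read_text())

    def is_done(self, step: str, inputs: list[str | Path]) -> bool:
        rec = self.data["steps"].get(step)
        if rec is None:
            return False
        sums = {str(p): _checksum(p) for p in inputs if p and Path(p).exists()}
        return rec.get("checksums") == sums

    def mark(self, step: str, inputs: list[str | Path], outputs: list[str | Path]) -> None:
        self.data["steps"][step] = {
            "checksums": {str(p): _checksum(p) for p in inputs if p and Path(p).exists()},
            "outputs": [str(p) for p in outputs],
        }
        self.path.write_text(json.dumps(self.data, indent=1))


def _load_expr_cache(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def step_select(cfg: PipelineConfig, outdir: str | Path, force: bool = False) -> None:
    """Load, filter, align, standardize, select genes, compute prizes."""
    out = Path(outdir) / "stage1"
    out.mkdir(parents=True, exist_ok=True)
    man = Manifest(Path(outdir))
    inputs = [cfg.mrna, cfg.survival]
    if man.is_done("select", inputs) and not force:
        logger.info("select: up to date, skipping")
        return
    mrna = oio.read_omics_matrix(cfg.mrna, "mRNA")
    surv = oio.filter_survival(oio.read_survival(cfg.survival), cfg.min_survival_days)
    common = oio.align_samples(mrna, surv)
    mrna, surv = oio.apply_alignment(common, mrna, surv)
    mrna = oio.standardize(oio.drop_zero_variance(mrna))
    X = mrna.samples_by_features()
    fit = sel.fit_elastic_net_cox(
        X, surv, l1_ratio_grid=cfg.l1_ratio_grid, n_folds=cfg.n_folds,
        seed=cfg.seed_for("select"),
    )
    chosen = sel.select_nonzero(fit, list(X.columns))
    pd.DataFrame(
        {"feature_id": list(X.columns), "coefficient": fit.coef_}
    ).query("coefficient != 0").to_csv(out / "selected_genes.tsv", sep="\t", index=False)
    fit.cv_results_.to_csv(out / "cv_curve.tsv", sep="\t", index=False)
    X[chosen].to_csv(out / "expr_selected.tsv", sep="\t", index_label="sample_id")
    oio.write_survival(surv, out / "survival_filtered.tsv")
    if chosen:
        prizes = sel.univariate_cox_prizes(X[chosen], surv)
    else:
        prizes = pd.Series(dtype=float, name="prize")
        logger.warning("no genes selected; downstream stages will be empty")
    prizes.rename_axis("gene_id").to_frame().to_csv(out / "prizes.tsv", sep="\t")
    man.mark("select", inputs, [out / "selected_genes.tsv"])


def step_modules(cfg: PipelineConfig, outdir: str | Path, force: bool = False) -> None:
    out = Path(outdir) / "stage1"
    man = Manifest(Path(outdir))
    inputs = [out / "expr_selected.tsv"]
    if man.is_done("modules", inputs) and not force:
        logger.info("modules: up to date, skipping")
        return
    expr = _load_expr_cache(out / "expr_selected.tsv")
    if expr.shape[1] == 0:
        pd.DataFrame(columns=["gene_id", "module_label"]).to_csv(
            out / "module_assignment.tsv", sep="\t", index=False
        )
        man.mark("modules", inputs, [out / "module_assignment.tsv"])
        logger.warning("zero selected genes: zero modules")
        return
    est = coex.CoexpressionModules(
        power=cfg.soft_power, min_module_size=cfg.min_module_size
    ).fit(expr.to_numpy(dtype=float))
    pd.DataFrame(
        {"gene_id": list(expr.columns), "module_label": est.labels_}
    ).to_csv(out / "module_assignment.tsv", sep="\t", index=False)
    # dendrogram export for inspection
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform

    diss = 1.0 - est.tom_
    np.fill_diagonal(diss, 0.0)
    Z = hierarchy.linkage(squareform(diss, checks=False), method="average")
    (out / "dendrogram.newick").write_text(
        coex.linkage_to_newick(Z, list(expr.columns))
    )
    with open(out / "modules_meta.json", "w") as fh:
        json.dump({"power": int(est.power_),
                   "n_modules": len(est.modules_),
                   "grey_pct": coex.grey_percentage(
                       int((est.labels_ == 0).sum()), len(est.labels_))}, fh)
    man.mark("modules", inputs, [out / "module_assignment.tsv"])


def _module_gene_sets(out: Path) -> dict[int, list[str]]:
    assign = pd.read_csv(out / "module_assignment.tsv", sep="\t")
    return {
        int(lab): grp["gene_id"].tolist()
        for lab, grp in assign.groupby("module_label")
        if lab != 0
    }


def step_trim(cfg: PipelineConfig, outdir: str | Path, force: bool = False) -> None:
    out = Path(outdir) / "stage1"
    man = Manifest(Path(outdir))
    inputs = [out / "module_assignment.tsv"]
    if man.is_done("trim", inputs) and not force:
        logger.info("trim: up to date, skipping")
        return
    expr = _load_expr_cache(out / "expr_selected.tsv")
    summaries = []
    for lab, genes in _module_gene_sets(out).items():
        mdir = out / f"module_{lab}"
        mdir.mkdir(exist_ok=True)
        trimmer = ggm.GGMTrimmer(fdr=cfg.fdr).fit(expr[genes].to_numpy(dtype=float))
        trimmer.edge_table(genes).to_csv(mdir / "edges.tsv", sep="\t", index=False)
        s = trimmer.summary_
        summaries.append(
            {"module": lab, "size": s.module_size, "candidate_pairs": s.candidate_pairs,
             "kept_pairs": s.kept_pairs, "trimmed_percent": s.trimmed_percent,
             "shrinkage": trimmer.shrinkage_}
        )
    pd.DataFrame(summaries).to_csv(out / "trim_summary.tsv", sep="\t", index=False)
    man.mark("trim", inputs, [out / "trim_summary.tsv"])


def step_pcst(cfg: PipelineConfig, outdir: str | Path, force: bool = False) -> None:
    out = Path(outdir) / "stage1"
    man = Manifest(Path(outdir))
    inputs = [out / "trim_summary.tsv", out / "prizes.tsv"]
    if man.is_done("pcst", inputs) and not force:
        logger.info("pcst: up to date, skipping")
        return
    expr = _load_expr_cache(out / "expr_selected.tsv")
    prizes = pd.read_csv(out / "prizes.tsv", sep="\t", index_col=0)["prize"]
    string_scores = (
        ev.read_string_scores(cfg.string_links) if cfg.string_links else None
    )
    for lab, genes in _module_gene_sets(out).items():
        mdir = out / f"module_{lab}"
        edges = pd.read_csv(mdir / "edges.tsv", sep="\t")
        kept = [
            (str(r.gene_a), str(r.gene_b))
            for r in edges.itertuples(index=False) if r.kept
        ]
        cors = expr[genes].corr()
        local = {(a, b): float(cors.loc[a, b]) for a, b in kept}
        G = ev.build_evidence_graph(
            kept, local, prizes.loc[genes], string_scores, cfg.prior
        )
        solution = ev.solve_pcst(G)
        subG = nx.Graph()
        for v in solution.nodes:
            subG.add_node(v, prize=float(prizes[v]))
        for a, b in solution.edges:
            subG.add_edge(a, b, **{k: v for k, v in G.edges[a, b].items()
                                   if np.isscalar(v)})
        ev.write_sif(subG, mdir / "subnetwork.sif")
        ev.write_graphml(subG, mdir / "subnetwork.graphml")
        with open(mdir / "pcst.json", "w") as fh:
            json.dump({"nodes": [str(v) for v in solution.nodes],
                       "edges": [list(map(str, e)) for e in solution.edges],
                       "objective": solution.objective}, fh, indent=1)
    man.mark("pcst", inputs, [out / "trim_summary.tsv"])


def step_regulators(cfg: PipelineConfig, outdir: str | Path, force: bool = False) -> None:
    """Screen regulators and run SPLS per refined module."""
    out = Path(outdir)
    s1 = out / "stage1"
    s2 = out / "stage2"
    s2.mkdir(parents=True, exist_ok=True)
    man = Manifest(out)
    inputs = [cfg.methylation, cfg.mirna, cfg.survival, s1 / "module_assignment.tsv"]
    if man.is_done("regulators", inputs) and not force:
        logger.info("regulators: up to date, skipping")
        return
    meth = oio.read_omics_matrix(cfg.methylation, "methylation") if cfg.methylation else None
    mir = oio.read_omics_matrix(cfg.mirna, "miRNA") if cfg.mirna else None
    surv = oio.filter_survival(oio.read_survival(cfg.survival), cfg.min_survival_days)
    expr = _load_expr_cache(s1 / "expr_selected.tsv")

    layers = [m for m in (meth, mir) if m is not None]
    mrna_samples = set(expr.index)  # expr cache is samples x genes
    common = sorted(
        set.intersection(mrna_samples, set(surv.sample_ids),
                         *(set(m.sample_ids) for m in layers))
    )
    if not common:
        raise ValueError("empty stage-2 sample intersection")
    surv2 = surv.subset_samples(common)
    meth2 = (oio.standardize(oio.drop_zero_variance(meth.subset_samples(common)))
             if meth is not None else None)
    mir2 = (oio.standardize(oio.drop_zero_variance(mir.subset_samples(common)))
            if mir is not None else None)
    cands = spls_mod.screen_regulators(
        meth2, mir2, surv2, cv_seed=cfg.seed_for("screen"),
        l1_ratio_grid=cfg.l1_ratio_grid, n_folds=cfg.n_folds,
    )
    cands.types.rename_axis("regulator_id").rename("type").to_frame().to_csv(
        s2 / "screened_regulators.tsv", sep="\t"
    )
    cands.matrix.to_csv(s2 / "regulator_matrix.tsv", sep="\t", index_label="sample_id")

    for lab in _module_gene_sets(s1):
        mdir_s1 = s1 / f"module_{lab}"
        pcst = json.loads((mdir_s1 / "pcst.json").read_text())
        genes = pcst["nodes"]
        if not genes:
            continue
        mdir = s2 / f"module_{lab}"
        mdir.mkdir(exist_ok=True)
        Y = expr.loc[common, genes]
        model, cv_table = spls_mod.fit_spls(
            Y, cands, K_grid=cfg.spls_K_grid, eta_grid=cfg.spls_eta_grid,
            n_folds=cfg.n_folds, seed=cfg.seed_for(f"spls_{lab}"),
        )
        cv_table.to_csv(mdir / "spls_cv.tsv", sep="\t", index=False)
        chosen = spls_mod.selected_regulators(model, cands.regulator_ids)
        recs = []
        for k in range(model.n_components_):
            for i in model.selected_:
                w = model.x_weights_[i, k]
                if w != 0:
                    rid = cands.regulator_ids[i]
                    recs.append({"regulator_id": rid, "type": cands.types[rid],
                                 "component": k + 1, "loading": w})
        pd.DataFrame(recs, columns=["regulator_id", "type", "component", "loading"]
                     ).to_csv(mdir / "spls_loadings.tsv", sep="\t", index=False)
        with open(mdir / "selected_regulators.json", "w") as fh:
            json.dump(chosen, fh)
    man.mark("regulators", inputs, [s2 / "screened_regulators.tsv"])


def step_map(cfg: PipelineConfig, outdir: str | Path, force: bool = False) -> None:
    """Correlation + sign + annotation filtering, then the merged network."""
    out = Path(outdir)
    s1, s2 = out / "stage1", out / "stage2"
    man = Manifest(out)
    inputs = [s2 / "screened_regulators.tsv"]
    if man.is_done("map", inputs) and not force:
        logger.info("map: up to date, skipping")
        return
    expr = _load_expr_cache(s1 / "expr_selected.tsv")
    D = pd.read_csv(s2 / "regulator_matrix.tsv", sep="\t", index_col=0)
    types = pd.read_csv(s2 / "screened_regulators.tsv", sep="\t", index_col=0)["type"]
    targets = regmap.read_target_list(cfg.mirna_targets) if cfg.mirna_targets else None
    site_map = regmap.read_site_map(cfg.site_map) if cfg.site_map else None
    if targets is None:
        logger.warning("no miRNA target list supplied: miRNA branch skipped")
    if site_map is None:
        logger.warning("no site annotation supplied: cis methylation branch skipped")

    subnets: dict[int, nx.Graph] = {}
    reg_edges: dict[int, pd.DataFrame] = {}
    for lab in _module_gene_sets(s1):
        pcst = json.loads((s1 / f"module_{lab}" / "pcst.json").read_text())
        G = nx.Graph()
        G.add_nodes_from(pcst["nodes"])
        G.add_edges_from([tuple(e) for e in pcst["edges"]])
        subnets[lab] = G
        sel_path = s2 / f"module_{lab}" / "selected_regulators.json"
        if not sel_path.exists():
            logger.info("module %s: no SPLS output; omitted from merge", lab)
            continue
        chosen = json.loads(sel_path.read_text())
        if not chosen:
            logger.info("module %s: zero SPLS selections; omitted from merge", lab)
            continue
        pairs = regmap.correlate_pairs(
            D.loc[:, chosen], expr.loc[D.index, pcst["nodes"]]
        )
        frames = []
        mir_pairs = pairs[pairs["regulator"].map(types) == "miRNA"]
        meth_pairs = pairs[pairs["regulator"].map(types) == "methylation"]
        if targets is not None and len(mir_pairs):
            frames.append(regmap.filter_mirna_edges(mir_pairs, targets, cfg.p_cutoff))
        if site_map is not None and len(meth_pairs):
            frames.append(regmap.annotate_cis(meth_pairs, site_map, cfg.p_cutoff))
        kept = (pd.concat(frames, ignore_index=True) if frames
                else pd.DataFrame(columns=["regulator", "gene", "r", "p",
                                           "edge_type", "annotated"]))
        kept.to_csv(s2 / f"module_{lab}" / "regulation_map.tsv", sep="\t", index=False)
        if len(kept):
            reg_edges[lab] = kept
    merged, degree_table = regmap.merge_modules(subnets, reg_edges)
    regmap.write_merged_graphml(merged, s2 / "merged.graphml")
    regmap.write_merged_sif(merged, s2 / "merged.sif")
    degree_table.to_csv(s2 / "degree_table.tsv", sep="\t", index=False)
    summary = {
        "n_modules": len(subnets),
        "n_regulator_edges": int(sum(len(df) for df in reg_edges.values())),
        "n_nodes_merged": merged.number_of_nodes(),
        "n_edges_merged": merged.number_of_edges(),
    }
    (s2 / "run_summary.json").write_text(json.dumps(summary, indent=1))
    man.mark("map", inputs, [s2 / "merged.graphml"])


def run_stage1(cfg: PipelineConfig, outdir: str | Path, force: bool = False) -> None:
    Path(outdir).mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(Path(outdir) / "config_resolved.yaml")
    for step in (step_select, step_modules, step_trim, step_pcst):
        step(cfg, outdir, force=force)


def run_stage2(cfg: PipelineConfig, outdir: str | Path, force: bool = False) -> None:
    for step in (step_regulators, step_map):
        step(cfg, outdir, force=force)


def run_all(cfg: PipelineConfig, outdir: str | Path, force: bool = False) -> None:
    run_stage1(cfg, outdir, force=force)
    modules = _module_gene_sets(Path(outdir) / "stage1")
    if not modules:
        logger.warning("stage 1 produced zero modules; stage 2 skipped")
        (Path(outdir) / "run_summary.json").write_text(
            json.dumps({"n_modules": 0, "stage2": "skipped"}, indent=1)
        )
        return
    run_stage2(cfg, outdir, force=force)
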