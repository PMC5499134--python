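# omicregnet

Survival-guided multi-omics regulatory network inference for transcriptomic
and epigenomic data.

Given mRNA expression, miRNA expression, and DNA-methylation matrices plus a
right-censored survival table, `omicregnet` builds compact, evidence-backed
gene subnetworks associated with survival and then attaches the methylation
sites and miRNAs that regulate each subnetwork, merging everything into one
global regulatory network. It is aimed at cancer-genomics analysts working
with TCGA-style level-3 data, but ships a synthetic-data generator with
planted ground truth so the whole pipeline is testable without any download.

## The method

**Stage 1 — survival-associated coexpression subnetworks.**

1. *Selection.* Elastic-net penalized Cox regression
   `β̂ = argmin −ℓ(β)/n + λ(α‖β‖₁ + (1−α)/2 ‖β‖₂²)` picks genes jointly
   associated with survival; (λ, α) are chosen by event-stratified 10-fold
   cross-validated partial-likelihood deviance.
2. *Modules.* Weighted coexpression analysis on the selected genes:
   unsigned soft-threshold adjacency `a_ij = |cor(g_i,g_j)|^β`, topological
   overlap TOM, average-linkage clustering of 1 − TOM, and a tree cut with
   minimum module size 15; leftovers form the grey (unassigned) pool.
3. *Trimming.* Within each module, a Gaussian graphical model removes
   indirect links: partial correlations `γ̂_ij = −ω̂_ij/√(ω̂_ii ω̂_jj)` from
   the inverse covariance, Fisher-z tested, Benjamini–Hochberg FDR ≤ 0.05.
4. *Refinement.* Remaining edges get a confidence score combining database
   channels (STRING-style subscores) and the local |correlation| through a
   prior-corrected naive-Bayes rule
   `S = [1 − Π_j(1 − (S_j − p)/(1 − p))](1 − p) + p` with prior `p = 0.063`.
   With edge costs `c_e = 1 − S` and node prizes `b_i = |univariate Cox
   coefficient|`, a prize-collecting Steiner tree
   `min Σ_{e∈E′} c_e − Σ_{i∈V′} b_i` over connected subgraphs keeps only the
   best-supported backbone of each module.

**Stage 2 — module regulators.** Methylation sites and miRNAs are screened
by the same elastic-net Cox model; sparse partial least squares (SPLS) then
finds the regulators co-varying with each refined module
(`max cov(Yα, Dβ)` with unit-norm, L1-sparsified loadings, CV-chosen
sparsity and component count). Regulator→gene edges require Pearson
`p ≤ 0.05`; miRNA edges additionally need a negative correlation and a
miRNA-target database annotation, methylation edges must be *cis* (the site
is annotated to the very gene). Module networks are merged, flagging
regulators shared between modules.

## Worked example

Simulate a dataset with two planted 20-gene survival-linked modules, five
module-suppressing miRNAs and five cis-methylation sites among null
features, then run both stages:

```python
from omicregnet import (SimulationConfig, simulate_dataset, export_fixture,
                        PipelineConfig, run_all)

paths = export_fixture(simulate_dataset(SimulationConfig(seed=1)), "data")
cfg = PipelineConfig(
    mrna=str(paths["mrna"]), mirna=str(paths["mirna"]),
    methylation=str(paths["methylation"]), survival=str(paths["survival"]),
    string_links=str(paths["string"]), mirna_targets=str(paths["targets"]),
    site_map=str(paths["site_map"]), seed=1,
)
run_all(cfg, "run")
```

or from the shell: `omicregnet simulate --out data --seed 1` followed by
`omicregnet run-all --config cfg.yaml --out run`. Inspecting the artifacts:

```
soft power: 2 | modules: 2 | unassigned: 12.5%
 module  size  candidate_pairs  kept_pairs  trimmed_percent
      1    30              435           0           100.00
      2    26              325           1            99.69
module_1 pcst nodes: 1 edges: 0 objective: -0.695
module_2 pcst nodes: 2 edges: 1 objective: -1.306
stage 2: {'n_modules': 2, 'n_regulator_edges': 1, 'n_nodes_merged': 4, 'n_edges_merged': 2}
regulator  type  degree  modules
   mir003 miRNA       1        2
```

Both planted modules are found — module 1 contains all 20 genes of the
first true block and module 2 all 18 selected genes of the second, with 18
null genes absorbed and 12.5% of selected genes left grey. The trimming
percentages are
extreme here by construction: synthetic module genes share one latent
factor, so almost every pairwise correlation is indirect once the other
genes are conditioned on, and the GGM correctly trims it — real coexpression
modules retain far more direct structure. The surviving backbone carries the
largest univariate hazard prizes, and stage 2 attaches a planted miRNA
(`mir003`) to module 2 with a negative, database-annotated correlation.

Per-run outputs land under `run/stage1/` and `run/stage2/`: selected-gene
and CV tables, module assignments with a Newick dendrogram, per-module edge
tables with partial correlations and q-values, subnetworks in SIF/GraphML,
SPLS loadings, the regulation map, the merged network, and a resolved
config + manifest for reproducibility.

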