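# Methods

This note records the statistical model behind `omicregnet`, the defaults
and why they are what they are, the numerical choices that affect results,
what the synthetic-data generator does and does not emulate, and known
limitations.

## Data model and preprocessing

Omics matrices are feature × sample on disk (TSV, gzip accepted) and
sample × feature in regression code. Samples are aligned across layers by
exact ID intersection in sorted order. Patients with survival below 30 days
are excluded (the boundary value 30 is kept); the filter runs *before*
standardization so feature moments are computed on the retained samples
only. Every feature is then scaled to mean 0, SD 1 using the sample SD
(divisor n − 1); zero-variance features are an error rather than silently
dropped, with a `drop_zero_variance` helper for callers that want the drop.
Features with missing values are dropped at load time with a logged count —
level-3-style matrices are near-complete and imputation would be invisible
downstream.

## Stage 1

### Elastic-net Cox selection

The penalized objective follows the glmnet parameterization

    (1/n) · NLL_Breslow(β) + λ ( r‖β‖₁ + (1 − r)/2 ‖β‖₂² ),

with the coordinate-descent solve delegated to scikit-survival's Coxnet and
everything around it — grids, folds, scoring, tie-breaks — owned here. The
paper-style writing λ(α|β| + (1−α)β²) differs only by reparameterization of
the grid, so the same family of solutions is traversed.

* λ path: 100 points, log-spaced from the data-derived λ_max down to
  0.01·λ_max (per L1 ratio).
* L1-ratio grid: {0.1, …, 1.0}. The ridge-leaning mixes matter: they are
  what pulls whole correlated modules into the selection rather than one
  representative per module.
* CV: 10 folds, event-stratified so no fold is event-free, seeded. The fold
  assignment is a deterministic function of the seed, so a seed pins the
  chosen (λ, r).
* CV loss: van Houwelingen deviance — full-data minus training-fold Breslow
  negative log partial likelihood at the training solution. Scoring the
  small held-out fold alone proved noticeably noisier and produced unstable
  selection sizes.
* Ties in mean CV deviance break toward larger λ, then larger r (the
  sparser model).
* Convergence: tol 1e−7, max 10⁵ iterations.

Node prizes for the Steiner step are |β̂| from one-covariate Cox fits per
gene (Newton on the scalar Breslow partial likelihood, 50 iterations,
divergence → prize 0 with a warning).

### Coexpression modules

Unsigned network: `a_ij = |Pearson cor|^β`, diagonal 1. The soft power is
the smallest candidate in {1..20} whose scale-free topology fit reaches
R² ≥ 0.8 (signed by the regression slope so only decreasing degree
distributions count); if none qualifies the power with maximal fit is used,
with a warning. TOM is the standard overlap

    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

clustered by average linkage on 1 − TOM. The tree cut is the deterministic
"tree-shaped" variant: cut at 0.99 × the final merge height; branches with
fewer than 15 genes go to the grey pool. Modules are numbered by decreasing
size. No eigengene-based module merging is performed.

Known limitation: the scale-free criterion is ill-posed on block-structured
data (planted-module simulations, saturated correlation blocks). The
fallback can then return extreme powers, and at low powers weakly
correlated background genes may be absorbed into module clusters. On real
coexpression data the R² ≥ 0.8 branch almost always triggers; for
simulation studies of the cut itself, fix `power=6`.

### GGM trimming

Within a module of m genes, the sample covariance is inverted directly and

    γ̂_ij = −ω̂_ij / √(ω̂_ii ω̂_jj).

If the covariance is ill-conditioned (condition number > 1e10, or m ≥ n),
a Ledoit–Wolf analytically shrunk covariance is substituted and the
intensity recorded; otherwise results equal brute-force inversion to
1e−10. Significance uses Fisher's z with the conditioning-set correction,
z = atanh(γ̂)·√(n − k − 3), k = m − 2, two-sided normal p, followed by
Benjamini–Hochberg over all C(m, 2) within-module pairs at FDR 0.05. The
trimmed percentage is 100·(C(m,2) − kept)/C(m,2), reported to two decimals.

Because BH controls a *rate*, kept edge sets are expected to contain
occasional false pairs (≈ 0.3 per 45-pair module at strong signal); exact
recovery of a sparse truth on every run is not the procedure's guarantee
and is not what the tests assert — they check full recall of true edges
plus a realized false-discovery proportion within the nominal 0.05.

### Evidence combination and Steiner refinement

Each GGM-kept edge carries the STRING-style channel subscores found for the
pair (0–1000 integer files are rescaled; channel columns are autodetected,
including textmining) plus the local |Pearson correlation| as one more
channel. Channels combine by the prior-corrected naive-Bayes rule with
p = 0.063; each corrected term is clamped to [0, 1], so S ∈ [p, 1], a
single channel passes through unchanged, and adding evidence never lowers
S. Edges without any database entry fall back to the local channel alone
(logged). Database evidence for GGM-trimmed pairs is discarded — the edge
universe is the direct-interaction set, and no connector genes outside the
module are imported.

The unrooted prize-collecting Steiner problem, min Σc_e − Σb_i over
connected subgraphs, is solved exactly for ≤ 14 nodes by node-subset
enumeration (for a fixed node set the optimal edge set is a minimum
spanning tree), with lexicographically smallest node set on ties. Larger
instances use minimum-spanning-tree construction followed by strong pruning
evaluated from every root, plus the best single node as a fallback; the
objective of the returned solution is reported and its connectivity is
verified. Module sizes in this workflow are ≤ ~50 genes, so both paths are
effectively instantaneous. Prizes and costs are used on their natural
scales (|Cox coefficient| and 1 − S).

## Stage 2

Screening reuses the elastic-net Cox machinery per regulator layer
(methylation, miRNA) on the samples common to all layers plus survival; the
union of nonzero features, with type tags, forms the regulator matrix D.

SPLS couples D to a module's expression Y by maximizing cov(Yα, Dβ) with
unit-norm loadings. Each component takes the leading singular-vector pair
of the deflated cross-covariance DᵀY, soft-thresholds the regulator-side
direction at a fraction η of its largest |entry|, renormalizes, and
deflates both blocks on the score t = Dβ. η ∈ {0.1..0.9} and K ∈ {1..5}
(capped at the cross-covariance rank) are chosen by 10-fold CV mean squared
error of predicting Y from the latent scores, ties toward larger η then
smaller K. At η = 0 and K = 1 the directions equal the cross-covariance
SVD, which the tests pin at 1e−6. Selected regulators are those with a
nonzero loading in any component.

Regulator→gene edges use the Pearson t-test, t = r√((n−2)/(1−r²)) on n − 2
df, at raw p ≤ 0.05 — no multiplicity correction at this stage, by design;
an optional BH flag exists upstream of the writers but is off by default.
miRNA edges additionally require r < 0 and a hit in the miRNA-target list
(any single source database suffices). Methylation edges are kept only when
the site's annotated gene is the tested gene (cis, defined by the
annotation map rather than a genomic window); their sign is reported, not
filtered. Module subnetworks and regulator edges merge into one graph with
per-node module-membership sets and a degree-ranked regulator table
(ties lexicographic). The merge is idempotent and order-invariant.

## Pipeline and configuration

Defaults are the method's stated values: 30-day filter, minimum module size
15, FDR 0.05, correlation p ≤ 0.05, prior 0.063, 10 CV folds. All
randomness flows from one top-level seed through named per-stage
substreams (SHA-256 of "seed:stage", reduced below 2³¹). Every run writes a
resolved config copy; a manifest with input checksums makes re-runs of
completed steps no-ops unless inputs changed or `--force` is given. CLI
exit codes: 0 success, 2 input/validation error, 3 numerical failure.

## Synthetic data

The generator plants exactly the structure the pipeline assumes:

* **Genes.** Per-module latent factors f_m; a module gene is
  √w·f_m + √(1−w)·ε with w the target within-module correlation
  (default 0.8, two modules of 20, 100 null genes).
* **Survival.** Exponential baseline with log-hazard Σ_m β_m f_m
  (default β = (1, −1)), independent exponential censoring with its scale
  bisected to hit the target censoring fraction (default 0.3) on the drawn
  sample, and all times shifted +30 days so the short-survival filter is a
  no-op unless contamination is explicitly requested.
* **Regulators.** A planted miRNA loads −ρ on its module factor with
  ρ = effect/√w, so its correlation with annotated targets is −effect
  (default 0.5) and it is genuinely hazard-linked; a planted cis site is
  −effect·(its gene) plus noise (default 0.5). Nulls are independent
  Gaussians. Annotation files cover planted and null entries alike.
* **Evidence.** Channel subscores are Beta(8, 2)-distributed on true
  within-module pairs and Beta(2, 8) on an equal number of false pairs,
  written on the 0–1000 integer scale.

A seed fully determines the dataset, byte-identically through export.

What it does **not** emulate: bounded beta-value methylation
distributions, count noise, batch effects, heavy-tailed expression,
trans-regulation, or realistic interaction-database sparsity. Passing
recovery tests therefore demonstrates that the pipeline's inference is
correct under its own model assumptions — not that those assumptions hold
on any particular real cohort. One consequence worth knowing: because
module genes share a single factor, their pairwise links are almost
entirely indirect, and the GGM step legitimately trims nearly all of them;
refined synthetic subnetworks are therefore very small, unlike the
band-structured backbones seen in real modules.

## Problem sizes in the test and reproduction harness

The suite runs end-to-end recovery at n = 300 with two 20-gene modules
(medians over 10 seeds in the tests, 5 in the reproduction script),
chain-graph GGM recovery at n = 2000 over 50 replicates, solver-vs-
enumeration checks on 20 instances of ≤ 10 nodes, and 1000-replicate
calibration of the Pearson filter at n = 100 — sizes chosen so every
property is measured with useful precision on a single CPU in minutes.
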