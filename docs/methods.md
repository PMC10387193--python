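# Methods

## Model

Genes are nodes of an undirected weighted network with edge weights
`m_ij ∈ (0, 1]` and weighted degree `deg_i = Σ_j m_ij`. Each gene carries a
prior `s_j ≥ 0`, the absolute Pearson (point-biserial) correlation of its
expression with the binary phenotype. The ranking score is the fixed point of
the damped update

    r_j = (1 − d) s_j + d Σ_i m_ij r_i / deg_i ,

i.e. `r = (1 − d) s + d Pᵀ r` with `P = D⁻¹ M` (rows of isolated nodes zero).
Interpretation: a random surfer restarts into gene j with weight proportional
to nothing — unlike PageRank there is no teleport vector or final
normalization; the score is simply prior mass plus damped inflow from
neighbors, each neighbor spreading its current score across its incident
weight. Isolated genes therefore hold `(1 − d) s_j` plus inflow and leak
nothing back; total score mass is not conserved and only the induced ranking
is meaningful within one run.

**Convergence.** `P` is row-(sub)stochastic — every node spreads its score
across its incident weight, dangling rows are zero — so `‖Pᵀ‖₁ ≤ 1` and the
iteration error obeys `‖e^n‖₁ = d ‖Pᵀ e^{n−1}‖₁ ≤ d ‖e^{n−1}‖₁`: for `d < 1`
the update contracts geometrically with factor ≤ d in the ℓ1 norm (the
supremum-norm residual, which the stopping rule monitors, is bounded by the
ℓ1 residual). Iterations to tolerance are therefore
≤ `log(tol)/log(d) + O(1)`, which the tests assert on random instances
(~30 iterations at d = 0.5, tol = 1e−9). The fixed point is unique since
`ρ(d Pᵀ) ≤ d‖P‖_∞ = d < 1`, and equals `(1 − d)(I − d Pᵀ)⁻¹ s`, which
`netrank_closed_form` computes densely (guarded to ≤ 2000 nodes) as the
independent oracle.

**Determinism.** Updates within an iteration read only the previous vector
(Jacobi style), so chunking the matrix-vector product over row blocks —
the `n_workers` knob — cannot change the result: outputs are bit-identical
for any worker count and across reruns.

## Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| `d` (damping) | 0.5 | trade-off between statistical association (0) and connectivity (1); 0.5 weighs them equally. The original analysis does not report its value, so ranks at other `d` are exploratory — a knob, not a constant. |
| `tol` | 1e−9 | sup-norm change at convergence; with contraction factor ≤ d this costs ≤ log(tol)/log(d) iterations (~30 at d = 0.5). |
| `max_iter` | 1000 | safety cap; reported along with the final residual. |
| prior sign | absolute | down-regulation is as informative as up-regulation, and negative priors would break the nonnegative score interpretation; `signed=True` available. |
| STRING score cutoff | 400 | the conventional "medium confidence" threshold on the 0–1000 scale; weights are `score/1000`. |
| soft-threshold β | 6 | WGCNA's customary default; `pick_soft_threshold` chooses the smallest β with sign-adjusted scale-free fit R² ≥ 0.8, falling back to 6 when the fit is degenerate. |
| `edge_floor` | 0.01 | drops near-zero co-expression weights so the adjacency is sparse rather than complete; a pragmatic knob, not part of the model. |
| signature `k`, `p_cutoff` | 100, 0.05 | top-K among genes with raw association p < 0.05; no multiple-testing correction by default (a Benjamini–Hochberg flag exists but changes the method). |
| SVM | RBF, C = 1, standardized features | the reference analysis does not state its kernel or hyperparameters; metrics are therefore comparable in protocol, not in exact value. |

## Pipeline order and leakage

Min-max normalization is computed on the full matrix *before* the stratified
70/30 split, mirroring the order of the original protocol. This leaks the
test extremes into the scaler; since the transform is per-gene affine it
cannot alter correlations or the SVM's standardized features, but the strict
alternative (`scale_after_split` / `--scale-after-split`) is provided.
Per-class development counts are `round(dev_fraction · n_class)` — within one
sample of the requested fraction, seeded and reproducible.

## Synthetic data generator

`make_dataset` draws `x_gs = ℓ·F_{m(g),s} + δ·y_s·[g planted] + ε_gs` with
per-sample standard-normal module factors `F`, labels `y`, loading
`ℓ = 1/√3`, noise `ε ~ N(0, 1)` and effect size `δ = 1.5`; the companion
network places edges with probability 0.3 within modules and 0.01 across,
weighted by the model's expected correlations (0.25 within, 0.05 across).
Defaults: 500 genes in 10 modules, 400 samples, 30% cases, 20 planted
biomarkers inside one module.

Why ℓ = 1/√3: the implied within-module correlation is
`ρ = ℓ²/(ℓ² + 1) = 0.25`, a moderate co-expression typical of real modules.
Because the module factor is common to the planted genes, the first principal
component of a planted signature separates the classes with
`d' = δ/√(ρ + 1/n_planted)`; ρ therefore bounds component-level recovery no
matter how many samples are drawn, and values ≳ 0.5 would make component AUC
≥ 0.9 unreachable at δ = 1.5 — inconsistent with the recovery regime the
generator is meant to emulate. Fixed once, not tuned per seed.

What the generator does **not** emulate: RNA-seq count noise (expression is
Gaussian; the pipeline consumes normalized expression, so this is adequate),
batch effects, correlated noise across modules, and label-associated module
factors. A green recovery test therefore establishes the statistical
machinery of the pipeline, not robustness to sequencing artifacts or
confounding.

All randomness flows through one `numpy.random.default_rng(seed)`; no global
state is touched, and identical seeds give bit-identical outputs.

## Numerical choices

- Iteration starts at `r⁰ = s` (any start converges for d < 1; this one is
  exact at d = 0 and nearly so for small d).
- Undefined correlations (zero-variance gene, or after cleaning) map to
  prior 0 with p-value 1 and a warning; a zero-variance *label* vector is a
  hard error.
- Constant genes min-max-normalize to all-zeros (the scaler is undefined;
  zeros keep them inert downstream).
- Rank ties break by gene ID ascending, everywhere, for reproducibility.
- PCA component sign is arbitrary: the component AUC is reported as
  `max(AUC, 1 − AUC)`. Under a true null this folding biases the statistic
  slightly above 0.5 (by the folded sampling noise), which the null tests
  account for.
- PCA is fitted on the test matrix itself by default (matching the reference
  protocol's description); `fit_expr`/`--fit-pca-on-dev` gives the stricter
  fit-on-dev variant.
- Duplicate edge orientations in input edge lists keep the maximum score;
  self-loops are dropped.

## Known limitations

- Score magnitudes are not comparable across runs or networks (no
  normalization of `s` or `r` — by design); only ranks are the product.
- The dense closed-form oracle is quadratic in memory and guarded to 2000
  nodes; it is a verification tool, not a production path.
- Identifier mapping between protein and gene namespaces is out of scope:
  network node IDs must already match expression gene IDs.
- `d = 1` with dangling nodes has a non-unique/mass-leaking fixed point; the
  solver warns and iterates anyway up to `max_iter`.
- The scale-free fit uses equal-width binning of connectivity (10 bins);
  very small gene sets (< ~20) make the fit unstable, hence the fallback β.
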