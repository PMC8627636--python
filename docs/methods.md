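# Methods

## Problem

Expression profiling studies (microarray and bulk/single-cell RNA-seq
summaries) routinely measure thousands of genes on a few dozen labeled
samples. Classifiers built on all genes overfit; the goal of gene selection
is a small subset that is discriminative (predicts the class), diverse
(spans the co-expression structure) and non-redundant (avoids near-copies
of the same signal). `mapsogs` implements MaPSOGS, a hybrid filter–wrapper
selector that combines a univariate relevance filter, a gene co-expression
graph, graph clustering, and a many-objective binary particle swarm search.

## Pipeline

Given a labeled samples × genes matrix:

1. **Fisher filtering.** Each gene `g` is scored by the ratio of
   between-class to within-class scatter,
   `score(g) = Σ_k n_k (m_k − m)² / Σ_k n_k σ_k²`, with population class
   variances. Two filter modes exist: an absolute threshold λ (keep
   `score ≥ λ`) and top-m (keep the m best, ties to earlier genes). The
   default is top-m with `m = min(300, n_genes)` — an absolute λ does not
   transfer across data scales, while a size cap does. Degenerate genes are
   handled deterministically: a constant gene scores 0 (0/0 convention) and
   a perfectly separating gene (zero within-class scatter, positive
   between-class scatter) is capped at 1e12 so min–max scaling stays finite.
2. **Similarity graph.** Edge weights start as absolute Pearson correlation
   `w_ij = |r(g_i, g_j)|` of the filtered genes across samples (zero-variance
   genes get similarity 0 by convention). Raw similarities are rescaled by a
   sigmoid centred on the empirical mean over all unordered pairs,
   `ŵ_ij = 1/(1+exp(−(w_ij − w̄)/σ))`, spreading the typically compressed
   correlation distribution over (0, 1) (all pairs map to 0.5 if σ = 0).
   Edges with `ŵ < θ` are removed (keep rule `ŵ ≥ θ`); nodes are kept and may
   become isolated. Default θ = 0.6: beyond that value cluster granularity
   keeps growing but reported selection accuracy starts to drop on the
   hardest benchmark dataset, so 0.6 is the largest safe default.
3. **Centralities** are computed once, on the thresholded graph, and looked
   up during the swarm loop (they must be cheap and stable inside the
   search). Node centrality defaults to principal-eigenvector centrality.
   Thresholding usually disconnects the graph, where the global dominant
   eigenvector concentrates on one component and zeroes the rest; we
   therefore take the principal eigenvector of each connected component
   (dense symmetric eigendecomposition — deterministic, no power-iteration
   convergence concerns), scale it to max 1 within the component, weight
   components by their spectral radius relative to the largest, and
   max-normalize globally. Isolated nodes get 0. A strength (weighted
   degree) measure is available as an alternative and as the automatic
   fallback. Edge centrality defaults to the retained edge weight itself
   (absent pairs → 0), which turns the f2 objective into a direct redundancy
   penalty; pair-normalized weighted edge betweenness (distance `1/ŵ`) is a
   pluggable alternative.
4. **Louvain clustering.** The thresholded graph is partitioned by
   modularity maximization in the standard two phases: repeated single-node
   moves driven by the incremental gain, then aggregation of clusters into
   super-nodes, iterated until no phase improves modularity. The gain of
   inserting a detached node `i` into cluster `C` is implemented as
   `ΔQ = k_in/m − Σ_tot·k_i/(2m²)` with `k_in` the (single-counted) weight
   from `i` to `C`; written with double-counted intra-cluster bookkeeping
   this is the familiar bracketed gain formula, and the convention is pinned
   by a brute-force test asserting `ΔQ` equals the exact modularity
   difference on random graphs. Ties in the gain go to the lowest cluster
   index; node visit order is shuffled by the run seed, so the partition is
   reproducible per seed. An edgeless graph (θ removed everything) degrades
   to singleton clusters with a logged warning. Isolated nodes always end as
   singletons.
5. **Many-objective swarm search.** Particles are binary masks over the
   filtered genes (bit = gene selected) with real velocities. Five
   objectives are minimized jointly:
   `f1` classification error of the wrapped evaluator, `f2` summed edge
   centrality over selected pairs (redundancy), `f3 = 1/NC` where NC is the
   summed node centrality of selected genes (representativeness), `f4 =
   1/specificity` (true-negative rate), `f5` the subset size. Candidates are
   compared by Pareto dominance (no worse everywhere, strictly better
   somewhere); mutually nondominated solutions accumulate in an external
   archive pruned to capacity by NSGA-II crowding distance, and the global
   guide is drawn from the archive by binary tournament on crowding distance
   (less crowded wins). Velocities follow the canonical update
   `v ← w·v + c1 r1 (pbest − x) + c2 r2 (gbest − x)` with fresh per-dimension
   `r1, r2 ~ U[0,1]`, clamped to ±v_max; bits are then re-drawn by the
   sigmoid transfer rule (bit = 1 with probability `1/(1+e^{−v})`), the
   dominant binarization of continuous PSO (the continuous position update
   is read with a unit time step). A particle's personal best is replaced
   when the new fitness dominates it; when the two are mutually
   nondominated, it is replaced with probability 0.5 (seeded) to avoid bias.
   The loop stops at `max_iterations` or when an iteration leaves every mask
   unchanged (velocities are not compared — masks define solutions).
6. **Repair operator.** Before each evaluation, every particle is repaired
   so that each Louvain cluster contributes at least `min(ω, cluster size)`
   selected genes: deficient clusters (ascending index) receive their
   highest-Fisher unselected genes, and in exchange the globally
   lowest-Fisher selected genes whose own clusters stay covered are
   dropped, keeping the subset size constant; if no such donor exists the
   gene is added without removal. ω = 0 disables repair; the default ω = 1
   guarantees one representative per co-expression cluster.
7. **Final solution.** Among archive members: minimum f1, ties broken by
   minimum f5, then minimum f4, then the lexicographically smallest mask.

Fitness `f1`/`f4` use stratified 5-fold cross-validation on the training
data with pooled out-of-fold confusion counts, seeded per run — leave-one-out
inside the swarm would cost n× more per evaluation; final reported accuracy
uses leave-one-out CV (below). The default evaluator is a linear-kernel SVM
with C = 1 (the common default for wide expression matrices); CART decision
trees and k-NN are available via spec strings (`"dt"`, `"knn:k=5"`).
Repeated masks within a run hit a fitness cache, which is sound because the
CV folds are fixed per run.

### Multi-class conventions

Error and specificity are defined on binary confusion counts; with more
than two classes, error is misclassified/total and specificity is the
macro-average of the per-class one-vs-rest true-negative rates (a class
with no negatives contributes 1). In the binary case the class appearing
second in the data is treated as the positive class. Since specificity and
node centrality can be 0, `f3` and `f4` divide by `max(·, ε)` with
ε = 1e−6, a large-but-finite penalty that keeps dominance comparisons
well-defined.

## Default parameters

| parameter | default | meaning / why |
|---|---|---|
| filter top-m | min(300, n_genes) | portable search-space cap; λ mode kept for fidelity |
| θ | 0.6 | edge threshold on normalized weights in [0,1]; see above |
| ω | 1 | min selected genes per cluster enforced by repair |
| swarm size | 30 | standard PSO population for ~10²–10³ bits |
| iterations | 100 | upper bound; mask-stability stop usually earlier |
| w | 0.7 | inertia, kept inside the recommended [0.5, 0.9] band |
| c1, c2 | 2.0 | canonical acceleration constants |
| v_max | 4.0 | clamp; sigmoid(±4) ≈ 0.018/0.982 keeps bits mobile |
| archive capacity | 50 | bounded Pareto store pruned by crowding distance |
| CV folds | 5 | fitness evaluation on the training split |
| ε | 1e−6 | guard for 1/NC and 1/specificity |

All defaults are configurable (`RunConfig`, `MaPSOGSSelector` parameters,
CLI flags, or a flat `key=value` config file).

## Evaluation utilities

Final subsets are scored by leave-one-out cross-validation (n single-sample
folds, accuracy in percent). Multi-method comparisons rank methods per
dataset (rank 1 = highest accuracy, ties averaged), average ranks across
datasets, and test the null of equal average ranks with the Friedman
statistic `χ² = 12n/(k(k+1)) Σ_j (R̄_j − (k+1)/2)²`, df = k−1, with an
optional tie correction; p-values come from the χ² upper tail. Display
values are rounded half-up to two decimals and raw values are always kept,
because published summary rows mix half-up rounding with truncation.

The package ships the published per-dataset benchmark results of MaPSOGS
and seven competitor selectors on seven microarray datasets
(`mapsogs.benchmarks`) as *inputs* to this machinery: the aggregate
arithmetic (column means, improvements, rank averages) is reproduced from
the per-dataset numbers. Two caveats are documented rather than patched:
a few published per-dataset ranks contradict the accuracies printed next
to them (the decision-tree SRBCT row and the k-NN Leukaemia row), so rank
averages recomputed from accuracies differ in four entries; and the
published Friedman test reports df = 3 for eight compared methods with a
χ² that cannot be reproduced from the published ranks under the standard
formula (which gives df = 7 and χ² ≈ 45.5 for the SVM table) — this
package reports the standard statistic.

LOOCV is applied to the dataset restricted to the already-selected genes;
when selection and evaluation use the same samples this carries the usual
selection-bias optimism, which is why held-out evaluation via
`split_stratified` is provided.

## Synthetic data

`SyntheticSpec`/`generate_dataset` emulate the structure of small-sample
expression studies: tens of samples, 10²–10⁴ genes, balanced classes,
co-expression modules, and a handful of class-relevant genes. Modules are
equicorrelated blocks sharing one latent factor
(`gene = √ρ·latent + √(1−ρ)·noise`, scaled by `noise_sd`), giving every
within-block pair correlation ρ in expectation — a closed-form target that
Louvain should recover. By default four near-equal blocks cover all genes.
Relevant genes sit at the heads of the blocks, round-robin, so informative
genes are spread across clusters and the repair operator's coverage
behaviour is exercised; class k's mean is shifted by `k·δ·noise_sd` on each
relevant gene, which extends to any number of classes with one parameter.

What the generator does **not** model: probe/batch effects,
heteroscedastic or heavy-tailed noise, count distributions (RNA-seq), or
irrelevant-but-structured covariates. Passing recovery tests on this
generator therefore show that the pipeline's stages interlock correctly
(filter finds shifted genes, clustering finds blocks, repair covers them),
not that the method transfers to any particular real platform.

One property of the equicorrelated design deserves emphasis: an unshifted
block-mate of a relevant gene shares the latent factor but not the class
shift, so a classifier can subtract the mate from the relevant gene and
cancel most non-class variance. Subsets of the form {relevant gene +
block-mates} can therefore have genuinely *lower* generalization error
than the set of planted relevant genes itself. A search that minimizes
classification error will exploit this, so "fraction of planted genes in
the final subset" systematically understates selection quality under this
generator; the reported recovery numbers should be read with that in
mind.

## Problem sizes and determinism

The standard synthetic benchmark used by the test-suite and the acceptance
script is 60 samples × 100 genes, four ρ = 0.8 blocks of 25, five relevant
genes at δ = 2, two classes, with a swarm of 30 run for 50 iterations,
repeated for ten seeds (and ten more with repair disabled for the
ablation). Every random draw in a run flows from one seed: the pipeline is
a pure function of (dataset, config), and the tests assert bit-identical
reruns.

## Known limitations

- The sigmoid transfer rule randomizes bits wherever velocity is near 0
  (flip probability 0.5), so early iterations explore densely regardless of
  initialization; the Fisher-score-biased initialization matters mostly
  through personal bests.
- Crowding-based archive eviction can drop interior Pareto points; extreme
  points per objective are always retained, which is what makes the
  archive-best-f1 trace non-increasing.
- Fitness CV folds are fixed per run; subsets can in principle adapt to the
  fold split, though the final LOOCV report is computed independently.
- Computing centralities once before the search (rather than on each
  selected subgraph) trades fidelity for a large constant-factor speedup;
  both interpretations of the published objective are defensible and the
  measures are pluggable.
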