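# Methods

## Problem and objective

Given a labelled expression matrix `X ∈ R^{n×N}` (n samples, N genes) with
class labels `y`, the package searches for a gene subset `R ⊆ {1..N}`
minimizing

```
f(R) = α · γ_R(D) + (1 − α) · |R| / N,        α ∈ [0, 1]
```

where `γ_R(D)` is the stratified k-fold cross-validated error rate of a
K-nearest-neighbour classifier using Euclidean distance over the columns
in `R`. Both terms lie in [0, 1], so `f ∈ [0, 1]`; the empty subset is
assigned the worst value 1.0 rather than raising, so search operators can
traverse it. With the default `α = 0.99` a change of one misclassified
sample (at n = 60, Δerror ≈ 0.0167) outweighs the cost of ~330 genes at
N = 200 (β/N = 5·10⁻⁵ per gene): accuracy strictly dominates, the size
term acts as a tie-breaker that prunes genes that do not reduce error.

Solutions are continuous genotypes `x ∈ [0, 1]^N` decoded to masks by
`mask_i = (x_i > 0.5)`. Keeping the genotype continuous makes the
arithmetic crossover well-defined; thresholding at the bound midpoint is
the standard continuous-to-binary bridge when no transfer function is
prescribed.

## Evaluation protocol

* **Folds.** Stratified k-fold (scikit-learn `StratifiedKFold`, shuffled,
  seeded), with k capped at the smallest class size (warned). Requesting
  `cv_folds ≥ n` yields leave-one-out. Folds are drawn **once per run**
  from `cv_seed` and reused for every fitness call, so the objective is a
  deterministic function of the mask and best-so-far traces are
  meaningful; per-mask results are cached.
* **KNN determinism.** k = 5 by default (odd enforced). Exact distance
  ties resolve to the lower sample index (stable argsort over
  index-ordered training columns); a residual vote tie resolves to the
  label of the nearest neighbour among the tied classes. A training fold
  smaller than k reduces k for that fold with a warning.
* **Normalization.** Every gene column is min-max rescaled to [0, 1]
  before evaluation (constant columns → 0). This makes Euclidean
  distances scale-comparable across genes and puts the IG temperature
  (below) on the same order as fitness deltas. It is an implementation
  decision — expression pre-processing for this family of benchmarks is
  conventionally unspecified — and is idempotent, so already-normalized
  input is unchanged.
* **Reported accuracy** is the CV accuracy of the final mask, recomputed
  from scratch on the same folds the search used. It is therefore the
  search-time (optimistically biased) estimate, not a nested-CV
  generalization estimate; the bias is shared by all methods compared.

## Black Widow Optimization

Population of `Npop = 10` widows, `max_iterations = 100`, procreation
rate `pr = 0.6`, mutation rate `mr = 0.4`, bounds [0, 1] — the published
tuning for this problem family. Each iteration:

1. **Procreation.** `Nr = round(pr·Npop)` rounded down to even (= 6).
   For each of `Nr/2` matings, two distinct parents are drawn uniformly;
   one crossover draw `a ~ U[0,1)^N` (a fresh per-coordinate vector per
   mating) produces `y1 = a∘x1 + (1−a)∘x2` and `y2 = a∘x2 + (1−a)∘x1`.
   Offspring satisfy `y1 + y2 = x1 + x2` exactly and stay in bounds by
   convexity.
2. **Cannibalism.** Each mating contributes its better parent and better
   child to the next population (ties: fewer selected genes, then the
   first argument). No separate cannibalism-rate parameter exists; the
   keep-the-better rule *is* the survivor selection.
3. **Mutation.** `Nm = Npop − Nr` (= 4) members drawn without replacement
   are swap-mutated (two distinct positions exchange values — a
   permutation, so the genotype multiset and bounds are preserved).

The closure `even(round(pr·Npop)) + round(mr·Npop) = Npop` is validated at
configuration time, so the population size is invariant by construction.
The incumbent best `W*` updates whenever any evaluated widow beats it;
its fitness trace is non-increasing by definition. The fitness-proportional
probability `Pro_i = f_i / Σf` is exposed as a utility
(`selection_probability`) but is not a gate in the loop — the operational
pseudocode is self-consistent without it. Stopping is by iteration count;
an optional `patience` criterion (default tolerance 1e-2) stops after a
run of iterations without material improvement.

## Iterated Greedy

Each IG iteration, starting from the incumbent solution:

* **Destruction.** `d` distinct selected genes, drawn uniformly, have
  their genotype entries set to the lower bound. Default
  `d = max(1, round(0.2 · |R|))` — proportional, so the operator scales
  from hundreds to tens of thousands of genes; capped so at least one
  gene stays selected. A solution with ≤ 1 selected gene returns an empty
  removal list (a signal, not an error).
* **Construction.** Removed genes are revisited in removal order; each is
  re-selected (entry set to the upper bound) iff that strictly lowers the
  fitness, ties favouring the smaller subset. This is the subset-encoding
  analogue of NEH insertion: position-wise insertion is meaningless for
  an unordered subset, so "best position" degenerates to
  "re-add or not". A `construct_mode="swap_aware"` variant additionally
  tries each removed gene as a one-for-one replacement of every selected
  gene, at ~|R|-fold higher evaluation cost.
* **Acceptance.** Improvements always replace the incumbent; a worse
  rebuild replaces it with probability `exp(−ΔE/T)` at the constant
  temperature `T = Σᵢⱼ Pᵢⱼ/(n·m·10)` = mean normalized expression / 10
  (so `T ∈ [0, 0.1]`, commensurate with fitness deltas; `t_scale`
  multiplies it, 0 disabling uphill moves). There is no cooling schedule.
  The best-so-far is tracked separately from the incumbent and is what
  `run_ig` returns, so refinement never degrades its input.

## Hybridization

`run_bwo_ig` executes the BWO loop and, after every `ig_period = 10`
iterations plus once after the final iteration, refines `W*` with
`ig_iterations = 10` IG steps. The refined solution replaces `W*` when at
least as good and is injected into the population in place of the current
worst widow, so the improvement feeds subsequent matings. All randomness
derives from one master seed split into labelled streams (init, pairing,
crossover, mutation, IG destruction, IG acceptance); IG consumes only its
own streams, so disabling the handoff reproduces plain BWO bit-for-bit —
a property the tests assert exactly.

## Synthetic data

The generator emulates the *shape* of public microarray benchmarks (tens
of samples, 2–4 classes, a handful of informative genes among thousands
of noise genes) with a Gaussian class-conditional model: informative gene
j in class c is `Normal(μ_cj, σ)` with adjacent class means separated by
`effect_size · σ`; every other gene is class-independent
`Normal(centre, σ)`. Class counts follow largest-remainder apportionment
of the requested proportions (balanced by default), the matrix is min-max
normalized, and the planted truth (informative indices, class means) is
returned separately so recovery metrics never leak into the data. It does
**not** simulate correlated gene blocks, heavy-tailed or log-normal
marginals, dropout, or batch structure — so passing tests demonstrate
correct optimizer behaviour and planted-signal recovery, not performance
on real microarray noise. `generate_tiny_separable` (≤ 12 genes, one
perfectly separating gene, wide margin) exists so exhaustive enumeration
of all 2^N masks can serve as a ground-truth oracle in optimizer tests.

## Problem sizes used in the checks

The oracle comparison uses 20 × 8 (LOOCV 5-NN; 256-mask brute force); the
recovery and method-comparison instance is 60 samples × 200 genes with 5
informative genes at effect size 3 and 10 paired optimizer seeds; the
multi-run harness defaults to 30 runs but the shipped checks use 10.
These sizes were chosen so the full battery re-runs from scratch in well
under a minute while the instances remain non-trivial (200 genes ≫
samples; BWO alone reliably leaves ~90 genes selected where the hybrid
reaches ~4).

## Behaviour worth knowing (and limitations)

* **Redundant informative genes are pruned.** Because β > 0, once a
  sub-subset of the planted genes reaches zero CV error, the remaining
  informative genes are *correctly* excluded by the objective. Recovery
  should therefore be read as "a sufficient discriminative subset", not
  "the complete causal set"; no wrapper objective of this form can
  distinguish redundant signal from noise.
* **Convergence measurement.** `RunTrace.iterations_to_within(tol)` uses
  an absolute band on the [0, 1] fitness scale (default reading), since a
  relative band around near-zero final fitness collapses to exact
  equality and stops measuring convergence speed.
* **Fold-dependence.** Fitness is conditional on the fold draw; a
  different `cv_seed` yields a (slightly) different objective. The
  experiment harness shares fold seeds across methods at equal run index
  so comparisons are paired.
* The t-test on accuracies is Welch's (unequal variances), two-sided,
  with the degenerate zero-variance policy p = 1 (equal means) / p = 0
  (unequal); with the hybrid frequently at accuracy 1.0 exactly, the
  normality assumption is strained and p-values on small run counts are
  indicative only.
* Runtime scales linearly in fitness evaluations × fold count; the mask
  cache typically absorbs 30–50 % of calls. Very large N is limited by
  the O(n²·|R|) distance computation per evaluation, not by the
  optimizers.
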