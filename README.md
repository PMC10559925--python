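# bwig — wrapper gene selection with Black Widow Optimization + Iterated Greedy

High-dimensional expression profiling (bulk microarray or RNA-seq style
matrices with tens of samples and thousands of genes) makes classification
easy to overfit and hard to interpret. **bwig** selects a small,
discriminative gene subset by *wrapper* feature selection: candidate
subsets are scored by the cross-validated error of a K-nearest-neighbour
classifier restricted to them, and the subset space is searched by

* **BWO** — Black Widow Optimization: a population of continuous genotypes
  in [0, 1]^N (decoded to gene masks by thresholding at 0.5) evolves by
  arithmetic crossover (`y1 = a∘x1 + (1−a)∘x2`, `y2 = a∘x2 + (1−a)∘x1`),
  cannibalistic survivor selection (each mating keeps the better parent
  and better child) and swap mutation;
* **IG** — Iterated Greedy: destruction (remove a random fraction of the
  selected genes) followed by greedy reconstruction (re-add a removed gene
  only if it strictly improves the objective), with constant-temperature
  simulated-annealing acceptance, `T = Σᵢⱼ Pᵢⱼ / (n·m·10)`;
* **BWO-IG** — the hybrid: every few BWO generations the incumbent best
  solution is refined by IG and re-injected into the population.

The objective, minimized throughout, is

```
fitness(R) = α · γ_R(D) + (1 − α) · |R| / N
```

where `γ_R(D)` is the stratified k-fold CV error of 5-NN on the selected
genes `R`, `N` the total gene count, and `α = 0.99` by default, so accuracy
dominates and the size term prunes redundant genes.

Intended users: anyone with a labelled expression matrix in delimited text
who wants a compact gene panel plus honest convergence and comparison
statistics — and methodologists who want a deterministic, stream-seeded
reference implementation of these optimizers.

## Worked example

The selectors follow the scikit-learn feature-selection API:

```python
from bwig import HybridBWOIGSelector, generate_tiny_separable

dataset, truth = generate_tiny_separable(20, 8, informative_index=3, seed=7)
sel = HybridBWOIGSelector(max_iterations=30, ig_period=10,
                          cv_folds=20, random_state=1)
sel.fit(dataset.values, dataset.labels)
print(sel.get_support().nonzero()[0], sel.cv_error_, sel.best_fitness_)
```

prints

```
[3] 0.0 0.0012500000000000011
```

— the search recovered exactly the planted separating gene (index 3), its
leave-one-out 5-NN error is 0, and the fitness equals the size term alone,
`0.01 · 1/8 = 0.00125`, which is also the exhaustive optimum over all 256
masks of this fixture.

The same machinery is scriptable from the shell:

```bash
gs synth --samples 60 --genes 200 --informative 5 --effect 3 --seed 11 --out data/
gs compare --data data/synthetic-11.csv --methods bwo,bwo-ig \
   --runs 10 --seed 1 --out report/
```

which writes `summary.json`, `per_run.csv`, `convergence.csv` and per-run
selected-gene lists, and prints per-method mean ± sd accuracy and the
Welch t-test comparing the methods. On this instance a typical printout is

```
bwo: accuracy 0.9950 +/- 0.0081, selected 89.0 genes
bwo-ig: accuracy 1.0000 +/- 0.0000, selected 4.2 genes
bwo_vs_bwo-ig: t = -1.964, p = 0.0811
```

— the hybrid matches or beats plain BWO's accuracy while selecting a
panel roughly twenty times smaller.

## Layout

| module | contents |
| --- | --- |
| `bwig.selectors` | sklearn-style `BlackWidowSelector`, `IteratedGreedySelector`, `HybridBWOIGSelector` |
| `bwig.datasets` | `ExpressionDataset`, delimited/ARFF loaders, min-max normalization, stratified folds |
| `bwig.synthetic` | planted-truth generators (`generate_synthetic`, `generate_tiny_separable`) |
| `bwig.fitness` | mask decoding, deterministic KNN-CV error, the weighted objective, mask cache |
| `bwig.bwo` | BWO operators and loop, labelled RNG streams, `RunTrace` |
| `bwig.ig` | temperature, destruction, greedy construction, SA acceptance, `run_ig` |
| `bwig.hybrid` | `run_bwo_ig`, method dispatch |
| `bwig.experiment` | multi-seed harness, summary statistics, Welch t-test, report I/O |
| `bwig.cli` | the `gs` command (`synth`, `run`, `compare`) |

See `docs/methods.md` for the model details, parameter defaults and known
limitations.
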