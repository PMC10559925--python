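"""Multi-seed experiment harness: repeated runs, summary statistics, t-tests.

Each method is run ``n_runs`` times with per-run seeds derived from one
master seed, so the whole experiment is bit-reproducible. For every run
the final mask's cross-validated accuracy is recomputed from scratch on
the same folds the search used, so reported accuracy cannot drift from
search-time fitness. Method pairs are compared with Welch's two-sample
t-test (robust to unequal variances across methods). Note the reported
accuracy is the search-time CV accuracy of the selected mask — the
standard wrapper-selection protocol, which is optimistically biased
relative to a nested, held-out evaluation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ExpressionDataset
from .fitness import build_cv_folds, knn_cv_error
from .hybrid import HybridConfig, run_method


@dataclass
class ExperimentReport:
    """Everything a multi-run comparison produces.

    ``per_run`` has one row per (method, run) with the seed, final CV
    accuracy, selected-gene count, final fitness and iterations-to-best.
    ``summary`` maps method -> {accuracy,fitness,n_selected} x
    {mean,std,std_error}; ``comparisons`` maps "A_vs_B" -> Welch t / p on
    accuracy; ``traces`` maps method -> per-run best-fitness histories.
    """

    per_run: list[dict]
    summary: dict[str, dict]
    comparisons: dict[str, dict]
    traces: dict[str, list[list[float]]]
    n_runs: int
    master_seed: int
    selected_genes: dict[str, list[list[str]]] = field(default_factory=dict)


def _derive_seed(master_seed: int, method_index: int, run: int) -> int:
    ss = np.random.SeedSequence(master_seed, spawn_key=(1000 + method_index, run))
    return int(ss.generate_state(1)[0] % (2**31))


def _summary_stats(x: np.ndarray) -> dict[str, float]:
    x = np.asarray(x, dtype=float)
    std = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return {
        "mean": float(np.mean(x)),
        "std": std,
        "std_error": std / math.sqrt(x.size),
    }


def two_sample_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch's unequal-variance two-sample t-test, two-sided.

    Degenerate policy when both samples have zero variance: equal means
    give (0, 1); unequal means give (signed infinity, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 observations")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return math.copysign(math.inf, np.mean(a) - np.mean(b)), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def run_experiment(
    dataset: ExpressionDataset,
    methods: list[str],
    config: HybridConfig,
    n_runs: int = 30,
) -> ExperimentReport:
    """Run every method ``n_runs`` times and summarize.

    Per-run seeds (optimizer and CV folds alike) derive from the master
    seed, method index and run index; runs of different methods with the
    same run index share their CV folds, making method comparisons paired.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    master_seed = config.master_seed
    per_run: list[dict] = []
    traces: dict[str, list[list[float]]] = {m: [] for m in methods}
    genes: dict[str, list[list[str]]] = {m: [] for m in methods}
    accuracies: dict[str, list[float]] = {m: [] for m in methods}
    fitnesses: dict[str, list[float]] = {m: [] for m in methods}
    sizes: dict[str, list[int]] = {m: [] for m in methods}

    for mi, method in enumerate(methods):
        for run in range(n_runs):
            run_seed = _derive_seed(master_seed, mi, run)
            cv_seed = _derive_seed(master_seed, 0, run)  # shared across methods
            cfg = replace(
                config,
                bwo=replace(config.bwo, seed=run_seed),
                ig=replace(config.ig, seed=run_seed),
                fitness=replace(config.fitness, cv_seed=cv_seed),
                seed=run_seed,
            )
            trace = run_method(dataset, method, cfg)
            final = trace.best_widow.evaluation
            # Recompute accuracy from scratch on the run's folds: no drift
            # between search-time fitness and reported accuracy.
            folds = build_cv_folds(dataset, cfg.fitness)
            error = knn_cv_error(dataset, final.mask, cfg.fitness, folds=folds)
            accuracy = 1.0 - error
            per_run.append(
                {
                    "method": method,
                    "run": run,
                    "seed": run_seed,
                    "accuracy": accuracy,
                    "n_selected": final.n_selected,
                    "fitness": final.fitness,
                    "iterations_to_best": trace.iterations_to_best,
                    "evaluations": trace.evaluations,
                }
            )
            traces[method].append([float(f) for f in trace.best_fitness_history])
            selected = [
                dataset.gene_ids[j] for j in np.flatnonzero(final.mask)
            ]
            genes[method].append(selected)
            accuracies[method].append(accuracy)
            fitnesses[method].append(final.fitness)
            sizes[method].append(final.n_selected)

    summary = {
        m: {
            "accuracy": _summary_stats(np.array(accuracies[m])),
            "fitness": _summary_stats(np.array(fitnesses[m])),
            "n_selected": _summary_stats(np.array(sizes[m], dtype=float)),
            "best_run_accuracy": float(np.max(accuracies[m])),
        }
        for m in methods
    }
    comparisons: dict[str, dict] = {}
    for i, a in enumerate(methods):
        for b in methods[i + 1 :]:
            t, p = two_sample_t_test(np.array(accuracies[a]), np.array(accuracies[b]))
            comparisons[f"{a}_vs_{b}"] = {"t_statistic": t, "p_value": p}
    return ExperimentReport(
        per_run=per_run,
        summary=summary,
        comparisons=comparisons,
        traces=traces,
        n_runs=n_runs,
        master_seed=master_seed,
        selected_genes=genes,
    )


def write_report(report: ExperimentReport, out_dir: str | Path) -> list[Path]:
    """Write summary JSON, per-run CSV, convergence CSV and gene lists.

    All files are plain text and reload to an equal report via
    :func:`read_report`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    summary_path = out_dir / "summary.json"
    summary_path.write_text(
        json.dumps(
            {
                "summary": report.summary,
                "comparisons": report.comparisons,
                "n_runs": report.n_runs,
                "master_seed": report.master_seed,
            },
            indent=2,
            allow_nan=True,
        )
        + "\n"
    )
    written.append(summary_path)

    per_run_path = out_dir / "per_run.csv"
    pd.DataFrame(report.per_run).to_csv(per_run_path, index=False)
    written.append(per_run_path)

    rows = []
    for method, hists in report.traces.items():
        for run, hist in enumerate(hists):
            for iteration, fitness in enumerate(hist):
                rows.append(
                    {
                        "method": method,
                        "run": run,
                        "iteration": iteration,
                        "best_fitness": fitness,
                    }
                )
    conv_path = out_dir / "convergence.csv"
    pd.DataFrame(rows).to_csv(conv_path, index=False)
    written.append(conv_path)

    for method, runs in report.selected_genes.items():
        for run, gene_list in enumerate(runs):
            p = out_dir / f"genes_{method}_run{run}.txt"
            p.write_text("\n".join(gene_list) + ("\n" if gene_list else ""))
            written.append(p)
    return written


def read_report(out_dir: str | Path) -> ExperimentReport:
    """Reload a written report (summary, per-run rows, traces, gene lists)."""
    out_dir = Path(out_dir)
    blob = json.loads((out_dir / "summary.json").read_text())
    per_run = pd.read_csv(out_dir / "per_run.csv").to_dict(orient="records")
    conv = pd.read_csv(out_dir / "convergence.csv")
    traces: dict[str, list[list[float]]] = {}
    for method, grp in conv.groupby("method", sort=False):
        traces[method] = [
            g.sort_values("iteration")["best_fitness"].tolist()
            for _, g in grp.groupby("run", sort=True)
        ]
    genes: dict[str, list[list[str]]] = {}
    gene_files: list[tuple[str, int, Path]] = []
    for path in out_dir.glob("genes_*_run*.txt"):
        stem = path.stem[len("genes_") :]
        method, _, run = stem.rpartition("_run")
        gene_files.append((method, int(run), path))
    for method, _, path in sorted(gene_files, key=lambda t: (t[0], t[1])):
        genes.setdefault(method, []).append(
            [line for line in path.read_text().splitlines() if line]
        )
    return ExperimentReport(
        per_run=per_run,
        summary=blob["summary"],
        comparisons=blob["comparisons"],
        traces=traces,
        n_runs=blob["n_runs"],
        master_seed=blob["master_seed"],
        selected_genes=genes,
    )
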