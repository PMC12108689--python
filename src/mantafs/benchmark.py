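"""Repeated-run benchmarking of the swarm selectors with rank statistics.

The harness mirrors the standard evaluation protocol for wrapper feature
selection: per run an unseen outer test fold is split off first and never
touched during selection; the selector runs on the remainder; the chosen
subset is then scored by the same KNN configuration on the unseen fold.
Runs are paired across algorithms — for run index ``r`` every algorithm sees
the same outer split and the same optimizer seed — so differences isolate the
search strategy.

Aggregation follows the field's reporting conventions: per-cell mean ± std
tables, Friedman average ranks across datasets (rank 1 = best), and pairwise
two-sided Wilcoxon signed-rank tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import RunResult
from .data import LabeledDataset, stratified_holdout, stratified_kfold
from .fitness import knn_classify
from .data import min_max_scale
from .selection import BinaryPSOSelector, MantaRayBPSOSelector

__all__ = [
    "ALGORITHMS",
    "BenchmarkResult",
    "RankSummary",
    "make_selector",
    "run_benchmark",
    "summarize",
    "friedman_average_ranks",
    "wilcoxon_signed_rank",
    "export_traces",
]

#: Registered algorithm names -> selector factories.
ALGORITHMS = {
    "mrfl": lambda **kw: MantaRayBPSOSelector(**kw),
    "sbpso": lambda **kw: BinaryPSOSelector(transfer="s", **kw),
    "vbpso": lambda **kw: BinaryPSOSelector(transfer="v", **kw),
}


def make_selector(name: str, **params):
    """Instantiate a registered selector by short name."""
    try:
        factory = ALGORITHMS[name]
    except KeyError:
        raise ValueError(f"unknown algorithm {name!r}; choose from {sorted(ALGORITHMS)}") from None
    return factory(**params)


@dataclass
class BenchmarkResult:
    """Per-run records plus convergence traces.

    ``records`` has one row per (algorithm, run) with columns: algorithm,
    run, seed, accuracy (unseen outer fold), inner_accuracy (1 - internal
    holdout error), n_features, fitness, n_evaluations.  ``traces`` maps
    ``(algorithm, run)`` to the global-best fitness trace.
    """

    records: pd.DataFrame
    traces: dict[tuple[str, int], np.ndarray]


@dataclass
class RankSummary:
    """Friedman average ranks: per-algorithm mean rank across datasets,
    the resulting order (best first), and the chi-square p-value when the
    test is defined (at least three algorithms)."""

    average_ranks: pd.Series
    order: list[str]
    p_value: float | None


def _unseen_accuracy(train: LabeledDataset, test: LabeledDataset, support: np.ndarray, k: int) -> float:
    tr_X, te_X = min_max_scale(train.X[:, support], test.X[:, support])
    pred = knn_classify(tr_X, train.y, te_X, k=k)
    return float(np.mean(pred == test.y))


def run_benchmark(
    algorithms: list[str],
    dataset: LabeledDataset,
    n_runs: int = 20,
    outer: str = "kfold",
    n_folds: int = 10,
    test_fraction: float = 0.2,
    base_seed: int = 0,
    **selector_params,
) -> BenchmarkResult:
    """Paired repeated runs of the named algorithms on one dataset.

    Per run the outer split is re-randomized (k-fold: a fresh shuffled fold
    assignment with fold ``r mod n_folds`` held out; holdout: a fresh
    stratified split) and shared by all algorithms, as is the optimizer seed.
    ``selector_params`` are forwarded to every selector (e.g.
    ``n_iterations=50``).
    """
    if outer not in ("kfold", "holdout"):
        raise ValueError("outer must be 'kfold' or 'holdout'")
    for name in algorithms:  # fail fast on unknown names
        make_selector(name)

    rows, traces = [], {}
    for r in range(n_runs):
        ss = np.random.SeedSequence([base_seed, r])
        split_seed, algo_seed = (int(s) % (2**31 - 1) for s in ss.generate_state(2))
        split_rng = np.random.default_rng(split_seed)
        if outer == "kfold":
            folds = stratified_kfold(dataset, n_folds, split_rng)
            train, test = folds[r % len(folds)][0], folds[r % len(folds)][1]
        else:
            train, test = stratified_holdout(dataset, test_fraction, split_rng)
        for name in algorithms:
            sel = make_selector(name, random_state=algo_seed, **selector_params)
            sel.fit(train.X, train.y)
            rows.append(
                {
                    "algorithm": name,
                    "run": r,
                    "seed": algo_seed,
                    "accuracy": _unseen_accuracy(train, test, sel.support_, sel.n_neighbors),
                    "inner_accuracy": 1.0 - sel.best_error_,
                    "n_features": sel.n_selected_,
                    "fitness": sel.best_fitness_,
                    "n_evaluations": sel.n_evaluations_,
                }
            )
            traces[(name, r)] = sel.fitness_trace_
    return BenchmarkResult(pd.DataFrame(rows), traces)


def summarize(result: BenchmarkResult) -> pd.DataFrame:
    """Aggregate ``mean ± std`` cells (4 decimals) per algorithm for accuracy,
    subset size, and fitness.  A single run reports std 0."""
    out = {}
    for metric in ("accuracy", "n_features", "fitness"):
        g = result.records.groupby("algorithm")[metric]
        mean, std = g.mean(), g.std(ddof=1).fillna(0.0)
        out[metric] = (mean.round(4).map("{:.4f}".format) + " ± " + std.round(4).map("{:.4f}".format))
    return pd.DataFrame(out)


def friedman_average_ranks(
    values: pd.DataFrame | np.ndarray,
    higher_is_better: bool = False,
) -> RankSummary:
    """Average ranks of algorithms (columns) across datasets (rows).

    Values are oriented internally so rank 1 is always best; exact ties share
    the average rank.  The chi-square significance stage is delegated to
    :func:`scipy.stats.friedmanchisquare` when at least three algorithms are
    compared.
    """
    df = pd.DataFrame(values)
    if df.shape[1] < 2 or df.shape[0] < 1:
        raise ValueError("need at least 2 algorithms and 1 dataset")
    arr = df.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("metric matrix contains non-finite values")
    oriented = -arr if higher_is_better else arr
    ranks = np.apply_along_axis(stats.rankdata, 1, oriented)
    avg = pd.Series(ranks.mean(axis=0), index=df.columns)
    order = list(avg.sort_values(kind="stable").index)
    p_value = None
    if df.shape[1] >= 3:
        p_value = float(stats.friedmanchisquare(*(arr[:, j] for j in range(arr.shape[1]))).pvalue)
    return RankSummary(avg, order, p_value)


def wilcoxon_signed_rank(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Identical samples (all differences zero) leave the statistic undefined
    and return NaN, the convention used when an algorithm pair performs
    identically on every run.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if np.all(a == b):
        return float("nan")
    return float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)


def export_traces(result: BenchmarkResult, out_dir: str | Path) -> list[Path]:
    """Write one ``iteration,gbest_fitness`` CSV per (algorithm, run) plus the
    aggregate summary table; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for (name, r), trace in sorted(result.traces.items()):
        p = out_dir / f"trace_{name}_run{r}.csv"
        pd.DataFrame({"iteration": np.arange(len(trace)), "gbest_fitness": trace}).to_csv(p, index=False)
        written.append(p)
    summary_path = out_dir / "summary.csv"
    summarize(result).to_csv(summary_path)
    written.append(summary_path)
    records_path = out_dir / "records.csv"
    result.records.to_csv(records_path, index=False)
    written.append(records_path)
    return written
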