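"""Planted-signal and null-calibration benchmarks.

These run the full pipeline on the synthetic generator's standard conditions and
report recovery and calibration summaries. They back both the heavier end-to-end
tests and the reproduction script. Forest size and inner split count are kept small
(25 trees, r = 3) so a benchmark finishes in minutes on one CPU; the benchmark
conditions themselves (group counts, effect size, sample sizes, iteration and seed
counts) are fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import GediNetConfig
from .cv_engine import aggregate_performance, run_gedinet
from .rank_aggregation import aggregate_ranked_lists, aggregate_rankings
from .synthetic import SyntheticSpec, generate

BENCH_CONFIG = dict(n_trees=25, scoring_r=3, iterations=20, max_j=10)


@dataclass
class PlantedRecovery:
    rank1_fraction: float  # fraction of iterations ranking the planted group #1
    min_p_fraction: float  # fraction of seeds where it has the smallest aggregated p
    planted_p_values: list[float]
    accuracy_j1: float  # mean over seeds of the top-1 model's MCCV accuracy
    auc_j1: float
    n_seeds: int
    n_iterations: int


def planted_recovery(n_seeds: int = 10, master_seed: int = 0) -> PlantedRecovery:
    """Recovery of one planted group (delta = 3, 10 genes, 50/50 samples, 20 groups)
    over ``n_seeds`` independent datasets and MCCV runs of 20 iterations each."""
    rank1_hits = 0
    total_iterations = 0
    min_p_hits = 0
    planted_ps: list[float] = []
    accs: list[float] = []
    aucs: list[float] = []
    for s in range(n_seeds):
        seed = int(np.random.SeedSequence([master_seed, s]).generate_state(1)[0] % 2**31)
        ds, catalog, truth = generate(SyntheticSpec(seed=seed))
        config = GediNetConfig(seed=seed, **BENCH_CONFIG)
        results = run_gedinet(ds, catalog, config)
        planted = truth.planted_groups[0]
        rank1_hits += sum(r.ranked_groups[0].group_name == planted for r in results)
        total_iterations += len(results)
        agg = aggregate_rankings(results, level="group", catalog=catalog)
        min_p_hits += agg[0].element == planted
        planted_ps.append(next(a.p_value for a in agg if a.element == planted))
        perf = aggregate_performance(results, descending=False)
        accs.append(float(perf.loc[perf["#Groups"] == 1, "Accuracy"].iloc[0]))
        aucs.append(float(perf.loc[perf["#Groups"] == 1, "AUC"].iloc[0]))
    return PlantedRecovery(
        rank1_fraction=rank1_hits / total_iterations,
        min_p_fraction=min_p_hits / n_seeds,
        planted_p_values=planted_ps,
        accuracy_j1=float(np.mean(accs)),
        auc_j1=float(np.mean(aucs)),
        n_seeds=n_seeds,
        n_iterations=total_iterations,
    )


def null_pipeline_accuracy(iterations: int = 50, seed: int = 0) -> tuple[float, int]:
    """Mean held-out accuracy of the top-1 model under the null (delta = 0,
    50 samples per class), over ``iterations`` independent permuted replicates.

    Each replicate draws a fresh label-free dataset — conditioning every
    replicate on one realized noise matrix would measure a dataset-specific
    quantity whose spurious signal never averages out. Replicates where the
    prefilter leaves no scorable group contribute no model and are skipped.
    Returns (mean accuracy, replicates used).
    """
    from .cv_engine import mccv_split, run_iteration, undersample
    from .io_formats import ValidationError

    accs: list[float] = []
    for i in range(iterations):
        rep_seeds = np.random.SeedSequence([seed, i]).generate_state(4) % 2**31
        ds, catalog, _ = generate(SyntheticSpec(delta=0.0, seed=int(rep_seeds[0])))
        config = GediNetConfig(seed=int(rep_seeds[1]), **BENCH_CONFIG)
        ds_bal = undersample(ds, int(rep_seeds[1]))
        train, test = mccv_split(ds_bal, config.train_frac, int(rep_seeds[2]))
        try:
            res = run_iteration(train, test, catalog, config, seed=int(rep_seeds[3]))
        except ValidationError:
            continue
        if res.performance:
            accs.append(res.performance[0].accuracy)
    return float(np.mean(accs)), len(accs)


def rra_null_fraction(
    n_universes: int = 200, n_elements: int = 50, n_lists: int = 20, seed: int = 0
) -> float:
    """Fraction of elements reaching corrected p < 0.05 when every ranked list is an
    independent uniform shuffle — the Bonferroni-corrected aggregation should keep
    this at or below the nominal 0.05."""
    rng = np.random.default_rng(seed)
    universe = [f"e{i}" for i in range(n_elements)]
    n_sig = 0
    for _ in range(n_universes):
        lists = []
        for _ in range(n_lists):
            lst = universe.copy()
            rng.shuffle(lst)
            lists.append(lst)
        agg = aggregate_ranked_lists(lists)
        n_sig += sum(a.p_value < 0.05 for a in agg)
    return n_sig / (n_universes * n_elements)
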