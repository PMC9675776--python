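"""Outer Monte Carlo cross-validation loop.

Each iteration: optionally under-sample the majority class, split 90/10 stratified
by class, prefilter genes on the training split only, build one subdataset per
disease group, score and rank the groups, then train and evaluate the cumulative
top-j model for j = 1..J on the held-out test split. Per-iteration rankings and
performance records are accumulated for rank aggregation and averaging.

All randomness derives from one master seed through per-iteration seed sequences,
so a full run is bit-reproducible and iterations are independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import GediNetConfig
from .grouping import EmptyGroupSkip, extract_subdataset, prefilter_genes
from .io_formats import (
    PERFORMANCE_COLUMNS,
    ExpressionDataset,
    GroupCatalog,
    ValidationError,
)
from .modeling import compute_metrics, fit_and_evaluate, merge_top_groups
from .scoring import (
    GroupScore,
    group_score_analytic,
    group_score_ml,
    rank_groups,
)
from .modeling import PerformanceRecord

logger = logging.getLogger(__name__)


@dataclass
class IterationResult:
    iteration: int
    ranked_groups: list[GroupScore]  # strictly ordered, rank 1 first
    performance: list[PerformanceRecord]  # one per evaluated j
    split_seed: int
    train_ids: frozenset[str]
    test_ids: frozenset[str]


def undersample(ds: ExpressionDataset, seed: int) -> ExpressionDataset:
    """Balance classes: keep the whole minority class, randomly thin the majority
    (without replacement) to the minority count."""
    rng = np.random.default_rng(seed)
    y = ds.y
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    minority, majority = (pos, neg) if pos.size <= neg.size else (neg, pos)
    if minority.size == majority.size:
        return ds
    kept = np.sort(np.concatenate([minority, rng.choice(majority, minority.size, replace=False)]))
    return ds.take_samples(kept)


def mccv_split(
    ds: ExpressionDataset, train_frac: float = 0.9, seed: int = 0
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Stratified random partition; per class round(frac * class size) samples train,
    the remainder test."""
    rng = np.random.default_rng(seed)
    y = ds.y
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if idx.size < 2:
            raise ValidationError(f"class {cls} has fewer than 2 samples")
        perm = rng.permutation(idx)
        n_train = int(round(train_frac * idx.size))
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return ds.take_samples(sorted(train_idx)), ds.take_samples(sorted(test_idx))


def _score_group(sub, config: GediNetConfig, seed: int) -> GroupScore:
    if config.scoring_method == "ml":
        return group_score_ml(
            sub,
            r=config.scoring_r,
            train_frac=config.scoring_train_frac,
            seed=seed,
            n_trees=config.n_trees,
            criterion=config.criterion,
            undersample=config.scoring_undersample,
        )
    if config.scoring_method == "analytic":
        return group_score_analytic(sub, use_absolute=config.use_absolute_t)
    raise ValueError(f"unknown scoring method {config.scoring_method!r}")


def run_iteration(
    train: ExpressionDataset,
    test: ExpressionDataset,
    catalog: GroupCatalog,
    config: GediNetConfig,
    seed: int,
    iteration: int = 0,
    split_seed: int = 0,
) -> IterationResult:
    """One G-S-M pass over an already-made train/test partition.

    Everything upstream of evaluation (prefilter, subdatasets, scoring, ranking,
    model fitting) sees only the training split.
    """
    seeds = np.random.SeedSequence(seed).generate_state(2 + len(catalog)).astype(np.int64)
    pf = prefilter_genes(train, config.prefilter_alpha, config.prefilter_max_genes)
    if not pf.kept_genes:
        raise ValidationError("prefilter kept no genes")
    train_kept = train.restrict_genes(pf.kept_genes)

    scores: list[GroupScore] = []
    for gi, name in enumerate(sorted(catalog)):
        try:
            sub = extract_subdataset(train_kept, catalog, name)
        except EmptyGroupSkip:
            continue
        if sub.n_genes < config.min_group_size:
            logger.debug("iteration %d: group %r below min size, skipped", iteration, name)
            continue
        scores.append(_score_group(sub, config, seed=int(seeds[2 + gi])))
    if not scores:
        raise ValidationError("all groups were skipped in this iteration")
    ranked = rank_groups(scores)

    performance: list[PerformanceRecord] = []
    y_test = test.y
    for j in range(1, min(config.max_j, len(ranked)) + 1):
        merged = merge_top_groups(ranked, j)
        gene_order = [g for g in train_kept.genes if g in merged]
        cc, s = fit_and_evaluate(
            train.restrict_genes(gene_order),
            test.restrict_genes(gene_order),
            seed=int(seeds[0]),
            n_trees=config.n_trees,
            criterion=config.criterion,
        )
        performance.append(compute_metrics(cc, s, y_test, j=j, n_genes=len(merged)))

    return IterationResult(
        iteration=iteration,
        ranked_groups=ranked,
        performance=performance,
        split_seed=split_seed,
        train_ids=frozenset(train.samples),
        test_ids=frozenset(test.samples),
    )


def run_gedinet(
    ds: ExpressionDataset, catalog: GroupCatalog, config: GediNetConfig
) -> list[IterationResult]:
    """The full outer MCCV loop; returns one IterationResult per successful iteration.

    Failed iterations are logged and skipped; more than 50% failures aborts the run.
    """
    if config.iterations < 1:
        raise ValueError("config.iterations must be >= 1")
    results: list[IterationResult] = []
    n_failed = 0
    for it in range(config.iterations):
        it_seeds = np.random.SeedSequence([config.seed, it]).generate_state(3).astype(np.int64)
        try:
            ds_it = undersample(ds, int(it_seeds[0])) if config.undersample else ds
            train, test = mccv_split(ds_it, config.train_frac, int(it_seeds[1]))
            results.append(
                run_iteration(
                    train,
                    test,
                    catalog,
                    config,
                    seed=int(it_seeds[2]),
                    iteration=it,
                    split_seed=int(it_seeds[1]),
                )
            )
        except (ValidationError, RuntimeError) as exc:
            n_failed += 1
            logger.warning("iteration %d failed: %s", it, exc)
        if (it + 1) % 10 == 0:
            logger.info("completed %d/%d iterations", it + 1, config.iterations)
    if n_failed > config.iterations / 2:
        raise RuntimeError(f"{n_failed}/{config.iterations} iterations failed")
    return results


def aggregate_performance(
    results: list[IterationResult], descending: bool = True
) -> pd.DataFrame:
    """Per-j arithmetic means over iterations, NaN-aware (metrics undefined in an
    iteration are excluded from that mean with a logged count)."""
    if not results:
        raise ValidationError("no successful iterations to aggregate")
    rows: dict[int, list[PerformanceRecord]] = {}
    for res in results:
        for rec in res.performance:
            rows.setdefault(rec.j, []).append(rec)
    n_missing = 0
    out = []
    for j in sorted(rows, reverse=descending):
        recs = rows[j]
        cols = {
            "#Genes": [r.n_genes for r in recs],
            "Accuracy": [r.accuracy for r in recs],
            "Sensitivity": [r.sensitivity for r in recs],
            "Specificity": [r.specificity for r in recs],
            "AUC": [r.auc for r in recs],
        }
        row = {"#Groups": j}
        for name, vals in cols.items():
            arr = np.asarray(vals, dtype=float)
            n_missing += int(np.isnan(arr).sum())
            row[name] = float(np.nanmean(arr)) if not np.isnan(arr).all() else float("nan")
        out.append(row)
    if n_missing:
        logger.info("excluded %d undefined metric values from the averages", n_missing)
    return pd.DataFrame(out, columns=PERFORMANCE_COLUMNS)
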