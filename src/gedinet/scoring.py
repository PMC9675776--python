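"""The S component: score each group's subdataset and rank the groups.

Two scorers are provided. The analytic scorer averages per-gene two-sample t
statistics over the group's k genes,

    T_i = (mu_pos - mu_neg) / sqrt(s2_pos/n1 + s2_neg/n0),
    S(group) = (1/k) * sum_i T_i        (|T_i| by default; see ``use_absolute``),

with unbiased sample variances. The machine-learning scorer trains a random forest
on r stratified random splits of the subdataset (default 90/10) and uses the mean
test accuracy as the group score — the variant the full pipeline uses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .grouping import SubDataset

logger = logging.getLogger(__name__)

DEFAULT_R = 5
DEFAULT_TRAIN_FRAC = 0.9
DEFAULT_N_TREES = 100
DEFAULT_CRITERION = "entropy"
INFINITE_T_CAP = 1e6
_SPLIT_RETRIES = 20


@dataclass(frozen=True)
class GeneTStat:
    gene: str
    T: float
    mu_pos: float
    mu_neg: float
    sd_pos: float
    sd_neg: float
    n1: int
    n0: int
    flagged: bool = False  # True when both variances were zero but means differ


@dataclass(frozen=True)
class GroupScore:
    group_name: str
    score: float
    gene_set: frozenset[str]
    method: str  # "analytic" or "ml"
    rank: int = 0  # populated by rank_groups
    flagged: bool = False

    @property
    def n_genes(self) -> int:
        return len(self.gene_set)


def gene_t_statistic(
    values_pos: np.ndarray, values_neg: np.ndarray, gene: str = ""
) -> GeneTStat:
    """Welch-style t statistic for one gene given per-class expression vectors."""
    pos = np.asarray(values_pos, dtype=float)
    neg = np.asarray(values_neg, dtype=float)
    n1, n0 = pos.size, neg.size
    if n1 < 2 or n0 < 2:
        raise ValueError("need at least 2 samples per class")
    mu_pos, mu_neg = pos.mean(), neg.mean()
    var_pos, var_neg = pos.var(ddof=1), neg.var(ddof=1)
    denom = math.sqrt(var_pos / n1 + var_neg / n0)
    flagged = False
    if denom == 0.0:
        if mu_pos == mu_neg:
            t = 0.0
        else:
            t = math.inf if mu_pos > mu_neg else -math.inf
            flagged = True
    else:
        t = (mu_pos - mu_neg) / denom
    return GeneTStat(
        gene=gene,
        T=t,
        mu_pos=float(mu_pos),
        mu_neg=float(mu_neg),
        sd_pos=float(math.sqrt(var_pos)),
        sd_neg=float(math.sqrt(var_neg)),
        n1=n1,
        n0=n0,
        flagged=flagged,
    )


def group_score_analytic(
    sub: SubDataset, use_absolute: bool = True, infinite_cap: float = INFINITE_T_CAP
) -> GroupScore:
    """Mean (absolute) per-gene t statistic over the group's genes.

    Signed averaging lets opposite-direction genes cancel, so the default takes
    |T_i|; the signed variant is kept for completeness. Infinite statistics
    (zero variance, shifted means) are clipped to ``infinite_cap`` and flag the
    group.
    """
    ds = sub.data
    if ds.n_genes < 1:
        raise ValueError("subdataset has no genes")
    y = ds.y
    pos = ds.values[y == 1, :]
    neg = ds.values[y == 0, :]
    total = 0.0
    flagged = False
    for i, gene in enumerate(ds.genes):
        t = gene_t_statistic(pos[:, i], neg[:, i], gene=gene)
        val = t.T
        if not math.isfinite(val):
            flagged = True
            val = math.copysign(infinite_cap, val)
        total += abs(val) if use_absolute else val
    return GroupScore(
        group_name=sub.group_name,
        score=total / ds.n_genes,
        gene_set=frozenset(ds.genes),
        method="analytic",
        flagged=flagged,
    )


def make_forest(
    n_trees: int = DEFAULT_N_TREES,
    criterion: str = DEFAULT_CRITERION,
    random_state: int | None = None,
) -> RandomForestClassifier:
    """The forest used everywhere: 100 entropy-split trees by default."""
    return RandomForestClassifier(
        n_estimators=n_trees,
        criterion=criterion,
        random_state=random_state,
        n_jobs=1,
    )


def _stratified_split(
    y: np.ndarray, train_frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random partition: round(frac * class size) to train, rest to test."""
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        perm = rng.permutation(idx)
        n_train = int(round(train_frac * idx.size))
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(test_idx))


def _undersample_indices(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Keep every minority sample; thin the majority to the minority count."""
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    minority, majority = (pos, neg) if pos.size <= neg.size else (neg, pos)
    if minority.size == majority.size:
        return np.arange(y.size)
    kept_major = rng.choice(majority, size=minority.size, replace=False)
    return np.sort(np.concatenate([minority, kept_major]))


def group_score_ml(
    sub: SubDataset,
    r: int = DEFAULT_R,
    train_frac: float = DEFAULT_TRAIN_FRAC,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    criterion: str = DEFAULT_CRITERION,
    undersample: bool = True,
) -> GroupScore:
    """Mean random-forest test accuracy over r stratified random splits.

    Splits are stratified by class so the small test side keeps both classes;
    classes are balanced by under-sampling first (a no-op on balanced data) when
    ``undersample`` is set. Fully deterministic for a fixed seed.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    if not 0.5 < train_frac < 0.95:
        raise ValueError("train_frac must be in (0.5, 0.95)")
    ds = sub.data
    rng = np.random.default_rng(seed)
    X, y = ds.values, ds.y
    if undersample:
        keep = _undersample_indices(y, rng)
        X, y = X[keep], y[keep]
    accuracies: list[float] = []
    for split in range(r):
        for _ in range(_SPLIT_RETRIES):
            tr, te = _stratified_split(y, train_frac, rng)
            if te.size and len(np.unique(y[te])) == 2 and len(np.unique(y[tr])) == 2:
                break
        else:
            logger.warning(
                "group %s: could not draw a two-class test split; skipping one split",
                sub.group_name,
            )
            continue
        clf = make_forest(n_trees, criterion, random_state=int(rng.integers(2**31 - 1)))
        clf.fit(X[tr], y[tr])
        accuracies.append(float((clf.predict(X[te]) == y[te]).mean()))
    if not accuracies:
        raise RuntimeError(f"group {sub.group_name}: every split failed")
    return GroupScore(
        group_name=sub.group_name,
        score=float(np.mean(accuracies)),
        gene_set=frozenset(ds.genes),
        method="ml",
    )


def rank_groups(scores: list[GroupScore]) -> list[GroupScore]:
    """Ranks 1..m by descending score; ties broken by larger gene set, then name."""
    if not scores:
        raise ValueError("no scores to rank")
    ordered = sorted(scores, key=lambda s: (-s.score, -s.n_genes, s.group_name))
    return [replace(s, rank=i + 1) for i, s in enumerate(ordered)]


def assign_gene_scores(ranked: list[GroupScore]) -> list[tuple[str, float]]:
    """Give each gene the score of its group; genes in several groups keep the max.

    Output is sorted by descending score (ties by gene symbol) so it can serve
    directly as a per-iteration gene ranking.
    """
    best: dict[str, float] = {}
    for gs in ranked:
        for gene in gs.gene_set:
            if gene not in best or gs.score > best[gene]:
                best[gene] = gs.score
    return sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))
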