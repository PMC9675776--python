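"""The M component: merge the genes of the top-j groups, train the final forest on
the training split and evaluate it on the held-out test split.

Metrics follow the usual confusion-matrix identities —
SEN = TP/(TP+FN), SPE = TN/(TN+FP), ACC = (TP+TN)/total — and AUC is the rank
(Mann-Whitney) area computed from continuous positive-class scores. Ratios with a
zero denominator are reported as missing (NaN), never as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import ExpressionDataset
from .scoring import GroupScore, make_forest

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class PerformanceRecord:
    j: int
    n_genes: int
    accuracy: float
    sensitivity: float  # NaN when TP+FN == 0
    specificity: float  # NaN when TN+FP == 0
    auc: float  # NaN when the test truth is single-class


def merge_top_groups(ranked: list[GroupScore], j: int) -> frozenset[str]:
    """Union of the gene sets of ranks 1..j."""
    if not 1 <= j <= len(ranked):
        raise ValueError(f"j={j} out of range 1..{len(ranked)}")
    by_rank = sorted(ranked, key=lambda s: s.rank)
    merged: set[str] = set()
    for gs in by_rank[:j]:
        merged |= gs.gene_set
    return frozenset(merged)


def fit_and_evaluate(
    train: ExpressionDataset,
    test: ExpressionDataset,
    seed: int = 0,
    n_trees: int = 100,
    criterion: str = "entropy",
) -> tuple[ConfusionCounts, np.ndarray]:
    """Train the forest on the training split only; return the confusion counts of
    its hard predictions on the test split plus continuous positive-class scores."""
    if train.genes != test.genes:
        raise ValueError("train and test must carry the same gene columns")
    y_train, y_test = train.y, test.y
    if len(np.unique(y_train)) < 2:
        raise ValueError("both classes required in the training split")
    if test.n_samples == 0:
        raise ValueError("test split is empty")
    clf = make_forest(n_trees, criterion, random_state=seed)
    clf.fit(train.values, y_train)
    pred = clf.predict(test.values)
    pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
    scores = clf.predict_proba(test.values)[:, pos_col]
    cc = ConfusionCounts(
        TP=int(((pred == 1) & (y_test == 1)).sum()),
        FP=int(((pred == 1) & (y_test == 0)).sum()),
        TN=int(((pred == 0) & (y_test == 0)).sum()),
        FN=int(((pred == 0) & (y_test == 1)).sum()),
    )
    return cc, scores


def rank_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie); NaN if one class."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    n1 = int((truth == 1).sum())
    n0 = int((truth == 0).sum())
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    r_pos = ranks[truth == 1].sum()
    return float((r_pos - n1 * (n1 + 1) / 2) / (n1 * n0))


def compute_metrics(
    cc: ConfusionCounts,
    scores: np.ndarray | None,
    truth: np.ndarray | None,
    j: int = 0,
    n_genes: int = 0,
) -> PerformanceRecord:
    """Confusion-derived metrics plus rank-based AUC for one top-j model."""
    if truth is not None and cc.total != len(truth):
        raise ValueError("confusion counts inconsistent with truth length")
    sen = cc.TP / (cc.TP + cc.FN) if (cc.TP + cc.FN) > 0 else float("nan")
    spe = cc.TN / (cc.TN + cc.FP) if (cc.TN + cc.FP) > 0 else float("nan")
    acc = (cc.TP + cc.TN) / cc.total if cc.total > 0 else float("nan")
    if scores is not None and truth is not None:
        auc = rank_auc(scores, truth)
    else:
        auc = float("nan")
    return PerformanceRecord(
        j=j, n_genes=n_genes, accuracy=acc, sensitivity=sen, specificity=spe, auc=auc
    )
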