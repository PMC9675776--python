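"""The G component: association filtering, group catalogs, differential-expression
prefiltering and per-group two-class subdatasets.

The prefilter follows the classic two-stage recipe: Brown-Forsythe (median-centred
Levene) test for equality of variances at level 0.05 decides, per gene, between the
pooled two-sample t-test and Welch's unequal-variance t-test; genes with a two-sided
p-value below ``alpha`` are kept, sorted ascending, and capped at ``max_kept``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import (
    AssociationRecord,
    ExpressionDataset,
    GroupCatalog,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_ALLOWED_TYPES = frozenset({"disease"})
DEFAULT_ALLOWED_SEMANTIC_TYPES = frozenset({"Neoplastic Process", "Disease"})
DEFAULT_ALPHA = 0.05
DEFAULT_MAX_KEPT = 2000
LEVENE_ALPHA = 0.05


@dataclass(frozen=True)
class PrefilterResult:
    """Genes surviving the differential-expression prefilter, most significant first."""

    kept_genes: tuple[str, ...]
    p_values: dict[str, float]  # per *kept* gene
    max_kept: int = DEFAULT_MAX_KEPT
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if len(self.kept_genes) > self.max_kept:
            raise ValidationError("kept more genes than max_kept")


@dataclass(frozen=True)
class SubDataset:
    """One group's view of the expression data: its genes, the original labels."""

    group_name: str
    data: ExpressionDataset  # restricted to the group's genes, labels preserved

    @property
    def genes(self) -> tuple[str, ...]:
        return self.data.genes

    @property
    def n_genes(self) -> int:
        return self.data.n_genes


def filter_associations(
    records: list[AssociationRecord],
    allowed_types: frozenset[str] = DEFAULT_ALLOWED_TYPES,
    allowed_semantic_types: frozenset[str] = DEFAULT_ALLOWED_SEMANTIC_TYPES,
) -> list[AssociationRecord]:
    """Keep records whose diseaseType and diseaseSemanticType are both allowed.

    Defaults keep type "disease" with semantic type "Neoplastic Process" or
    "Disease", the standard restriction for gene-disease catalogs of this kind.
    """
    if not allowed_types or not allowed_semantic_types:
        raise ValueError("allowed type sets must be non-empty")
    kept = [
        r
        for r in records
        if r.disease_type in allowed_types
        and r.disease_semantic_type in allowed_semantic_types
    ]
    if not kept:
        logger.warning("association filter removed every record")
    return kept


def build_group_catalog(
    records: list[AssociationRecord],
    min_group_size: int = 2,
    max_group_size: int | None = None,
) -> GroupCatalog:
    """Group (already filtered) association records by disease into gene sets.

    Gene sets are deduplicated; groups outside [min_group_size, max_group_size]
    are dropped with a logged count. Raises if no group survives.
    """
    if min_group_size < 1:
        raise ValueError("min_group_size must be >= 1")
    by_disease: dict[str, set[str]] = {}
    for r in records:
        by_disease.setdefault(r.disease, set()).add(r.gene)
    groups: dict[str, frozenset[str]] = {}
    n_dropped = 0
    for disease, genes in by_disease.items():
        if len(genes) < min_group_size or (
            max_group_size is not None and len(genes) > max_group_size
        ):
            n_dropped += 1
            continue
        groups[disease] = frozenset(genes)
    if n_dropped:
        logger.info("dropped %d groups outside size bounds", n_dropped)
    if not groups:
        raise ValidationError("no groups survive the size filter")
    return GroupCatalog(groups=groups)


def _brown_forsythe_p(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Vectorized two-group Brown-Forsythe test p-values, one per gene (column).

    Equivalent to scipy.stats.levene(center="median") applied column-wise: a
    one-way ANOVA F statistic on absolute deviations from the group medians.
    """
    n1, n0 = pos.shape[0], neg.shape[0]
    z1 = np.abs(pos - np.median(pos, axis=0, keepdims=True))
    z0 = np.abs(neg - np.median(neg, axis=0, keepdims=True))
    m1 = z1.mean(axis=0)
    m0 = z0.mean(axis=0)
    grand = (n1 * m1 + n0 * m0) / (n1 + n0)
    between = n1 * (m1 - grand) ** 2 + n0 * (m0 - grand) ** 2  # df = 1
    within = ((z1 - m1) ** 2).sum(axis=0) + ((z0 - m0) ** 2).sum(axis=0)
    dof = n1 + n0 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = between / (within / dof)
    p = stats.f.sf(f, 1, dof)
    # degenerate: no spread in the deviations at all -> variances trivially equal
    return np.where(np.isfinite(f), p, 1.0)


def prefilter_genes(
    train: ExpressionDataset,
    alpha: float = DEFAULT_ALPHA,
    max_kept: int = DEFAULT_MAX_KEPT,
) -> PrefilterResult:
    """Differential-expression prefilter on a training split.

    Per gene: Brown-Forsythe at 0.05 chooses pooled vs Welch t-test; keep genes with
    two-sided t-test p < alpha, sorted by ascending p (ties broken by gene symbol),
    truncated to max_kept. Genes with zero variance in both classes get p = 1.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    y = train.y
    pos = train.values[y == 1, :]
    neg = train.values[y == 0, :]
    if pos.shape[0] < 2 or neg.shape[0] < 2:
        raise ValidationError("need at least 2 samples per class for the prefilter")

    levene_p = _brown_forsythe_p(pos, neg)
    unequal = levene_p < LEVENE_ALPHA

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant genes trigger precision warnings; they are mapped to p = 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        p_pooled = stats.ttest_ind(pos, neg, axis=0, equal_var=True).pvalue
        p_welch = stats.ttest_ind(pos, neg, axis=0, equal_var=False).pvalue
    p = np.where(unequal, p_welch, p_pooled)

    both_flat = (pos.var(axis=0) == 0) & (neg.var(axis=0) == 0)
    p = np.where(both_flat | ~np.isfinite(p), 1.0, p)

    order = sorted(
        (i for i in range(train.n_genes) if p[i] < alpha),
        key=lambda i: (p[i], train.genes[i]),
    )
    order = order[:max_kept]
    kept = tuple(train.genes[i] for i in order)
    return PrefilterResult(
        kept_genes=kept,
        p_values={train.genes[i]: float(p[i]) for i in order},
        max_kept=max_kept,
        alpha=alpha,
    )


class EmptyGroupSkip(Exception):
    """Raised when a group has no genes in the dataset; callers skip the group."""


def extract_subdataset(
    ds: ExpressionDataset, catalog: GroupCatalog, group_name: str
) -> SubDataset:
    """Restrict the dataset to one group's genes (intersection), labels preserved.

    Gene order follows the dataset's column order for determinism. A group whose
    genes are all absent raises EmptyGroupSkip, which callers treat as a skip.
    """
    if group_name not in catalog:
        raise KeyError(f"unknown group {group_name!r}")
    members = catalog[group_name]
    genes = [g for g in ds.genes if g in members]
    if not genes:
        raise EmptyGroupSkip(group_name)
    return SubDataset(group_name=group_name, data=ds.restrict_genes(genes))
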