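"""Synthetic two-class expression data with planted disease groups.

The generator emulates a processed microarray study: Gaussian expression, a catalog
of gene groups, and a configurable subset of "planted" groups whose member genes
have their positive-class mean shifted by delta noise-sd units. Everything else is
pure noise, so ground truth is exact and every pipeline stage is testable offline.

Defaults mirror the benchmark condition used throughout the test suite: 50 samples
per class, 20 groups of 10 genes among 300 genes total, one planted group at
delta = 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import ExpressionDataset, GroupCatalog


@dataclass(frozen=True)
class SyntheticSpec:
    n_pos: int = 50
    n_neg: int = 50
    n_genes: int = 300
    n_groups: int = 20
    group_size: int = 10
    n_planted: int = 1
    delta: float = 3.0  # class-mean shift of planted genes, in noise-sd units
    overlap_frac: float = 0.0  # fraction of genes shared between adjacent groups
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted > self.n_groups:
            raise ValueError("planted groups must be a subset of the groups")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if not 0 <= self.overlap_frac < 1:
            raise ValueError("overlap_frac must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass(frozen=True)
class GroundTruth:
    planted_groups: tuple[str, ...]
    planted_genes: frozenset[str]


def _group_memberships(spec: SyntheticSpec) -> dict[str, frozenset[str]]:
    """Sliding-window group assignment: adjacent groups share
    floor(overlap_frac * group_size) genes."""
    shared = int(spec.overlap_frac * spec.group_size)
    step = spec.group_size - shared
    genes_needed = spec.group_size + step * (spec.n_groups - 1)
    if genes_needed > spec.n_genes:
        raise ValueError(
            f"groups need {genes_needed} genes but only {spec.n_genes} are available"
        )
    width = len(str(spec.n_genes))
    names = [f"G{i + 1:0{width}d}" for i in range(spec.n_genes)]
    groups = {}
    for g in range(spec.n_groups):
        start = g * step
        members = names[start : start + spec.group_size]
        groups[f"disease_{g + 1:02d}"] = frozenset(members)
    return groups


def generate(spec: SyntheticSpec) -> tuple[ExpressionDataset, GroupCatalog, GroundTruth]:
    """Draw the dataset, the group catalog and the ground truth, seed-deterministically.

    Planted groups are the first ``n_planted`` groups; their member genes get
    +delta * noise_sd added to every positive-class sample.
    """
    rng = np.random.default_rng(spec.seed)
    groups = _group_memberships(spec)
    n_samples = spec.n_pos + spec.n_neg
    values = rng.normal(0.0, spec.noise_sd, size=(n_samples, spec.n_genes))

    width = len(str(spec.n_genes))
    gene_names = tuple(f"G{i + 1:0{width}d}" for i in range(spec.n_genes))
    gene_index = {g: i for i, g in enumerate(gene_names)}

    group_names = list(groups)
    planted = tuple(group_names[: spec.n_planted])
    planted_genes: set[str] = set()
    for name in planted:
        planted_genes |= set(groups[name])
    pos_rows = np.arange(spec.n_pos)  # positive samples come first
    for gene in planted_genes:
        values[pos_rows, gene_index[gene]] += spec.delta * spec.noise_sd

    samples = tuple(
        f"S{i + 1:03d}_{'pos' if i < spec.n_pos else 'neg'}" for i in range(n_samples)
    )
    labels = tuple("pos" if i < spec.n_pos else "neg" for i in range(n_samples))
    ds = ExpressionDataset(samples=samples, genes=gene_names, values=values, labels=labels)
    truth = GroundTruth(planted_groups=planted, planted_genes=frozenset(planted_genes))
    return ds, GroupCatalog(groups=groups), truth
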