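"""Robust rank aggregation of per-iteration ranked lists.

Each element's positions across L ranked lists are normalized to (0, 1] against the
universe size n (position k -> k/n; absence from a list -> 1.0, the worst rank).
For the sorted normalized ranks r_(1) <= ... <= r_(L), the beta score

    b_k = P(Beta(k, L-k+1) <= r_(k)) = sum_{i=k}^{L} C(L,i) r_(k)^i (1-r_(k))^(L-i)

is the probability that the k-th order statistic of L independent uniforms falls at
or below r_(k); rho = min_k b_k, and the reported significance is the
Bonferroni-corrected p = min(1, rho * n).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GroupCatalog, ValidationError
from .scoring import assign_gene_scores


@dataclass(frozen=True)
class AggregatedRanking:
    element: str
    rho: float
    p_value: float  # min(1, rho * universe size)
    mean_rank: float  # mean normalized rank, imputed 1.0 where absent
    n_lists: int  # number of lists the element actually appeared in


def normalize_ranks(
    lists: Sequence[Sequence[str]],
    universe_size: int | None = None,
    universe: Sequence[str] | None = None,
) -> dict[str, np.ndarray]:
    """Per-element vectors of normalized ranks, one entry per input list.

    Position k (1-based) in a universe of n maps to k/n; elements absent from a
    list are imputed the worst rank 1.0. ``universe`` optionally pads the element
    set with names that appear in no list (their vectors are all 1.0).
    """
    elements: list[str] = list(universe) if universe is not None else []
    seen: set[str] = set(elements)
    for lst in lists:
        if len(set(lst)) != len(lst):
            raise ValidationError("duplicate element within one ranked list")
        for el in lst:
            if el not in seen:
                seen.add(el)
                elements.append(el)
    n = universe_size if universe_size is not None else len(elements)
    if n < max((len(lst) for lst in lists), default=0):
        raise ValueError("universe_size smaller than the longest list")
    out = {el: np.ones(len(lists)) for el in elements}
    for li, lst in enumerate(lists):
        for pos, el in enumerate(lst, start=1):
            out[el][li] = pos / n
    return out


def rra_rho(norm_ranks: Iterable[float]) -> float:
    """Minimum beta score over the sorted normalized rank vector.

    Uses the Beta(k, L-k+1) CDF, which equals the binomial tail
    sum_{i>=k} C(L,i) r^i (1-r)^(L-i) exactly.
    """
    r = np.sort(np.asarray(list(norm_ranks), dtype=float))
    L = r.size
    if L == 0:
        raise ValueError("empty rank vector")
    if (r <= 0).any() or (r > 1).any():
        raise ValueError("normalized ranks must lie in (0, 1]")
    k = np.arange(1, L + 1)
    b = stats.beta.cdf(r, k, L - k + 1)
    return float(b.min())


def corrected_p(rho: float, universe_size: int) -> float:
    """Bonferroni correction over the universe of aggregated elements."""
    return min(1.0, rho * universe_size)


def aggregate_ranked_lists(
    lists: Sequence[Sequence[str]],
    universe_size: int | None = None,
    universe: Sequence[str] | None = None,
) -> list[AggregatedRanking]:
    """RRA over explicit ranked lists; output sorted by ascending corrected p."""
    vectors = normalize_ranks(lists, universe_size, universe)
    n = universe_size if universe_size is not None else len(vectors)
    appear = {el: 0 for el in vectors}
    for lst in lists:
        for el in lst:
            appear[el] += 1
    out = []
    for el, vec in vectors.items():
        rho = rra_rho(vec)
        out.append(
            AggregatedRanking(
                element=el,
                rho=rho,
                p_value=corrected_p(rho, n),
                mean_rank=float(vec.mean()),
                n_lists=appear[el],
            )
        )
    return sorted(out, key=lambda a: (a.p_value, a.mean_rank, a.element))


def aggregate_rankings(
    results: Sequence,
    level: str = "group",
    top_k: int | None = None,
    catalog: GroupCatalog | None = None,
) -> list[AggregatedRanking]:
    """Aggregate per-iteration rankings from the MCCV loop.

    level="group" ranks disease groups by their per-iteration rank; level="gene"
    orders genes by the group-score inheritance rule (each gene takes its best
    group's score). ``top_k`` truncates each per-iteration list before aggregation.
    A ``catalog`` pads the group universe so diseases skipped in every iteration
    still appear (with p = 1).
    """
    if not results:
        raise ValidationError("no iteration results to aggregate")
    lists: list[list[str]] = []
    for res in results:
        ranked = sorted(res.ranked_groups, key=lambda g: g.rank)
        if level == "group":
            lst = [g.group_name for g in ranked]
        elif level == "gene":
            lst = [gene for gene, _ in assign_gene_scores(ranked)]
        else:
            raise ValueError(f"unknown level {level!r}")
        lists.append(lst[:top_k] if top_k is not None else lst)
    universe = sorted(catalog) if (catalog is not None and level == "group") else None
    return aggregate_ranked_lists(lists, universe=universe)


def ranking_to_frame(
    agg: list[AggregatedRanking],
    catalog: GroupCatalog | None = None,
    level: str = "group",
) -> pd.DataFrame:
    """Render an aggregated ranking as the output table shape.

    Group level: Disease name, P-value, #Genes, List of genes (gene annotations
    from the catalog when given). Gene level: Gene, P-value.
    """
    if level == "gene":
        return pd.DataFrame(
            {"Gene": [a.element for a in agg], "P-value": [a.p_value for a in agg]}
        )
    rows = []
    for a in agg:
        genes = sorted(catalog[a.element]) if catalog and a.element in catalog else []
        rows.append(
            {
                "Disease name": a.element,
                "P-value": a.p_value,
                "#Genes": len(genes),
                "List of genes": ", ".join(genes),
            }
        )
    return pd.DataFrame(rows, columns=["Disease name", "P-value", "#Genes", "List of genes"])
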