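"""Disease-disease association indices over the top-ranked disease groups.

Two overlap families are exposed: the Jaccard index |A∩B|/|A∪B| over gene sets
(or variant sets), and the Simpson-style shared-gene fraction |A∩B|/min(|A|,|B|).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

INDEX_KINDS = ("jaccard_gene", "jaccard_variant", "shared_fraction")


@dataclass(frozen=True)
class DiseaseGeneSet:
    disease: str
    genes: frozenset[str]
    variants: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"disease {self.disease!r} has an empty gene set")


@dataclass
class DDAMatrix:
    diseases: tuple[str, ...]
    values: np.ndarray  # symmetric, entries in [0, 1] (NaN where undefined)
    index_kind: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.diseases), columns=list(self.diseases))


def jaccard_index(set1: frozenset | set, set2: frozenset | set) -> float:
    """|intersection| / |union|; NaN when both sets are empty."""
    union = set1 | set2
    if not union:
        return float("nan")
    return len(set1 & set2) / len(union)


def shared_fraction(set1: frozenset | set, set2: frozenset | set) -> float:
    """Simpson overlap |intersection| / min(|set1|, |set2|); NaN if either is empty."""
    if not set1 or not set2:
        return float("nan")
    return len(set1 & set2) / min(len(set1), len(set2))


def build_dda_matrix(
    sets: list[DiseaseGeneSet], index_kind: str = "shared_fraction", top_k: int | None = None
) -> DDAMatrix:
    """Symmetric pairwise overlap matrix over the first top_k disease sets."""
    if index_kind not in INDEX_KINDS:
        raise ValueError(f"index_kind must be one of {INDEX_KINDS}")
    if top_k is not None:
        if top_k > len(sets):
            logger.warning("top_k=%d exceeds %d available diseases; truncating", top_k, len(sets))
        sets = sets[:top_k]
    if index_kind == "jaccard_variant" and any(not s.variants for s in sets):
        raise ValueError("jaccard_variant requires variant sets for every disease")

    def members(s: DiseaseGeneSet) -> frozenset[str]:
        return s.variants if index_kind == "jaccard_variant" else s.genes

    fn = shared_fraction if index_kind == "shared_fraction" else jaccard_index
    n = len(sets)
    values = np.zeros((n, n))
    for i in range(n):
        for k in range(i, n):
            v = fn(members(sets[i]), members(sets[k]))
            values[i, k] = values[k, i] = v
    return DDAMatrix(
        diseases=tuple(s.disease for s in sets), values=values, index_kind=index_kind
    )


def export_edge_list(matrix: DDAMatrix, threshold: float = 0.0) -> pd.DataFrame:
    """Rows (disease1, disease2, index) for unordered pairs with index >= threshold,
    disease1 < disease2 lexicographically."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    rows = []
    n = len(matrix.diseases)
    for i in range(n):
        for k in range(i + 1, n):
            v = matrix.values[i, k]
            if np.isnan(v) or v < threshold:
                continue
            d1, d2 = sorted((matrix.diseases[i], matrix.diseases[k]))
            rows.append({"disease1": d1, "disease2": d2, "index": float(v)})
    return pd.DataFrame(rows, columns=["disease1", "disease2", "index"])
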