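"""End-to-end convenience: MCCV run -> averaged performance, aggregated rankings,
disease-disease association matrix, all bundled for write_results."""

from __future__ import annotations

from .config import GediNetConfig
from .cv_engine import IterationResult, aggregate_performance, run_gedinet
from .dda import DiseaseGeneSet, build_dda_matrix, export_edge_list
from .io_formats import ExpressionDataset, GroupCatalog, ResultsBundle
from .rank_aggregation import aggregate_rankings, ranking_to_frame


def analyze(
    ds: ExpressionDataset,
    catalog: GroupCatalog,
    config: GediNetConfig | None = None,
    dda_top_k: int = 10,
    dda_index_kind: str = "shared_fraction",
    dda_threshold: float = 0.0,
) -> tuple[ResultsBundle, list[IterationResult]]:
    """Run the full pipeline and assemble every output table.

    The DDA matrix is built over the ``dda_top_k`` most significant diseases of the
    aggregated ranking, using their catalog gene sets.
    """
    config = config or GediNetConfig()
    results = run_gedinet(ds, catalog, config)
    performance = aggregate_performance(results)

    group_agg = aggregate_rankings(results, level="group", catalog=catalog)
    gene_agg = aggregate_rankings(results, level="gene")

    top = [a.element for a in group_agg[:dda_top_k] if a.element in catalog]
    sets = [DiseaseGeneSet(disease=d, genes=catalog[d]) for d in top]
    dda_matrix = build_dda_matrix(sets, index_kind=dda_index_kind) if sets else None

    bundle = ResultsBundle(
        performance=performance,
        disease_ranking=ranking_to_frame(group_agg, catalog=catalog, level="group"),
        gene_ranking=ranking_to_frame(gene_agg, level="gene"),
        dda_matrix=dda_matrix.to_frame() if dda_matrix is not None else None,
        dda_edges=export_edge_list(dda_matrix, dda_threshold) if dda_matrix is not None else None,
    )
    return bundle, results
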