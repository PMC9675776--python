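"""Disease-disease association matrices from gene-set overlap.

Builds a tiny gene-disease catalog from association records, then compares the two
overlap indices: Jaccard |A∩B|/|A∪B| and the shared-gene (Simpson) fraction
|A∩B|/min(|A|,|B|). The Simpson fraction is 1.0 whenever the smaller set is nested
in the larger one, while Jaccard still penalizes the size difference.
"""

from gedinet import (
    AssociationRecord,
    DiseaseGeneSet,
    build_dda_matrix,
    build_group_catalog,
    export_edge_list,
    filter_associations,
)

rows = [
    ("TP53", "Glioma"), ("EGFR", "Glioma"), ("PTEN", "Glioma"), ("IDH1", "Glioma"),
    ("TP53", "Breast carcinoma"), ("BRCA2", "Breast carcinoma"), ("PTEN", "Breast carcinoma"),
    ("TP53", "Li-Fraumeni syndrome"), ("PTEN", "Li-Fraumeni syndrome"),
]
records = filter_associations(
    [AssociationRecord(g, d, "disease", "Neoplastic Process") for g, d in rows]
)
catalog = build_group_catalog(records, min_group_size=2)
sets = [DiseaseGeneSet(d, catalog[d]) for d in sorted(catalog)]

for kind in ("jaccard_gene", "shared_fraction"):
    m = build_dda_matrix(sets, index_kind=kind)
    print(f"\n{kind} matrix:")
    print(m.to_frame().round(3).to_string())

print("\nedges with shared fraction >= 0.5:")
print(export_edge_list(build_dda_matrix(sets, "shared_fraction"), 0.5).to_string(index=False))
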