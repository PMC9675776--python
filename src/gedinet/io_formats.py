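"""Readers and writers for expression tables, gene-disease tables, GMT files and results.

Expression input is a delimited table with samples in rows, genes in columns and one
class-label column. Gene groupings come either from a DisGeNET-dialect TSV of
gene-disease associations or from a Broad-dialect GMT file. All result tables are
written as plain TSV.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

POS = "pos"
NEG = "neg"

#: canonical lower-cased names for the gene-disease TSV columns we require
_DISGENET_COLUMNS = {
    "genesymbol": "gene",
    "diseasename": "disease",
    "diseasetype": "disease_type",
    "diseasesemantictype": "disease_semantic_type",
}


class FormatError(ValueError):
    """A file does not conform to its expected dialect."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


@dataclass(frozen=True)
class ExpressionDataset:
    """A two-class expression matrix: samples x genes plus a pos/neg label per sample."""

    samples: tuple[str, ...]
    genes: tuple[str, ...]
    values: np.ndarray  # shape (n_samples, n_genes), float
    labels: tuple[str, ...]  # each in {"pos", "neg"}

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene symbols")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample identifiers")
        if self.values.shape != (len(self.samples), len(self.genes)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.genes)} genes"
            )
        label_set = set(self.labels)
        if not label_set <= {POS, NEG}:
            raise ValidationError(f"labels must be in {{pos, neg}}, got {label_set}")
        # both classes are required of any *input* dataset (the reader enforces at
        # least 2 samples per class); sample subsets such as test splits may be
        # single-class, so the container itself only requires non-emptiness
        if not label_set:
            raise ValidationError("dataset has no samples")
        if len(self.labels) != len(self.samples):
            raise ValidationError("one label per sample required")
        if np.isnan(self.values).any():
            raise ValidationError("missing values must be removed before construction")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def y(self) -> np.ndarray:
        """Binary label vector, 1 for the positive class."""
        return np.asarray([1 if l == POS else 0 for l in self.labels], dtype=int)

    def class_counts(self) -> tuple[int, int]:
        """(n_pos, n_neg)."""
        y = self.y
        return int(y.sum()), int((1 - y).sum())

    def restrict_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        """Column subset, preserving the given gene order; unknown genes are an error."""
        index = {g: i for i, g in enumerate(self.genes)}
        try:
            cols = [index[g] for g in genes]
        except KeyError as exc:
            raise KeyError(f"gene not in dataset: {exc.args[0]}") from None
        return ExpressionDataset(
            samples=self.samples,
            genes=tuple(genes),
            values=self.values[:, cols],
            labels=self.labels,
        )

    def take_samples(self, idx: Sequence[int]) -> "ExpressionDataset":
        idx = list(idx)
        return ExpressionDataset(
            samples=tuple(self.samples[i] for i in idx),
            genes=self.genes,
            values=self.values[idx, :],
            labels=tuple(self.labels[i] for i in idx),
        )

    def to_frame(self, label_column: str = "class") -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=list(self.samples), columns=list(self.genes))
        df[label_column] = list(self.labels)
        return df


@dataclass(frozen=True)
class AssociationRecord:
    """One gene-disease association row."""

    gene: str
    disease: str
    disease_type: str
    disease_semantic_type: str

    def __post_init__(self) -> None:
        if not self.gene or not self.disease:
            raise ValidationError("gene and disease must be non-empty")


@dataclass
class GroupCatalog:
    """Ordered mapping of disease (group) name -> gene set."""

    groups: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.groups.items():
            if not genes:
                raise ValidationError(f"group {name!r} is empty")

    @property
    def sizes(self) -> dict[str, int]:
        return {name: len(genes) for name, genes in self.groups.items()}

    def __len__(self) -> int:
        return len(self.groups)

    def __iter__(self):
        return iter(self.groups)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.groups[name]

    def __contains__(self, name: str) -> bool:
        return name in self.groups


def _detect_delimiter(path: str) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_expression_table(
    path: str,
    label_column: str = "class",
    delimiter: str | None = None,
    pos_label: str | None = None,
) -> ExpressionDataset:
    """Read a samples x genes table with one label column.

    Rows containing any missing value are dropped (and the count logged). Labels may
    be any two distinct strings: they are mapped onto pos/neg, with ``pos_label``
    naming the positive class explicitly; by default the lexicographically later
    label is taken as positive.
    """
    if delimiter is None:
        delimiter = _detect_delimiter(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delimiter)
    gene_cols = [c for c in header[1:] if c != label_column]
    if len(set(gene_cols)) != len(gene_cols):
        raise ValidationError("duplicate gene columns")
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if label_column not in df.columns:
        raise FormatError(f"label column {label_column!r} not found in {path}")
    n_before = len(df)
    df = df.dropna(axis=0, how="any")
    dropped = n_before - len(df)
    if dropped:
        logger.info("dropped %d rows with missing values from %s", dropped, path)

    raw_labels = df[label_column].astype(str)
    values = df.drop(columns=[label_column])
    distinct = sorted(set(raw_labels))
    if len(distinct) != 2:
        raise ValidationError(
            f"expected exactly two classes, found {len(distinct)}: {distinct}"
        )
    if pos_label is None:
        pos_label = distinct[1] if distinct != [NEG, POS] else POS
    elif pos_label not in distinct:
        raise ValidationError(f"pos_label {pos_label!r} not among labels {distinct}")
    labels = tuple(POS if l == pos_label else NEG for l in raw_labels)
    for cls in (POS, NEG):
        if labels.count(cls) < 2:
            raise ValidationError(f"fewer than 2 samples in class {cls!r}")
    if values.columns.duplicated().any():
        raise ValidationError("duplicate gene columns")
    return ExpressionDataset(
        samples=tuple(str(s) for s in df.index),
        genes=tuple(str(g) for g in values.columns),
        values=values.to_numpy(dtype=float),
        labels=labels,
    )


def write_expression_table(ds: ExpressionDataset, path: str, label_column: str = "class") -> None:
    ds.to_frame(label_column).to_csv(path, sep="\t", index_label="sample")


def read_disgenet_table(path: str) -> list[AssociationRecord]:
    """Read a gene-disease association TSV (DisGeNET v7 dialect), unfiltered, in file order.

    Required columns (matched case-insensitively): geneSymbol, diseaseName,
    diseaseType, diseaseSemanticType. Rows with an empty gene or disease field are
    rejected with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    colmap: dict[str, str] = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in _DISGENET_COLUMNS:
            colmap[_DISGENET_COLUMNS[key]] = col
    missing = set(_DISGENET_COLUMNS.values()) - set(colmap)
    if missing:
        raise FormatError(f"missing required column(s) in {path}: {sorted(missing)}")
    records: list[AssociationRecord] = []
    n_rejected = 0
    cols = [colmap[k] for k in ("gene", "disease", "disease_type", "disease_semantic_type")]
    for gene, disease, dtype, dsem in df[cols].itertuples(index=False, name=None):
        if not gene.strip() or not disease.strip():
            n_rejected += 1
            continue
        records.append(
            AssociationRecord(
                gene=gene.strip(),
                disease=disease.strip(),
                disease_type=dtype.strip(),
                disease_semantic_type=dsem.strip(),
            )
        )
    if n_rejected:
        logger.warning("rejected %d rows with empty gene/disease fields in %s", n_rejected, path)
    return records


def read_gmt(path: str) -> GroupCatalog:
    """Read a Broad-dialect GMT file: name TAB description TAB gene1 TAB gene2 ..."""
    groups: dict[str, frozenset[str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise FormatError(f"{path}:{lineno}: empty gene list for group {name!r}")
            if name in groups:
                raise FormatError(f"{path}:{lineno}: duplicate group name {name!r}")
            groups[name] = genes
            order.append(name)
    return GroupCatalog(groups={name: groups[name] for name in order})


def write_gmt(catalog: GroupCatalog, path: str, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in catalog.groups.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


@dataclass
class ResultsBundle:
    """Everything one analysis run writes to disk."""

    performance: pd.DataFrame  # columns #Groups, #Genes, Accuracy, Sensitivity, Specificity, AUC
    disease_ranking: pd.DataFrame  # Disease name, P-value, #Genes, List of genes
    gene_ranking: pd.DataFrame  # Gene, P-value
    dda_matrix: pd.DataFrame | None = None  # square, disease x disease
    dda_edges: pd.DataFrame | None = None


PERFORMANCE_COLUMNS = ["#Groups", "#Genes", "Accuracy", "Sensitivity", "Specificity", "AUC"]


def write_results(bundle: ResultsBundle, out_dir: str) -> list[str]:
    """Write all result tables as TSV into out_dir; returns the written paths."""
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []

    def _write(df: pd.DataFrame, name: str, index: bool = False, float_format: str = "%.6f") -> None:
        p = os.path.join(out_dir, name)
        df.to_csv(p, sep="\t", index=index, float_format=float_format)
        written.append(p)

    _write(bundle.performance[PERFORMANCE_COLUMNS], "performance.tsv")
    _write(bundle.disease_ranking, "disease_ranking.tsv")
    _write(bundle.gene_ranking, "gene_ranking.tsv")
    if bundle.dda_matrix is not None:
        _write(bundle.dda_matrix, "dda_matrix.tsv", index=True)
    if bundle.dda_edges is not None:
        _write(bundle.dda_edges, "dda_edges.tsv")
    return written


def read_performance_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
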