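"""Somatic mutation input handling.

Reads MAF-like variant tables (or precomputed count matrices), drops
synonymous variants, and builds the per-patient mutation-count matrix whose
binarized view seeds the network propagation.  Samples and genes with no
retained mutations are removed so the matrix never contains all-zero rows
or columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError

#: MAF column names recognized by default, in (sample, gene, classification) order.
DEFAULT_COLUMNS = ("Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification")

#: Variant classifications treated as silent and dropped by default.
DEFAULT_SILENT_CLASSES = frozenset({"Silent", "Synonymous"})


class VariantRecord(NamedTuple):
    sample: str
    gene: str
    classification: str


@dataclass(frozen=True)
class MutationMatrix:
    """Patients x genes mutation-count matrix.

    ``counts`` is a pandas DataFrame with unique, lexicographically sorted
    sample IDs as the index and gene symbols as columns; entries are
    non-negative integers.  Construction guarantees no all-zero row or
    column.
    """

    counts: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise FormatError("sample IDs and gene symbols must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("mutation counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def binarized(self) -> pd.DataFrame:
        """Mutated-vs-not view used as the propagation seed (counts clamped to {0,1})."""
        return (self.counts > 0).astype(np.int8)

    def mutated_genes(self, sample_id: str) -> list[str]:
        row = self.counts.loc[sample_id]
        return list(row.index[row > 0])


def read_maf_table(
    path: str | Path,
    drop_synonymous: bool = True,
    column_aliases: Sequence[str] | None = None,
    silent_classes: Iterable[str] = DEFAULT_SILENT_CLASSES,
) -> list[VariantRecord]:
    """Parse a MAF-like TSV into (sample, gene, classification) records.

    Parameters
    ----------
    path
        Tab-separated file with at least sample-ID, gene-symbol and
        variant-classification columns.  MAF names are recognized by
        default; pass ``column_aliases`` as a (sample, gene, classification)
        triple to override.
    drop_synonymous
        When true, records whose classification is in ``silent_classes``
        are removed.  All non-silent classes are kept.
    """
    columns = tuple(column_aliases) if column_aliases else DEFAULT_COLUMNS
    if len(columns) != 3:
        raise FormatError("column_aliases must name exactly 3 columns")
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty mutation file: {path}") from None
    if table.empty:
        raise FormatError(f"mutation file has a header but no records: {path}")
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise FormatError(f"missing required column(s) {missing} in {path}")

    silent = frozenset(silent_classes)
    records: list[VariantRecord] = []
    for sample, gene, cls in table[list(columns)].itertuples(index=False):
        cls = str(cls).strip()
        if drop_synonymous and cls in silent:
            continue
        records.append(VariantRecord(str(sample).strip(), str(gene).strip(), cls))
    return records


def build_mutation_matrix(records: Iterable[VariantRecord | tuple]) -> MutationMatrix:
    """Aggregate variant records into a MutationMatrix.

    counts[s, g] is the number of records for (s, g).  All-zero rows and
    columns cannot arise from non-empty record aggregation, but the pruning
    is applied anyway for matrices assembled from other sources.  Ordering
    is lexicographic in both axes, so the result is invariant to input
    record order.
    """
    records = [VariantRecord(*r) for r in records]
    if not records:
        raise FormatError("no variant records to build a matrix from "
                          "(all records may have been filtered out)")
    frame = pd.DataFrame(records)
    counts = (
        frame.groupby(["sample", "gene"], sort=True)
        .size()
        .unstack(fill_value=0)
        .sort_index(axis=0)
        .sort_index(axis=1)
    )
    counts = _prune_zero(counts)
    counts.index.name = "sample_id"
    counts.columns.name = None
    return MutationMatrix(counts.astype(np.int64))


def matrix_from_frame(counts: pd.DataFrame) -> MutationMatrix:
    """Wrap a precomputed samples-x-genes count DataFrame, pruning zero rows/columns."""
    counts = _prune_zero(counts.sort_index(axis=0).sort_index(axis=1))
    if counts.empty:
        raise FormatError("mutation matrix is empty after removing zero rows/columns")
    return MutationMatrix(counts.astype(np.int64))


def read_matrix_tsv(path: str | Path) -> MutationMatrix:
    """Read a precomputed mutation-count matrix (TSV, samples as rows)."""
    try:
        counts = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty matrix file: {path}") from None
    counts.index = counts.index.astype(str).str.strip()
    counts.columns = counts.columns.astype(str).str.strip()
    return matrix_from_frame(counts)


def write_matrix_tsv(matrix: MutationMatrix, path: str | Path) -> None:
    matrix.counts.to_csv(path, sep="\t")


def _prune_zero(counts: pd.DataFrame) -> pd.DataFrame:
    counts = counts.loc[counts.sum(axis=1) > 0, :]
    return counts.loc[:, counts.sum(axis=0) > 0]
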