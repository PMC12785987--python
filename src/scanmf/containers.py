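"""Core in-memory containers shared across the package.

The central object is :class:`ExpressionMatrix`, a dense gene-by-cell
matrix with gene symbols on the rows and cell barcodes on the columns.
Genes are rows throughout the package, matching the factorization
``X ≈ U Vᵀ`` where ``U`` holds gene–factor loadings and ``V`` holds
cell–factor coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ExpressionMatrix:
    """A gene-by-cell expression matrix with identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_cells)
        Expression values. Must be non-negative when passed to the model.
    gene_ids : list of str
        Unique gene symbols, one per row.
    cell_ids : list of str
        Unique cell barcodes, one per column.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        m, n = self.values.shape
        if len(self.gene_ids) != m:
            raise ValueError(
                f"gene_ids length {len(self.gene_ids)} does not match {m} rows"
            )
        if len(self.cell_ids) != n:
            raise ValueError(
                f"cell_ids length {len(self.cell_ids)} does not match {n} columns"
            )
        if len(set(self.gene_ids)) != m:
            raise ValueError("gene_ids must be unique")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell_ids must be unique")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def cell_index(self) -> dict[str, int]:
        return {c: j for j, c in enumerate(self.cell_ids)}

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``genes``, in the given order."""
        idx = self.gene_index()
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(self.values[rows, :], list(genes), self.cell_ids)

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        """Return a new matrix keeping the cells where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        cells = [c for c, keep in zip(self.cell_ids, mask) if keep]
        return ExpressionMatrix(self.values[:, mask], self.gene_ids, cells)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), list(self.gene_ids), list(self.cell_ids)
        )


@dataclass
class PriorSet:
    """Expanded marker and label constraint matrices.

    ``marker_matrix`` (M, genes × types) is 1 where a gene is a marker of a
    type and for every entry of a non-marker gene; the penalty
    ``α·||U ⊙ (1−M)||₁`` therefore only touches marker genes loading on
    types they do not mark.  ``label_matrix`` (P, cells × types) is one-hot
    for labeled cells and all-ones for unlabeled cells, so
    ``β·||V ⊙ (1−P)||₁`` pins labeled cells to their annotated factor and
    leaves the rest unconstrained.

    Cell types are kept in a fixed (lexicographic) order that defines the
    meaning of the factor columns for the model and the metrics.
    """

    marker_matrix: np.ndarray
    label_matrix: np.ndarray
    cell_types: list[str]
    marker_gene_count: int
    labeled_cell_count: int
    labeled_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.marker_matrix = np.asarray(self.marker_matrix, dtype=float)
        self.label_matrix = np.asarray(self.label_matrix, dtype=float)
        if self.marker_matrix.shape[1] != len(self.cell_types):
            raise ValueError("marker_matrix columns must match cell_types")
        if self.label_matrix.shape[1] != len(self.cell_types):
            raise ValueError("label_matrix columns must match cell_types")
        if self.labeled_mask is None:
            # unlabeled rows are all-ones; labeled rows are one-hot
            self.labeled_mask = self.label_matrix.sum(axis=1) == 1
        self.labeled_mask = np.asarray(self.labeled_mask, dtype=bool)

    @property
    def n_types(self) -> int:
        return len(self.cell_types)
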