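"""Quality control, normalization, feature selection and prior construction.

The pipeline follows the standard scRNA-seq recipe: remove low-quality
cells and rarely detected genes, library-size normalize and log-transform,
select highly variable genes against a fitted mean–variance trend,
standardize gene-wise, and clip negatives so the resulting feature matrix
is non-negative as the factorization model requires.  The final feature
rows are the union of HVGs and the supplied marker genes, with marker
genes placed first so their rows align with the marker-constraint matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import ExpressionMatrix, PriorSet

logger = logging.getLogger(__name__)

UNLABELED = "unassigned"


@dataclass
class QCConfig:
    """Cell- and gene-level quality-control thresholds."""

    min_genes_per_cell: int = 200
    max_mito_fraction: float = 0.20
    min_cells_per_gene: int = 3
    mito_prefixes: tuple[str, ...] = ("MT-", "mt-")

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in [0, 1]")
        if self.min_genes_per_cell < 0 or self.min_cells_per_gene < 0:
            raise ValueError("QC counts must be non-negative")


@dataclass
class HVGConfig:
    """Highly-variable-gene selection settings.

    ``trend_fit`` names the mean–variance trend estimator: ``"lowess"``
    (local regression of log10 variance on log10 mean, Seurat-vst style)
    or ``"poly"`` (quadratic fit, robust on tiny gene sets).
    """

    n_top_genes: int = 1000
    trend_fit: str = "lowess"

    def __post_init__(self) -> None:
        if self.n_top_genes < 1:
            raise ValueError("n_top_genes must be >= 1")
        if self.trend_fit not in {"lowess", "poly"}:
            raise ValueError(f"unknown trend_fit: {self.trend_fit!r}")


def filter_cells(x: ExpressionMatrix, qc: QCConfig) -> ExpressionMatrix:
    """Remove cells with few detected genes or a high mitochondrial fraction.

    A gene counts as detected in a cell when its value is nonzero.  The
    mitochondrial fraction is the share of a cell's total counts carried by
    genes whose symbol starts with one of ``qc.mito_prefixes``.
    """
    detected = (x.values > 0).sum(axis=0)
    mito_rows = np.array(
        [g.startswith(qc.mito_prefixes) for g in x.gene_ids], dtype=bool
    )
    totals = x.values.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(
            totals > 0, x.values[mito_rows, :].sum(axis=0) / totals, 0.0
        )
    keep = (detected >= qc.min_genes_per_cell) & (
        mito_frac <= qc.max_mito_fraction
    )
    if not keep.any():
        raise ValueError("cell QC removed every cell; relax the thresholds")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_cells: removed %d of %d cells", n_drop, x.n_cells)
    return x.subset_cells(keep)


def filter_genes(x: ExpressionMatrix, qc: QCConfig) -> ExpressionMatrix:
    """Keep genes expressed (nonzero) in at least ``min_cells_per_gene`` cells."""
    n_cells_expr = (x.values > 0).sum(axis=1)
    keep = n_cells_expr >= qc.min_cells_per_gene
    if not keep.any():
        raise ValueError("gene QC removed every gene; relax the thresholds")
    genes = [g for g, k in zip(x.gene_ids, keep) if k]
    return ExpressionMatrix(x.values[keep, :], genes, x.cell_ids)


def normalize_log(x: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Library-size normalize to ``scale`` counts per cell and log1p.

    x'_{ij} = log(x⁰_{ij} / s_j · scale + 1) with s_j the library size of
    cell j and natural log.
    """
    s = x.values.sum(axis=0)
    zero = np.flatnonzero(s <= 0)
    if zero.size:
        raise ValueError(
            f"zero library size for cell(s): {[x.cell_ids[j] for j in zero[:5]]}"
        )
    out = np.log1p(x.values / s[None, :] * scale)
    return ExpressionMatrix(out, x.gene_ids, x.cell_ids)


def _fit_trend(mean: np.ndarray, var: np.ndarray, kind: str) -> np.ndarray:
    """Expected variance at each gene's mean, from the fitted trend.

    The trend is fitted on log10 scale over genes with positive mean and
    variance, then evaluated per gene; genes outside the fit support get
    the nearest fitted value.
    """
    ok = (mean > 0) & (var > 0)
    lx, ly = np.log10(mean[ok]), np.log10(var[ok])
    if ok.sum() < 3 or np.unique(lx).size < 3:
        # degenerate input: flat trend at the overall mean variance
        fill = var[ok].mean() if ok.any() else 1.0
        return np.full_like(mean, max(fill, 1e-12))
    if kind == "lowess" and ok.sum() >= 10:
        fitted = lowess(ly, lx, frac=0.3, return_sorted=False)
        # interpolate onto all genes through the sorted fit
        order = np.argsort(lx)
        xs, ys = lx[order], fitted[order]
        pred = np.interp(
            np.where(mean > 0, np.log10(np.clip(mean, 1e-300, None)), xs.min()),
            xs, ys,
        )
    else:
        deg = min(2, ok.sum() - 1)
        coef = np.polyfit(lx, ly, deg)
        pred = np.polyval(coef, np.where(mean > 0,
                                         np.log10(np.clip(mean, 1e-300, None)),
                                         lx.min()))
    return np.maximum(10.0 ** pred, 1e-12)


def select_hvgs(x: ExpressionMatrix, cfg: HVGConfig) -> list[str]:
    """Rank genes by standardized variance v = σ² / f(μ) and take the top.

    ``f`` is the fitted mean–variance trend, so v measures excess variance
    relative to genes of similar abundance.  Ties are broken by gene id,
    which also makes the ranking invariant to the input gene order.
    """
    mean = x.values.mean(axis=1)
    var = x.values.var(axis=1, ddof=1) if x.n_cells > 1 else np.zeros(x.n_genes)
    expected = _fit_trend(mean, var, cfg.trend_fit)
    v = var / expected
    if cfg.n_top_genes >= x.n_genes:
        logger.warning(
            "requested %d HVGs but only %d genes present; returning all",
            cfg.n_top_genes, x.n_genes,
        )
        n_top = x.n_genes
    else:
        n_top = cfg.n_top_genes
    order = sorted(range(x.n_genes), key=lambda i: (-v[i], x.gene_ids[i]))
    return [x.gene_ids[i] for i in order[:n_top]]


def standardize_genes(x: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale each gene to unit variance, then clip negatives to 0.

    Clipping restores the non-negativity the factorization requires; a
    zero-variance gene is mapped to an all-zero row.
    """
    mu = x.values.mean(axis=1, keepdims=True)
    sd = x.values.std(axis=1, ddof=1, keepdims=True) if x.n_cells > 1 else \
        np.zeros((x.n_genes, 1))
    flat = sd[:, 0] <= 0
    if flat.any():
        logger.warning("standardize_genes: %d zero-variance gene(s) set to 0",
                       int(flat.sum()))
    sd_safe = np.where(sd > 0, sd, 1.0)
    z = (x.values - mu) / sd_safe
    z[flat, :] = 0.0
    return ExpressionMatrix(np.clip(z, 0.0, None), x.gene_ids, x.cell_ids)


def assemble_feature_matrix(
    x: ExpressionMatrix,
    hvgs: list[str],
    markers: dict[str, list[str]],
) -> ExpressionMatrix:
    """Subset to the union of HVGs and marker genes, markers first.

    Marker genes absent from the matrix are dropped with a warning; the
    marker rows come first (sorted by symbol) so row i < c of the result
    corresponds to row i of the marker-constraint matrix.
    """
    present = set(x.gene_ids)
    marker_union: set[str] = set()
    for t, genes in markers.items():
        for g in genes:
            if g in present:
                marker_union.add(g)
            else:
                logger.warning("marker gene %s (type %s) not in matrix; excluded",
                               g, t)
    if not marker_union:
        raise ValueError(
            "no marker gene found in the expression matrix; "
            "check gene symbol conventions (case, species prefixes)"
        )
    marker_rows = sorted(marker_union)
    rest = [g for g in hvgs if g not in marker_union and g in present]
    return x.subset_genes(marker_rows + rest)


def build_priors(
    markers: dict[str, list[str]],
    labels: pd.DataFrame | None,
    feature_genes: list[str],
    cells: list[str],
) -> PriorSet:
    """Build the expanded marker (M) and label (P) constraint matrices.

    The factor columns are the lexicographically sorted union of cell
    types appearing in the marker map and the label table.  A marker gene
    row of M is the indicator of the types it marks; non-marker genes get
    all-ones rows (unconstrained).  A labeled cell's P row is one-hot;
    unlabeled cells get all-ones rows.
    """
    label_map: dict[str, str] = {}
    if labels is not None and len(labels):
        cell_set = set(cells)
        unknown = [c for c in labels["cell_id"] if c not in cell_set]
        if unknown:
            raise ValueError(f"labeled cell id(s) not in matrix: {unknown[:5]}")
        label_map = dict(zip(labels["cell_id"], labels["cell_type"]))

    types = sorted(set(markers) | set(label_map.values()))
    if not types:
        raise ValueError("no cell types found in markers or labels")
    t_index = {t: k for k, t in enumerate(types)}
    p = len(types)

    gene_types: dict[str, set[str]] = {}
    for t, genes in markers.items():
        for g in genes:
            gene_types.setdefault(g, set()).add(t)

    m = len(feature_genes)
    M = np.ones((m, p))
    c = 0
    for i, g in enumerate(feature_genes):
        if g in gene_types:
            row = np.zeros(p)
            for t in gene_types[g]:
                row[t_index[t]] = 1.0
            M[i] = row
            c += 1

    n = len(cells)
    P = np.ones((n, p))
    labeled_mask = np.zeros(n, dtype=bool)
    for j, cell in enumerate(cells):
        if cell in label_map:
            row = np.zeros(p)
            row[t_index[label_map[cell]]] = 1.0
            P[j] = row
            labeled_mask[j] = True

    return PriorSet(
        marker_matrix=M,
        label_matrix=P,
        cell_types=types,
        marker_gene_count=c,
        labeled_cell_count=int(labeled_mask.sum()),
        labeled_mask=labeled_mask,
    )
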