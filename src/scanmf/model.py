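"""Semi-supervised, prior- and graph-regularized NMF for cell annotation.

The model factorizes a non-negative gene-by-cell matrix X (m×n) as
X ≈ U Vᵀ with U ∈ R≥0^{m×p} gene–factor loadings and V ∈ R≥0^{n×p}
cell–factor coefficients, one factor per cell type, minimizing

    O(U, V) = ||X − UVᵀ||_F²
            + α0 ||U||₁
            + α  ||U ⊙ (1−M)||₁
            + β  ||V ⊙ (1−P)||₁
            + γ  Tr(Vᵀ L V),        U ≥ 0, V ≥ 0,

where M and P are the expanded marker- and label-constraint matrices and
L is the unnormalized Laplacian of the mutual-KNN cell graph.  The α term
discourages marker genes from loading on factors of types they do not
mark, the β term pins labeled cells to their annotated factor, and the γ
term smooths coefficients over the cell graph.  Optimization alternates
the multiplicative updates

    u_ik ← u_ik · (2XV)_ik / (2UVᵀV + α0·1 + α(1−M))_ik
    v_jk ← v_jk · 2(XᵀU + γWV)_jk / (2VUᵀU + β(1−P) + 2γDV)_jk

which preserve non-negativity and do not increase the objective.  A cell
is annotated with the type whose factor carries its largest coefficient.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from statsmodels.iolib.table import SimpleTable

from .containers import ExpressionMatrix, PriorSet
from .graph import CellGraph, laplacian_quadratic

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class ModelConfig:
    """Weights and optimizer settings for the factorization.

    ``alpha0`` is the global L1 sparsity weight on U (default 50);
    ``alpha``, ``beta`` and ``gamma`` weight the marker, label and graph
    penalties.  The defaults are the within-dataset settings
    (α = β = 10 000, γ = 10).  One iteration is one U update followed by
    one V update; iteration stops when the relative objective change
    drops below ``rel_tol`` or after ``max_iter`` iterations.
    """

    alpha0: float = 50.0
    alpha: float = 1e4
    beta: float = 1e4
    gamma: float = 10.0
    max_iter: int = 50
    rel_tol: float = 1e-4
    eps: float = 1e-12
    init: str = "random"  # "random" (uniform on (0,1]) or "nndsvd"
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.alpha0, self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("penalty weights must be non-negative")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.init not in {"random", "nndsvd"}:
            raise ValueError(f"unknown init: {self.init!r}")


# ---------------------------------------------------------------------------
# objective and updates (module-level, operate on plain arrays)
# ---------------------------------------------------------------------------

def objective(
    X: np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    priors: PriorSet,
    graph: CellGraph | None,
    cfg: ModelConfig,
) -> float:
    """Evaluate the full objective O(U, V)."""
    for name, a in (("X", X), ("U", U), ("V", V)):
        if not np.isfinite(a).all():
            raise ValueError(f"non-finite values in {name}")
    resid = X - U @ V.T
    val = float(np.sum(resid * resid))
    val += cfg.alpha0 * float(np.abs(U).sum())
    if cfg.alpha > 0:
        val += cfg.alpha * float((np.abs(U) * (1.0 - priors.marker_matrix)).sum())
    if cfg.beta > 0:
        val += cfg.beta * float((np.abs(V) * (1.0 - priors.label_matrix)).sum())
    if cfg.gamma > 0 and graph is not None:
        val += cfg.gamma * laplacian_quadratic(V, graph)
    return val


def update_U(
    X: np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    priors: PriorSet,
    cfg: ModelConfig,
) -> np.ndarray:
    numer = 2.0 * (X @ V)
    denom = 2.0 * U @ (V.T @ V) + cfg.alpha0
    if cfg.alpha > 0:
        denom = denom + cfg.alpha * (1.0 - priors.marker_matrix)
    return U * numer / (denom + cfg.eps)


def update_V(
    X: np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    priors: PriorSet,
    graph: CellGraph | None,
    cfg: ModelConfig,
) -> np.ndarray:
    numer = X.T @ U
    denom = V @ (U.T @ U)
    if cfg.beta > 0:
        denom = denom + 0.5 * cfg.beta * (1.0 - priors.label_matrix)
    if cfg.gamma > 0 and graph is not None:
        numer = numer + cfg.gamma * (graph.W @ V)
        denom = denom + cfg.gamma * (graph.degrees[:, None] * V)
    return V * numer / (denom + cfg.eps)


def _nndsvd_init(X: np.ndarray, p: int, eps: float) -> tuple[np.ndarray, np.ndarray]:
    """NNDSVD initialization; zeros are lifted to eps so multiplicative
    updates are not permanently locked."""
    Uf, s, Vt = np.linalg.svd(X, full_matrices=False)
    m, n = X.shape
    U = np.zeros((m, p))
    V = np.zeros((n, p))
    U[:, 0] = np.sqrt(s[0]) * np.abs(Uf[:, 0])
    V[:, 0] = np.sqrt(s[0]) * np.abs(Vt[0, :])
    for k in range(1, min(p, len(s))):
        u, v = Uf[:, k], Vt[k, :]
        up, un = np.clip(u, 0, None), np.clip(-u, 0, None)
        vp, vn = np.clip(v, 0, None), np.clip(-v, 0, None)
        norm_p = np.linalg.norm(up) * np.linalg.norm(vp)
        norm_n = np.linalg.norm(un) * np.linalg.norm(vn)
        if norm_p >= norm_n:
            uu = up / max(np.linalg.norm(up), eps)
            vv = vp / max(np.linalg.norm(vp), eps)
            sig = norm_p
        else:
            uu = un / max(np.linalg.norm(un), eps)
            vv = vn / max(np.linalg.norm(vn), eps)
            sig = norm_n
        U[:, k] = np.sqrt(s[k] * sig) * uu
        V[:, k] = np.sqrt(s[k] * sig) * vv
    small = 1e-4
    return np.maximum(U, small), np.maximum(V, small)


# ---------------------------------------------------------------------------
# the model / results pair
# ---------------------------------------------------------------------------

class ScANMF:
    """The annotation model, bound to data, priors and an optional graph.

    Parameters
    ----------
    x : ExpressionMatrix or ndarray
        Non-negative preprocessed gene-by-cell matrix.
    priors : PriorSet
        Marker- and label-constraint matrices aligned to the rows and
        columns of ``x``.
    graph : CellGraph, optional
        Mutual-KNN cell graph; required when ``gamma > 0``.
    config : ModelConfig, optional
        Penalty weights and optimizer settings; keyword overrides are
        applied on top (``ScANMF(x, priors, g, gamma=0)``).
    """

    def __init__(
        self,
        x: ExpressionMatrix | np.ndarray,
        priors: PriorSet,
        graph: CellGraph | None = None,
        config: ModelConfig | None = None,
        **overrides: float,
    ) -> None:
        if isinstance(x, ExpressionMatrix):
            self.data = x
            X = x.values
        else:
            X = np.asarray(x, dtype=float)
            self.data = None
        if X.size == 0:
            raise ValueError("empty expression matrix")
        if not np.isfinite(X).all():
            raise ValueError("non-finite values in the expression matrix")
        if X.min() < 0:
            raise ValueError("the model requires a non-negative matrix")
        m, n = X.shape
        if priors.marker_matrix.shape[0] != m:
            raise ValueError(
                f"marker matrix has {priors.marker_matrix.shape[0]} rows, "
                f"matrix has {m} genes"
            )
        if priors.label_matrix.shape[0] != n:
            raise ValueError(
                f"label matrix has {priors.label_matrix.shape[0]} rows, "
                f"matrix has {n} cells"
            )
        cfg = config if config is not None else ModelConfig()
        if overrides:
            cfg = replace(cfg, **overrides)
        if cfg.gamma > 0 and graph is None:
            raise ValueError("gamma > 0 requires a cell graph")
        if graph is not None and graph.n_cells != n:
            raise ValueError("graph size does not match number of cells")
        self.X = X
        self.priors = priors
        self.graph = graph
        self.config = cfg

    @classmethod
    def from_expression(
        cls,
        x: ExpressionMatrix,
        markers: dict[str, list[str]],
        labels: pd.DataFrame | None = None,
        graph: CellGraph | None = None,
        **overrides: float,
    ) -> "ScANMF":
        """Build priors from a marker map and partial label table, then
        construct the model on the given (already preprocessed) matrix."""
        from .preprocess import build_priors

        priors = build_priors(markers, labels, x.gene_ids, x.cell_ids)
        return cls(x, priors, graph=graph, **overrides)

    @property
    def n_factors(self) -> int:
        return self.priors.n_types

    def fit(self, seed: int | None = None) -> "ScANMFResults":
        """Run the multiplicative-update optimization.

        U and V start from uniform random values on (0, 1] (strictly
        positive, since exact zeros are fixed points of multiplicative
        updates); the run is reproducible given ``seed``.
        """
        cfg = self.config
        if seed is None:
            seed = cfg.seed
        m, n = self.X.shape
        p = self.n_factors
        rng = np.random.default_rng(seed)
        if cfg.init == "nndsvd":
            U, V = _nndsvd_init(self.X, p, cfg.eps)
        else:
            # 1 - uniform[0,1) is uniform on (0,1]
            U = 1.0 - rng.random((m, p))
            V = 1.0 - rng.random((n, p))
        trace = [objective(self.X, U, V, self.priors, self.graph, cfg)]
        converged = False
        for _ in range(cfg.max_iter):
            U = update_U(self.X, U, V, self.priors, cfg)
            V = update_V(self.X, U, V, self.priors, self.graph, cfg)
            trace.append(objective(self.X, U, V, self.priors, self.graph, cfg))
            prev, cur = trace[-2], trace[-1]
            if prev > 0 and abs(cur - prev) / prev < cfg.rel_tol:
                converged = True
                break
        return ScANMFResults(
            model=self,
            U=U,
            V=V,
            objective_trace=np.asarray(trace),
            converged=converged,
            n_iter=len(trace) - 1,
            seed=seed,
        )


@dataclass
class ScANMFResults:
    """Fitted factorization with annotation and diagnostics."""

    model: ScANMF
    U: np.ndarray
    V: np.ndarray
    objective_trace: np.ndarray
    converged: bool
    n_iter: int
    seed: int | None = None

    @property
    def cell_types(self) -> list[str]:
        return self.model.priors.cell_types

    @property
    def final_objective(self) -> float:
        return float(self.objective_trace[-1])

    @property
    def reconstruction_error(self) -> float:
        """Squared Frobenius reconstruction error ||X − UVᵀ||_F²."""
        resid = self.model.X - self.U @ self.V.T
        return float(np.sum(resid * resid))

    def annotate(self) -> pd.Series:
        """Per-cell type assignment: argmax over each row of V.

        Ties go to the lowest factor index; an all-zero row cannot be
        assigned and receives the ``"unassigned"`` sentinel.
        """
        types = np.asarray(self.cell_types, dtype=object)
        pred = types[np.argmax(self.V, axis=1)]
        dead = ~(self.V > 0).any(axis=1)
        if dead.any():
            logger.warning("%d cell(s) have an all-zero coefficient row; "
                           "marked %s", int(dead.sum()), UNASSIGNED)
            pred[dead] = UNASSIGNED
        index = (self.model.data.cell_ids
                 if self.model.data is not None
                 else pd.RangeIndex(self.V.shape[0]))
        return pd.Series(pred, index=index, name="predicted_type")

    def annotation_frame(self) -> pd.DataFrame:
        """Annotations with the winning coefficient, for export."""
        pred = self.annotate()
        return pd.DataFrame({
            "cell_id": pred.index,
            "predicted_type": pred.to_numpy(),
            "max_weight": self.V.max(axis=1),
        })

    def summary(self) -> SimpleTable:
        """Human-readable fit summary."""
        cfg = self.model.config
        counts = self.annotate().value_counts()
        rows = [
            ("genes (m)", str(self.U.shape[0])),
            ("cells (n)", str(self.V.shape[0])),
            ("factors (p)", str(len(self.cell_types))),
            ("labeled cells", str(self.model.priors.labeled_cell_count)),
            ("marker genes", str(self.model.priors.marker_gene_count)),
            ("alpha0 / alpha / beta / gamma",
             f"{cfg.alpha0:g} / {cfg.alpha:g} / {cfg.beta:g} / {cfg.gamma:g}"),
            ("iterations", str(self.n_iter)),
            ("converged", str(self.converged)),
            ("final objective", f"{self.final_objective:.6g}"),
            ("reconstruction error", f"{self.reconstruction_error:.6g}"),
        ] + [(f"cells annotated {t}", str(counts.get(t, 0)))
             for t in self.cell_types]
        return SimpleTable(
            [[k, v] for k, v in rows],
            headers=["", ""],
            title="scANMF factorization results",
        )

    def save(self, path: str) -> None:
        """Dump U, V, cell types, config and trace to a single NPZ archive."""
        cfg = self.model.config
        np.savez_compressed(
            path,
            U=self.U,
            V=self.V,
            cell_types=np.asarray(self.cell_types, dtype=object),
            objective_trace=self.objective_trace,
            converged=np.asarray(self.converged),
            n_iter=np.asarray(self.n_iter),
            config=np.asarray(
                [cfg.alpha0, cfg.alpha, cfg.beta, cfg.gamma,
                 cfg.max_iter, cfg.rel_tol]
            ),
        )


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------

def tune(
    x: ExpressionMatrix | np.ndarray,
    priors: PriorSet,
    graph: CellGraph | None,
    alpha_grid: list[float] = (1e2, 1e3, 1e4, 1e5),
    beta_grid: list[float] = (1e2, 1e3, 1e4, 1e5),
    gamma_grid: list[float] = (0.1, 1.0, 10.0, 100.0),
    folds: int = 5,
    base_config: ModelConfig | None = None,
    seed: int | None = 0,
) -> tuple[ModelConfig, pd.DataFrame]:
    """Grid search over (α, β, γ) by cross-validated annotation accuracy.

    The labeled cells are split into stratified folds; for each grid
    point each fold's labels are hidden in turn (their P rows reset to
    all-ones), the model is refitted, and accuracy is measured on the
    held-out labeled cells.  Ties in mean CV accuracy go to the smallest
    weights.  Returns the winning config and the full results table.
    """
    X = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x)
    base = base_config if base_config is not None else ModelConfig()
    lab_idx = np.flatnonzero(priors.labeled_mask)
    if lab_idx.size == 0:
        raise ValueError("tuning requires labeled cells")
    y = np.argmax(priors.label_matrix[lab_idx], axis=1)
    min_class = np.bincount(y).min() if y.size else 0
    if min_class < 2:
        raise ValueError(
            "every cell type needs at least 2 labeled cells for "
            "cross-validation; add labels or merge rare types"
        )
    n_splits = min(folds, int(min_class))
    if n_splits < folds:
        logger.warning("reducing CV folds from %d to %d (smallest class)",
                       folds, n_splits)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)

    grid = sorted(itertools.product(alpha_grid, beta_grid, gamma_grid))
    records = []
    best: tuple[float, ModelConfig] | None = None
    for a, b, g in grid:
        cfg = replace(base, alpha=a, beta=b, gamma=g)
        accs = []
        for f, (_, test) in enumerate(skf.split(lab_idx, y)):
            hide = lab_idx[test]
            P_cv = priors.label_matrix.copy()
            P_cv[hide, :] = 1.0
            mask_cv = priors.labeled_mask.copy()
            mask_cv[hide] = False
            cv_priors = PriorSet(
                marker_matrix=priors.marker_matrix,
                label_matrix=P_cv,
                cell_types=list(priors.cell_types),
                marker_gene_count=priors.marker_gene_count,
                labeled_cell_count=int(mask_cv.sum()),
                labeled_mask=mask_cv,
            )
            res = ScANMF(X, cv_priors, graph=graph, config=cfg).fit(
                seed=None if seed is None else seed + f
            )
            pred = np.argmax(res.V[hide], axis=1)
            accs.append(float(np.mean(pred == y[test])))
        mean_acc = float(np.mean(accs))
        records.append({"alpha": a, "beta": b, "gamma": g,
                        "cv_accuracy": mean_acc})
        if best is None or mean_acc > best[0]:
            best = (mean_acc, cfg)
    assert best is not None
    return best[1], pd.DataFrame.from_records(records)
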