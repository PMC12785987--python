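"""End-to-end pipelines: preprocess → priors → graph → fit → evaluate.

Also the robustness and ablation experiment drivers used to study how
annotation accuracy degrades when the prior knowledge is subsampled,
corrupted, or partially switched off.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .containers import ExpressionMatrix, PriorSet
from .graph import CellGraph, build_cell_graph, default_n_neighbors
from .metrics import EvaluationReport, evaluation_report, marker_consistency
from .model import ModelConfig, ScANMF, ScANMFResults
from .preprocess import (HVGConfig, QCConfig, assemble_feature_matrix,
                         build_priors, filter_cells, filter_genes,
                         normalize_log, select_hvgs, standardize_genes)
from .simulate import (SimulationConfig, corrupt_labels, corrupt_markers,
                       simulate)

logger = logging.getLogger(__name__)

ABLATION_VARIANTS: dict[str, dict[str, float]] = {
    "full": {},
    "marker_only": {"beta": 0.0, "gamma": 0.0},
    "label_only": {"alpha": 0.0, "gamma": 0.0},
    "marker_label": {"gamma": 0.0},
    "label_graph": {"alpha": 0.0},
    "marker_graph": {"beta": 0.0},
}


@dataclass
class RunConfig:
    """Paths and settings for one annotation run.

    ``preprocess`` selects how the input matrix is treated: ``"counts"``
    applies the full QC → normalize → HVG → standardize recipe,
    ``"none"`` uses the matrix as-is (already preprocessed or simulated
    data).  ``mode`` is ``"within"`` for a single dataset or
    ``"concat-reference"`` where a fully labeled reference is
    concatenated with an unlabeled query.
    """

    matrix_path: str
    markers_path: str
    out_dir: str
    labels_path: str | None = None
    truth_path: str | None = None
    qc: QCConfig = field(default_factory=QCConfig)
    hvg: HVGConfig = field(default_factory=HVGConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    n_neighbors: int | None = None
    preprocess: str = "counts"
    mode: str = "within"
    reference_matrix_path: str | None = None
    reference_labels_path: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preprocess not in {"counts", "none"}:
            raise ValueError("preprocess must be 'counts' or 'none'")
        if self.mode not in {"within", "concat-reference"}:
            raise ValueError("mode must be 'within' or 'concat-reference'")


def preprocess_counts(
    x: ExpressionMatrix,
    markers: dict[str, list[str]],
    qc: QCConfig,
    hvg: HVGConfig,
) -> ExpressionMatrix:
    """Full preprocessing recipe on raw counts, ending marker-rows-first."""
    x = filter_cells(x, qc)
    x = filter_genes(x, qc)
    x = normalize_log(x)
    hvgs = select_hvgs(x, hvg)
    x = assemble_feature_matrix(x, hvgs, markers)
    return standardize_genes(x)


def _concat_reference(cfg: RunConfig, markers) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Cross-dataset protocol: intersect genes, concatenate reference and
    query cells, and mark every reference cell as labeled."""
    if cfg.reference_matrix_path is None or cfg.reference_labels_path is None:
        raise ValueError("concat-reference mode needs reference matrix and labels")
    query = sio.read_matrix(cfg.matrix_path)
    ref = sio.read_matrix(cfg.reference_matrix_path)
    shared = sorted(set(query.gene_ids) & set(ref.gene_ids))
    if not shared:
        raise ValueError("no genes shared between reference and query")
    query = query.subset_genes(shared)
    ref = ref.subset_genes(shared)
    cells = [f"ref:{c}" for c in ref.cell_ids] + [f"query:{c}" for c in query.cell_ids]
    values = np.concatenate([ref.values, query.values], axis=1)
    labels = sio.read_labels(cfg.reference_labels_path)
    labels = labels.assign(cell_id="ref:" + labels["cell_id"])
    return ExpressionMatrix(values, shared, cells), labels


def run_pipeline(cfg: RunConfig) -> tuple[ScANMFResults, EvaluationReport | None]:
    """Execute one full annotation run and write its artifacts.

    Writes to ``cfg.out_dir``: annotations.csv, model.npz, the resolved
    config snapshot, and report.json when ground truth is available.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        markers = sio.read_markers(cfg.markers_path)
    except Exception as exc:
        raise RuntimeError(f"[stage markers] {exc}; check --markers") from exc

    try:
        if cfg.mode == "concat-reference":
            x, labels = _concat_reference(cfg, markers)
        else:
            x = sio.read_matrix(cfg.matrix_path)
            labels = (sio.read_labels(cfg.labels_path)
                      if cfg.labels_path else None)
    except RuntimeError:
        raise
    except Exception as exc:
        raise RuntimeError(f"[stage load] {exc}") from exc

    try:
        if cfg.preprocess == "counts":
            x = preprocess_counts(x, markers, cfg.qc, cfg.hvg)
            if labels is not None:  # drop labels of QC-removed cells
                labels = labels[labels["cell_id"].isin(set(x.cell_ids))]
        else:
            x = assemble_feature_matrix(x, list(x.gene_ids), markers)
    except Exception as exc:
        raise RuntimeError(f"[stage preprocess] {exc}") from exc

    try:
        priors = build_priors(markers, labels, x.gene_ids, x.cell_ids)
        graph = None
        if cfg.model.gamma > 0:
            K = cfg.n_neighbors or default_n_neighbors(x.n_cells)
            graph = build_cell_graph(x, K=K)
        res = ScANMF(x, priors, graph=graph, config=cfg.model).fit(seed=cfg.seed)
    except Exception as exc:
        raise RuntimeError(f"[stage fit] {exc}") from exc

    res.annotation_frame().to_csv(out / "annotations.csv", index=False)
    res.save(str(out / "model.npz"))
    snapshot = {
        "matrix_path": cfg.matrix_path,
        "markers_path": cfg.markers_path,
        "labels_path": cfg.labels_path,
        "preprocess": cfg.preprocess,
        "mode": cfg.mode,
        "seed": cfg.seed,
        "qc": dataclasses.asdict(cfg.qc),
        "hvg": dataclasses.asdict(cfg.hvg),
        "model": dataclasses.asdict(cfg.model),
        "n_neighbors": cfg.n_neighbors,
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(snapshot, fh)

    report = None
    if cfg.truth_path:
        truth = sio.read_labels(cfg.truth_path).set_index("cell_id")["cell_type"]
        pred = res.annotate()
        eval_cells = [c for c in pred.index if c in truth.index]
        if labels is not None:  # score the unlabeled cells only
            supervised = set(labels["cell_id"])
            eval_cells = [c for c in eval_cells if c not in supervised]
        report = evaluation_report(pred.loc[eval_cells], truth.loc[eval_cells])
        with open(out / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)
        report.confusion.to_csv(out / "confusion.csv")
    return res, report


# ---------------------------------------------------------------------------
# simulation experiments
# ---------------------------------------------------------------------------

def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=n)


def fit_simulated(
    sim,
    labels: pd.DataFrame | None,
    markers: dict[str, list[str]],
    model_cfg: ModelConfig,
    n_neighbors: int | None = None,
    seed: int | None = None,
    graph: CellGraph | None = None,
) -> tuple[ScANMFResults, PriorSet]:
    """Fit the model directly on a simulated matrix (no preprocessing)."""
    x = sim.matrix
    priors = build_priors(markers, labels, x.gene_ids, x.cell_ids)
    if model_cfg.gamma > 0 and graph is None:
        K = n_neighbors or default_n_neighbors(x.n_cells)
        graph = build_cell_graph(x, K=K)
    res = ScANMF(x, priors, graph=graph, config=model_cfg).fit(seed=seed)
    return res, priors


def score_simulated(
    sim, res: ScANMFResults, labels: pd.DataFrame | None,
    include_labeled: bool = False,
) -> EvaluationReport:
    """Score a fit against the simulator's ground truth.

    By default the cells carried as supervision are excluded, so the
    score reflects the annotation of genuinely unlabeled cells.
    """
    pred = res.annotate()
    truth = sim.true_labels
    if labels is not None and not include_labeled:
        supervised = set(labels["cell_id"])
        keep = [c for c in pred.index if c not in supervised]
        pred, truth = pred.loc[keep], truth.loc[keep]
    return evaluation_report(pred, truth)


def run_robustness(
    sim_cfg: SimulationConfig,
    scenario: str,
    levels: list[float],
    replicates: int = 5,
    model_cfg: ModelConfig | None = None,
    retain_fraction: float = 0.1,
    n_neighbors: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy under degraded priors, per level × replicate.

    Scenarios: ``retain`` keeps only the level fraction of labels;
    ``label_noise`` keeps ``retain_fraction`` of labels and flips the
    level fraction of them to wrong types; ``marker_noise`` keeps clean
    labels at ``retain_fraction`` and swaps the level fraction of each
    type's marker genes for random non-markers.  Returns a tidy table
    (scenario, level, replicate, accuracy, weighted_f1).
    """
    if scenario not in {"retain", "label_noise", "marker_noise"}:
        raise ValueError(f"unknown scenario: {scenario!r}")
    model_cfg = model_cfg or ModelConfig()
    rows = []
    seeds = _child_seeds(seed, len(levels) * replicates * 3).reshape(
        len(levels), replicates, 3
    )
    for li, level in enumerate(levels):
        for r in range(replicates):
            s_sim, s_cor, s_fit = (int(s) for s in seeds[li, r])
            sim = simulate(sim_cfg, seed=s_sim)
            markers = sim.marker_sets
            if scenario == "retain":
                labels = corrupt_labels(sim.true_labels,
                                        retain_fraction=level, seed=s_cor)
            elif scenario == "label_noise":
                labels = corrupt_labels(sim.true_labels,
                                        retain_fraction=retain_fraction,
                                        error_rate=level, seed=s_cor)
            else:  # marker_noise
                labels = corrupt_labels(sim.true_labels,
                                        retain_fraction=retain_fraction,
                                        seed=s_cor)
                markers = corrupt_markers(sim.marker_sets, level,
                                          gene_pool=sim.matrix.gene_ids,
                                          seed=s_cor)
            res, _ = fit_simulated(sim, labels, markers, model_cfg,
                                   n_neighbors=n_neighbors, seed=s_fit)
            rep = score_simulated(sim, res, labels)
            rows.append({
                "scenario": scenario, "level": level, "replicate": r,
                "accuracy": rep.accuracy / 100.0,
                "weighted_f1": rep.weighted_f1,
            })
    return pd.DataFrame(rows)


def summarize_robustness(table: pd.DataFrame) -> pd.DataFrame:
    """Mean ± standard error per scenario × level."""
    g = table.groupby(["scenario", "level"])
    out = g.agg(
        mean_accuracy=("accuracy", "mean"),
        se_accuracy=("accuracy", lambda s: s.std(ddof=1) / np.sqrt(len(s))),
        mean_weighted_f1=("weighted_f1", "mean"),
        n=("accuracy", "size"),
    )
    return out.reset_index()


def run_ablation(
    sim_cfg: SimulationConfig,
    variants: list[str] | None = None,
    replicates: int = 5,
    model_cfg: ModelConfig | None = None,
    retain_fraction: float = 0.1,
    n_neighbors: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy of model variants with components switched off.

    Variants zero the corresponding weights: e.g. ``marker_only`` sets
    β = γ = 0, ``label_graph`` sets α = 0; ``full`` keeps everything.
    """
    variants = variants or list(ABLATION_VARIANTS)
    unknown = [v for v in variants if v not in ABLATION_VARIANTS]
    if unknown:
        raise ValueError(f"unknown variant(s): {unknown}; "
                         f"choose from {sorted(ABLATION_VARIANTS)}")
    model_cfg = model_cfg or ModelConfig()
    rows = []
    seeds = _child_seeds(seed, replicates * 3).reshape(replicates, 3)
    for r in range(replicates):
        s_sim, s_cor, s_fit = (int(s) for s in seeds[r])
        sim = simulate(sim_cfg, seed=s_sim)
        labels = corrupt_labels(sim.true_labels,
                                retain_fraction=retain_fraction, seed=s_cor)
        graph = build_cell_graph(
            sim.matrix, K=n_neighbors or default_n_neighbors(sim.matrix.n_cells)
        )
        for name in variants:
            cfg = dataclasses.replace(model_cfg, **ABLATION_VARIANTS[name])
            res, _ = fit_simulated(sim, labels, sim.marker_sets, cfg,
                                   seed=s_fit, graph=graph)
            rep = score_simulated(sim, res, labels)
            rows.append({
                "variant": name, "replicate": r,
                "accuracy": rep.accuracy / 100.0,
                "weighted_f1": rep.weighted_f1,
            })
    return pd.DataFrame(rows)
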