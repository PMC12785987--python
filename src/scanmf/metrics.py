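"""Annotation quality metrics and marker-consistency analysis.

Cell-level metrics are standard multi-class classification scores:
accuracy (percent), per-class precision/recall/F1 and class-size-weighted
F1.  The gene-level marker-consistency analysis asks whether the learned
factors respect the marker structure: each marker gene is sent to the
factor with its maximal loading; counting these per cell type gives the
normalized proportion matrix P_{c→k}, each factor is assigned the type
whose markers dominate it, and the marker accuracy is the fraction of
annotated marker genes whose dominant factor maps to one of their types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support

from .containers import PriorSet

logger = logging.getLogger(__name__)

UNASSIGNED_FACTOR = "unassigned"


@dataclass
class EvaluationReport:
    """Cell-level classification scores against ground truth."""

    accuracy: float  # percent, [0, 100]
    weighted_f1: float  # [0, 1]
    per_class: pd.DataFrame  # precision, recall, f1, support per type
    confusion: pd.DataFrame  # truth (rows) × prediction (columns)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "weighted_f1": self.weighted_f1,
            "per_class": self.per_class.to_dict(orient="index"),
        }


@dataclass
class MarkerConsistency:
    """Agreement between gene–factor loadings and marker annotations."""

    P_ck: pd.DataFrame  # type (rows) × factor (columns) proportions
    factor_assignment: dict[int, str]  # factor index -> type (or unassigned)
    accuracy_marker: float  # [0, 1]
    dominant_factor: pd.Series  # marker gene -> factor index
    weights: pd.DataFrame  # gene × type, 1/|C_i| on annotated pairs


def _check_labels(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if pred.size == 0:
        raise ValueError("empty label vectors")
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    return pred, truth


def accuracy(pred, truth) -> float:
    """Percentage of correctly annotated cells, 100·n_correct/n_all."""
    pred, truth = _check_labels(pred, truth)
    return 100.0 * float(np.mean(pred == truth))


def weighted_f1(pred, truth) -> float:
    """Class-size-weighted mean of per-class F1 scores.

    Classes are those present in the truth; a class never predicted has
    precision 0 by convention (logged by sklearn as zero_division=0).
    """
    pred, truth = _check_labels(pred, truth)
    classes = sorted(set(truth))
    _, _, f1, support = precision_recall_fscore_support(
        truth, pred, labels=classes, zero_division=0
    )
    return float(np.sum(f1 * support) / np.sum(support))


def evaluation_report(pred, truth) -> EvaluationReport:
    """Full cell-level report: accuracy, weighted F1, per-class table,
    confusion matrix (truth rows × predicted columns)."""
    pred, truth = _check_labels(pred, truth)
    classes = sorted(set(truth) | set(pred))
    prec, rec, f1, support = precision_recall_fscore_support(
        truth, pred, labels=classes, zero_division=0
    )
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "f1": f1, "support": support},
        index=pd.Index(classes, name="cell_type"),
    )
    confusion = pd.crosstab(
        pd.Series(truth, name="truth"), pd.Series(pred, name="predicted")
    ).reindex(index=classes, columns=classes, fill_value=0)
    truth_classes = sorted(set(truth))
    w = per_class.loc[truth_classes]
    wf1 = float((w["f1"] * w["support"]).sum() / w["support"].sum())
    return EvaluationReport(
        accuracy=accuracy(pred, truth),
        weighted_f1=wf1,
        per_class=per_class,
        confusion=confusion,
    )


def marker_consistency(
    U: np.ndarray,
    priors: PriorSet,
    marker_map: dict[str, list[str]],
    gene_ids: list[str],
) -> MarkerConsistency:
    """Evaluate factor/marker agreement from the fitted loadings.

    For each annotated marker gene i, the dominant factor is
    k*(i) = argmax_k U_{ik} (ties to the lowest index).  n_{c→k} counts
    the markers of type c dominated by factor k, and P_{c→k} divides by
    the type's marker count so each row sums to 1.  Factor k is assigned
    the type c*(k) = argmax_c n_{c→k} (a factor dominating no marker is
    unassigned), and the marker accuracy is the fraction of annotated
    marker genes with c*(k*(i)) among their own types.
    """
    U = np.asarray(U, dtype=float)
    types = priors.cell_types
    p = len(types)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    # annotated type sets C_i, restricted to genes present in the matrix
    type_sets: dict[str, set[str]] = {}
    for t, genes in marker_map.items():
        for g in genes:
            if g in gene_pos:
                type_sets.setdefault(g, set()).add(t)
    marker_genes = sorted(type_sets)
    if not marker_genes:
        raise ValueError("no annotated marker gene present in the matrix")

    dominant = pd.Series(
        {g: int(np.argmax(U[gene_pos[g]])) for g in marker_genes},
        name="dominant_factor",
    )
    weights = pd.DataFrame(0.0, index=marker_genes, columns=types)
    for g in marker_genes:
        share = 1.0 / len(type_sets[g])
        for t in type_sets[g]:
            weights.loc[g, t] = share

    n_ck = pd.DataFrame(0, index=pd.Index(types, name="cell_type"),
                        columns=range(p))
    for g in marker_genes:
        k = dominant[g]
        for t in type_sets[g]:
            n_ck.loc[t, k] += 1
    totals = n_ck.sum(axis=1)
    P_ck = n_ck.div(totals.where(totals > 0, 1.0), axis=0)

    factor_assignment: dict[int, str] = {}
    for k in range(p):
        col = n_ck[k]
        if col.sum() == 0:
            factor_assignment[k] = UNASSIGNED_FACTOR
            logger.warning("factor %d dominates no marker gene; unassigned", k)
        else:
            factor_assignment[k] = col.idxmax()  # ties -> first type

    correct = sum(
        1 for g in marker_genes
        if factor_assignment[dominant[g]] in type_sets[g]
    )
    acc = correct / len(marker_genes)
    return MarkerConsistency(
        P_ck=P_ck,
        factor_assignment=factor_assignment,
        accuracy_marker=acc,
        dominant_factor=dominant,
        weights=weights,
    )
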