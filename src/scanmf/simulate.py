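"""Synthetic scRNA-seq expression with planted cell-type structure.

Genes split into type-specific marker blocks and shared background genes.
Each gene draws a base mean m_i ~ N(μ0, σ0²); in a cell of type k the
mean is a·m_i for the markers of k (fold factor a > 1) and m_i − δ for
every other gene (depression δ > 0).  Observed values add Gaussian noise
with variance σ_hetero·μ + σ_homo² (larger for more-expressed genes),
negatives are truncated at zero, and dropout zeroes entries independently
with probability π0.  Optional batch groups receive fixed additive shifts
to their gene means.  The matrices reproduce the key traits of real
single-cell data — sparsity, mean-dependent noise and batch-level
variation — but not count statistics (no negative-binomial sampling).

The corruption utilities degrade the priors for robustness experiments:
subsample labels, flip an exact fraction of labels to a different type,
or swap an exact fraction of each type's markers for unrelated genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix


@dataclass
class SimulationConfig:
    """Study design and noise parameters of the generator.

    Defaults describe the benchmark configuration used throughout the
    package: 1200 cells, 4 equally frequent cell types with 20 disjoint
    marker genes each, plus 100 background genes; μ0 = 5, σ0 = 1, fold
    factor a = 3, depression δ = 1, dropout π0 = 0.3, noise coefficients
    σ_hetero = 0.2 and σ_homo = 0.5.
    """

    n_cells: int = 1200
    n_types: int = 4
    markers_per_type: int = 20
    n_background_genes: int = 100
    mu0: float = 5.0
    sigma0: float = 1.0
    a: float = 3.0
    delta: float = 1.0
    pi0: float = 0.3
    sigma_hetero: float = 0.2
    sigma_homo: float = 0.5
    batch_shifts: tuple[float, ...] | None = None
    type_proportions: tuple[float, ...] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.a <= 1:
            raise ValueError("fold factor a must exceed 1")
        if self.delta <= 0:
            raise ValueError("depression delta must be positive")
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValueError("dropout probability pi0 must lie in [0, 1]")
        if self.type_proportions is not None:
            props = np.asarray(self.type_proportions, dtype=float)
            if len(props) != self.n_types:
                raise ValueError("type_proportions length must equal n_types")
            if not np.isclose(props.sum(), 1.0):
                raise ValueError("type_proportions must sum to 1")


@dataclass
class SimulatedDataset:
    """Generated matrix plus the ground truth that produced it."""

    matrix: ExpressionMatrix
    true_labels: pd.Series  # cell_id -> type name
    marker_sets: dict[str, list[str]]
    config: SimulationConfig

    def label_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": self.true_labels.index,
            "cell_type": self.true_labels.to_numpy(),
        })


def _type_counts(cfg: SimulationConfig) -> np.ndarray:
    if cfg.type_proportions is None:
        props = np.full(cfg.n_types, 1.0 / cfg.n_types)
    else:
        props = np.asarray(cfg.type_proportions, dtype=float)
    counts = np.floor(props * cfg.n_cells).astype(int)
    # hand the rounding remainder to the largest fractional parts
    rem = cfg.n_cells - counts.sum()
    frac = props * cfg.n_cells - counts
    for idx in np.argsort(-frac)[:rem]:
        counts[idx] += 1
    return counts


def simulate(cfg: SimulationConfig, seed: int | None = None) -> SimulatedDataset:
    """Generate one dataset under ``cfg``; reproducible given a seed."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    types = [f"type_{k + 1}" for k in range(cfg.n_types)]
    marker_sets = {
        t: [f"marker_{k + 1}_{i + 1:02d}" for i in range(cfg.markers_per_type)]
        for k, t in enumerate(types)
    }
    genes = [g for t in types for g in marker_sets[t]]
    genes += [f"bg_{i + 1:03d}" for i in range(cfg.n_background_genes)]
    m = len(genes)

    base = rng.normal(cfg.mu0, cfg.sigma0, size=m)  # m_i

    # type-specific means mu[i, k]
    mu = np.tile((base - cfg.delta)[:, None], (1, cfg.n_types))
    for k in range(cfg.n_types):
        rows = slice(k * cfg.markers_per_type, (k + 1) * cfg.markers_per_type)
        mu[rows, k] = cfg.a * base[rows]

    counts = _type_counts(cfg)
    type_of_cell = np.repeat(np.arange(cfg.n_types), counts)
    cells = [f"cell_{j + 1:05d}" for j in range(cfg.n_cells)]

    means = mu[:, type_of_cell]  # m × n
    if cfg.batch_shifts is not None and len(cfg.batch_shifts) > 0:
        batch_of_cell = np.arange(cfg.n_cells) % len(cfg.batch_shifts)
        means = means + np.asarray(cfg.batch_shifts)[batch_of_cell][None, :]

    variance = cfg.sigma_hetero * means + cfg.sigma_homo ** 2
    if (variance < 0).any():
        raise ValueError(
            "negative noise variance sigma_hetero*mu + sigma_homo^2; "
            "a depressed gene mean is too negative for this sigma_hetero"
        )
    X = means + rng.normal(0.0, 1.0, size=means.shape) * np.sqrt(variance)
    np.clip(X, 0.0, None, out=X)  # truncation
    if cfg.pi0 > 0:
        X[rng.random(X.shape) < cfg.pi0] = 0.0  # dropout

    labels = pd.Series([types[k] for k in type_of_cell], index=cells,
                       name="cell_type")
    matrix = ExpressionMatrix(X, genes, cells)
    return SimulatedDataset(matrix=matrix, true_labels=labels,
                            marker_sets=marker_sets, config=cfg)


def _n_exact(rate: float, n: int) -> int:
    return int(round(rate * n))


def corrupt_labels(
    labels: pd.Series | pd.DataFrame,
    retain_fraction: float = 1.0,
    error_rate: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Subsample and/or flip labels, with exact corrupted counts.

    ``retain_fraction`` keeps a uniformly random round(f·n) of the labels;
    ``error_rate`` then reassigns round(e·kept) of those to a uniformly
    random *different* type.  Exact-fraction sampling (not i.i.d.
    Bernoulli) keeps robustness curves on controlled x-axes.
    """
    if not 0.0 <= retain_fraction <= 1.0:
        raise ValueError("retain_fraction must lie in [0, 1]")
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must lie in [0, 1]")
    if isinstance(labels, pd.DataFrame):
        series = pd.Series(
            labels["cell_type"].to_numpy(), index=labels["cell_id"].to_numpy()
        )
    else:
        series = labels
    rng = np.random.default_rng(seed)
    n = len(series)
    keep = rng.choice(n, size=_n_exact(retain_fraction, n), replace=False)
    keep.sort()
    out = series.iloc[keep].copy()

    n_err = _n_exact(error_rate, len(out))
    if n_err > 0:
        all_types = sorted(series.unique())
        if len(all_types) < 2:
            raise ValueError("cannot corrupt labels: only one type present")
        flip = rng.choice(len(out), size=n_err, replace=False)
        for pos in flip:
            others = [t for t in all_types if t != out.iloc[pos]]
            out.iloc[pos] = others[rng.integers(len(others))]
    return pd.DataFrame({"cell_id": out.index, "cell_type": out.to_numpy()})


def corrupt_markers(
    marker_sets: dict[str, list[str]],
    error_rate: float,
    gene_pool: list[str],
    seed: int | None = None,
) -> dict[str, list[str]]:
    """Swap an exact fraction of each type's markers for unrelated genes.

    Each corrupted marker is replaced by a gene drawn (without
    replacement) from ``gene_pool`` minus the genes currently marking that
    type, so per-type set sizes are preserved.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out: dict[str, list[str]] = {}
    for t in marker_sets:
        genes = list(marker_sets[t])
        n_swap = _n_exact(error_rate, len(genes))
        if n_swap == 0:
            out[t] = genes
            continue
        swap_pos = rng.choice(len(genes), size=n_swap, replace=False)
        forbidden = set(genes)
        candidates = [g for g in gene_pool if g not in forbidden]
        if len(candidates) < n_swap:
            raise ValueError(
                f"gene pool exhausted for type {t}: need {n_swap} "
                f"replacements, {len(candidates)} candidates"
            )
        replacements = rng.choice(len(candidates), size=n_swap, replace=False)
        for pos, ridx in zip(swap_pos, replacements):
            genes[pos] = candidates[ridx]
        out[t] = genes
    return out
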