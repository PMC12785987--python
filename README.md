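# scanmf

Semi-supervised, prior- and graph-regularized non-negative matrix
factorization (NMF) for cell-type annotation in single-cell RNA-seq.

## The problem

Annotating cells with their types is a central step in scRNA-seq analysis,
but the available prior knowledge is usually heterogeneous and imperfect:
a curated list of marker genes per type, a small set of confidently
labeled cells, or both — each possibly incomplete or partly wrong.
`scanmf` integrates all three sources of information — marker genes,
partial labels, and the local cell–cell manifold — in one factorization
model, aimed at analysts who have *some* prior knowledge and want robust,
interpretable annotations on the remaining cells.

## The model

Given a non-negative gene-by-cell matrix **X** (m × n), the model seeks
non-negative **U** (m × p, gene–factor loadings) and **V** (n × p,
cell–factor coefficients), with one factor per cell type, minimizing

```
O(U, V) = ‖X − UVᵀ‖²_F + α₀‖U‖₁ + α‖U ⊙ (1−M)‖₁ + β‖V ⊙ (1−P)‖₁ + γ·Tr(VᵀLV)
```

* **M** (m × p) is the expanded marker-constraint matrix: for a marker
  gene it indicates the types it marks; non-marker genes get all-ones
  rows, so the α-penalty discourages marker genes from loading on foreign
  factors and leaves other genes free.
* **P** (n × p) is the expanded label-constraint matrix: one-hot for
  labeled cells, all-ones for unlabeled cells, so the β-penalty pins
  labeled cells to their annotated factor.
* **L = D − W** is the unnormalized Laplacian of a mutual K-nearest-neighbor
  cell graph with Gaussian edge weights w = exp(−d²/2σ²); the γ-term
  smooths coefficients over neighboring cells.
* α₀ adds global ℓ₁ sparsity on U to stabilize the scale.

Optimization uses multiplicative updates (non-negativity-preserving,
monotone in the objective), and cell *j* is annotated with the type whose
factor holds the largest entry of row **V**ⱼ.

The package also ships the full preprocessing recipe (QC, library-size
log-normalization, highly-variable-gene selection against a fitted
mean–variance trend, gene-wise standardization), a synthetic-data
generator with marker-driven structure, dropout, heteroscedastic noise
and batch shifts, prior-corruption utilities for robustness studies, and
evaluation metrics including a marker-consistency analysis of the learned
factors.

## Worked example

```python
from scanmf import (SimulationConfig, simulate, corrupt_labels,
                    ModelConfig, ScANMF, build_cell_graph)
from scanmf.preprocess import build_priors
from scanmf.metrics import evaluation_report

sim = simulate(SimulationConfig(), seed=1)        # 1200 cells, 4 types
labels = corrupt_labels(sim.true_labels, retain_fraction=0.1, seed=2)
priors = build_priors(sim.marker_sets, labels,
                      sim.matrix.gene_ids, sim.matrix.cell_ids)
graph = build_cell_graph(sim.matrix)              # mutual KNN, K = n/3
model = ScANMF(sim.matrix, priors, graph, ModelConfig())
res = model.fit(seed=3)
print(res.summary())

pred = res.annotate()
unlabeled = [c for c in pred.index if c not in set(labels["cell_id"])]
rep = evaluation_report(pred.loc[unlabeled], sim.true_labels.loc[unlabeled])
print(f"accuracy {rep.accuracy:.2f}%  weighted F1 {rep.weighted_f1:.4f}")
```

Output:

```
             scANMF factorization results
=====================================================
-----------------------------------------------------
                    genes (m)                     180
                    cells (n)                    1200
                  factors (p)                       4
                labeled cells                     120
                 marker genes                      80
alpha0 / alpha / beta / gamma 50 / 10000 / 10000 / 10
                   iterations                      46
                    converged                    True
              final objective              2.1588e+06
         reconstruction error             1.98403e+06
       cells annotated type_1                     300
       cells annotated type_2                     300
       cells annotated type_3                     300
       cells annotated type_4                     300
-----------------------------------------------------
accuracy 100.00%  weighted F1 1.0000
```

With clean priors and 10% labeled cells, every one of the 1080 unlabeled
cells is assigned its true type; the four factors align one-to-one with
the four simulated cell types.

The same pipelines are available from a shell:

```bash
scanmf simulate --out sim/ --seed 1
scanmf fit --matrix sim/ --markers sim/markers.json \
    --labels sim/labels.csv --preprocess none --out run/
scanmf robustness --scenario label_noise --levels 0.2,0.4,0.6 --out rob.csv
```

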