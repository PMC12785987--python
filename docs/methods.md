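# Methods

This note documents the modeling choices, parameter conventions and known
limitations of `scanmf`, in the spirit of a model reference rather than a
tutorial.

## The factorization model

`scanmf` annotates cells by factorizing the non-negative gene-by-cell
matrix X (m genes × n cells) as X ≈ UVᵀ with U ∈ R≥0^{m×p},
V ∈ R≥0^{n×p}.  The factor count p is *always* the number of distinct
cell types in the union of the marker map and the label table — there is
no automatic rank selection, because the model's interpretability rests
on a one-to-one correspondence between factors and types.

The objective combines five terms:

| term | weight | role | default |
|------|--------|------|---------|
| ‖X − UVᵀ‖²_F | — | reconstruction | — |
| ‖U‖₁ | α₀ | global sparsity / scale stabilization | 50 |
| ‖U ⊙ (1−M)‖₁ | α | marker-gene consistency | 10 000 |
| ‖V ⊙ (1−P)‖₁ | β | label supervision | 10 000 |
| Tr(VᵀLV) | γ | graph smoothness | 10 |

The defaults are the within-dataset settings; cross-dataset analyses
should be tuned with `scanmf.model.tune`, which grid-searches
α, β ∈ {10², …, 10⁵} and γ ∈ {0.1, 1, 10, 100} by stratified
cross-validated accuracy on the labeled cells (ties resolved toward the
smallest weights).  Note both α₀‖U‖₁ and α‖U ⊙ (1−M)‖₁ apply to marker
genes' own-type loadings through α₀; this overlap is part of the model
definition, not an accident of implementation.

Effective penalty strengths scale with the Frobenius norm of the
standardized matrix and with the graph density, so the defaults are
sensible for matrices preprocessed by this package (entries O(1) after
standardization) and K ≈ n/3 graphs; wildly different scales call for
re-tuning.

### Optimization

Multiplicative updates derived from the KKT conditions:

```
u_ik ← u_ik · (2XV)_ik / (2UVᵀV + α₀·1 + α(1−M))_ik
v_jk ← v_jk · 2(XᵀU + γWV)_jk / (2VUᵀU + β(1−P) + 2γDV)_jk
```

* One *iteration* is a U update followed by a V update; the convergence
  check |O(t) − O(t−1)| / O(t−1) < 1e-4 (absolute value taken; the
  updates make the difference non-positive anyway) runs after each pair,
  with a cap of 50 iterations.  The objective is evaluated every
  iteration and stored as the trace.
* Denominators carry an additive guard ε = 1e-12; entries that reach
  exactly zero stay zero (a structural property of multiplicative
  updates), which is why initialization draws from the half-open uniform
  (0, 1] — strictly positive, so no entry starts locked.
* NNDSVD initialization is available (`init="nndsvd"`, zeros lifted to
  1e-4) but random initialization is the default; in our experiments the
  deterministic start bought no accuracy.
* Monotone descent of the objective under one sweep is a tested
  invariant (the ℓ₁ and graph terms are linear respectively quadratic in
  the blocks, so the classical auxiliary-function argument applies).

Annotation is `argmax_k V_{jk}` per cell, ties to the lowest factor
index; a cell whose entire row underflows to zero is reported as
`unassigned` rather than silently assigned.

By default, evaluation utilities exclude the supervised cells, so
reported accuracies describe the genuinely unlabeled cells.

## The cell graph

Edges connect cells that are *mutually* within each other's K nearest
neighbors (Euclidean distances in the preprocessed expression space).
Ties at the K-th neighbor distance are all included, which makes the
construction invariant to cell ordering.  Defaults: K = min(⌊n/3⌋, 1000).
Edge weights are Gaussian, w = exp(−d²/2σ²), with σ the median distance
over the retained edges (each undirected edge counted once).

Degenerate geometry: when many cells coincide exactly (noiseless
simulations), the median edge distance can be zero; σ then falls back to
the median of the *positive* edge distances, and only if every edge has
zero length is the bandwidth declared undefined (error).  Isolated cells
are permitted — their Laplacian row is zero, so the graph term simply
ignores them.  Distances are computed in the full preprocessed gene
space; a PCA-space graph would scale better at atlas sizes but is out of
scope here.

## Preprocessing

QC and normalization follow the standard recipe: drop cells with < 200
detected genes or > 20% mitochondrial counts (symbols prefixed `MT-` /
`mt-`, configurable), keep genes detected in ≥ 3 cells, library-size
normalize to 10⁴ and log-transform with the natural log.

Highly variable genes are ranked by standardized variance
v = σ² / f(μ), where f is a lowess fit of log₁₀ variance on log₁₀ mean
(span 0.3) — a local-regression analog of the Seurat vst trend; a
quadratic-polynomial trend is available for tiny gene panels where
lowess is underdetermined.  Ties break by gene symbol, making selection
deterministic and permutation-equivariant.

The model requires X ≥ 0, but gene-wise standardization produces
negative values.  We clip negatives at zero: it is the minimal repair,
keeps low-expression entries sparse, and turns each gene into an
"above-average expression" signal, which is exactly what the
factorization needs.  (A per-gene min-shift was rejected: it densifies
the matrix and inflates the reconstruction term with uninformative
offsets.)  Zero-variance genes standardize to all-zero rows rather than
erroring.  The final feature rows are the union of HVGs and marker genes
with marker genes first (sorted by symbol), aligning row i < c with row
i of M; marker genes absent from the matrix are dropped with a warning,
and markers outside the HVG set are always appended.

Constraint matrices: M rows are type-indicator vectors for marker genes
and all-ones for other genes; P rows are one-hot for labeled cells and
all-ones otherwise, so (1−M) and (1−P) vanish exactly where the data are
unconstrained.  Cell-type columns are the lexicographically sorted type
union, fixed once and shared by the model and all metrics.

## The simulator

The generator plants a known type structure to measure annotation
accuracy against ground truth.  Per gene, a base mean m_i ~ N(μ0, σ0²);
per type k with marker set G_k, the type mean is a·m_i for i ∈ G_k and
m_i − δ otherwise.  Observations add Gaussian noise with variance
σ_hetero·μ + σ_homo² (mean-dependent, as in real data), negatives are
truncated at zero, then entries drop out independently with probability
π0.  Optional batch groups add fixed shifts to their cells' gene means
(cells assigned round-robin).  Stage order — means, noise, truncation,
dropout — keeps the final zeros interpretable as dropout ∪ truncation.

Benchmark configuration (the package default): 1200 cells, 4 equally
frequent types, 20 disjoint markers per type, 100 background genes.  The
noise calibration (μ0 = 5, σ0 = 1, a = 3, δ = 1, π0 = 0.3,
σ_hetero = 0.2, σ_homo = 0.5) was chosen once to produce ≈30% zeros,
clearly overlapping type distributions at the single-gene level, and
mean-dependent noise — a regime where the priors matter but the problem
is solvable.  All parameters are exposed in `SimulationConfig`.

What the simulator does *not* emulate: count statistics (no
negative-binomial / UMI sampling — values are truncated Gaussians),
ambient RNA, doublets, or correlated gene programs within a type.
Consequently, passing simulation benchmarks demonstrates the
optimization and the prior-integration machinery, not performance on the
full messiness of real tissue atlases.

Prior corruption uses exact fractions (round(rate·n) items sampled
without replacement) rather than i.i.d. Bernoulli, so robustness curves
have controlled x-axes: label corruption flips the chosen labels to a
uniformly random *different* type; marker corruption swaps the chosen
markers for genes not currently marking that type, preserving set sizes.
In the robustness experiments the label-noise and marker-noise scenarios
supply 10% of cells as (possibly corrupted) supervision, mirroring a
realistically sparse labeling effort.

## Evaluation metrics

Cell level: accuracy (percent) and class-size-weighted F1 from one-vs-
rest precision/recall (zero-division convention: 0).  Gene level, the
marker-consistency analysis: each annotated marker gene i is sent to its
maximal-loading factor k*(i) = argmax_k U_ik; n_{c→k} counts type-c
markers dominated by factor k and P_{c→k} = n_{c→k}/|G_c| normalizes per
type (rows sum to 1); factor k is assigned the type c*(k) with the most
dominated markers, and the marker accuracy is the fraction of annotated
marker genes with c*(k*(i)) among their own annotated types — a gene
marking several types is counted correct if *any* of them matches.  The
per-pair weights w_ic = 1/|C_i| are computed and exposed for downstream
many-to-many analyses, though the accuracy itself uses the unweighted
count.  All argmax ties resolve to the lowest index.

## Problem sizes used in the test and acceptance suites

Unit and property tests run on matrices up to ~50 × 50 and simulations
of 60–300 cells; end-to-end quality checks use the full 1200-cell
benchmark with 5 replicate seeds per corruption condition and 10 seeds
for the noiseless-recovery check.  These sizes make every fit exact to
the study design (the benchmark is simulated at full size, never scaled
down) while the whole suite completes in well under a minute of compute
per experiment.

## Known limitations

* Three hyperparameters must be set; the defaults assume standardized
  input and the K ≈ n/3 graph.  Extreme mis-specification (e.g. α or β
  orders of magnitude beyond the reconstruction term) suppresses the
  data-driven structure.
* The additive combination of priors assumes their errors are
  independent; correlated errors (e.g. labels derived from the same
  markers) are not modeled.
* Dense distance computation makes graph construction O(n²m); for
  n ≫ 10⁴ an approximate-NN / PCA-space graph would be needed.
* No novel-type discovery: a cell of a type absent from the priors is
  necessarily forced into one of the p known factors.
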