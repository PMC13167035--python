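# superclust

Supercell-based multi-omics graph clustering for single-cell data.

`superclust` addresses the integration problem faced by CITE-seq and
paired RNA/ATAC experiments: `V` modalities profile the same `n` cells
(RNA expression, ADT surface-protein abundance, chromatin accessibility),
and the analyst wants one partition of the cells that is simultaneously
well separated in every modality — at a cost that scales to large datasets
and without washing out rare subpopulations. It is written for
computational biologists who work with per-modality cell × feature
matrices (MatrixMarket trios or delimited tables) and want both a Python
API (`Model.fit() → Results`) and a shell tool.

## Method

**Stage 1 — supercells.** Cell similarity is *angle-aware*: the Pearson
correlation `PCC(x_i, x_j)`, i.e. the cosine between mean-centered
profiles, which is invariant to per-cell scale. Each cell receives an
adaptive, row-stochastic neighborhood over its top γ+1 correlations
(γ = 10 or 20 depending on feature dimensionality),

    a_ij = (r_{γ+1} − r_j) / (γ·r_{γ+1} − Σ_{k≤γ} r_k).

A second-order co-occurrence graph links `i` and `j` when each is in the
other's α-neighborhood and they share at least β neighbors (defaults
α = 5, β = 2); the per-modality graphs are fused by strict majority vote
into a consistency graph `M`. Connected components of `M` are supercell
candidates; within each component a cell's degree centrality
`DC_i = deg(i)/(|comp|−1)` is min-max normalized to `HS_i`, and the cell
is removed with probability `P_i = 1 − HS_i` (one seeded pass). Surviving
component cores and every pruned cell become the supercells.

**Stage 2 — clustering.** Cell similarities are coarsened,
`as_yz = Σ_{i∈SC(y)} Σ_{j∈SC(z)} (a_ij + a_ji)`, and with `L(v)` the
unnormalized Laplacian of `AS(v)` the partition `E ∈ {0,1}^{S×C}`,
`E·1 = 1`, and modality weights `ω(v)` minimize

    Σ_v ω(v) Σ_p ‖L(v) e_p‖₁   s.t.  Σ_v 1/ω(v) = 1,  ω ≻ 0,

an omics-weighted L1-Laplacian cut. Block coordinate descent alternates
the closed-form weights `ω(v) = Σ_{v'} ε(v') / ε(v)` with exact row-wise
indicator updates against the fused Laplacian
`L̂ = Σ_v ω(v)(L(v)+L(v)ᵀ)`; the indicator is initialized by FINCH
(first-integer-neighbor) agglomeration. When `C` is unknown it is
estimated per modality by a k-means SSE elbow scan, with a weighted
fusion across modalities when they disagree. Cells inherit their
supercell's cluster.

The package also ships evaluation metrics (ARI, NMI, accuracy, purity,
pair-counting metrics, per-supercell pruning recall), one-sided Welch
marker detection with Benjamini–Hochberg correction, and a synthetic-data
generator with planted clusters, cross-omics micro-structure and rare
populations. See `docs/methods.md` for modeling details and design
choices.

## Worked example

```python
from superclust import MultiOmicsClustering, SimulationConfig, simulate_multiomics

cfg = SimulationConfig(n_cells=500, n_clusters=4, feature_counts=(500, 100), seed=7)
ds, truth = simulate_multiomics(cfg)

model = MultiOmicsClustering(ds)   # C estimated adaptively
res = model.fit(seed=0)
res.evaluate(truth)
print(res.summary())
```

```
Supercell multi-omics clustering
================================================
cells                 500
modalities            2 ['OTHER(500)', 'OTHER(100)']
metric / pruning      angle / on
gamma / alpha / beta  10 / 5 / 2
supercells S          479
pruned cells          18
clusters C            4  (estimated)
  per-modality C      [4, 4]  fused None
modality weights      [2.157, 1.864]
BCD iterations        10 (converged)
final objective       3.8495e-13
metrics               {"ARI": 1.0, "NMI": 1.0, "ACC": 1.0, "purity": 1.0, "RI": 1.0, "precision": 1.0, "recall": 1.0, "F1": 1.0}
cluster sizes         [125, 125, 125, 125]
```

Reading the output: 500 cells condensed into 479 supercells (18
low-centrality cells were pruned into singletons), both modalities'
elbow scans agreed on C = 4, the learned modality weights satisfy
Σ 1/ω = 1, the objective converged to (numerically) zero — a perfect
cut — and all agreement metrics against the planted labels equal 1.

The same pipeline is available from the shell:

```bash
superclust simulate -n 500 -K 4 --features 500 --features 100 -o sim/
superclust run -m sim/modality0/matrix.mtx -m sim/modality1/matrix.mtx \
    --format mtx-trio --labels sim/labels.tsv -o run/
superclust evaluate --truth sim/labels.tsv --pred run/labels.tsv
```

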