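# Methods

This note documents the model implemented by `superclust`, the parameters
that matter, the numerical choices made where the construction was open,
and what the synthetic-data generator does and does not emulate.

## Problem and model

Input is a collection of `V` matrices `X(v) ∈ R^{n×m_v}` profiling the
same `n` cells in different omics layers, assumed row-aligned (the loader
realigns permutations and rejects mismatched cell sets). The method makes
two structural assumptions: (i) cells of one biological population have
correlated feature *profiles* within each modality, even when their
absolute scales differ; (ii) locally coherent neighborhoods are
reproducible across modalities, whereas spurious neighbors are not.

**Similarity.** Cell–cell similarity is the Pearson correlation of
feature vectors — the cosine of the angle after mean-centering — rather
than Euclidean distance. This makes the graph invariant under per-cell
affine rescaling (`x → a·x + b`, `a > 0`), which absorbs depth and scale
artifacts. From the correlation matrix each cell `i` keeps its top γ
neighbors with adaptive weights

    a_ij = (r_{γ+1} − r_j) / (γ·r_{γ+1} − Σ_{k≤γ} r_k),

where `r_1 ≥ … ≥ r_{γ+1}` are its best γ+1 correlations. Rows are
non-negative and sum to 1; if the γ+1 scores tie exactly the weights
degenerate to 0/0 and the row falls back to the limiting uniform `1/γ`.
Ties in ranking always resolve to the smaller cell index, making the
whole pipeline deterministic given its inputs. A cell with zero feature
variance has no defined correlation; it is assigned correlation 0 to
every cell, which keeps it rankable (and clusterable) without NaNs. The
graph is kept asymmetric; every symmetric quantity downstream uses
`a_ij + a_ji` explicitly.

**Supercells.** The second-order co-occurrence graph of one modality
links `i` and `j` when each lies in the other's α-nearest neighborhood
*and* `|N_i ∩ N_j| ≥ β` — a shared-nearest-neighbor filter that removes
one-off links. The printed one-directional variant (`j ∈ N_i` alone) is
available behind `second_order="one-directional"`, but mutuality is the
default since the construction is meant to capture reciprocal local
coherence; the fusion step OR-symmetrizes in either case, so the
consistency graph is always a valid undirected adjacency. Layers vote:
`m_ij = 1` iff more than `⌊V/2⌋` modalities carry the edge (for `V = 2`
both must agree). Connected components of `M` seed supercells. Within a
component, degree centrality `DC_i = deg(i)/(|comp|−1)` is min-max
normalized to `HS_i` (components of size < 3, and components with uniform
centrality, take `HS = 1` for every member — the 0/0 case signals a
coherent group and disables pruning); each cell is removed iff its
uniform draw satisfies `U_i ≤ P_i = 1 − HS_i` and `P_i > 0`, so the
maximum-centrality cell of a component always survives and no component
ever empties. Pruning is a **single pass** with centralities computed
once: repeated passes with recomputation exist behind
`pruning="iterative"`, but the single seeded pass is the default because
it keeps repeated runs reproducible and the first pass already removes
the low-centrality boundary cells that matter. All draws come from one
generator seeded by the run seed, consumed in ascending (component, cell)
order. Each component's surviving core is one supercell; each pruned
cell becomes a singleton supercell, so `S = #components + #pruned`.

**Coarse objective.** Similarities are summed over supercell pairs
(`as_yz`, diagonal zeroed — within-supercell mass cannot contribute to a
cut and would distort degrees), and `L(v) = D − AS(v)` is the
*unnormalized* Laplacian: for a one-hot indicator column `e_p`,
`‖L(v) e_p‖₁` is exactly twice the cut between cluster `p` and the rest,
so the L1 objective is the weighted multi-omics cut. The weights'
closed form `ω(v) = Σ ε(v') / ε(v)` (with `ε(v)` the modality's raw cut)
satisfies `Σ 1/ω = 1` identically and up-weights modalities that are
already well cut. A modality with `ε = 0` would receive infinite weight;
its ε is floored so ω caps near 1e12 and the constraint still holds.

**Optimization.** Block coordinate descent: per outer iteration the
weights are recomputed, the fused Laplacian
`L̂ = Σ ω(v)(L(v)+L(v)ᵀ)` is rebuilt, and indicator rows are swept in
ascending order until a pass changes nothing. Reassigning row `d` uses
the exact incremental score `2 u_iᵀ l̂_d + l̂_dd` (with `u_i` the cluster-i
indicator excluding `d`), which equals the full objective difference of
recomputing the quadratic form; argmin ties break to the smallest cluster
index, and the unique move that would empty a cluster is skipped so `C`
stays fixed. Stopping: relative objective change below 1e−20 after the
first 10 iterations, or 50 iterations.

The **trace** records the *reduced* objective: the weighted cut with the
weights re-synced to the current partition, which by the closed form
equals `V · Σ_v ε(v)`. Successive entries are then evaluations of one
function of `E` and are non-increasing in practice. Recording the cut
under each iteration's own stale weights instead would compare values of
different weighted objectives, and the weight re-sync (an inverse-
objective reweighting, not a descent step on the weighted sum) can bump
such a mixed sequence upward even at the fixed point.

**Initialization.** FINCH: every supercell links to its single most
similar other supercell; connected components of the resulting graph
(with the shared-first-neighbor rule) form the first partition, and the
procedure recurses on between-group aggregated similarity until the
count drops to ≤ C. The hierarchy level actually used is the finest one
with count ≥ C, repaired to exactly C by greedily merging the most
similar group pair (falling back to the two smallest groups when no
positive between-similarity remains). Which hierarchy level feeds the
indicator was an open choice; merging down from the finest adequate
level was chosen because it never has to split a FINCH group.

## Cluster-number estimation

Each (variance-selected) modality is scanned with seeded k-means
(10 restarts) over `C ∈ [2, min(20, ⌊√n⌋)]` — the scan range is a
package choice, configurable — and the elbow statistic is the ratio of
successive SSE drops, `r(C) = (SSE_C − SSE_{C−1}) / (SSE_{C+1} − SSE_C)`;
flat-tail candidates with zero trailing drop are skipped. Two
conventions are exposed: the default `ratio-only` returns `argmax r(C)`
itself, while `plus-one` adds an offset of one. The default drops the
offset deliberately: on cleanly clustered data the ratio peaks exactly
at the true cluster count (the trailing drop collapses there), so the
offset convention systematically reports one cluster too many and could
not reproduce exact cluster-number recovery; both conventions are
available for comparison. Datasets beyond 2000 cells are subsampled
(seeded) for the scans, since the SSE curve's shape is stable in the
sample size and the scan dominates runtime otherwise.

When per-modality estimates agree, their consensus is final and the
fused matrix is never touched. Otherwise the fused high-order similarity
`Ã = (1/V) Σ (A(v)+A(v)ᵀ)/2` — a package construction, since only the
existence of a fused matrix is prescribed — is scanned the same way on
its rows, and the final C is the half-away-from-zero round of the
weighted sum with modality weights ∝ (2, 3, …) in input order and the
fused term always carrying the largest share (2/9, 3/9, 4/9 for V = 2).
The generalization beyond two modalities is an extrapolation and is
flagged as such here.

## Markers and evaluation

Marker detection compares one cluster against all remaining cells per
feature with Welch's unequal-variance t statistic and Welch–Satterthwaite
degrees of freedom, one-sided for up-regulation; p-values are BH-adjusted
across the cluster's features, and `log2FC = log2(x̄_c+ε) − log2(x̄_r+ε)`
with `ε = 1e−6`. The pass flag requires raw `p < 0.05` and
`log2FC > 0.25` (both configurable); features higher in the rest keep
their rows with a False flag so the table remains auditable. Zero
variance in both groups yields p = 0.5 on equal means and the 0/1 limit
otherwise.

ARI and NMI are computed from the contingency table (natural logs; the
normalization is base-invariant); pair-counting metrics enumerate
co-clustered pairs through the table, with 0/0 ratios reported as 0;
accuracy uses optimal rectangular one-to-one matching
(maximum-weight assignment), purity a majority-vote mapping. The
per-supercell pruning recall averages `TP_s/(TP_s+FN_s)` over supercells,
excluding supercells with no mislabelled cells — they carry no signal
about pruning quality.

## Synthetic data

The generator emulates `V` modalities under one shared assignment of `n`
cells to `K` clusters. Each cluster owns a disjoint marker block per
modality (block size auto-chosen up to 20 features) whose means are
shifted so that any two cluster mean vectors sit `separation`
within-cluster standard deviations apart; remaining features are noise
around a per-feature baseline. The default noise is Gaussian in
log-expression space with unit SD, which makes the separation exact; a
negative-binomial mode (gamma–Poisson with configurable dispersion)
exists for count realism. The default `separation = 30` corresponds to
two cell types differing by a few dozen markers at 2–3 SD each —
strongly separated, as appropriate for recovery and determinism checks.

Cells additionally come in within-cluster micro-groups (sizes 1–5) that
share a low-magnitude offset (0.5 SD per feature), drawn independently
per modality but tied to the same membership. These emulate the locally
coherent, cross-omics-reproducible neighborhoods (cell states,
micro-niches) that the supercell construction is premised on; without
them, exchangeable Gaussian clusters produce almost no reciprocal
neighbors and the consistency graph degenerates to singletons. With
them, a 5000-cell run condenses to ≈4800 supercells with a small pruned
fraction — the regime the method is designed for.

Optional extras: a planted rare population (default 30 cells inside a
500-cell parent cluster, own cross-modality marker block at 3 SD per
feature), used to test that rare cells condense into few supercells and
that their markers are significant at supercell resolution but diluted
below the fold-change threshold at cluster resolution; and per-cell
positive rescaling (`exp(N(0, σ²))` factors), the scenario separating
the angle-aware metric from the Euclidean ablation arm.

What the generator does **not** emulate: dropout and zero inflation,
batch effects, doublets, ambient contamination, or realistic
feature–feature correlation structure. Passing tests therefore
demonstrate correctness of the algorithmic machinery and its behavior
under the stated geometry, not performance on real tissue atlases.

## Problem sizes and tolerances

Default test and acceptance problem sizes were chosen to exercise every
code path at desk scale: unit oracles at n ≤ 30, pipeline recovery at
n = 300–400, and the scalability scenario at n = 5000 (two modalities,
5000/2000 features, K = 15) as a scaled stand-in for a 100,000-cell run.
Monotonicity assertions allow 1e−9 relative slack for floating-point
accumulation; the weight constraint is checked to 1e−12; incremental
row-update scores match full recomputation to 1e−9. Variance-based
feature selection triggers at 5000 features and keeps the top 125
(unbiased estimator; ties to the earlier column). No normalization or
log transform is applied by default — correlation's centering absorbs
per-cell location and scale — but an optional `log1p` flag exists.

## Known limitations

- The consistency graph's strict majority vote is conservative for
  `V = 2` (both layers must agree); discordant modalities yield many
  singleton supercells, which is safe but forfeits coarsening speedups.
- Exact top-k neighbor ranking is O(n²) time and memory per modality;
  the implementation targets datasets up to tens of thousands of cells.
- The BCD objective is non-convex; the FINCH initialization is good in
  practice but the optimizer only guarantees a one-move-optimal fixed
  point.
- Cluster-number estimation inherits k-means' preference for convex,
  similarly sized clusters.
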