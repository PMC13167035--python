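"""Supercell construction: second-order co-occurrence, consistency fusion,
and degree-centrality probabilistic pruning.

Two cells co-occur in one modality when each lies in the other's α-nearest
neighborhood *and* the two neighborhoods share at least β cells (a shared-
nearest-neighbor condition that suppresses spurious one-off links). Layers
are fused by strict majority vote across modalities, giving a binary
consistency graph whose connected components are supercell candidates.

Within each component, a cell's degree centrality DC = deg / (|comp| − 1)
measures how strongly it agrees with the group consensus. Centralities are
min-max normalized to a high-order similarity HS (components smaller than 3,
or with uniform centrality, take HS = 1 for all members), and each cell is
removed with probability P = 1 − HS using one seeded uniform stream. Every
pruned component and every eliminated cell becomes a "supercell" — the
intermediate-resolution unit clustered downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _cc

from .io import MultiOmicsDataset, select_top_variance_features
from .similarity import (
    SimilarityGraph,
    adaptive_similarity,
    default_gamma,
    neighbor_order,
    score_matrix,
)

__all__ = [
    "CooccurrenceGraph",
    "ConsistencyGraph",
    "SupercellAssignment",
    "second_order_cooccurrence",
    "consistency_fuse",
    "connected_components",
    "centrality_and_pruning",
    "build_supercells",
    "DEFAULT_ALPHA",
    "DEFAULT_BETA",
]

DEFAULT_ALPHA = 5
DEFAULT_BETA = 2


@dataclass
class CooccurrenceGraph:
    """Binary second-order co-occurrence graph N for one modality."""

    N: sp.csr_matrix
    alpha: int
    beta: int
    modality: str = "OTHER"

    @property
    def n_cells(self) -> int:
        return self.N.shape[0]


@dataclass
class ConsistencyGraph:
    """Binary symmetric cross-omics consistency graph M (zero diagonal)."""

    M: sp.csr_matrix

    @property
    def n_cells(self) -> int:
        return self.M.shape[0]


@dataclass
class SupercellAssignment:
    """Partition of cells into supercells.

    ``supercell_of[i]`` is the supercell index of cell *i* (0-based);
    ``provenance[s]`` is ``"pruned-component"`` for a component's surviving
    core or ``"singleton-from-pruning"`` for an eliminated cell. The pruning
    audit (per-cell component, DC, HS, P, uniform draw, removed flag) is in
    ``records``.
    """

    supercell_of: np.ndarray
    n_supercells: int
    provenance: list[str] = field(default_factory=list)
    records: pd.DataFrame | None = None

    @property
    def n_cells(self) -> int:
        return len(self.supercell_of)

    def members(self) -> list[np.ndarray]:
        """Cell indices of each supercell."""
        order = np.argsort(self.supercell_of, kind="stable")
        bounds = np.searchsorted(self.supercell_of[order], np.arange(self.n_supercells + 1))
        return [order[bounds[s] : bounds[s + 1]] for s in range(self.n_supercells)]

    def indicator(self) -> sp.csr_matrix:
        """Sparse n × S cell-to-supercell membership matrix."""
        n = self.n_cells
        return sp.csr_matrix(
            (np.ones(n), (np.arange(n), self.supercell_of)),
            shape=(n, self.n_supercells),
        )


def second_order_cooccurrence(
    P: np.ndarray,
    alpha: int = DEFAULT_ALPHA,
    beta: int = DEFAULT_BETA,
    order: np.ndarray | None = None,
    mode: str = "mutual",
    modality: str = "OTHER",
) -> CooccurrenceGraph:
    """Second-order co-occurrence graph from neighbor-ranking scores ``P``.

    𝒩_i is the α most similar other cells of *i* (ties to the smaller
    index). In the default ``"mutual"`` mode, n_ij = 1 iff i and j are in
    each other's α-neighborhood and |𝒩_i ∩ 𝒩_j| ≥ β (symmetric output).
    ``"one-directional"`` drops the mutuality requirement (j ∈ 𝒩_i
    suffices), yielding a possibly asymmetric graph that downstream fusion
    symmetrizes by OR.
    """
    n = P.shape[0]
    if alpha >= n:
        raise ValueError(f"alpha={alpha} must be < n={n}")
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if mode not in ("mutual", "one-directional"):
        raise ValueError(f"unknown mode {mode!r}")
    if beta > alpha:  # shared-neighbor count can never reach beta
        return CooccurrenceGraph(sp.csr_matrix((n, n)), alpha, beta, modality)

    if order is None:
        order = neighbor_order(P, alpha)
    nbrs = order[:, :alpha]
    rows = np.repeat(np.arange(n), alpha)
    H = sp.csr_matrix((np.ones(n * alpha, dtype=np.int32), (rows, nbrs.ravel())), shape=(n, n))

    shared = (H @ H.T) >= beta  # sparse bool: |𝒩_i ∩ 𝒩_j| ≥ β
    linked = H.multiply(H.T) if mode == "mutual" else H
    N = linked.multiply(shared).astype(np.int8)
    N.setdiag(0)
    N.eliminate_zeros()
    return CooccurrenceGraph(N.tocsr(), alpha, beta, modality)


def consistency_fuse(graphs: list[CooccurrenceGraph]) -> ConsistencyGraph:
    """Strict-majority fusion of per-modality co-occurrence graphs.

    m_ij = 1 iff more than ⌊V/2⌋ modalities have the edge; the result is
    OR-symmetrized so it is a valid undirected adjacency even when fed
    one-directional layers.
    """
    if not graphs:
        raise ValueError("empty graph list")
    n = graphs[0].n_cells
    if any(g.n_cells != n for g in graphs):
        raise ValueError("co-occurrence graphs disagree on cell count")
    V = len(graphs)
    votes = graphs[0].N.astype(np.int32)
    for g in graphs[1:]:
        votes = votes + g.N.astype(np.int32)
    M = (votes > (V // 2)).astype(np.int8)
    M = ((M + M.T) > 0).astype(np.int8)  # OR-symmetrize
    M.setdiag(0)
    M = sp.csr_matrix(M)
    M.eliminate_zeros()
    return ConsistencyGraph(M)


def connected_components(M: ConsistencyGraph | sp.spmatrix) -> list[np.ndarray]:
    """Connected components of the consistency graph, ordered by the
    smallest member index; isolated cells are singletons."""
    adj = M.M if isinstance(M, ConsistencyGraph) else M
    _, labels = _cc(adj, directed=False)
    comps: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        comps.setdefault(lab, []).append(i)
    out = [np.array(v) for v in comps.values()]
    out.sort(key=lambda a: a[0])
    return out


def centrality_and_pruning(
    component: np.ndarray,
    M: ConsistencyGraph | sp.spmatrix,
    rng: np.random.Generator,
    iterative: bool = False,
) -> pd.DataFrame:
    """Degree-centrality pruning records for one component.

    DC_i = deg(i)/(|comp|−1) in the component's induced subgraph; HS is the
    min-max normalization of DC for components of size ≥ 3 (1 for everyone
    when all centralities coincide, and in smaller components); the removal
    probability is P = 1 − HS and cell *i* is removed iff its uniform draw
    U_i ≤ P_i (with P = 0 never removing, so the maximum-centrality cell
    always survives). By default a single pass is made with centralities
    computed once; ``iterative=True`` repeats passes on the survivors,
    recomputing DC, until a pass removes nobody.

    Returns one row per cell: cell, DC, HS, P, U, removed. Uniform draws are
    consumed in ascending cell-index order within the component.
    """
    adj = M.M if isinstance(M, ConsistencyGraph) else M
    comp = np.sort(np.asarray(component))
    if comp.size == 0:
        raise ValueError("empty component")

    active = comp.copy()
    rec: dict[int, tuple[float, float, float, float, bool]] = {}
    while True:
        size = active.size
        sub = adj[np.ix_(active, active)]
        deg = np.asarray(sub.sum(axis=1)).ravel().astype(float)
        dc = deg / (size - 1) if size > 1 else np.zeros(size)
        if size >= 3:
            lo, hi = dc.min(), dc.max()
            hs = np.ones(size) if hi - lo < 1e-15 else (dc - lo) / (hi - lo)
        else:
            hs = np.ones(size)
        prob = 1.0 - hs
        draws = rng.random(size)
        removed = (draws <= prob) & (prob > 0)
        for idx, cell in enumerate(active):
            rec[cell] = (dc[idx], hs[idx], prob[idx], draws[idx], bool(removed[idx]))
        if not iterative or not removed.any():
            break
        active = active[~removed]
        if active.size == 0:  # cannot happen: P=0 cells survive every pass
            break

    rows = [(c, *rec[c]) for c in comp]
    return pd.DataFrame(rows, columns=["cell", "DC", "HS", "P", "U", "removed"])


def build_supercells(
    ds: MultiOmicsDataset,
    alpha: int = DEFAULT_ALPHA,
    beta: int = DEFAULT_BETA,
    gamma: int | None = None,
    seed: int = 0,
    metric: str = "angle",
    pruning: str = "on",
    second_order: str = "mutual",
    var_trigger: int = 5000,
    var_keep: int = 125,
    return_graphs: bool = False,
):
    """End-to-end supercell construction from a validated multi-omics dataset.

    Composes per-modality similarity graphs, second-order co-occurrence,
    consistency fusion, component finding and pruning. Surviving component
    members share one supercell; each pruned cell becomes its own singleton
    supercell, so S = #components + #pruned. ``pruning`` is ``"on"`` (one
    seeded pass), ``"off"`` (supercells are exactly the components), or
    ``"iterative"``. Deterministic given the seed.

    With ``return_graphs=True`` also returns the per-modality
    :class:`~superclust.similarity.SimilarityGraph` list (computed on the
    variance-selected matrices), for reuse downstream.
    """
    if pruning not in ("on", "off", "iterative"):
        raise ValueError(f"unknown pruning mode {pruning!r}")
    if gamma is None:
        gamma = default_gamma(ds.feature_counts())

    graphs: list[SimilarityGraph] = []
    layers: list[CooccurrenceGraph] = []
    for X in ds.modalities:
        Xs = select_top_variance_features(X, trigger=var_trigger, keep=var_keep)
        scores = score_matrix(Xs, metric=metric)
        order = neighbor_order(scores, max(gamma + 1, alpha))
        graphs.append(adaptive_similarity(scores, gamma, order=order, modality=X.modality))
        layers.append(
            second_order_cooccurrence(
                scores, alpha, beta, order=order, mode=second_order, modality=X.modality
            )
        )
        del scores, order

    M = consistency_fuse(layers)
    comps = connected_components(M)

    rng = np.random.default_rng(seed)
    n = ds.n_cells
    supercell_of = np.full(n, -1, dtype=int)
    provenance: list[str] = []
    all_records: list[pd.DataFrame] = []
    pruned_cells: list[int] = []

    next_id = 0
    for ci, comp in enumerate(comps):
        if pruning == "off":
            rec = pd.DataFrame(
                {
                    "cell": np.sort(comp),
                    "DC": np.nan,
                    "HS": np.nan,
                    "P": 0.0,
                    "U": np.nan,
                    "removed": False,
                }
            )
        else:
            rec = centrality_and_pruning(comp, M, rng, iterative=(pruning == "iterative"))
        rec.insert(1, "component", ci)
        all_records.append(rec)
        kept = rec.loc[~rec["removed"], "cell"].to_numpy()
        supercell_of[kept] = next_id
        provenance.append("pruned-component")
        next_id += 1
        pruned_cells.extend(rec.loc[rec["removed"], "cell"].tolist())

    for cell in pruned_cells:  # (component, cell) order by construction
        supercell_of[cell] = next_id
        provenance.append("singleton-from-pruning")
        next_id += 1

    records = pd.concat(all_records, ignore_index=True)
    sc = SupercellAssignment(
        supercell_of=supercell_of,
        n_supercells=next_id,
        provenance=provenance,
        records=records,
    )
    if return_graphs:
        return sc, graphs, M
    return sc
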