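"""Supercell-level graphs and the omics-weighted L1-Laplacian optimization.

Cell-level similarity graphs are coarsened to the supercell level:

    as_yz = Σ_{i∈SC(y)} Σ_{j∈SC(z)} (a_ij + a_ji),   y ≠ z,

with zero diagonal, and L(v) = D − AS(v) is the unnormalized graph
Laplacian. For a one-hot S × C indicator E = (e_1 … e_C) with exactly one 1
per row, ‖L(v) e_p‖₁ equals twice the weight of the cut between cluster p
and its complement, so minimizing

    Σ_v ω(v) Σ_p ‖L(v) e_p‖₁    s.t.  Σ_v 1/ω(v) = 1,  ω ≻ 0

seeks a partition that is maximally separable simultaneously in every
modality, with modality weights learned alongside the labels. Optimization
is block coordinate descent: the weights have the closed form
ω(v) = Σ_{v'} ε(v') / ε(v) with ε(v) the modality's raw cut objective, and
each indicator row is reassigned exactly by an O(deg) incremental score
against the fused symmetrized Laplacian L̂ = Σ_v ω(v)(L(v) + L(v)ᵀ).

The indicator is initialized by first-integer-neighbor (FINCH) hierarchical
agglomeration of the fused supercell similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _cc

from .similarity import SimilarityGraph
from .supercells import SupercellAssignment

__all__ = [
    "CoarseGraph",
    "OmicsWeights",
    "OptimizationTrace",
    "supercell_similarity",
    "laplacian",
    "labels_to_indicator",
    "indicator_to_labels",
    "objective",
    "update_weights",
    "fuse_laplacian",
    "row_update_scores",
    "update_row",
    "finch_init",
    "bcd_optimize",
    "expand_labels",
]

#: cap applied to the weight of a modality whose partition is already perfect
WEIGHT_CAP = 1e12


@dataclass
class CoarseGraph:
    """Supercell-level similarity AS and its Laplacian L for one modality."""

    AS: sp.csr_matrix
    L: sp.csr_matrix
    modality: str = "OTHER"


@dataclass
class OmicsWeights:
    """Learned modality weights ω and the raw objectives ε they come from.

    Invariant: Σ_v 1/ω(v) = 1 (to numerical tolerance), all ω positive.
    """

    omega: np.ndarray
    epsilon: np.ndarray


@dataclass
class OptimizationTrace:
    """Per-iteration objective, weights and row-change counts of the BCD.

    The recorded objective is the *reduced* weighted cut: the closed-form
    weights make Σ_v ω(v) ε(v) equal V·Σ_v ε(v) whenever ω is in sync with
    the partition, so successive entries are evaluations of the same
    function of E and are directly comparable (and non-increasing, to
    tolerance).
    """

    objective: list[float] = field(default_factory=list)
    weights: list[np.ndarray] = field(default_factory=list)
    changed_rows: list[int] = field(default_factory=list)
    converged: bool = False

    @property
    def n_iterations(self) -> int:
        return len(self.objective)


def supercell_similarity(A: SimilarityGraph | sp.spmatrix, sc: SupercellAssignment) -> sp.csr_matrix:
    """Coarsen a cell-level similarity graph to the supercell level.

    as_yz sums a_ij + a_ji over all cell pairs straddling supercells y and z;
    the diagonal (within-supercell mass) is zeroed because self-similarity
    never contributes to a cut and would distort node degrees.
    """
    Amat = A.A if isinstance(A, SimilarityGraph) else A
    if Amat.shape[0] != sc.n_cells:
        raise ValueError("similarity graph and supercell assignment disagree on n")
    G = sc.indicator()
    B = Amat + Amat.T
    AS = (G.T @ B @ G).tocsr()
    AS.setdiag(0)
    AS.eliminate_zeros()
    return AS


def laplacian(AS: sp.spmatrix) -> sp.csr_matrix:
    """Unnormalized Laplacian L = D − AS with D = diag(row sums)."""
    d = np.asarray(AS.sum(axis=1)).ravel()
    return (sp.diags(d) - AS).tocsr()


def labels_to_indicator(labels: np.ndarray, n_clusters: int) -> np.ndarray:
    """Dense one-hot S × C matrix from integer labels."""
    labels = np.asarray(labels, dtype=int)
    E = np.zeros((len(labels), n_clusters))
    E[np.arange(len(labels)), labels] = 1.0
    return E


def indicator_to_labels(E: np.ndarray) -> np.ndarray:
    return np.argmax(E, axis=1)


def _modality_objective(L: sp.spmatrix, E: np.ndarray) -> float:
    """ε(v) = Σ_p ‖L e_p‖₁ for one modality."""
    return float(np.abs(L @ E).sum())


def objective(E: np.ndarray, Ls: list[sp.spmatrix], w: OmicsWeights | np.ndarray) -> float:
    """Weighted multi-omics cut objective Σ_v ω(v) Σ_p ‖L(v) e_p‖₁."""
    omega = w.omega if isinstance(w, OmicsWeights) else np.asarray(w, dtype=float)
    return float(sum(om * _modality_objective(L, E) for om, L in zip(omega, Ls)))


def update_weights(E: np.ndarray, Ls: list[sp.spmatrix]) -> OmicsWeights:
    """Closed-form modality weights ω(v) = Σ_{v'} ε(v') / ε(v).

    The harmonic constraint Σ 1/ω = 1 holds exactly in exact arithmetic. A
    modality whose partition is already perfect (ε = 0) would get infinite
    weight; its ε is floored so the weight caps at ~1e12 and the constraint
    still holds.
    """
    eps = np.array([_modality_objective(L, E) for L in Ls], dtype=float)
    total = eps.sum()
    if total <= 0.0:  # every modality already perfectly cut: uniform weights
        V = len(Ls)
        return OmicsWeights(omega=np.full(V, float(V)), epsilon=eps)
    floored = np.maximum(eps, total / WEIGHT_CAP)
    omega = floored.sum() / floored
    return OmicsWeights(omega=omega, epsilon=eps)


def fuse_laplacian(Ls: list[sp.spmatrix], w: OmicsWeights | np.ndarray) -> sp.csr_matrix:
    """Fused symmetrized Laplacian L̂ = Σ_v ω(v) (L(v) + L(v)ᵀ)."""
    omega = w.omega if isinstance(w, OmicsWeights) else np.asarray(w, dtype=float)
    Lhat = None
    for om, L in zip(omega, Ls):
        term = om * (L + L.T)
        Lhat = term if Lhat is None else Lhat + term
    return Lhat.tocsr()


def row_update_scores(
    Lhat: sp.spmatrix, labels: np.ndarray, d: int, n_clusters: int
) -> np.ndarray:
    """Incremental assignment scores for row ``d`` against every cluster.

    With u_i the indicator of cluster i excluding supercell d and l̂_d the
    d-th column of L̂, the change of the quadratic form when row d is
    assigned to cluster i (relative to d unassigned) is

        score_i = 2 u_iᵀ l̂_d + l̂_dd,

    identical for symmetric L̂ to the textbook difference ℒ_{i,i} − ℒ_{0,i}
    of full objective recomputations. The argmin over i is the exact best
    reassignment of row d.
    """
    col = Lhat.getcol(d)
    idx = col.indices if sp.issparse(col) else np.nonzero(col)[0]
    dat = col.data if sp.issparse(col) else col[idx]
    binned = np.zeros(n_clusters)
    np.add.at(binned, labels[idx], dat)
    ldd = Lhat[d, d]
    binned[labels[d]] -= ldd  # exclude d itself from its own cluster sum
    return 2.0 * binned + ldd


def update_row(
    labels: np.ndarray,
    sizes: np.ndarray,
    Lhat: sp.spmatrix,
    d: int,
    n_clusters: int,
) -> bool:
    """Reassign row ``d`` to its exact argmin cluster, in place.

    Ties break to the smallest cluster index. The unique move that would
    empty the current cluster is skipped so the cluster count stays fixed.
    Returns True when the row changed.
    """
    scores = row_update_scores(Lhat, labels, d, n_clusters)
    y = int(np.argmin(scores))
    j = labels[d]
    if y == j:
        return False
    if sizes[j] == 1:  # emptying a cluster is not allowed
        return False
    labels[d] = y
    sizes[j] -= 1
    sizes[y] += 1
    return True


def _first_neighbor_partition(W: sp.csr_matrix) -> np.ndarray:
    """One FINCH level: link every node to its single most-similar other node
    and take connected components of the resulting graph.

    Adjacency follows the FINCH rule: i ~ j if j is i's first neighbor, i is
    j's, or they share a first neighbor. Nodes with no positive similarity
    stay isolated. Ties break to the smaller index.
    """
    S = W.shape[0]
    dense = np.asarray(W.todense(), dtype=float)
    np.fill_diagonal(dense, -np.inf)
    kappa = np.argmax(dense, axis=1)  # argmax takes the first (smallest) index on ties
    best = dense[np.arange(S), kappa]
    has_nbr = best > 0

    rows, cols = [], []
    idx = np.nonzero(has_nbr)[0]
    rows.extend(idx)
    cols.extend(kappa[idx])
    # shared first neighbor: group nodes by kappa
    for target in np.unique(kappa[idx]):
        members = idx[kappa[idx] == target]
        if len(members) > 1:
            rows.extend(members[:-1])
            cols.extend(members[1:])
    adj = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(S, S))
    _, labels = _cc(adj, directed=False)
    return _canonical_labels(labels)


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by order of first appearance (deterministic)."""
    _, first = np.unique(labels, return_index=True)
    mapping = {labels[i]: rank for rank, i in enumerate(np.sort(first))}
    return np.array([mapping[l] for l in labels], dtype=int)


def _aggregate(W: sp.csr_matrix, labels: np.ndarray) -> sp.csr_matrix:
    """Between-group similarity: sum of W entries straddling two groups."""
    k = labels.max() + 1
    G = sp.csr_matrix((np.ones(len(labels)), (np.arange(len(labels)), labels)), shape=(W.shape[0], k))
    agg = (G.T @ W @ G).tocsr()
    agg.setdiag(0)
    agg.eliminate_zeros()
    return agg


def finch_init(AS_fused: sp.spmatrix, n_clusters: int) -> np.ndarray:
    """FINCH-style initial partition of supercells into exactly C clusters.

    Builds the first-neighbor-graph hierarchy (each level re-links the
    aggregated groups of the previous one) until the partition count drops
    to ≤ C, takes the finest level with count ≥ C, and merges the closest
    group pair (largest between-group similarity; if none, the two smallest
    groups) until exactly C groups remain. Returns integer labels over the
    S supercells.
    """
    W = sp.csr_matrix(AS_fused).copy()
    W.setdiag(0)
    S = W.shape[0]
    if S < n_clusters:
        raise ValueError(f"cannot form {n_clusters} clusters from {S} supercells")
    if S == n_clusters:
        return np.arange(S, dtype=int)

    levels = [np.arange(S, dtype=int)]  # level 0: singletons
    cur = levels[0]
    agg = W
    while True:
        part = _first_neighbor_partition(agg)
        k = part.max() + 1
        if k >= cur.max() + 1:  # no further merging possible
            break
        cur = _canonical_labels(part[cur])
        levels.append(cur)
        if k <= n_clusters:
            break
        agg = _aggregate(W, cur)

    # finest level with count >= C (level 0 always qualifies)
    chosen = levels[0]
    for lab in levels:
        if lab.max() + 1 >= n_clusters:
            chosen = lab
    labels = chosen.copy()
    labels = _merge_to(W, labels, n_clusters)
    return labels


def _merge_to(W: sp.csr_matrix, labels: np.ndarray, n_clusters: int) -> np.ndarray:
    """Greedily merge the closest pair of groups until exactly C remain."""
    labels = _canonical_labels(labels)
    while labels.max() + 1 > n_clusters:
        agg = _aggregate(W, labels)
        dense = np.asarray(agg.todense())
        iu = np.triu_indices_from(dense, k=1)
        if dense[iu].max() > 0:
            flat = np.argmax(dense[iu])
            a, b = iu[0][flat], iu[1][flat]
        else:  # disconnected: merge the two smallest groups
            counts = np.bincount(labels)
            order = np.lexsort((np.arange(len(counts)), counts))
            a, b = sorted(order[:2])
        labels[labels == b] = a
        labels = _canonical_labels(labels)
    return labels


def bcd_optimize(
    Ls: list[sp.spmatrix],
    labels0: np.ndarray,
    n_clusters: int,
    tol: float = 1e-20,
    min_iter: int = 10,
    max_iter: int = 50,
    max_inner_passes: int = 50,
) -> tuple[np.ndarray, OmicsWeights, OptimizationTrace]:
    """Block coordinate descent over indicator rows and modality weights.

    Each outer iteration recomputes the closed-form weights from the current
    partition, rebuilds the fused Laplacian, and sweeps rows d = 1..S in
    ascending order (repeating the sweep until a pass changes nothing).
    Stops when the relative objective change falls below ``tol`` after the
    first ``min_iter`` iterations, or at ``max_iter``.
    """
    labels = np.asarray(labels0, dtype=int).copy()
    S = len(labels)
    if labels.min() < 0 or labels.max() >= n_clusters:
        raise ValueError("initial labels out of range")
    sizes = np.bincount(labels, minlength=n_clusters)
    if (sizes == 0).any():
        raise ValueError("initial partition has empty clusters")

    trace = OptimizationTrace()
    weights = update_weights(labels_to_indicator(labels, n_clusters), Ls)
    prev_obj = None
    for it in range(max_iter):
        if it > 0:
            weights = update_weights(labels_to_indicator(labels, n_clusters), Ls)
        Lhat = fuse_laplacian(Ls, weights).tocsc()
        changed_total = 0
        for _ in range(max_inner_passes):
            changed = 0
            for d in range(S):
                if update_row(labels, sizes, Lhat, d, n_clusters):
                    changed += 1
            changed_total += changed
            if changed == 0:
                break
        E = labels_to_indicator(labels, n_clusters)
        # reduced objective: Eq-19 value with the weights re-synced to E
        obj = len(Ls) * float(sum(_modality_objective(L, E) for L in Ls))
        trace.objective.append(obj)
        trace.weights.append(weights.omega.copy())
        trace.changed_rows.append(changed_total)
        if prev_obj is not None and it + 1 >= min_iter:
            rel = abs(prev_obj - obj) / max(abs(prev_obj), np.finfo(float).tiny)
            if rel < tol:
                trace.converged = True
                break
        prev_obj = obj

    weights = update_weights(labels_to_indicator(labels, n_clusters), Ls)
    return labels, weights, trace


def expand_labels(supercell_labels: np.ndarray, sc: SupercellAssignment) -> np.ndarray:
    """Map per-supercell cluster labels back to the n cells."""
    supercell_labels = np.asarray(supercell_labels)
    if len(supercell_labels) != sc.n_supercells:
        raise ValueError("label vector length does not match supercell count")
    return supercell_labels[sc.supercell_of]
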