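"""Angle-aware cell similarity and the adaptive γ-nearest-neighbor graph.

Cell–cell similarity is the Pearson correlation of the two cells' feature
vectors — the cosine of the angle between mean-centered profiles. It is
invariant to per-cell affine rescaling, so cells with the same expression
*shape* but different sequencing depth or scale still rank as neighbors.

From the correlation matrix each cell gets an adaptive, row-stochastic
neighborhood: with the top γ+1 correlations of cell *i* (self excluded,
sorted descending) written r_1 ≥ … ≥ r_{γ+1}, neighbor *j* of rank ≤ γ gets

    a_ij = (r_{γ+1} − r_j) / (γ·r_{γ+1} − Σ_{k≤γ} r_k)

and every other entry is 0. Each row is non-negative and sums to one; the
(γ+1)-th neighbor acts as a local reference that scales the weights, in the
style of clustering-with-adaptive-neighbors (CAN) graphs. An ablation mode
replaces the correlation ranking with negative Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io import OmicsMatrix

__all__ = [
    "SimilarityGraph",
    "pearson_matrix",
    "score_matrix",
    "default_gamma",
    "neighbor_order",
    "adaptive_similarity",
]

#: feature-count threshold separating the two default neighborhood sizes
GAMMA_FEATURE_THRESHOLD = 5000


@dataclass
class SimilarityGraph:
    """Row-stochastic γ-NN similarity graph A for one modality.

    ``A`` is sparse n × n with zero diagonal, at most ``gamma`` nonzeros per
    row and unit row sums (up to degenerate rows, see
    :func:`adaptive_similarity`). Kept asymmetric; symmetric quantities
    downstream always use a_ij + a_ji explicitly.
    """

    A: sp.csr_matrix
    gamma: int
    modality: str = "OTHER"

    @property
    def n_cells(self) -> int:
        return self.A.shape[0]


def pearson_matrix(X: OmicsMatrix | np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation between cells (rows).

    Constant cells (zero variance across features) get correlation 0 with
    every cell including themselves, which keeps them rankable without NaNs.
    Non-constant cells have unit diagonal.
    """
    vals = X.dense() if isinstance(X, OmicsMatrix) else np.asarray(X, dtype=float)
    n, m = vals.shape
    if n < 2:
        raise ValueError("need at least two cells")
    if m < 2:
        raise ValueError("need at least two features")
    Z = vals - vals.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Z, axis=1)
    nz = norms > 0
    Z[nz] /= norms[nz, None]
    Z[~nz] = 0.0
    P = Z @ Z.T
    np.clip(P, -1.0, 1.0, out=P)
    return P


def score_matrix(X: OmicsMatrix | np.ndarray, metric: str = "angle") -> np.ndarray:
    """Neighbor-ranking scores: higher means more similar.

    ``"angle"`` gives the Pearson correlation matrix; ``"euclidean"`` (the
    ablation arm) gives negative Euclidean distance, so the CAN-style weight
    formula applied to scores reduces to distance differences.
    """
    if metric == "angle":
        return pearson_matrix(X)
    if metric == "euclidean":
        vals = X.dense() if isinstance(X, OmicsMatrix) else np.asarray(X, dtype=float)
        sq = (vals * vals).sum(axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (vals @ vals.T)
        np.maximum(d2, 0.0, out=d2)
        return -np.sqrt(d2)
    raise ValueError(f"unknown metric {metric!r}")


def default_gamma(feature_counts: list[int] | tuple[int, ...]) -> int:
    """Default neighborhood size from the modalities' feature counts.

    10 when the widest modality has fewer than 5000 features, else 20.
    Feature counts are the original (pre-selection) dimensionalities.
    """
    if len(feature_counts) == 0:
        raise ValueError("empty feature count list")
    return 10 if max(feature_counts) < GAMMA_FEATURE_THRESHOLD else 20


def neighbor_order(scores: np.ndarray, k: int | None = None) -> np.ndarray:
    """Per-row neighbor ranking by descending score, self excluded.

    Ties resolve to the smaller cell index (stable sort). Returns the first
    ``k`` columns of the full ordering (all n−1 if ``k`` is None).
    """
    S = np.array(scores, dtype=float)
    np.fill_diagonal(S, -np.inf)
    order = np.argsort(-S, axis=1, kind="stable")
    ncol = S.shape[0] - 1 if k is None else min(k, S.shape[0] - 1)
    return order[:, :ncol]


def adaptive_similarity(
    P: np.ndarray,
    gamma: int,
    order: np.ndarray | None = None,
    modality: str = "OTHER",
) -> SimilarityGraph:
    """Row-stochastic adaptive weights from the top γ+1 neighbors of each cell.

    ``P`` holds ranking scores (correlations, or negative distances in the
    ablation arm). If the γ+1 top scores of a row are all equal the weight
    formula degenerates to 0/0; that row falls back to uniform weights 1/γ,
    the limiting value.
    """
    n = P.shape[0]
    if gamma + 1 > n - 1:
        raise ValueError(f"gamma+1={gamma + 1} exceeds n-1={n - 1} available neighbors")
    if order is None:
        order = neighbor_order(P, gamma + 1)
    top = order[:, : gamma + 1]
    svals = np.take_along_axis(P, top, axis=1)  # descending per row
    ref = svals[:, gamma]  # (γ+1)-th best score
    denom = gamma * ref - svals[:, :gamma].sum(axis=1)
    weights = np.empty((n, gamma), dtype=float)
    degen = np.abs(denom) < 1e-12
    ok = ~degen
    weights[ok] = (ref[ok, None] - svals[ok, :gamma]) / denom[ok, None]
    weights[degen] = 1.0 / gamma
    np.maximum(weights, 0.0, out=weights)

    rows = np.repeat(np.arange(n), gamma)
    cols = top[:, :gamma].ravel()
    A = sp.csr_matrix((weights.ravel(), (rows, cols)), shape=(n, n))
    return SimilarityGraph(A=A, gamma=gamma, modality=modality)
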