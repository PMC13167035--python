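"""Adaptive estimation of the cluster number C.

Each modality is scanned with k-means over a range of candidate C values
and the within-cluster sum of squared errors (SSE). The elbow statistic at
candidate C is the ratio of the SSE drop entering C to the drop leaving it,

    r(C) = (SSE_C − SSE_{C−1}) / (SSE_{C+1} − SSE_C),

which peaks where the marginal benefit of an extra cluster collapses. Two
conventions are exposed: ``"ratio-only"`` returns the argmax itself (the
default — on clean data the peak sits exactly at the true cluster count),
while ``"plus-one"`` adds an offset of one to the argmax.

When the per-modality estimates agree, their consensus is final and the
fused similarity matrix is never consulted. When they disagree, the row
space of the fused high-order similarity Ã = (1/V) Σ_v (A(v)+A(v)ᵀ)/2 is
scanned the same way, and the final C is a weighted round of all estimates
with the fused term carrying the largest share (weights 2/9, 3/9, 4/9 for a
two-modality dataset).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.cluster import KMeans

from .io import MultiOmicsDataset, OmicsMatrix
from .similarity import SimilarityGraph, adaptive_similarity, default_gamma, score_matrix

__all__ = [
    "ClusterNumberEstimate",
    "kmeans_sse",
    "elbow_from_sse",
    "elbow_estimate",
    "fused_matrix",
    "estimate_clusters",
]

#: k-means restarts per candidate C
KMEANS_RESTARTS = 10
#: cells subsampled (seeded) for the SSE scans on large datasets
MAX_ELBOW_CELLS = 2000


@dataclass
class ClusterNumberEstimate:
    """Per-modality, fused and final cluster-number estimates."""

    per_modality: list[int]
    fused: int | None  # None when the consensus branch fired
    weights: np.ndarray | None
    final: int


def kmeans_sse(X: np.ndarray, n_clusters: int, seed: int = 0) -> float:
    """Best within-cluster SSE of seeded multi-restart k-means."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters={n_clusters} outside [1, {n}]")
    if n_clusters == n:
        return 0.0  # every point its own center
    km = KMeans(n_clusters=n_clusters, n_init=KMEANS_RESTARTS, random_state=seed)
    km.fit(X)
    return float(km.inertia_)


def elbow_from_sse(
    sse: dict[int, float], cmin: int, cmax: int, convention: str = "ratio-only"
) -> int:
    """Elbow location from a precomputed SSE curve.

    ``sse`` must cover C = cmin−1 .. cmax+1. Candidates whose trailing SSE
    drop is zero (flat tail) are skipped. Returns the argmax of the drop
    ratio, plus one under the ``"plus-one"`` convention.
    """
    if convention not in ("ratio-only", "plus-one"):
        raise ValueError(f"unknown convention {convention!r}")
    best_c, best_r = None, -np.inf
    for c in range(cmin, cmax + 1):
        denom = sse[c + 1] - sse[c]
        if denom == 0.0:
            continue  # flat tail: ratio undefined, candidate skipped
        r = (sse[c] - sse[c - 1]) / denom
        if r > best_r:
            best_c, best_r = c, r
    if best_c is None:
        raise ValueError("all candidate ratios had zero denominators")
    return best_c + 1 if convention == "plus-one" else best_c


def _scan_range(n: int, cmin: int | None, cmax: int | None) -> tuple[int, int]:
    lo = 2 if cmin is None else cmin
    hi = min(20, int(np.sqrt(n))) if cmax is None else cmax
    hi = min(hi, n - 1)
    hi = max(hi, lo)
    return lo, hi


def elbow_estimate(
    X: np.ndarray,
    cmin: int | None = None,
    cmax: int | None = None,
    seed: int = 0,
    convention: str = "ratio-only",
) -> int:
    """Elbow-based cluster-number estimate for one feature matrix.

    Scans C ∈ [cmin, cmax] (default [2, min(20, ⌊√n⌋)]); datasets larger
    than ``MAX_ELBOW_CELLS`` are subsampled with the given seed, since the
    SSE curve's shape is stable in the sample size. The result is clamped
    to [2, cmax].
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n > MAX_ELBOW_CELLS:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(n, MAX_ELBOW_CELLS, replace=False)]
        n = MAX_ELBOW_CELLS
    lo, hi = _scan_range(n, cmin, cmax)
    if lo < 2:
        raise ValueError("cmin must be >= 2")
    sse = {c: kmeans_sse(X, c, seed=seed) for c in range(lo - 1, hi + 2)}
    est = elbow_from_sse(sse, lo, hi, convention=convention)
    return int(np.clip(est, 2, hi))


def fused_matrix(graphs: list[SimilarityGraph]) -> np.ndarray:
    """Fused high-order multi-view similarity Ã = (1/V) Σ_v (A(v)+A(v)ᵀ)/2.

    Rows of Ã serve as feature vectors for the fused elbow scan.
    """
    if not graphs:
        raise ValueError("empty graph list")
    acc = None
    for g in graphs:
        sym = (g.A + g.A.T) * 0.5
        acc = sym if acc is None else acc + sym
    acc = acc / len(graphs)
    return np.asarray(acc.todense(), dtype=float)


def _fusion_weights(V: int) -> np.ndarray:
    """Modality weights proportional to (2, 3, …, V+1) in input order, the
    fused term at V+2 (always the largest share), normalized to sum 1.
    Reproduces (2/9, 3/9, 4/9) for two modalities."""
    raw = np.array(list(range(2, V + 2)) + [V + 2], dtype=float)
    return raw / raw.sum()


def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def estimate_clusters(
    ds: MultiOmicsDataset,
    seed: int = 0,
    cmin: int | None = None,
    cmax: int | None = None,
    gamma: int | None = None,
    convention: str = "ratio-only",
    graphs: list[SimilarityGraph] | None = None,
) -> ClusterNumberEstimate:
    """Consensus / weighted-fusion estimate of the cluster number.

    Per-modality elbow estimates that all agree are adopted as-is (the
    fused matrix is never computed in that branch). Otherwise the fused
    similarity's row space is scanned too and the final C is the weighted
    round of all estimates. Pass precomputed ``graphs`` to reuse the
    pipeline's similarity graphs for Ã.
    """
    per_mod = [
        elbow_estimate(X.dense(), cmin=cmin, cmax=cmax, seed=seed, convention=convention)
        for X in ds.modalities
    ]
    if len(set(per_mod)) == 1:
        return ClusterNumberEstimate(per_mod, None, None, per_mod[0])

    if graphs is None:
        if gamma is None:
            gamma = default_gamma(ds.feature_counts())
        graphs = [
            adaptive_similarity(score_matrix(X), gamma, modality=X.modality)
            for X in ds.modalities
        ]
    At = fused_matrix(graphs)
    fused_c = elbow_estimate(At, cmin=cmin, cmax=cmax, seed=seed, convention=convention)
    w = _fusion_weights(len(per_mod))
    final = _round_half_away(float(np.dot(w, per_mod + [fused_c])))
    final = max(final, 2)
    return ClusterNumberEstimate(per_mod, fused_c, w, final)
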