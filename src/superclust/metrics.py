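"""Clustering agreement metrics, supercell pruning recall, and marker tests.

Partition agreement is measured from the contingency table n_ij between
truth classes and predicted clusters: the adjusted Rand index (pair counting
corrected for chance), normalized mutual information with sum-of-entropies
normalization, raw pair-counting metrics (Rand index, precision, recall,
F1), and matching-based metrics (accuracy via optimal one-to-one cluster
assignment, purity).

Pruning quality is summarized by the mean per-supercell recall of
mislabelled cells, Recall_sc = (1/S) Σ_s TP_s/(TP_s+FN_s), where TP_s counts
the mislabelled cells pruning removed from supercell s and FN_s those it
left behind.

Markers are detected per cluster with one-sided Welch t-tests (H0: the
cluster mean is ≤ the rest; unequal variances, Welch–Satterthwaite degrees
of freedom), Benjamini–Hochberg correction across the cluster's features,
and a log2 fold change log2((x̄_cluster+ε)/(x̄_rest+ε)) with ε = 1e−6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .io import OmicsMatrix
from .supercells import SupercellAssignment

__all__ = [
    "contingency",
    "ari",
    "nmi",
    "pair_metrics",
    "matching_metrics",
    "SupercellConfusion",
    "recall_sc",
    "welch_markers",
    "supercell_ablation_report",
    "clustering_report",
]

LOG2FC_EPSILON = 1e-6
DEFAULT_P_THRESHOLD = 0.05
DEFAULT_LFC_THRESHOLD = 0.25


def contingency(truth, pred) -> np.ndarray:
    """Contingency table n_ij over (truth class i, predicted cluster j)."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ValueError("label vectors differ in length")
    _, ti = np.unique(truth, return_inverse=True)
    _, pi = np.unique(pred, return_inverse=True)
    table = np.zeros((ti.max() + 1, pi.max() + 1), dtype=np.int64)
    np.add.at(table, (ti, pi), 1)
    return table


def _comb2(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    return x * (x - 1) / 2.0


def ari(truth, pred) -> float:
    """Adjusted Rand index in [−1, 1]; 1 for identical partitions."""
    table = contingency(truth, pred)
    n = table.sum()
    if n < 2:
        raise ValueError("need at least two samples")
    a = table.sum(axis=1)
    b = table.sum(axis=0)
    sum_ij = _comb2(table).sum()
    sum_a = _comb2(a).sum()
    sum_b = _comb2(b).sum()
    expected = sum_a * sum_b / _comb2(np.array([n]))[0]
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def nmi(truth, pred) -> float:
    """Normalized mutual information, 2·MI / (H_truth + H_pred), in [0, 1].

    0·log 0 terms are 0; if both partitions carry no information they are
    necessarily identical single-cluster partitions and the value is 1.
    """
    table = contingency(truth, pred).astype(float)
    n = table.sum()
    if n < 1:
        raise ValueError("empty label vectors")
    a = table.sum(axis=1)
    b = table.sum(axis=0)
    nz = table > 0
    outer = np.outer(a, b)
    mi_terms = np.zeros_like(table)
    mi_terms[nz] = table[nz] * np.log(n * table[nz] / outer[nz])
    num = 2.0 * mi_terms.sum()
    h_t = -np.sum(a * np.log(a / n))
    h_p = -np.sum(b * np.log(b / n))
    denom = h_t + h_p
    if denom <= 0:
        return 1.0
    return float(max(0.0, min(1.0, num / denom)))


def pair_metrics(truth, pred) -> dict[str, float]:
    """Pair-counting Rand index, precision, recall and F1.

    A pair of samples is a positive when co-clustered; predicted positives
    come from the prediction, actual positives from the truth. 0/0 ratios
    are reported as 0.
    """
    table = contingency(truth, pred)
    n = table.sum()
    total = _comb2(np.array([n]))[0]
    tp = _comb2(table).sum()
    pp = _comb2(table.sum(axis=0)).sum()  # predicted positive pairs
    ap = _comb2(table.sum(axis=1)).sum()  # actual positive pairs
    tn = total - pp - ap + tp
    precision = tp / pp if pp > 0 else 0.0
    recall = tp / ap if ap > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    ri = (tp + tn) / total if total > 0 else 0.0
    return {"RI": float(ri), "precision": float(precision), "recall": float(recall), "F1": float(f1)}


def matching_metrics(truth, pred) -> dict[str, float]:
    """Accuracy under optimal one-to-one cluster/class matching, and purity.

    ACC uses maximum-weight rectangular bipartite matching on the
    contingency table (unmatched clusters contribute nothing); purity maps
    every predicted cluster to its majority class.
    """
    table = contingency(truth, pred)
    n = table.sum()
    ri, ci = linear_sum_assignment(table, maximize=True)
    acc = table[ri, ci].sum() / n
    purity = table.max(axis=0).sum() / n
    return {"ACC": float(acc), "purity": float(purity)}


@dataclass
class SupercellConfusion:
    """Pruning confusion counts for one supercell.

    TP: mislabelled (minority-label) cells removed by pruning; FN:
    mislabelled cells retained; FP / TN: majority-label cells removed /
    retained.
    """

    supercell: int
    TP: int
    FN: int
    FP: int = 0
    TN: int = 0


def recall_sc(confusions: list[SupercellConfusion]) -> float:
    """Mean per-supercell recall of mislabelled cells, in [0, 1].

    Supercells with no mislabelled cells (TP + FN = 0) carry no signal and
    are excluded from the average.
    """
    if not confusions:
        raise ValueError("empty confusion list")
    ratios = [c.TP / (c.TP + c.FN) for c in confusions if c.TP + c.FN > 0]
    if not ratios:
        raise ValueError("no supercell has TP + FN > 0")
    return float(np.mean(ratios))


def welch_markers(
    X: OmicsMatrix | np.ndarray,
    labels,
    target,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    epsilon: float = LOG2FC_EPSILON,
) -> pd.DataFrame:
    """One-sided Welch marker test of a target cluster against the rest.

    Per feature: Welch's unequal-variance t statistic with
    Welch–Satterthwaite degrees of freedom, one-sided p for up-regulation in
    the target, BH-adjusted p across the cluster's features, and the log2
    fold change of the two group means. The pass flag requires p <
    ``p_threshold`` and log2FC > ``lfc_threshold``; features higher in the
    rest are retained with a False flag rather than dropped, so the table
    stays auditable. Features with zero variance in both groups get p = 0.5
    when the means agree and the 0/1 limit otherwise.
    """
    if isinstance(X, OmicsMatrix):
        vals = X.dense()
        feat_ids = X.feature_ids
    else:
        vals = np.asarray(X, dtype=float)
        feat_ids = [f"feat{j}" for j in range(vals.shape[1])]
    labels = np.asarray(labels)
    mask = labels == target
    n1, n2 = int(mask.sum()), int((~mask).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("target cluster and its complement each need >= 2 cells")

    g1, g2 = vals[mask], vals[~mask]
    m1, m2 = g1.mean(axis=0), g2.mean(axis=0)
    v1 = g1.var(axis=0, ddof=1)
    v2 = g2.var(axis=0, ddof=1)
    se2 = v1 / n1 + v2 / n2

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        pvals = t_dist.sf(tstat, df)

    degenerate = se2 == 0
    if degenerate.any():
        eq = degenerate & (m1 == m2)
        up = degenerate & (m1 > m2)
        dn = degenerate & (m1 < m2)
        pvals[eq], tstat[eq] = 0.5, 0.0
        pvals[up], tstat[up] = 0.0, np.inf
        pvals[dn], tstat[dn] = 1.0, -np.inf

    p_adj = multipletests(pvals, method="fdr_bh")[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(m1 + epsilon) - np.log2(m2 + epsilon)
    passed = (pvals < p_threshold) & (lfc > lfc_threshold)

    return pd.DataFrame(
        {
            "feature": feat_ids,
            "cluster": target,
            "t": tstat,
            "p": pvals,
            "p_adj": p_adj,
            "log2FC": lfc,
            "passed": passed,
        }
    )


def supercell_ablation_report(
    truth, sc: SupercellAssignment, min_size: int = 3
) -> list[SupercellConfusion]:
    """Pruning confusion counts for every mixed-label supercell candidate.

    Operates on the pre-pruning components recorded in ``sc.records``: for
    each component of at least ``min_size`` cells spanning two or more
    ground-truth labels, the majority label is the most frequent (ties to
    the lexicographically smaller label) and the counts split by
    (minority/majority) × (removed/retained).
    """
    if sc.records is None:
        raise ValueError("supercell assignment carries no pruning records")
    truth = np.asarray(truth)
    out: list[SupercellConfusion] = []
    for comp_id, grp in sc.records.groupby("component"):
        cells = grp["cell"].to_numpy()
        if len(cells) < min_size:
            continue
        labs = truth[cells]
        uniq, counts = np.unique(labs, return_counts=True)
        if len(uniq) < 2:
            continue
        majority = uniq[np.lexsort((uniq, -counts))][0]
        removed = grp["removed"].to_numpy()
        minority = labs != majority
        out.append(
            SupercellConfusion(
                supercell=int(comp_id),
                TP=int((minority & removed).sum()),
                FN=int((minority & ~removed).sum()),
                FP=int((~minority & removed).sum()),
                TN=int((~minority & ~removed).sum()),
            )
        )
    return out


def clustering_report(truth, pred) -> dict[str, float]:
    """All agreement metrics in one flat dict (ARI, NMI, ACC, purity, RI,
    precision, recall, F1)."""
    rep = {"ARI": ari(truth, pred), "NMI": nmi(truth, pred)}
    rep.update(matching_metrics(truth, pred))
    rep.update(pair_metrics(truth, pred))
    return rep
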