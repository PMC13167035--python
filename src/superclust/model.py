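"""Model / results interface for the full two-stage clustering pipeline.

:class:`MultiOmicsClustering` is constructed from a
:class:`~superclust.io.MultiOmicsDataset` (or from files) together with the
pipeline hyperparameters; :meth:`MultiOmicsClustering.fit` runs

    validate → variance selection → per-modality similarity graphs →
    second-order co-occurrence → consistency fusion → supercells (pruned) →
    supercell Laplacians → (cluster-number estimation if not given) →
    FINCH initialization → block coordinate descent → per-cell labels

and returns a :class:`ClusteringResults` carrying the labels, the supercell
assignment and pruning audit, the learned modality weights, the
optimization trace, and reporting helpers (``summary()``, ``evaluate()``,
``markers()``, ``save()``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as _io
from .cluster_number import ClusterNumberEstimate, estimate_clusters
from .coarse import (
    CoarseGraph,
    OmicsWeights,
    OptimizationTrace,
    bcd_optimize,
    expand_labels,
    finch_init,
    laplacian,
    supercell_similarity,
)
from .io import MultiOmicsDataset, OmicsMatrix, select_top_variance_features, validate_dataset
from .metrics import clustering_report, welch_markers
from .similarity import default_gamma
from .supercells import DEFAULT_ALPHA, DEFAULT_BETA, SupercellAssignment, build_supercells

__all__ = ["MultiOmicsClustering", "ClusteringResults"]


class MultiOmicsClustering:
    """Supercell-based multi-omics clustering model.

    Parameters
    ----------
    dataset
        Multi-omics dataset; modalities are realigned to a shared cell
        order on construction.
    n_clusters
        Number of clusters C, or None to estimate it adaptively.
    gamma
        Similarity-graph neighborhood size; None selects 10 or 20 from the
        widest modality's (original) feature count.
    alpha, beta
        Second-order co-occurrence neighborhood size and shared-neighbor
        threshold.
    metric
        ``"angle"`` (Pearson correlation, default) or ``"euclidean"``
        (ablation arm).
    pruning
        ``"on"`` (single seeded pass, default), ``"off"``, or
        ``"iterative"``.
    second_order
        ``"mutual"`` (default) or ``"one-directional"``.
    var_trigger, var_keep
        Variance-based feature selection: modalities with at least
        ``var_trigger`` features keep their ``var_keep`` most variable ones.
    log1p
        Apply log1p to the matrices before anything else (off by default).
    tol, min_iter, max_iter
        BCD stopping rule: relative objective change below ``tol`` after the
        first ``min_iter`` iterations, or ``max_iter``.
    elbow_convention
        ``"ratio-only"`` (default) or ``"plus-one"`` for cluster-number
        estimation.
    """

    def __init__(
        self,
        dataset: MultiOmicsDataset,
        n_clusters: int | None = None,
        gamma: int | None = None,
        alpha: int = DEFAULT_ALPHA,
        beta: int = DEFAULT_BETA,
        metric: str = "angle",
        pruning: str = "on",
        second_order: str = "mutual",
        var_trigger: int = _io.VAR_SELECT_TRIGGER,
        var_keep: int = _io.VAR_SELECT_KEEP,
        log1p: bool = False,
        tol: float = 1e-20,
        min_iter: int = 10,
        max_iter: int = 50,
        elbow_convention: str = "ratio-only",
    ) -> None:
        if alpha < beta or beta < 1:
            raise ValueError("require alpha >= beta >= 1")
        if log1p:
            dataset = MultiOmicsDataset(
                [
                    OmicsMatrix(np.log1p(X.dense()), X.modality, X.cell_ids, X.feature_ids)
                    for X in dataset.modalities
                ],
                labels=dataset.labels,
            )
        self.dataset = validate_dataset(dataset)
        self.n_clusters = n_clusters
        self.gamma = gamma
        self.alpha = alpha
        self.beta = beta
        self.metric = metric
        self.pruning = pruning
        self.second_order = second_order
        self.var_trigger = var_trigger
        self.var_keep = var_keep
        self.tol = tol
        self.min_iter = min_iter
        self.max_iter = max_iter
        self.elbow_convention = elbow_convention

    @classmethod
    def from_files(
        cls,
        paths: list[str],
        formats: list[str] | str = "delimited",
        orientations: list[str] | str = "cells-by-features",
        modalities: list[str] | None = None,
        labels_path: str | None = None,
        **kwargs,
    ) -> "MultiOmicsClustering":
        """Build the model straight from on-disk matrices (one per modality)."""
        V = len(paths)
        formats = [formats] * V if isinstance(formats, str) else formats
        orientations = [orientations] * V if isinstance(orientations, str) else orientations
        modalities = modalities or ["OTHER"] * V
        mats = [
            _io.load_matrix(p, format=f, orientation=o, modality=m)
            for p, f, o, m in zip(paths, formats, orientations, modalities)
        ]
        labels = None
        if labels_path is not None:
            labels = _io.load_labels(labels_path, mats[0].cell_ids)
        return cls(MultiOmicsDataset(mats, labels=labels), **kwargs)

    def fit(self, seed: int = 0) -> "ClusteringResults":
        """Run the full pipeline; deterministic given the seed."""
        ds = self.dataset
        gamma = self.gamma if self.gamma is not None else default_gamma(ds.feature_counts())

        sc, graphs, M = build_supercells(
            ds,
            alpha=self.alpha,
            beta=self.beta,
            gamma=gamma,
            seed=seed,
            metric=self.metric,
            pruning=self.pruning,
            second_order=self.second_order,
            var_trigger=self.var_trigger,
            var_keep=self.var_keep,
            return_graphs=True,
        )

        coarse = []
        for g in graphs:
            AS = supercell_similarity(g, sc)
            coarse.append(CoarseGraph(AS=AS, L=laplacian(AS), modality=g.modality))
        Ls = [c.L for c in coarse]

        estimate: ClusterNumberEstimate | None = None
        if self.n_clusters is None:
            selected = MultiOmicsDataset(
                [
                    select_top_variance_features(X, self.var_trigger, self.var_keep)
                    for X in ds.modalities
                ],
                labels=ds.labels,
            )
            estimate = estimate_clusters(
                selected,
                seed=seed,
                convention=self.elbow_convention,
                graphs=graphs,
            )
            C = estimate.final
        else:
            C = int(self.n_clusters)

        AS_fused = coarse[0].AS.copy()
        for c in coarse[1:]:
            AS_fused = AS_fused + c.AS
        labels0 = finch_init(AS_fused, C)
        sc_labels, weights, trace = bcd_optimize(
            Ls, labels0, C, tol=self.tol, min_iter=self.min_iter, max_iter=self.max_iter
        )
        cell_labels = expand_labels(sc_labels, sc)

        return ClusteringResults(
            model=self,
            seed=seed,
            gamma=gamma,
            n_clusters=C,
            labels=cell_labels,
            supercell_labels=sc_labels,
            supercells=sc,
            coarse=coarse,
            weights=weights,
            trace=trace,
            cluster_estimate=estimate,
        )


@dataclass
class ClusteringResults:
    """Fitted clustering: labels, supercells, learned weights, diagnostics."""

    model: MultiOmicsClustering
    seed: int
    gamma: int
    n_clusters: int
    labels: np.ndarray
    supercell_labels: np.ndarray
    supercells: SupercellAssignment
    coarse: list[CoarseGraph]
    weights: OmicsWeights
    trace: OptimizationTrace
    cluster_estimate: ClusterNumberEstimate | None = None
    metrics: dict[str, float] | None = field(default=None, init=True)

    @property
    def n_cells(self) -> int:
        return len(self.labels)

    @property
    def n_supercells(self) -> int:
        return self.supercells.n_supercells

    def evaluate(self, truth=None) -> dict[str, float]:
        """Agreement metrics against ground truth (defaults to the dataset's
        stored labels)."""
        if truth is None:
            truth = self.model.dataset.labels
        if truth is None:
            raise ValueError("no ground-truth labels available")
        self.metrics = clustering_report(truth, self.labels)
        return self.metrics

    def markers(self, modality_index: int, cluster: int, **kwargs) -> pd.DataFrame:
        """Welch one-sided marker table for one cluster in one modality."""
        X = self.model.dataset.modalities[modality_index]
        return welch_markers(X, self.labels, cluster, **kwargs)

    def summary(self) -> str:
        """Human-readable fit summary."""
        m = self.model
        ds = m.dataset
        lines = [
            "Supercell multi-omics clustering",
            "=" * 48,
            f"cells                 {ds.n_cells}",
            f"modalities            {ds.n_modalities} "
            + str([f"{x.modality}({x.n_features})" for x in ds.modalities]),
            f"metric / pruning      {m.metric} / {m.pruning}",
            f"gamma / alpha / beta  {self.gamma} / {m.alpha} / {m.beta}",
            f"supercells S          {self.n_supercells}",
            f"pruned cells          {int(self.supercells.records['removed'].sum())}",
            f"clusters C            {self.n_clusters}"
            + ("  (estimated)" if self.cluster_estimate is not None else "  (given)"),
        ]
        if self.cluster_estimate is not None:
            e = self.cluster_estimate
            lines.append(f"  per-modality C      {e.per_modality}  fused {e.fused}")
        om = ", ".join(f"{w:.4g}" for w in self.weights.omega)
        lines += [
            f"modality weights      [{om}]",
            f"BCD iterations        {self.trace.n_iterations} "
            + ("(converged)" if self.trace.converged else "(max iterations)"),
            f"final objective       {self.trace.objective[-1]:.6g}",
        ]
        if self.metrics:
            lines.append("metrics               " + json.dumps(self.metrics, default=float))
        counts = np.bincount(self.labels, minlength=self.n_clusters)
        lines.append("cluster sizes         " + str(counts.tolist()))
        return "\n".join(lines)

    def save(self, outdir: str) -> None:
        """Write labels, supercells, pruning audit, weights, trace, metrics
        and a provenance record under ``outdir``."""
        import os

        os.makedirs(outdir, exist_ok=True)
        ds = self.model.dataset
        cells = ds.cell_ids
        pd.DataFrame({"cell_id": cells, "cluster": self.labels}).to_csv(
            os.path.join(outdir, "labels.tsv"), sep="\t", index=False
        )
        pd.DataFrame(
            {"cell_id": cells, "supercell_id": self.supercells.supercell_of}
        ).to_csv(os.path.join(outdir, "supercells.tsv"), sep="\t", index=False)
        rec = self.supercells.records.copy()
        rec.insert(0, "cell_id", [cells[i] for i in rec["cell"]])
        rec.to_csv(os.path.join(outdir, "pruning.tsv"), sep="\t", index=False)
        with open(os.path.join(outdir, "weights.txt"), "w") as fh:
            for c, om, ep in zip(self.coarse, self.weights.omega, self.weights.epsilon):
                fh.write(f"{c.modality}\tomega={om:.10g}\tepsilon={ep:.10g}\n")
        pd.DataFrame(
            {
                "iteration": np.arange(1, self.trace.n_iterations + 1),
                "objective": self.trace.objective,
                "changed_rows": self.trace.changed_rows,
            }
        ).to_csv(os.path.join(outdir, "trace.tsv"), sep="\t", index=False)
        if ds.labels is not None:
            metrics = self.evaluate()
            with open(os.path.join(outdir, "metrics.json"), "w") as fh:
                json.dump(metrics, fh, indent=2)
        prov = {
            "seed": self.seed,
            "gamma": self.gamma,
            "alpha": self.model.alpha,
            "beta": self.model.beta,
            "metric": self.model.metric,
            "pruning": self.model.pruning,
            "second_order": self.model.second_order,
            "n_clusters": self.n_clusters,
            "n_supercells": self.n_supercells,
        }
        with open(os.path.join(outdir, "provenance.json"), "w") as fh:
            json.dump(prov, fh, indent=2)
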