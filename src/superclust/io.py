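"""Loading, validation and preprocessing of per-modality cell × feature matrices.

A multi-omics experiment is a collection of ``V`` matrices that profile the
same ``n`` cells with modality-specific feature spaces: RNA expression, ADT
surface-protein abundance, ATAC accessibility, or anything else that comes as
a numeric cell × feature table. Two on-disk layouts are supported:

* a MatrixMarket "trio": the ``.mtx`` matrix plus two plain-text companion
  files listing cell barcodes and feature names (one per line);
* a delimited table (CSV/TSV) with a header row of feature IDs and a first
  column of cell IDs.

High-dimensional modalities are reduced to their most variable features
before any similarity computation (see :func:`select_top_variance_features`).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "OmicsMatrix",
    "MultiOmicsDataset",
    "load_matrix",
    "write_matrix",
    "load_labels",
    "select_top_variance_features",
    "validate_dataset",
]

MODALITY_TAGS = ("RNA", "ADT", "ATAC", "OTHER")

#: feature count at which variance-based selection kicks in
VAR_SELECT_TRIGGER = 5000
#: number of highest-variance features retained once triggered
VAR_SELECT_KEEP = 125


@dataclass
class OmicsMatrix:
    """One modality's cell × feature matrix with row/column identifiers.

    ``values`` may be dense ``ndarray`` or any scipy sparse matrix; rows are
    cells, columns are features. IDs must be unique and match the matrix
    shape. No NaNs are allowed.
    """

    values: np.ndarray | sp.spmatrix
    modality: str = "OTHER"
    cell_ids: list[str] = field(default_factory=list)
    feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.modality not in MODALITY_TAGS:
            raise ValueError(f"modality must be one of {MODALITY_TAGS}, got {self.modality!r}")
        n, m = self.values.shape
        if not self.cell_ids:
            self.cell_ids = [f"cell{i}" for i in range(n)]
        if not self.feature_ids:
            self.feature_ids = [f"feat{j}" for j in range(m)]
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell IDs for {n} rows")
        if len(self.feature_ids) != m:
            raise ValueError(f"{len(self.feature_ids)} feature IDs for {m} columns")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell IDs")
        if len(set(self.feature_ids)) != m:
            raise ValueError("duplicate feature IDs")
        dat = self.values.data if sp.issparse(self.values) else self.values
        if not np.isfinite(np.asarray(dat, dtype=float)).all():
            raise ValueError("matrix contains NaN or infinite entries")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        """Return the values as a dense float array (copying if sparse)."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)


@dataclass
class MultiOmicsDataset:
    """Ordered collection of modalities profiling the same cells.

    All modalities must list identical ``cell_ids`` in identical order (use
    :func:`validate_dataset` to realign permuted modalities). ``labels`` is an
    optional ground-truth cluster assignment per cell, aligned to the shared
    cell order.
    """

    modalities: list[OmicsMatrix]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.modalities) < 1:
            raise ValueError("need at least one modality")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.modalities[0].n_cells:
                raise ValueError("labels length does not match cell count")

    @property
    def n_cells(self) -> int:
        return self.modalities[0].n_cells

    @property
    def n_modalities(self) -> int:
        return len(self.modalities)

    @property
    def cell_ids(self) -> list[str]:
        return self.modalities[0].cell_ids

    def feature_counts(self) -> list[int]:
        return [m.n_features for m in self.modalities]


def _delimiter_for(path: str) -> str:
    return "\t" if os.path.splitext(path)[1].lower() in {".tsv", ".txt", ".tab"} else ","


def load_matrix(
    path: str,
    format: str = "delimited",
    orientation: str = "cells-by-features",
    modality: str = "OTHER",
    cells_path: str | None = None,
    features_path: str | None = None,
) -> OmicsMatrix:
    """Read one modality from disk into cells × features orientation.

    ``format`` is ``"mtx-trio"`` (MatrixMarket matrix + ID companions) or
    ``"delimited"`` (CSV/TSV, dialect chosen by extension; header = feature
    IDs, first column = cell IDs). ``orientation`` describes the file; a
    features-by-cells file is transposed on load. Sparse input stays sparse.
    """
    if orientation not in ("cells-by-features", "features-by-cells"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)

    if format == "mtx-trio":
        if cells_path is None:
            cells_path = _sibling(path, ("barcodes.tsv", "cells.tsv", "barcodes.txt"))
        if features_path is None:
            features_path = _sibling(path, ("features.tsv", "genes.tsv", "features.txt"))
        values = mmread(path)
        if sp.issparse(values):
            values = values.tocsr()
        else:
            values = np.asarray(values)
        with open(cells_path) as fh:
            cell_ids = [line.split("\t")[0].strip() for line in fh if line.strip()]
        with open(features_path) as fh:
            feature_ids = [line.split("\t")[0].strip() for line in fh if line.strip()]
        if orientation == "features-by-cells":
            values = values.T
            if sp.issparse(values):
                values = values.tocsr()
        if values.shape[0] != len(cell_ids) or values.shape[1] != len(feature_ids):
            raise ValueError(
                f"matrix shape {values.shape} does not match "
                f"{len(cell_ids)} cell IDs x {len(feature_ids)} feature IDs"
            )
        return OmicsMatrix(values, modality, cell_ids, feature_ids)

    if format == "delimited":
        df = pd.read_csv(path, sep=_delimiter_for(path), index_col=0)
        if orientation == "features-by-cells":
            df = df.T
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError(f"non-numeric or missing entries in {path}")
        return OmicsMatrix(values, modality, [str(c) for c in df.index], [str(f) for f in df.columns])

    raise ValueError(f"unknown format {format!r}")


def _sibling(path: str, candidates: Sequence[str]) -> str:
    d = os.path.dirname(path)
    for name in candidates:
        p = os.path.join(d, name)
        if os.path.exists(p):
            return p
    raise FileNotFoundError(f"no companion file among {candidates} next to {path}")


def write_matrix(X: OmicsMatrix, path: str, format: str = "delimited") -> None:
    """Write a modality back to disk in either supported layout."""
    if format == "mtx-trio":
        vals = X.values if sp.issparse(X.values) else sp.coo_matrix(X.values)
        mmwrite(path, vals)
        d = os.path.dirname(path)
        with open(os.path.join(d, "barcodes.tsv"), "w") as fh:
            fh.write("\n".join(X.cell_ids) + "\n")
        with open(os.path.join(d, "features.tsv"), "w") as fh:
            fh.write("\n".join(X.feature_ids) + "\n")
    elif format == "delimited":
        df = pd.DataFrame(X.dense(), index=X.cell_ids, columns=X.feature_ids)
        df.to_csv(path, sep=_delimiter_for(path))
    else:
        raise ValueError(f"unknown format {format!r}")


def load_labels(path: str, cell_ids: Sequence[str]) -> np.ndarray:
    """Read a two-column (cell_id, label) TSV and align it to ``cell_ids``."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "label"], dtype=str)
    mapping = dict(zip(df["cell_id"], df["label"]))
    missing = [c for c in cell_ids if c not in mapping]
    if missing:
        raise ValueError(f"{len(missing)} cells have no label (first: {missing[0]!r})")
    return np.array([mapping[c] for c in cell_ids])


def select_top_variance_features(
    X: OmicsMatrix,
    trigger: int = VAR_SELECT_TRIGGER,
    keep: int = VAR_SELECT_KEEP,
) -> OmicsMatrix:
    """Retain the ``keep`` highest-variance features of a wide modality.

    Applies only when the modality has at least ``trigger`` features;
    narrower matrices pass through unchanged. Variance is the unbiased
    sample estimator; ties are broken in favour of earlier columns, and the
    surviving columns keep their original order. Idempotent for fixed
    parameters.
    """
    if keep < 1:
        raise ValueError("keep must be >= 1")
    if X.n_features < trigger:
        return X
    if keep > X.n_features:
        raise ValueError(f"keep={keep} exceeds feature count {X.n_features}")
    dense = X.dense()
    variances = dense.var(axis=0, ddof=1)
    # stable sort on -variance: ties resolve to the earlier column
    order = np.argsort(-variances, kind="stable")[:keep]
    cols = np.sort(order)
    vals = X.values[:, cols]
    if sp.issparse(vals):
        vals = vals.tocsr()
    return replace(
        X,
        values=vals,
        feature_ids=[X.feature_ids[j] for j in cols],
    )


def validate_dataset(ds: MultiOmicsDataset) -> MultiOmicsDataset:
    """Check that all modalities profile the same cells; realign permutations.

    Modalities whose rows are a permutation of the first modality's cell
    order are reordered in place of an error; disjoint or partially
    overlapping cell sets raise ``ValueError``.
    """
    ref = ds.modalities[0].cell_ids
    ref_set = set(ref)
    fixed = [ds.modalities[0]]
    for X in ds.modalities[1:]:
        if X.cell_ids == ref:
            fixed.append(X)
            continue
        if set(X.cell_ids) != ref_set:
            raise ValueError(
                f"modality {X.modality}: cell ID set differs from the first modality"
            )
        pos = {c: i for i, c in enumerate(X.cell_ids)}
        perm = np.array([pos[c] for c in ref])
        vals = X.values[perm, :]
        if sp.issparse(vals):
            vals = vals.tocsr()
        fixed.append(replace(X, values=vals, cell_ids=list(ref)))
    return MultiOmicsDataset(fixed, labels=ds.labels)
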