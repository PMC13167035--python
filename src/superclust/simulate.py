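"""Synthetic multi-omics data with known cluster structure.

The generator emulates the setting the pipeline targets: V modalities that
profile the same n cells under one shared cluster assignment. Each cluster
owns a disjoint block of marker features per modality whose means are
shifted so that the Euclidean distance between any two cluster mean vectors
equals ``separation`` within-cluster standard deviations; non-marker
features are pure noise around a per-feature baseline. The default noise
model is Gaussian in log-transformed expression space, which makes the
separation exact and analysis transparent; a negative-binomial mode is
available for count realism.

Optional extras: a planted rare population (a small coherent subgroup of a
parent cluster with its own cross-modality marker block), and per-cell
positive rescaling (cells that differ in scale but not in profile shape —
the scenario where angle-aware similarity is invariant and Euclidean
distance is not).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import MultiOmicsDataset, OmicsMatrix

__all__ = [
    "SimulationConfig",
    "RarePopulationCase",
    "simulate_multiomics",
    "simulate_scalability_benchmark",
    "simulate_rare_population_case",
]

#: default distance between cluster means, in within-cluster SD units;
#: comparable to two cell types differing by a few dozen markers at 2–3 SD
DEFAULT_SEPARATION = 30.0
#: baseline log-expression level, keeps simulated values positive
BASELINE_MEAN = 5.0
#: cap on marker features per cluster per modality
MAX_MARKERS_PER_CLUSTER = 20


@dataclass
class SimulationConfig:
    """Configuration of one synthetic multi-omics experiment.

    ``separation`` is the Euclidean distance between any two cluster mean
    vectors in units of the within-cluster (per-feature) standard
    deviation. ``feature_counts`` gives m_v per modality; ``modalities``
    optionally tags them. ``rare_size``/``rare_parent`` plant a rare
    subgroup with an extra marker block shifted by ``rare_shift`` SDs per
    feature, coherent across all modalities. ``cell_scale_sigma`` > 0
    multiplies every cell's row by exp(N(0, σ²)) in all modalities.

    ``micro_group_max`` / ``micro_sd`` control within-cluster
    microstructure: cells come in micro-groups of 1..``micro_group_max``
    cells sharing a low-magnitude offset (``micro_sd`` per feature, drawn
    independently per modality but tied to the same group membership).
    These emulate the locally coherent cross-omics neighborhoods — cell
    states, doublet-free micro-niches — that supercells are meant to
    capture; set ``micro_group_max`` ≤ 1 or ``micro_sd = 0`` to disable.
    """

    n_cells: int = 500
    n_clusters: int = 4
    feature_counts: tuple[int, ...] = (500, 100)
    modalities: tuple[str, ...] | None = None
    proportions: tuple[float, ...] | None = None
    separation: float = DEFAULT_SEPARATION
    noise: str = "gaussian-log-space"  # or "negative-binomial"
    nb_dispersion: float = 0.5
    markers_per_cluster: int | None = None
    rare_size: int = 0
    rare_parent: int = 0
    rare_shift: float = 3.0
    micro_group_max: int = 5
    micro_sd: float = 0.5
    cell_scale_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < self.n_clusters:
            raise ValueError("fewer cells than clusters")
        if self.noise not in ("gaussian-log-space", "negative-binomial"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.proportions is not None:
            p = np.asarray(self.proportions, dtype=float)
            if len(p) != self.n_clusters or abs(p.sum() - 1.0) > 1e-8 or (p <= 0).any():
                raise ValueError("proportions must be positive and sum to 1")
        if self.rare_size:
            sizes = _cluster_sizes(self)
            if self.rare_size >= sizes.min():
                raise ValueError("rare population must be smaller than every cluster")
            if not 0 <= self.rare_parent < self.n_clusters:
                raise ValueError("rare_parent out of range")


@dataclass
class RarePopulationCase:
    """Bundle returned by :func:`simulate_rare_population_case`."""

    dataset: MultiOmicsDataset
    parent_labels: np.ndarray
    sublabels: np.ndarray  # parent labels with '<k>.rare' for the subgroup
    rare_mask: np.ndarray
    marker_features: dict[int, list[int]] = field(default_factory=dict)


def _cluster_sizes(cfg: SimulationConfig) -> np.ndarray:
    """Deterministic largest-remainder allocation of n cells to K clusters."""
    if cfg.proportions is None:
        p = np.full(cfg.n_clusters, 1.0 / cfg.n_clusters)
    else:
        p = np.asarray(cfg.proportions, dtype=float)
    raw = p * cfg.n_cells
    sizes = np.floor(raw).astype(int)
    rem = cfg.n_cells - sizes.sum()
    order = np.argsort(-(raw - sizes), kind="stable")
    sizes[order[:rem]] += 1
    if (sizes == 0).any():
        raise ValueError("proportions leave an empty cluster")
    return sizes


def _micro_groups(
    cfg: SimulationConfig,
    labels: np.ndarray,
    rare_mask: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray | None:
    """Partition cells into within-cluster micro-groups of 1..max cells.

    Grouping is stratified by (cluster, rare membership) so a rare subgroup
    never shares a micro-group with ordinary parent-cluster cells. Returns
    a group id per cell, or None when microstructure is disabled.
    """
    if cfg.micro_group_max <= 1 or cfg.micro_sd <= 0:
        return None
    group_of = np.empty(cfg.n_cells, dtype=int)
    gid = 0
    for k in range(cfg.n_clusters):
        for rare in (False, True):
            cells = np.nonzero((labels == k) & (rare_mask == rare))[0]
            pos = 0
            while pos < len(cells):
                size = int(rng.integers(1, cfg.micro_group_max + 1))
                group_of[cells[pos : pos + size]] = gid
                gid += 1
                pos += size
    return group_of


def _marker_block_size(m: int, k: int, requested: int | None) -> int:
    if requested is not None:
        b = requested
    else:
        b = min(MAX_MARKERS_PER_CLUSTER, max(1, m // (2 * k)))
    if b * k > m:
        b = max(1, m // k)
    return b


def simulate_multiomics(cfg: SimulationConfig) -> tuple[MultiOmicsDataset, np.ndarray]:
    """Generate a dataset and its ground-truth labels from a config.

    One shared cluster assignment (deterministic sizes, seeded cell order)
    drives every modality. Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    sizes = _cluster_sizes(cfg)
    labels = np.repeat(np.arange(cfg.n_clusters), sizes)
    rng.shuffle(labels)

    rare_mask = np.zeros(cfg.n_cells, dtype=bool)
    if cfg.rare_size:
        parent_cells = np.nonzero(labels == cfg.rare_parent)[0]
        rare_mask[rng.choice(parent_cells, cfg.rare_size, replace=False)] = True

    group_of = _micro_groups(cfg, labels, rare_mask, rng)

    scale = None
    if cfg.cell_scale_sigma > 0:
        scale = np.exp(rng.normal(0.0, cfg.cell_scale_sigma, size=cfg.n_cells))

    tags = cfg.modalities or tuple("OTHER" for _ in cfg.feature_counts)
    mods: list[OmicsMatrix] = []
    rare_features: dict[int, list[int]] = {}
    for vi, (m, tag) in enumerate(zip(cfg.feature_counts, tags)):
        b = _marker_block_size(m, cfg.n_clusters, cfg.markers_per_cluster)
        shift = cfg.separation / np.sqrt(2.0 * b)  # per-marker mean shift (SD units)
        baseline = rng.normal(BASELINE_MEAN, 0.5, size=m)
        means = np.tile(baseline, (cfg.n_cells, 1))
        for k in range(cfg.n_clusters):
            cols = np.arange(k * b, (k + 1) * b)
            means[np.ix_(labels == k, cols)] += shift
        if cfg.rare_size:
            start = cfg.n_clusters * b
            bb = min(b, m - start)
            if bb <= 0:
                raise ValueError(f"modality {vi}: no features left for the rare marker block")
            cols = np.arange(start, start + bb)
            means[np.ix_(rare_mask, cols)] += cfg.rare_shift
            rare_features[vi] = cols.tolist()

        if group_of is not None:
            offsets = rng.normal(0.0, cfg.micro_sd, size=(group_of.max() + 1, m))
            means += offsets[group_of]

        if cfg.noise == "gaussian-log-space":
            vals = means + rng.standard_normal((cfg.n_cells, m))
        else:
            log_mean = np.log(2.0) + 0.5 * (means - BASELINE_MEAN)
            mu = np.exp(np.clip(log_mean, None, np.log(1e4)))
            lam = rng.gamma(1.0 / cfg.nb_dispersion, mu * cfg.nb_dispersion)
            vals = rng.poisson(lam).astype(float)

        if scale is not None:
            vals = vals * scale[:, None]
        mods.append(
            OmicsMatrix(
                vals,
                modality=tag if tag in ("RNA", "ADT", "ATAC") else "OTHER",
                cell_ids=[f"cell{i}" for i in range(cfg.n_cells)],
                feature_ids=[f"{tag.lower()}{vi}_f{j}" for j in range(m)],
            )
        )

    ds = MultiOmicsDataset(mods, labels=labels)
    if cfg.rare_size:
        ds._rare_mask = rare_mask  # stashed for simulate_rare_population_case
        ds._rare_features = rare_features
    return ds, labels


def simulate_scalability_benchmark(
    n: int = 5000, seed: int = 0
) -> tuple[MultiOmicsDataset, np.ndarray]:
    """Two-modality, 15-cluster scalability scenario.

    ATAC-like and RNA-like modalities with 5000 and 2000 features, equal
    cluster proportions and well-separated cluster means. ``n = 5000`` is a
    desk-scale default; the scenario mirrors a 100,000-cell benchmark.
    """
    if n < 15 * 20:
        raise ValueError("need at least 20 cells per cluster")
    cfg = SimulationConfig(
        n_cells=n,
        n_clusters=15,
        feature_counts=(5000, 2000),
        modalities=("ATAC", "RNA"),
        separation=DEFAULT_SEPARATION,
        seed=seed,
    )
    return simulate_multiomics(cfg)


def simulate_rare_population_case(seed: int = 0) -> RarePopulationCase:
    """Planted rare population: 30 cells inside a 500-cell parent cluster.

    The subgroup carries a dedicated marker block (shift 3 SD per feature)
    coherent across both modalities, so it should condense into few
    supercells and its markers reach significance at the supercell level
    while being diluted at the parent-cluster level.
    """
    cfg = SimulationConfig(
        n_cells=1200,
        n_clusters=3,
        proportions=(500 / 1200, 400 / 1200, 300 / 1200),
        feature_counts=(500, 200),
        rare_size=30,
        rare_parent=0,
        rare_shift=3.0,
        seed=seed,
    )
    ds, labels = simulate_multiomics(cfg)
    rare_mask = ds._rare_mask
    sub = labels.astype(str).astype(object)
    sub[rare_mask] = f"{cfg.rare_parent}.rare"
    return RarePopulationCase(
        dataset=ds,
        parent_labels=labels,
        sublabels=np.asarray(sub),
        rare_mask=rare_mask,
        marker_features=ds._rare_features,
    )
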