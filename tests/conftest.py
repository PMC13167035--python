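import numpy as np
import pytest

from superclust.io import MultiOmicsDataset, OmicsMatrix
from superclust.simulate import SimulationConfig, simulate_multiomics


@pytest.fixture(scope="session")
def small_dataset():
    """Two-modality, 3-cluster, well-separated dataset (n=300)."""
    cfg = SimulationConfig(n_cells=300, n_clusters=3, feature_counts=(300, 100), seed=11)
    return simulate_multiomics(cfg)


@pytest.fixture(scope="session")
def medium_dataset():
    """Two-modality, 4-cluster dataset (n=400) for pipeline-level tests."""
    cfg = SimulationConfig(n_cells=400, n_clusters=4, feature_counts=(400, 120), seed=23)
    return simulate_multiomics(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_dataset(seed: int, n: int = 30, ms=(15, 8)) -> MultiOmicsDataset:
    """Unstructured random dataset for property tests."""
    r = np.random.default_rng(seed)
    mods = [OmicsMatrix(r.normal(size=(n, m))) for m in ms]
    return MultiOmicsDataset(mods)
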