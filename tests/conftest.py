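import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from fcpipe import (
    CohortConfig,
    ConnectivityMatrix,
    ThresholdedNetwork,
    generate_atlas,
    generate_cohort,
)


def make_network(weights: np.ndarray) -> ThresholdedNetwork:
    """Wrap a symmetric nonzero-pattern weight matrix as a ThresholdedNetwork."""
    w = np.asarray(weights, dtype=float)
    mask = w != 0
    np.fill_diagonal(mask, False)
    iu = np.triu_indices(w.shape[0], k=1)
    return ThresholdedNetwork(
        weights=np.where(mask, w, 0.0),
        mask=mask,
        edge_count=int(mask[iu].sum()),
        sparsity=float(mask[iu].sum()) / len(iu[0]),
        backbone_edges=frozenset(),
    )


def random_connectivity(n: int, rng: np.random.Generator) -> ConnectivityMatrix:
    a = rng.uniform(-1, 1, size=(n, n))
    c = np.clip((a + a.T) / 2.0, -1, 1)
    np.fill_diagonal(c, 0.0)
    return ConnectivityMatrix(values=c, kind="raw")


@pytest.fixture(scope="session")
def small_atlas():
    return generate_atlas(n_parcels=20, n_networks=4, seed=3)


@pytest.fixture(scope="session")
def small_cohort():
    """A 2-group cohort with a strong planted clique and no other effects."""
    cfg = CohortConfig(
        n_per_group=30,
        groups=("HC", "UC"),
        n_parcels=60,
        n_networks=6,
        group_fc_offset={},
        planted_delta={"UC": 0.15},
        n_planted_nodes=10,
        stability_mean={"HC": 0.9, "UC": 0.9},
        stability_sd=0.01,
        state_contrast=0.0,  # stationary: isolates the static-analysis path
    )
    series, phen, truth = generate_cohort(cfg, seed=5)
    return cfg, series, phen, truth
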