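import numpy as np
import pytest

import modbrain as mb


@pytest.fixture(scope="session")
def planted_connectome():
    """100-node, 8-module connectome with sharp block structure.

    Within-module weights in [0.8, 1.0], between in [0, 0.2], so every
    within-module edge outranks every between edge; the density at which the
    within-module graph is exactly complete is known by construction.
    """
    rng = np.random.default_rng(42)
    n = 100
    labels = np.arange(n) % 8
    same = np.equal.outer(labels, labels)
    w = np.where(same, rng.uniform(0.8, 1.0, (n, n)), rng.uniform(0.0, 0.2, (n, n)))
    w = np.triu(w, 1)
    w = w + w.T
    conn = mb.WeightedConnectome(w)
    n_within = int(np.triu(same, 1).sum())
    d_within = 2.0 * n_within / (n * n - n) * 100.0
    return conn, labels, d_within


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 2x5 synthetic cohort for integration-style tests."""
    spec = mb.CohortSpec(group_sizes={"YA": 5, "OA": 5}, seed=7)
    return mb.generate_cohort(spec)


def restored_edge_toy():
    """7-node connectome where local thresholding rescues a weak hub edge.

    Two strong triangles {0,1,2} and {3,4,5}, a mid-weight bridge 2-3, and a
    peripheral node 6 whose single positive edge (to node 0, weight 0.3) is
    globally the weakest candidate.  At 34% density (7 edges) the global
    threshold keeps the bridge and isolates node 6, while the local threshold
    keeps node 6's nearest neighbour and drops the bridge.
    """
    w = np.zeros((7, 7))
    for i, j, v in [
        (0, 1, 0.9), (0, 2, 0.85), (1, 2, 0.8),
        (3, 4, 0.9), (3, 5, 0.85), (4, 5, 0.8),
        (2, 3, 0.5), (0, 6, 0.3),
    ]:
        w[i, j] = w[j, i] = v
    return mb.WeightedConnectome(w)
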