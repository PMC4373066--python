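import numpy as np
import pytest

import cnatree as ct


@pytest.fixture(scope="session")
def fig2_truth():
    """One loss, one gain, one CNLOH segment on separate chromosomes."""
    return [
        ct.TruthSegment("chr1", 300, 600, 1, 0),
        ct.TruthSegment("chr2", 200, 500, 3, 2),
        ct.TruthSegment("chr3", 400, 700, 2, 2),
    ]


@pytest.fixture(scope="session")
def aberrant_track(fig2_truth):
    """A 6-chromosome sample at purity 0.4 with known truth."""
    cfg = ct.SimulationConfig(n_chromosomes=6, purity=0.4,
                              truth_segments=fig2_truth, seed=11)
    track, truth = ct.simulate_sample(cfg)
    return cfg, track, truth


@pytest.fixture(scope="session")
def null_track():
    """A copy-neutral 6-chromosome sample."""
    cfg = ct.SimulationConfig(n_chromosomes=6, purity=0.4, seed=29)
    track, _ = ct.simulate_sample(cfg)
    return cfg, track


def best_match_accuracy(assignments, truth, n_clusters):
    """Cluster agreement under the best label permutation."""
    from scipy.optimize import linear_sum_assignment

    k = max(n_clusters, int(truth.max()) + 1)
    conf = np.zeros((k, k))
    for a, t in zip(assignments, truth):
        conf[a, t] += 1
    r, c = linear_sum_assignment(-conf)
    return conf[r, c].sum() / len(truth)
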