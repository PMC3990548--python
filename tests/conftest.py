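import numpy as np
import pytest

import coexnet as cx


@pytest.fixture(scope="session")
def standard_study():
    """Two preserved + one weak + one specific module over 120 noise genes.

    The canonical small study used across test modules: 8 time points x 3
    replicates per condition, log-ratio scale, noise sd 0.3.
    """
    config = cx.SimulationConfig(
        modules=(
            cx.ModuleSpec("alpha", 40, 0.7, 0.95, "preserved", 11),
            cx.ModuleSpec("beta", 35, 0.7, 0.95, "preserved", 12),
            cx.ModuleSpec("gamma", 30, 0.7, 0.95, "weak", 13),
            cx.ModuleSpec("delta", 30, 0.7, 0.95, "specific_to_test", 14),
        ),
        n_background_genes=120,
        noise_sd=0.3,
        rng_seed=11,
    )
    return cx.simulate_two_condition_dataset(config)


@pytest.fixture(scope="session")
def truth_partition(standard_study):
    labels = standard_study.truth_labels.where(
        standard_study.truth_labels != "background", cx.UNASSIGNED
    )
    return cx.ModulePartition(labels=labels)


@pytest.fixture(scope="session")
def standard_networks(standard_study):
    test_net = cx.build_network(standard_study.test, power=6)
    ref_net = cx.build_network(standard_study.reference, power=6)
    return ref_net, test_net


def random_symmetric_adjacency(n, rng):
    a = rng.uniform(0.0, 1.0, size=(n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    return a
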