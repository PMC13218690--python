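import numpy as np
import pandas as pd
import pytest

from tespipe.ppi_network import build_transition_matrix, network_from_edges
from tespipe.survival import SurvivalTable


def make_network(rows):
    """Network from (node1, node2, score) tuples, with transition matrix."""
    return build_transition_matrix(
        network_from_edges(pd.DataFrame(rows, columns=["node1", "node2", "score"])))


@pytest.fixture
def path_network():
    """Path graph A-B-C with unit-like scores."""
    return make_network([("A", "B", 900), ("B", "C", 900)])


@pytest.fixture
def triangle_network():
    return make_network([("A", "B", 800), ("A", "C", 800), ("B", "C", 1600)])


def random_network(n_nodes, rng, p=0.1):
    """Connected Erdos-Renyi-ish random network for property tests."""
    rows = []
    names = [f"N{i:03d}" for i in range(n_nodes)]
    for i in range(1, n_nodes):  # spanning tree guarantees connectivity
        j = int(rng.integers(0, i))
        rows.append((names[j], names[i], int(rng.integers(701, 1001))))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                rows.append((names[i], names[j], int(rng.integers(701, 1001))))
    return make_network(rows)


def make_survival(times, events, ids=None):
    ids = ids or [f"S{i}" for i in range(len(times))]
    return SurvivalTable(pd.DataFrame(
        {"time": np.asarray(times, dtype=float), "event": np.asarray(events, dtype=int)},
        index=pd.Index(ids, name="sample_id")))


@pytest.fixture(scope="session")
def small_cohort():
    """Strong-signal synthetic cohort at reduced scale, shared across tests."""
    from tespipe.synthetic_data import SyntheticConfig, generate_cohort

    return generate_cohort(SyntheticConfig(
        n_genes=120, n_samples=120, n_genesets=20, n_planted_sets_per_subtype=4,
        n_drivers_per_subtype=8, seed=11))
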