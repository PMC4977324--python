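from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

import wntbn as w
from wntbn.tables import ConditionalTable
from wntbn.topology import ModelTopology, NodeSpec


@pytest.fixture(scope="session")
def toy_fixture():
    """Six-sample worked example plus its hand-derived expected fragments."""
    return w.make_worked_fixture()


@pytest.fixture(scope="session")
def ref_net():
    """The full (t1) network under the printed parameter set."""
    return w.reference_network()


@pytest.fixture(scope="session")
def small_cohort():
    """A 4+4 synthetic cohort for fast end-to-end contracts."""
    dataset, truth = w.generate_cohort(w.GeneratorConfig(n_normal=4, n_tumor=4, seed=11))
    return dataset, truth


@pytest.fixture(scope="session")
def clean_cohort():
    """A well-separated 8+8 cohort (low emission noise)."""
    dataset, truth = w.generate_cohort(
        w.GeneratorConfig(n_normal=8, n_tumor=8, sigma=0.05, seed=5)
    )
    return dataset, truth


def random_network(rng: np.random.Generator, n_nodes: int, max_parents: int = 3):
    """A random binary-node DAG with random strictly-positive CPTs."""
    names = [f"G{i:02d}" for i in range(n_nodes)]
    nodes = []
    tables = {}
    for i, name in enumerate(names):
        k = int(rng.integers(0, min(i, max_parents) + 1))
        parents = tuple(
            names[j] for j in sorted(rng.choice(i, size=k, replace=False))
        ) if k else ()
        probs_on = rng.uniform(0.05, 0.95, size=2 ** k)
        probs = np.vstack([1 - probs_on, probs_on])
        nodes.append(NodeSpec(name, "gene", ("ia", "a"), parents))
        tables[name] = ConditionalTable(name, parents, probs)
    topo = ModelTopology(variant="t1", nodes=tuple(nodes))
    return w.TrainedNetwork(topology=topo, parameters=tables)


def random_dag(rng: np.random.Generator, n_nodes: int, p_edge: float = 0.35):
    """Random DAG as a ModelTopology (for d-separation sweeps)."""
    names = [f"N{i}" for i in range(n_nodes)]
    nodes = []
    for i, name in enumerate(names):
        parents = tuple(
            names[j] for j in range(i) if rng.random() < p_edge
        )
        nodes.append(NodeSpec(name, "gene", ("ia", "a"), parents))
    return ModelTopology(variant="t1", nodes=tuple(nodes))
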