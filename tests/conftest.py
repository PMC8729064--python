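import numpy as np
import pytest

from hetrwr import OntologyDAG, RunConfig, SimilarityBuilder
from hetrwr.synth import SynthSpec, planted_network


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def benchmark():
    """The default planted-structure benchmark (fixed generator seed)."""
    return planted_network(SynthSpec())


@pytest.fixture(scope="session")
def builder(benchmark, config):
    return SimilarityBuilder(benchmark.data, config)


@pytest.fixture
def sibling_dag():
    """Two leaves a, b under a shared root r."""
    return OntologyDAG({"a": {"r"}, "b": {"r"}})


@pytest.fixture
def chain_dag():
    """Three-level chain r -> m -> a (a is the deepest term)."""
    return OntologyDAG({"a": {"m"}, "m": {"r"}})


def random_dag_arrays(rng, n_terms):
    """Random labeled DAG: term i (> 0) draws 1-2 parents among 0..i-1."""
    edges = {}
    for i in range(1, n_terms):
        k = int(rng.integers(1, min(3, i + 1)))
        parents = rng.choice(i, size=k, replace=False)
        edges[f"t{i}"] = {f"t{p}" for p in parents}
    return OntologyDAG(edges, terms=["t0"])
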