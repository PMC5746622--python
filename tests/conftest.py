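import random

import pytest

from sanops_alert.fixtures import FIXTURE_NAMES, build_fixture
from sanops_alert.terminology_graph import (
    Concept,
    Edge,
    RelationType,
    TerminologyGraph,
)

CANDIDATES = ("loinc", "loinc_rsna", "radlex", "fma", "snomed")


@pytest.fixture(scope="session")
def bundles():
    return {name: build_fixture(name) for name in FIXTURE_NAMES}


@pytest.fixture(scope="session")
def backends(bundles):
    return {name: bundles[name].backend for name in FIXTURE_NAMES}


@pytest.fixture(scope="session")
def candidate_backends(backends):
    return {name: backends[name] for name in CANDIDATES}


def make_random_graph(
    rng: random.Random,
    n: int,
    rootward_edges: int,
    has_part_edges: int,
    name: str = "random",
) -> TerminologyGraph:
    """Random graph with guaranteed-acyclic rootward sub-graph.

    Rootward edges only go from lower to higher node index; has_part
    edges are unconstrained (full-graph cycles are legal).
    """
    ids = [f"N{i}" for i in range(n)]
    concepts = [Concept(i, f"node {i}", name) for i in ids]
    rootward_pool = [
        RelationType.IS_A,
        RelationType.PART_OF,
        RelationType.REGIONAL_PART_OF,
        RelationType.CONSTITUTIONAL_PART_OF,
    ]
    edges: set[Edge] = set()
    for _ in range(rootward_edges):
        i = rng.randrange(0, n - 1)
        j = rng.randrange(i + 1, n)
        edges.add(Edge(ids[i], ids[j], rng.choice(rootward_pool)))
    for _ in range(has_part_edges):
        i, j = rng.sample(range(n), 2)
        edges.add(Edge(ids[i], ids[j], RelationType.HAS_PART))
    return TerminologyGraph(name, concepts, edges)
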