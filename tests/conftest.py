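import numpy as np
import pytest

from comorbinet import FixtureSpec, GeneNetwork, generate_fixture


@pytest.fixture
def path_graph() -> GeneNetwork:
    """Unweighted path A-B-C-D-E."""
    nodes = ["A", "B", "C", "D", "E"]
    return GeneNetwork.from_edges(
        {(u, v): 1.0 for u, v in zip(nodes, nodes[1:])}
    )


@pytest.fixture
def two_cliques() -> tuple[GeneNetwork, set[str], set[str]]:
    """Two 10-node cliques joined by one bridge edge."""
    a = [f"a{i}" for i in range(10)]
    b = [f"b{i}" for i in range(10)]
    edges = {}
    for grp in (a, b):
        for i in range(len(grp)):
            for j in range(i + 1, len(grp)):
                edges[(grp[i], grp[j])] = 1.0
    edges[(a[0], b[0])] = 1.0
    return GeneNetwork.from_edges(edges), set(a), set(b)


def random_network(rng: np.random.Generator, n: int, p: float) -> GeneNetwork:
    """Erdős–Rényi network over n genes with a guaranteed spanning cycle."""
    genes = [f"g{i:03d}" for i in range(n)]
    edges = {(genes[i], genes[(i + 1) % n]): 1.0 for i in range(n)}
    mask = rng.random((n, n)) < p
    for i in range(n):
        for j in range(i + 1, n):
            if mask[i, j]:
                edges[(genes[i], genes[j])] = 1.0
    return GeneNetwork.from_edges(edges)


@pytest.fixture(scope="session")
def small_fixture():
    """Scaled-down synthetic study shared by pipeline-level tests."""
    spec = FixtureSpec(n_patients=5_000, seed=7)
    return generate_fixture(spec)
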