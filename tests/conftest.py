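import itertools

import networkx as nx
import numpy as np
import pytest

import pggnet as pg


@pytest.fixture(scope="session")
def path3() -> pg.Network:
    return pg.Network.from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture(scope="session")
def cycle6() -> pg.Network:
    return pg.Network.from_edges(6, [(i, (i + 1) % 6) for i in range(6)])


def complete(n: int) -> pg.Network:
    return pg.Network(1.0 - np.eye(n))


@pytest.fixture(scope="session")
def k8() -> pg.Network:
    return complete(8)


def brute_force_connected(n: int):
    """All connected graphs on n nodes up to isomorphism, by filtering
    every labeled graph — an enumeration oracle independent of the
    package's canonical-augmentation generator (n <= 5 stays cheap)."""
    reps: list[nx.Graph] = []
    all_edges = list(itertools.combinations(range(n), 2))
    for mask in range(2 ** len(all_edges)):
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(e for b, e in enumerate(all_edges) if mask >> b & 1)
        if not nx.is_connected(g):
            continue
        if any(nx.is_isomorphic(g, h) for h in reps):
            continue
        reps.append(g)
    return [pg.Network.from_networkx(g) for g in reps]


@pytest.fixture(scope="session")
def small_graph_zoo(path3, cycle6):
    """Assorted small connected graphs: irregular, regular, and dense."""
    star5 = pg.make_star(5)
    lollipop = pg.Network.from_edges(5, [(0, 1), (1, 2), (2, 0), (2, 3), (3, 4)])
    return [path3, cycle6, star5, lollipop, complete(4), pg.make_ceiling_fan(2)]
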