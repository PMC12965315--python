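"""Exhaustive census of small connected graphs and their thresholds.

Connected simple graphs are enumerated up to isomorphism by node-by-node
augmentation: every connected graph on n nodes contains a non-cut vertex,
so attaching one new node (with every non-empty neighbor subset) to every
connected graph on n-1 nodes reaches every isomorphism class. Duplicates
are removed with a canonical certificate (BLISS canonical permutation via
igraph). The known class counts are 2, 6, 21, 112, 853, 11117 for
N = 3..8 — 12,111 connected structures in total.

For each structure the census evaluates the weak-selection threshold for
any requested (game, rule, payoff scheme) combinations, classifies it
(relaxed / strict / no support), and ranks structures by how easily they
support cooperation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Iterator

import numpy as np

from .coalescence import solve_coalescence_times
from .graphs import Network
from .thresholds import ThresholdResult, dg_critical_bc, pgg_critical_r

__all__ = [
    "CensusRecord",
    "canonical_certificate",
    "enumerate_connected",
    "census_thresholds",
    "classify_census",
    "rank_percentile",
    "CENSUS_COUNTS",
]

#: known numbers of connected simple graphs up to isomorphism
CENSUS_COUNTS = {1: 1, 2: 1, 3: 2, 4: 6, 5: 21, 6: 112, 7: 853, 8: 11117}


@dataclass
class CensusRecord:
    """One isomorphism class with its thresholds."""

    network: Network
    n_nodes: int
    thresholds: dict[tuple[str, str, str], ThresholdResult]


def _to_igraph(edges: frozenset, n: int):
    import igraph as ig

    return ig.Graph(n=n, edges=[tuple(e) for e in edges])


def canonical_certificate(edges: frozenset, n: int) -> tuple:
    """Canonical edge tuple under the BLISS canonical node permutation."""
    g = _to_igraph(edges, n)
    perm = g.canonical_permutation()
    relab = [tuple(sorted((perm[u], perm[v]))) for (u, v) in edges]
    return tuple(sorted(relab))


def _augment(graphs_prev: list[tuple], n_new: int) -> list[tuple]:
    """All connected classes on n_new nodes from those on n_new - 1."""
    seen: dict[tuple, None] = {}
    new_node = n_new - 1
    for cert in graphs_prev:
        base = set(cert)
        for r in range(1, n_new):
            for subset in combinations(range(n_new - 1), r):
                edges = frozenset(base | {(min(t, new_node), max(t, new_node))
                                          for t in subset})
                key = canonical_certificate(edges, n_new)
                seen.setdefault(key, None)
    return sorted(seen.keys())


def _connected_certificates(n_nodes: int) -> list[tuple]:
    certs = [((0, 1),)]  # the single edge, N = 2
    for n in range(3, n_nodes + 1):
        certs = _augment(certs, n)
    return certs


def enumerate_connected(n_nodes: int) -> Iterator[Network]:
    """One canonical representative per isomorphism class of connected
    simple graphs on ``n_nodes`` nodes, in deterministic order."""
    if not 3 <= n_nodes <= 8:
        raise ValueError("census enumeration supports 3 <= N <= 8")
    for cert in _connected_certificates(n_nodes):
        yield Network.from_edges(n_nodes, list(cert))


def census_thresholds(
    networks: Iterable[Network],
    combos: Iterable[tuple[str, str, str]],
) -> list[CensusRecord]:
    """Thresholds for each (game, rule, payoff_scheme) combo, amortizing
    the coalescence solves across combos for each graph."""
    combos = list(combos)
    need_bd = any(rule == "bd" for _, rule, _ in combos)
    records = []
    for net in networks:
        t = solve_coalescence_times(net, "uniform")
        tbd = solve_coalescence_times(net, "bd") if need_bd else None
        th = {}
        for game, rule, scheme in combos:
            fn = pgg_critical_r if game == "pgg" else dg_critical_bc
            th[(game, rule, scheme)] = fn(
                net, rule=rule, payoff_scheme=scheme, times=t, times_bd=tbd
            )
        records.append(CensusRecord(net, net.n_nodes, th))
    return records


def classify_census(
    n_range: Iterable[int] = range(3, 9),
    game: str = "pgg",
    rule: str = "pc",
    payoff_scheme: str = "average",
    records: list[CensusRecord] | None = None,
) -> dict[str, float]:
    """Fractions of census graphs per threshold category."""
    key = (game, rule, payoff_scheme)
    if records is None:
        nets: list[Network] = []
        for n in n_range:
            nets.extend(enumerate_connected(n))
        records = census_thresholds(nets, [key])
    counts = {"finite_supporting": 0, "strict": 0, "no_support": 0}
    for rec in records:
        counts[rec.thresholds[key].category] += 1
    total = len(records)
    return {cat: cnt / total for cat, cnt in counts.items()}


def _sort_key(result: ThresholdResult) -> tuple:
    """Ascending by threshold; structures that cannot support cooperation
    sort after every finite threshold."""
    if result.category == "no_support":
        return (1, np.inf)
    return (0, result.value)


def rank_percentile(
    target: Network,
    n_nodes: int,
    game: str = "pgg",
    rule: str = "pc",
    payoff_scheme: str = "average",
    records: list[CensusRecord] | None = None,
) -> float:
    """Percentile rank (100 * rank / total, minimal rank on ties) of the
    target's isomorphism class among all size-n census graphs."""
    if target.n_nodes != n_nodes:
        raise ValueError("target size does not match n_nodes")
    key = (game, rule, payoff_scheme)
    if records is None:
        records = census_thresholds(enumerate_connected(n_nodes), [key])
    edges = frozenset(
        (int(i), int(j)) for i, j in zip(*np.nonzero(np.triu(target.adjacency)))
    )
    target_cert = canonical_certificate(edges, n_nodes)
    target_idx = None
    values = []
    for rec in records:
        e = frozenset(
            (int(i), int(j)) for i, j in zip(*np.nonzero(np.triu(rec.network.adjacency)))
        )
        if canonical_certificate(e, n_nodes) == target_cert:
            target_idx = len(values)
        values.append(_sort_key(rec.thresholds[key]))
    if target_idx is None:
        raise ValueError("target class not found in the census")
    tv = values[target_idx]
    better = sum(1 for v in values if v < tv)
    rank = better + 1  # minimal rank among ties
    return 100.0 * rank / len(values)
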