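"""Network construction, file I/O, and structural descriptors.

All population structures are simple, undirected, unweighted, connected
graphs. Internally a :class:`Network` stores a dense 0/1 adjacency matrix
(population sizes of interest are at most a few thousand) together with
cached degree and neighbor-list views used by the coalescent solvers.

Generators cover the synthetic families studied in the accompanying
analyses: stars, joint stars (a clique of hubs, each with private leaves),
ceiling fans (triangle blades sharing one hub), periodic square lattices
(von Neumann / Moore neighborhoods), Erdős–Rényi G(N,p), Watts–Strogatz
small worlds, and Krapivsky-style preferential attachment with tunable
exponent gamma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "Network",
    "make_star",
    "make_joint_stars",
    "make_ceiling_fan",
    "make_lattice",
    "make_erdos_renyi",
    "make_watts_strogatz",
    "make_scale_free",
    "read_edge_list",
    "write_edge_list",
    "clustering_coefficient",
]

_MAX_CONNECT_ATTEMPTS = 10_000


@dataclass
class Network:
    """A simple undirected graph on nodes ``0..N-1``.

    Attributes
    ----------
    adjacency:
        Symmetric ``(N, N)`` array of 0/1 (float64), zero diagonal.
    """

    adjacency: np.ndarray
    _neighbors: list[np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=np.float64)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        if not np.isin(a, (0.0, 1.0)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = a

    # -- derived views -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        """Degree k_i of every node."""
        return self.adjacency.sum(axis=1)

    @property
    def group_sizes(self) -> np.ndarray:
        """G_i = k_i + 1: node i plus its neighbors."""
        return self.degrees + 1.0

    @property
    def neighbors(self) -> list[np.ndarray]:
        """Neighbor index arrays, one per node."""
        if self._neighbors is None:
            self._neighbors = [
                np.flatnonzero(self.adjacency[i]).astype(np.int64)
                for i in range(self.n_nodes)
            ]
        return self._neighbors

    @property
    def n_edges(self) -> int:
        return int(round(self.adjacency.sum() / 2))

    def is_connected(self) -> bool:
        return nx.is_connected(self.to_networkx()) if self.n_nodes > 0 else False

    def require_connected(self) -> None:
        if self.n_nodes < 2 or not self.is_connected():
            raise ValueError("network must be connected with N >= 2")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        rows, cols = np.nonzero(np.triu(self.adjacency))
        g.add_edges_from(zip(rows.tolist(), cols.tolist()))
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Network":
        nodes = sorted(g.nodes())
        index = {v: i for i, v in enumerate(nodes)}
        a = np.zeros((len(nodes), len(nodes)))
        for u, v in g.edges():
            if u == v:
                raise ValueError("self-loops are not allowed")
            a[index[u], index[v]] = a[index[v], index[u]] = 1.0
        return cls(a)

    @classmethod
    def from_edges(cls, n_nodes: int, edges) -> "Network":
        a = np.zeros((n_nodes, n_nodes))
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop at node {u}")
            a[u, v] = a[v, u] = 1.0
        return cls(a)


# -- deterministic families ---------------------------------------------


def make_star(n_leaves: int) -> Network:
    """Star: one hub (node 0) with ``n_leaves`` degree-1 leaves."""
    if n_leaves < 1:
        raise ValueError("n_leaves must be >= 1")
    return Network.from_edges(n_leaves + 1, [(0, i) for i in range(1, n_leaves + 1)])


def make_joint_stars(m_hubs: int, n_leaves: int) -> Network:
    """``m_hubs`` mutually connected hubs, each carrying ``n_leaves`` private leaves.

    ``m_hubs=1`` reduces to :func:`make_star`. N = m(1+n).
    """
    if m_hubs < 1 or n_leaves < 1:
        raise ValueError("m_hubs and n_leaves must be >= 1")
    n = m_hubs * (1 + n_leaves)
    edges = [(a, b) for a in range(m_hubs) for b in range(a + 1, m_hubs)]
    nxt = m_hubs
    for hub in range(m_hubs):
        for _ in range(n_leaves):
            edges.append((hub, nxt))
            nxt += 1
    return Network.from_edges(n, edges)


def make_ceiling_fan(n_fans: int) -> Network:
    """Hub plus ``n_fans`` triangle blades (each blade: two leaves joined
    to each other and to the hub). N = 2n+1."""
    if n_fans < 1:
        raise ValueError("n_fans must be >= 1")
    edges = []
    for f in range(n_fans):
        a, b = 1 + 2 * f, 2 + 2 * f
        edges += [(0, a), (0, b), (a, b)]
    return Network.from_edges(2 * n_fans + 1, edges)


_NEIGHBORHOODS = {
    "von_neumann": [(1, 0), (-1, 0), (0, 1), (0, -1)],
    "moore": [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)],
}


def make_lattice(side: int, neighborhood: str = "von_neumann") -> Network:
    """Periodic ``side x side`` square lattice.

    von Neumann: degree 4 (group size 5); Moore: degree 8 (group size 9).
    ``side >= 3`` is required so wrap-around creates no duplicate edges
    (a 3x3 Moore lattice degenerates to K9, which is still simple).
    """
    if neighborhood not in _NEIGHBORHOODS:
        raise ValueError(f"unknown neighborhood {neighborhood!r}")
    if side < 3:
        raise ValueError("side must be >= 3")
    offs = _NEIGHBORHOODS[neighborhood]
    n = side * side
    a = np.zeros((n, n))
    for x in range(side):
        for y in range(side):
            i = x * side + y
            for dx, dy in offs:
                j = ((x + dx) % side) * side + (y + dy) % side
                if i != j:
                    a[i, j] = a[j, i] = 1.0
    return Network(a)


# -- random families -----------------------------------------------------


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def make_erdos_renyi(n_nodes: int, p_edge: float, seed=None) -> Network:
    """G(N, p) conditioned on connectivity (whole-graph rejection sampling)."""
    if not 0 < p_edge <= 1:
        raise ValueError("p_edge must be in (0, 1]")
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    rng = _rng(seed)
    iu = np.triu_indices(n_nodes, k=1)
    for _ in range(_MAX_CONNECT_ATTEMPTS):
        a = np.zeros((n_nodes, n_nodes))
        mask = rng.random(len(iu[0])) < p_edge
        a[iu[0][mask], iu[1][mask]] = 1.0
        a += a.T
        net = Network(a)
        if net.is_connected():
            return net
    raise RuntimeError("failed to draw a connected G(N,p) graph")


def make_watts_strogatz(
    n_nodes: int, d_halfwidth: int, p_rewire: float, seed=None
) -> Network:
    """Small-world graph: ring with neighbors within distance d on both
    sides, each original clockwise edge rewired once with probability p.

    Rewiring targets are uniform among non-self, non-neighbor nodes; the
    draw is rejected and repeated until connected. Total edge count is
    preserved for every p.
    """
    if d_halfwidth < 1 or 2 * d_halfwidth >= n_nodes - 1:
        raise ValueError("need 1 <= 2*d < N-1")
    if not 0 <= p_rewire <= 1:
        raise ValueError("p_rewire must be in [0, 1]")
    rng = _rng(seed)
    n, d = n_nodes, d_halfwidth
    for _ in range(_MAX_CONNECT_ATTEMPTS):
        a = np.zeros((n, n))
        for i in range(n):
            for off in range(1, d + 1):
                j = (i + off) % n
                a[i, j] = a[j, i] = 1.0
        for i in range(n):
            for off in range(1, d + 1):
                j = (i + off) % n
                if a[i, j] == 1.0 and rng.random() < p_rewire:
                    candidates = np.flatnonzero(a[i] == 0.0)
                    candidates = candidates[candidates != i]
                    if len(candidates) == 0:
                        continue
                    k = int(rng.choice(candidates))
                    a[i, j] = a[j, i] = 0.0
                    a[i, k] = a[k, i] = 1.0
        net = Network(a)
        if net.is_connected():
            return net
    raise RuntimeError("failed to draw a connected small-world graph")


def make_scale_free(n_nodes: int, m_attach: int, gamma: float, seed=None) -> Network:
    """Growing network with preferential attachment of strength gamma.

    Starts from ``m_attach`` isolated nodes; each arriving node attaches to
    ``m_attach`` distinct existing nodes chosen with probability
    proportional to k^gamma (nodes of degree 0 get unit weight so the
    process can start). gamma=1 is the classic Barabási–Albert rule;
    gamma=0 is uniform attachment. Edge count is exactly m(N-m), hence
    mean degree 2m(1-m/N).
    """
    if m_attach < 1:
        raise ValueError("m_attach must be >= 1")
    if n_nodes <= m_attach:
        raise ValueError("n_nodes must exceed m_attach")
    rng = _rng(seed)
    n, m = n_nodes, m_attach
    a = np.zeros((n, n))
    deg = np.zeros(n)
    for new in range(m, n):
        targets: list[int] = []
        existing = np.arange(new)
        w = np.where(deg[:new] > 0, deg[:new] ** gamma, 1.0)
        for _ in range(m):
            avail = np.setdiff1d(existing, targets, assume_unique=False)
            ww = w[avail]
            t = int(rng.choice(avail, p=ww / ww.sum()))
            targets.append(t)
        for t in targets:
            a[new, t] = a[t, new] = 1.0
            deg[new] += 1
            deg[t] += 1
    net = Network(a)
    # attachment to m >= 1 prior nodes makes the growth graph connected
    return net


# -- file I/O -------------------------------------------------------------


def read_edge_list(path) -> Network:
    """Read a whitespace- or comma-separated edge list.

    Node labels are arbitrary strings, mapped to 0..N-1 in sorted order.
    Duplicate edges collapse; self-loops raise; a disconnected graph only
    warns (threshold computations will reject it later).
    """
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two node labels")
            u, v = parts
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop at {u!r}")
            edges.append((u, v))
    if not edges:
        raise ValueError(f"{path}: no edges found")
    labels = sorted({x for e in edges for x in e})
    index = {lab: i for i, lab in enumerate(labels)}
    net = Network.from_edges(len(labels), [(index[u], index[v]) for u, v in edges])
    if not net.is_connected():
        warnings.warn(f"{path}: graph is not connected", stacklevel=2)
    return net


def write_edge_list(network: Network, path) -> None:
    with open(path, "w") as fh:
        fh.write("# edge list, one edge per line\n")
        rows, cols = np.nonzero(np.triu(network.adjacency))
        for u, v in zip(rows.tolist(), cols.tolist()):
            fh.write(f"{u} {v}\n")


def clustering_coefficient(network: Network) -> float:
    """Mean local clustering coefficient (degree <2 nodes contribute 0)."""
    return float(nx.average_clustering(network.to_networkx(), count_zeros=True))
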