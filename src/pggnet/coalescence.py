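"""Random-walk kernels and pairwise coalescence times.

The weak-selection condition for cooperation on a graph reduces to linear
functionals of the meeting times of two coalescing random walkers. Two
ancestral (backward-in-time) chains appear:

* ``uniform`` — the voter-model chain underlying both the pairwise
  comparison (PC) and death-birth (DB) rules: every node is replaced at
  the same rate, and a replaced node copies a uniformly random neighbor.
  The meeting times solve, for i != j,

      tau_ij = 1 + (1/(2 k_i)) sum_{l in N_i} tau_lj
                 + (1/(2 k_j)) sum_{l in N_j} tau_il,     tau_ii = 0.

* ``bd`` — the chain underlying the birth-death (BD) rule: a reproducer
  is chosen uniformly and replaces a uniform neighbor, so node i is
  replaced at rate d_i/N per elementary step, d_i = sum_l k_il / k_l
  (non-uniform across nodes). Backward in time the lineage at i jumps to
  l with weight k_il / k_l. Because the mutant is placed uniformly at
  random, the quantity entering the selection condition is the expected
  number of elementary steps until the two lineages meet, giving a
  constant source term (overall time scale is irrelevant, only ratios of
  tau-functionals enter any threshold):

      (d_i + d_j) tau_ij = 1 + sum_l (k_il/k_l) tau_lj
                             + sum_l (k_jl/k_l) tau_il.

Both systems are solved over the N(N-1)/2 unordered pairs, by sparse LU
for moderate sizes and by an exact automorphism-orbit reduction for the
large highly symmetric families (lattices, fans, joint stars), where the
number of distinct pair classes is tiny.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graphs import Network

__all__ = [
    "step_distribution",
    "n_step_distribution",
    "solve_coalescence_times",
    "weighted_tau",
    "coalescence_residual",
]

# above this many pair unknowns, try the automorphism-orbit reduction first
# (hubs make the pair system fill in badly under sparse LU, so symmetric
# families switch to the exact orbit quotient early)
_ORBIT_PAIR_THRESHOLD = 2_000


def step_distribution(network: Network) -> np.ndarray:
    """One-step simple random-walk kernel p_ij = k_ij / k_i."""
    network.require_connected()
    a = network.adjacency
    return a / a.sum(axis=1, keepdims=True)

def n_step_distribution(kernel: np.ndarray, n: int) -> np.ndarray:
    """n-th power of the one-step kernel (n = 0 gives the identity)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return np.linalg.matrix_power(kernel, n)


def _pair_coefficients(network: Network, kind: str):
    """Per-pair recurrence: coefficients c_il such that

        s_ij * tau_ij = b_ij + sum_l c_il tau_lj + sum_l c_jl tau_il.

    uniform: c_il = k_il/(2 k_i), s_ij = 1.  bd: c_il = k_il/k_l,
    s_ij = d_i + d_j.  The source b_ij = 1 in both systems.
    """
    a = network.adjacency
    k = network.degrees
    if kind == "uniform":
        coef = a / (2.0 * k[:, None])
        move = np.full(network.n_nodes, 0.5)
    elif kind == "bd":
        coef = a / k[None, :]
        move = coef.sum(axis=1)  # d_i
    else:
        raise ValueError(f"unknown coalescence kind {kind!r}")
    return coef, move


def _solve_pairs_direct(network: Network, kind: str) -> np.ndarray:
    n = network.n_nodes
    coef, move = _pair_coefficients(network, kind)
    neighbors = network.neighbors
    idx = -np.ones((n, n), dtype=np.int64)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    for p, (i, j) in enumerate(pairs):
        idx[i, j] = idx[j, i] = p
    rows, cols, vals = [], [], []
    rhs = np.empty(len(pairs))
    for p, (i, j) in enumerate(pairs):
        s = move[i] + move[j]
        rows.append(p)
        cols.append(p)
        vals.append(s)
        rhs[p] = 1.0
        for l in neighbors[i]:
            if l != j:  # tau_jj = 0
                rows.append(p)
                cols.append(idx[l, j])
                vals.append(-coef[i, l])
        for l in neighbors[j]:
            if l != i:
                rows.append(p)
                cols.append(idx[i, l])
                vals.append(-coef[j, l])
    mat = sp.csc_matrix((vals, (rows, cols)), shape=(len(pairs), len(pairs)))
    if len(pairs) <= 600:
        sol = np.linalg.solve(mat.toarray(), rhs)
    else:
        sol = spla.splu(mat).solve(rhs)
    t = np.zeros((n, n))
    for p, (i, j) in enumerate(pairs):
        t[i, j] = t[j, i] = sol[p]
    return t


def _pair_orbits(network: Network) -> np.ndarray | None:
    """Orbit label for every unordered pair under Aut(G), or None if the
    reduction would not pay off. Labels index into (n, n) via min/max."""
    import igraph as ig

    n = network.n_nodes
    g = ig.Graph.Adjacency((network.adjacency > 0).tolist(), mode="undirected")
    gens = [np.asarray(p, dtype=np.int64) for p in g.automorphism_group()]
    if not gens:
        return None
    # pair orbits = connected components of pair ids linked by generators;
    # a generator can move pair (i, j) only if it moves i or j, so edges
    # are built from each generator's support (usually a handful of nodes)
    iu, ju = np.triu_indices(n, k=1)
    pid = iu * n + ju
    ident = np.arange(n, dtype=np.int64)
    rows, cols = [], []
    for perm in gens:
        support = np.flatnonzero(perm != ident)
        if support.size == 0:
            continue
        a = np.repeat(support, n)
        b = np.tile(ident, support.size)
        keep = a != b
        a, b = a[keep], b[keep]
        src = np.minimum(a, b) * n + np.maximum(a, b)
        ga, gb = perm[a], perm[b]
        dst = np.minimum(ga, gb) * n + np.maximum(ga, gb)
        rows.append(src)
        cols.append(dst)
    if not rows:
        return None
    nnz = sum(len(r) for r in rows)
    mat = sp.csr_matrix(
        (np.ones(nnz, dtype=np.int8), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n * n, n * n),
    )
    from scipy.sparse.csgraph import connected_components

    _, comp = connected_components(mat, directed=False)
    comp_pairs = comp[pid]
    _, orbit = np.unique(comp_pairs, return_inverse=True)
    n_orbits = int(orbit.max()) + 1
    if n_orbits * 20 > len(pid):  # reduction not worthwhile
        return None
    labels = np.full((n, n), -1, dtype=np.int64)
    labels[iu, ju] = orbit
    labels[ju, iu] = orbit
    return labels


def _solve_pairs_orbits(network: Network, kind: str, labels: np.ndarray) -> np.ndarray:
    n = network.n_nodes
    coef, move = _pair_coefficients(network, kind)
    neighbors = network.neighbors
    n_orb = int(labels.max()) + 1
    # one representative pair per orbit
    reps = [None] * n_orb
    for i in range(n):
        for j in range(i + 1, n):
            lab = labels[i, j]
            if reps[lab] is None:
                reps[lab] = (i, j)
    mat = np.zeros((n_orb, n_orb))
    rhs = np.empty(n_orb)
    for o, (i, j) in enumerate(reps):
        s = move[i] + move[j]
        mat[o, o] += s
        rhs[o] = 1.0
        for l in neighbors[i]:
            if l != j:
                mat[o, labels[l, j]] -= coef[i, l]
        for l in neighbors[j]:
            if l != i:
                mat[o, labels[i, l]] -= coef[j, l]
    sol = np.linalg.solve(mat, rhs)
    t = np.zeros((n, n))
    mask = labels >= 0
    t[mask] = sol[labels[mask]]
    return t


def solve_coalescence_times(
    network: Network, kind: str = "uniform", method: str = "auto"
) -> np.ndarray:
    """Pairwise meeting times of the coalescing ancestral chain.

    Parameters
    ----------
    kind:
        ``"uniform"`` (PC/DB ancestral chain) or ``"bd"``.
    method:
        ``"direct"`` forces the sparse pair-system solve; ``"orbits"``
        forces the automorphism reduction; ``"auto"`` reduces by orbits
        only when the pair system is large and the graph symmetric.

    Returns the symmetric (N, N) matrix with zero diagonal.
    """
    network.require_connected()
    n_pairs = network.n_nodes * (network.n_nodes - 1) // 2
    if method == "orbits" or (method == "auto" and n_pairs > _ORBIT_PAIR_THRESHOLD):
        labels = _pair_orbits(network)
        if labels is not None:
            return _solve_pairs_orbits(network, kind, labels)
        if method == "orbits":
            raise ValueError("graph has too little symmetry for orbit reduction")
    return _solve_pairs_direct(network, kind)


def coalescence_residual(network: Network, times: np.ndarray, kind: str = "uniform") -> float:
    """Max-norm residual of the pair recurrence; ~1e-12 for a valid solve."""
    coef, move = _pair_coefficients(network, kind)
    n = network.n_nodes
    res = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            s = move[i] + move[j]
            lhs = s * times[i, j]
            rhs = 1.0 + coef[i] @ times[:, j] + coef[j] @ times[i, :]
            res = max(res, abs(lhs - rhs))
    return res


def weighted_tau(network: Network, times: np.ndarray, n: int) -> float:
    """Degree- and walk-weighted coalescence sum
    tau(n) = sum_{i,j} k_i p_ij^(n) tau_ij."""
    if times.shape != (network.n_nodes, network.n_nodes):
        raise ValueError("times matrix does not match the network")
    k = network.degrees
    pn = n_step_distribution(step_distribution(network), n)
    return float(np.sum(k[:, None] * pn * times))
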