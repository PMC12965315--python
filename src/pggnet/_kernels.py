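"""Numba-compiled inner loops for mass Monte-Carlo replication.

The state bookkeeping keeps, for every node l, the number of cooperators
S_l in the group it organizes ({l} plus neighbors). A strategy flip at
node v updates S only on v's group, and a payoff evaluation reads only
the focal node's group sums, so an elementary step costs O(k^2) at most
regardless of the population size.
"""

import numpy as np
from numba import njit

__all__ = ["run_batch"]


@njit(cache=True)
def _payoff(j, x, s, indptr, indices, inv_g, g, scheme, r, c):
    # sum over games organized by j and by its neighbors
    acc = s[j] * inv_g[j]
    for p in range(indptr[j], indptr[j + 1]):
        l = indices[p]
        acc += s[l] * inv_g[l]
    if scheme == 0:  # average
        return r * c * acc * inv_g[j] - c * x[j]
    return r * c * acc - c * g[j] * x[j]


@njit(cache=True)
def _flip(i, x, s, indptr, indices):
    d = np.int64(1 - 2 * x[i])  # +1 if D->C else -1
    x[i] = 1 - x[i]
    s[i] += d
    for p in range(indptr[i], indptr[i + 1]):
        s[indices[p]] += d
    return d


@njit(cache=True)
def run_batch(indptr, indices, gsize, rule, scheme, r, c, delta,
              max_mcs, n_runs, seeds):
    """Independent runs from a uniformly placed single cooperator.

    Returns (sum, sum of squares) of the final cooperator fraction."""
    n = indptr.shape[0] - 1
    inv_g = 1.0 / gsize
    g = gsize
    max_steps = max_mcs * n
    total = 0.0
    total_sq = 0.0
    wloc = np.empty(n, dtype=np.float64)
    for run in range(n_runs):
        np.random.seed(seeds[run])
        x = np.zeros(n, dtype=np.int8)
        s = np.zeros(n, dtype=np.int64)
        start = np.random.randint(0, n)
        x[start] = 1
        s[start] = 1
        for p in range(indptr[start], indptr[start + 1]):
            s[indices[p]] = 1
        ncoop = 1
        for _ in range(max_steps):
            if rule == 0:  # pairwise comparison
                i = np.random.randint(0, n)
                deg = indptr[i + 1] - indptr[i]
                j = indices[indptr[i] + np.random.randint(0, deg)]
                if x[i] != x[j]:
                    fi = _payoff(i, x, s, indptr, indices, inv_g, g, scheme, r, c)
                    fj = _payoff(j, x, s, indptr, indices, inv_g, g, scheme, r, c)
                    if np.random.random() < 1.0 / (1.0 + np.exp(-delta * (fj - fi))):
                        ncoop += _flip(i, x, s, indptr, indices)
            elif rule == 1:  # death-birth
                i = np.random.randint(0, n)
                tot = 0.0
                m = 0
                mixed = False
                first = x[indices[indptr[i]]]
                for p in range(indptr[i], indptr[i + 1]):
                    jj = indices[p]
                    w = np.exp(delta * _payoff(jj, x, s, indptr, indices,
                                               inv_g, g, scheme, r, c))
                    wloc[m] = w
                    tot += w
                    m += 1
                    if x[jj] != first:
                        mixed = True
                if not mixed and first == x[i]:
                    continue  # all competitors share i's strategy
                u = np.random.random() * tot
                acc = 0.0
                j = indices[indptr[i]]
                for p in range(m):
                    acc += wloc[p]
                    if u <= acc:
                        j = indices[indptr[i] + p]
                        break
                if x[j] != x[i]:
                    ncoop += _flip(i, x, s, indptr, indices)
            else:  # birth-death
                tot = 0.0
                for jj in range(n):
                    w = np.exp(delta * _payoff(jj, x, s, indptr, indices,
                                               inv_g, g, scheme, r, c))
                    wloc[jj] = w
                    tot += w
                u = np.random.random() * tot
                acc = 0.0
                j = n - 1
                for jj in range(n):
                    acc += wloc[jj]
                    if u <= acc:
                        j = jj
                        break
                deg = indptr[j + 1] - indptr[j]
                i = indices[indptr[j] + np.random.randint(0, deg)]
                if x[i] != x[j]:
                    ncoop += _flip(i, x, s, indptr, indices)
            if ncoop == 0 or ncoop == n:
                break
        rho = ncoop / n
        total += rho
        total_sq += rho * rho
    return total, total_sq
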