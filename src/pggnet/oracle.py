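"""Exact fixation probabilities from the full 2^N strategy Markov chain.

For populations of up to ~12 agents the evolutionary process is a finite
Markov chain over all 2^N strategy profiles with two absorbing states
(all-defect and all-cooperate). Fixation probabilities follow from one
sparse linear solve, with no sampling error — this module is the ground
truth against which the weak-selection threshold formulas are tested.

The critical parameter value is located from the delta-derivative of the
fixation probability at delta = 0, estimated by central finite
differences; that derivative is exactly linear in the game parameter
(payoffs are linear in it), so two evaluations determine the root.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graphs import Network
from .thresholds import ThresholdResult, _categorize, payoff_matrices

__all__ = ["ChainSpec", "exact_fixation_probability", "oracle_critical"]

_MAX_N = 12


@dataclass(frozen=True)
class ChainSpec:
    """Full specification of one exact chain evaluation."""

    network: Network
    rule: str = "pc"
    game: str = "pgg"
    payoff_scheme: str = "average"
    theta: float = 2.0  # synergy factor r (pgg) or benefit b (dg)
    cost: float = 1.0
    delta: float = 0.01


def _states_matrix(n: int) -> np.ndarray:
    """(2^n, n) array of strategy vectors; state index is the bitmask."""
    s = np.arange(2**n, dtype=np.uint32)
    return ((s[:, None] >> np.arange(n)) & 1).astype(np.float64)


def _flip_probabilities(spec: ChainSpec) -> np.ndarray:
    """q[s, i]: probability that one elementary step flips node i's
    strategy when the population is in state s."""
    net = spec.network
    n = net.n_nodes
    a = net.adjacency
    k = net.degrees
    x = _states_matrix(n)  # (S, n)
    phi_c, phi_b = payoff_matrices(net, spec.game, spec.payoff_scheme)
    phi = spec.cost * (-phi_c + spec.theta * phi_b)
    f = x @ phi.T  # payoffs, (S, n)
    fit = np.exp(spec.delta * f)
    diff = x[:, None, :] != x[:, :, None]  # diff[s, i, j] = (x_j != x_i)
    if spec.rule == "pc":
        # focal i (1/n), neighbor j (1/k_i), Fermi adoption
        w = 1.0 / (1.0 + np.exp(-spec.delta * (f[:, None, :] - f[:, :, None])))
        q = (a[None] / k[None, :, None] * w * diff).sum(axis=2) / n
    elif spec.rule == "db":
        # focal i dies (1/n); neighbors compete proportionally to fitness
        neigh_fit = a[None] * fit[:, None, :]  # (S, i, j)
        q = (neigh_fit * diff).sum(axis=2) / neigh_fit.sum(axis=2) / n
    elif spec.rule == "bd":
        # reproducer j global fitness-proportional, replaces uniform neighbor i
        tot = fit.sum(axis=1, keepdims=True)  # (S, 1)
        pj = fit / tot  # (S, j)
        q = (a[None] * pj[:, None, :] / k[None, None, :] * diff).sum(axis=2)
    else:
        raise ValueError(f"unknown rule {spec.rule!r}")
    return q


def exact_fixation_probability(spec: ChainSpec) -> float:
    """Probability that a single cooperator placed uniformly at random
    takes over the population, from the exact absorbing-chain solve."""
    n = spec.network.n_nodes
    if n > _MAX_N:
        raise ValueError(f"N = {n} exceeds the exact-chain limit {_MAX_N}")
    spec.network.require_connected()
    q = _flip_probabilities(spec)
    n_states = 2**n
    full = n_states - 1
    # transient states: everything except 0 and full
    trans = np.arange(1, full)
    pos = -np.ones(n_states, dtype=np.int64)
    pos[trans] = np.arange(len(trans))
    # jump-chain form: (sum_i q_si) phi(s) = sum_i q_si phi(s with i flipped)
    mat = np.zeros((len(trans), len(trans)))
    rhs = np.zeros(len(trans))
    bits = 1 << np.arange(n, dtype=np.uint32)
    for row, s in enumerate(trans):
        for i in range(n):
            qi = q[s, i]
            if qi == 0.0:
                continue
            mat[row, row] += qi
            s2 = int(s) ^ int(bits[i])
            if s2 == full:
                rhs[row] += qi
            elif s2 != 0:
                mat[row, pos[s2]] -= qi
    phi = np.linalg.solve(mat, rhs)
    singles = [pos[1 << i] for i in range(n)]
    return float(np.mean(phi[singles]))


def _slope(spec: ChainSpec, delta: float) -> float:
    """d/d(delta) of the fixation probability at delta = 0 (central diff)."""
    up = exact_fixation_probability(
        ChainSpec(spec.network, spec.rule, spec.game, spec.payoff_scheme,
                  spec.theta, spec.cost, delta)
    )
    dn = exact_fixation_probability(
        ChainSpec(spec.network, spec.rule, spec.game, spec.payoff_scheme,
                  spec.theta, spec.cost, -delta)
    )
    return (up - dn) / (2.0 * delta)


def oracle_critical(
    network: Network,
    rule: str = "pc",
    game: str = "pgg",
    payoff_scheme: str = "average",
    delta: float = 1e-4,
    theta_probes: tuple[float, float] = (1.0, 5.0),
) -> ThresholdResult:
    """Critical parameter from the exact chain.

    The fixation-probability slope in delta is linear in the game
    parameter theta; two probe values give slope(theta) = a + b*theta and
    the threshold is the root -a/b. A second estimate at delta/2
    (Richardson check) guards against finite-difference truncation.
    """
    t1, t2 = theta_probes
    spec1 = ChainSpec(network, rule, game, payoff_scheme, t1)
    spec2 = ChainSpec(network, rule, game, payoff_scheme, t2)
    s1, s2 = _slope(spec1, delta), _slope(spec2, delta)
    s1b, s2b = _slope(spec1, delta / 2.0), _slope(spec2, delta / 2.0)
    s1, s2 = (4 * s1b - s1) / 3.0, (4 * s2b - s2) / 3.0  # Richardson
    b = (s2 - s1) / (t2 - t1)
    a = s1 - b * t1
    scale = max(abs(a), abs(b) * max(abs(t1), abs(t2)), 1e-30)
    if abs(b) < 1e-9 * scale:
        value = np.inf if a <= 0 else -np.inf
        return ThresholdResult(game, rule, payoff_scheme, float(value),
                               "no_support", favored_above=False)
    value = -a / b
    return ThresholdResult(game, rule, payoff_scheme, float(value),
                           _categorize(value, b > 0), favored_above=b > 0)
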