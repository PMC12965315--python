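"""Critical synergy factors and benefit-to-cost ratios under weak selection.

For every update rule the first-order (in the selection strength delta)
condition for a single cooperator to fix with probability above the
neutral benchmark 1/N takes the form

    sum_{i,j} W_ij  E[ (x_j - x_i) * (f_j(x) - g_i(x)) ]  >  0,

where the expectation is over the rule's neutral recurrent state
distribution, W is a rule-specific symmetric edge weighting, and g_i is
either f_i (PC, BD) or the neighbor-averaged payoff (DB, because the
dying node's own payoff plays no role). Payoffs are linear in the state,
f = Phi x, and the neutral pair correlations reduce to coalescence times:
E[(x_j - x_i) x_m] is proportional to tau_im - tau_jm. The condition is
therefore linear in the game parameter (synergy factor r, or benefit b),
and the threshold is a ratio of two tau-functionals.

Rule specifics:

=====  ===================  =================  ==================
rule   W_ij                 g_i                ancestral chain
=====  ===================  =================  ==================
PC     k_ij                 f_i                uniform (voter)
DB     k_ij                 sum_l p_il f_l     uniform (voter)
BD     k_ij/(k_i k_j)       f_i                bd (non-uniform)
=====  ===================  =================  ==================

For PC with average public-goods payoffs this machinery reproduces the
closed form r* = tau(1)/Upsilon(1) and for DB r* = tau(2)/Upsilon(2),
with Upsilon assembled from coalescence times by :func:`upsilon_matrix`;
both identities are exercised in the test suite, and every rule/game/
payoff combination is validated against an exact 2^N Markov-chain oracle
on all connected graphs with N <= 6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coalescence import solve_coalescence_times, step_distribution
from .graphs import Network

__all__ = [
    "ThresholdResult",
    "upsilon_matrix",
    "payoff_matrices",
    "condition_coefficients",
    "pgg_critical_r",
    "dg_critical_bc",
    "FINITE_SUPPORT_MAX",
    "NUMERIC_INFINITY",
]

RULES = ("pc", "db", "bd")
GAMES = ("pgg", "dg")
SCHEMES = ("average", "accumulated")

#: upper edge of the "relaxed condition" category
FINITE_SUPPORT_MAX = 30.0
#: thresholds beyond this magnitude are treated as divergent (r -> inf)
NUMERIC_INFINITY = 1000.0


@dataclass(frozen=True)
class ThresholdResult:
    """A critical value with its qualitative classification.

    ``value`` is the critical synergy factor r* (PGG) or critical
    benefit-to-cost ratio (b/c)* (DG); cooperation is favored for
    parameter values above it when ``favored_above`` is true.

    Categories: ``finite_supporting`` (0 < value <= 30), ``strict``
    (30 < value <= 1000), ``no_support`` (negative, divergent, or a
    condition that large parameters cannot satisfy).
    """

    game: str
    rule: str
    payoff_scheme: str
    value: float
    category: str
    favored_above: bool = True


def _categorize(value: float, favored_above: bool) -> str:
    if not favored_above or not np.isfinite(value):
        return "no_support"
    if 0 < value <= FINITE_SUPPORT_MAX:
        return "finite_supporting"
    if FINITE_SUPPORT_MAX < value <= NUMERIC_INFINITY:
        return "strict"
    return "no_support"


def upsilon_matrix(network: Network, times: np.ndarray) -> np.ndarray:
    """Group-weighted coalescence combination Upsilon_ij.

    Upsilon_ij = (1/G_i) [ (tau_ij + sum_{l in N_i} (tau_jl - tau_il)) / G_i
                 + sum_{l in N_i} ( (tau_jl - tau_il)
                   + sum_{m in N_l} (tau_jm - tau_im) ) / G_l ]

    Upsilon_ii = 0, and Upsilon is generally asymmetric on heterogeneous
    graphs because of the group-size weights.
    """
    if times.shape != (network.n_nodes, network.n_nodes):
        raise ValueError("times matrix does not match the network")
    a = network.adjacency
    g = network.group_sizes
    t = times
    # D_ij,l = tau_jl - tau_il summed over l in N_i with various weights
    # sum_{l in N_i} tau_jl = (A t)_{ij}... careful with orientation:
    at = a @ t  # at[i, m] = sum_{l in N_i} tau_lm
    # sum_{l in N_i} tau_jl = (a @ t)[i, j]; sum_{l in N_i} tau_il = (a @ t)[i, i]
    s1 = at - np.diag(at)[:, None]  # s1[i, j] = sum_{l in N_i}(tau_jl - tau_il)
    # group-size weighted first-neighbor sums:
    ag = a / g[None, :]  # ag[i, l] = a_il / G_l
    s1g = ag @ t - (ag @ t)[np.arange(len(g)), np.arange(len(g))][:, None]
    # s1g[i, j] = sum_{l in N_i} (tau_jl - tau_il)/G_l
    # second-neighbor sums through l: for each l, R[l, j] = sum_{m in N_l} tau_jm = (a@t)[l, j]
    r2 = at  # r2[l, j] = sum_{m in N_l} tau_jm
    s2g = ag @ r2 - (ag @ r2)[np.arange(len(g)), np.arange(len(g))][:, None]
    # s2g[i, j] = sum_{l in N_i} (1/G_l) sum_{m in N_l} (tau_jm - tau_im)
    ups = ((t + s1) / g[:, None] + s1g + s2g) / g[:, None]
    np.fill_diagonal(ups, 0.0)
    return ups


def payoff_matrices(network: Network, game: str, payoff_scheme: str):
    """Linear payoff maps: f = c * (-Phi_cost + theta * Phi_benefit) @ x,
    where theta is the synergy factor r (PGG) or benefit b (DG), c = 1.

    PGG (public goods with groups G_i = {i} u N_i): each agent plays the
    G_i games organized by itself and its neighbors; 'average' divides the
    total by G_i, 'accumulated' does not.
    DG (pairwise donation game): one game per edge; 'average' divides by
    the number of games k_i.
    """
    if game not in GAMES:
        raise ValueError(f"unknown game {game!r}")
    if payoff_scheme not in SCHEMES:
        raise ValueError(f"unknown payoff scheme {payoff_scheme!r}")
    a = network.adjacency
    n = network.n_nodes
    eye = np.eye(n)
    if game == "pgg":
        g = network.group_sizes
        m = a + eye  # group membership indicator
        core = m @ (m / g[:, None])  # (M D_G^{-1} M), symmetric
        if payoff_scheme == "average":
            return eye, core / g[:, None]
        return np.diag(g), core
    k = network.degrees
    if payoff_scheme == "average":
        return eye, a / k[:, None]
    return np.diag(k), a.copy()


def _functional(w: np.ndarray, phi: np.ndarray, times: np.ndarray,
                mix: np.ndarray | None) -> float:
    """sum_{ij} W_ij sum_m [phi_jm - (mix phi)_im] (tau_im - tau_jm)."""
    phit = phi @ times
    kphit = phit if mix is None else mix @ phit
    rw = w.sum(axis=1)
    return float(
        (w * phit.T).sum()
        - rw @ np.diag(phit)
        - rw @ np.diag(kphit)
        + (w * kphit).sum()
    )


def condition_coefficients(
    network: Network,
    rule: str,
    game: str,
    payoff_scheme: str,
    times: np.ndarray | None = None,
    times_bd: np.ndarray | None = None,
) -> tuple[float, float]:
    """Coefficients (L_cost, L_benefit) of the weak-selection condition
    ``theta * L_benefit > L_cost``; precomputed coalescence times may be
    passed to amortize solves across game variants."""
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}")
    a = network.adjacency
    if rule == "bd":
        t = times_bd if times_bd is not None else solve_coalescence_times(network, "bd")
        k = network.degrees
        w = a / np.outer(k, k)
        mix = None
    else:
        t = times if times is not None else solve_coalescence_times(network, "uniform")
        w = a
        mix = step_distribution(network) if rule == "db" else None
    phi_cost, phi_benefit = payoff_matrices(network, game, payoff_scheme)
    l_cost = _functional(w, phi_cost, t, mix)
    l_benefit = _functional(w, phi_benefit, t, mix)
    return l_cost, l_benefit


def _threshold(network, rule, game, payoff_scheme, times, times_bd) -> ThresholdResult:
    network.require_connected()
    if network.n_nodes < 3:
        raise ValueError("thresholds require N >= 3")
    l_cost, l_benefit = condition_coefficients(
        network, rule, game, payoff_scheme, times=times, times_bd=times_bd
    )
    scale = max(abs(l_cost), 1.0)
    if abs(l_benefit) < 1e-12 * scale:
        # condition cannot be satisfied by any finite parameter
        value = np.inf if l_cost >= 0 else -np.inf
        return ThresholdResult(game, rule, payoff_scheme, float(value),
                               "no_support", favored_above=False)
    value = l_cost / l_benefit
    favored_above = l_benefit > 0
    return ThresholdResult(
        game, rule, payoff_scheme, float(value),
        _categorize(value, favored_above), favored_above
    )


def pgg_critical_r(
    network: Network,
    rule: str = "pc",
    payoff_scheme: str = "average",
    times: np.ndarray | None = None,
    times_bd: np.ndarray | None = None,
) -> ThresholdResult:
    """Critical synergy factor r* for the public goods game."""
    return _threshold(network, rule, "pgg", payoff_scheme, times, times_bd)


def dg_critical_bc(
    network: Network,
    rule: str = "pc",
    payoff_scheme: str = "average",
    times: np.ndarray | None = None,
    times_bd: np.ndarray | None = None,
) -> ThresholdResult:
    """Critical benefit-to-cost ratio (b/c)* for the pairwise donation game."""
    return _threshold(network, rule, "dg", payoff_scheme, times, times_bd)
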