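"""Agent-based Monte-Carlo simulation of strategy evolution.

The simulation follows the standard protocol: a single cooperator is
placed uniformly at random among N-1 defectors; each elementary step one
agent updates its strategy under the chosen rule (PC, DB or BD) with
fitness exp(delta * payoff); a full Monte-Carlo step (MCS) is N
elementary steps; a run ends at fixation (all-C or all-D) or is
truncated after ``max_mcs`` MCS, in which case the current cooperator
fraction is recorded. Averaging the final cooperator fraction rho_C over
many runs estimates the fixation probability; cooperation is favored
when the average exceeds the neutral benchmark 1/N.

The public functions keep a readable pure-Python step implementation
(:func:`update_step`) used by the unit tests; mass replication goes
through a numba-compiled kernel that maintains the per-group cooperator
counts incrementally, so an elementary step touches only a second-order
neighborhood.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .graphs import Network
from .thresholds import payoff_matrices

__all__ = [
    "SimConfig",
    "actual_payoffs",
    "update_step",
    "run_to_fixation",
    "estimate_cooperation",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulation campaign (public goods game)."""

    r: float
    c: float = 1.0
    delta: float = 0.01
    rule: str = "pc"
    payoff_scheme: str = "average"
    max_mcs: int = 400_000
    n_runs: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r <= 0 or self.c < 0 or self.delta < 0 or self.max_mcs < 1:
            raise ValueError("invalid simulation parameters")
        if self.rule not in ("pc", "db", "bd"):
            raise ValueError(f"unknown rule {self.rule!r}")


def actual_payoffs(
    state: np.ndarray,
    network: Network,
    payoff_scheme: str = "average",
    r: float = 2.0,
    c: float = 1.0,
) -> np.ndarray:
    """Public-goods payoff of every node: each agent i takes part in the
    G_i games organized by itself and its neighbors; 'average' divides
    the total by G_i."""
    x = np.asarray(state, dtype=np.float64)
    if x.shape != (network.n_nodes,):
        raise ValueError("state length does not match the network")
    phi_cost, phi_benefit = payoff_matrices(network, "pgg", payoff_scheme)
    return c * (r * phi_benefit - phi_cost) @ x


def _fermi(delta: float, diff: float) -> float:
    return 1.0 / (1.0 + np.exp(-delta * diff))


def update_step(
    state: np.ndarray,
    network: Network,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One elementary step; at most one node changes strategy."""
    x = np.asarray(state).copy()
    n = network.n_nodes
    f = actual_payoffs(x, network, config.payoff_scheme, config.r, config.c)
    if config.rule == "pc":
        i = int(rng.integers(n))
        j = int(rng.choice(network.neighbors[i]))
        if rng.random() < _fermi(config.delta, f[j] - f[i]):
            x[i] = x[j]
    elif config.rule == "db":
        i = int(rng.integers(n))
        nb = network.neighbors[i]
        w = np.exp(config.delta * f[nb])
        j = int(rng.choice(nb, p=w / w.sum()))
        x[i] = x[j]
    else:  # bd
        w = np.exp(config.delta * f)
        j = int(rng.choice(n, p=w / w.sum()))
        i = int(rng.choice(network.neighbors[j]))
        x[i] = x[j]
    return x


def run_to_fixation(
    network: Network, config: SimConfig, rng: np.random.Generator | None = None
) -> float:
    """One run from a uniformly placed single cooperator; returns the
    final cooperator fraction (1, 0, or the truncation-time value)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = network.n_nodes
    x = np.zeros(n, dtype=np.int8)
    x[int(rng.integers(n))] = 1
    for _ in range(config.max_mcs * n):
        s = int(x.sum())
        if s == 0 or s == n:
            break
        x = update_step(x, network, config, rng)
    return float(x.sum()) / n


def _csr(network: Network):
    indptr = np.zeros(network.n_nodes + 1, dtype=np.int64)
    indices = []
    for i, nb in enumerate(network.neighbors):
        indices.extend(nb.tolist())
        indptr[i + 1] = len(indices)
    return indptr, np.asarray(indices, dtype=np.int64)


_RULE_CODES = {"pc": 0, "db": 1, "bd": 2}


def estimate_cooperation(
    network: Network,
    r_grid,
    config: SimConfig,
    use_numba: bool = True,
) -> pd.DataFrame:
    """Mean final cooperator fraction (with standard error) per synergy
    factor in ``r_grid``, from ``config.n_runs`` independent runs each.

    Per-run seeds are derived deterministically from ``config.seed``, so
    results are reproducible and runs are independent across the grid.
    """
    network.require_connected()
    indptr, indices = _csr(network)
    gsize = network.group_sizes
    rows = []
    ss = np.random.SeedSequence(config.seed)
    for r in r_grid:
        seeds = np.random.SeedSequence(
            entropy=ss.entropy, spawn_key=(int(round(r * 1e6)),)
        ).generate_state(config.n_runs).astype(np.uint32)
        if use_numba:
            from ._kernels import run_batch

            total, total_sq = run_batch(
                indptr, indices, gsize,
                _RULE_CODES[config.rule],
                0 if config.payoff_scheme == "average" else 1,
                float(r), float(config.c), float(config.delta),
                int(config.max_mcs), int(config.n_runs), seeds,
            )
        else:
            total = total_sq = 0.0
            for s in seeds:
                rho = run_to_fixation(
                    network, replace(config, r=float(r), seed=int(s))
                )
                total += rho
                total_sq += rho * rho
        mean = total / config.n_runs
        var = max(total_sq / config.n_runs - mean**2, 0.0)
        stderr = float(np.sqrt(var / config.n_runs))
        rows.append({"r": float(r), "mean_rhoC": mean, "stderr": stderr,
                     "n_runs": config.n_runs})
    return pd.DataFrame(rows)
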