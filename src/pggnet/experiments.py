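"""Scripted desk-scale reproductions of the headline analyses.

Three canned experiments mirror the main computational studies:

* ``run_family_thresholds`` — critical synergy factors for the synthetic
  families (stars, joint stars, ceiling fans, periodic lattices) at a
  ladder of finite sizes, with an infinite-size extrapolation column
  obtained from a least-squares fit of r*(n) = a + b/n.
* ``run_random_sweep`` — mean threshold over ensembles of random graphs
  (Erdős–Rényi edge probability, Watts–Strogatz rewiring probability, or
  preferential-attachment exponent sweeps) at N = 100.
* ``run_census`` — the exhaustive small-graph census with category
  fractions and rankings.

Each experiment returns plain pandas DataFrames and, when given an
output directory, writes them as CSV together with a YAML manifest
(config, package version, seeds) sufficient for an exact re-run.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .census import census_thresholds, classify_census, enumerate_connected, rank_percentile
from .graphs import (
    Network,
    make_ceiling_fan,
    make_erdos_renyi,
    make_joint_stars,
    make_lattice,
    make_scale_free,
    make_star,
    make_watts_strogatz,
)
from .thresholds import pgg_critical_r

__all__ = [
    "ExperimentConfig",
    "extrapolate_inverse_size",
    "run_family_thresholds",
    "run_random_sweep",
    "run_census",
]


@dataclass
class ExperimentConfig:
    """Serializable experiment description."""

    name: str
    seed: int = 0
    out_dir: str | None = None
    params: dict = field(default_factory=dict)

    def manifest(self) -> dict:
        return {"config": asdict(self), "pggnet_version": _version}


def _write(df: pd.DataFrame, config: ExperimentConfig, stem: str) -> None:
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / f"{stem}.csv", index=False)
    with open(out / f"{stem}.manifest.yaml", "w") as fh:
        yaml.safe_dump(config.manifest(), fh)


def extrapolate_inverse_size(sizes, values) -> tuple[float, float]:
    """Least-squares fit v = a + b/n; returns (a, max abs fit residual).

    The leading finite-size correction of the thresholds decays like the
    inverse of the family's size parameter, which the residual verifies.
    """
    sizes = np.asarray(sizes, dtype=float)
    values = np.asarray(values, dtype=float)
    design = np.vstack([np.ones_like(sizes), 1.0 / sizes]).T
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    return float(coef[0]), float(np.abs(design @ coef - values).max())


_FAMILIES = {
    "star": (make_star, (10, 20, 40, 80)),
    "joint_stars_m2": (lambda n: make_joint_stars(2, n), (25, 50, 100, 200)),
    "joint_stars_m3": (lambda n: make_joint_stars(3, n), (25, 50, 100, 200)),
    "ceiling_fan": (make_ceiling_fan, (20, 40, 80, 160)),
    "lattice_von_neumann": (lambda s: make_lattice(s, "von_neumann"), (10, 14, 20)),
    "lattice_moore": (lambda s: make_lattice(s, "moore"), (10, 14, 20)),
}


def run_family_thresholds(
    config: ExperimentConfig | None = None,
    rules: tuple[str, ...] = ("pc", "db"),
    payoff_scheme: str = "average",
    families: dict | None = None,
) -> pd.DataFrame:
    """Finite-size thresholds and infinite-size extrapolations for the
    deterministic synthetic families. Lattice families extrapolate
    against 1/N = 1/side^2."""
    config = config or ExperimentConfig("family_thresholds")
    families = families or _FAMILIES
    rows = []
    for fam, (builder, sizes) in families.items():
        for rule in rules:
            vals = []
            for s in sizes:
                net = builder(s)
                res = pgg_critical_r(net, rule=rule, payoff_scheme=payoff_scheme)
                vals.append(res.value)
                rows.append({"family": fam, "rule": rule, "size": s,
                             "n_nodes": net.n_nodes, "r_star": res.value,
                             "extrapolated": np.nan})
            xs = [builder(s).n_nodes for s in sizes] if "lattice" in fam else sizes
            a, resid = extrapolate_inverse_size(xs, vals)
            rows.append({"family": fam, "rule": rule, "size": -1,
                         "n_nodes": -1, "r_star": np.nan, "extrapolated": a})
    df = pd.DataFrame(rows)
    _write(df, config, "family_thresholds")
    return df


def run_random_sweep(
    config: ExperimentConfig | None = None,
    model: str = "er",
    sweep=None,
    n_nodes: int = 100,
    n_samples: int = 50,
    rule: str = "db",
    payoff_scheme: str = "average",
) -> pd.DataFrame:
    """Mean threshold versus the ensemble parameter over random draws.

    ``model``: 'er' (sweep edge probability p), 'ws' (rewiring p at
    d = 2), or 'ba' (attachment exponent gamma at m = 2)."""
    config = config or ExperimentConfig("random_sweep", params={"model": model})
    if sweep is None:
        sweep = {"er": (0.04, 0.06, 0.1), "ws": (0.0, 0.5, 1.0),
                 "ba": (0.0, 1.0, 2.0)}[model]
    ss = np.random.SeedSequence(config.seed)
    rows = []
    for value in sweep:
        seeds = ss.spawn(n_samples)
        thresholds = []
        for sd in seeds:
            seed = int(sd.generate_state(1)[0] % (2**31))
            if model == "er":
                net = make_erdos_renyi(n_nodes, value, seed)
            elif model == "ws":
                net = make_watts_strogatz(n_nodes, 2, value, seed)
            elif model == "ba":
                net = make_scale_free(n_nodes, 2, value, seed)
            else:
                raise ValueError(f"unknown model {model!r}")
            res = pgg_critical_r(net, rule=rule, payoff_scheme=payoff_scheme)
            if res.category != "no_support":
                thresholds.append(res.value)
        rows.append({
            "model": model, "parameter": value, "rule": rule,
            "mean_r_star": float(np.mean(thresholds)),
            "stderr": float(np.std(thresholds) / np.sqrt(len(thresholds))),
            "n_networks": len(thresholds),
        })
    df = pd.DataFrame(rows)
    _write(df, config, f"random_sweep_{model}")
    return df


def run_census(
    config: ExperimentConfig | None = None,
    n_range=range(3, 9),
    combos=None,
) -> dict:
    """Exhaustive census: per-combination category fractions, plus the
    star-graph percentile ranks among the largest enumerated size."""
    config = config or ExperimentConfig("census")
    if combos is None:
        combos = [(g, r, "average") for g in ("pgg", "dg") for r in ("pc", "db", "bd")]
    nets = []
    for n in n_range:
        nets.extend(enumerate_connected(n))
    records = census_thresholds(nets, combos)
    fractions = {}
    for game, rule, scheme in combos:
        fractions[f"{game}/{rule}/{scheme}"] = classify_census(
            records=records, game=game, rule=rule, payoff_scheme=scheme
        )
    n_max = max(n_range)
    recs_max = [r for r in records if r.n_nodes == n_max]
    ranks = {}
    for game, rule, scheme in combos:
        if game == "pgg":
            ranks[f"star/{rule}"] = rank_percentile(
                make_star(n_max - 1), n_max, game, rule, scheme, records=recs_max
            )
    result = {"n_graphs": len(records), "fractions": fractions,
              "star_rank_percent": ranks}
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "census.json", "w") as fh:
            json.dump(result, fh, indent=2)
        with open(out / "census.manifest.yaml", "w") as fh:
            yaml.safe_dump(config.manifest(), fh)
    return result
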