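"""Scenario orchestration: intensity sweeps, surrogate comparisons and
parameter sweeps.

A scenario simulates a base network and its degree-matched randomized and
latticized surrogates over a grid of external arrival rates, with several
replicate runs per (network, λ) cell.  Per-run network-level statistics feed
the λ-curves; per-run node-level statistics feed the ensemble comparison
machinery.  All runs derive their seeds from a single master seed through a
spawn tree keyed by (family, realization, λ index, repetition), so any cell
can be reproduced in isolation.

Full-scale protocols (100 runs × 100 realizations, 2·10⁶ time-unit
horizons) are supported via the same interface; defaults are desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compare import fisher_r_to_z_diff
from .generators import latticize, maslov_rewire, rich_club_synthetic
from .network import DirectedNetwork
from .simulation import SimConfig, run_simulation
from .stats import network_stats, node_stats, remove_transient

__all__ = ["ScenarioReport", "run_scenario", "scenario_similarity", "sweep"]

NETWORK_METRICS = ["mean_transit_time", "mean_utilization", "mean_blocking",
                   "throughput"]


@dataclass
class ScenarioReport:
    """Output of :func:`run_scenario`.

    ``runs``: long-format frame with one row per simulation
    (family, realization, lam, rep, the four network metrics).
    ``curves``: grand-mean metric per (family, lam).
    ``node_metrics``: dict (family, lam, metric) → array shaped
    (n_realizations, n_reps, n_nodes) for ensemble comparison.
    """

    runs: pd.DataFrame
    curves: pd.DataFrame
    node_metrics: dict
    node_ids: list
    config: dict = field(default_factory=dict)

    def metric_vector(self, metrics=NETWORK_METRICS):
        """Flattened (family × λ × metric) grand-mean vector, for
        scenario-similarity correlations."""
        c = self.curves.sort_index()
        return c[metrics].to_numpy().ravel(), c.index


def _run_cell(net, lam, cfg: SimConfig, seed):
    config = SimConfig(lambda_ext=lam, mu=cfg.mu, buffer_size=cfg.buffer_size,
                       t_end=cfg.t_end, t_transient=cfg.t_transient,
                       seed=seed, arrival_mode=cfg.arrival_mode,
                       rng_backend=cfg.rng_backend)
    trace = run_simulation(net, config)
    w = remove_transient(trace)
    return network_stats(w), node_stats(w)


def run_scenario(base_net: DirectedNetwork, n_randomized=0, n_latticized=0,
                 lambdas=(0.05, 0.10, 0.15, 0.20), n_reps=10,
                 config: SimConfig = None, seed=None,
                 node_metric_names=("utilization", "blocking", "mean_contents")):
    """Simulate a base network and its surrogate families over a λ grid.

    Every (family, realization, λ, rep) cell is one simulation.  The base
    family has a single "realization" (the network itself); randomized and
    latticized families have ``n_randomized`` / ``n_latticized`` independent
    degree-matched realizations, each simulated ``n_reps`` times per λ.
    """
    if config is None:
        config = SimConfig()
    if n_reps < 1 or min(n_randomized, n_latticized) < 0:
        raise ValueError("infeasible replication counts")
    master = np.random.SeedSequence(seed)
    net_ss, run_ss = master.spawn(2)

    families = {"base": [base_net]}
    if n_randomized:
        rnd_seeds = net_ss.spawn(n_randomized + n_latticized)
        families["randomized"] = [
            maslov_rewire(base_net, seed=rnd_seeds[r]) for r in range(n_randomized)
        ]
        if n_latticized:
            families["latticized"] = [
                latticize(base_net, seed=rnd_seeds[n_randomized + r])
                for r in range(n_latticized)
            ]
    elif n_latticized:
        lat_seeds = net_ss.spawn(n_latticized)
        families["latticized"] = [
            latticize(base_net, seed=lat_seeds[r]) for r in range(n_latticized)
        ]

    rows = []
    node_metrics = {}
    n_nodes = base_net.n_nodes
    fam_code = {"base": 0, "randomized": 1, "latticized": 2}
    for fam, nets in families.items():
        for li, lam in enumerate(lambdas):
            per = {m: np.empty((len(nets), n_reps, n_nodes))
                   for m in node_metric_names}
            for ri, net in enumerate(nets):
                for rep in range(n_reps):
                    # deterministic per-cell seed derived from the master
                    cell = np.random.SeedSequence(
                        entropy=run_ss.entropy,
                        spawn_key=(fam_code[fam], ri, li, rep))
                    ns_net, ns_node = _run_cell(net, lam, config, cell)
                    rows.append({"family": fam, "realization": ri,
                                 "lam": lam, "rep": rep, **ns_net})
                    for m in node_metric_names:
                        per[m][ri, rep] = ns_node[m].to_numpy()
            for m in node_metric_names:
                node_metrics[(fam, lam, m)] = per[m]
    runs = pd.DataFrame(rows)
    curves = runs.groupby(["family", "lam"])[NETWORK_METRICS].mean()
    return ScenarioReport(runs=runs, curves=curves, node_metrics=node_metrics,
                          node_ids=list(base_net.node_ids),
                          config={"lambdas": list(lambdas), "n_reps": n_reps,
                                  "n_randomized": n_randomized,
                                  "n_latticized": n_latticized,
                                  "mu": config.mu,
                                  "buffer_size": config.buffer_size,
                                  "t_end": config.t_end,
                                  "t_transient": config.t_transient,
                                  "seed": seed})


def scenario_similarity(report_ref: ScenarioReport, report_a: ScenarioReport,
                        report_b: ScenarioReport, metrics=NETWORK_METRICS):
    """Correlate scenario metric patterns and contrast the correlations.

    The grand-mean metric values across (family × λ) cells of each scenario
    are flattened into vectors; Pearson correlations r(ref, a) and r(ref, b)
    are contrasted with Fisher's r-to-z.  All reports must share the λ grid
    and family structure.
    """
    v_ref, idx = report_ref.metric_vector(metrics)
    v_a, idx_a = report_a.metric_vector(metrics)
    v_b, idx_b = report_b.metric_vector(metrics)
    if not (len(v_ref) == len(v_a) == len(v_b)):
        raise ValueError("scenario reports do not share a grid")
    r_a = float(np.corrcoef(v_ref, v_a)[0, 1])
    r_b = float(np.corrcoef(v_ref, v_b)[0, 1])
    n = len(v_ref)
    if np.isclose(abs(r_a), 1) or np.isclose(abs(r_b), 1):
        z = float("nan")
    else:
        z = fisher_r_to_z_diff(r_a, n, r_b, n)
    return {"r_ref_a": r_a, "r_ref_b": r_b, "n": n, "fisher_z": z}


def sweep(parameter, values, base_net=None, config: SimConfig = None,
          lambdas=(0.10,), n_reps=5, seed=None, rc_kwargs=None):
    """Parameter sweep over buffer size or planted rich-club size.

    ``parameter="buffer_size"`` reruns the scenario on ``base_net`` with each
    buffer value; ``parameter="rich_club_size"`` generates a planted
    rich-club network per club size (default 100 nodes) and runs each.
    Returns a long frame of per-run network statistics tagged by value,
    with per-node statistics attached for the buffer sweep.
    """
    if config is None:
        config = SimConfig()
    master = np.random.SeedSequence(seed)
    frames = []
    node_frames = []
    for vi, val in enumerate(values):
        if parameter == "buffer_size":
            net = base_net
            cfg = SimConfig(lambda_ext=config.lambda_ext, mu=config.mu,
                            buffer_size=int(val), t_end=config.t_end,
                            t_transient=config.t_transient,
                            arrival_mode=config.arrival_mode,
                            rng_backend=config.rng_backend)
        elif parameter == "rich_club_size":
            kw = dict(rc_kwargs or {})
            kw.setdefault("n", 100)
            net, _ = rich_club_synthetic(
                n_rc=int(val), seed=np.random.SeedSequence(
                    entropy=master.entropy, spawn_key=(99, vi)), **kw)
            cfg = config
        else:
            raise ValueError("parameter must be 'buffer_size' or 'rich_club_size'")
        for li, lam in enumerate(lambdas):
            for rep in range(n_reps):
                cell = np.random.SeedSequence(entropy=master.entropy,
                                              spawn_key=(vi, li, rep))
                ns_net, ns_node = _run_cell(net, lam, cfg, cell)
                frames.append({parameter: val, "lam": lam, "rep": rep,
                               **ns_net})
                nf = ns_node.reset_index()
                nf[parameter] = val
                nf["lam"] = lam
                nf["rep"] = rep
                node_frames.append(nf)
    return {"system": pd.DataFrame(frames),
            "nodes": pd.concat(node_frames, ignore_index=True)}
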