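"""Analytic steady-state approximations and exact small-system solutions.

Two independent routes for verifying the simulator:

1. An open-network decomposition: the expected per-node traffic generated by
   uniformly routed random walks is obtained exactly from the fundamental
   matrix of the absorbing walk, and each node is then treated as an
   independent M/M/1/K queue (capacity K+1 counting the server slot).  The
   decomposition ignores blocking-induced flow thinning and queueing
   correlations between nodes, so it is accurate at low load and degrades
   as blocking grows.  LIFO ordering does not affect occupancy laws, so the
   standard finite-buffer formulas apply unchanged.

2. An exact continuous-time Markov chain over the complete system state
   (per-node ordered stacks of unit destinations), feasible for very small
   networks only, used as a brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import DirectedNetwork, degrees

__all__ = [
    "AnalyticPrediction",
    "absorbing_visit_counts",
    "node_arrival_rates",
    "mm1k_metrics",
    "predict_stats",
    "exact_ctmc",
]


def _transition_matrix(net):
    a = net.adjacency_matrix().astype(float)
    out = a.sum(axis=1)
    if (out == 0).any():
        raise ValueError("every node needs out-degree >= 1")
    return a / out[:, None]


def absorbing_visit_counts(net: DirectedNetwork, destination) -> pd.DataFrame:
    """Expected visits to each transient node by the uniform random walk
    absorbed at ``destination``, for every starting node.

    Row s, column i gives the expected number of times a walker started at s
    occupies node i before absorption (the start counts as one visit, so the
    diagonal is ≥ 1).  Rows for sources that cannot reach the destination
    are NaN-flagged.
    """
    import networkx as nx

    if isinstance(destination, str):
        d = net.node_index(destination)
    else:
        d = int(destination)
    p = _transition_matrix(net)
    n = net.n_nodes
    labels = net.node_ids
    g = net.to_networkx()
    reach = {net.node_index(x) for x in nx.ancestors(g, labels[d])}
    transient = [i for i in range(n) if i != d]
    ok = [i for i in transient if i in reach]
    result = np.full((n, n), np.nan)
    if ok:
        q = p[np.ix_(ok, ok)]
        fund = np.linalg.solve(np.eye(len(ok)) - q, np.eye(len(ok)))
        for r, s in enumerate(ok):
            result[s, :] = 0.0
            for c, i in enumerate(ok):
                result[s, i] = fund[r, c]
    return pd.DataFrame(result, index=pd.Index(labels, name="source"),
                        columns=pd.Index(labels, name="node"))


def node_arrival_rates(net: DirectedNetwork, lambda_ext) -> pd.Series:
    """Effective per-node traffic rate λ_i under uniform source/destination.

    Each of the N(N−1) ordered pairs receives external rate λ/(N(N−1)); the
    walk started at s toward d visits node i an expected V_d[s, i] times
    (injection included), so λ_i = λ/(N(N−1)) Σ_d Σ_{s≠d} V_d[s, i].
    Unreachable (s, d) pairs are excluded from the sum.
    """
    n = net.n_nodes
    per_pair = lambda_ext / (n * (n - 1))
    rates = np.zeros(n)
    for d in range(n):
        v = absorbing_visit_counts(net, d).to_numpy()
        rows = [s for s in range(n) if s != d and np.isfinite(v[s]).any()]
        if rows:
            rates += per_pair * np.nansum(v[rows, :], axis=0)
    return pd.Series(rates, index=pd.Index(net.node_ids, name="node"),
                     name="arrival_rate")


def mm1k_metrics(arrival_rate, mu, capacity):
    """Stationary metrics of the M/M/1/K single-server queue with total
    capacity ``capacity`` (in service + waiting).

    p_n = ρⁿ (1−ρ) / (1−ρ^{cap+1}) for ρ ≠ 1, uniform for ρ = 1.
    Returns dict with utilization = 1 − p_0, blocking = p_cap (the loss
    fraction: under push-out ejections occur exactly when an arrival finds
    the system full, and by PASTA that fraction is p_cap), and
    mean_contents = Σ n p_n.  Vectorized over ``arrival_rate``.
    """
    if capacity < 1:
        raise ValueError("capacity must be >= 1")
    if mu <= 0:
        raise ValueError("mu must be > 0")
    rho = np.asarray(arrival_rate, dtype=float) / mu
    scalar = rho.ndim == 0
    rho = np.atleast_1d(rho)
    ns = np.arange(capacity + 1)
    p = np.empty((len(rho), capacity + 1))
    for ix, r in enumerate(rho):
        if np.isclose(r, 1.0):
            p[ix] = 1.0 / (capacity + 1)
        else:
            p[ix] = r ** ns * (1 - r) / (1 - r ** (capacity + 1))
    out = {
        "utilization": 1.0 - p[:, 0],
        "blocking": p[:, capacity],
        "mean_contents": p @ ns,
    }
    if scalar:
        out = {k: float(v[0]) for k, v in out.items()}
    return out


@dataclass
class AnalyticPrediction:
    """Per-node steady-state prediction plus network aggregates."""

    per_node: pd.DataFrame  # arrival_rate, utilization, blocking, mean_contents
    network_means: dict


def predict_stats(net: DirectedNetwork, config) -> AnalyticPrediction:
    """Decomposition prediction of node statistics for a simulation config.

    Composes :func:`node_arrival_rates` with :func:`mm1k_metrics` per node
    at capacity K+1.  Accurate when predicted blocking is small everywhere.
    """
    rates = node_arrival_rates(net, config.lambda_ext)
    m = mm1k_metrics(rates.to_numpy(), config.mu, config.buffer_size + 1)
    per_node = pd.DataFrame(
        {"arrival_rate": rates.to_numpy(), **m},
        index=rates.index,
    )
    network_means = {
        "mean_utilization": float(per_node.utilization.mean()),
        "mean_blocking": float(per_node.blocking.mean()),
        "mean_contents": float(per_node.mean_contents.mean()),
    }
    return AnalyticPrediction(per_node, network_means)


# --------------------------------------------------------------------------
# exact CTMC for tiny systems
# --------------------------------------------------------------------------

def exact_ctmc(net: DirectedNetwork, lambda_ext, mu, buffer_size,
               max_states=200_000):
    """Exact stationary statistics by brute-force CTMC enumeration.

    The state is, per node, the ordered tuple of unit destinations present:
    element 0 is in service, the rest the waiting stack (oldest first).
    Transitions are external arrivals to each (source, destination) pair at
    rate λ/(N(N−1)) and service completions at rate μ split uniformly over
    out-neighbours, with absorption, LIFO promotion and oldest-ejection
    exactly as in the simulator.  Feasible only for very small networks.

    Returns a DataFrame (node × {utilization, blocking, mean_contents}).
    """
    n = net.n_nodes
    K = buffer_size
    succ_lab = net.successors()
    succ = [[net.node_index(v) for v in succ_lab[lab]] for lab in net.node_ids]
    if any(len(s) == 0 for s in succ):
        raise ValueError("every node needs out-degree >= 1")
    pair_rate = lambda_ext / (n * (n - 1))

    def arrive(state, i, dest):
        """Return (new_state, ejected_flag) after a unit with destination
        ``dest`` arrives at node i (absorption must be excluded upstream)."""
        node = state[i]
        if not node:
            new = (dest,)
            ej = False
        elif len(node) - 1 < K:
            new = node + (dest,)
            ej = False
        else:
            # push the newcomer, eject the oldest waiting unit (index 1)
            new = (node[0],) + node[2:] + (dest,)
            ej = True
        return state[:i] + (new,) + state[i + 1:], ej

    empty = tuple(() for _ in range(n))
    index = {empty: 0}
    order = [empty]
    rows, cols, rates = [], [], []
    # per-node flow accumulators: arrival and ejection rates by state
    arr_flow = [[] for _ in range(n)]   # (state_idx, rate)
    ej_flow = [[] for _ in range(n)]
    frontier = [empty]
    while frontier:
        state = frontier.pop()
        si = index[state]
        # external arrivals
        for s in range(n):
            for d in range(n):
                if d == s:
                    continue
                new, ej = arrive(state, s, d)
                arr_flow[s].append((si, pair_rate))
                if ej:
                    ej_flow[s].append((si, pair_rate))
                if new not in index:
                    if len(index) >= max_states:
                        raise RuntimeError("state space too large for exact CTMC")
                    index[new] = len(order)
                    order.append(new)
                    frontier.append(new)
                rows.append(si)
                cols.append(index[new])
                rates.append(pair_rate)
        # service completions
        for i in range(n):
            node = state[i]
            if not node:
                continue
            dest = node[0]
            # LIFO promotion: newest waiting unit (last element) serves next
            rest = (node[-1],) + node[1:-1] if len(node) > 1 else ()
            base = state[:i] + (rest,) + state[i + 1:]
            hop_rate = mu / len(succ[i])
            for j in succ[i]:
                if j == dest:
                    new = base
                else:
                    new, ej = arrive(base, j, dest)
                    arr_flow[j].append((si, hop_rate))
                    if ej:
                        ej_flow[j].append((si, hop_rate))
                if new not in index:
                    if len(index) >= max_states:
                        raise RuntimeError("state space too large for exact CTMC")
                    index[new] = len(order)
                    order.append(new)
                    frontier.append(new)
                rows.append(si)
                cols.append(index[new])
                rates.append(hop_rate)

    m = len(order)
    q = sp.coo_matrix((rates, (rows, cols)), shape=(m, m)).tolil()
    q.setdiag(0.0)
    diag = -np.asarray(q.sum(axis=1)).ravel()
    q.setdiag(diag)
    # stationary distribution: π Q = 0, Σπ = 1
    a = q.transpose().tocsr().astype(float).tolil()
    a[-1, :] = 1.0
    b = np.zeros(m)
    b[-1] = 1.0
    pi = spla.spsolve(a.tocsc(), b)
    pi = np.maximum(pi, 0)
    pi /= pi.sum()

    contents = np.array([[len(st[i]) for i in range(n)] for st in order])
    util = pi @ (contents >= 1)
    mean_contents = pi @ contents
    blocking = np.empty(n)
    for i in range(n):
        a_rate = sum(pi[s] * r for s, r in arr_flow[i])
        e_rate = sum(pi[s] * r for s, r in ej_flow[i])
        blocking[i] = e_rate / a_rate if a_rate > 0 else np.nan
    return pd.DataFrame(
        {"utilization": util, "blocking": blocking,
         "mean_contents": mean_contents},
        index=pd.Index(net.node_ids, name="node"),
    )
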