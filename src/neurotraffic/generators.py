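"""Surrogate and synthetic directed-network generators.

Degree-matched surrogates (randomized, latticized) are produced by Markov
edge switching: a swap picks two edges (A→B, C→D) and exchanges their targets
to give (A→D, C→B), which preserves every node's in- and out-degree exactly.
Randomization accepts any swap that creates no self-loop or duplicate edge;
latticization additionally requires the swap to move edge endpoints closer
together in a fixed node ordering, driving the adjacency matrix toward the
diagonal (a ring-lattice-like topology).

Scenario networks: directed ring lattices, small-world networks (a lattice
with a fraction of edges displaced by degree-preserving swaps) and planted
rich-club networks (a dense subgraph of designated hub nodes embedded in a
sparser random graph).
"""

from __future__ import annotations

import warnings

import numpy as np

from .network import DirectedNetwork, check_simulatable

__all__ = [
    "maslov_rewire",
    "latticize",
    "lattice_cost",
    "ring_lattice",
    "small_world",
    "rich_club_synthetic",
    "random_directed",
]


class SwapExhaustionWarning(UserWarning):
    """Emitted when the swap budget is exhausted before n_swaps acceptances."""


def _swap_engine(net, n_swaps, rng, accept_extra=None, max_attempts=None,
                 stop_check=None):
    """Shared double-edge-swap loop.

    ``accept_extra(edges, i, j, new_i, new_j) -> bool`` imposes an additional
    acceptance rule (latticization's cost decrease).  ``stop_check(edges)``
    may terminate early (small-world displacement target).  Returns the new
    edge list.
    """
    edges = list(net.edges)
    edge_set = set(edges)
    m = len(edges)
    if m < 2:
        return edges
    if max_attempts is None:
        max_attempts = 100 * max(n_swaps, 1)
    accepted = attempts = 0
    while accepted < n_swaps and attempts < max_attempts:
        attempts += 1
        i = int(rng.random() * m)
        j = int(rng.random() * m)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if a == d or c == b:
            continue  # would create a self-loop
        e1, e2 = (a, d), (c, b)
        if e1 in edge_set or e2 in edge_set:
            continue  # would create a duplicate
        if accept_extra is not None and not accept_extra(edges, i, j, e1, e2):
            continue
        edge_set.discard(edges[i])
        edge_set.discard(edges[j])
        edges[i], edges[j] = e1, e2
        edge_set.add(e1)
        edge_set.add(e2)
        accepted += 1
        if stop_check is not None and stop_check(edges):
            break
    if accepted < n_swaps and attempts >= max_attempts and stop_check is None:
        warnings.warn(
            f"swap budget exhausted after {attempts} attempts "
            f"({accepted}/{n_swaps} accepted)",
            SwapExhaustionWarning,
        )
    return edges


def maslov_rewire(net, n_swaps=None, seed=None, max_attempts=None):
    """Degree-preserving randomization by repeated double-edge swaps.

    Parameters
    ----------
    n_swaps : int, optional
        Number of *accepted* swaps; rejected attempts do not count.
        Defaults to 10 per edge.
    """
    rng = np.random.default_rng(seed)
    if n_swaps is None:
        n_swaps = 10 * net.n_edges
    edges = _swap_engine(net, n_swaps, rng, max_attempts=max_attempts)
    return DirectedNetwork(list(net.node_ids), edges,
                           order_index=dict(net.order_index))


def lattice_cost(net):
    """Σ over edges of |order_index(source) − order_index(target)|."""
    oi = net.order_index
    return sum(abs(oi[u] - oi[v]) for u, v in net.edges)


def latticize(net, n_swaps=None, seed=None, max_attempts=None):
    """Degree-preserving latticization: swaps accepted only if they strictly
    reduce the total edge span in the node ordering.

    The result approximates a ring-lattice topology with the original degree
    sequence.  By default attempts continue until ``10 × edges`` consecutive
    rejections, treated as convergence (no warning).
    """
    rng = np.random.default_rng(seed)
    oi = net.order_index
    if n_swaps is None:
        n_swaps = 10 * net.n_edges

    def closer(edges, i, j, e1, e2):
        a, b = edges[i]
        c, d = edges[j]
        old = abs(oi[a] - oi[b]) + abs(oi[c] - oi[d])
        new = abs(oi[e1[0]] - oi[e1[1]]) + abs(oi[e2[0]] - oi[e2[1]])
        return new < old

    # convergence detection: stop after a run of consecutive rejections
    edges = list(net.edges)
    edge_set = set(edges)
    m = len(edges)
    if m < 2:
        return DirectedNetwork(list(net.node_ids), edges,
                               order_index=dict(net.order_index))
    reject_limit = max_attempts if max_attempts is not None else 10 * m
    accepted = 0
    consecutive_rejects = 0
    while accepted < n_swaps and consecutive_rejects < reject_limit:
        i = int(rng.random() * m)
        j = int(rng.random() * m)
        ok = False
        if i != j:
            a, b = edges[i]
            c, d = edges[j]
            if a != d and c != b:
                e1, e2 = (a, d), (c, b)
                if e1 not in edge_set and e2 not in edge_set:
                    if closer(edges, i, j, e1, e2):
                        edge_set.discard(edges[i])
                        edge_set.discard(edges[j])
                        edges[i], edges[j] = e1, e2
                        edge_set.add(e1)
                        edge_set.add(e2)
                        accepted += 1
                        consecutive_rejects = 0
                        ok = True
        if not ok:
            consecutive_rejects += 1
    return DirectedNetwork(list(net.node_ids), edges,
                           order_index=dict(net.order_index))


def ring_lattice(n, k_neighbors):
    """Directed ring lattice: node i connects to its k nearest successors and
    k nearest predecessors, giving in-degree = out-degree = 2k everywhere."""
    if n <= 2 * k_neighbors:
        raise ValueError("ring lattice requires n > 2*k_neighbors")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    nodes = [str(i) for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(1, k_neighbors + 1):
            edges.append((nodes[i], nodes[(i + j) % n]))
            edges.append((nodes[i], nodes[(i - j) % n]))
    return DirectedNetwork(nodes, edges)


def small_world(n, k_neighbors, fraction=0.10, seed=None, variant="swap"):
    """Small-world network: a ring lattice with a fraction of edges displaced.

    ``variant="swap"`` (default) uses degree-preserving double-edge swaps
    until ``ceil(fraction * edges)`` edges no longer sit at lattice positions,
    so the result is exactly degree-matched to the lattice.  ``variant="ws"``
    is the classical rewiring that points each selected edge at a uniformly
    random new target (degrees not preserved).
    """
    base = ring_lattice(n, k_neighbors)
    if fraction == 0:
        return base
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    m = base.n_edges
    target = int(np.ceil(fraction * m))
    lattice_set = set(base.edges)

    if variant == "ws":
        edges = list(base.edges)
        edge_set = set(edges)
        idx = rng.permutation(m)
        displaced = 0
        nodes = base.node_ids
        for i in idx:
            if displaced >= target:
                break
            u, _v = edges[i]
            for _ in range(100):
                w = nodes[int(rng.random() * n)]
                if w != u and (u, w) not in edge_set:
                    edge_set.discard(edges[i])
                    edges[i] = (u, w)
                    edge_set.add((u, w))
                    displaced += 1
                    break
        return DirectedNetwork(list(nodes), edges)

    def displaced_enough(edges):
        return sum(1 for e in edges if e not in lattice_set) >= target

    # plenty of headroom: each accepted swap displaces at most 2 edges
    edges = _swap_engine(base, n_swaps=100 * m, rng=rng,
                         max_attempts=10000 * m, stop_check=displaced_enough)
    if sum(1 for e in edges if e not in lattice_set) < target:
        warnings.warn("small_world displacement target not reached",
                      SwapExhaustionWarning)
    return DirectedNetwork(list(base.node_ids), edges)


def random_directed(n, p, seed=None, require_simulatable=True, max_tries=100):
    """Erdős–Rényi-style directed graph G(n, p), optionally resampled until
    every node has in- and out-degree ≥ 1."""
    rng = np.random.default_rng(seed)
    nodes = [str(i) for i in range(n)]
    for _ in range(max_tries):
        a = (rng.random((n, n)) < p)
        np.fill_diagonal(a, False)
        net = DirectedNetwork.from_adjacency(a.astype(int), nodes)
        if not require_simulatable or check_simulatable(net).ok:
            return net
    raise RuntimeError("could not generate a simulatable random graph; raise p")


def rich_club_synthetic(n=100, n_rc=20, p_local=0.05, p_feeder=0.20,
                        p_rich=0.80, seed=None, max_tries=100):
    """Planted rich-club network.

    The first ``n_rc`` nodes form the club.  Ordered pairs are connected
    independently with probability ``p_rich`` (club→club), ``p_feeder``
    (club↔non-club, both directions) or ``p_local`` (non-club→non-club).
    Regenerates until every node has in- and out-degree ≥ 1.

    Returns
    -------
    (DirectedNetwork, membership) where membership maps node → bool (in club).
    """
    for p, name in ((p_local, "p_local"), (p_feeder, "p_feeder"), (p_rich, "p_rich")):
        if not 0 < p <= 1:
            raise ValueError(f"{name} must be in (0, 1]")
    if not n_rc < n:
        raise ValueError("n_rc must be < n")
    rng = np.random.default_rng(seed)
    nodes = [str(i) for i in range(n)]
    club = np.zeros(n, dtype=bool)
    club[:n_rc] = True
    pmat = np.full((n, n), p_local)
    pmat[club, :] = p_feeder
    pmat[:, club] = p_feeder
    pmat[np.ix_(club, club)] = p_rich
    for _ in range(max_tries):
        a = rng.random((n, n)) < pmat
        np.fill_diagonal(a, False)
        net = DirectedNetwork.from_adjacency(a.astype(int), nodes)
        if check_simulatable(net).ok:
            membership = {nodes[i]: bool(club[i]) for i in range(n)}
            return net, membership
    raise RuntimeError("could not generate a simulatable rich-club graph")
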