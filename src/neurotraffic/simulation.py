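"""Discrete-event simulation of signal traffic on a directed network.

Each node is a single server with exponential service (rate μ) and a finite
push-out buffer: at most K units may wait, and an arrival finding the buffer
full evicts the *oldest* waiting unit, which is dropped.  Waiting units are
served last-come-first-served (LIFO, non-preemptive).  Signal units enter the
network as a Poisson stream with rate λ, each with an independently uniform
source and destination (source ≠ destination), and perform a uniform random
walk over out-neighbours — one hop per service completion, hops instantaneous
— until they reach their destination, where they are absorbed immediately
(no queueing at the destination).

Every unit's full trajectory (per-node arrival, service-start and departure
times) is traced, so all congestion statistics can be recomputed exactly
after the fact.  All randomness derives from a single seeded uniform stream
transformed by inversion, making runs bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from heapq import heappush, heappop

import numpy as np

from .network import DirectedNetwork, check_simulatable

__all__ = ["SimConfig", "SignalUnit", "SimTrace", "run_simulation"]


@dataclass
class SimConfig:
    """Simulation parameters.

    Parameters
    ----------
    lambda_ext : float
        External arrival rate λ of the network-global Poisson process
        (units per time unit).  In ``arrival_mode="per_node"`` each node
        sources an independent Poisson stream of rate λ (global rate N·λ,
        realised as a superposed process).
    mu : float
        Service rate μ per node.  The time scale is dimensionless; only
        λ/μ matters for the dynamics.
    buffer_size : int
        K, the number of units that may *wait* at a node; the unit in
        service occupies a separate slot, so node contents ≤ K + 1.
    t_end, t_transient : float
        Simulation horizon and default warmup cutoff for statistics.
    seed : int or SeedSequence
    arrival_mode : {"global", "per_node"}
    rng_backend : {"pcg64", "mt19937"}
    """

    lambda_ext: float = 0.1
    mu: float = 1.0
    buffer_size: int = 5
    t_end: float = 2_000_000.0
    t_transient: float = 40_000.0
    seed: object = None
    arrival_mode: str = "global"
    rng_backend: str = "pcg64"

    def __post_init__(self):
        if self.lambda_ext < 0:
            raise ValueError("lambda_ext must be >= 0")
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.buffer_size < 0:
            raise ValueError("buffer_size must be >= 0")
        if not 0 <= self.t_transient < self.t_end:
            raise ValueError("need 0 <= t_transient < t_end")
        if self.arrival_mode not in ("global", "per_node"):
            raise ValueError("arrival_mode must be 'global' or 'per_node'")
        if self.rng_backend not in ("pcg64", "mt19937"):
            raise ValueError("rng_backend must be 'pcg64' or 'mt19937'")


class SignalUnit:
    """One traced message.

    ``segments`` is an ordered list of ``[node_index, t_arrive,
    t_service_start, t_depart]``; service-start/depart are None if the unit
    was dropped while queued or is still in the network at the horizon.
    ``status`` is "in_network", "delivered" or "dropped"; ``t_final`` the
    delivery or drop time (None while in the network).
    """

    __slots__ = ("uid", "source", "destination", "t_created", "segments",
                 "status", "t_final")

    def __init__(self, uid, source, destination, t_created):
        self.uid = uid
        self.source = source
        self.destination = destination
        self.t_created = t_created
        self.segments = []
        self.status = "in_network"
        self.t_final = None

    def __repr__(self):
        return (f"SignalUnit({self.uid}, {self.source}->{self.destination}, "
                f"{self.status})")


@dataclass
class SimTrace:
    """Complete record of one simulation run."""

    net: DirectedNetwork
    config: SimConfig
    units: list
    t_end: float
    n_created: int
    n_delivered: int
    n_dropped: int
    # per-edge in-transit counts are identically zero under instantaneous
    # hops; kept so the total-load bookkeeping N(t) = Σ X_i + Σ X_ij retains
    # its channel term explicitly
    channel_contents: dict = field(default_factory=dict)

    @property
    def n_in_network(self):
        return self.n_created - self.n_delivered - self.n_dropped

    def node_label(self, idx):
        return self.net.node_ids[idx]


class _UniformStream:
    """Buffered uniform draws from a seeded bit generator (inverse-transform
    source for every random quantity in the simulation)."""

    __slots__ = ("_rng", "_buf", "_i", "_n")

    def __init__(self, seed, backend="pcg64", chunk=1 << 14):
        bitgen = np.random.MT19937(seed) if backend == "mt19937" \
            else np.random.PCG64(seed)
        self._rng = np.random.Generator(bitgen)
        self._n = chunk
        self._buf = self._rng.random(chunk)
        self._i = 0

    def __call__(self):
        i = self._i
        if i >= self._n:
            self._buf = self._rng.random(self._n)
            i = 0
        self._i = i + 1
        return self._buf[i]


def run_simulation(net: DirectedNetwork, config: SimConfig) -> SimTrace:
    """Run the discrete-event model and return the full trace.

    Requires every node to have in-degree ≥ 1 and out-degree ≥ 1.
    """
    report = check_simulatable(net)
    if not report.ok:
        raise ValueError(
            f"network not simulatable: nodes with in-degree 0: "
            f"{report.offenders_in[:5]}, out-degree 0: {report.offenders_out[:5]}"
        )
    n = net.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    succ_by_label = net.successors()
    idx = {lab: i for i, lab in enumerate(net.node_ids)}
    succ = [[idx[v] for v in succ_by_label[lab]] for lab in net.node_ids]
    n_out = [len(s) for s in succ]

    u = _UniformStream(config.seed, config.rng_backend)
    lam = config.lambda_ext * (n if config.arrival_mode == "per_node" else 1.0)
    inv_lam = 1.0 / lam if lam > 0 else math.inf
    inv_mu = 1.0 / config.mu
    K = config.buffer_size
    t_end = config.t_end
    log = math.log

    server = [None] * n          # unit in service per node
    queue = [[] for _ in range(n)]  # waiting stacks, index 0 = oldest
    units = []
    heap = []
    seq = 0
    n_delivered = 0
    n_dropped = 0

    def draw_exp(inv_rate):
        return -log(1.0 - u()) * inv_rate

    def handle_arrival(i, unit, t):
        """Buffer/queue mechanics at node i; absorption already excluded."""
        nonlocal n_dropped, seq
        unit.segments.append([i, t, None, None])
        if server[i] is None:
            server[i] = unit
            unit.segments[-1][2] = t
            seq += 1
            heappush(heap, (t + draw_exp(inv_mu), seq, i))
        else:
            q = queue[i]
            q.append(unit)
            if len(q) > K:
                old = q.pop(0)
                old.status = "dropped"
                old.t_final = t
                n_dropped += 1

    if lam > 0:
        seq += 1
        heappush(heap, (draw_exp(inv_lam), seq, -1))

    while heap:
        t, _, code = heappop(heap)
        if t > t_end:
            break
        if code == -1:
            # external arrival: draw (source, destination), inject, schedule next
            s = int(u() * n)
            d = int(u() * (n - 1))
            if d >= s:
                d += 1
            unit = SignalUnit(len(units), s, d, t)
            units.append(unit)
            handle_arrival(s, unit, t)
            seq += 1
            heappush(heap, (t + draw_exp(inv_lam), seq, -1))
        else:
            # service completion at node `code`: hop, then start next service
            i = code
            unit = server[i]
            unit.segments[-1][3] = t
            k = n_out[i]
            j = succ[i][int(u() * k)] if k > 1 else succ[i][0]
            if j == unit.destination:
                unit.status = "delivered"
                unit.t_final = t
                n_delivered += 1
            else:
                handle_arrival(j, unit, t)
            q = queue[i]
            if q:
                nxt = q.pop()  # LIFO: newest waiting unit enters service
                server[i] = nxt
                nxt.segments[-1][2] = t
                seq += 1
                heappush(heap, (t + draw_exp(inv_mu), seq, i))
            else:
                server[i] = None

    return SimTrace(net=net, config=config, units=units, t_end=t_end,
                    n_created=len(units), n_delivered=n_delivered,
                    n_dropped=n_dropped)
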