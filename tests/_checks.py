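"""Independent trace-validity oracles shared across tests.

These re-derive the queueing mechanics from each unit's recorded trajectory
alone, without reusing any simulator internals: conservation of units, edge
existence for every hop, the node-capacity bound, LIFO start order and
oldest-first ejection.
"""

import numpy as np


def iter_hops(trace):
    labels = trace.net.node_ids
    for u in trace.units:
        segs = u.segments
        for a, b in zip(segs, segs[1:]):
            yield labels[a[0]], labels[b[0]], a[3]
        if u.status == "delivered":
            yield labels[segs[-1][0]], labels[u.destination], u.t_final


def validate_trace(trace):
    """Assert every structural invariant of a simulation trace."""
    # conservation
    n_del = sum(1 for u in trace.units if u.status == "delivered")
    n_drop = sum(1 for u in trace.units if u.status == "dropped")
    n_in = sum(1 for u in trace.units if u.status == "in_network")
    assert n_del == trace.n_delivered
    assert n_drop == trace.n_dropped
    assert n_del + n_drop + n_in == trace.n_created == len(trace.units)

    # every hop follows an existing directed edge; segment times are ordered
    edge_set = trace.net.edge_set
    for u, v, t in iter_hops(trace):
        assert (u, v) in edge_set, f"hop {u}->{v} uses a non-edge"
    for u in trace.units:
        assert u.source != u.destination
        assert u.segments, "unit with no trajectory"
        prev_dep = -np.inf
        for node, t_a, t_s, t_d in u.segments:
            assert t_a >= prev_dep
            if t_s is not None:
                assert t_a <= t_s
            if t_d is not None:
                assert t_s is not None and t_s <= t_d
                prev_dep = t_d
        if u.status == "delivered":
            assert u.segments[-1][3] == u.t_final

    _check_queue_discipline(trace)


def _check_queue_discipline(trace):
    """Replay per-node events: LIFO service order, oldest-queued ejection,
    contents never above buffer_size + 1."""
    K = trace.config.buffer_size
    per_node = {}
    for u in trace.units:
        last = len(u.segments) - 1
        for si, seg in enumerate(u.segments):
            node, t_a, t_s, t_d = seg
            ev = per_node.setdefault(node, [])
            ev.append((t_a, 1, u.uid))          # arrive
            if t_s is not None:
                ev.append((t_s, 3, u.uid))      # start service
            if t_d is not None:
                ev.append((t_d, 0, u.uid))      # depart
            if u.status == "dropped" and si == last:
                ev.append((u.t_final, 2, u.uid))  # ejected while waiting
    for node, events in per_node.items():
        events.sort()
        waiting = {}   # uid -> arrival time
        in_service = None
        for t, kind, uid in events:
            if kind == 1:
                waiting[uid] = t
                assert len(waiting) + (in_service is not None) <= K + 2
            elif kind == 0:
                assert in_service == uid
                in_service = None
            elif kind == 3:
                assert uid in waiting
                # LIFO: the started unit is the most recent arrival waiting
                assert waiting[uid] == max(waiting.values())
                del waiting[uid]
                assert in_service is None
                in_service = uid
            else:
                assert uid in waiting
                # push-out: the ejected unit is the oldest one waiting, and
                # the buffer (incl. the just-arrived unit) was over capacity
                assert waiting[uid] == min(waiting.values())
                assert len(waiting) == K + 1
                del waiting[uid]
            assert len(waiting) + (in_service is not None) <= K + 1 or kind == 1
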