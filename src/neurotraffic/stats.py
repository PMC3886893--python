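"""Congestion statistics computed from simulation traces.

Four statistic families, all computed over a post-warmup observation window:

* node level — utilization (fraction of window the server is busy), blocking
  (ejections ÷ arrivals) and mean contents (time-average number of units at
  the node, waiting plus in service);
* edge level — throughput, the number of unit traversals per directed edge;
* network level — mean utilization/blocking across nodes, throughput
  (delivered units) and mean transit time of delivered units;
* path level — deliveries and mean delay per (source, destination) pair,
  with per-source and per-target marginals.

Time averages use exact piecewise-constant integration of the traced
occupancy.  A linear-interpolation pathway (resampling the event-time series
onto a uniform grid before averaging) is also provided to mirror the
uniform-resampling workflow common in simulation tooling; it is a faithful
estimator only when the series level is large relative to its unit jumps
(e.g. total network load on a loaded system) and the exact route is the
default everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulation import SimTrace

__all__ = [
    "WindowedTrace",
    "remove_transient",
    "node_stats",
    "edge_throughput",
    "network_stats",
    "path_stats",
    "load_series",
    "contents_series",
    "interpolate_uniform",
    "detect_transient",
    "hop_list",
]


@dataclass
class WindowedTrace:
    """A trace restricted to the observation window [t0, t1]."""

    trace: SimTrace
    t0: float
    t1: float

    @property
    def length(self):
        return self.t1 - self.t0


def remove_transient(trace: SimTrace, t0: float = None) -> WindowedTrace:
    """Restrict statistics to [t0, t_end); t0 defaults to config.t_transient.

    Units created before t0 but alive afterwards contribute only their
    post-t0 occupancy; delivery/drop classification uses t_final ≥ t0.
    """
    if t0 is None:
        t0 = trace.config.t_transient
    if not 0 <= t0 < trace.t_end:
        raise ValueError("need 0 <= t0 < t_end")
    return WindowedTrace(trace, float(t0), float(trace.t_end))


def _as_window(tw):
    if isinstance(tw, SimTrace):
        return WindowedTrace(tw, 0.0, tw.t_end)
    return tw


def _segment_leave_time(unit, si, t_end):
    """Time the unit ceases to occupy the node of segment si."""
    seg = unit.segments[si]
    if seg[3] is not None:
        return seg[3]
    if unit.status == "dropped":
        return unit.t_final
    return t_end  # still in the network at the horizon


def node_stats(tw, method="exact", dt=10.0) -> pd.DataFrame:
    """Per-node utilization, blocking and mean contents over the window.

    ``method="interpolated"`` computes mean contents by resampling the
    node-contents event series onto a uniform grid of step ``dt`` with
    linear interpolation before averaging (utilization and blocking are
    count/time-exact in both modes).  Blocking is NaN at nodes with no
    window arrivals.
    """
    tw = _as_window(tw)
    trace, t0, t1 = tw.trace, tw.t0, tw.t1
    n = trace.net.n_nodes
    busy = np.zeros(n)
    occupancy = np.zeros(n)
    arrivals = np.zeros(n, dtype=np.int64)
    ejections = np.zeros(n, dtype=np.int64)
    win_len = t1 - t0
    for unit in trace.units:
        segs = unit.segments
        last = len(segs) - 1
        for si, seg in enumerate(segs):
            node, t_a, t_s, t_d = seg
            if t0 <= t_a < t1:
                arrivals[node] += 1
            leave = t_d if t_d is not None else (
                unit.t_final if unit.status == "dropped" and si == last
                else trace.t_end)
            lo, hi = max(t_a, t0), min(leave, t1)
            if hi > lo:
                occupancy[node] += hi - lo
            if t_s is not None:
                s_hi = t_d if t_d is not None else trace.t_end
                lo, hi = max(t_s, t0), min(s_hi, t1)
                if hi > lo:
                    busy[node] += hi - lo
        if unit.status == "dropped" and t0 <= unit.t_final < t1:
            ejections[segs[-1][0]] += 1

    if method == "interpolated":
        for i in range(n):
            ts, xs = contents_series(trace, i)
            occupancy[i] = _windowed_interp_mean(ts, xs, t0, t1, dt) * win_len
    elif method != "exact":
        raise ValueError("method must be 'exact' or 'interpolated'")

    with np.errstate(invalid="ignore", divide="ignore"):
        blocking = np.where(arrivals > 0, ejections / np.maximum(arrivals, 1),
                            np.nan)
    return pd.DataFrame(
        {
            "utilization": busy / win_len,
            "blocking": blocking,
            "mean_contents": occupancy / win_len,
            "arrivals": arrivals,
            "ejections": ejections,
        },
        index=pd.Index(trace.net.node_ids, name="node"),
    )


def hop_list(trace: SimTrace):
    """All edge traversals as (source_idx, target_idx, time) triples.

    A hop occurs at each departure: consecutive trajectory segments give
    intermediate hops, and a delivered unit's final hop lands on its
    destination at the delivery instant.
    """
    hops = []
    for unit in trace.units:
        segs = unit.segments
        for a, b in zip(segs, segs[1:]):
            hops.append((a[0], b[0], a[3]))
        if unit.status == "delivered":
            hops.append((segs[-1][0], unit.destination, unit.t_final))
    return hops


def edge_throughput(tw, membership=None, level="RC2") -> pd.DataFrame:
    """Traversal counts per directed edge in the window.

    With a rich-club ``membership``, each edge also gets its
    rich/feeder/local class and class-mean throughputs are available via
    ``groupby("rfl_class")``.
    """
    tw = _as_window(tw)
    trace, t0, t1 = tw.trace, tw.t0, tw.t1
    labels = trace.net.node_ids
    counts = {e: 0 for e in trace.net.edges}
    for i, j, t in hop_list(trace):
        if t0 <= t < t1:
            counts[(labels[i], labels[j])] += 1
    df = pd.DataFrame(
        [(u, v, c) for (u, v), c in counts.items()],
        columns=["source", "target", "throughput"],
    )
    if membership is not None:
        from .richclub import classify_edges

        lab = classify_edges(trace.net, membership, level=level)
        df["rfl_class"] = [lab[(u, v)] for u, v in zip(df.source, df.target)]
    return df


def network_stats(tw) -> dict:
    """Network-level means: utilization, blocking, throughput, transit time.

    Throughput counts units delivered within the window; mean transit time
    averages T = t_delivered − t_created over those units only (dropped
    units never contribute).
    """
    tw = _as_window(tw)
    trace, t0, t1 = tw.trace, tw.t0, tw.t1
    ns = node_stats(tw)
    transits = [u.t_final - u.t_created for u in trace.units
                if u.status == "delivered" and t0 <= u.t_final < t1]
    n_dropped = sum(1 for u in trace.units
                    if u.status == "dropped" and t0 <= u.t_final < t1)
    return {
        "mean_utilization": float(ns.utilization.mean()),
        "mean_blocking": float(np.nanmean(ns.blocking.to_numpy()))
        if ns.arrivals.sum() else float("nan"),
        "throughput": len(transits),
        "dropped": n_dropped,
        "mean_transit_time": float(np.mean(transits)) if transits
        else float("nan"),
    }


def path_stats(tw):
    """Per (source, destination) deliveries and mean delay, plus marginals.

    Returns a dict with ``deliveries`` and ``mean_delay`` DataFrames
    (rows = sources, columns = targets; delay NaN where no deliveries) and
    ``source_marginals`` / ``target_marginals`` frames averaging each
    statistic across the other endpoint.
    """
    tw = _as_window(tw)
    trace, t0, t1 = tw.trace, tw.t0, tw.t1
    labels = trace.net.node_ids
    n = len(labels)
    deliveries = np.zeros((n, n), dtype=np.int64)
    delay_sum = np.zeros((n, n))
    for u in trace.units:
        if u.status == "delivered" and t0 <= u.t_final < t1:
            deliveries[u.source, u.destination] += 1
            delay_sum[u.source, u.destination] += u.t_final - u.t_created
    with np.errstate(invalid="ignore"):
        mean_delay = np.where(deliveries > 0,
                              delay_sum / np.maximum(deliveries, 1), np.nan)
    idx = pd.Index(labels, name="source")
    cols = pd.Index(labels, name="target")
    ddf = pd.DataFrame(deliveries, index=idx, columns=cols)
    tdf = pd.DataFrame(mean_delay, index=idx, columns=cols)
    off = ~np.eye(n, dtype=bool)
    src_marg = pd.DataFrame({
        "deliveries": [deliveries[i, off[i]].mean() for i in range(n)],
        "mean_delay": [np.nanmean(mean_delay[i, off[i]])
                       if np.isfinite(mean_delay[i, off[i]]).any() else np.nan
                       for i in range(n)],
    }, index=pd.Index(labels, name="node"))
    tgt_marg = pd.DataFrame({
        "deliveries": [deliveries[off[:, j], j].mean() for j in range(n)],
        "mean_delay": [np.nanmean(mean_delay[off[:, j], j])
                       if np.isfinite(mean_delay[off[:, j], j]).any() else np.nan
                       for j in range(n)],
    }, index=pd.Index(labels, name="node"))
    return {"deliveries": ddf, "mean_delay": tdf,
            "source_marginals": src_marg, "target_marginals": tgt_marg}


def _step_series(changes, t_end):
    """Accumulate (time, ±1) changes into a right-open step function."""
    if not changes:
        return np.array([0.0, t_end]), np.array([0.0, 0.0])
    changes.sort()
    ts, vals = [0.0], [0.0]
    level = 0.0
    for t, dv in changes:
        level += dv
        if ts[-1] == t:
            vals[-1] = level
        else:
            ts.append(t)
            vals.append(level)
    if ts[-1] < t_end:
        ts.append(t_end)
        vals.append(level)
    return np.asarray(ts), np.asarray(vals)


def load_series(trace: SimTrace):
    """Total network load N(t) = Σ_i X_i(t) + Σ_ij X_ij(t) as a step series.

    Channel contents are identically zero (hops are instantaneous), so N(t)
    jumps +1 at each unit creation and −1 at each delivery or drop.
    Returns (times, values) with values holding on [t_k, t_{k+1}).
    """
    changes = []
    for u in trace.units:
        changes.append((u.t_created, 1))
        if u.t_final is not None:
            changes.append((u.t_final, -1))
    return _step_series(changes, trace.t_end)


def contents_series(trace: SimTrace, node):
    """Node contents X_i(t) (in service + waiting) as a step series."""
    if isinstance(node, str):
        node = trace.net.node_index(node)
    changes = []
    for u in trace.units:
        last = len(u.segments) - 1
        for si, seg in enumerate(u.segments):
            if seg[0] != node:
                continue
            changes.append((seg[1], 1))
            leave = _segment_leave_time(u, si, trace.t_end)
            if leave < trace.t_end or seg[3] is not None:
                changes.append((leave, -1))
    return _step_series(changes, trace.t_end)


def interpolate_uniform(times, values, dt):
    """Linearly interpolate a time series onto a uniform grid of step dt.

    The grid spans the original support; endpoints are preserved.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size == 0:
        raise ValueError("empty series")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    grid = np.arange(times[0], times[-1] + 0.5 * dt, dt)
    if grid[-1] > times[-1]:
        grid[-1] = times[-1]
    return grid, np.interp(grid, times, values)


def _windowed_interp_mean(ts, xs, t0, t1, dt):
    grid, vals = interpolate_uniform(ts, xs, dt)
    sel = (grid >= t0) & (grid <= t1)
    return float(vals[sel].mean()) if sel.any() else float("nan")


def detect_transient(series_list, tolerance=0.05):
    """Suggest a warmup cutoff from replicate load series (ensemble-average
    method): the first grid time after which the ensemble-mean series stays
    within ``tolerance`` × its long-run level for the rest of the horizon.

    Parameters
    ----------
    series_list : list of (times, values)
        ≥ 2 replicate series sampled on a common uniform grid.

    Returns (t0, stabilized_flag); t0 is the horizon end when the ensemble
    never stabilizes.
    """
    if len(series_list) < 2:
        raise ValueError("need at least 2 replicate series")
    grid = np.asarray(series_list[0][0], dtype=float)
    for ts, _ in series_list[1:]:
        if len(ts) != len(grid) or not np.allclose(ts, grid):
            raise ValueError("replicates must share a common grid")
    ens = np.mean([vals for _, vals in series_list], axis=0)
    long_run = float(ens[len(ens) // 2:].mean())
    band = tolerance * abs(long_run)
    inside = np.abs(ens - long_run) <= band
    # first index from which `inside` holds for the remainder
    ok_from = len(ens)
    for i in range(len(ens) - 1, -1, -1):
        if inside[i]:
            ok_from = i
        else:
            break
    if ok_from >= len(ens):
        return float(grid[-1]), False
    return float(grid[ok_from]), True
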