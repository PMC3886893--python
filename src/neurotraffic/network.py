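"""Directed-network data model and file I/O.

The networks handled here are directed, unweighted and simple (no self-loops,
no duplicate edges), matching inter-regional connectivity matrices: nodes are
grey-matter regions, edges are axonal projections.  Two on-disk formats are
supported: a two-column edge-list TSV and a square 0/1 adjacency CSV with
node labels as header row and index column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DirectedNetwork",
    "DegreeRecord",
    "SimulatabilityReport",
    "read_network",
    "write_network",
    "degrees",
    "check_simulatable",
]


class NetworkValidationError(ValueError):
    """Raised when a network violates the simple-directed-graph invariants."""


@dataclass
class DirectedNetwork:
    """A simple directed graph with labelled nodes and a node ordering.

    Parameters
    ----------
    node_ids : list of str
        Node labels in declared order.  The order doubles as the default
        ``order_index`` used by latticization.
    edges : list of (str, str)
        Directed (source, target) pairs, kept in insertion order.
    order_index : dict, optional
        Integer position per node.  Defaults to list position.
    """

    node_ids: list
    edges: list
    order_index: dict = field(default=None)

    def __post_init__(self):
        self.node_ids = [str(n) for n in self.node_ids]
        self.edges = [(str(u), str(v)) for u, v in self.edges]
        nodes = set(self.node_ids)
        if len(nodes) != len(self.node_ids):
            raise NetworkValidationError("duplicate node labels")
        seen = set()
        bad_loops, bad_dups = [], []
        for e in self.edges:
            if e[0] == e[1]:
                bad_loops.append(e)
            if e in seen:
                bad_dups.append(e)
            seen.add(e)
            if e[0] not in nodes or e[1] not in nodes:
                raise NetworkValidationError(f"edge {e} references undeclared node")
        if bad_loops:
            raise NetworkValidationError(f"self-loops not allowed: {bad_loops}")
        if bad_dups:
            raise NetworkValidationError(f"duplicate edges: {bad_dups}")
        if self.order_index is None:
            self.order_index = {n: i for i, n in enumerate(self.node_ids)}
        self._edge_set = seen
        self._index = {n: i for i, n in enumerate(self.node_ids)}

    # -- basic queries -----------------------------------------------------

    @property
    def n_nodes(self):
        return len(self.node_ids)

    @property
    def n_edges(self):
        return len(self.edges)

    @property
    def edge_set(self):
        return self._edge_set

    def node_index(self, node):
        return self._index[node]

    def has_edge(self, u, v):
        return (u, v) in self._edge_set

    def successors(self):
        """Out-neighbour lists as a dict keyed by node, in edge order."""
        succ = {n: [] for n in self.node_ids}
        for u, v in self.edges:
            succ[u].append(v)
        return succ

    def adjacency_matrix(self):
        """Dense 0/1 matrix in declared node order (rows = sources)."""
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=np.int8)
        for u, v in self.edges:
            a[self._index[u], self._index[v]] = 1
        return a

    def to_networkx(self):
        g = nx.DiGraph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_adjacency(cls, matrix, node_ids=None):
        a = np.asarray(matrix)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise NetworkValidationError("adjacency matrix must be square")
        if not np.isin(a, (0, 1)).all():
            raise NetworkValidationError("adjacency entries must be 0 or 1")
        n = a.shape[0]
        if node_ids is None:
            node_ids = [str(i) for i in range(n)]
        node_ids = [str(x) for x in node_ids]
        edges = [(node_ids[i], node_ids[j]) for i, j in zip(*np.nonzero(a))]
        return cls(node_ids, edges)

    def __eq__(self, other):
        if not isinstance(other, DirectedNetwork):
            return NotImplemented
        return self.node_ids == other.node_ids and self._edge_set == other._edge_set


@dataclass
class DegreeRecord:
    """Per-node in-, out- and total degree, keyed by node label."""

    in_degree: dict
    out_degree: dict
    total_degree: dict

    def as_arrays(self, node_ids):
        ind = np.array([self.in_degree[n] for n in node_ids])
        outd = np.array([self.out_degree[n] for n in node_ids])
        return ind, outd, ind + outd


@dataclass
class SimulatabilityReport:
    min_in_ok: bool
    min_out_ok: bool
    strongly_connected: bool
    offenders_in: list
    offenders_out: list

    @property
    def ok(self):
        return self.min_in_ok and self.min_out_ok


def degrees(net: DirectedNetwork) -> DegreeRecord:
    """In/out/total degree per node; sums obey the handshake identity."""
    ind = {n: 0 for n in net.node_ids}
    outd = {n: 0 for n in net.node_ids}
    for u, v in net.edges:
        outd[u] += 1
        ind[v] += 1
    tot = {n: ind[n] + outd[n] for n in net.node_ids}
    return DegreeRecord(ind, outd, tot)


def check_simulatable(net: DirectedNetwork) -> SimulatabilityReport:
    """Report whether every node has in-degree ≥ 1 and out-degree ≥ 1.

    The random-walk dynamics require every node to be able to both receive
    and forward units.  Strong connectivity is reported but not required:
    units that can never reach their destination are eventually pushed out
    of a full buffer.
    """
    rec = degrees(net)
    off_in = [n for n in net.node_ids if rec.in_degree[n] == 0]
    off_out = [n for n in net.node_ids if rec.out_degree[n] == 0]
    sc = net.n_nodes > 0 and nx.is_strongly_connected(net.to_networkx())
    return SimulatabilityReport(not off_in, not off_out, sc, off_in, off_out)


def read_network(path, format="edge_list") -> DirectedNetwork:
    """Load a network from an edge-list TSV or adjacency CSV.

    Edge-list rows are ``source<TAB>target``; lines starting with ``#`` are
    comments.  Node order follows first appearance.  Adjacency CSVs must be
    square 0/1 with node labels as header row and first column; node order
    follows row order.
    """
    if format == "edge_list":
        edges = []
        node_ids = []
        seen_nodes = set()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                if line.startswith("#"):
                    # "#node<TAB>label" comments declare node order explicitly
                    # (emitted by write_network); other comments are skipped.
                    if line.startswith("#node\t"):
                        n = line.split("\t", 1)[1]
                        if n not in seen_nodes:
                            seen_nodes.add(n)
                            node_ids.append(n)
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise NetworkValidationError(
                        f"{path}:{lineno}: expected 'source<TAB>target', got {line!r}"
                    )
                u, v = parts
                for n in (u, v):
                    if n not in seen_nodes:
                        seen_nodes.add(n)
                        node_ids.append(n)
                edges.append((u, v))
        return DirectedNetwork(node_ids, edges)
    elif format == "adjacency":
        df = pd.read_csv(path, index_col=0)
        labels = [str(x) for x in df.index]
        if labels != [str(c) for c in df.columns]:
            raise NetworkValidationError("adjacency row and column labels differ")
        return DirectedNetwork.from_adjacency(df.to_numpy(), labels)
    raise ValueError(f"unknown format {format!r}")


def write_network(net: DirectedNetwork, path, format="edge_list"):
    """Write a network so that :func:`read_network` round-trips it exactly."""
    if format == "edge_list":
        with open(path, "w") as fh:
            fh.write("# directed edge list: source<TAB>target\n")
            # node-order declarations keep read∘write an identity even for
            # isolated nodes or orders differing from first edge appearance
            for n in net.node_ids:
                fh.write(f"#node\t{n}\n")
            for u, v in net.edges:
                fh.write(f"{u}\t{v}\n")
    elif format == "adjacency":
        a = net.adjacency_matrix()
        pd.DataFrame(a, index=net.node_ids, columns=net.node_ids).to_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path
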