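"""Rich-club coefficient, normalization against degree-matched nulls, and
node/edge classification.

A rich club is a set of high-degree nodes that are more densely connected
among themselves than expected from their degrees alone.  For each degree
threshold k, all nodes with total degree ≤ k are stripped and the density of
the surviving directed subgraph,

    φ(k) = E_{>k} / (m (m − 1)),

is computed, where E_{>k} counts surviving directed edges and m the surviving
nodes.  φ(k) is normalized by the mean φ(k) of an ensemble of degree-matched
randomized surrogates; φ_norm(k) > 1 over a range of high k indicates
rich-club organization.

Node classification assigns nested club levels: RC1 (conservative, higher
degree threshold) ⊆ RC2 (liberal).  Edges are then labelled *rich* (both
endpoints in the club), *feeder* (exactly one) or *local* (neither).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .generators import maslov_rewire
from .network import DirectedNetwork, degrees

__all__ = [
    "RichClubProfile",
    "Membership",
    "rich_club_coefficient",
    "rich_club_profile",
    "classify_nodes",
    "classify_edges",
]


def _degree_vector(net, degree_mode="total"):
    rec = degrees(net)
    ind, outd, tot = rec.as_arrays(net.node_ids)
    return {"total": tot, "in": ind, "out": outd}[degree_mode]


def rich_club_coefficient(net, k, degree_mode="total"):
    """Density φ(k) of the subgraph of nodes with degree strictly above k.

    Returns NaN when fewer than two nodes survive the stripping.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    deg = _degree_vector(net, degree_mode)
    keep = {n for n, d in zip(net.node_ids, deg) if d > k}
    m = len(keep)
    if m < 2:
        return float("nan")
    e = sum(1 for u, v in net.edges if u in keep and v in keep)
    return e / (m * (m - 1))


@dataclass
class RichClubProfile:
    k_grid: np.ndarray
    phi: np.ndarray
    phi_norm: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    n_null: int
    degree_mode: str = "total"

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"k": self.k_grid, "phi": self.phi, "null_mean": self.null_mean,
             "null_sd": self.null_sd, "phi_norm": self.phi_norm}
        )


def _phi_over_grid(net, k_grid, degree_mode):
    """φ(k) for every k, computed in one pass via sorted degrees."""
    deg = _degree_vector(net, degree_mode)
    idx = {n: i for i, n in enumerate(net.node_ids)}
    src = np.fromiter((deg[idx[u]] for u, v in net.edges), dtype=int,
                      count=net.n_edges)
    tgt = np.fromiter((deg[idx[v]] for u, v in net.edges), dtype=int,
                      count=net.n_edges)
    edge_min = np.minimum(src, tgt)
    phi = np.empty(len(k_grid))
    for i, k in enumerate(k_grid):
        m = int((deg > k).sum())
        if m < 2:
            phi[i] = np.nan
        else:
            phi[i] = int((edge_min > k).sum()) / (m * (m - 1))
    return phi


def rich_club_profile(net, n_null=100, n_swaps_per_edge=10, seed=None,
                      degree_mode="total"):
    """φ(k), null statistics, and φ_norm(k) over the full degree grid.

    ``k`` runs from the lowest to the second-highest distinct total degree.
    Each null is a degree-matched randomization of the input
    (:func:`~neurotraffic.generators.maslov_rewire` with
    ``n_swaps_per_edge`` accepted swaps per edge).  φ_norm(k) =
    φ(k) / mean_null φ(k); NaN where the null mean is zero or φ undefined.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    deg = _degree_vector(net, degree_mode)
    distinct = np.unique(deg)
    if len(distinct) < 2:
        k_grid = np.array([int(distinct[0])]) if len(distinct) else np.array([], int)
    else:
        k_grid = np.arange(int(distinct[0]), int(distinct[-2]) + 1)
    phi = _phi_over_grid(net, k_grid, degree_mode)

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_null)
    null_phis = np.empty((n_null, len(k_grid)))
    n_swaps = n_swaps_per_edge * net.n_edges
    for r in range(n_null):
        null_net = maslov_rewire(net, n_swaps=n_swaps, seed=child_seeds[r])
        null_phis[r] = _phi_over_grid(null_net, k_grid, degree_mode)
    import warnings as _warnings

    with _warnings.catch_warnings():
        # grid points where phi is undefined in every null give all-NaN
        # columns; the NaN result is the intended flag
        _warnings.simplefilter("ignore", RuntimeWarning)
        null_mean = np.nanmean(null_phis, axis=0)
        null_sd = np.nanstd(null_phis, axis=0, ddof=1) if n_null > 1 else \
            np.zeros(len(k_grid))
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_norm = np.where(null_mean > 0, phi / null_mean, np.nan)
    return RichClubProfile(k_grid, phi, phi_norm, null_mean, null_sd,
                           n_null, degree_mode)


@dataclass
class Membership:
    """Per-node rich-club level: 'RC1', 'RC2' or 'none' (RC1 ⊆ RC2)."""

    rc_level: dict

    def club(self, level):
        if level == "RC1":
            return {n for n, lv in self.rc_level.items() if lv == "RC1"}
        if level == "RC2":
            return {n for n, lv in self.rc_level.items() if lv in ("RC1", "RC2")}
        raise ValueError("level must be 'RC1' or 'RC2'")

    @classmethod
    def from_node_lists(cls, all_nodes, rc1_nodes, rc2_nodes):
        """Explicit assignment (e.g. a published club for an empirical net)."""
        rc1, rc2 = set(rc1_nodes), set(rc2_nodes)
        if not rc1 <= rc2:
            raise ValueError("RC1 must be a subset of RC2")
        lv = {}
        for n in all_nodes:
            lv[n] = "RC1" if n in rc1 else ("RC2" if n in rc2 else "none")
        return cls(lv)


def classify_nodes(net, k_rc1, k_rc2, degree_mode="total"):
    """Threshold-based nested membership: RC1 = degree > k_rc1,
    RC2 = degree > k_rc2, with k_rc1 ≥ k_rc2 so RC1 ⊆ RC2."""
    if k_rc1 < k_rc2:
        raise ValueError("k_rc1 must be >= k_rc2 (RC1 is the stricter level)")
    deg = _degree_vector(net, degree_mode)
    lv = {}
    for n, d in zip(net.node_ids, deg):
        if d > k_rc1:
            lv[n] = "RC1"
        elif d > k_rc2:
            lv[n] = "RC2"
        else:
            lv[n] = "none"
    return Membership(lv)


def classify_edges(net, membership, level="RC2"):
    """Label each edge rich / feeder / local at the given club level.

    Returns a dict edge → label.  The three label counts always partition
    the edge set.
    """
    club = membership.club(level) if isinstance(membership, Membership) \
        else set(membership)
    missing = [n for n in net.node_ids if isinstance(membership, Membership)
               and n not in membership.rc_level]
    if missing:
        raise ValueError(f"membership missing nodes: {missing[:5]}")
    labels = {}
    for u, v in net.edges:
        inside = (u in club) + (v in club)
        labels[(u, v)] = ("local", "feeder", "rich")[inside]
    return labels
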