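"""Reference graph measures: efficiency and modularity on metric networks.

These are the standard comparators for the volume entropy in the
benchmark: global efficiency (mean inverse shortest-path distance over
node pairs), average local efficiency (global efficiency of each node's
open neighbourhood subgraph) and Newman modularity of a Louvain partition.
Both efficiencies scale as ``1/c`` under a global rescaling of lengths by
``c``, which is exactly why the networks must be volume-normalized before
any cross-network comparison.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .graph import WeightedNetwork

__all__ = ["global_efficiency", "local_efficiency", "modularity"]


def _shortest_paths(D: np.ndarray) -> np.ndarray:
    return dijkstra(csr_matrix(D), directed=False)


def global_efficiency(network: WeightedNetwork) -> float:
    """Mean of ``1 / d_shortest(i, t)`` over ordered node pairs.

    Shortest paths are metric (Dijkstra on edge lengths).  Raises on
    disconnected networks, where some distances are infinite.
    """
    p = network.p
    if p < 2:
        raise ValueError("need at least two nodes")
    sp = _shortest_paths(network.distance_matrix())
    off = sp[~np.eye(p, dtype=bool)]
    if np.any(np.isinf(off)):
        raise ValueError("network is disconnected: infinite shortest paths")
    return float(np.mean(1.0 / off))


def local_efficiency(network: WeightedNetwork) -> float:
    """Mean over nodes of the efficiency of the open neighbourhood subgraph.

    For each node, take the subgraph induced on its neighbours (the node
    itself excluded, original edge lengths kept) and compute its global
    efficiency, treating disconnected neighbour pairs as contributing 0;
    nodes with fewer than two neighbours contribute 0.  A triangle-free
    network therefore has local efficiency exactly 0.
    """
    D = network.distance_matrix()
    adj = network.adjacency_lists()
    effs = []
    for v in range(network.p):
        nbrs = adj[v]
        m = len(nbrs)
        if m < 2:
            effs.append(0.0)
            continue
        sub = D[np.ix_(nbrs, nbrs)]
        sp = _shortest_paths(sub)
        off = sp[~np.eye(m, dtype=bool)]
        with np.errstate(divide="ignore"):
            inv = np.where(np.isinf(off), 0.0, 1.0 / off)
        effs.append(float(np.mean(inv)))
    return float(np.mean(effs))


def modularity(
    network: WeightedNetwork,
    seed: int = 0,
    weight: str = "inverse_distance",
    resolution: float = 1.0,
) -> float:
    """Newman modularity ``Q`` of the best Louvain partition.

    Community detection needs *similarity* weights, whereas the network
    carries metric lengths; by default each edge gets weight ``1/l(e)``
    (``weight="unit"`` ignores lengths).  Deterministic for a fixed seed.
    """
    if weight not in ("inverse_distance", "unit"):
        raise ValueError("weight must be 'inverse_distance' or 'unit'")
    G = nx.Graph()
    G.add_nodes_from(range(network.p))
    for (u, v), l in zip(network.edge_pairs, network.lengths):
        w = 1.0 / l if weight == "inverse_distance" else 1.0
        G.add_edge(u, v, weight=w)
    communities = nx.community.louvain_communities(
        G, weight="weight", seed=seed, resolution=resolution
    )
    return float(
        nx.community.modularity(G, communities, weight="weight", resolution=resolution)
    )
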