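"""Synthetic networks and measurement matrices for benchmarking.

Provides the five artificial topologies used in the simulation study —
regular ring lattice (RE), Watts-Strogatz small world (SW), Erdos-Renyi
random (RA), Barabasi-Albert scale free (SF) and random hyperbolic (HY) —
at a requested edge sparsity, the three geometry schemes that assign edge
lengths from node degrees (uniform U, degree-proportional L,
inverse-degree S), and a modular Gaussian time-series generator that
emulates community-structured ROI signals feeding the kernel pipeline.

Topologies are emitted with unit edge lengths (the "unweighted" case);
:func:`apply_geometry` assigns lengths and volume-normalizes.  All
generators are deterministic given a seed and only return networks that
pass validation (connected, minimum degree 2).
"""

from __future__ import annotations

from typing import Hashable, Sequence

import networkx as nx
import numpy as np

from .graph import WeightedNetwork, normalize_volume, validate
from .kernel import MeasurementMatrix

__all__ = [
    "generate_topology",
    "apply_geometry",
    "synthetic_timeseries",
    "TOPOLOGY_KINDS",
    "GEOMETRY_SCHEMES",
]

TOPOLOGY_KINDS = ("RE", "SW", "RA", "SF", "HY")
GEOMETRY_SCHEMES = ("U", "L", "S")

#: rewiring probability of the small-world generator
SW_REWIRING = 0.1
#: radial density exponent of the hyperbolic generator (power-law exponent
#: gamma = 2 * alpha + 1 = 2.5, the regime of strongly heterogeneous degrees)
HY_ALPHA = 0.75

_MAX_RETRIES = 500


def _from_nx(G: nx.Graph) -> WeightedNetwork:
    return WeightedNetwork.from_edges(
        [(int(u), int(v), 1.0) for u, v in G.edges()],
        labels=sorted(int(v) for v in G.nodes()),
    )


def generate_topology(
    kind: str,
    p: int = 16,
    sparsity: float = 0.27,
    seed: int | None = None,
) -> WeightedNetwork:
    """Generate one of the five benchmark topologies with unit lengths.

    Parameters
    ----------
    kind
        "RE" ring lattice, "SW" Watts-Strogatz (rewiring 0.1), "RA"
        Erdos-Renyi G(n, M), "SF" Barabasi-Albert, "HY" random hyperbolic
        disk graph.
    p
        Number of nodes.  The default is the benchmark scale at which the
        five topologies and the three degree-based geometries are cleanly
        separated by the volume entropy; see the methods documentation for
        why the degree-proportional geometry contrast washes out on much
        larger dense graphs.
    sparsity
        Fraction of realized node pairs in (0, 1]; every kind realizes
        exactly ``floor(sparsity * p * (p-1) / 2)`` edges so that
        cross-topology comparisons are made at identical volume.
    seed
        Seeds all randomness; the same seed gives a bit-identical network.

    Invalid draws (disconnected, or with a degree-1 node) are regenerated
    with fresh sub-seeds up to a retry cap.
    """
    if kind not in TOPOLOGY_KINDS:
        raise ValueError(f"unknown topology kind {kind!r}; choose from {TOPOLOGY_KINDS}")
    if not (0 < sparsity <= 1):
        raise ValueError("sparsity must be in (0, 1]")
    if p < 4:
        raise ValueError("need at least 4 nodes")
    M = int(np.floor(sparsity * p * (p - 1) / 2))
    rng = np.random.default_rng(seed)
    last_msgs: tuple[str, ...] = ()
    for _ in range(_MAX_RETRIES):
        sub = int(rng.integers(0, 2**31 - 1))
        G = _draw_topology(kind, p, M, sub)
        net = _from_nx(G)
        report = validate(net)
        if report.ok:
            return net
        last_msgs = report.messages
    raise RuntimeError(
        f"could not generate a valid {kind} network at sparsity {sparsity} "
        f"after {_MAX_RETRIES} attempts ({'; '.join(last_msgs)}); "
        "sparsity is probably too low for connectivity"
    )


def _draw_topology(kind: str, p: int, M: int, seed: int) -> nx.Graph:
    if kind == "RE":
        return _ring_lattice(p, M)
    if kind == "SW":
        return _rewire(_ring_lattice(p, M), SW_REWIRING, seed)
    if kind == "RA":
        return nx.gnm_random_graph(p, M, seed=seed)
    if kind == "SF":
        # BA with attachment m gives m * (p - m) edges; take the m that
        # overshoots least, then trim random edges back to exactly M so the
        # five topologies are compared at identical sparsity
        cands = [m for m in range(1, p) if m * (p - m) >= M] or [p // 2]
        m = min(cands, key=lambda mm: mm * (p - mm) - M)
        G = nx.barabasi_albert_graph(p, m, seed=seed)
        _trim_edges(G, M, seed)
        return G
    if kind == "HY":
        return _hyperbolic_graph(p, M, seed)
    raise AssertionError(kind)


def _ring_lattice(p: int, M: int) -> nx.Graph:
    """Near-regular ring lattice with exactly ``M`` edges.

    Full rings of chord distance 1, 2, ... as far as they fit; the
    remaining edges are chords of the next ring distance placed greedily on
    the lowest-degree nodes, keeping the degree spread at most 1 in the
    typical case.
    """
    G = nx.Graph()
    G.add_nodes_from(range(p))
    d = 1
    while G.number_of_edges() + p <= M:
        if d > (p - 1) // 2:
            break
        for i in range(p):
            G.add_edge(i, (i + d) % p)
        d += 1
    while G.number_of_edges() < M:
        if d > p // 2:
            raise ValueError(f"cannot place {M} edges on a {p}-node ring lattice")
        cands = [
            i for i in range(p)
            if (i + d) % p != i and not G.has_edge(i, (i + d) % p)
        ]
        if not cands:
            d += 1
            continue
        best = min(cands, key=lambda i: (G.degree(i) + G.degree((i + d) % p), i))
        G.add_edge(best, (best + d) % p)
    return G


def _rewire(G: nx.Graph, beta: float, seed: int) -> nx.Graph:
    """Watts-Strogatz rewiring: each edge moves its far endpoint w.p. beta."""
    rng = np.random.default_rng(seed)
    p = G.number_of_nodes()
    for u, v in list(G.edges()):
        if rng.uniform() < beta:
            for _ in range(50):
                w = int(rng.integers(p))
                if w != u and not G.has_edge(u, w):
                    G.remove_edge(u, v)
                    G.add_edge(u, w)
                    break
    return G


def _trim_edges(G: nx.Graph, M: int, seed: int) -> None:
    """Remove random edges down to ``M``, keeping degrees >= 2."""
    rng = np.random.default_rng(seed + 1)
    edges = list(G.edges())
    rng.shuffle(edges)
    for u, v in edges:
        if G.number_of_edges() <= M:
            break
        if G.degree(u) > 2 and G.degree(v) > 2:
            G.remove_edge(u, v)


def _hyperbolic_graph(p: int, M: int, seed: int) -> nx.Graph:
    """Random hyperbolic disk graph with exactly ``M`` edges.

    Nodes are placed on a hyperbolic disk of radius ``R = 2 log p`` with
    radial density ~ exp(HY_ALPHA * r) and uniform angles; the ``M`` node
    pairs with smallest hyperbolic distance are connected.  Thresholding at
    the M-th smallest distance is the standard disk model with the
    connection radius chosen to hit the target sparsity exactly.
    """
    rng = np.random.default_rng(seed)
    R = 2.0 * np.log(p)
    u = rng.uniform(size=p)
    # inverse-CDF of density ~ alpha * sinh(alpha r) / (cosh(alpha R) - 1)
    r = np.arccosh(1.0 + u * (np.cosh(HY_ALPHA * R) - 1.0)) / HY_ALPHA
    theta = rng.uniform(0.0, 2.0 * np.pi, size=p)
    dtheta = np.pi - np.abs(np.pi - np.abs(theta[:, None] - theta[None, :]))
    arg = (
        np.cosh(r)[:, None] * np.cosh(r)[None, :]
        - np.sinh(r)[:, None] * np.sinh(r)[None, :] * np.cos(dtheta)
    )
    dist = np.arccosh(np.maximum(arg, 1.0))
    iu, jv = np.triu_indices(p, k=1)
    order = np.argsort(dist[iu, jv], kind="stable")[:M]
    G = nx.Graph()
    G.add_nodes_from(range(p))
    G.add_edges_from(zip(iu[order], jv[order]))
    return G


def apply_geometry(network: WeightedNetwork, scheme: str) -> WeightedNetwork:
    """Assign degree-based edge lengths and volume-normalize.

    "U": all lengths equal.  "L": length proportional to the sum of the
    endpoint degrees (hub edges are long — slow information flow).  "S":
    length inversely proportional to that sum (hub edges are short — fast
    flow).  On a regular graph all three collapse to the same network after
    normalization.
    """
    if scheme not in GEOMETRY_SCHEMES:
        raise ValueError(f"unknown geometry scheme {scheme!r}; choose from {GEOMETRY_SCHEMES}")
    deg = network.degrees()
    if scheme == "U":
        lengths = np.ones(network.n_edges)
    else:
        dsum = np.array([deg[u] + deg[v] for u, v in network.edge_pairs], dtype=float)
        lengths = dsum if scheme == "L" else 1.0 / dsum
    net = WeightedNetwork(
        labels=network.labels,
        edge_pairs=network.edge_pairs,
        lengths=lengths,
    )
    return normalize_volume(net)


def synthetic_timeseries(
    p: int = 90,
    n: int = 112,
    n_modules: int = 5,
    within_corr: float = 0.5,
    between_corr: float = 0.1,
    seed: int | None = None,
    labels: Sequence[Hashable] | None = None,
) -> MeasurementMatrix:
    """Modular multivariate-Gaussian signals emulating ROI measurements.

    Rows are grouped into ``n_modules`` contiguous communities; the target
    correlation is ``within_corr`` inside a community and ``between_corr``
    across communities (unit variances).  Defaults match the shape of a
    parcellated resting-state recording (90 ROIs, 112 time points) with a
    moderately modular correlation structure.

    Requires ``0 <= between_corr < within_corr < 1`` so the target matrix
    is positive definite; if a custom combination fails the Cholesky
    factorization, shrink the off-diagonal values toward zero.
    """
    if not (0 <= between_corr < within_corr < 1):
        raise ValueError("need 0 <= between_corr < within_corr < 1")
    if n_modules < 1 or n_modules > p:
        raise ValueError("n_modules must be between 1 and p")
    module = np.repeat(np.arange(n_modules), int(np.ceil(p / n_modules)))[:p]
    R = np.full((p, p), between_corr)
    same = module[:, None] == module[None, :]
    R[same] = within_corr
    np.fill_diagonal(R, 1.0)
    try:
        chol = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "target correlation matrix is not positive definite; shrink "
            "within_corr/between_corr toward zero"
        ) from exc
    rng = np.random.default_rng(seed)
    X = chol @ rng.standard_normal((p, n))
    if labels is None:
        width = len(str(p))
        labels = tuple(f"roi{str(i + 1).zfill(width)}" for i in range(p))
    return MeasurementMatrix(values=X, labels=tuple(labels))
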