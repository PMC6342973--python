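"""Weighted metric graphs and their oriented-edge representation.

A :class:`WeightedNetwork` is a connected, undirected graph in which every
edge ``e`` carries a positive length ``l(e)``.  The information-flow model
treats each undirected edge as a pair of oriented edges of equal length, so
the *oriented volume* of the network is ``2 * sum(l(e))`` over undirected
edges.  The convention used throughout the package is that a *normalized*
network has oriented volume exactly 2 (equivalently, undirected length sum 1).

Entropy calculations additionally require that the graph has no terminal
node, i.e. minimum degree two: a path that reaches a degree-1 node has no
non-backtracking continuation and the covering tree stops growing there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "WeightedNetwork",
    "OrientedEdgeSet",
    "ValidationReport",
    "orient",
    "normalize_volume",
    "validate",
]

#: relative length threshold below which an edge is treated as degenerate
DEGENERATE_LENGTH_FACTOR = 1e-12


@dataclass(frozen=True)
class WeightedNetwork:
    """Undirected graph with positive edge lengths.

    Parameters
    ----------
    labels
        Ordered node identifiers; node *indices* used everywhere else refer
        to positions in this tuple.
    edge_pairs
        Undirected edges as ``(u, v)`` index pairs with ``u < v``, sorted
        lexicographically.  Parallel edges and self-loops are rejected.
    lengths
        Positive length per edge, aligned with ``edge_pairs``.
    original_volume
        Oriented volume of the network this one was rescaled from, recorded
        by :func:`normalize_volume` so that entropies can be mapped back to
        the unnormalized scale.  ``None`` for networks built directly.
    """

    labels: tuple[Hashable, ...]
    edge_pairs: tuple[tuple[int, int], ...]
    lengths: np.ndarray
    original_volume: float | None = None

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=float)
        object.__setattr__(self, "lengths", lengths)
        p = len(self.labels)
        if len(set(self.labels)) != p:
            raise ValueError("node labels must be unique")
        if lengths.shape != (len(self.edge_pairs),):
            raise ValueError("lengths must align with edge_pairs")
        seen: set[tuple[int, int]] = set()
        for u, v in self.edge_pairs:
            if u == v:
                raise ValueError(f"self-loop at node index {u} is not allowed")
            if not (0 <= u < p and 0 <= v < p):
                raise ValueError(f"edge ({u},{v}) references unknown node index")
            if u > v:
                raise ValueError("edge pairs must be stored as (min, max)")
            if (u, v) in seen:
                raise ValueError(f"parallel edge ({u},{v}) is not allowed")
            seen.add((u, v))
        if list(self.edge_pairs) != sorted(self.edge_pairs):
            raise ValueError("edge pairs must be sorted lexicographically")
        if lengths.size and not np.all(np.isfinite(lengths)):
            raise ValueError("edge lengths must be finite")
        if np.any(lengths <= 0):
            raise ValueError("all edge lengths must be positive")
        if lengths.size:
            floor = DEGENERATE_LENGTH_FACTOR * float(lengths.mean())
            if np.any(lengths < floor):
                raise ValueError(
                    "edge lengths below 1e-12 of the mean length are "
                    "numerically degenerate"
                )

    # ------------------------------------------------------------------ #
    # constructors

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[Hashable, Hashable, float]],
        labels: Sequence[Hashable] | None = None,
    ) -> "WeightedNetwork":
        """Build a network from ``(u, v, length)`` triples with node labels."""
        triples = list(edges)
        if labels is None:
            seen: dict[Hashable, None] = {}
            for u, v, _ in triples:
                seen.setdefault(u)
                seen.setdefault(v)
            labels = sorted(seen, key=str)
        index = {lab: i for i, lab in enumerate(labels)}
        pairs: dict[tuple[int, int], float] = {}
        for u, v, l in triples:
            iu, iv = index[u], index[v]
            key = (min(iu, iv), max(iu, iv))
            if key in pairs:
                raise ValueError(f"parallel edge between {u!r} and {v!r}")
            pairs[key] = float(l)
        ordered = sorted(pairs)
        return cls(
            labels=tuple(labels),
            edge_pairs=tuple(ordered),
            lengths=np.array([pairs[k] for k in ordered], dtype=float),
        )

    @classmethod
    def from_distance_matrix(
        cls,
        D: np.ndarray,
        labels: Sequence[Hashable] | None = None,
    ) -> "WeightedNetwork":
        """Build a network from a symmetric distance matrix.

        Zero (or missing/NaN) off-diagonal entries mean "no edge"; the
        diagonal is ignored.
        """
        D = np.asarray(D, dtype=float)
        p = D.shape[0]
        if D.shape != (p, p):
            raise ValueError("distance matrix must be square")
        if labels is None:
            labels = tuple(range(p))
        if not np.allclose(np.nan_to_num(D), np.nan_to_num(D.T), atol=0, rtol=0):
            raise ValueError("distance matrix must be symmetric")
        edges = []
        for u in range(p):
            for v in range(u + 1, p):
                d = D[u, v]
                if np.isfinite(d) and d != 0.0:
                    if d < 0:
                        raise ValueError("negative distances are not allowed")
                    edges.append((labels[u], labels[v], float(d)))
        return cls.from_edges(edges, labels=labels)

    # ------------------------------------------------------------------ #
    # basic properties

    @property
    def p(self) -> int:
        """Number of nodes."""
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        """Number of undirected edges."""
        return len(self.edge_pairs)

    @property
    def oriented_volume(self) -> float:
        """Sum of lengths over oriented edges (each undirected edge twice)."""
        return 2.0 * float(self.lengths.sum())

    @property
    def is_normalized(self) -> bool:
        return abs(self.oriented_volume - 2.0) <= 1e-9

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.p, dtype=int)
        for u, v in self.edge_pairs:
            deg[u] += 1
            deg[v] += 1
        return deg

    def adjacency_lists(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.p)]
        for u, v in self.edge_pairs:
            adj[u].append(v)
            adj[v].append(u)
        return adj

    def distance_matrix(self) -> np.ndarray:
        """Dense node-by-node length matrix with zeros for absent edges."""
        D = np.zeros((self.p, self.p))
        for (u, v), l in zip(self.edge_pairs, self.lengths):
            D[u, v] = D[v, u] = l
        return D

    def length_of(self, u: Hashable, v: Hashable) -> float:
        """Length of the edge between two node labels."""
        iu = self.labels.index(u)
        iv = self.labels.index(v)
        key = (min(iu, iv), max(iu, iv))
        try:
            k = self.edge_pairs.index(key)
        except ValueError:
            raise KeyError(f"no edge between {u!r} and {v!r}") from None
        return float(self.lengths[k])

    def relabeled(self, mapping: Mapping[Hashable, Hashable]) -> "WeightedNetwork":
        """Return the same graph with nodes renamed via ``mapping``."""
        return WeightedNetwork.from_edges(
            [
                (mapping[self.labels[u]], mapping[self.labels[v]], l)
                for (u, v), l in zip(self.edge_pairs, self.lengths)
            ]
        )


@dataclass(frozen=True)
class OrientedEdgeSet:
    """Indexed oriented (directed) edges of a :class:`WeightedNetwork`.

    Undirected edge ``k`` (in the canonical sorted order) becomes oriented
    edges ``2k`` (min-node -> max-node) and ``2k + 1`` (the reverse), so the
    reversal involution is simply ``e ^ 1``.
    """

    p: int
    init: np.ndarray  # initial node index per oriented edge
    term: np.ndarray  # terminal node index per oriented edge
    length: np.ndarray  # l(e) = l(reverse(e))
    labels: tuple[Hashable, ...] = field(default=(), repr=False)

    @property
    def q(self) -> int:
        """Number of oriented edges (twice the undirected count)."""
        return len(self.init)

    def reverse(self, e: int) -> int:
        return e ^ 1

    def describe(self, e: int) -> tuple[Hashable, Hashable]:
        """Labels ``(i(e), t(e))`` of an oriented edge."""
        return self.labels[self.init[e]], self.labels[self.term[e]]

    def index_of(self, u: Hashable, v: Hashable) -> int:
        """Index of the oriented edge from label ``u`` to label ``v``."""
        iu = self.labels.index(u)
        iv = self.labels.index(v)
        hits = np.flatnonzero((self.init == iu) & (self.term == iv))
        if hits.size == 0:
            raise KeyError(f"no oriented edge {u!r} -> {v!r}")
        return int(hits[0])

    def successors(self) -> list[np.ndarray]:
        """Non-backtracking successor edges ``f`` of each ``e``.

        ``f`` succeeds ``e`` iff ``t(e) = i(f)`` and ``f != reverse(e)``.
        """
        by_init: list[list[int]] = [[] for _ in range(self.p)]
        for f in range(self.q):
            by_init[self.init[f]].append(f)
        out: list[np.ndarray] = []
        for e in range(self.q):
            cands = [f for f in by_init[self.term[e]] if f != (e ^ 1)]
            out.append(np.array(cands, dtype=np.int64))
        return out


@dataclass(frozen=True)
class ValidationReport:
    """Diagnostic summary of the entropy-solver preconditions."""

    connected: bool
    min_degree: int
    positive_lengths: bool
    n_nodes: int
    n_edges: int
    messages: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return self.connected and self.min_degree >= 2 and self.positive_lengths


def validate(network: WeightedNetwork) -> ValidationReport:
    """Check connectivity, minimum degree and length positivity.

    The report is diagnostic: it never raises.  ``report.ok`` is True iff
    the network satisfies every precondition of the entropy solver
    (connected, no terminal node, strictly positive lengths — positivity is
    already enforced by the constructor but re-reported here).
    """
    msgs: list[str] = []
    deg = network.degrees() if network.p else np.array([], dtype=int)
    min_deg = int(deg.min()) if deg.size else 0
    if min_deg < 2:
        msgs.append(
            f"terminal node(s) present: minimum degree {min_deg} < 2"
        )
    connected = _is_connected(network)
    if not connected:
        msgs.append("graph is not connected")
    positive = bool(np.all(network.lengths > 0)) if network.n_edges else True
    if not positive:
        msgs.append("non-positive edge length")
    return ValidationReport(
        connected=connected,
        min_degree=min_deg,
        positive_lengths=positive,
        n_nodes=network.p,
        n_edges=network.n_edges,
        messages=tuple(msgs),
    )


def _is_connected(network: WeightedNetwork) -> bool:
    if network.p == 0:
        return False
    adj = network.adjacency_lists()
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == network.p


def require_valid(network: WeightedNetwork) -> None:
    """Raise ``ValueError`` with the diagnostic messages if invalid."""
    report = validate(network)
    if not report.ok:
        raise ValueError(
            "invalid network: " + "; ".join(report.messages)
        )


def normalize_volume(network: WeightedNetwork) -> WeightedNetwork:
    """Rescale edge lengths so the oriented volume equals 2.

    The oriented volume counts both orientations of every undirected edge,
    so after normalization the undirected length sum is 1.  The input's
    oriented volume is recorded on the result (``original_volume``) so the
    entropy of the unnormalized network can be recovered via the rescaling
    identity ``h_unnormalized = (2 / volume) * h_normalized``.

    Idempotent: a network already at volume 2 is returned with identical
    lengths.
    """
    if network.n_edges == 0:
        raise ValueError("cannot normalize a network with no edges")
    vol = network.oriented_volume
    if vol <= 0:
        raise ValueError("volume must be positive")
    scale = 2.0 / vol
    return replace(
        network,
        lengths=network.lengths * scale,
        original_volume=vol,
    )


def orient(network: WeightedNetwork) -> OrientedEdgeSet:
    """Split each undirected edge into its two orientations.

    Edges are indexed canonically: undirected edges sorted by
    ``(min node, max node)``, forward orientation (min -> max) before the
    reverse.  This makes every downstream result reproducible across runs.
    """
    require_valid(network)
    m = network.n_edges
    init = np.empty(2 * m, dtype=np.int64)
    term = np.empty(2 * m, dtype=np.int64)
    length = np.empty(2 * m, dtype=float)
    for k, ((u, v), l) in enumerate(zip(network.edge_pairs, network.lengths)):
        init[2 * k], term[2 * k] = u, v
        init[2 * k + 1], term[2 * k + 1] = v, u
        length[2 * k] = length[2 * k + 1] = l
    return OrientedEdgeSet(
        p=network.p, init=init, term=term, length=length, labels=network.labels
    )


def ensure_normalized(network: WeightedNetwork) -> WeightedNetwork:
    """Return a volume-2 version of the network, warning if rescaled."""
    if network.is_normalized:
        return network
    warnings.warn(
        "network volume is not 2; normalizing before solving "
        f"(oriented volume was {network.oriented_volume:.6g})",
        stacklevel=3,
    )
    return normalize_volume(network)
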