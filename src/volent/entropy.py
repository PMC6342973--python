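"""Volume entropy and information-flow capacities via the edge-transition matrix.

The information-propagation model places a generalized Markov system on the
oriented edges of a metric graph.  For an entropy parameter ``h >= 0`` the
edge-transition matrix is the sparse ``q x q`` matrix

    L_ef(h) = a_ef * exp(-h * l(f)),

where ``a_ef = 1`` iff the oriented edge ``f`` continues ``e`` without
backtracking (``t(e) = i(f)`` and ``f != reverse(e)``).  The volume entropy
``h_vol`` is the unique ``h`` at which the Perron root of ``L(h)`` equals 1;
the corresponding positive eigenvector ``z`` (normalized to sum 1) is the
stationary distribution of information flow, interpreted edge-wise as *edge
capacity* and aggregated node-wise as *node capacity* (incoming minus
outgoing mass).

``rho(L(h))`` is strictly decreasing in ``h`` for a connected graph of
minimum degree two, so the root is found by bracketing and Brent's method on
``log rho(L(h))``.  Graphs whose non-backtracking adjacency has spectral
radius <= 1 (cycles) are *non-expansive*: path counts grow at most linearly
and ``h_vol = 0`` is reported with a flag rather than an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import brentq

from .graph import (
    OrientedEdgeSet,
    WeightedNetwork,
    ensure_normalized,
    orient,
)

__all__ = [
    "EntropyResult",
    "CapacityTables",
    "edge_transition_matrix",
    "spectral_radius",
    "solve_volume_entropy",
    "stationary_distribution",
    "edge_capacity_matrix",
    "node_capacities",
    "rescale_unnormalized_entropy",
    "capacity_tables",
]

_DENSE_CUTOFF = 300  # dense eigensolver below, ARPACK above


def _transition_structure(edges: OrientedEdgeSet) -> tuple[np.ndarray, np.ndarray]:
    """Row/column index arrays of the non-backtracking adjacency a_ef."""
    q = edges.q
    by_init: list[list[int]] = [[] for _ in range(edges.p)]
    for f in range(q):
        by_init[edges.init[f]].append(f)
    rows: list[int] = []
    cols: list[int] = []
    for e in range(q):
        rev = e ^ 1
        for f in by_init[edges.term[e]]:
            if f != rev:
                rows.append(e)
                cols.append(f)
    return np.asarray(rows, dtype=np.int64), np.asarray(cols, dtype=np.int64)


def edge_transition_matrix(
    edges: OrientedEdgeSet, h: float
) -> sp.csr_matrix:
    """Sparse edge-transition matrix ``L(h)`` on the oriented edges.

    At ``h = 0`` this is the 0/1 non-backtracking adjacency matrix; for
    ``h > 0`` each admissible transition into edge ``f`` is damped by
    ``exp(-h * l(f))``.
    """
    if h < 0:
        raise ValueError("entropy parameter h must be nonnegative")
    rows, cols = _transition_structure(edges)
    data = np.exp(-h * edges.length[cols])
    return sp.csr_matrix((data, (rows, cols)), shape=(edges.q, edges.q))


def _perron(
    L: sp.spmatrix,
    v0: np.ndarray | None = None,
    need_vector: bool = True,
) -> tuple[float, np.ndarray | None]:
    """Largest-magnitude eigenpair of a nonnegative matrix.

    Dense solve for small systems (eigenvalues only when the vector is not
    needed, which roughly halves the root-finder cost); ARPACK
    (warm-started when ``v0`` is given) for large ones, with a dense
    fallback on convergence failure.
    """
    q = L.shape[0]
    if q == 1:
        return float(L[0, 0]), np.ones(1)
    if q <= _DENSE_CUTOFF:
        A = L.toarray() if sp.issparse(L) else np.asarray(L)
        if not need_vector:
            vals = np.linalg.eigvals(A)
            return float(np.max(np.abs(vals))), None
        vals, vecs = np.linalg.eig(A)
        k = int(np.argmax(np.abs(vals)))
        return float(np.abs(vals[k])), np.real(vecs[:, k])
    try:
        vals, vecs = spla.eigs(L.astype(float), k=1, which="LM", v0=v0, maxiter=5000)
        return float(np.abs(vals[0])), np.real(vecs[:, 0])
    except (spla.ArpackNoConvergence, spla.ArpackError) as exc:  # pragma: no cover
        A = L.toarray()
        vals, vecs = np.linalg.eig(A)
        k = int(np.argmax(np.abs(vals)))
        if not np.isfinite(vals[k]):
            raise RuntimeError(f"eigensolver failed: {exc}") from exc
        return float(np.abs(vals[k])), np.real(vecs[:, k])


def spectral_radius(L: sp.spmatrix | np.ndarray) -> float:
    """Perron root (largest-magnitude eigenvalue) of a nonnegative matrix."""
    M = sp.csr_matrix(L) if not sp.issparse(L) else L
    if M.nnz and M.data.min() < 0:
        raise ValueError("spectral_radius expects a nonnegative matrix")
    rho, _ = _perron(M)
    return rho


@dataclass(frozen=True)
class EntropyResult:
    """Solved volume entropy with diagnostics.

    Attributes
    ----------
    h_vol
        Volume entropy of the (normalized) network: the root of
        ``rho(L(h)) = 1``.
    z
        Stationary edge distribution: positive, sums to 1, indexed like the
        oriented edges.
    residual
        ``|rho(L(h_vol)) - 1|`` at the solution.
    iterations
        Number of spectral-radius evaluations spent by the root finder.
    normalized_input
        Whether the input already had oriented volume 2.
    unnormalized_h_vol
        Entropy on the scale of the original (unnormalized) lengths, via
        the rescaling identity; equals ``h_vol`` when the input was already
        normalized and no earlier volume was recorded.
    non_expansive
        True when path counts do not grow exponentially (``rho(L(0)) <= 1``,
        e.g. cycles); then ``h_vol = 0``.
    q, p
        Oriented-edge and node counts.
    """

    h_vol: float
    z: np.ndarray
    residual: float
    iterations: int
    normalized_input: bool
    unnormalized_h_vol: float
    non_expansive: bool
    q: int
    p: int
    edges: OrientedEdgeSet


def solve_volume_entropy(
    network: WeightedNetwork,
    tol: float = 1e-10,
    bracket_hint: float | None = None,
    compute_stationary: bool = True,
) -> EntropyResult:
    """Solve the stationary equation for the volume entropy.

    The network is volume-normalized first (with a warning if it was not
    already).  ``g(h) = log rho(L(h))`` is strictly decreasing, so the root
    is bracketed by doubling and polished with Brent's method.

    Parameters
    ----------
    network
        Valid weighted network (connected, min degree 2, positive lengths).
    tol
        Bound on the residual ``|rho(L(h_vol)) - 1|``.
    bracket_hint
        Optional initial guess for ``h_vol`` used to seed the bracket; a
        good hint (e.g. the solution for a nearby network) cuts the number
        of eigensolves roughly in half.
    compute_stationary
        When False, skip the eigenvector extraction and return an empty
        ``z`` (useful in permutation loops that only need ``h_vol``).
    """
    was_normalized = network.is_normalized
    prior_volume = network.original_volume
    net = ensure_normalized(network)
    edges = orient(net)
    rows, cols = _transition_structure(edges)
    lengths = edges.length
    q = edges.q
    lcol = lengths[cols]

    neval = 0
    warm: dict[str, np.ndarray | None] = {"v": None}
    dense = q <= _DENSE_CUTOFF
    if dense:
        A = np.zeros((q, q))

    def rho_at(h: float) -> float:
        nonlocal neval
        neval += 1
        if dense:
            A[rows, cols] = np.exp(-h * lcol)
            return float(np.max(np.abs(np.linalg.eigvals(A))))
        L = sp.csr_matrix((np.exp(-h * lcol), (rows, cols)), shape=(q, q))
        rho, v = _perron(L, v0=warm["v"], need_vector=False)
        if v is not None and np.all(v != 0):
            warm["v"] = np.abs(v)
        return rho

    rho0 = rho_at(0.0)
    if rho0 <= 1.0 + 1e-12:
        # Non-expansive graph (e.g. a cycle): path counts grow at most
        # linearly, h_vol = 0.  L(0) may be reducible there (the two travel
        # directions of a cycle never mix), in which case no unique
        # stationary distribution exists and a uniform vector is reported.
        try:
            z = _stationary_from_structure(edges, rows, cols, 0.0)
        except RuntimeError:
            z = np.full(q, 1.0 / q)
        return EntropyResult(
            h_vol=0.0,
            z=z,
            residual=abs(rho0 - 1.0),
            iterations=neval,
            normalized_input=was_normalized,
            unnormalized_h_vol=0.0,
            non_expansive=True,
            q=q,
            p=net.p,
            edges=edges,
        )

    def g(h: float) -> float:
        return np.log(rho_at(h))

    # bracket the unique root of the strictly decreasing g
    if bracket_hint is not None and bracket_hint > 0:
        lo, hi = 0.9 * float(bracket_hint), 1.1 * float(bracket_hint)
        for _ in range(200):
            if g(lo) > 0:
                break
            hi = lo
            lo *= 0.7
            if lo < 1e-12:
                lo = 0.0
                break
        for _ in range(200):
            if g(hi) < 0:
                break
            lo = hi
            hi *= 1.5
    else:
        lo, hi = 0.0, 1.0
        doublings = 0
        while g(hi) > 0:
            lo = hi
            hi *= 2.0
            doublings += 1
            if doublings > 60:
                raise RuntimeError(
                    "failed to bracket the entropy root: rho(L(h)) stayed "
                    f"above 1 up to h = {hi:.3g}"
                )

    h_vol = brentq(g, lo, hi, xtol=1e-13, rtol=8.9e-16)
    residual = abs(rho_at(h_vol) - 1.0)
    if residual > tol:
        raise RuntimeError(
            f"entropy solve did not reach tolerance: residual {residual:.3g} > {tol:.3g}"
        )
    z = (
        _stationary_from_structure(edges, rows, cols, h_vol)
        if compute_stationary
        else np.empty(0)
    )

    # Entropy on the original length scale.  If this network is itself the
    # result of normalize_volume, `original_volume` carries the raw volume.
    vol = prior_volume if prior_volume is not None else network.oriented_volume
    return EntropyResult(
        h_vol=float(h_vol),
        z=z,
        residual=float(residual),
        iterations=neval,
        normalized_input=was_normalized,
        unnormalized_h_vol=float(2.0 / vol * h_vol),
        non_expansive=False,
        q=q,
        p=net.p,
        edges=edges,
    )


def _stationary_from_structure(
    edges: OrientedEdgeSet,
    rows: np.ndarray,
    cols: np.ndarray,
    h: float,
) -> np.ndarray:
    structure = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(edges.q, edges.q)
    )
    n_comp, _ = sp.csgraph.connected_components(structure, connection="strong")
    if n_comp > 1:
        raise RuntimeError(
            "edge-transition matrix is reducible (the non-backtracking "
            "digraph has several strongly connected components, as happens "
            "for pure cycles); the stationary distribution is not unique — "
            "check that the network is connected with minimum degree 2 and "
            "not a single cycle"
        )
    data = np.exp(-h * edges.length[cols])
    L = sp.csr_matrix((data, (rows, cols)), shape=(edges.q, edges.q))
    rho, v = _perron(L)
    # Perron-Frobenius: irreducibility guarantees a strictly positive
    # eigenvector.  The raw eigensolver output can carry sign noise on
    # entries many orders of magnitude below the dominant ones; polish with
    # a few power iterations from the (positive) absolute vector, which
    # converges back to the Perron direction without leaving the positive
    # cone.
    v = np.abs(v)
    v /= v.sum()
    for _ in range(60):
        w = L @ v
        s = w.sum()
        if s <= 0:
            raise RuntimeError("power-iteration polish collapsed to zero")
        w /= s
        if np.max(np.abs(w - v)) < 1e-15:
            v = w
            break
        v = w
    return v


def stationary_distribution(
    edges: OrientedEdgeSet, h_vol: float, tol: float = 1e-8
) -> np.ndarray:
    """Positive eigenvector of ``L(h_vol)`` for eigenvalue 1, sum-normalized.

    Requires ``rho(L(h_vol))`` to be 1 within ``tol`` — i.e. ``h_vol`` must
    actually be the solved volume entropy of this edge set.
    """
    rows, cols = _transition_structure(edges)
    data = np.exp(-h_vol * edges.length[cols])
    L = sp.csr_matrix((data, (rows, cols)), shape=(edges.q, edges.q))
    rho, _ = _perron(L)
    if abs(rho - 1.0) > tol:
        raise ValueError(
            f"rho(L(h)) = {rho:.6g} is not 1 within {tol:g}; "
            "h must be the solved volume entropy"
        )
    return _stationary_from_structure(edges, rows, cols, h_vol)


def edge_capacity_matrix(
    z: np.ndarray, edges: OrientedEdgeSet, p: int | None = None
) -> np.ndarray:
    """Reshape the stationary edge vector into the p x p capacity matrix.

    ``Pi[i, t] = z_e`` for the oriented edge ``e : i -> t``; the diagonal is
    zero and the entries sum to 1.  ``Pi`` is generally *asymmetric*: mass
    flowing i -> t need not equal mass flowing t -> i.
    """
    p = edges.p if p is None else p
    Pi = np.zeros((p, p))
    Pi[edges.init, edges.term] = z
    return Pi


def node_capacities(Pi: np.ndarray) -> np.ndarray:
    """Incoming-minus-outgoing capacity per node.

    ``pi_i = sum_t Pi[t, i] - sum_t Pi[i, t]``.  Positive values mark
    absorbing nodes (net receivers of information), negative values mark
    source nodes.  The vector always sums to zero.
    """
    Pi = np.asarray(Pi, dtype=float)
    return Pi.sum(axis=0) - Pi.sum(axis=1)


@dataclass(frozen=True)
class CapacityTables:
    """Edge-capacity matrix and node-capacity vector of a solved network."""

    Pi: np.ndarray
    node_capacity: np.ndarray
    labels: tuple


def capacity_tables(result: EntropyResult) -> CapacityTables:
    """Derive edge and node capacities from a solved entropy result."""
    Pi = edge_capacity_matrix(result.z, result.edges)
    return CapacityTables(
        Pi=Pi,
        node_capacity=node_capacities(Pi),
        labels=result.edges.labels,
    )


def rescale_unnormalized_entropy(h_vol: float, original_volume: float) -> float:
    """Map the normalized-network entropy back to the raw length scale.

    Replacing normalized lengths ``l = 2 * l_raw / vol`` in the stationary
    equation shows the unnormalized entropy is ``(2 / vol) * h_vol``.
    """
    if original_volume <= 0:
        raise ValueError("original volume must be positive")
    return 2.0 / original_volume * h_vol
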