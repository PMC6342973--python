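"""Correlation-kernel construction of metric networks from measurements.

Given a ``p x n`` measurement matrix (rows = nodes/ROIs, columns =
observations, e.g. fMRI time points or across-subject PET uptake vectors),
edge weights are the Gaussian kernel of the Pearson correlation distance,

    w_it = exp(-(1 - corr(x_i, x_t)) / (sigma_i * sigma_t)),

with node-adaptive widths ``sigma_i`` taken as the k-th smallest value of
``1 - corr(x_i, x_t)`` over the other nodes (k = 10 by default).  Since
``sqrt(1 - corr)`` is conditionally negative semi-definite, this kernel is
positive definite for all positive widths, and the kernel trick gives the
feature-space Euclidean distance

    d_it = sqrt(2 - 2 * w_it),

which serves as the edge length of a fully connected weighted network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np

from .graph import WeightedNetwork, normalize_volume

__all__ = [
    "MeasurementMatrix",
    "KernelWidths",
    "kernel_widths",
    "correlation_kernel",
    "kernel_distance_matrix",
    "build_network",
    "network_from_measurements",
]


@dataclass(frozen=True)
class MeasurementMatrix:
    """``p x n`` signal matrix with one row per node.

    Every row must have nonzero variance (Pearson correlation is undefined
    for constant signals) and ``n >= 2``.
    """

    values: np.ndarray
    labels: tuple[Hashable, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", X)
        if X.ndim != 2:
            raise ValueError("values must be a 2-D (p x n) array")
        p, n = X.shape
        if len(self.labels) != p:
            raise ValueError("one label per row required")
        if n < 2:
            raise ValueError("at least two observations per node required")
        if not np.all(np.isfinite(X)):
            raise ValueError("measurements must be finite")
        if np.any(X.std(axis=1) == 0):
            bad = [self.labels[i] for i in np.flatnonzero(X.std(axis=1) == 0)]
            raise ValueError(
                f"constant row(s) {bad}: Pearson correlation undefined"
            )

    @classmethod
    def from_array(
        cls, X: np.ndarray, labels: Sequence[Hashable] | None = None
    ) -> "MeasurementMatrix":
        X = np.asarray(X, dtype=float)
        if labels is None:
            labels = tuple(range(X.shape[0]))
        return cls(values=X, labels=tuple(labels))

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def correlation(self) -> np.ndarray:
        """Pearson correlation matrix of the rows (centered once)."""
        X = self.values
        Xc = X - X.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(Xc, axis=1)
        C = (Xc @ Xc.T) / np.outer(norms, norms)
        np.fill_diagonal(C, 1.0)
        return np.clip(C, -1.0, 1.0)


@dataclass(frozen=True)
class KernelWidths:
    """Node-adaptive Gaussian kernel widths, one positive value per node."""

    sigma: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma, dtype=float)
        object.__setattr__(self, "sigma", s)
        if np.any(s <= 0):
            raise ValueError("all kernel widths must be positive")


def kernel_widths(X: MeasurementMatrix, k: int = 10) -> KernelWidths:
    """k-th smallest correlation distance per node as its kernel width.

    ``sigma_i`` is the k-th order statistic of ``{1 - corr(x_i, x_t) :
    t != i}``.  A small width sharpens the kernel around each node's nearest
    correlation neighbours.  If the k-th smallest value is not positive
    (ties at perfect correlation), the smallest *positive* value is used
    instead; if no positive value exists the rows are effectively
    duplicated and an error is raised.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    if X.p <= k:
        raise ValueError(f"need more than k={k} nodes, got p={X.p}")
    C = X.correlation()
    sigma = np.empty(X.p)
    for i in range(X.p):
        dists = np.sort(np.delete(1.0 - C[i], i))
        s = dists[k - 1]
        if s <= 0:
            positive = dists[dists > 0]
            if positive.size == 0:
                raise ValueError(
                    f"node {X.labels[i]!r} is perfectly correlated with all "
                    "others; kernel width undefined"
                )
            s = positive[0]
        sigma[i] = s
    return KernelWidths(sigma=sigma)


def correlation_kernel(X: MeasurementMatrix, widths: KernelWidths) -> np.ndarray:
    """Gaussian correlation kernel matrix ``w_it``.

    Symmetric with unit diagonal; positive definite for positive widths.
    """
    if widths.sigma.shape != (X.p,):
        raise ValueError("one width per node required")
    C = X.correlation()
    denom = np.outer(widths.sigma, widths.sigma)
    W = np.exp(-(1.0 - C) / denom)
    np.fill_diagonal(W, 1.0)
    return W


def kernel_distance_matrix(K: np.ndarray) -> np.ndarray:
    """Feature-space distances ``d_it = sqrt(2 - 2 * w_it)`` from a kernel.

    Requires a symmetric kernel with unit diagonal and entries <= 1 (any
    valid normalized kernel).  Distances are bounded by ``sqrt(2)`` for
    nonnegative kernels and by 2 in general.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("kernel matrix must be square")
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError("kernel matrix must be symmetric")
    if not np.allclose(np.diag(K), 1.0, atol=1e-10):
        raise ValueError("kernel matrix must have unit diagonal")
    if np.any(K > 1.0 + 1e-12):
        raise ValueError("kernel entries above 1 are inconsistent with w <= 1")
    D = np.sqrt(np.maximum(2.0 - 2.0 * K, 0.0))
    np.fill_diagonal(D, 0.0)
    return D


def build_network(
    D: np.ndarray,
    labels: Sequence[Hashable] | None = None,
    normalize: bool = True,
) -> WeightedNetwork:
    """Fully connected weighted network from a distance matrix.

    Every off-diagonal distance becomes an edge length (complete graph on
    ``p`` nodes, ``p(p-1)`` oriented edges), then the volume is normalized
    to 2.  Zero off-diagonal distances are rejected: a zero-length edge
    breaks the metric-graph model.
    """
    D = np.asarray(D, dtype=float)
    p = D.shape[0]
    if D.shape != (p, p):
        raise ValueError("distance matrix must be square")
    off = D[~np.eye(p, dtype=bool)]
    if np.any(off <= 0):
        raise ValueError(
            "all off-diagonal distances must be positive; a zero distance "
            "means two nodes are metrically identical"
        )
    if labels is None:
        labels = tuple(range(p))
    edges = [
        (labels[u], labels[v], float(D[u, v]))
        for u in range(p)
        for v in range(u + 1, p)
    ]
    net = WeightedNetwork.from_edges(edges, labels=labels)
    return normalize_volume(net) if normalize else net


def network_from_measurements(
    X: MeasurementMatrix | np.ndarray,
    k: int = 10,
    normalize: bool = True,
) -> WeightedNetwork:
    """Full pipeline: measurements -> kernel -> distances -> network."""
    if not isinstance(X, MeasurementMatrix):
        X = MeasurementMatrix.from_array(X)
    widths = kernel_widths(X, k=min(k, X.p - 1))
    K = correlation_kernel(X, widths)
    D = kernel_distance_matrix(K)
    return build_network(D, labels=X.labels, normalize=normalize)
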