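"""Small built-in example networks.

The two-module toy network is the worked example used throughout the
documentation and tests: two fully connected modules — A = {v1, v2, v3, v4}
(4 nodes, 6 edges) and B = {v5, v6, v7} (3 nodes, 3 edges) — joined by three
bridge edges v5-v3, v7-v4 and v6-v4, for 7 nodes and 12 undirected edges
(24 oriented edges).  Because module A is larger, the covering tree grows
faster inside A, and the stationary distribution puts more mass on the
bridge edges oriented *into* A than on their reverses.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .graph import WeightedNetwork, normalize_volume

__all__ = ["toy_two_module_network", "TOY_BRIDGES"]

#: bridge edges of the toy network, oriented from module B into module A
TOY_BRIDGES = (("v5", "v3"), ("v7", "v4"), ("v6", "v4"))

_TOY_EDGES = (
    # module A, complete on v1..v4
    ("v1", "v2"),
    ("v1", "v3"),
    ("v1", "v4"),
    ("v2", "v3"),
    ("v2", "v4"),
    ("v3", "v4"),
    # module B, complete on v5..v7
    ("v5", "v6"),
    ("v5", "v7"),
    ("v6", "v7"),
    # bridges
    ("v3", "v5"),
    ("v4", "v6"),
    ("v4", "v7"),
)


def toy_two_module_network(
    lengths: Sequence[float] | float | None = None,
    normalized: bool = True,
) -> WeightedNetwork:
    """Two complete modules (4 and 3 nodes) joined by three bridges.

    Parameters
    ----------
    lengths
        Either a scalar length applied to every edge, a sequence of 12
        lengths aligned with the edge order ``(v1-v2, v1-v3, v1-v4, v2-v3,
        v2-v4, v3-v4, v5-v6, v5-v7, v6-v7, v3-v5, v4-v6, v4-v7)``, or None
        for unit lengths.
    normalized
        Rescale to oriented volume 2 (the convention the entropy solver
        expects) when True.
    """
    if lengths is None:
        vals = np.ones(len(_TOY_EDGES))
    elif np.isscalar(lengths):
        vals = np.full(len(_TOY_EDGES), float(lengths))
    else:
        vals = np.asarray(lengths, dtype=float)
        if vals.shape != (len(_TOY_EDGES),):
            raise ValueError(f"expected {len(_TOY_EDGES)} edge lengths")
    labels = [f"v{i}" for i in range(1, 8)]
    net = WeightedNetwork.from_edges(
        [(u, v, l) for (u, v), l in zip(_TOY_EDGES, vals)], labels=labels
    )
    return normalize_volume(net) if normalized else net
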