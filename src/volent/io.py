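"""Readers, writers and the end-to-end pipeline.

Supported network formats
-------------------------
``matrix-csv``
    Square node-by-node length matrix with a header row of node labels (and
    optionally a label column).  Zero, missing or NaN off-diagonal entries
    mean "no edge"; the diagonal is ignored.  The matrix must be symmetric
    within 1e-8; tiny asymmetries below that are averaged with a warning.
``edgelist``
    Three-column CSV/TSV ``source,target,distance``.
``graphml``
    GraphML with a ``distance`` edge attribute.

Measurement matrices are CSV/TSV with one row per node, the first column
holding node labels and the remaining columns observations.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Any, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .entropy import (
    capacity_tables,
    rescale_unnormalized_entropy,
    solve_volume_entropy,
)
from .graph import WeightedNetwork, normalize_volume, validate
from .kernel import MeasurementMatrix, network_from_measurements

__all__ = [
    "read_network",
    "write_network",
    "read_measurements",
    "load_config",
    "run_pipeline",
    "result_bundle_to_json",
]


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a pipeline configuration from YAML or JSON."""
    import yaml

    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError("config file must contain a mapping")
    return config

_SYMMETRY_TOL = 1e-8


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".graphml":
        return "graphml"
    if suffix in (".csv", ".tsv", ".txt"):
        # a square numeric block (with or without a label column) is a
        # matrix; otherwise a 3-column table is an edge list
        df = _read_table(path)
        n_rows, n_cols = df.shape
        has_label_col = not _looks_numeric(df.iloc[:, 0])
        if has_label_col and n_cols - 1 == n_rows:
            return "matrix-csv"
        if not has_label_col and n_cols == n_rows:
            return "matrix-csv"
        if n_cols == 3:
            return "edgelist"
        return "matrix-csv"
    raise ValueError(f"cannot infer network format from {path.name!r}")


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    return pd.read_csv(path, sep=sep)


def read_network(path: str | Path, format: str | None = None) -> WeightedNetwork:
    """Read a weighted network from disk.

    ``format`` is one of "matrix-csv", "edgelist", "graphml"; inferred from
    the file when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "graphml":
        G = nx.read_graphml(path)
        edges = []
        for u, v, data in G.edges(data=True):
            if "distance" not in data:
                raise ValueError("GraphML edges must carry a 'distance' attribute")
            edges.append((u, v, float(data["distance"])))
        return WeightedNetwork.from_edges(edges, labels=sorted(G.nodes(), key=str))
    if fmt == "edgelist":
        df = _read_table(path)
        if df.shape[1] != 3:
            raise ValueError("edge list must have exactly 3 columns")
        return WeightedNetwork.from_edges(
            [(str(r[0]), str(r[1]), float(r[2])) for r in df.itertuples(index=False)]
        )
    if fmt == "matrix-csv":
        df = _read_table(path)
        first = df.columns[0]
        if not _looks_numeric(df[first]):
            df = df.set_index(first)
        labels = [str(c) for c in df.columns]
        M = df.to_numpy(dtype=float)
        if M.shape[0] != M.shape[1]:
            raise ValueError(
                f"matrix file is {M.shape[0]}x{M.shape[1]}, expected square"
            )
        asym = np.nanmax(np.abs(M - M.T)) if M.size else 0.0
        if asym > _SYMMETRY_TOL:
            raise ValueError(
                f"distance matrix is asymmetric (max deviation {asym:.3g})"
            )
        if asym > 0:
            warnings.warn(
                f"symmetrizing distance matrix (max asymmetry {asym:.3g})"
            )
            M = 0.5 * (M + M.T)
        return WeightedNetwork.from_distance_matrix(M, labels=labels)
    raise ValueError(f"unknown format {fmt!r}")


def _looks_numeric(col: pd.Series) -> bool:
    try:
        pd.to_numeric(col)
        return True
    except (ValueError, TypeError):
        return False


def write_network(
    network: WeightedNetwork, path: str | Path, format: str | None = None
) -> None:
    """Write a network as a distance matrix CSV, edge list, or GraphML."""
    path = Path(path)
    fmt = format
    if fmt is None:
        fmt = "graphml" if path.suffix.lower() == ".graphml" else "matrix-csv"
    if fmt == "graphml":
        G = nx.Graph()
        G.add_nodes_from(str(l) for l in network.labels)
        for (u, v), l in zip(network.edge_pairs, network.lengths):
            G.add_edge(
                str(network.labels[u]), str(network.labels[v]), distance=float(l)
            )
        nx.write_graphml(G, path)
        return
    if fmt == "edgelist":
        rows = [
            (network.labels[u], network.labels[v], l)
            for (u, v), l in zip(network.edge_pairs, network.lengths)
        ]
        pd.DataFrame(rows, columns=["source", "target", "distance"]).to_csv(
            path, index=False
        )
        return
    if fmt == "matrix-csv":
        D = network.distance_matrix()
        labels = [str(l) for l in network.labels]
        pd.DataFrame(D, index=labels, columns=labels).to_csv(
            path, index_label="node"
        )
        return
    raise ValueError(f"unknown format {fmt!r}")


def read_measurements(path: str | Path) -> MeasurementMatrix:
    """Read a node-by-observation measurement matrix (labels in column 1)."""
    path = Path(path)
    df = _read_table(path)
    labels = tuple(str(x) for x in df.iloc[:, 0])
    X = df.iloc[:, 1:].to_numpy(dtype=float)
    return MeasurementMatrix(values=X, labels=labels)


def run_pipeline(config: Mapping[str, Any]) -> dict[str, Any]:
    """Execute build -> validate -> normalize -> solve -> capacities.

    Config keys
    -----------
    ``network``: path to a network file, or ``measurements``: path to a
    measurement matrix (one of the two is required); ``format``: optional
    network format; ``kernel_k``: neighbour index for kernel widths
    (default 10); ``normalize``: volume-normalize before solving (default
    True); ``tol``: solver residual tolerance (default 1e-10); ``out_dir``:
    optional directory to write ``result.json``, ``edge_capacity.csv`` and
    ``node_capacity.csv``.

    Returns the result bundle: entropy, diagnostics, stationary vector,
    capacity tables and the stage log.
    """
    log: list[str] = []
    if ("network" in config) == ("measurements" in config):
        raise ValueError("config needs exactly one of 'network' or 'measurements'")
    if "network" in config:
        net = read_network(config["network"], format=config.get("format"))
        log.append(f"read network: p={net.p}, edges={net.n_edges}")
    else:
        X = read_measurements(config["measurements"])
        log.append(f"read measurements: p={X.p}, n={X.n}")
        net = network_from_measurements(
            X, k=int(config.get("kernel_k", 10)), normalize=False
        )
        log.append("built fully connected kernel network")

    report = validate(net)
    log.append(
        f"validate: connected={report.connected}, min_degree={report.min_degree}"
    )
    if not report.ok:
        raise ValueError("network failed validation: " + "; ".join(report.messages))

    raw_volume = net.oriented_volume
    do_normalize = bool(config.get("normalize", True))
    if do_normalize:
        net = normalize_volume(net)
        log.append(f"normalized volume: {raw_volume:.6g} -> 2")

    tol = float(config.get("tol", 1e-10))
    result = solve_volume_entropy(net, tol=tol)
    log.append(
        f"solved: h_vol={result.h_vol:.10g}, residual={result.residual:.3g}, "
        f"evals={result.iterations}"
    )
    caps = capacity_tables(result)

    bundle: dict[str, Any] = {
        "h_vol": result.h_vol,
        "normalized_h_vol": result.h_vol,
        "unnormalized_h_vol": rescale_unnormalized_entropy(result.h_vol, raw_volume),
        "residual": result.residual,
        "non_expansive": result.non_expansive,
        "q": result.q,
        "p": result.p,
        "labels": [str(l) for l in caps.labels],
        "z": result.z.tolist(),
        "Pi": caps.Pi.tolist(),
        "node_capacity": caps.node_capacity.tolist(),
        "volume": raw_volume,
        "log": log,
    }

    out_dir = config.get("out_dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "result.json").write_text(result_bundle_to_json(bundle))
        labels = bundle["labels"]
        pd.DataFrame(caps.Pi, index=labels, columns=labels).to_csv(
            out / "edge_capacity.csv", index_label="node"
        )
        pd.DataFrame(
            {"node": labels, "capacity": caps.node_capacity}
        ).to_csv(out / "node_capacity.csv", index=False)
        log.append(f"wrote outputs to {out}")
    return bundle


def result_bundle_to_json(bundle: Mapping[str, Any]) -> str:
    return json.dumps(bundle, indent=2)
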