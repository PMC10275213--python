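"""Standard-format readers and writers for pipeline artifacts.

Matrices travel as Matrix Market coordinate files (1-based), tables as
headed CSV, circuits as GraphML plus a 3-column edge list. Every writer
has a loader such that load(save(x)) round-trips.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from sbmcircuit.blockmodel import Circuit
from sbmcircuit.consensus import ConsensusPartition


def save_strengths(matrix, path) -> None:
    mmwrite(str(path), sp.coo_matrix(matrix), field="integer")


def load_strengths(path) -> sp.csr_matrix:
    try:
        M = mmread(str(path))
    except ValueError as exc:
        raise ValueError(f"malformed Matrix Market file {path}: {exc}") from exc
    M = sp.csr_matrix(M)
    if M.shape[0] != M.shape[1]:
        raise ValueError(f"{path}: strength matrix must be square, got {M.shape}")
    if M.nnz and M.data.min() < 0:
        raise ValueError(f"{path}: strengths must be nonnegative")
    return M.astype(np.int64)


def save_partition(partition: ConsensusPartition, path, neuron_ids=None) -> None:
    n = partition.labels.size
    ids = neuron_ids if neuron_ids is not None else [f"neuron_{i:06d}" for i in range(n)]
    out = pd.DataFrame(
        {
            "neuron_id": ids,
            "class_id": [str(l) if l > 0 else "unassigned" for l in partition.labels],
        }
    )
    out.to_csv(path, index=False)


def load_partition(path, tau=np.nan, c_size=1) -> ConsensusPartition:
    frame = pd.read_csv(path)
    labels = np.array(
        [0 if v == "unassigned" else int(v) for v in frame["class_id"]], dtype=np.int64
    )
    kappa = int(labels.max()) if labels.size else 0
    return ConsensusPartition(labels=labels, kappa=kappa, tau=tau, c_size=c_size)


def save_circuit(circuit: Circuit, graphml_path=None, edgelist_path=None) -> None:
    if edgelist_path is not None:
        rows, cols = np.nonzero(circuit.p)
        pd.DataFrame(
            {
                "source_class": rows + 1,
                "target_class": cols + 1,
                "probability": circuit.p[rows, cols],
            }
        ).to_csv(edgelist_path, index=False)
    if graphml_path is not None:
        G = nx.DiGraph(floor_threshold=float(circuit.floor_threshold))
        for k in range(circuit.kappa):
            G.add_node(k + 1, size=int(circuit.class_sizes[k]))
        for i, j, p in circuit.edges:
            G.add_edge(i + 1, j + 1, probability=float(p))
        nx.write_graphml(G, graphml_path)


def load_circuit(graphml_path) -> Circuit:
    G = nx.read_graphml(graphml_path, node_type=int)
    kappa = G.number_of_nodes()
    p = np.zeros((kappa, kappa))
    sizes = np.zeros(kappa, dtype=np.int64)
    for node, attrs in G.nodes(data=True):
        sizes[node - 1] = attrs.get("size", 0)
    for u, v, attrs in G.edges(data=True):
        p[u - 1, v - 1] = attrs["probability"]
    return Circuit(
        p=p, class_sizes=sizes, floor_threshold=float(G.graph.get("floor_threshold", 0.0))
    )


def save_matrix_csv(matrix: np.ndarray, path, prefix: str = "class") -> None:
    kappa = matrix.shape[0]
    names = [f"{prefix}_{k + 1}" for k in range(kappa)]
    pd.DataFrame(matrix, index=names, columns=names[: matrix.shape[1]]).to_csv(path)


def load_matrix_csv(path) -> np.ndarray:
    return pd.read_csv(path, index_col=0).to_numpy(dtype=float)


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def _jsonify(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    raise TypeError(f"cannot serialize {type(value)!r}")
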