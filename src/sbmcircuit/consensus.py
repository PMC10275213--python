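"""Modified iterative voting consensus over an ensemble of clusterings.

Each of the G per-graph clusterings serves in turn as the reference for an
IVC pass (majority-label center vectors, Hamming-nearest reassignment,
iterated to a fixed point). Pairwise co-clustering proportions of the
updated clusterings are chained at threshold tau and the resulting
components filtered by a minimum class size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

#: label marking a neuron absent from a (trimmed) clustering
MISSING = -1

_IVC_MAX_ITER = 100


@dataclass
class ClusteringEnsemble:
    """G clusterings over a common neuron index.

    ``labels`` is a ``G x n`` integer array; positive entries are cluster
    labels, :data:`MISSING` marks neurons trimmed out of that graph.
    """

    labels: np.ndarray = field(repr=False)
    converged: np.ndarray | None = None

    @property
    def G(self) -> int:
        return self.labels.shape[0]

    @property
    def n(self) -> int:
        return self.labels.shape[1]

    @property
    def kappas(self) -> np.ndarray:
        return np.array([np.unique(row[row != MISSING]).size for row in self.labels])


@dataclass
class ConsensusPartition:
    """Final consensus classes plus unassigned neurons.

    ``labels[i]`` is the class of neuron i in ``1..kappa`` (classes are
    numbered by decreasing size) or 0 for unassigned.
    """

    labels: np.ndarray
    kappa: int
    tau: float
    c_size: int

    @property
    def class_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.kappa + 1)[1:]

    @property
    def assigned_fraction(self) -> float:
        return float(np.mean(self.labels > 0))

    def members(self, k: int) -> np.ndarray:
        return np.nonzero(self.labels == k)[0]


def ensemble_from_graph_labels(per_graph, n: int) -> ClusteringEnsemble:
    """Assemble an ensemble from (labels, retained_indices) pairs."""
    G = len(per_graph)
    labels = np.full((G, n), MISSING, dtype=np.int64)
    for row, (graph_labels, retained) in zip(labels, per_graph):
        row[np.asarray(retained)] = np.asarray(graph_labels)
    return ClusteringEnsemble(labels=labels)


def _majority(column: np.ndarray) -> int:
    """Most common non-missing value, lowest value on ties."""
    vals = column[column != MISSING]
    if vals.size == 0:
        return MISSING
    uniq, counts = np.unique(vals, return_counts=True)
    return int(uniq[np.argmax(counts)])  # unique is sorted -> lowest wins ties


def _centers(labels: np.ndarray, cluster_ids, ensemble_labels: np.ndarray) -> np.ndarray:
    """Center vector per reference cluster: majority label under each of
    the G clusterings."""
    G = ensemble_labels.shape[0]
    C = np.empty((len(cluster_ids), G), dtype=np.int64)
    for row, k in enumerate(cluster_ids):
        members = np.nonzero(labels == k)[0]
        for j in range(G):
            C[row, j] = _majority(ensemble_labels[j, members])
    return C


def ivc_update_one(
    reference: np.ndarray,
    ensemble: ClusteringEnsemble,
    max_iter: int = _IVC_MAX_ITER,
) -> tuple[np.ndarray, bool]:
    """One IVC fixed-point iteration with ``reference`` as the start.

    Repeats until no label changes: compute the majority-label center per
    reference cluster, then reassign every neuron to the cluster whose
    center is Hamming-nearest to the neuron's label vector
    ``(pi_1(x_i), ..., pi_G(x_i))``. Ties break to the lowest cluster
    index. Empty clusters are dropped between passes. Returns the final
    labeling and a convergence flag.
    """
    L = ensemble.labels  # G x n
    current = np.asarray(reference, dtype=np.int64).copy()
    n = current.size
    for _ in range(max_iter):
        cluster_ids = [k for k in np.unique(current) if k != MISSING]
        if not cluster_ids:
            return current, True
        C = _centers(current, cluster_ids, L)  # kappa x G
        # distance d[i, k] = #{j : L[j, i] != C[k, j]}; chunk over neurons
        new = np.empty(n, dtype=np.int64)
        chunk = max(1, int(4e6 // max(1, len(cluster_ids) * L.shape[0])))
        for start in range(0, n, chunk):
            stop = min(start + chunk, n)
            block = L[:, start:stop].T  # (m, G)
            dist = (block[:, None, :] != C[None, :, :]).sum(axis=2)  # (m, kappa)
            new[start:stop] = np.argmin(dist, axis=1)  # first (lowest) index on ties
        new_labels = np.asarray(cluster_ids, dtype=np.int64)[new]
        if np.array_equal(new_labels, current):
            return current, True
        current = new_labels
    return current, False


def ivc_update_all(ensemble: ClusteringEnsemble, max_iter: int = _IVC_MAX_ITER) -> ClusteringEnsemble:
    """Apply :func:`ivc_update_one` with every clustering as the reference.

    Each update reads only the original ensemble, so the result is
    independent of processing order.
    """
    if ensemble.G < 2:
        raise ValueError("ensemble must hold at least 2 clusterings")
    updated = np.empty_like(ensemble.labels)
    flags = np.empty(ensemble.G, dtype=bool)
    for l in range(ensemble.G):
        updated[l], flags[l] = ivc_update_one(ensemble.labels[l], ensemble, max_iter=max_iter)
    return ClusteringEnsemble(labels=updated, converged=flags)


def similarity_matrix(ensemble: ClusteringEnsemble) -> np.ndarray:
    """Proportion of clusterings placing each neuron pair together.

    A neuron missing from a clustering counts as "not together" with every
    neuron in that clustering. The diagonal is 1 and every entry is a
    multiple of 1/G.
    """
    n, G = ensemble.n, ensemble.G
    together = np.zeros((n, n), dtype=np.int32)
    for row in ensemble.labels:
        for k in np.unique(row[row != MISSING]):
            idx = np.nonzero(row == k)[0]
            together[np.ix_(idx, idx)] += 1
    S = together / G
    np.fill_diagonal(S, 1.0)
    return S


def chain_components(S: np.ndarray, tau: float) -> np.ndarray:
    """Partition neurons by the transitive closure of ``s_ij >= tau``.

    Returns a component id per neuron (0-based, arbitrary numbering).
    """
    if not 0.0 < tau <= 1.0:
        raise ValueError(f"tau must lie in (0, 1], got {tau}")
    adj = sp.csr_matrix(S >= tau)
    _, comp = connected_components(adj, directed=False)
    return comp


def size_filter(component_labels: np.ndarray, c_size: int, tau: float = np.nan) -> ConsensusPartition:
    """Keep components of size >= c_size; renumber 1..kappa by decreasing size.

    Smaller components become unassigned (label 0). Size ties break by the
    smallest member index, keeping the numbering deterministic.
    """
    if c_size < 1:
        raise ValueError(f"c_size must be >= 1, got {c_size}")
    comp = np.asarray(component_labels)
    ids, sizes = np.unique(comp, return_counts=True)
    first_member = np.array([np.argmax(comp == i) for i in ids])
    order = np.lexsort((first_member, -sizes))
    labels = np.zeros(comp.size, dtype=np.int64)
    next_class = 1
    for pos in order:
        if sizes[pos] >= c_size:
            labels[comp == ids[pos]] = next_class
            next_class += 1
    return ConsensusPartition(labels=labels, kappa=next_class - 1, tau=tau, c_size=c_size)


def consensus_cluster(
    ensemble: ClusteringEnsemble,
    tau: float = 0.95,
    c_size: int = 100,
) -> tuple[ConsensusPartition, np.ndarray]:
    """Full consensus: IVC update, similarity, tau-chaining, size filter."""
    updated = ivc_update_all(ensemble)
    S = similarity_matrix(updated)
    comp = chain_components(S, tau)
    partition = size_filter(comp, c_size, tau=tau)
    return partition, S
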