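"""Block probability estimation and circuit construction.

Estimates the class-to-class connection probability matrix by averaging,
over the binary ensemble, the proportion of realized ordered neuron pairs;
floors small entries to zero (greedily, subject to every class keeping at
least one incident edge) to obtain the mesoscale circuit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from sbmcircuit.binarize import BinaryEnsemble
from sbmcircuit.consensus import ConsensusPartition


@dataclass
class BlockProbabilityMatrix:
    """Estimated class-to-class connection probabilities."""

    p_hat: np.ndarray = field(repr=False)
    class_sizes: np.ndarray = field(repr=False)
    kappa: int
    warning: str | None = None


@dataclass
class Circuit:
    """Directed weighted circuit over consensus classes.

    ``p`` holds the floored probability matrix; entries below (or at) the
    recorded ``floor_threshold`` were zeroed during construction, except
    where that would isolate a class.
    """

    p: np.ndarray = field(repr=False)
    class_sizes: np.ndarray = field(repr=False)
    floor_threshold: float = 0.0
    isolated_flagged: tuple = ()

    @property
    def kappa(self) -> int:
        return self.p.shape[0]

    @property
    def edges(self) -> list:
        """Directed edges as (source, target, probability), 0-based classes."""
        rows, cols = np.nonzero(self.p)
        return [(int(i), int(j), float(self.p[i, j])) for i, j in zip(rows, cols)]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.p))


def _pair_sums(partition, ensemble, member_mask=None):
    """Per-graph edge counts and ordered-pair counts between classes.

    Neurons trimmed from a graph contribute no edges and are excluded from
    that graph's denominators. ``member_mask`` restricts both numerator and
    denominator to a neuron subset.
    """
    kappa = partition.kappa
    num = np.zeros((kappa, kappa))
    den = np.zeros((kappa, kappa))
    n_graphs = np.zeros((kappa, kappa))
    for A, retained in zip(ensemble.graphs, ensemble.retained):
        retained = np.asarray(retained)
        labels_g = partition.labels[retained] if retained.size else np.empty(0, dtype=int)
        keep = labels_g > 0
        if member_mask is not None:
            keep &= member_mask[retained]
        if not keep.any():
            continue
        sub = A[np.ix_(keep.nonzero()[0], keep.nonzero()[0])]
        lab = labels_g[keep]
        ind = sp.csr_matrix(
            (np.ones(lab.size), (lab - 1, np.arange(lab.size))), shape=(kappa, lab.size)
        )
        counts = np.asarray((ind @ sub @ ind.T).todense(), dtype=float)
        sizes = np.bincount(lab - 1, minlength=kappa).astype(float)
        pairs = np.outer(sizes, sizes)
        np.fill_diagonal(pairs, sizes * (sizes - 1.0))
        valid = pairs > 0
        num[valid] += (counts / np.where(valid, pairs, 1.0))[valid]
        den[valid] += 1.0
        n_graphs += valid
    return num, den, n_graphs


def estimate_block_probabilities(
    partition: ConsensusPartition, ensemble: BinaryEnsemble
) -> BlockProbabilityMatrix:
    """Average, over graphs, the proportion of realized ordered pairs.

    Within-class denominators exclude self-pairs (``|V_i| * (|V_i| - 1)``),
    since the graphs carry no self-loops.
    """
    if partition.kappa == 0:
        raise ValueError("partition has no classes")
    if np.any(partition.class_sizes == 0):
        raise ValueError("partition contains an empty class")
    if ensemble.G == 0:
        raise ValueError("ensemble is empty")
    num, den, _ = _pair_sums(partition, ensemble)
    p_hat = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return BlockProbabilityMatrix(
        p_hat=p_hat, class_sizes=partition.class_sizes, kappa=partition.kappa
    )


def restricted_block_probabilities(
    partition: ConsensusPartition,
    ensemble: BinaryEnsemble,
    neuron_mask: np.ndarray,
) -> BlockProbabilityMatrix:
    """Block probabilities recomputed over a neuron subset only.

    Both the numerator edges and the denominator pair counts use masked
    neurons exclusively; classes with no masked neurons get zero rows and
    columns. An empty mask yields an all-zero matrix with a warning flag.
    """
    mask = np.asarray(neuron_mask, dtype=bool)
    if mask.shape != partition.labels.shape:
        raise ValueError("neuron_mask must align with the partition's neuron index")
    warning = None
    if not mask.any():
        warning = "empty neuron mask: all-zero block probabilities"
        p_hat = np.zeros((partition.kappa, partition.kappa))
    else:
        num, den, _ = _pair_sums(partition, ensemble, member_mask=mask)
        p_hat = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    sizes = np.array(
        [np.sum(mask[partition.labels == k]) for k in range(1, partition.kappa + 1)]
    )
    return BlockProbabilityMatrix(
        p_hat=p_hat, class_sizes=sizes, kappa=partition.kappa, warning=warning
    )


def floor_to_circuit(bpm: BlockProbabilityMatrix) -> Circuit:
    """Zero small entries while keeping every class covered by an edge.

    Nonzero entries are removed greedily in ascending order; removal stops
    just before the first entry whose deletion would leave some class with
    no incident (incoming or outgoing) edge. The floor threshold is the
    last removed value.
    """
    P = np.array(bpm.p_hat, dtype=float)
    kappa = bpm.kappa
    rows, cols = np.nonzero(P)
    if rows.size == 0:
        raise ValueError("block probability matrix is all zero")
    order = np.lexsort((cols, rows, P[rows, cols]))
    incident = np.zeros(kappa, dtype=np.int64)
    for i, j in zip(rows, cols):
        incident[i] += 1
        if j != i:
            incident[j] += 1
    floored = P.copy()
    threshold = 0.0
    for idx in order:
        i, j = rows[idx], cols[idx]
        loss = incident[i] <= 1 or (j != i and incident[j] <= 1)
        if loss:
            break
        floored[i, j] = 0.0
        threshold = float(P[i, j])
        incident[i] -= 1
        if j != i:
            incident[j] -= 1
    return Circuit(p=floored, class_sizes=np.asarray(bpm.class_sizes), floor_threshold=threshold)


def top_fraction_edges(circuit: Circuit, fraction: float) -> Circuit:
    """Keep the heaviest ``ceil(fraction * n_edges)`` edges.

    Edges tied with the cutoff weight are all kept. Classes left without
    incident edges are retained but flagged in ``isolated_flagged``.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    weights = circuit.p[circuit.p > 0]
    if weights.size == 0:
        return circuit
    n_keep = int(np.ceil(fraction * weights.size))
    cutoff = np.sort(weights)[::-1][n_keep - 1]
    kept = np.where(circuit.p >= cutoff, circuit.p, 0.0)
    incident = (kept.sum(axis=0) + kept.sum(axis=1)) == 0
    return Circuit(
        p=kept,
        class_sizes=circuit.class_sizes,
        floor_threshold=circuit.floor_threshold,
        isolated_flagged=tuple(np.nonzero(incident)[0]),
    )
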