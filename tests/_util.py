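"""Shared helpers for the test suite."""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from sbmcircuit.binarize import BinaryEnsemble
from sbmcircuit.consensus import ConsensusPartition
from sbmcircuit.walks import WalkCircuit


def planted_block_probabilities(kappa: int, p_in: float, p_out: float) -> np.ndarray:
    P = np.full((kappa, kappa), p_out)
    np.fill_diagonal(P, p_in)
    return P


def block_labels(n: int, kappa: int) -> np.ndarray:
    """Equal-size contiguous block assignment, labels 1..kappa."""
    return np.repeat(np.arange(1, kappa + 1), n // kappa)[:n]


def direct_sbm_ensemble(labels: np.ndarray, P: np.ndarray, G: int, seed: int) -> BinaryEnsemble:
    """Sample G binary graphs straight from SBM probabilities (no trimming
    surprises: all neurons retained; isolated neurons are left in)."""
    n = labels.size
    prob = P[labels - 1][:, labels - 1]
    rng = np.random.default_rng(seed)
    graphs = []
    for _ in range(G):
        mask = rng.random((n, n)) < prob
        np.fill_diagonal(mask, False)
        graphs.append(sp.csr_matrix(mask.astype(np.int8)))
    retained = [np.arange(n) for _ in range(G)]
    return BinaryEnsemble(graphs=graphs, retained=retained, n=n, seed=seed)


def partition_from_labels(labels: np.ndarray, tau=0.95, c_size=1) -> ConsensusPartition:
    labels = np.asarray(labels, dtype=np.int64)
    return ConsensusPartition(labels=labels, kappa=int(labels.max()), tau=tau, c_size=c_size)


def random_walk_circuit(rng: np.random.Generator, kappa: int, density: float = 0.6) -> WalkCircuit:
    """Random cost-weighted circuit with a guaranteed directed ring (so
    every ordered pair is reachable)."""
    cost = np.full((kappa, kappa), np.inf)
    for i in range(kappa):
        cost[i, (i + 1) % kappa] = rng.uniform(0.5, 5.0)
    extra = rng.random((kappa, kappa)) < density
    np.fill_diagonal(extra, False)
    cost = np.where(extra & np.isinf(cost), rng.uniform(0.5, 5.0, (kappa, kappa)), cost)
    return WalkCircuit.from_cost(cost)
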