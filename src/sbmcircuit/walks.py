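"""Random-walk absorption and driftiness on the mesoscale circuit.

A step from class i to class j costs ``1 / (P_ij * s_i * s_j)`` where the
``s`` are block sizes scaled by the minimum size, so steps with a larger
expected edge count are cheaper. Absorption between a source and a target
is the mean total cost over all simple directed paths (exhaustively
enumerated for small circuits, Monte-Carlo sampled otherwise); driftiness
is absorption divided by the shortest-path cost.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

from sbmcircuit.binarize import as_seed_sequence

ENUM_CAP = 10  # exhaustive path enumeration up to this many classes


@dataclass
class WalkCircuit:
    """Cost-weighted view of a circuit for random-walk analysis."""

    kappa: int
    sizes: np.ndarray
    scaled_sizes: np.ndarray
    P: np.ndarray = field(repr=False)
    cost: np.ndarray = field(repr=False)  # kappa x kappa, inf where no edge

    @classmethod
    def from_circuit(cls, circuit) -> "WalkCircuit":
        sizes = np.asarray(circuit.class_sizes, dtype=float)
        scaled = sizes / sizes.min()
        P = np.array(circuit.p, dtype=float)
        np.fill_diagonal(P, 0.0)  # self-loops ignored by the walk
        with np.errstate(divide="ignore"):
            cost = np.where(P > 0, 1.0 / (P * np.outer(scaled, scaled)), np.inf)
        return cls(kappa=P.shape[0], sizes=sizes, scaled_sizes=scaled, P=P, cost=cost)

    @classmethod
    def from_cost(cls, cost: np.ndarray) -> "WalkCircuit":
        """Build directly from a cost matrix (unit sizes)."""
        cost = np.array(cost, dtype=float)
        np.fill_diagonal(cost, np.inf)
        kappa = cost.shape[0]
        with np.errstate(divide="ignore"):
            P = np.where(np.isfinite(cost), 1.0 / cost, 0.0)
        return cls(
            kappa=kappa,
            sizes=np.ones(kappa),
            scaled_sizes=np.ones(kappa),
            P=np.clip(P, 0.0, None),
            cost=cost,
        )


@dataclass
class WalkStats:
    """Pairwise and per-class walk statistics.

    Matrices hold NaN for undefined (unreachable) pairs; diagonals are 0
    for absorption/shortest and excluded from every average.
    """

    absorption: np.ndarray = field(repr=False)
    shortest: np.ndarray = field(repr=False)
    driftiness: np.ndarray = field(repr=False)
    out_absorption: np.ndarray = field(default=None, repr=False)
    in_absorption: np.ndarray = field(default=None, repr=False)
    out_driftiness: np.ndarray = field(default=None, repr=False)
    in_driftiness: np.ndarray = field(default=None, repr=False)
    m: int = 0
    n_undefined: int = 0


def step_cost(circuit: WalkCircuit, i: int, j: int) -> float:
    """Cost of stepping i -> j; ``inf`` when the edge is absent."""
    return float(circuit.cost[i, j])


def _neighbors(circuit: WalkCircuit):
    return [np.nonzero(np.isfinite(circuit.cost[i]))[0].tolist() for i in range(circuit.kappa)]


def enumerate_absorption(circuit: WalkCircuit, s: int, t: int) -> tuple[float, int]:
    """Exhaustively average the cost of all simple directed paths s -> t.

    Returns ``(mean cost, path count)``; ``(nan, 0)`` when t is
    unreachable. The target is terminal, so edges out of t are irrelevant.
    """
    if circuit.kappa > ENUM_CAP:
        raise ValueError(f"enumeration capped at kappa <= {ENUM_CAP}, got {circuit.kappa}")
    if s == t:
        return 0.0, 0
    nbrs = _neighbors(circuit)
    cost = circuit.cost
    total = 0.0
    count = 0
    visited = [False] * circuit.kappa
    visited[s] = True

    def dfs(node: int, acc: float):
        nonlocal total, count
        for nxt in nbrs[node]:
            if nxt == t:
                total += acc + cost[node, t]
                count += 1
            elif not visited[nxt]:
                visited[nxt] = True
                dfs(nxt, acc + cost[node, nxt])
                visited[nxt] = False

    dfs(s, 0.0)
    if count == 0:
        return float("nan"), 0
    return total / count, count


def sample_absorption(
    circuit: WalkCircuit,
    s: int,
    t: int,
    m: int,
    seed: int = 0,
    importance_weighted: bool = True,
    max_attempts_factor: int = 50,
) -> tuple[float, float, int]:
    """Monte-Carlo absorption estimate from m sampled simple paths s -> t.

    Paths are self-avoiding walks choosing the next class uniformly among
    unvisited out-neighbors; dead ends and non-arrivals are resampled. That
    law does not weight paths uniformly, so by default each path carries an
    importance weight (the product of the branching factors along it, i.e.
    the inverse of its sampling probability), making the self-normalized
    estimator converge to the enumerated uniform-over-paths mean.

    Returns ``(estimate, standard_error, paths_sampled)``; NaNs when no
    path is found within the attempt budget.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if s == t:
        return 0.0, 0.0, 0
    nbrs = _neighbors(circuit)
    cost = circuit.cost
    rng = random.Random(int(as_seed_sequence(seed).generate_state(1)[0]))
    lengths = np.empty(m)
    weights = np.empty(m)
    found = 0
    attempts = 0
    budget = m * max_attempts_factor
    while found < m and attempts < budget:
        attempts += 1
        node = s
        visited = {s}
        acc = 0.0
        w = 1.0
        while True:
            options = [v for v in nbrs[node] if v not in visited]
            if t in visited or not options:
                break
            w *= len(options)
            nxt = options[rng.randrange(len(options))]
            acc += cost[node, nxt]
            visited.add(nxt)
            node = nxt
            if node == t:
                lengths[found] = acc
                weights[found] = w
                found += 1
                break
    if found == 0:
        return float("nan"), float("nan"), 0
    lengths, weights = lengths[:found], weights[:found]
    if not importance_weighted:
        weights = np.ones(found)
    wsum = weights.sum()
    estimate = float(np.dot(weights, lengths) / wsum)
    se = float(np.sqrt(np.sum(weights**2 * (lengths - estimate) ** 2)) / wsum)
    return estimate, se, found


def shortest_path_costs(circuit: WalkCircuit) -> np.ndarray:
    """All-pairs minimal total step cost (Dijkstra); NaN when unreachable."""
    finite = np.isfinite(circuit.cost)
    graph = sp.csr_matrix(
        (circuit.cost[finite], np.nonzero(finite)), shape=circuit.cost.shape
    )
    dist = dijkstra(graph, directed=True)
    dist[np.isinf(dist)] = np.nan
    np.fill_diagonal(dist, 0.0)
    return dist


def shortest_path_cost(circuit: WalkCircuit, s: int, t: int) -> float:
    return float(shortest_path_costs(circuit)[s, t])


def walk_stats(
    circuit: WalkCircuit,
    m: int = 100_000,
    seed: int = 0,
    enum_cap: int = ENUM_CAP,
) -> WalkStats:
    """Pairwise absorption, shortest-path cost and driftiness plus per-class
    averages (self and undefined pairs excluded, exclusions counted).

    Absorption is enumerated exactly when ``kappa <= enum_cap`` and sampled
    with importance weighting otherwise.
    """
    kappa = circuit.kappa
    if kappa < 2:
        raise ValueError("walk statistics need at least 2 classes")
    A = np.full((kappa, kappa), np.nan)
    np.fill_diagonal(A, 0.0)
    children = as_seed_sequence(seed).spawn(kappa * kappa)
    for s in range(kappa):
        for t in range(kappa):
            if s == t:
                continue
            if kappa <= enum_cap:
                A[s, t], _ = enumerate_absorption(circuit, s, t)
            else:
                A[s, t], _, _ = sample_absorption(
                    circuit, s, t, m, seed=children[s * kappa + t]
                )
    delta = shortest_path_costs(circuit)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = A / delta
    np.fill_diagonal(D, np.nan)
    off = ~np.eye(kappa, dtype=bool)
    n_undefined = int(np.sum(np.isnan(A[off])))

    def _avg(M, axis):
        valid = off & ~np.isnan(M)
        sums = np.where(valid, M, 0.0).sum(axis=axis)
        counts = valid.sum(axis=axis)
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    return WalkStats(
        absorption=A,
        shortest=delta,
        driftiness=D,
        out_absorption=_avg(A, 1),
        in_absorption=_avg(A, 0),
        out_driftiness=_avg(D, 1),
        in_driftiness=_avg(D, 0),
        m=m if kappa > enum_cap else 0,
        n_undefined=n_undefined,
    )


def percentile_flags(
    stats: WalkStats, low_pct: float = 20.0, high_pct: float = 10.0
) -> dict:
    """Flag accessible/originating classes and critical pairwise links.

    Classes in the bottom ``low_pct`` percent of average in-absorption
    (accessible) or out-absorption (origination) are flagged, as are pairs
    in the top ``high_pct`` percent of pairwise driftiness. Ties share
    rank, so tied values are flagged together.
    """
    def _low(values):
        vals = values[~np.isnan(values)]
        if vals.size == 0:
            return np.zeros(values.size, dtype=bool)
        thresh = np.percentile(vals, low_pct)
        return np.where(np.isnan(values), False, values <= thresh)

    D = stats.driftiness
    dvals = D[~np.isnan(D)]
    if dvals.size:
        dthresh = np.percentile(dvals, 100.0 - high_pct)
        critical = np.where(np.isnan(D), False, D >= dthresh)
    else:
        critical = np.zeros_like(D, dtype=bool)
    return {
        "accessible": _low(stats.in_absorption),
        "originating": _low(stats.out_absorption),
        "critical_links": critical,
    }
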