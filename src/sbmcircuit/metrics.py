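"""Graph-theoretic circuit metrics, goodness of fit and robustness checks.

Hub detection via weighted degree and betweenness centrality, a binomial
goodness-of-fit check of the block model against the observed ensemble,
histogram-intersection distribution comparison, connectome summary
statistics and the subsample-robustness protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class HubReport:
    weighted_degree: np.ndarray
    betweenness: np.ndarray
    hubs: np.ndarray = field(default=None)  # boolean per class


def weighted_degree(circuit) -> np.ndarray:
    """Incoming plus outgoing connection probabilities, times class size."""
    P = np.asarray(circuit.p, dtype=float)
    return (P.sum(axis=1) + P.sum(axis=0)) * np.asarray(circuit.class_sizes, dtype=float)


def betweenness_unweighted(circuit) -> np.ndarray:
    """Directed betweenness on the unweighted edge set.

    Shortest paths are hop counts; each node's raw pass-through count is
    normalized by its number of reachable ordered (s, t) pairs with
    s != t != node, so values lie in [0, 1] and a pure relay on a line
    scores 1.
    """
    P = np.asarray(circuit.p, dtype=float)
    kappa = P.shape[0]
    if kappa < 3:
        raise ValueError("betweenness needs at least 3 classes")
    G = nx.DiGraph()
    G.add_nodes_from(range(kappa))
    G.add_edges_from((int(i), int(j)) for i, j in zip(*np.nonzero(P)) if i != j)
    raw = nx.betweenness_centrality(G, normalized=False)
    reach = {v: set(nx.descendants(G, v)) for v in G.nodes}
    out = np.zeros(kappa)
    for v in range(kappa):
        pairs = sum(
            1
            for s in range(kappa)
            if s != v
            for t in reach[s]
            if t != v and t != s
        )
        out[v] = raw[v] / pairs if pairs else 0.0
    return out


def identify_hubs(report: HubReport, quantile: float = 0.9) -> HubReport:
    """Flag classes at or above the given quantile on BOTH measures."""
    wd, bc = report.weighted_degree, report.betweenness
    hubs = (wd >= np.quantile(wd, quantile)) & (bc >= np.quantile(bc, quantile))
    return HubReport(weighted_degree=wd, betweenness=bc, hubs=hubs)


def hub_report(circuit, quantile: float = 0.9) -> HubReport:
    report = HubReport(
        weighted_degree=weighted_degree(circuit), betweenness=betweenness_unweighted(circuit)
    )
    return identify_hubs(report, quantile=quantile)


def binomial_fit_fraction(partition, ensemble, bpm) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of per-neuron connection counts within 2 SD of the binomial.

    For each class pair (i, j) the observed values are, for every neuron in
    V_i in every graph, its number of connections into V_j; the reference
    is Binomial(|V_j|, p_hat_ij). Returns the within-2-SD fraction matrix
    and a boolean matrix flagging degenerate (p_hat in {0, 1}) intervals.
    """
    kappa = partition.kappa
    totals = np.zeros((kappa, kappa))
    within = np.zeros((kappa, kappa))
    p_hat = np.asarray(bpm.p_hat, dtype=float)
    for A, retained in zip(ensemble.graphs, ensemble.retained):
        retained = np.asarray(retained)
        labels_g = partition.labels[retained]
        keep = labels_g > 0
        idx = np.nonzero(keep)[0]
        if idx.size == 0:
            continue
        sub = A[np.ix_(idx, idx)]
        lab = labels_g[keep]
        ind = sp.csr_matrix(
            (np.ones(lab.size), (np.arange(lab.size), lab - 1)), shape=(lab.size, kappa)
        )
        counts = np.asarray((sub @ ind).todense())  # neuron x target-class
        sizes = np.bincount(lab - 1, minlength=kappa).astype(float)
        for j in range(kappa):
            nj = sizes[j]
            if nj == 0:
                continue
            for i in range(kappa):
                # within-class pairs exclude the neuron itself
                trials = nj - 1.0 if i == j else nj
                if trials <= 0:
                    continue
                mean = trials * p_hat[i, j]
                sd = np.sqrt(trials * p_hat[i, j] * (1.0 - p_hat[i, j]))
                obs = counts[lab == i + 1, j]
                totals[i, j] += obs.size
                within[i, j] += np.sum(
                    (obs >= mean - 2 * sd - 1e-9) & (obs <= mean + 2 * sd + 1e-9)
                )
    frac = np.divide(within, totals, out=np.full_like(within, np.nan), where=totals > 0)
    degenerate = (p_hat <= 0.0) | (p_hat >= 1.0)
    return frac, degenerate


def histogram_intersection(sample_a, sample_b, bins) -> float:
    """Overlap area of the density-normalized histograms of two samples."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be nonempty")
    edges = np.histogram_bin_edges(np.concatenate([a, b]), bins=bins)
    fa, _ = np.histogram(a, bins=edges, density=True)
    fb, _ = np.histogram(b, bins=edges, density=True)
    widths = np.diff(edges)
    return float(np.sum(np.minimum(fa, fb) * widths))


def connectome_summary(matrix) -> dict:
    """Sparsity, average total vertex degree and mean nonzero edge strength."""
    M = sp.csr_matrix(matrix)
    n = M.shape[0]
    nnz = M.nnz
    sparsity = nnz / (n * n) if n else 0.0
    out_deg = np.asarray((M != 0).sum(axis=1)).ravel()
    in_deg = np.asarray((M != 0).sum(axis=0)).ravel()
    avg_degree = float(np.mean(out_deg + in_deg)) if n else 0.0
    avg_strength = float(M.data.mean()) if nnz else float("nan")
    return {
        "sparsity": float(sparsity),
        "avg_vertex_degree": avg_degree,
        "avg_edge_strength": avg_strength,
    }


def ensemble_summary(ensemble) -> dict:
    """Mean and SD of the per-graph summary statistics of an ensemble."""
    rows = [connectome_summary(A) for A in ensemble.graphs]
    frame = pd.DataFrame(rows)
    return {
        key: (float(frame[key].mean()), float(frame[key].std(ddof=0)))
        for key in frame.columns
    }


def subsample_robustness(
    strengths,
    fractions,
    config,
    seed: int = 0,
    min_subsample: int = 50,
    metadata=None,
) -> pd.DataFrame:
    """Rerun the pipeline on random subsamples and compare partitions.

    For each fraction f a simple random sample (without replacement) of
    ``round(f * n)`` neurons is clustered with ``c_size`` scaled by f.
    Returns a table with pairwise ARI over commonly classified neurons and
    the percentage classified by both (of all n neurons). ``metadata`` is
    accepted for interface parity but not needed by the comparison.
    """
    from dataclasses import replace

    from sbmcircuit.annotate import adjusted_rand_index
    from sbmcircuit.pipeline import run_core

    strengths = sp.csr_matrix(strengths)
    n = strengths.shape[0]
    rng = np.random.default_rng(seed)
    runs = {}
    for frac in fractions:
        if not 0.0 < frac <= 1.0:
            raise ValueError(f"fractions must lie in (0, 1], got {frac}")
        ns = int(round(frac * n))
        if ns < min_subsample:
            raise ValueError(
                f"subsample of {ns} neurons is too small for reliable block recovery; "
                f"use a larger fraction or dataset (minimum {min_subsample})"
            )
        idx = np.sort(rng.choice(n, size=ns, replace=False))
        sub = strengths[np.ix_(idx, idx)]
        c_size = max(1, int(round(config.c_size * ns / n)))
        cfg = replace(config, c_size=c_size)
        result = run_core(sub, cfg)
        labels = np.zeros(n, dtype=np.int64)
        labels[idx] = result.partition.labels
        runs[frac] = labels
    fractions = list(runs)
    table = pd.DataFrame(index=fractions, columns=fractions, dtype=object)
    for a in fractions:
        for b in fractions:
            both = (runs[a] > 0) & (runs[b] > 0)
            ari = (
                adjusted_rand_index(runs[a][both], runs[b][both])
                if both.sum() >= 2
                else np.nan
            )
            table.loc[a, b] = (round(float(ari), 4), round(100.0 * both.mean(), 2))
    return table
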