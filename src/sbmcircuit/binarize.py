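"""Weighted strengths to connection probabilities and binary ensembles.

The strength matrix is converted elementwise to a connection probability
``a_p = 1 - (1 - p_conn)**a_c`` (one Bernoulli trial per overlapping
segment pair), and an ensemble of G independent binary realizations is
sampled and trimmed so no surviving neuron lacks an incoming or outgoing
edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

DEFAULT_GRID = np.round(np.arange(0.01, 1.0 + 1e-9, 0.01), 2)


def as_seed_sequence(seed) -> np.random.SeedSequence:
    """Accept an int seed or pass through an existing SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


@dataclass
class ProbabilityMatrix:
    """Sparse matrix of per-pair connection probabilities."""

    matrix: sp.csr_matrix
    p_conn: float

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class BinaryEnsemble:
    """G trimmed binary adjacency matrices sampled from a probability matrix.

    ``graphs[l]`` is a CSR 0/1 matrix over the neurons listed in
    ``retained[l]`` (original indices, increasing). ``degenerate`` flags
    ensembles in which some realization trimmed away every neuron.
    """

    graphs: list = field(repr=False)
    retained: list = field(repr=False)
    n: int
    seed: int | None = None
    degenerate: bool = False

    @property
    def G(self) -> int:
        return len(self.graphs)


def strength_to_probability(strengths: sp.spmatrix, p_conn: float) -> ProbabilityMatrix:
    """Apply ``a_p = 1 - (1 - p_conn)**a_c`` elementwise.

    The sparsity pattern is preserved: zero strengths map to zero
    probability exactly.
    """
    if not 0.0 < p_conn <= 1.0:
        raise ValueError(f"p_conn must lie in (0, 1], got {p_conn}")
    strengths = sp.csr_matrix(strengths)
    probs = strengths.copy().astype(float)
    probs.data = 1.0 - (1.0 - p_conn) ** strengths.data
    return ProbabilityMatrix(matrix=probs, p_conn=p_conn)


def choose_p_conn(
    strengths: sp.spmatrix,
    target_mean: float = 0.5,
    grid: np.ndarray | None = None,
) -> float:
    """Pick the grid value of ``p_conn`` whose mean nonzero probability is
    closest to ``target_mean``.

    The default grid steps by 0.01 over (0, 1].
    """
    strengths = sp.csr_matrix(strengths)
    if strengths.nnz == 0:
        raise ValueError("strength matrix has no nonzero entries")
    if grid is None:
        grid = DEFAULT_GRID
    a_c = strengths.data.astype(float)
    best_p, best_err = None, np.inf
    for p in grid:
        mean_ap = np.mean(1.0 - (1.0 - p) ** a_c)
        err = abs(mean_ap - target_mean)
        if err < best_err:
            best_p, best_err = float(p), err
    return best_p


def trim_matrix(A: sp.spmatrix) -> tuple[sp.csr_matrix, np.ndarray]:
    """Iteratively remove neurons lacking an in-edge or an out-edge.

    Removal can zero out other neurons' degrees, so the rule is applied to
    a fixed point. Returns the trimmed matrix and the retained original
    indices (increasing). May return an empty matrix.
    """
    A = sp.csr_matrix(A)
    n = A.shape[0]
    retained = np.arange(n)
    while retained.size:
        sub = A[np.ix_(retained, retained)]
        out_deg = np.asarray(sub.sum(axis=1)).ravel()
        in_deg = np.asarray(sub.sum(axis=0)).ravel()
        keep = (out_deg > 0) & (in_deg > 0)
        if keep.all():
            return sp.csr_matrix(sub), retained
        retained = retained[keep]
    return sp.csr_matrix((0, 0)), retained


def sample_binary_ensemble(
    probs: ProbabilityMatrix | sp.spmatrix,
    G: int,
    seed: int = 0,
) -> BinaryEnsemble:
    """Sample G independent Bernoulli realizations and trim each.

    One master seed spawns a substream per matrix, so individual graphs are
    reproducible independently of G.
    """
    if G < 1:
        raise ValueError(f"G must be >= 1, got {G}")
    matrix = probs.matrix if isinstance(probs, ProbabilityMatrix) else sp.csr_matrix(probs)
    matrix = sp.coo_matrix(matrix)
    n = matrix.shape[0]
    children = as_seed_sequence(seed).spawn(G)
    graphs, retained_lists = [], []
    degenerate = False
    for child in children:
        rng = np.random.default_rng(child)
        keep = rng.random(matrix.nnz) < matrix.data
        A = sp.csr_matrix(
            (np.ones(int(keep.sum()), dtype=np.int8), (matrix.row[keep], matrix.col[keep])),
            shape=(n, n),
        )
        trimmed, retained = trim_matrix(A)
        if retained.size == 0:
            degenerate = True
        graphs.append(trimmed)
        retained_lists.append(retained)
    return BinaryEnsemble(
        graphs=graphs, retained=retained_lists, n=n, seed=seed, degenerate=degenerate
    )
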