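"""Synthetic stochastic-block-model connectomes with weighted strengths.

Generates ground-truth datasets: a sparse directed integer strength matrix
with planted block structure, plus categorical per-neuron metadata
(neurotransmitter-like categories and developmental birthtimes) whose
association with the planted blocks is tunable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmwrite

NEUROTRANSMITTERS = ("ACh", "DA", "GABA", "Glu", "OA", "5-HT")
BIRTHTIMES = ("embryo",) + tuple(f"day{i}" for i in range(1, 10))


@dataclass(frozen=True)
class SBMSpec:
    """Parameters of a directed stochastic block model.

    Attributes
    ----------
    n : int
        Number of neurons (vertices).
    kappa : int
        Number of blocks.
    rho : tuple of float
        Block membership probabilities, length ``kappa``, summing to 1.
    P : ndarray
        ``kappa x kappa`` block connection probabilities in [0, 1];
        ``P[a, b]`` is the probability of a directed edge from a block-``a``
        neuron to a block-``b`` neuron.
    strength_mean : float
        Target mean of the nonzero integer strengths (>= 1).
    seed : int
        Seed for all randomness in generation.
    """

    n: int
    kappa: int
    rho: tuple
    P: np.ndarray = field(repr=False)
    strength_mean: float = 7.8
    seed: int = 0

    def __post_init__(self):
        if self.kappa < 1:
            raise ValueError(f"kappa must be >= 1, got {self.kappa}")
        if self.n < self.kappa:
            raise ValueError(f"n must be >= kappa, got n={self.n}, kappa={self.kappa}")
        rho = np.asarray(self.rho, dtype=float)
        if rho.shape != (self.kappa,):
            raise ValueError(f"rho must have length kappa={self.kappa}, got {rho.shape}")
        if abs(rho.sum() - 1.0) > 1e-12:
            raise ValueError(f"rho must sum to 1 (got {rho.sum()!r})")
        if np.any(rho < 0):
            raise ValueError("rho entries must be nonnegative")
        P = np.asarray(self.P, dtype=float)
        if P.shape != (self.kappa, self.kappa):
            raise ValueError(f"P must be {self.kappa}x{self.kappa}, got {P.shape}")
        if np.any(P < 0) or np.any(P > 1):
            raise ValueError("P entries must lie in [0, 1]")
        if self.strength_mean < 1:
            raise ValueError(f"strength_mean must be >= 1, got {self.strength_mean}")
        object.__setattr__(self, "rho", tuple(rho))
        object.__setattr__(self, "P", P)


@dataclass
class SyntheticDataset:
    """A generated connectome with its ground truth.

    ``strengths`` is a CSR integer matrix with zero diagonal,
    ``true_labels`` assigns each neuron a block in ``1..kappa``, and
    ``metadata`` holds one row per neuron (at minimum ``neuron_id``).
    """

    strengths: sp.csr_matrix
    true_labels: np.ndarray
    metadata: pd.DataFrame

    @property
    def n(self) -> int:
        return self.strengths.shape[0]


def generate_sbm_strengths(spec: SBMSpec) -> SyntheticDataset:
    """Sample a weighted directed connectome from a planted SBM.

    A directed edge i -> j is present independently with probability
    ``P[b(i), b(j)]``; each present edge carries a positive integer strength
    drawn from a shifted geometric distribution (support {1, 2, ...}) with
    mean ``strength_mean``. Self-connections are excluded.
    """
    rng = np.random.default_rng(spec.seed)
    n, kappa = spec.n, spec.kappa
    rho = np.asarray(spec.rho)

    # multinomial block sizes, then a fixed (sorted) membership vector
    labels = rng.choice(np.arange(1, kappa + 1), size=n, p=rho)
    labels = np.sort(labels)
    # guarantee every block is populated (rare misses at small n)
    for b in range(1, kappa + 1):
        if not np.any(labels == b):
            labels[rng.integers(n)] = b
    labels = np.sort(labels)

    prob = spec.P[labels - 1][:, labels - 1]
    mask = rng.random((n, n)) < prob
    np.fill_diagonal(mask, False)
    rows, cols = np.nonzero(mask)
    if spec.strength_mean == 1.0:
        data = np.ones(rows.size, dtype=np.int64)
    else:
        data = rng.geometric(1.0 / spec.strength_mean, size=rows.size).astype(np.int64)
    strengths = sp.csr_matrix((data, (rows, cols)), shape=(n, n), dtype=np.int64)

    metadata = pd.DataFrame({"neuron_id": [f"neuron_{i:06d}" for i in range(n)]})
    return SyntheticDataset(strengths=strengths, true_labels=labels, metadata=metadata)


def generate_metadata(
    true_labels: np.ndarray,
    concordance: float,
    category_set,
    seed: int = 0,
) -> np.ndarray:
    """Draw one category per neuron with tunable block association.

    With probability ``concordance`` a neuron's category is a fixed function
    of its block (block b -> category ``category_set[(b - 1) % len]``);
    otherwise the category is drawn uniformly from ``category_set``.
    """
    categories = list(category_set)
    if not categories:
        raise ValueError("category_set must not be empty")
    if not 0.0 <= concordance <= 1.0:
        raise ValueError(f"concordance must lie in [0, 1], got {concordance}")
    true_labels = np.asarray(true_labels)
    kappa = int(true_labels.max())
    if concordance == 1.0 and len(categories) < kappa:
        raise ValueError(
            f"need at least {kappa} categories for concordance=1, got {len(categories)}"
        )
    rng = np.random.default_rng(seed)
    mapped = np.array([categories[(b - 1) % len(categories)] for b in true_labels])
    uniform = rng.choice(categories, size=true_labels.size)
    take_mapped = rng.random(true_labels.size) < concordance
    return np.where(take_mapped, mapped, uniform)


def generate_birthtimes(
    true_labels: np.ndarray,
    day_profiles: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Sample a birthtime per neuron from its block's day profile.

    ``day_profiles`` is ``kappa x 10``: row b-1 is a probability vector over
    ``("embryo", "day1", ..., "day9")`` for block b.
    """
    true_labels = np.asarray(true_labels)
    profiles = np.asarray(day_profiles, dtype=float)
    kappa = int(true_labels.max())
    if profiles.shape != (kappa, len(BIRTHTIMES)):
        raise ValueError(
            f"day_profiles must be {kappa}x{len(BIRTHTIMES)}, got {profiles.shape}"
        )
    sums = profiles.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-9):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValueError(f"day profile for block {bad + 1} sums to {sums[bad]!r}, not 1")
    rng = np.random.default_rng(seed)
    days = np.arange(len(BIRTHTIMES))
    out = np.empty(true_labels.size, dtype=object)
    for b in range(1, kappa + 1):
        idx = np.nonzero(true_labels == b)[0]
        draws = rng.choice(days, size=idx.size, p=profiles[b - 1])
        out[idx] = np.array(BIRTHTIMES, dtype=object)[draws]
    return out.astype(str)


def make_dataset(
    spec: SBMSpec,
    nt_concordance: float = 0.8,
    day_profiles: np.ndarray | None = None,
) -> SyntheticDataset:
    """Generate strengths plus a full metadata table in one call."""
    ds = generate_sbm_strengths(spec)
    sub = np.random.SeedSequence(spec.seed).spawn(3)
    ds.metadata["neurotransmitter"] = generate_metadata(
        ds.true_labels, nt_concordance, NEUROTRANSMITTERS, seed=sub[0]
    )
    if day_profiles is None:
        rng = np.random.default_rng(sub[1])
        day_profiles = rng.dirichlet(np.ones(len(BIRTHTIMES)), size=spec.kappa)
    ds.metadata["birthtime"] = generate_birthtimes(ds.true_labels, day_profiles, seed=sub[2])
    ds.metadata["community"] = generate_metadata(
        ds.true_labels, nt_concordance, [f"community_{i}" for i in range(spec.kappa)], seed=sub[0]
    )
    return ds


def save_dataset(ds: SyntheticDataset, out_dir) -> None:
    """Write the strength matrix (Matrix Market), labels and metadata (CSV)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(out_dir / "strengths.mtx"), ds.strengths.tocoo(), field="integer")
    pd.DataFrame(
        {"neuron_id": ds.metadata["neuron_id"], "true_label": ds.true_labels}
    ).to_csv(out_dir / "true_labels.csv", index=False)
    ds.metadata.to_csv(out_dir / "metadata.csv", index=False)
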