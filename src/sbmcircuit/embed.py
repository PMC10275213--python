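"""Spectral graph clustering of a single binary connectome.

Adjacency spectral embedding (rank-d SVD, latent positions
``[U_d sqrt(D_d) | V_d sqrt(D_d)]``), embedding-dimension selection by the
two-group Gaussian profile likelihood of the singular values (elbow
method), and Gaussian-mixture clustering with BIC model selection
initialized from Ward agglomerative partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, ward
from sklearn.mixture import GaussianMixture
from sklearn.utils.extmath import randomized_svd

_DENSE_SVD_MAX = 1200  # exact dense SVD below this size, randomized above
_VARIANCE_FLOOR = 1e-12


@dataclass
class SpectralEmbedding:
    """Rank-d spectral embedding of an adjacency matrix."""

    singular_values: np.ndarray
    latent: np.ndarray  # n x 2d, [X | Y]
    d: int


@dataclass
class DimensionSelection:
    """Profile-likelihood elbow selection over sorted singular values."""

    first_elbow: int
    second_elbow: int | None
    profile: np.ndarray  # log-likelihood per candidate cut (index q-1 <-> cut q)


@dataclass
class GmmClustering:
    """GMM/EM clustering with BIC-selected component count.

    ``labels`` are 1-based; ``criterion_trace[k-1]`` is the (negated) BIC
    for k components, so the selected k maximizes the trace.
    """

    labels: np.ndarray
    k: int
    criterion_trace: np.ndarray = field(repr=False)
    converged: bool = True


def _svd(A, k: int, seed: int = 0):
    """Top-k singular triplets; exact for small matrices."""
    n = min(A.shape)
    if n <= _DENSE_SVD_MAX:
        dense = A.toarray() if sp.issparse(A) else np.asarray(A, dtype=float)
        U, s, Vt = np.linalg.svd(dense, full_matrices=False)
        return U[:, :k], s[:k], Vt[:k]
    return randomized_svd(A.astype(float), n_components=k, n_iter=7, random_state=seed)


def ase_embed(A, d: int, seed: int = 0) -> SpectralEmbedding:
    """Adjacency spectral embedding of ``A`` at rank ``d``.

    Returns latent positions ``[X | Y]`` with ``X = U_d sqrt(D_d)`` and
    ``Y = V_d sqrt(D_d)``; ``X @ Y.T`` is the best rank-d approximation of
    ``A`` in Frobenius norm (exactly so when the SVD is computed densely).
    """
    n = min(A.shape)
    if not 1 <= d <= n:
        raise ValueError(f"d must lie in [1, {n}], got {d}")
    U, s, Vt = _svd(A, d, seed=seed)
    if d <= s.size and np.any(s[:d] < -1e-12):
        raise ValueError("negative singular values: invalid decomposition")
    root = np.sqrt(np.maximum(s[:d], 0.0))
    X = U[:, :d] * root
    Y = Vt[:d].T * root
    return SpectralEmbedding(singular_values=s[:d], latent=np.hstack([X, Y]), d=d)


def _profile_loglik(values: np.ndarray) -> np.ndarray:
    """Two-group Gaussian profile log-likelihood for each cut q=1..r-1.

    Both groups share a pooled MLE variance, floored to avoid degeneracy
    when all values in both groups coincide.
    """
    values = np.asarray(values, dtype=float)
    r = values.size
    profile = np.empty(r - 1)
    for q in range(1, r):
        g1, g2 = values[:q], values[q:]
        ss = ((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()
        var = max(ss / r, _VARIANCE_FLOOR)
        profile[q - 1] = -0.5 * r * np.log(2 * np.pi * var) - ss / (2 * var)
    return profile


def select_dimension(singular_values, max_rank: int | None = None) -> DimensionSelection:
    """Pick the elbow cut maximizing the profile likelihood of the values.

    Values are sorted nonincreasing and truncated to ``max_rank``. The
    second elbow (first elbow of the remaining tail) is also reported, as
    scree plots of block-model spectra often place the informative cut
    there. All-equal values return an elbow of 1 by convention.
    """
    values = np.sort(np.asarray(singular_values, dtype=float))[::-1]
    if max_rank is not None:
        values = values[:max_rank]
    if values.size < 3:
        raise ValueError(f"need at least 3 singular values, got {values.size}")
    profile = _profile_loglik(values)
    first = int(np.argmax(profile)) + 1
    second = None
    tail = values[first:]
    if tail.size >= 3:
        second = first + int(np.argmax(_profile_loglik(tail))) + 1
    return DimensionSelection(first_elbow=first, second_elbow=second, profile=profile)


def _agglomerative_init(X: np.ndarray, k: int):
    """Ward-linkage partition of the latent vectors as EM initialization."""
    if k == 1:
        return np.zeros(X.shape[0], dtype=int)
    Z = ward(X)
    return fcluster(Z, t=k, criterion="maxclust") - 1


def _init_params(X: np.ndarray, init_labels: np.ndarray, k: int, reg: float):
    n, dim = X.shape
    weights = np.empty(k)
    means = np.empty((k, dim))
    precisions = np.empty((k, dim, dim))
    for j in range(k):
        members = X[init_labels == j]
        if members.shape[0] == 0:  # degenerate ward cut; reseed from global mean
            members = X
        weights[j] = members.shape[0] / n
        means[j] = members.mean(axis=0)
        cov = np.cov(members, rowvar=False) if members.shape[0] > 1 else np.eye(dim)
        cov = np.atleast_2d(cov) + reg * np.eye(dim)
        precisions[j] = np.linalg.inv(cov)
    weights /= weights.sum()
    return weights, means, precisions


def fit_gmm_bic(
    embedding: SpectralEmbedding | np.ndarray,
    k_max: int,
    seed: int = 0,
    covariance: str = "full",
    max_iter: int = 500,
    tol: float = 1e-6,
    reg_covar: float = 1e-6,
    ward_tree=None,
) -> GmmClustering:
    """Fit GMMs for k = 1..k_max and keep the BIC-optimal one.

    Each EM run is initialized from a Ward agglomerative partition of the
    latent vectors (a deterministic stand-in for model-based hierarchical
    initialization). Non-convergence of the selected model is surfaced via
    ``converged``.
    """
    X = embedding.latent if isinstance(embedding, SpectralEmbedding) else np.asarray(embedding)
    n = X.shape[0]
    if k_max < 1:
        raise ValueError(f"k_max must be >= 1, got {k_max}")
    k_max = min(k_max, n)
    Z = ward_tree if ward_tree is not None else (ward(X) if n > 1 else None)

    best = None
    trace = np.full(k_max, -np.inf)
    for k in range(1, k_max + 1):
        init_labels = (
            np.zeros(n, dtype=int) if (k == 1 or Z is None) else fcluster(Z, t=k, criterion="maxclust") - 1
        )
        kwargs = {}
        if covariance == "full":
            w, mu, prec = _init_params(X, init_labels, k, reg_covar)
            kwargs = dict(weights_init=w, means_init=mu, precisions_init=prec)
        else:
            mu = np.vstack([X[init_labels == j].mean(axis=0) if np.any(init_labels == j) else X.mean(axis=0) for j in range(k)])
            kwargs = dict(means_init=mu)
        gm = GaussianMixture(
            n_components=k,
            covariance_type=covariance,
            max_iter=max_iter,
            tol=tol,
            reg_covar=reg_covar,
            random_state=seed,
            **kwargs,
        )
        gm.fit(X)
        trace[k - 1] = -gm.bic(X)
        if best is None or trace[k - 1] > trace[best[0] - 1]:
            best = (k, gm)
    k, gm = best
    labels = gm.predict(X) + 1
    # renumber so labels are contiguous 1..#distinct
    uniq = np.unique(labels)
    remap = {old: new for new, old in enumerate(uniq, start=1)}
    labels = np.array([remap[v] for v in labels])
    return GmmClustering(labels=labels, k=len(uniq), criterion_trace=trace, converged=bool(gm.converged_))


def cluster_single_graph(
    A,
    d: int | None = None,
    k_max: int = 20,
    seed: int = 0,
    elbow: int = 1,
    max_rank: int | None = None,
    covariance: str = "full",
) -> GmmClustering:
    """Spectral clustering of one trimmed binary connectome.

    Embeds ``A`` at rank ``d`` (selected via profile likelihood when not
    given: ``elbow=1`` takes the first elbow, ``elbow=2`` the second) then
    clusters the latent vectors with :func:`fit_gmm_bic`.
    """
    n = min(A.shape)
    if n == 0:
        raise ValueError("empty matrix cannot be clustered")
    if d is None:
        scan = max_rank if max_rank is not None else min(n - 1, 50)
        scan = max(scan, 3)
        _, svals, _ = _svd(A, min(scan, n), seed=seed)
        sel = select_dimension(svals)
        d = sel.first_elbow if (elbow == 1 or sel.second_elbow is None) else sel.second_elbow
    emb = ase_embed(A, d, seed=seed)
    return fit_gmm_bic(emb, k_max=k_max, seed=seed, covariance=covariance)
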