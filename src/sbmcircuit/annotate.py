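"""Biomarker mapping and comparison between classification schemes.

Posterior category tables per class with dominant-label assignment, and
information-theoretic dependence measures between labelings: entropy,
mutual information, directional normalized mutual information, the
adjusted Rand index and the mean absolute difference of category
distributions. Logs are base 2 throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import comb


def _paired(x, y):
    x = pd.Series(np.asarray(x, dtype=object))
    y = pd.Series(np.asarray(y, dtype=object))
    if len(x) != len(y):
        raise ValueError("labelings must cover the same neuron index")
    keep = x.notna() & y.notna()
    return x[keep].to_numpy(), y[keep].to_numpy()


def posterior_table(x, y) -> pd.DataFrame:
    """Empirical conditional probabilities ``p(Y = col | X = row)``.

    Pairs where either labeling is missing (None/NaN) are dropped; rows of
    the returned table sum to 1.
    """
    xv, yv = _paired(x, y)
    if xv.size == 0:
        raise ValueError("no neurons labeled by both schemes")
    counts = pd.crosstab(pd.Series(xv, name="X"), pd.Series(yv, name="Y"))
    return counts.div(counts.sum(axis=1), axis=0)


def dominant_label(posteriors: pd.DataFrame, threshold: float = 0.67) -> dict:
    """Assign class i the category j iff ``p(Y=j | X=i) > threshold``.

    The inequality is strict; classes with no dominant category map to
    None.
    """
    out = {}
    for cls, row in posteriors.iterrows():
        best = row.idxmax()
        out[cls] = best if row[best] > threshold else None
    return out


def _probs(values) -> np.ndarray:
    _, counts = np.unique(np.asarray(values, dtype=object), return_counts=True)
    return counts / counts.sum()


def entropy(x) -> float:
    """Shannon entropy in bits of the empirical label distribution."""
    p = _probs(x)
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def mutual_information(x, y) -> float:
    """Empirical mutual information I(X; Y) in bits."""
    xv, yv = _paired(x, y)
    joint = pd.crosstab(pd.Series(xv), pd.Series(yv)).to_numpy(dtype=float)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (px * py))
    return float(np.nansum(terms))


def nmi(x, y) -> tuple[float, bool]:
    """Directional NMI(X -> Y) = I(X; Y) / H(Y).

    Returns ``(value, degenerate)``; when H(Y) = 0 the value is reported
    as 1 if X is also constant and 0 otherwise, with the degeneracy
    flagged.
    """
    xv, yv = _paired(x, y)
    hy = entropy(yv)
    if hy == 0.0:
        return (1.0 if entropy(xv) == 0.0 else 0.0), True
    return mutual_information(xv, yv) / hy, False


def adjusted_rand_index(x, y) -> float:
    """Permutation-model adjusted Rand index between two labelings.

    Restricted to items labeled under both schemes; 1 for identical
    partitions, expectation 0 for independent ones.
    """
    xv, yv = _paired(x, y)
    n = xv.size
    if n < 2:
        raise ValueError("need at least 2 co-labeled neurons for ARI")
    table = pd.crosstab(pd.Series(xv), pd.Series(yv)).to_numpy()
    sum_comb = comb(table, 2).sum()
    sum_a = comb(table.sum(axis=1), 2).sum()
    sum_b = comb(table.sum(axis=0), 2).sum()
    expected = sum_a * sum_b / comb(n, 2)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))


def mean_absolute_difference(dist_a, dist_b) -> float:
    """Mean of |a_c - b_c| over a common category set.

    Accepts mappings/Series keyed by category (sets must match) or aligned
    vectors.
    """
    if isinstance(dist_a, (dict, pd.Series)) and isinstance(dist_b, (dict, pd.Series)):
        a, b = pd.Series(dist_a), pd.Series(dist_b)
        if set(a.index) != set(b.index):
            raise ValueError("category sets differ between the two distributions")
        b = b.reindex(a.index)
        return float(np.mean(np.abs(a.to_numpy(float) - b.to_numpy(float))))
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("distributions must share the same categories")
    return float(np.mean(np.abs(a - b)))


def nmi_matrix(schemes: dict) -> pd.DataFrame:
    """Pairwise directional NMI table: entry (row X, col Y) = NMI(X -> Y)."""
    names = list(schemes)
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for a in names:
        for b in names:
            out.loc[a, b] = nmi(schemes[a], schemes[b])[0]
    return out
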