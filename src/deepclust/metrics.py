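"""Clustering-quality metrics computed from the label contingency table.

NMI (mutual information normalized by the arithmetic mean of the label
entropies), Rand index and its adjusted form, unsupervised clustering
accuracy (best one-to-one cluster/class matching via the Hungarian
algorithm), homogeneity/completeness, the train/validation
generalizability ratio G, within-cluster sum of squares and the Elbow
knee rule.  All entropies use natural logarithms; NMI itself is
base-invariant but the intermediate values are reproducible this way.

Density-based algorithms may emit a noise label of -1; by default each
noise point is treated as its own singleton cluster (``noise="singleton"``),
or noise points can be dropped entirely (``noise="exclude"``).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import comb

from .containers import MetricsReport

__all__ = [
    "nmi",
    "rand_index",
    "adjusted_rand_index",
    "unsupervised_accuracy",
    "homogeneity_completeness",
    "generalizability",
    "wcss",
    "elbow_select",
    "evaluate_clustering",
]


def _resolve_noise(y: np.ndarray, c: np.ndarray, noise: str):
    """Apply the noise-label policy to predicted labels."""
    if noise == "singleton":
        if np.any(c == -1):
            c = c.copy()
            nxt = c.max() + 1
            for i in np.flatnonzero(c == -1):
                c[i] = nxt
                nxt += 1
        return y, c
    if noise == "exclude":
        keep = c != -1
        return y[keep], c[keep]
    raise ValueError("noise policy must be 'singleton' or 'exclude'")


def _labels(y, c, noise: str = "singleton"):
    y = np.asarray(y).ravel()
    c = np.asarray(c).ravel()
    if y.shape != c.shape:
        raise ValueError("label vectors must have equal length")
    return _resolve_noise(y, c, noise)


def _contingency(y: np.ndarray, c: np.ndarray) -> np.ndarray:
    _, yi = np.unique(y, return_inverse=True)
    _, ci = np.unique(c, return_inverse=True)
    table = np.zeros((yi.max() + 1, ci.max() + 1), dtype=np.int64)
    np.add.at(table, (yi, ci), 1)
    return table


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def nmi(y, c, noise: str = "singleton") -> float:
    """NMI(y, c) = I(y, c) / ((H(y) + H(c)) / 2), in [0, 1].

    Symmetric and invariant to relabeling.  When both partitions are
    trivial (a single cluster each) the value is 1.0 by convention.
    """
    y, c = _labels(y, c, noise)
    if y.size == 0:
        raise ValueError("empty label vectors")
    table = _contingency(y, c)
    hy = _entropy(table.sum(axis=1))
    hc = _entropy(table.sum(axis=0))
    if hy == 0.0 and hc == 0.0:
        return 1.0
    n = table.sum()
    pij = table / n
    outer = np.outer(table.sum(axis=1), table.sum(axis=0)) / (n * n)
    mask = pij > 0
    mi = float((pij[mask] * np.log(pij[mask] / outer[mask])).sum())
    return mi / (0.5 * (hy + hc))


def _pair_counts(table: np.ndarray) -> tuple[float, float, float, float]:
    """(TP, FP, FN, TN) over all n(n-1)/2 sample pairs."""
    n = table.sum()
    total = comb(n, 2)
    same_both = comb(table, 2).sum()  # TP
    same_c = comb(table.sum(axis=0), 2).sum()
    same_y = comb(table.sum(axis=1), 2).sum()
    fp = same_c - same_both  # same cluster, different class
    fn = same_y - same_both  # same class, different cluster
    tn = total - same_both - fp - fn
    return float(same_both), float(fp), float(fn), float(tn)


def rand_index(y, c, noise: str = "singleton") -> float:
    """RI = (TP + TN) / all pairs: fraction of pairwise decisions correct."""
    y, c = _labels(y, c, noise)
    if y.size < 2:
        raise ValueError("rand index needs at least 2 samples")
    tp, fp, fn, tn = _pair_counts(_contingency(y, c))
    return (tp + tn) / (tp + fp + fn + tn)


def adjusted_rand_index(y, c, noise: str = "singleton") -> float:
    """ARI: Rand index corrected for chance under the permutation model.

    (Index - E[Index]) / (Max - E[Index]) with fixed marginals; 1 for
    identical partitions, ~0 for independent labelings, can be negative.
    Degenerate cases with zero denominator (e.g. both partitions trivial)
    return 1.0 by convention.
    """
    y, c = _labels(y, c, noise)
    if y.size < 2:
        raise ValueError("adjusted rand index needs at least 2 samples")
    table = _contingency(y, c)
    n = table.sum()
    sum_ij = comb(table, 2).sum()
    a = comb(table.sum(axis=1), 2).sum()
    b = comb(table.sum(axis=0), 2).sum()
    expected = a * b / comb(n, 2)
    max_index = 0.5 * (a + b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def unsupervised_accuracy(y, c, noise: str = "singleton") -> float:
    """ACC = max over one-to-one cluster->class mappings of match fraction.

    The optimal mapping is found with the Hungarian algorithm on the
    (square-padded) negated contingency table; invariant to any
    relabeling of ``c``.
    """
    y, c = _labels(y, c, noise)
    if y.size == 0:
        raise ValueError("empty label vectors")
    table = _contingency(y, c)
    k = max(table.shape)
    padded = np.zeros((k, k), dtype=np.int64)
    padded[: table.shape[0], : table.shape[1]] = table
    rows, cols = linear_sum_assignment(-padded)
    return float(padded[rows, cols].sum() / y.size)


def homogeneity_completeness(y, c, noise: str = "singleton") -> tuple[float, float]:
    """(homogeneity, completeness) via conditional entropies.

    homogeneity = 1 - H(y|c)/H(y): each cluster contains members of a
    single class.  completeness = 1 - H(c|y)/H(c): all members of a class
    land in the same cluster.  Either is 1.0 when its reference entropy
    is zero (documented convention, matching the V-measure treatment).
    """
    y, c = _labels(y, c, noise)
    if y.size == 0:
        raise ValueError("empty label vectors")
    table = _contingency(y, c)
    n = table.sum()
    hy = _entropy(table.sum(axis=1))
    hc = _entropy(table.sum(axis=0))

    def cond_entropy(t: np.ndarray) -> float:
        # H(row | col) for table t: sum over cols of p(col) * H(rows in col)
        total = 0.0
        for j in range(t.shape[1]):
            col = t[:, j]
            cs = col.sum()
            if cs == 0:
                continue
            p = col[col > 0] / cs
            total += (cs / n) * float(-(p * np.log(p)).sum())
        return total

    h_y_given_c = cond_entropy(table)
    h_c_given_y = cond_entropy(table.T)
    hom = 1.0 if hy == 0 else 1.0 - h_y_given_c / hy
    com = 1.0 if hc == 0 else 1.0 - h_c_given_y / hc
    return float(hom), float(com)


def generalizability(L_train: float, L_validation: float) -> float:
    """G = L_train / L_validation; values well below 1 indicate overfitting."""
    if L_validation <= 0:
        raise ValueError("validation loss must be positive")
    return float(L_train) / float(L_validation)


def wcss(Z: np.ndarray, labels, centroids: np.ndarray,
         noise: str = "singleton") -> float:
    """Within-cluster sum of squared distances to the assigned centroid.

    Noise points (-1) are excluded under either policy (a singleton is
    its own centroid and contributes zero).
    """
    Z = np.asarray(Z, dtype=float)
    labels = np.asarray(labels).ravel()
    centroids = np.asarray(centroids, dtype=float)
    total = 0.0
    for lab in np.unique(labels):
        if lab == -1:
            continue
        if lab < 0 or lab >= len(centroids):
            raise ValueError(f"label {lab} has no centroid")
        diff = Z[labels == lab] - centroids[int(lab)]
        total += float((diff ** 2).sum())
    return total


def elbow_select(wcss_by_k: dict[int, float]) -> int:
    """Knee of the WCSS-vs-K curve by the maximum discrete second difference.

    Requires at least 3 contiguous K values; ties break toward smaller K.
    """
    ks = sorted(wcss_by_k)
    if len(ks) < 3:
        raise ValueError("need at least 3 K values")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("K values must be contiguous")
    w = np.array([wcss_by_k[k] for k in ks])
    second = w[:-2] - 2 * w[1:-1] + w[2:]
    return ks[1 + int(np.argmax(second))]


def evaluate_clustering(y, c, Z: np.ndarray | None = None,
                        centroids: np.ndarray | None = None,
                        G: float | None = None,
                        noise: str = "singleton") -> MetricsReport:
    """Compute the full metric suite for one run."""
    hom, com = homogeneity_completeness(y, c, noise)
    report = MetricsReport(
        acc=unsupervised_accuracy(y, c, noise),
        nmi=nmi(y, c, noise),
        ri=rand_index(y, c, noise),
        ari=adjusted_rand_index(y, c, noise),
        homogeneity=hom,
        completeness=com,
        G=G,
    )
    if Z is not None and centroids is not None:
        k = len(centroids)
        report.wcss_by_k = {k: wcss(Z, c, centroids, noise)}
    return report
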