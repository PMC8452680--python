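"""Distances, embedding, clustering and reference-class assignment.

Samples are compared by one minus the variance-weighted Pearson
correlation of their beta profiles; the resulting distance matrix feeds
an exact t-SNE (no input PCA, 2,500 iterations, perplexity 20).
Hierarchical views use Ward linkage on Euclidean distances between
samples and complete linkage between probes.  Query samples are
assigned to a reference methylation class by majority vote among their
k nearest references under the weighted-correlation distance, which
formalizes reading class membership off the embedding.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.manifold import TSNE

logger = logging.getLogger(__name__)

__all__ = [
    "select_probes",
    "weighted_pearson_distance",
    "cross_weighted_pearson_distance",
    "tsne_embed",
    "ward_cluster",
    "order_probes",
    "assign_class",
    "ClassAssignment",
]


def select_probes(beta: pd.DataFrame, n: int, criterion: str = "sd") -> pd.Index:
    """Top-n probes by across-sample standard deviation.

    Ties are broken by lexicographic probe id so the selection is
    deterministic.  ``criterion='all'`` returns every probe.
    """
    if criterion == "all":
        return beta.columns
    if criterion != "sd":
        raise ValueError(f"unknown criterion {criterion!r}")
    if n <= 0:
        raise ValueError("n must be > 0")
    n = min(n, beta.shape[1])
    sds = beta.std(axis=0, ddof=1)
    order = sorted(beta.columns, key=lambda p: (-sds[p], p))
    return pd.Index(order[:n])


def _weighted_corr(X: np.ndarray, Y: np.ndarray, w: np.ndarray,
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted Pearson correlation between all rows of X and all rows of Y.

    Returns (corr, var_x, var_y); zero-variance rows yield NaN columns/rows.
    """
    w = w / w.sum()
    mx = X @ w
    my = Y @ w
    Xc = X - mx[:, None]
    Yc = Y - my[:, None]
    cov = (Xc * w) @ Yc.T
    vx = (Xc * w * Xc).sum(axis=1)
    vy = (Yc * w * Yc).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.sqrt(np.outer(vx, vy))
    return corr, vx, vy


def weighted_pearson_distance(beta: pd.DataFrame,
                              weights: np.ndarray | str = "variance",
                              ) -> pd.DataFrame:
    """Pairwise distance 1 - r_w between samples (rows of ``beta``).

    ``weights`` is a per-probe nonnegative vector, or ``'variance'`` to
    use the across-sample variance of each probe (the default reading of
    a variance-weighted correlation), or ``'uniform'``.  A sample with
    zero weighted variance (constant profile) is assigned distance 1 to
    every other sample, with a log notice.
    """
    if beta.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    X = beta.to_numpy(dtype=float)
    if isinstance(weights, str):
        if weights == "variance":
            w = X.var(axis=0, ddof=1)
        elif weights == "uniform":
            w = np.ones(X.shape[1])
        else:
            raise ValueError(f"unknown weights {weights!r}")
    else:
        w = np.asarray(weights, dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be nonnegative and not all zero")
    corr, vx, _ = _weighted_corr(X, X, w)
    D = 1.0 - corr
    degenerate = vx <= 0
    if degenerate.any():
        logger.info("constant profile for %d sample(s); distance set to 1",
                    int(degenerate.sum()))
        D[degenerate, :] = 1.0
        D[:, degenerate] = 1.0
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, 2.0)
    return pd.DataFrame(D, index=beta.index, columns=beta.index)


def cross_weighted_pearson_distance(query: pd.DataFrame, reference: pd.DataFrame,
                                    weights: np.ndarray) -> pd.DataFrame:
    """Distance 1 - r_w from each query row to each reference row."""
    common = reference.columns
    corr, vq, _ = _weighted_corr(query.loc[:, common].to_numpy(dtype=float),
                                 reference.to_numpy(dtype=float),
                                 np.asarray(weights, dtype=float))
    D = 1.0 - corr
    D[vq <= 0, :] = 1.0
    return pd.DataFrame(np.clip(D, 0.0, 2.0), index=query.index,
                        columns=reference.index)


def tsne_embed(distance: pd.DataFrame, perplexity: float = 20.0,
               max_iter: int = 2500, seed: int = 42) -> pd.DataFrame:
    """Exact t-SNE on a precomputed distance matrix.

    Runs with theta = 0 (exact gradients), no input PCA, 2,500
    iterations and perplexity 20 by default; coordinates are
    deterministic given the seed.  If the cohort is too small for the
    requested perplexity (n < 3*perplexity + 1) the perplexity is
    reduced with a warning.
    """
    # copy: the solver works on the distance matrix in place
    D = distance.to_numpy(dtype=float, copy=True)
    if not np.isfinite(D).all():
        raise ValueError("non-finite distances")
    n = D.shape[0]
    if n < 3 * perplexity + 1:
        new = max((n - 1) / 3.0, 2.0)
        warnings.warn(f"perplexity {perplexity} too large for n={n}; "
                      f"reduced to {new:.1f}")
        perplexity = new
    model = TSNE(n_components=2, metric="precomputed", method="exact",
                 init="random", perplexity=perplexity, max_iter=max_iter,
                 random_state=seed)
    coords = model.fit_transform(D)
    return pd.DataFrame(coords, index=distance.index, columns=["tsne_1", "tsne_2"])


def ward_cluster(beta: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Ward-linkage dendrogram over samples (Euclidean distance).

    Returns the scipy linkage matrix and the leaf order as sample ids.
    """
    if beta.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    Z = hierarchy.linkage(beta.to_numpy(dtype=float), method="ward")
    order = [beta.index[i] for i in hierarchy.leaves_list(Z)]
    return Z, order


def order_probes(beta: pd.DataFrame) -> list[str]:
    """Probe display order from complete-linkage clustering of probes."""
    if beta.shape[1] < 2:
        raise ValueError("need >= 2 probes")
    Z = hierarchy.linkage(pdist(beta.to_numpy(dtype=float).T), method="complete")
    return [beta.columns[i] for i in hierarchy.leaves_list(Z)]


@dataclass
class ClassAssignment:
    sample_id: str
    label: str
    votes: dict[str, int]
    mean_neighbor_distance: float


def assign_class(query: pd.DataFrame, reference: pd.DataFrame,
                 reference_labels: pd.Series, k: int = 5,
                 weights: str = "variance") -> list[ClassAssignment]:
    """k-nearest-reference class assignment under the weighted distance.

    Probe weights are the per-probe variances of the reference cohort
    (or uniform).  Each query is labeled by majority vote among its k
    nearest references; a vote tie goes to the class with the smallest
    mean neighbor distance, and an exact distance tie to the
    lexicographically first label.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > reference.shape[0]:
        raise ValueError("k exceeds reference count")
    labels = reference_labels.loc[reference.index]
    if labels.nunique() < 2:
        raise ValueError("references must span >= 2 classes")
    R = reference.to_numpy(dtype=float)
    if weights == "variance":
        w = R.var(axis=0, ddof=1)
    elif weights == "uniform":
        w = np.ones(R.shape[1])
    else:
        raise ValueError(f"unknown weights {weights!r}")
    if w.sum() <= 0:
        raise ValueError("reference cohort has zero variance everywhere")
    D = cross_weighted_pearson_distance(query, reference, w)

    out: list[ClassAssignment] = []
    lab_arr = labels.to_numpy()
    for qid in query.index:
        d = D.loc[qid].to_numpy()
        nn = np.argsort(d, kind="stable")[:k]
        votes: dict[str, int] = {}
        for i in nn:
            votes[lab_arr[i]] = votes.get(lab_arr[i], 0) + 1
        best_count = max(votes.values())
        tied = sorted(c for c, v in votes.items() if v == best_count)
        if len(tied) > 1:
            mean_d = {c: float(d[nn][lab_arr[nn] == c].mean()) for c in tied}
            lo = min(mean_d.values())
            tied = sorted(c for c in tied if mean_d[c] <= lo + 1e-12)
        label = tied[0]
        mask = lab_arr[nn] == label
        out.append(ClassAssignment(
            sample_id=qid, label=label, votes=votes,
            mean_neighbor_distance=float(d[nn][mask].mean())))
    return out
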