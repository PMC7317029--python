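"""Phenotype-profile clustering.

Three pieces: row scaling for display and distance computation, model-based
selection of the number of clusters (BIC over spherical Gaussian mixtures),
agglomerative clustering with Euclidean distance, and resampling-based
consensus clustering of categories with CDF-delta-area model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .exceptions import DegenerateInputError, InvalidArgumentError

LINKAGES = ("single", "complete", "average", "ward")


@dataclass
class ClusteringResult:
    k: int
    labels: pd.Series           # item -> cluster id (1..k)
    linkage_matrix: np.ndarray  # scipy linkage encoding of the dendrogram
    leaf_order: list
    distance: str = "euclidean"

    def __post_init__(self):
        if not (1 <= self.k <= len(self.labels)):
            raise InvalidArgumentError("k out of range")


@dataclass
class ConsensusResult:
    k: int
    labels: pd.Series
    consensus: dict = field(default_factory=dict)   # K -> DataFrame (item x item)
    cdf_area: dict = field(default_factory=dict)    # K -> area under consensus CDF
    delta_area: dict = field(default_factory=dict)  # K -> relative increase


def _as_frame(matrix) -> pd.DataFrame:
    df = pd.DataFrame(matrix)
    return df


def row_scale(matrix) -> tuple[pd.DataFrame, pd.Series]:
    """Center each row to mean 0 and scale to unit (population) SD.

    Constant rows map to all-zero and are flagged.  Returns (scaled, flags).
    """
    df = _as_frame(matrix).astype(float)
    if df.shape[1] < 2:
        raise InvalidArgumentError("row scaling needs >= 2 columns")
    vals = df.to_numpy()
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    constant = sd[:, 0] == 0
    sd[constant, 0] = 1.0
    scaled = (vals - mu) / sd
    scaled[constant, :] = 0.0
    return (pd.DataFrame(scaled, index=df.index, columns=df.columns),
            pd.Series(constant, index=df.index, name="constant_row"))


def select_k(matrix, k_min: int = 1, k_max: int = 15,
             seed: int = 0) -> tuple[int, pd.Series]:
    """Model-based choice of K: BIC over spherical-component mixtures.

    Each K is fit as a mixture of spherical Gaussian components sharing one
    variance parameter (centers from seeded k-means); the shared variance
    keeps BIC from rewarding the splitting of a single tight cloud, which a
    per-component variance does through the usual likelihood singularity.
    Returns the K minimizing BIC and the full criterion curve for audit.
    """
    df = _as_frame(matrix).astype(float)
    X = df.to_numpy()
    n_unique = len(np.unique(X, axis=0)) if X.size else 0
    if n_unique == 0:
        raise DegenerateInputError("empty matrix")
    if n_unique == 1:
        return 1, pd.Series({1: float("nan")}, name="bic")
    if not (1 <= k_min <= k_max):
        raise InvalidArgumentError("need 1 <= k_min <= k_max")
    if k_max >= len(df):
        raise InvalidArgumentError("k_max must be smaller than the number of rows")
    n, d = X.shape
    k_hi = min(k_max, n_unique)
    bics = {}
    for k in range(k_min, k_hi + 1):
        km = KMeans(n_clusters=k, random_state=seed, n_init=10)
        labels = km.fit_predict(X)
        sse = float(km.inertia_)
        sigma2 = max(sse / (n * d), 1e-12)
        sizes = np.bincount(labels, minlength=k).astype(float)
        sizes = sizes[sizes > 0]
        log_lik = (np.sum(sizes * np.log(sizes / n))
                   - 0.5 * n * d * np.log(2 * np.pi * sigma2)
                   - 0.5 * n * d)
        n_params = (k - 1) + k * d + 1
        bics[k] = float(-2.0 * log_lik + n_params * np.log(n))
    curve = pd.Series(bics, name="bic")
    return int(curve.idxmin()), curve


def hierarchical(matrix, k: int, linkage: str = "average",
                 scale_rows: bool = False) -> ClusteringResult:
    """Agglomerative clustering with Euclidean distance; cut at K clusters."""
    if linkage not in LINKAGES:
        raise InvalidArgumentError(f"unknown linkage: {linkage!r}")
    df = _as_frame(matrix).astype(float)
    if k > len(df):
        raise InvalidArgumentError("k exceeds number of rows")
    X = df.to_numpy()
    if scale_rows:
        X = row_scale(df)[0].to_numpy()
    Z = hierarchy.linkage(X, method=linkage, metric="euclidean")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    order = hierarchy.leaves_list(Z)
    return ClusteringResult(k=k, labels=pd.Series(labels, index=df.index),
                            linkage_matrix=Z,
                            leaf_order=[df.index[i] for i in order])


def _cdf_area(values: np.ndarray) -> float:
    """Area under the empirical CDF of off-diagonal consensus values on [0,1]."""
    v = np.sort(values)
    n = len(v)
    if n == 0:
        return 0.0
    # stepwise CDF integral: sum over sorted points of CDF * width to next point
    xs = np.concatenate([v, [1.0]])
    cdf = np.arange(1, n + 1) / n
    return float(np.sum(cdf * np.diff(xs)))


def consensus(matrix, k_min: int = 2, k_max: int = 6,
              n_resamples: int = 1000, subsample_frac: float = 0.8,
              seed: int = 0, linkage: str = "average") -> ConsensusResult:
    """Resampling consensus clustering over the rows of ``matrix``.

    For each K, items are repeatedly subsampled and clustered with
    :func:`hierarchical`; co-clustering frequencies are normalized by
    co-sampling counts.  K is chosen by the largest relative increase in the
    area under the consensus CDF; final labels come from average-linkage
    clustering of 1 - consensus at the chosen K.
    """
    if n_resamples < 10:
        raise InvalidArgumentError("n_resamples must be >= 10")
    if not (0.0 < subsample_frac <= 1.0):
        raise InvalidArgumentError("subsample_frac must lie in (0, 1]")
    df = _as_frame(matrix).astype(float)
    n = len(df)
    if k_max >= n:
        raise InvalidArgumentError("k_max must be smaller than the number of items")
    rng = np.random.default_rng(seed)
    m = max(2, int(round(subsample_frac * n)))
    X = df.to_numpy()

    consensus_mats: dict[int, pd.DataFrame] = {}
    areas: dict[int, float] = {}
    # pre-draw subsamples shared across K so the K comparison is paired
    subsamples = [np.sort(rng.choice(n, size=m, replace=False))
                  for _ in range(n_resamples)]
    co_sampled = np.zeros((n, n))
    for idx in subsamples:
        co_sampled[np.ix_(idx, idx)] += 1
    if np.any(co_sampled == 0):
        raise InvalidArgumentError(
            "some item pair was never co-sampled; increase n_resamples or "
            "subsample_frac")
    for k in range(k_min, k_max + 1):
        co_clustered = np.zeros((n, n))
        for idx in subsamples:
            sub = X[idx]
            Z = hierarchy.linkage(sub, method=linkage, metric="euclidean")
            lab = hierarchy.fcluster(Z, t=min(k, len(idx)), criterion="maxclust")
            same = lab[:, None] == lab[None, :]
            co_clustered[np.ix_(idx, idx)] += same
        C = co_clustered / co_sampled
        np.fill_diagonal(C, 1.0)
        consensus_mats[k] = pd.DataFrame(C, index=df.index, columns=df.index)
        iu = np.triu_indices(n, k=1)
        areas[k] = _cdf_area(C[iu])

    deltas: dict[int, float] = {}
    ks = sorted(areas)
    for i, k in enumerate(ks):
        if i == 0:
            deltas[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            deltas[k] = (areas[k] - prev) / prev if prev > 0 else areas[k]
    best_k = max(deltas, key=lambda k: (deltas[k], -k))

    D = 1.0 - consensus_mats[best_k].to_numpy()
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=best_k, criterion="maxclust")
    return ConsensusResult(k=best_k,
                           labels=pd.Series(labels, index=df.index),
                           consensus=consensus_mats,
                           cdf_area=areas, delta_area=deltas)
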