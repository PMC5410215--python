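"""Resampled k-means consensus clustering and stable-k selection.

For each candidate number of clusters k the samples are repeatedly
subsampled, k-means is run on each subsample, and the consensus matrix
entry M(i, j) records the fraction of co-inclusions in which samples i and
j landed in the same cluster.  A clean clustering drives the entries of M
toward {0, 1}; the area under the empirical CDF of the consensus entries
summarizes this, and k is chosen as the smallest value after which the
relative (delta) area gain falls below a threshold.  Final labels come
from average-linkage hierarchical clustering of 1 − M.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .expression_io import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_N_RESAMPLES = 1000
DEFAULT_SUBSAMPLE_FRACTION = 0.8
DEFAULT_DELTA_THRESHOLD = 0.05
DEFAULT_KMEANS_RESTARTS = 10


@dataclass
class ConsensusMatrix:
    """Consensus and co-inclusion counts for one value of k."""

    sample_ids: list[str]
    M: np.ndarray
    I: np.ndarray
    k: int
    n_resamples: int
    subsample_fraction: float
    seed: int | None


class ECDF(NamedTuple):
    """Empirical CDF evaluated at its jump points."""

    x: np.ndarray
    y: np.ndarray


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, CDF areas, delta areas, chosen k and labels."""

    matrices: dict[int, ConsensusMatrix]
    areas: dict[int, float]
    deltas: dict[int, float]
    chosen_k: int
    labels: pd.Series


def _feature_matrix(matrix: ExpressionMatrix, standardize: bool) -> np.ndarray:
    X = matrix.values.to_numpy(dtype=float).T  # samples x probes
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    return X


def consensus_matrix(
    matrix: ExpressionMatrix,
    k: int,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    subsample_fraction: float = DEFAULT_SUBSAMPLE_FRACTION,
    seed: int | None = None,
    n_init: int = DEFAULT_KMEANS_RESTARTS,
    standardize: bool = True,
) -> ConsensusMatrix:
    """Build the consensus matrix at one k by resampled k-means.

    Each resample draws ``ceil(fraction * n)`` samples without replacement,
    clusters them with k-means (features = probes, standardized per probe
    by default) and accumulates co-cluster and co-inclusion counts; M is
    their elementwise ratio.  Deterministic given ``seed``.
    """
    n = matrix.n_samples
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    if not 0.0 < subsample_fraction <= 1.0:
        raise ValueError("subsample_fraction must lie in (0, 1]")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")

    X = _feature_matrix(matrix, standardize)
    m = math.ceil(subsample_fraction * n)
    if m < k:
        raise ValueError("subsample smaller than k")
    rng = np.random.default_rng(seed)
    co_cluster = np.zeros((n, n))
    co_include = np.zeros((n, n))
    eye_k = np.eye(k)
    for _ in range(n_resamples):
        idx = rng.choice(n, size=m, replace=False) if m < n else np.arange(n)
        labels = KMeans(
            n_clusters=k,
            n_init=n_init,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit_predict(X[idx])
        onehot = eye_k[labels]
        block = np.ix_(idx, idx)
        co_include[block] += 1.0
        co_cluster[block] += onehot @ onehot.T
    M = np.divide(co_cluster, co_include, out=np.zeros_like(co_cluster), where=co_include > 0)
    return ConsensusMatrix(
        sample_ids=matrix.sample_ids, M=M, I=co_include, k=k,
        n_resamples=n_resamples, subsample_fraction=subsample_fraction, seed=seed,
    )


def cdf_and_area(cm: ConsensusMatrix) -> tuple[ECDF, float]:
    """Empirical CDF of the upper-triangle consensus entries and its area.

    The area is ``sum (x_{i+1} − x_i) * CDF(x_i)`` over the sorted unique
    entry values augmented with {0, 1}; a perfectly binary consensus with a
    fraction p of zero entries yields area p.
    """
    entries = cm.M[np.triu_indices(len(cm.sample_ids), k=1)]
    xs = np.unique(np.concatenate([[0.0, 1.0], entries]))
    sorted_entries = np.sort(entries)
    y = np.searchsorted(sorted_entries, xs, side="right") / entries.size
    area = float(np.sum(np.diff(xs) * y[:-1]))
    return ECDF(x=xs, y=y), area


def delta_areas(areas: Mapping[int, float]) -> dict[int, float]:
    """Proportional CDF-area increase per k: Δ(2)=A(2), Δ(k)=(A(k)−A(k−1))/A(k−1)."""
    ks = sorted(areas)
    if not ks or ks[0] != 2 or ks != list(range(2, ks[-1] + 1)):
        raise ValueError("areas must cover consecutive k values starting at 2")
    deltas = {2: float(areas[2])}
    for k in ks[1:]:
        prev = areas[k - 1]
        deltas[k] = float((areas[k] - prev) / prev)
    return deltas


def choose_k(deltas: Mapping[int, float], threshold: float = DEFAULT_DELTA_THRESHOLD) -> int:
    """Smallest k whose next delta area falls below ``threshold``.

    If every delta stays at or above the threshold, returns the largest k
    scanned with a warning — the scan did not reach the plateau.
    """
    ks = sorted(deltas)
    if not ks or ks[-1] < 3:
        raise ValueError("need delta areas for k up to at least 3")
    for k in ks[:-1]:
        if deltas[k + 1] < threshold:
            return k
    logger.warning(
        "no delta area fell below %.3g; returning k_max=%d", threshold, ks[-1]
    )
    return ks[-1]


def final_assignments(cm: ConsensusMatrix, k: int) -> pd.Series:
    """Cut the average-linkage tree of 1 − M into k groups.

    Labels are renamed by decreasing group size: ``C1`` is the largest.
    """
    n = len(cm.sample_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    D = 1.0 - cm.M
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=k, criterion="maxclust")
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    rename = {c: f"C{i + 1}" for i, c in enumerate(order)}
    return pd.Series([rename[c] for c in raw], index=cm.sample_ids, name="subtype")


def run_consensus(
    matrix: ExpressionMatrix,
    k_min: int = 2,
    k_max: int = 10,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    subsample_fraction: float = DEFAULT_SUBSAMPLE_FRACTION,
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
    seed: int | None = None,
    n_init: int = DEFAULT_KMEANS_RESTARTS,
    standardize: bool = True,
) -> ConsensusResult:
    """Scan k over [k_min, k_max], pick the stable k, assign final labels."""
    if k_min != 2:
        raise ValueError("the delta-area rule requires the scan to start at k=2")
    if k_max < 3:
        raise ValueError("k_max must be >= 3")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(k_max - k_min + 1)]
    matrices: dict[int, ConsensusMatrix] = {}
    areas: dict[int, float] = {}
    for k, k_seed in zip(range(k_min, k_max + 1), child_seeds):
        cm = consensus_matrix(
            matrix, k, n_resamples=n_resamples,
            subsample_fraction=subsample_fraction,
            seed=k_seed, n_init=n_init, standardize=standardize,
        )
        matrices[k] = cm
        _, areas[k] = cdf_and_area(cm)
    deltas = delta_areas(areas)
    k_star = choose_k(deltas, threshold=delta_threshold)
    labels = final_assignments(matrices[k_star], k_star)
    logger.info("consensus scan k=%d..%d chose k=%d", k_min, k_max, k_star)
    return ConsensusResult(
        matrices=matrices, areas=areas, deltas=deltas, chosen_k=k_star, labels=labels
    )
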