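"""Sample clustering over cell-fraction profiles.

Three routes: agglomerative Ward on Euclidean distances, restarted K-means,
and subsampled consensus clustering whose stability is summarized by the
proportion of ambiguous clustering (PAC). k is selected as the PAC argmin
(ties to the smaller k); the delta-area of the consensus CDF is also
reported for inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .containers import ConsensusResult

logger = logging.getLogger(__name__)

__all__ = [
    "hierarchical_cluster",
    "kmeans_cluster",
    "consensus_cluster",
    "pac_score",
    "ConsensusRun",
]


def _as_array(x) -> tuple[np.ndarray, list]:
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), list(x.index)
    arr = np.asarray(x, dtype=float)
    return arr, list(range(arr.shape[0]))


def hierarchical_cluster(x, k: int) -> np.ndarray:
    """Ward-linkage agglomerative clustering cut to exactly k groups.

    Uses the Lance-Williams Ward update on Euclidean distances (scipy
    ``linkage(method="ward")``). Deterministic given input order; equal merge
    costs are broken by scipy's stable ordering of the condensed distance
    list, which is lexicographic in (row, column) of the input — identical
    inputs therefore always produce the same split.
    """
    arr, _ = _as_array(x)
    n = arr.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n={n}")
    z = linkage(arr, method="ward")
    return fcluster(z, t=k, criterion="maxclust") - 1


def kmeans_cluster(x, k: int, n_restarts: int = 10, seed: int = 0) -> np.ndarray:
    """Best-of-restarts k-means++ labels (by within-cluster sum of squares)."""
    arr, _ = _as_array(x)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= arr.shape[0]:
        raise ValueError(f"k={k} must be smaller than n={arr.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    return km.fit_predict(arr)


def pac_score(consensus: np.ndarray, lower: float = 0.1, upper: float = 0.9) -> float:
    """Proportion of off-diagonal consensus entries strictly inside
    (lower, upper) — the ambiguous co-clustering mass."""
    iu = np.triu_indices_from(consensus, k=1)
    vals = consensus[iu]
    if not vals.size:
        return 0.0
    return float(np.mean((vals > lower) & (vals < upper)))


@dataclass
class ConsensusRun:
    """Consensus results across a k range plus the PAC-selected k."""

    results: dict  # k -> ConsensusResult
    selected_k: int
    delta_area: dict  # k -> change in consensus-CDF area vs previous k


def _consensus_for_k(
    arr: np.ndarray,
    k: int,
    n_iter: int,
    subsample_fraction: float,
    base: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, int]:
    n = arr.shape[0]
    m = max(int(np.ceil(subsample_fraction * n)), k + 1)
    co = np.zeros((n, n))
    tog = np.zeros((n, n))
    skipped = 0
    for _ in range(n_iter):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        sub = arr[idx]
        try:
            if base == "hierarchical":
                labels = hierarchical_cluster(sub, k)
            elif base == "kmeans":
                labels = kmeans_cluster(
                    sub, k, n_restarts=3, seed=int(rng.integers(2**31 - 1))
                )
            else:
                raise ValueError(f"unknown base clusterer {base!r}")
        except ValueError:
            skipped += 1
            continue
        if len(np.unique(labels)) < k:
            skipped += 1
            continue
        tog[np.ix_(idx, idx)] += 1.0
        same = labels[:, None] == labels[None, :]
        co[np.ix_(idx, idx)] += same
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(tog > 0, co / np.maximum(tog, 1), 0.0)
    never = int(np.sum((tog == 0)[np.triu_indices(n, k=1)]))
    if never:
        logger.warning("%d sample pairs never co-sampled at k=%d", never, k)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0
    return consensus, tog, skipped


def _cdf_area(consensus: np.ndarray) -> float:
    iu = np.triu_indices_from(consensus, k=1)
    vals = np.sort(consensus[iu])
    if not vals.size:
        return 0.0
    # area under the empirical CDF of consensus values over [0, 1]
    grid = np.concatenate([vals, [1.0]])
    cdf = np.arange(1, vals.size + 1) / vals.size
    widths = np.diff(grid)
    return float(np.sum(cdf * widths))


def consensus_cluster(
    x,
    k_range=(2, 3, 4, 5),
    n_iter: int = 1000,
    subsample_fraction: float = 0.8,
    base: str = "hierarchical",
    seed: int = 0,
    pac_interval: tuple = (0.1, 0.9),
) -> ConsensusRun:
    """Subsampled consensus clustering over a range of k.

    Per iteration a ``subsample_fraction`` of samples is drawn without
    replacement and clustered with the base method; consensus_ij is the
    co-assignment frequency among co-samplings. Final labels for each k come
    from average-linkage hierarchical clustering of 1 - consensus. Iterations
    whose subsample produces an empty cluster are skipped and counted
    (warning above 10%).
    """
    arr, names = _as_array(x)
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    if not 0.0 < subsample_fraction <= 1.0:
        raise ValueError("subsample_fraction must be in (0, 1]")
    ks = sorted(set(int(k) for k in k_range))
    if any(k < 2 for k in ks):
        raise ValueError("every k must be >= 2")
    rng = np.random.default_rng(seed)

    results: dict[int, ConsensusResult] = {}
    areas: dict[int, float] = {}
    for k in ks:
        consensus, _tog, skipped = _consensus_for_k(
            arr, k, n_iter, subsample_fraction, base, rng
        )
        if skipped > 0.1 * n_iter:
            logger.warning(
                "%d/%d consensus iterations skipped at k=%d", skipped, n_iter, k
            )
        dist = 1.0 - consensus
        np.fill_diagonal(dist, 0.0)
        z = linkage(squareform(dist, checks=False), method="average")
        labels = fcluster(z, t=k, criterion="maxclust") - 1
        results[k] = ConsensusResult(
            k=k,
            consensus_matrix=pd.DataFrame(consensus, index=names, columns=names),
            labels=pd.Series(labels, index=names, name=f"consensus_k{k}"),
            pac=pac_score(consensus, *pac_interval),
            n_iter=n_iter - skipped,
            subsample_fraction=subsample_fraction,
        )
        areas[k] = _cdf_area(consensus)

    delta_area = {}
    prev = None
    for k in ks:
        delta_area[k] = areas[k] - prev if prev is not None else areas[k]
        prev = areas[k]

    pacs = {k: results[k].pac for k in ks}
    best = min(pacs.values())
    tied = [k for k, p in pacs.items() if p == best]
    # among equally unambiguous solutions prefer the finest: a coarse stable
    # partition merely merges clusters of a finer stable one, and ambiguity
    # (PAC > 0) only appears once k exceeds the recoverable structure
    selected_k = max(tied) if best == 0.0 else min(tied)
    return ConsensusRun(results=results, selected_k=selected_k, delta_area=delta_area)
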