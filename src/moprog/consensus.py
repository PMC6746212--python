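"""Resampling-based consensus clustering of a single omics block.

The Monti scheme: repeatedly subsample items and features, cluster each
subsample with a base clusterer (Ward linkage on the Pearson
dissimilarity, or k-means on the raw features), and record for every
sample pair the fraction of co-sampled runs in which the pair landed in
the same cluster. Stability of the resulting consensus matrices across a
range of cluster numbers k — summarized by the CDF of consensus entries
and its area — drives the choice of k.

Defaults follow common practice for this analysis: 1000 resamplings,
pItem = pFeature = 0.90, Pearson distance with Ward linkage, k from 2
to 6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .data_io import OmicsMatrix

__all__ = [
    "ConsensusResult",
    "pearson_dissimilarity",
    "consensus_cluster",
    "cdf_area",
    "select_k_cdf",
]


def pearson_dissimilarity(matrix: OmicsMatrix) -> np.ndarray:
    """Sample-sample dissimilarity d(i, j) = 1 - r(i, j) over features.

    Symmetric with zero diagonal, values in [0, 2].
    """
    return _pearson_dissimilarity_values(matrix.values, matrix.sample_ids)


def _pearson_dissimilarity_values(values: np.ndarray, sample_ids=None) -> np.ndarray:
    if values.shape[0] < 2:
        raise ValueError("need at least 2 features")
    sd = values.std(axis=0)
    zero = np.flatnonzero(sd == 0.0)
    if zero.size:
        name = sample_ids[zero[0]] if sample_ids is not None else str(zero[0])
        raise ValueError(f"zero-variance sample {name!r} in Pearson dissimilarity")
    r = np.corrcoef(values.T)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


@dataclass
class ConsensusResult:
    """Consensus matrices and derived quantities for each evaluated k."""

    sample_ids: list[str]
    consensus: dict[int, np.ndarray]  # k -> samples x samples in [0, 1]
    assignments: dict[int, np.ndarray]  # k -> labels 1..k
    areas: dict[int, float]  # k -> area under the consensus CDF
    delta_area: dict[int, float]  # k -> relative area gain
    selected_k: int
    settings: dict
    item_log: list[np.ndarray]  # per-resample subsampled item indices
    cosampled: np.ndarray  # pairwise co-sampling counts

    def assignment_series(self, k: int | None = None):
        import pandas as pd

        k = self.selected_k if k is None else k
        return pd.Series(self.assignments[k], index=self.sample_ids, name="cluster")


def _base_cluster(
    values: np.ndarray, k: int, method: str, rng: np.random.Generator
) -> np.ndarray:
    """Cluster samples (columns of ``values``) into k groups."""
    if method == "ward":
        d = _pearson_dissimilarity_values(values)
        z = linkage(squareform(d, checks=False), method="ward")
        return fcluster(z, t=k, criterion="maxclust")
    if method == "kmeans":
        km = KMeans(
            n_clusters=k,
            n_init=20,
            random_state=int(rng.integers(2**31 - 1)),
        )
        return km.fit_predict(values.T) + 1
    raise ValueError(f"unknown base method {method!r}")


def consensus_cluster(
    matrix: OmicsMatrix,
    k_range=range(2, 7),
    base_method: str = "ward",
    n_resamples: int = 1000,
    p_item: float = 0.9,
    p_feature: float = 0.9,
    seed: int = 0,
    select_threshold: float = 0.1,
    force_k: int | None = None,
) -> ConsensusResult:
    """Monti consensus clustering of one omics block.

    For every resample, items (samples) and features are subsampled
    without replacement at rates ``p_item`` / ``p_feature``; the
    consensus entry for a pair is its co-clustering count divided by its
    co-sampling count (0/0 treated as 0). The final assignment at each k
    is a Ward cut of ``1 - consensus``. Deterministic given ``seed``.
    """
    ks = sorted(set(int(k) for k in k_range))
    if len(ks) < 1 or ks[0] < 2:
        raise ValueError("k_range must contain integers >= 2")
    n = matrix.n_samples
    if n < max(ks) + 1:
        raise ValueError(f"need at least {max(ks) + 1} samples for k_max={max(ks)}")
    n_items = math.ceil(p_item * n)
    if n_items < max(ks):
        raise ValueError(
            f"p_item * n_samples = {n_items} is below k_max = {max(ks)}"
        )
    n_feats = max(2, math.ceil(p_feature * matrix.n_features))
    rng = np.random.default_rng(seed)
    values = matrix.values

    cocluster = {k: np.zeros((n, n)) for k in ks}
    cosampled = np.zeros((n, n))
    item_log: list[np.ndarray] = []
    for _ in range(n_resamples):
        items = np.sort(rng.choice(n, size=n_items, replace=False))
        feats = np.sort(rng.choice(matrix.n_features, size=n_feats, replace=False))
        item_log.append(items)
        sub = values[np.ix_(feats, items)]
        ind = np.zeros(n)
        ind[items] = 1.0
        cosampled += np.outer(ind, ind)
        for k in ks:
            labels = _base_cluster(sub, k, base_method, rng)
            for lab in np.unique(labels):
                members = items[labels == lab]
                sel = np.zeros(n)
                sel[members] = 1.0
                cocluster[k] += np.outer(sel, sel)

    consensus: dict[int, np.ndarray] = {}
    assignments: dict[int, np.ndarray] = {}
    areas: dict[int, float] = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for k in ks:
            m = np.where(cosampled > 0, cocluster[k] / np.maximum(cosampled, 1), 0.0)
            m = (m + m.T) / 2.0
            np.fill_diagonal(m, 1.0)
            consensus[k] = m
            z = linkage(squareform(1.0 - m, checks=False), method="ward")
            assignments[k] = fcluster(z, t=k, criterion="maxclust")
            areas[k] = cdf_area(m)

    delta = {}
    for i, k in enumerate(ks):
        if i == 0:
            delta[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            gain = areas[k] - prev
            delta[k] = gain / prev if prev > 0 else (np.inf if gain > 0 else 0.0)

    settings = {
        "n_resamples": n_resamples,
        "p_item": p_item,
        "p_feature": p_feature,
        "base_method": base_method,
        "seed": seed,
    }
    result = ConsensusResult(
        sample_ids=list(matrix.sample_ids),
        consensus=consensus,
        assignments=assignments,
        areas=areas,
        delta_area=delta,
        selected_k=ks[0],
        settings=settings,
        item_log=item_log,
        cosampled=cosampled,
    )
    result.selected_k = select_k_cdf(
        result, threshold=select_threshold, override=force_k
    )
    return result


def cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of the off-diagonal consensus
    entries (the standard consensus-clustering summary)."""
    iu = np.triu_indices_from(consensus, k=1)
    v = np.sort(consensus[iu])
    if v.size == 0:
        return 0.0
    cdf = np.arange(1, v.size + 1) / v.size
    return float(np.sum(np.diff(v) * cdf[:-1]))


def select_k_cdf(
    result: ConsensusResult, threshold: float = 0.1, override: int | None = None
) -> int:
    """Choose k from the relative gain in CDF area.

    Returns the smallest k whose successor adds less than ``threshold``
    relative area (no meaningful gain from more clusters); falls back to
    the largest evaluated k when every step keeps gaining. ``override``
    forces a user-chosen k, mirroring by-inspection choices.
    """
    ks = sorted(result.consensus)
    if override is not None:
        if override not in ks:
            raise ValueError(f"override k={override} was not evaluated")
        return int(override)
    if len(ks) < 2:
        return ks[0]
    for i, k in enumerate(ks[:-1]):
        if result.delta_area[ks[i + 1]] < threshold:
            return k
    return ks[-1]
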