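"""Multi-block latent-factor integration and gap-statistic clustering.

The three omics blocks (methylation, mRNA, miRNA) are feature-centered,
scaled to equal Frobenius norm so no block dominates, row-concatenated
and decomposed by SVD — consensus PCA, giving one set of global sample
scores across blocks. The scores are clustered by Ward linkage, with the
number of clusters chosen by Tibshirani's gap statistic against uniform
reference draws over each score dimension's observed range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .data_io import OmicsMatrix, align_samples

__all__ = [
    "LatentFactors",
    "block_scale",
    "consensus_pca",
    "gap_statistic_cluster",
    "GapResult",
]


@dataclass
class LatentFactors:
    """Global sample scores with per-block loadings.

    Factors are ordered by decreasing variance explained; each factor's
    sign is fixed by making its largest-magnitude loading positive.
    """

    sample_ids: list[str]
    scores: np.ndarray  # samples x J
    loadings: dict[str, np.ndarray]  # block name -> features x J
    block_names: list[str]
    variance_explained: np.ndarray  # length J, fractions of total variance


def block_scale(blocks: list[OmicsMatrix]) -> list[OmicsMatrix]:
    """Center every feature and scale each block to unit Frobenius norm.

    Blocks are first restricted to their common samples (at least 2
    required). Centered values are no longer beta values or counts, so
    every output block is tagged with the generic continuous kind
    ``expression_log``.
    """
    if len(blocks) == 0:
        raise ValueError("no blocks supplied")
    aligned = align_samples(*blocks) if len(blocks) > 1 else list(blocks)
    out = []
    for b in aligned:
        centered = b.values - b.values.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(centered)
        if norm == 0:
            raise ValueError(f"block of kind {b.kind} has no variance")
        out.append(
            OmicsMatrix(centered / norm, b.feature_ids, b.sample_ids, "expression_log")
        )
    return out


def consensus_pca(
    blocks: list[OmicsMatrix],
    n_factors: int = 10,
    block_names: list[str] | None = None,
) -> LatentFactors:
    """Exact-SVD consensus PCA of pre-scaled blocks.

    The global sample scores are the top right singular vectors of the
    row-concatenated block matrix, scaled by their singular values;
    deterministic up to the documented sign convention.
    """
    if not blocks:
        raise ValueError("no blocks supplied")
    sample_ids = blocks[0].sample_ids
    for b in blocks[1:]:
        if b.sample_ids != sample_ids:
            raise ValueError("blocks must share an identical sample order")
    names = block_names or [f"block{i}" for i in range(len(blocks))]
    stacked = np.vstack([b.values for b in blocks])
    max_j = min(stacked.shape[0], len(sample_ids) - 1)
    if not 1 <= n_factors <= max_j:
        raise ValueError(f"n_factors must be in [1, {max_j}]")
    u, s, vt = np.linalg.svd(stacked, full_matrices=False)
    u, s, vt = u[:, :n_factors], s[:n_factors], vt[:n_factors]
    # sign convention: largest-magnitude loading of each factor positive
    for j in range(n_factors):
        i_max = int(np.argmax(np.abs(u[:, j])))
        if u[i_max, j] < 0:
            u[:, j] *= -1.0
            vt[j] *= -1.0
    scores = vt.T * s[None, :]
    total_var = float(np.sum(np.linalg.svd(stacked, compute_uv=False) ** 2))
    var_explained = s**2 / total_var
    loadings = {}
    row = 0
    for name, b in zip(names, blocks):
        loadings[name] = u[row : row + b.n_features]
        row += b.n_features
    return LatentFactors(
        sample_ids=list(sample_ids),
        scores=scores,
        loadings=loadings,
        block_names=names,
        variance_explained=var_explained,
    )


def _within_dispersion(scores: np.ndarray, labels: np.ndarray) -> float:
    """Sum over clusters of within-cluster sum of squared distances to
    the centroid (the gap statistic's W_k)."""
    w = 0.0
    for lab in np.unique(labels):
        pts = scores[labels == lab]
        w += float(np.sum((pts - pts.mean(axis=0)) ** 2))
    return w


def _ward_labels(scores: np.ndarray, k: int) -> np.ndarray:
    if k == 1:
        return np.ones(scores.shape[0], dtype=int)
    z = linkage(pdist(scores), method="ward")
    return fcluster(z, t=k, criterion="maxclust")


@dataclass
class GapResult:
    labels: np.ndarray
    selected_k: int
    gap: dict[int, float]
    sk: dict[int, float]
    log_w: dict[int, float]


def gap_statistic_cluster(
    scores: np.ndarray,
    k_range=range(1, 13),
    n_references: int = 50,
    seed: int = 0,
    override: int | None = None,
) -> GapResult:
    """Ward clustering of latent scores with gap-statistic k selection.

    Gap(k) = mean_b log W*_kb - log W_k with B reference datasets drawn
    uniformly over each score dimension's observed range. The selected k
    is the smallest with Gap(k) >= Gap(k+1) - s_{k+1}; ``override``
    forces a user choice.
    """
    if n_references < 10:
        raise ValueError("need at least 10 reference datasets")
    scores = np.asarray(scores, dtype=float)
    ks = sorted(set(int(k) for k in k_range))
    if ks[0] < 1:
        raise ValueError("k_range must contain integers >= 1")
    rng = np.random.default_rng(seed)
    n, d = scores.shape
    lo, hi = scores.min(axis=0), scores.max(axis=0)

    log_w = {k: np.log(_within_dispersion(scores, _ward_labels(scores, k))) for k in ks}
    ref_log_w = {k: np.empty(n_references) for k in ks}
    for b in range(n_references):
        ref = rng.uniform(lo, hi, size=(n, d))
        for k in ks:
            ref_log_w[k][b] = np.log(_within_dispersion(ref, _ward_labels(ref, k)))
    gap = {k: float(ref_log_w[k].mean() - log_w[k]) for k in ks}
    sk = {
        k: float(ref_log_w[k].std(ddof=0) * np.sqrt(1.0 + 1.0 / n_references))
        for k in ks
    }
    if override is not None:
        if override not in ks:
            raise ValueError(f"override k={override} was not evaluated")
        selected = int(override)
    else:
        selected = ks[-1]
        for i, k in enumerate(ks[:-1]):
            if gap[k] >= gap[ks[i + 1]] - sk[ks[i + 1]]:
                selected = k
                break
    return GapResult(
        labels=_ward_labels(scores, selected),
        selected_k=selected,
        gap=gap,
        sk=sk,
        log_w=log_w,
    )
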