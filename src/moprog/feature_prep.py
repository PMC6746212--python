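"""Transformations and variance-based feature selection before clustering.

Expression matrices (RPKM/RPM-like or raw counts) are log2-transformed
with a pseudocount; features are then ranked by median absolute deviation
(MAD) and the most variable fraction retained — 10% for methylation
probes, 20% for genes and miRNAs in the default pipeline.
"""

from __future__ import annotations

import math

import numpy as np

from .data_io import OmicsMatrix

__all__ = ["log2_transform", "select_top_mad"]


def log2_transform(matrix: OmicsMatrix, pseudocount: float = 1.0) -> OmicsMatrix:
    """Elementwise ``log2(x + pseudocount)``; the result is tagged
    ``expression_log``."""
    if np.any(matrix.values < 0):
        raise ValueError("log2_transform requires nonnegative values")
    return OmicsMatrix(
        np.log2(matrix.values + pseudocount),
        matrix.feature_ids,
        matrix.sample_ids,
        "expression_log",
    )


def mad(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Unscaled median absolute deviation from the median.

    No 1.4826 consistency constant: only the feature ranking matters here.
    """
    med = np.median(values, axis=axis, keepdims=True)
    return np.median(np.abs(values - med), axis=axis)


def select_top_mad(matrix: OmicsMatrix, fraction: float) -> OmicsMatrix:
    """Keep the ``ceil(fraction * n_features)`` features with largest MAD.

    Ties are broken by lexicographic feature id; the surviving features
    keep their original row order.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if matrix.n_features == 0:
        raise ValueError("empty matrix")
    n_keep = math.ceil(fraction * matrix.n_features)
    mads = mad(matrix.values, axis=1)
    ranked = sorted(
        range(matrix.n_features),
        key=lambda i: (-mads[i], matrix.feature_ids[i]),
    )
    keep = sorted(ranked[:n_keep])  # restore original feature order
    return OmicsMatrix(
        matrix.values[keep, :],
        [matrix.feature_ids[i] for i in keep],
        matrix.sample_ids,
        matrix.kind,
    )
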