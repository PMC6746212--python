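"""Mutation burden, per-gene mutation-frequency tests, 96-channel
catalogs and mutational-signature decomposition.

Catalogs follow the canonical pyrimidine-centered convention: variants
recorded on the purine strand are reverse-complemented into one of the
96 (substitution, 5' base, 3' base) channels. Signature fitting mimics
the deconstructSigs procedure: greedy forward selection of reference
signatures with a bounded one-dimensional weight search per step, a
relative-improvement stopping rule (1e-3), and discarding of weights
below 0.06 followed by one re-fit of the survivors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .core_stats import TestResult, fisher_exact, t_test_two_sided
from .data_io import CHANNELS_96, MutationSet, SignatureMatrix, reverse_complement

logger = logging.getLogger("moprog")

__all__ = [
    "Catalog96",
    "SignatureFit",
    "burden_by_sample",
    "burden_group_test",
    "gene_mutation_test",
    "build_catalog",
    "fit_signatures",
]

PYRIMIDINES = {"C", "T"}
WEIGHT_CUTOFF = 0.06
IMPROVEMENT_STOP = 1e-3


@dataclass
class Catalog96:
    """Counts over the 96 canonical trinucleotide channels."""

    counts: pd.Series  # index CHANNELS_96
    label: str = ""

    def __post_init__(self) -> None:
        self.counts = self.counts.reindex(CHANNELS_96, fill_value=0.0)
        if (self.counts < 0).any():
            raise ValueError("negative catalog count")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def fractions(self) -> pd.Series:
        if self.total == 0:
            raise ValueError("empty catalog has no fraction form")
        return self.counts / self.total


@dataclass
class SignatureFit:
    """Nonnegative signature weights (summing to at most 1) with the
    unexplained sum-of-squares residual."""

    weights: pd.Series  # index signature names
    residual: float
    discarded: list[str]

    def __post_init__(self) -> None:
        if (self.weights < 0).any():
            raise ValueError("negative signature weight")
        if self.weights.sum() > 1.0 + 1e-6:
            raise ValueError("signature weights exceed 1")


def burden_by_sample(muts: MutationSet, sample_ids=None) -> pd.Series:
    """Nonsynonymous mutation count per sample (0 for unmutated samples
    when ``sample_ids`` supplies the cohort universe)."""
    r = muts.records
    nonsyn = r[r["consequence"] == "nonsynonymous"]
    counts = nonsyn.groupby("sample_id").size()
    if sample_ids is not None:
        counts = counts.reindex(list(sample_ids), fill_value=0)
    return counts.rename("nonsynonymous_burden").astype(int)


def burden_group_test(
    muts: MutationSet, group_a, group_b
) -> TestResult:
    """Two-sided Student t test of nonsynonymous burden, group_a vs
    group_b."""
    burden_a = burden_by_sample(muts, group_a).to_numpy(dtype=float)
    burden_b = burden_by_sample(muts, group_b).to_numpy(dtype=float)
    return t_test_two_sided(burden_a, burden_b)


def gene_mutation_test(
    muts: MutationSet, grouping: pd.Series, gene: str
) -> TestResult:
    """Fisher's exact test of per-patient mutation frequency of one gene
    between two groups.

    ``grouping`` maps sample to one of exactly two group names; a
    patient counts once however many mutations they carry in the gene.
    A gene absent from the records yields the p = 1 degenerate table.
    """
    grouping = grouping.astype(str)
    names = sorted(grouping.unique())
    if len(names) != 2:
        raise ValueError("grouping must contain exactly 2 groups")
    if (grouping.value_counts() == 0).any():
        raise ValueError("empty group")
    r = muts.records
    hit = r[(r["gene"] == gene) & (r["consequence"] == "nonsynonymous")]
    mutated = set(hit["sample_id"])
    table = []
    for name in names:
        members = set(grouping.index[grouping == name])
        m = len(members & mutated)
        table.append([m, len(members) - m])
    if not mutated:
        return TestResult(np.nan, 1.0, np.nan, float(len(grouping)))
    return fisher_exact(table)


def _channel_of(ref: str, alt: str, context: str) -> str | None:
    if len(context) != 3 or ref not in "ACGT" or alt not in "ACGT" or ref == alt:
        return None
    if context[1] != ref:
        return None
    if ref not in PYRIMIDINES:
        context = reverse_complement(context)
        ref = context[1]
        alt = reverse_complement(alt)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def build_catalog(
    muts: MutationSet, per_sample: bool = False, label: str = ""
):
    """Aggregate SNV records into 96-channel catalogs.

    Purine-reference records are reverse-complemented into the
    pyrimidine-centered channel. Invalid contexts and non-SNVs are
    skipped with a logged count. Returns one pooled :class:`Catalog96`,
    or a dict of per-sample catalogs when ``per_sample`` is set.
    """
    r = muts.records
    channels = []
    skipped = 0
    for ref, alt, ctx in zip(r["ref_allele"], r["alt_allele"], r["context3"]):
        ch = _channel_of(str(ref), str(alt), str(ctx))
        if ch is None:
            skipped += 1
        channels.append(ch)
    if skipped:
        logger.info("build_catalog: skipped %d non-SNV/invalid records", skipped)
    frame = r.assign(channel=channels).dropna(subset=["channel"])
    if per_sample:
        out = {}
        for sample, sub in frame.groupby("sample_id"):
            counts = sub["channel"].value_counts().astype(float)
            out[str(sample)] = Catalog96(counts, label=str(sample))
        return out
    counts = frame["channel"].value_counts().astype(float)
    return Catalog96(counts, label=label)


def _sse(target: np.ndarray, sig: np.ndarray, weights: np.ndarray) -> float:
    return float(np.sum((target - sig @ weights) ** 2))


def _best_weight(
    target: np.ndarray, sig: np.ndarray, weights: np.ndarray, j: int
) -> tuple[float, float]:
    """Re-optimized total weight for signature j, holding the others.

    The search interval is [0, current w_j + remaining budget], so a
    previously overshot weight can shrink as other signatures enter.
    """
    upper = weights[j] + (1.0 - weights.sum())
    if upper <= 0:
        return float(weights[j]), _sse(target, sig, weights)

    def objective(w_j: float) -> float:
        w = weights.copy()
        w[j] = w_j
        return _sse(target, sig, w)

    res = minimize_scalar(objective, bounds=(0.0, upper), method="bounded")
    return float(res.x), float(res.fun)


def _forward_select(
    target: np.ndarray,
    sig: np.ndarray,
    allowed: np.ndarray,
    max_iter: int = 200,
) -> np.ndarray:
    weights = np.zeros(sig.shape[1])
    err = _sse(target, sig, weights)
    for _ in range(max_iter):
        best = None
        for j in np.flatnonzero(allowed):
            w_j, new_err = _best_weight(target, sig, weights, j)
            if best is None or new_err < best[2]:
                best = (j, w_j, new_err)
        if best is None or err <= 0:
            break
        j, w_j, new_err = best
        if (err - new_err) / err < IMPROVEMENT_STOP:
            break
        weights[j] = w_j
        err = new_err
    return weights


def fit_signatures(
    catalog: Catalog96,
    signatures: SignatureMatrix,
    cutoff: float = WEIGHT_CUTOFF,
) -> SignatureFit:
    """Decompose a catalog into a nonnegative mixture of reference
    signatures (greedy forward selection, deconstructSigs-style).

    Weights below ``cutoff`` are zeroed and the surviving signatures are
    re-fit once; the residual is the final sum of squared channel
    errors.
    """
    if catalog.total < 1:
        raise ValueError("catalog must contain at least one mutation")
    target = catalog.fractions().to_numpy()
    sig = signatures.weights.to_numpy()
    allowed = np.ones(sig.shape[1], dtype=bool)
    weights = _forward_select(target, sig, allowed)
    discarded = [
        name
        for name, w in zip(signatures.signature_names, weights)
        if 0 < w < cutoff
    ]
    survivors = weights >= cutoff
    if discarded or not survivors.all():
        weights = _forward_select(target, sig, survivors)
        weights[~survivors] = 0.0
    residual = _sse(target, sig, weights)
    return SignatureFit(
        weights=pd.Series(weights, index=signatures.signature_names),
        residual=residual,
        discarded=discarded,
    )
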