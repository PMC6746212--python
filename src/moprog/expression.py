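"""Differential expression, overrepresentation analysis, single-sample
gene-set scores and prognostic-gene screening.

Differential expression uses a negative-binomial Wald approximation on
median-of-ratios-normalized counts: per-gene dispersions are the larger
of a method-of-moments estimate and a fitted mean-dispersion trend
``a0 + a1/mu``, and the Wald z compares log group means with
delta-method variances. Calls follow |log2FC| > 1 and BH-adjusted
p < 0.001. Immune/stromal scores are rank-weighted single-sample GSEA
running sums (exponent 0.25), which makes them invariant under any
strictly monotone transform of a sample's expression profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_stats import TestResult, bh_adjust, hypergeom_upper_tail
from .data_io import ClinicalTable, GeneSetCollection, OmicsMatrix
from .survival import KMCurve, hazard_ratio, km_estimate, logrank_test

logger = logging.getLogger("moprog")

__all__ = [
    "DiffExprResult",
    "size_factors",
    "nb_wald_test",
    "ora",
    "ssgsea_score",
    "score_table",
    "SplitSurvival",
    "score_survival_split",
    "prognostic_screen",
]

LOG2FC_THRESHOLD = 1.0
PADJ_THRESHOLD = 1e-3


@dataclass
class DiffExprResult:
    """Per-gene differential expression table.

    ``log2_fold_change`` is the second group relative to the first;
    ``call`` is ``up``/``down`` only when |log2FC| exceeds 1 and the
    BH-adjusted p is below 0.001.
    """

    table: pd.DataFrame  # gene, base_mean_a, base_mean_b, log2_fold_change,
    #                      p, p_adjusted, call

    def calls(self, direction: str) -> list[str]:
        t = self.table
        return list(t.loc[t["call"] == direction, "gene"])


def size_factors(counts: OmicsMatrix) -> np.ndarray:
    """DESeq-style median-of-ratios per-sample normalization factors.

    Only genes with strictly positive counts in every sample contribute;
    factor_j is the median over those genes of count_gj divided by the
    gene's geometric mean.
    """
    v = counts.values
    positive = np.all(v > 0, axis=1)
    if not positive.any():
        raise ValueError("no gene with all-positive counts")
    ref = v[positive]
    log_geo_mean = np.mean(np.log(ref), axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(ref) - log_geo_mean, axis=0))
    return factors


def _dispersion_estimates(norm: np.ndarray, idx_a, idx_b) -> np.ndarray:
    """Per-gene NB dispersion: max of the method-of-moments estimate and
    a fitted a0 + a1/mu trend across genes."""
    mu_a = norm[:, idx_a].mean(axis=1)
    mu_b = norm[:, idx_b].mean(axis=1)
    var_a = norm[:, idx_a].var(axis=1, ddof=1)
    var_b = norm[:, idx_b].var(axis=1, ddof=1)
    mu = (mu_a + mu_b) / 2.0
    var = (var_a + var_b) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        mom = np.where(mu > 0, (var - mu) / mu**2, 0.0)
    mom = np.clip(np.nan_to_num(mom), 0.0, None)
    use = mu > 0
    if use.sum() >= 2:
        x = np.column_stack([np.ones(use.sum()), 1.0 / mu[use]])
        coef, *_ = np.linalg.lstsq(x, mom[use], rcond=None)
        a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)
    else:
        a0 = a1 = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        trend = np.where(mu > 0, a0 + a1 / mu, 0.0)
    return np.maximum(mom, trend)


def nb_wald_test(
    counts: OmicsMatrix, group_a, group_b
) -> DiffExprResult:
    """Negative-binomial Wald test of group_b versus group_a.

    Counts are normalized by :func:`size_factors`; the Wald z compares
    log normalized group means with delta-method variances
    ``(1/n) * (1/(mu + 0.5) + alpha)`` per group. log2FC uses a 0.5
    pseudocount on the normalized means. All-zero genes are reported as
    ``ns`` with p = 1.
    """
    ids = {s: j for j, s in enumerate(counts.sample_ids)}
    idx_a = [ids[s] for s in group_a]
    idx_b = [ids[s] for s in group_b]
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("need at least 2 samples per group")
    sf = size_factors(counts)
    norm = counts.values / sf[None, :]
    alpha = _dispersion_estimates(norm, idx_a, idx_b)
    mu_a = norm[:, idx_a].mean(axis=1)
    mu_b = norm[:, idx_b].mean(axis=1)
    n_a, n_b = len(idx_a), len(idx_b)
    se2 = (1.0 / (mu_a + 0.5) + alpha) / n_a + (1.0 / (mu_b + 0.5) + alpha) / n_b
    log_fc = np.log((mu_b + 0.5) / (mu_a + 0.5))
    z = log_fc / np.sqrt(se2)
    p = 2.0 * stats.norm.sf(np.abs(z))
    all_zero = (mu_a == 0) & (mu_b == 0)
    p[all_zero] = 1.0
    z[all_zero] = 0.0
    log2_fc = np.log2((mu_b + 0.5) / (mu_a + 0.5))
    p_adj = bh_adjust(p)
    call = np.where(
        (log2_fc > LOG2FC_THRESHOLD) & (p_adj < PADJ_THRESHOLD),
        "up",
        np.where(
            (log2_fc < -LOG2FC_THRESHOLD) & (p_adj < PADJ_THRESHOLD), "down", "ns"
        ),
    )
    call[all_zero] = "ns"
    table = pd.DataFrame(
        {
            "gene": counts.feature_ids,
            "base_mean_a": mu_a,
            "base_mean_b": mu_b,
            "log2_fold_change": log2_fc,
            "p": p,
            "p_adjusted": p_adj,
            "call": call,
        }
    )
    return DiffExprResult(table)


def ora(
    gene_list,
    universe,
    sets: GeneSetCollection,
    alpha_adj: float = 0.01,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation analysis against a gene-set
    collection.

    Sets are intersected with the explicit universe first; sets disjoint
    from the universe are skipped with a warning. Returns the sets with
    at least one overlapping gene and BH-adjusted p <= ``alpha_adj``,
    with overlap counts and enrichment ratios.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_set = set(gene_list)
    if not gene_set <= universe:
        raise ValueError("gene_list must be a subset of the universe")
    rows = []
    for name in sets:
        members = sets[name] & universe
        if not members:
            logger.warning("ora: set %r disjoint from universe, skipped", name)
            continue
        k = len(members & gene_set)
        p = hypergeom_upper_tail(k, len(members), len(gene_set), len(universe))
        ratio = (
            (k / len(gene_set)) / (len(members) / len(universe))
            if gene_set
            else np.nan
        )
        rows.append((name, k, len(members), p, ratio))
    if not rows:
        return pd.DataFrame(
            columns=["set", "overlap", "set_size", "p", "p_adjusted", "enrichment_ratio"]
        )
    table = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "p", "enrichment_ratio"]
    )
    table["p_adjusted"] = bh_adjust(table["p"])
    table = table[(table["overlap"] >= 1) & (table["p_adjusted"] <= alpha_adj)]
    return table.sort_values("p").reset_index(drop=True)[
        ["set", "overlap", "set_size", "p", "p_adjusted", "enrichment_ratio"]
    ]


def ssgsea_score(
    expr: OmicsMatrix, signature, exponent: float = 0.25
) -> pd.Series:
    """Single-sample GSEA score of one gene set for every sample.

    Genes are ranked per sample (average ranks at ties; the highest
    expression receives the largest rank). Walking the genes in order of
    decreasing expression, the score is the running-sum integral of the
    rank-weighted in-set ECDF (weights = rank ** exponent) minus the
    uniform out-of-set ECDF. Depends on the expression values only
    through their ranks.
    """
    in_set = np.array([g in set(signature) for g in expr.feature_ids])
    if in_set.sum() < 2:
        raise ValueError("fewer than 2 signature genes present in the matrix")
    n = expr.n_features
    n_out = n - int(in_set.sum())
    scores = np.empty(expr.n_samples)
    for j in range(expr.n_samples):
        x = expr.values[:, j]
        ranks = stats.rankdata(x, method="average")  # largest value -> rank n
        order = np.lexsort((np.arange(n), -ranks))  # decreasing expression
        w = np.where(in_set, ranks**exponent, 0.0)[order]
        w_total = w.sum()
        hit = np.cumsum(w) / w_total
        miss = np.cumsum(~in_set[order]) / n_out
        scores[j] = float(np.sum(hit - miss))
    return pd.Series(scores, index=expr.sample_ids, name="ssgsea")


def score_table(
    expr: OmicsMatrix,
    gene_sets: GeneSetCollection,
    immune_set: str = "IMMUNE",
    stromal_set: str = "STROMAL",
    exponent: float = 0.25,
) -> pd.DataFrame:
    """Per-sample immune and stromal ssGSEA scores."""
    return pd.DataFrame(
        {
            "immune_score": ssgsea_score(expr, gene_sets[immune_set], exponent),
            "stromal_score": ssgsea_score(expr, gene_sets[stromal_set], exponent),
        }
    )


@dataclass
class SplitSurvival:
    """Log-rank comparison of the top versus bottom score fraction."""

    test: TestResult
    hr_high_vs_low: float
    hr_ci: tuple[float, float]
    km_high: KMCurve
    km_low: KMCurve
    n_per_arm: int


_SPLIT_FRACTIONS = {"tertile": 1.0 / 3.0, "quartile": 0.25}


def score_survival_split(
    scores: pd.Series,
    clinical: ClinicalTable,
    split: str = "tertile",
) -> SplitSurvival:
    """Compare survival between the top and bottom score fraction.

    The middle of the distribution is discarded; arm size is
    ``floor(n * fraction)``. Boundary ties are resolved by stable sample
    id order.
    """
    if split not in _SPLIT_FRACTIONS:
        raise ValueError(f"split must be one of {sorted(_SPLIT_FRACTIONS)}")
    scores = scores.dropna()
    n = len(scores)
    if n < 6:
        raise ValueError("need at least 6 scored samples")
    m = int(np.floor(n * _SPLIT_FRACTIONS[split]))
    if m < 2:
        raise ValueError("fewer than 2 samples per arm")
    ordered = scores.sort_index().sort_values(kind="stable")
    low_ids = list(ordered.index[:m])
    high_ids = list(ordered.index[-m:])
    high = clinical.survival_arrays(high_ids)
    low = clinical.survival_arrays(low_ids)
    res = logrank_test([high, low])
    try:
        hr, ci = hazard_ratio(high, low)
    except ValueError:
        hr, ci = np.nan, (np.nan, np.nan)
    return SplitSurvival(
        test=res,
        hr_high_vs_low=hr,
        hr_ci=ci,
        km_high=km_estimate(*high),
        km_low=km_estimate(*low),
        n_per_arm=m,
    )


def prognostic_screen(
    expr: OmicsMatrix,
    clinical: ClinicalTable,
    candidate_genes,
    alpha: float = 0.01,
    split: str = "quartile",
    validation_cohorts=None,
) -> list[str]:
    """Screen candidate genes for a protective high-expression effect.

    A gene survives when the high-expression arm (top split fraction)
    shows significantly better OS (log-rank p < alpha and HR(high/low)
    < 1). With ``validation_cohorts`` (``(expr, clinical)`` pairs or
    objects with those attributes), survivors must additionally pass a
    tertile split in *every* cohort that carries the gene; genes missing
    from any cohort are excluded, and constant-expression genes are
    skipped with a warning.
    """
    feature_index = {g: i for i, g in enumerate(expr.feature_ids)}
    missing = [g for g in candidate_genes if g not in feature_index]
    if missing:
        raise ValueError(f"candidate genes absent from matrix: {missing[:5]}")
    survivors = []
    for gene in candidate_genes:
        values = expr.values[feature_index[gene], :]
        if np.all(values == values[0]):
            logger.warning("prognostic_screen: constant gene %r skipped", gene)
            continue
        series = pd.Series(values, index=expr.sample_ids)
        result = score_survival_split(series, clinical, split=split)
        if result.test.p_value < alpha and result.hr_high_vs_low < 1.0:
            survivors.append(gene)
    if validation_cohorts is None:
        return survivors
    validated = []
    for gene in survivors:
        ok = True
        for cohort in validation_cohorts:
            v_expr = getattr(cohort, "expression", None) or cohort[0]
            v_clin = getattr(cohort, "clinical", None) or cohort[1]
            v_index = {g: i for i, g in enumerate(v_expr.feature_ids)}
            if gene not in v_index:
                ok = False
                break
            series = pd.Series(
                v_expr.values[v_index[gene], :], index=v_expr.sample_ids
            )
            res = score_survival_split(series, v_clin, split="tertile")
            if not (res.test.p_value < alpha and res.hr_high_vs_low < 1.0):
                ok = False
                break
        if ok:
            validated.append(gene)
    return validated
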