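"""SAM-style differential methylation, gene- and region-level
aggregation, and genomic-region enrichment.

Probe-level testing follows the significance-analysis-of-microarrays
scheme: a moderated d statistic on log2 methylation intensities
(beta + 1e-3) with the fudge factor s0 fixed at the median per-probe
standard error, and permutation-based q-values (the minimum false
discovery rate at which a probe's |d| would be called). Probes are
called hypermethylated at fold-change > 1.25 and q < 0.01, and
hypomethylated at fold-change < 0.8 and q < 0.01, with the fold change
a ratio of group geometric means of beta.

Region annotation treats the promoter as the 3,000 bp window centered on
the transcription start site (1,500 bp upstream and downstream,
half-open on the genomic coordinate); a probe may carry several region
classes at once.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core_stats import bh_adjust, fisher_exact, t_test_two_sided
from .data_io import OmicsMatrix, RegionAnnotation

logger = logging.getLogger("moprog")

__all__ = [
    "DiffMethResult",
    "RegionSummary",
    "sam_test",
    "call_dm_genes",
    "annotate_probes",
    "region_means",
    "region_enrichment",
    "PROMOTER_HALF_WIDTH",
]

FC_HYPER = 1.25
FC_HYPO = 0.8
Q_THRESHOLD = 0.01
PROMOTER_HALF_WIDTH = 1500
BETA_PSEUDOCOUNT = 1e-3


@dataclass
class DiffMethResult:
    """Per-probe d statistic, permutation q-value, beta fold change
    (second group over first, ratio of geometric means) and call."""

    table: pd.DataFrame  # probe_id, fold_change, d_statistic, q_value, call

    def calls(self, direction: str) -> list[str]:
        t = self.table
        return list(t.loc[t["call"] == direction, "probe_id"])


@dataclass
class RegionSummary:
    """Mean beta per region class and group plus pairwise tests, or the
    per-class enrichment of differential calls."""

    means: pd.DataFrame | None = None  # region_class x group
    tests: pd.DataFrame | None = None  # pairwise group t tests per class
    enrichment: pd.DataFrame | None = None  # per class: odds_ratio, p, p_adjusted


def _moderated_d(x: np.ndarray, idx_a, idx_b, s0: float | None = None):
    """SAM d statistic of group b minus group a on log intensities."""
    a, b = x[:, idx_a], x[:, idx_b]
    na, nb = a.shape[1], b.shape[1]
    pooled_var = (
        (na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)
    ) / (na + nb - 2)
    s = np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    if s0 is None:
        s0 = float(np.median(s))
    d = (b.mean(axis=1) - a.mean(axis=1)) / (s + s0)
    return d, s0


def sam_test(
    meth: OmicsMatrix,
    group_a,
    group_b,
    n_permutations: int = 100,
    seed: int = 0,
) -> DiffMethResult:
    """Permutation SAM test of methylation differences, group_b versus
    group_a.

    q-values come from label permutations: for the observed |d| order
    statistics, the FDR at each threshold is the average number of
    permuted |d| values at or above it divided by the observed count,
    and a probe's q is the minimum FDR over the thresholds that call it.
    Deterministic given ``seed``.
    """
    ids = {s: j for j, s in enumerate(meth.sample_ids)}
    idx_a = np.array([ids[s] for s in group_a])
    idx_b = np.array([ids[s] for s in group_b])
    if idx_a.size < 2 or idx_b.size < 2:
        raise ValueError("need at least 2 samples per group")
    if n_permutations < 25:
        logger.warning(
            "sam_test: %d permutations is low; q-value resolution will be coarse",
            n_permutations,
        )
    x = np.log2(meth.values + BETA_PSEUDOCOUNT)
    d, s0 = _moderated_d(x, idx_a, idx_b)
    abs_d = np.abs(d)
    m = abs_d.size

    rng = np.random.default_rng(seed)
    pool = np.concatenate([idx_a, idx_b])
    perm_abs = np.empty((n_permutations, m))
    for p in range(n_permutations):
        shuffled = rng.permutation(pool)
        pa, pb = shuffled[: idx_a.size], shuffled[idx_a.size :]
        d_perm, _ = _moderated_d(x, pa, pb, s0=s0)
        perm_abs[p] = np.abs(d_perm)
    perm_sorted = np.sort(perm_abs.ravel())

    order = np.argsort(-abs_d, kind="stable")
    thresholds = abs_d[order]
    # mean permuted count of |d_perm| >= threshold, per threshold
    exceed = perm_sorted.size - np.searchsorted(perm_sorted, thresholds, side="left")
    fdr = (exceed / n_permutations) / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted

    log_beta = np.log(meth.values + BETA_PSEUDOCOUNT)
    fc = np.exp(
        log_beta[:, idx_b].mean(axis=1) - log_beta[:, idx_a].mean(axis=1)
    )
    call = np.where(
        (fc > FC_HYPER) & (q < Q_THRESHOLD),
        "hyper",
        np.where((fc < FC_HYPO) & (q < Q_THRESHOLD), "hypo", "ns"),
    )
    table = pd.DataFrame(
        {
            "probe_id": meth.feature_ids,
            "fold_change": fc,
            "d_statistic": d,
            "q_value": q,
            "call": call,
        }
    )
    return DiffMethResult(table)


def annotate_probes(regions: RegionAnnotation) -> dict[str, frozenset[str]]:
    """Map each probe to the set of region classes its position overlaps.

    Classes are the annotated interval classes plus ``promoter``
    (TSS +/- 1,500 bp, half-open: the lower bound is included). Probes
    overlapping nothing get class ``none``; probes on chromosomes absent
    from the annotation get ``none`` with a warning.
    """
    trees: dict[str, IntervalTree] = {}
    for row in regions.intervals.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(
            int(row.start), int(row.end), row.region_class
        )
    for row in regions.tss_table.itertuples(index=False):
        tss = int(row.tss_position)
        start = max(0, tss - PROMOTER_HALF_WIDTH)
        trees.setdefault(row.chrom, IntervalTree()).addi(
            start, tss + PROMOTER_HALF_WIDTH, "promoter"
        )
    known_chroms = set(trees)
    out: dict[str, frozenset[str]] = {}
    warned: set[str] = set()
    for row in regions.probe_positions.itertuples(index=False):
        if row.chrom not in known_chroms:
            if row.chrom not in warned:
                logger.warning(
                    "annotate_probes: unknown chromosome %r; probes set to 'none'",
                    row.chrom,
                )
                warned.add(row.chrom)
            out[row.probe_id] = frozenset({"none"})
            continue
        hits = trees[row.chrom][int(row.position)]
        classes = frozenset(h.data for h in hits) or frozenset({"none"})
        out[row.probe_id] = classes
    return out


def call_dm_genes(
    result: DiffMethResult, regions: RegionAnnotation
) -> pd.DataFrame:
    """Gene-level differential methylation from promoter probes.

    A gene is hyper-/hypomethylated when at least one probe in its
    promoter carries that call and none carries the opposite call; genes
    whose promoters harbor both are excluded (and logged). Genes without
    promoter probes are absent from the output.
    """
    probe_call = dict(zip(result.table["probe_id"], result.table["call"]))
    probe_pos = regions.probe_positions
    rows = []
    n_mixed = 0
    for gene_row in regions.tss_table.itertuples(index=False):
        tss = int(gene_row.tss_position)
        lo, hi = tss - PROMOTER_HALF_WIDTH, tss + PROMOTER_HALF_WIDTH
        in_prom = probe_pos[
            (probe_pos["chrom"] == gene_row.chrom)
            & (probe_pos["position"] >= lo)
            & (probe_pos["position"] < hi)
        ]["probe_id"]
        calls = {probe_call.get(p, "ns") for p in in_prom}
        has_hyper, has_hypo = "hyper" in calls, "hypo" in calls
        if has_hyper and has_hypo:
            n_mixed += 1
            continue
        if has_hyper:
            rows.append((gene_row.gene, "hyper"))
        elif has_hypo:
            rows.append((gene_row.gene, "hypo"))
    if n_mixed:
        logger.info("call_dm_genes: %d mixed-promoter genes excluded", n_mixed)
    return pd.DataFrame(rows, columns=["gene", "call"])


def region_means(
    meth: OmicsMatrix,
    grouping: pd.Series,
    annotation: RegionAnnotation,
    probe_subset=None,
) -> RegionSummary:
    """Mean beta per region class and patient group, with pairwise
    Student t tests on the per-sample region means.

    ``probe_subset`` restricts the computation (e.g. to probes annotated
    to a particular gene list). Empty classes are omitted.
    """
    classes = annotate_probes(annotation)
    probe_index = {p: i for i, p in enumerate(meth.feature_ids)}
    allowed = set(probe_subset) if probe_subset is not None else None
    by_class: dict[str, list[int]] = {}
    for probe, cls_set in classes.items():
        if probe not in probe_index:
            continue
        if allowed is not None and probe not in allowed:
            continue
        for cls in cls_set:
            if cls != "none":
                by_class.setdefault(cls, []).append(probe_index[probe])
    grouping = grouping.astype(str)
    groups = sorted(grouping.unique())
    col = {s: j for j, s in enumerate(meth.sample_ids)}
    sample_idx = {
        g: [col[s] for s in grouping.index[grouping == g]] for g in groups
    }
    mean_rows, test_rows = [], []
    for cls in sorted(by_class):
        rows = by_class[cls]
        per_sample = meth.values[rows, :].mean(axis=0)
        class_means = {g: float(per_sample[sample_idx[g]].mean()) for g in groups}
        mean_rows.append({"region_class": cls, **class_means})
        for ga, gb in itertools.combinations(groups, 2):
            res = t_test_two_sided(per_sample[sample_idx[ga]], per_sample[sample_idx[gb]])
            test_rows.append(
                {
                    "region_class": cls,
                    "group_a": ga,
                    "group_b": gb,
                    "statistic": res.statistic,
                    "p": res.p_value,
                    "mean_difference": res.estimate,
                }
            )
    means = pd.DataFrame(mean_rows).set_index("region_class") if mean_rows else pd.DataFrame()
    tests = pd.DataFrame(test_rows)
    return RegionSummary(means=means, tests=tests)


def region_enrichment(
    result: DiffMethResult,
    annotation: RegionAnnotation,
    direction: str,
) -> RegionSummary:
    """Fisher enrichment of ``direction`` calls in each region class.

    The background is every probe in the result table (the array). Per
    class the 2x2 table crosses in-class membership with called status;
    p-values are BH-adjusted across classes.
    """
    if direction not in ("hyper", "hypo"):
        raise ValueError("direction must be 'hyper' or 'hypo'")
    classes = annotate_probes(annotation)
    probes = list(result.table["probe_id"])
    called = set(result.calls(direction))
    class_names = sorted(
        {c for s in classes.values() for c in s if c != "none"}
    )
    rows = []
    for cls in class_names:
        in_class = {p for p in probes if cls in classes.get(p, frozenset())}
        a = len(in_class & called)
        b = len(in_class) - a
        c = len(called) - a
        d = len(probes) - len(in_class) - c
        if len(called) == 0:
            rows.append({"region_class": cls, "odds_ratio": np.nan, "p": 1.0})
            continue
        res = fisher_exact([[a, b], [c, d]])
        # an all-called (or all-uncalled-in-both-arms) table carries no
        # enrichment information: report the neutral odds ratio
        odds = 1.0 if np.isnan(res.estimate) else res.estimate
        rows.append({"region_class": cls, "odds_ratio": odds, "p": res.p_value})
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adjusted"] = bh_adjust(table["p"])
    return RegionSummary(enrichment=table)
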