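"""Survival statistics and the survival-labeled cluster-pooling rule.

Implements the product-limit (Kaplan-Meier) estimator, the log-rank
(Mantel-Cox) test via observed/expected event accumulation over risk
sets, the Pike hazard-ratio estimator built from the same quantities,
and the two-stage procedure that turns three independent cluster
assignments into one prognostic grouping:

1. within each clustering approach, a cluster is labeled ``better`` if
   it shows significantly better OS than at least one other cluster and
   worse than none (``poorer`` symmetrically, otherwise ``neutral``);
2. per patient, the three labels are pooled: a patient with only
   ``better`` labels (and at least one) is ``better``; with only
   ``poorer`` labels, ``poorer``; a patient labeled both ways needs the
   majority (at least two of three) to land in either group, otherwise
   ``intermediate``.

Deaths are processed before censorings at tied times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_stats import TestResult
from .data_io import ClinicalTable

__all__ = [
    "KMCurve",
    "SurvivalLabeling",
    "PrognosticGrouping",
    "km_estimate",
    "logrank_test",
    "hazard_ratio",
    "label_clusters",
    "pool_groups",
]


@dataclass
class KMCurve:
    """Product-limit estimate on the grid of distinct observed times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n_censored: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival estimate must be non-increasing")

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _check_surv(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size != events.size:
        raise ValueError("times and events must have equal length")
    if times.size == 0:
        raise ValueError("empty survival input")
    if np.any(times < 0):
        raise ValueError("negative survival time")
    if not set(np.unique(events)) <= {0, 1}:
        raise ValueError("events must be 0/1")
    return times, events


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimator; censored subjects leave the risk set after
    their time (deaths first at ties)."""
    times, events = _check_surv(times, events)
    grid = np.unique(times)
    at_risk = np.empty(grid.size)
    d = np.empty(grid.size)
    c = np.empty(grid.size)
    surv = np.empty(grid.size)
    s = 1.0
    for i, t in enumerate(grid):
        at_risk[i] = np.sum(times >= t)
        d[i] = np.sum((times == t) & (events == 1))
        c[i] = np.sum((times == t) & (events == 0))
        if d[i] > 0:
            s *= 1.0 - d[i] / at_risk[i]
        surv[i] = s
    return KMCurve(grid, surv, at_risk, d, c)


def _logrank_tables(groups):
    """Observed events, expected events and covariance over risk sets."""
    g = len(groups)
    all_times = np.concatenate([t for t, _ in groups])
    event_times = np.unique(
        np.concatenate([t[e == 1] for t, e in groups if np.any(e == 1)])
    )
    observed = np.array([float(np.sum(e)) for _, e in groups])
    expected = np.zeros(g)
    cov = np.zeros((g, g))
    for t in event_times:
        n_at = np.array([float(np.sum(times >= t)) for times, _ in groups])
        d_at = np.array(
            [float(np.sum((times == t) & (e == 1))) for times, e in groups]
        )
        n_tot, d_tot = n_at.sum(), d_at.sum()
        if n_tot == 0 or d_tot == 0:
            continue
        expected += d_tot * n_at / n_tot
        if n_tot > 1:
            factor = d_tot * (n_tot - d_tot) / (n_tot - 1.0)
            p = n_at / n_tot
            cov += factor * (np.diag(p) - np.outer(p, p))
    return observed, expected, cov


def logrank_test(groups) -> TestResult:
    """Log-rank (Mantel-Cox) test across two or more groups.

    ``groups`` is a sequence of ``(times, events)`` pairs. The statistic
    is chi-squared with ``g - 1`` degrees of freedom; the estimate slot
    carries the first group's O/E ratio relative to the last group's
    (the Pike hazard ratio) when both are defined.
    """
    groups = [_check_surv(t, e) for t, e in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(t.size == 0 for t, _ in groups):
        raise ValueError("a group has zero subjects")
    if sum(int(np.sum(e)) for _, e in groups) == 0:
        raise ValueError("no events in any group")
    observed, expected, cov = _logrank_tables(groups)
    diff = (observed - expected)[:-1]
    v = cov[:-1, :-1]
    if diff.size == 1:
        chi2 = float(diff[0] ** 2 / v[0, 0]) if v[0, 0] > 0 else 0.0
    else:
        chi2 = float(diff @ np.linalg.pinv(v) @ diff)
    df = len(groups) - 1
    p = float(stats.chi2.sf(chi2, df))
    est = np.nan
    if expected[0] > 0 and expected[-1] > 0 and observed[-1] > 0:
        est = (observed[0] / expected[0]) / (observed[-1] / expected[-1])
    return TestResult(chi2, p, float(est), float(df))


def hazard_ratio(group_a, group_b) -> tuple[float, tuple[float, float]]:
    """Pike estimator of the hazard ratio of group_a relative to group_b.

    HR = (O_a/E_a)/(O_b/E_b); the 95% CI is
    exp(log HR +/- 1.96 * sqrt(1/E_a + 1/E_b)).
    """
    a = _check_surv(*group_a)
    b = _check_surv(*group_b)
    if np.sum(a[1]) < 1 or np.sum(b[1]) < 1:
        raise ValueError("need at least one event in each group")
    observed, expected, _ = _logrank_tables([a, b])
    if expected[0] <= 0 or expected[1] <= 0:
        raise ValueError("zero expected events")
    hr = (observed[0] / expected[0]) / (observed[1] / expected[1])
    half = 1.96 * np.sqrt(1.0 / expected[0] + 1.0 / expected[1])
    log_hr = np.log(hr)
    return float(hr), (float(np.exp(log_hr - half)), float(np.exp(log_hr + half)))


@dataclass
class SurvivalLabeling:
    """Per-sample {better, poorer, neutral} labels for one clustering
    approach, with the pairwise log-rank p and HR tables they derive
    from."""

    approach: str
    labels: pd.Series  # index sample_id
    cluster_labels: dict
    p_table: pd.DataFrame
    hr_table: pd.DataFrame


@dataclass
class PrognosticGrouping:
    """Pooled {better, poorer, intermediate} assignment with the three
    per-approach labels it was derived from."""

    groups: pd.Series  # index sample_id
    provenance: pd.DataFrame  # one column per approach

    def sizes(self) -> dict[str, int]:
        return self.groups.value_counts().to_dict()


def label_clusters(
    assignment: pd.Series,
    clinical: ClinicalTable,
    alpha: float = 0.01,
    approach: str = "clustering",
    label_map: dict | None = None,
) -> SurvivalLabeling:
    """Label each cluster better/poorer/neutral from pairwise log-rank
    comparisons.

    Cluster i *beats* cluster j when their log-rank p is below ``alpha``
    and i's Pike HR versus j is below 1. A cluster beating at least one
    other and beaten by none is ``better``; beaten by at least one and
    beating none, ``poorer``; anything else ``neutral``. Samples inherit
    their cluster's label. ``label_map`` (cluster -> label) overrides
    the rule entirely.
    """
    assignment = assignment.astype(str)
    clusters = sorted(assignment.unique())
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters to label")
    missing = set(assignment.index) - set(clinical.sample_ids)
    if missing:
        raise ValueError(f"samples without survival data: {sorted(missing)[:5]}")
    surv = {
        c: clinical.survival_arrays(assignment.index[assignment == c])
        for c in clusters
    }
    p_table = pd.DataFrame(np.nan, index=clusters, columns=clusters)
    hr_table = pd.DataFrame(np.nan, index=clusters, columns=clusters)
    beats = {c: set() for c in clusters}
    for i, ci in enumerate(clusters):
        for cj in clusters[i + 1 :]:
            res = logrank_test([surv[ci], surv[cj]])
            try:
                hr, _ = hazard_ratio(surv[ci], surv[cj])
            except ValueError:
                hr = np.nan
            p_table.loc[ci, cj] = p_table.loc[cj, ci] = res.p_value
            hr_table.loc[ci, cj] = hr
            hr_table.loc[cj, ci] = 1.0 / hr if hr and np.isfinite(hr) else np.nan
            if res.p_value < alpha and np.isfinite(hr):
                if hr < 1.0:
                    beats[ci].add(cj)
                elif hr > 1.0:
                    beats[cj].add(ci)
    if label_map is not None:
        cluster_labels = {str(c): label_map[c] for c in label_map}
        for c in clusters:
            cluster_labels.setdefault(c, "neutral")
    else:
        beaten = {c: {d for d in clusters if c in beats[d]} for c in clusters}
        cluster_labels = {}
        for c in clusters:
            if beats[c] and not beaten[c]:
                cluster_labels[c] = "better"
            elif beaten[c] and not beats[c]:
                cluster_labels[c] = "poorer"
            else:
                cluster_labels[c] = "neutral"
    labels = assignment.map(cluster_labels).rename("label")
    return SurvivalLabeling(approach, labels, cluster_labels, p_table, hr_table)


def pool_groups(labelings) -> PrognosticGrouping:
    """Pool exactly three per-approach labelings into the final grouping.

    Per sample, with b = number of ``better`` labels and p = number of
    ``poorer`` labels: only-better (b >= 1, p = 0) pools to ``better``
    and only-poorer to ``poorer``; a conflicted sample (b >= 1 and
    p >= 1) needs a two-of-three majority either way, otherwise — like a
    sample with no significant label at all — it is ``intermediate``.
    """
    if len(labelings) != 3:
        raise ValueError("exactly 3 labelings required")
    universe = set(labelings[0].labels.index)
    for lab in labelings[1:]:
        if set(lab.labels.index) != universe:
            raise ValueError("labelings cover different sample sets")
    order = list(labelings[0].labels.index)
    prov = pd.DataFrame(
        {lab.approach: lab.labels.reindex(order) for lab in labelings},
        index=order,
    )
    b = (prov == "better").sum(axis=1)
    p = (prov == "poorer").sum(axis=1)
    groups = pd.Series("intermediate", index=order, name="prognostic_group")
    groups[(b >= 1) & (p == 0)] = "better"
    groups[(p >= 1) & (b == 0)] = "poorer"
    conflicted = (b >= 1) & (p >= 1)
    groups[conflicted & (b >= 2)] = "better"
    groups[conflicted & (p >= 2)] = "poorer"
    return PrognosticGrouping(groups, prov)
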