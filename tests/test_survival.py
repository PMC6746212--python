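"""Kaplan-Meier, log-rank, Pike hazard ratio, cluster labeling and the
two-of-three pooling rule."""

import itertools

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import multivariate_logrank_test

from moprog.data_io import ClinicalTable
from moprog.survival import (
    SurvivalLabeling,
    hazard_ratio,
    km_estimate,
    label_clusters,
    logrank_test,
    pool_groups,
)


def _clinical(times, events, ids=None):
    ids = ids or [f"p{i}" for i in range(len(times))]
    return ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": ids,
                "os_days": times,
                "event": events,
                "age_years": 60.0,
                "sex": "female",
                "stage": "II",
            }
        )
    )


class TestKaplanMeier:
    def test_all_censored_stays_at_one(self):
        km = km_estimate([5.0, 10.0, 15.0], [0, 0, 0])
        assert np.all(km.survival == 1.0)

    def test_hand_product_limit(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        assert km.survival == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_death_processed_before_censoring_at_tie(self):
        # the subject censored at t=2 is still at risk for the death at 2
        km = km_estimate([1.0, 2.0, 2.0, 3.0], [1, 1, 0, 1])
        assert km.at_risk[1] == 3
        assert km.survival[1] == pytest.approx(0.75 * (2 / 3))

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        times = rng.exponential(10, size=40)
        events = rng.integers(0, 2, size=40)
        km = km_estimate(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t, s in zip(km.times, km.survival):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-10
            )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        g = (np.array([1.0, 2.0, 3.0]), np.array([1, 1, 0]))
        res = logrank_test([g, g])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_risk_set_computation(self):
        a = (np.array([1.0, 2.0]), np.array([1, 1]))
        b = (np.array([3.0, 4.0]), np.array([1, 1]))
        res = logrank_test([a, b])
        assert res.statistic == pytest.approx(2.8824, abs=1e-3)

    def test_relabeling_invariance(self, rng):
        a = (rng.exponential(5, 20), rng.integers(0, 2, 20))
        b = (rng.exponential(9, 25), rng.integers(0, 2, 25))
        if a[1].sum() + b[1].sum() == 0:
            a[1][0] = 1
        assert logrank_test([a, b]).statistic == pytest.approx(
            logrank_test([b, a]).statistic
        )

    @pytest.mark.parametrize("n_groups", [2, 3])
    def test_matches_lifelines(self, rng, n_groups):
        times = rng.exponential(10, size=30 * n_groups)
        events = rng.integers(0, 2, size=30 * n_groups)
        events[0] = 1
        labels = np.repeat(np.arange(n_groups), 30)
        groups = [
            (times[labels == g], events[labels == g]) for g in range(n_groups)
        ]
        mine = logrank_test(groups)
        ref = multivariate_logrank_test(times, labels, events)
        assert mine.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert mine.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([(np.array([1.0]), np.array([1])), (np.array([]), np.array([]))])


class TestHazardRatio:
    def test_identical_groups_unity(self):
        g = (np.array([1.0, 2.0, 3.0, 4.0]), np.array([1, 1, 1, 0]))
        hr, (lo, hi) = hazard_ratio(g, g)
        assert hr == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_hand_pike_estimate(self):
        a = (np.array([1.0, 2.0]), np.array([1, 1]))
        b = (np.array([3.0, 4.0]), np.array([1, 1]))
        hr, _ = hazard_ratio(a, b)
        assert hr == pytest.approx((2 / (5 / 6)) / (2 / (19 / 6)), rel=1e-9)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            hazard_ratio(
                (np.array([1.0, 2.0]), np.array([0, 0])),
                (np.array([1.0, 2.0]), np.array([1, 1])),
            )


class TestLabelClusters:
    def _planted(self, hazards, n_per=60, seed=0):
        rng = np.random.default_rng(seed)
        times, ids, clusters = [], [], []
        for c, h in enumerate(hazards):
            t = rng.exponential(1.0 / h, size=n_per)
            times.extend(t)
            ids.extend([f"c{c}_{i}" for i in range(n_per)])
            clusters.extend([f"C{c}"] * n_per)
        events = (np.array(times) < np.quantile(times, 0.8)).astype(int)
        clin = _clinical(times, events, ids)
        return pd.Series(clusters, index=ids), clin

    def test_single_elevated_hazard_cluster(self):
        assignment, clin = self._planted([0.01, 0.01, 0.05])
        lab = label_clusters(assignment, clin, alpha=0.01)
        assert lab.cluster_labels == {"C0": "better", "C1": "better", "C2": "poorer"}

    def test_no_significant_pair_all_neutral(self):
        assignment, clin = self._planted([0.01, 0.0101, 0.0102], n_per=15)
        lab = label_clusters(assignment, clin, alpha=0.001)
        assert set(lab.cluster_labels.values()) == {"neutral"}

    def test_beaten_cluster_cannot_be_better(self):
        assignment, clin = self._planted([0.005, 0.02, 0.08])
        lab = label_clusters(assignment, clin, alpha=0.01)
        # the middle cluster beats C2 but is beaten by C0 -> not better
        assert lab.cluster_labels["C1"] != "better"

    def test_label_map_override(self):
        assignment, clin = self._planted([0.01, 0.05])
        lab = label_clusters(
            assignment, clin, label_map={"C0": "poorer", "C1": "better"}
        )
        assert lab.cluster_labels == {"C0": "poorer", "C1": "better"}

    def test_single_cluster_rejected(self):
        assignment, clin = self._planted([0.01])
        with pytest.raises(ValueError):
            label_clusters(assignment, clin)


def _labeling(approach, labels, ids):
    return SurvivalLabeling(
        approach,
        pd.Series(labels, index=ids, name="label"),
        {},
        pd.DataFrame(),
        pd.DataFrame(),
    )


def pooled_label_oracle(triple) -> str:
    """Direct restatement of the pooling rule for one sample."""
    b = triple.count("better")
    p = triple.count("poorer")
    if b >= 1 and p == 0:
        return "better"
    if p >= 1 and b == 0:
        return "poorer"
    if b >= 2:
        return "better"
    if p >= 2:
        return "poorer"
    return "intermediate"


class TestPoolGroups:
    def test_exhaustive_truth_table(self):
        """pool_groups agrees with the stated rule on all 27 label
        triples."""
        triples = list(
            itertools.product(["better", "poorer", "neutral"], repeat=3)
        )
        ids = [f"s{i}" for i in range(len(triples))]
        labelings = [
            _labeling(f"approach{j}", [t[j] for t in triples], ids)
            for j in range(3)
        ]
        grouping = pool_groups(labelings)
        for sid, triple in zip(ids, triples):
            assert grouping.groups[sid] == pooled_label_oracle(triple), triple

    def test_single_better_vote_suffices_without_conflict(self):
        ids = ["s"]
        grouping = pool_groups(
            [
                _labeling("a", ["better"], ids),
                _labeling("b", ["neutral"], ids),
                _labeling("c", ["neutral"], ids),
            ]
        )
        assert grouping.groups["s"] == "better"

    def test_conflict_needs_majority(self):
        ids = ["s"]
        grouping = pool_groups(
            [
                _labeling("a", ["better"], ids),
                _labeling("b", ["poorer"], ids),
                _labeling("c", ["neutral"], ids),
            ]
        )
        assert grouping.groups["s"] == "intermediate"

    def test_wrong_arity_or_universe_rejected(self):
        ids = ["s1", "s2"]
        labs = [_labeling(f"a{j}", ["neutral", "neutral"], ids) for j in range(2)]
        with pytest.raises(ValueError):
            pool_groups(labs)
        labs3 = labs + [_labeling("a2", ["neutral"], ["s1"])]
        with pytest.raises(ValueError):
            pool_groups(labs3)


def test_logrank_null_pvalues_uniform():
    """Null log-rank p-values are uniform on [0, 1] (KS test)."""
    rng = np.random.default_rng(2024)
    pvals = []
    for _ in range(1000):
        times = rng.exponential(10.0, size=60)
        events = (rng.random(60) < 0.7).astype(int)
        if events.sum() == 0:
            events[0] = 1
        labels = rng.permutation(np.repeat([0, 1], 30))
        groups = [(times[labels == g], events[labels == g]) for g in (0, 1)]
        pvals.append(logrank_test(groups).p_value)
    from scipy.stats import kstest

    assert kstest(pvals, "uniform").pvalue > 0.01
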