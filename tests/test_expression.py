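"""Differential expression, ORA, ssGSEA scores and prognostic screens."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from moprog.data_io import ClinicalTable, GeneSetCollection, OmicsMatrix
from moprog.expression import (
    nb_wald_test,
    ora,
    prognostic_screen,
    score_survival_split,
    size_factors,
    ssgsea_score,
)


def _counts(values):
    values = np.asarray(values, dtype=float)
    return OmicsMatrix(
        values,
        [f"g{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        "expression_counts",
    )


def _log_matrix(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return OmicsMatrix(
        values, genes, [f"s{j}" for j in range(values.shape[1])], "expression_log"
    )


class TestSizeFactors:
    def test_identical_columns_unity(self):
        m = _counts(np.tile([[4], [10], [7]], (1, 5)))
        assert size_factors(m) == pytest.approx(np.ones(5))

    def test_doubled_column(self):
        base = np.array([[4.0, 8.0], [10.0, 20.0], [6.0, 12.0]])
        factors = size_factors(_counts(base))
        assert factors[1] / factors[0] == pytest.approx(2.0)

    def test_gene_order_invariance(self, rng):
        v = rng.integers(1, 100, size=(20, 6)).astype(float)
        m = _counts(v)
        perm = rng.permutation(20)
        m2 = _counts(v[perm])
        assert size_factors(m) == pytest.approx(size_factors(m2))

    def test_requires_all_positive_gene(self):
        with pytest.raises(ValueError):
            size_factors(_counts([[0, 1], [2, 0]]))


class TestNBWald:
    def test_identical_groups_zero_fold_change(self, rng):
        v = rng.integers(0, 50, size=(30, 8)).astype(float)
        m = _counts(np.hstack([v[:, :4], v[:, :4]]))
        res = nb_wald_test(m, m.sample_ids[:4], m.sample_ids[4:])
        assert res.table["log2_fold_change"].abs().max() == pytest.approx(0.0)

    def test_group_swap_flips_sign_preserves_p(self, rng):
        v = rng.poisson(30, size=(50, 10)).astype(float)
        v[0, 5:] *= 4
        m = _counts(v)
        fwd = nb_wald_test(m, m.sample_ids[:5], m.sample_ids[5:])
        rev = nb_wald_test(m, m.sample_ids[5:], m.sample_ids[:5])
        assert fwd.table["log2_fold_change"].to_numpy() == pytest.approx(
            -rev.table["log2_fold_change"].to_numpy()
        )
        assert fwd.table["p"].to_numpy() == pytest.approx(rev.table["p"].to_numpy())

    def test_call_thresholds(self, rng):
        v = rng.poisson(100, size=(60, 20)).astype(float)
        v[0, 10:] *= 8  # clearly up, |log2FC| > 1, tiny p
        v[1, 10:] = np.round(v[1, 10:] * 1.15)  # below fold threshold
        m = _counts(v)
        res = nb_wald_test(m, m.sample_ids[:10], m.sample_ids[10:])
        t = res.table.set_index("gene")
        assert t.loc["g0", "call"] == "up"
        assert t.loc["g1", "call"] == "ns"
        # the call column is exactly the thresholded rule
        expect = np.where(
            (t["log2_fold_change"] > 1) & (t["p_adjusted"] < 1e-3),
            "up",
            np.where(
                (t["log2_fold_change"] < -1) & (t["p_adjusted"] < 1e-3), "down", "ns"
            ),
        )
        assert list(t["call"]) == list(expect)

    def test_all_zero_gene_is_ns(self):
        v = np.ones((5, 6))
        v[2] = 0.0
        res = nb_wald_test(_counts(v), [f"s{j}" for j in range(3)], [f"s{j}" for j in range(3, 6)])
        row = res.table.set_index("gene").loc["g2"]
        assert row["call"] == "ns" and row["p"] == 1.0

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(3)
        mu = rng.lognormal(np.log(50), 1, 2000)
        disp = 0.15
        lam = rng.gamma(1 / disp, mu[:, None] * disp, size=(2000, 40))
        m = _counts(rng.poisson(lam).astype(float))
        res = nb_wald_test(m, m.sample_ids[:20], m.sample_ids[20:])
        rate = float((res.table["p"] < 0.05).mean())
        assert abs(rate - 0.05) <= 0.02


class TestORA:
    def _sets(self):
        return GeneSetCollection(
            {
                "A": frozenset({f"g{i}" for i in range(5)}),
                "B": frozenset({f"g{i}" for i in range(50, 60)}),
                "ELSEWHERE": frozenset({"x1", "x2"}),
            }
        )

    def test_whole_set_enriched(self):
        universe = [f"g{i}" for i in range(200)]
        res = ora([f"g{i}" for i in range(5)], universe, self._sets(), alpha_adj=0.05)
        assert list(res["set"]) == ["A"]
        assert res["overlap"].iloc[0] == 5

    def test_hypergeometric_value(self):
        universe = [f"g{i}" for i in range(20)]
        sets = GeneSetCollection({"S": frozenset({f"g{i}" for i in range(5)})})
        res = ora([f"g{i}" for i in [0, 1, 2, 3, 10]], universe, sets, alpha_adj=1.0)
        assert res["p"].iloc[0] == pytest.approx(76 / 15504)

    def test_alpha_one_returns_every_overlapping_set(self):
        universe = [f"g{i}" for i in range(100)]
        res = ora(["g0", "g55"], universe, self._sets(), alpha_adj=1.0)
        assert set(res["set"]) == {"A", "B"}  # ELSEWHERE skipped (disjoint)

    def test_gene_list_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            ora(["nope"], ["g1"], self._sets())


def brute_force_running_sum(values, genes, signature, exponent=0.25):
    """Independent oracle: literal position-by-position running sum."""
    ranks = rankdata(values, method="average")
    order = sorted(range(len(genes)), key=lambda i: (-ranks[i], i))
    in_set = [genes[i] in signature for i in order]
    w_total = sum(ranks[order[i]] ** exponent for i in range(len(order)) if in_set[i])
    n_out = len(genes) - sum(in_set)
    hit = miss = total = 0.0
    for i in range(len(order)):
        if in_set[i]:
            hit += ranks[order[i]] ** exponent / w_total
        else:
            miss += 1.0 / n_out
        total += hit - miss
    return total


class TestSsgsea:
    def test_matches_bruteforce_on_all_orderings(self):
        genes = ["a", "b", "c", "d", "e"]
        signature = {"b", "d"}
        for perm in itertools.permutations([1.0, 2.0, 3.0, 4.0, 5.0]):
            m = _log_matrix(np.array(perm).reshape(5, 1), genes)
            mine = ssgsea_score(m, signature).iloc[0]
            assert mine == pytest.approx(
                brute_force_running_sum(np.array(perm), genes, signature)
            )

    def test_top_rank_placement_is_maximal(self):
        genes = [f"g{i}" for i in range(8)]
        values = np.arange(8, 0, -1, dtype=float).reshape(8, 1)
        scores = {}
        for pair in itertools.combinations(range(8), 2):
            sig = {genes[i] for i in pair}
            scores[pair] = ssgsea_score(_log_matrix(values, genes), sig).iloc[0]
        assert max(scores, key=scores.get) == (0, 1)

    def test_invariant_under_monotone_transform(self, rng):
        v = rng.lognormal(size=(30, 4))
        m = _log_matrix(v)
        sig = {f"g{i}" for i in range(0, 30, 7)}
        before = ssgsea_score(m, sig)
        after = ssgsea_score(_log_matrix(np.log2(v)), sig)
        assert before.to_numpy() == pytest.approx(after.to_numpy())

    def test_requires_two_signature_genes(self, rng):
        with pytest.raises(ValueError):
            ssgsea_score(_log_matrix(rng.normal(size=(5, 2))), {"g0"})


def _clinical_from_hazard(scores, loghr, seed=0, censor_frac=0.3):
    rng = np.random.default_rng(seed)
    hazards = 0.01 * np.exp(-loghr * (scores - scores.mean()) / scores.std())
    times = rng.exponential(1.0 / hazards)
    events = (rng.random(len(scores)) > censor_frac).astype(int)
    return ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": list(scores.index),
                "os_days": times,
                "event": events,
                "age_years": 60.0,
                "sex": "male",
                "stage": "III",
            }
        )
    )


class TestScoreSurvivalSplit:
    def test_tertile_arm_sizes(self, rng):
        scores = pd.Series(rng.normal(size=9), index=[f"p{i}" for i in range(9)])
        clin = _clinical_from_hazard(scores, 0.0)
        res = score_survival_split(scores, clin, split="tertile")
        assert res.n_per_arm == 3

    def test_quartile_arm_sizes(self, rng):
        scores = pd.Series(rng.normal(size=100), index=[f"p{i}" for i in range(100)])
        clin = _clinical_from_hazard(scores, 0.0)
        res = score_survival_split(scores, clin, split="quartile")
        assert res.n_per_arm == 25

    def test_planted_association_detected(self, rng):
        scores = pd.Series(rng.normal(size=120), index=[f"p{i}" for i in range(120)])
        clin = _clinical_from_hazard(scores, loghr=1.0, seed=1)
        res = score_survival_split(scores, clin, split="tertile")
        assert res.test.p_value < 0.05
        assert res.hr_high_vs_low < 1.0

    def test_too_small_rejected(self, rng):
        scores = pd.Series(rng.normal(size=5), index=[f"p{i}" for i in range(5)])
        clin = _clinical_from_hazard(scores, 0.0)
        with pytest.raises(ValueError):
            score_survival_split(scores, clin)


class TestPrognosticScreen:
    def _expr_clinical(self, n=120, protective_gene=True, seed=2):
        rng = np.random.default_rng(seed)
        samples = [f"p{i}" for i in range(n)]
        values = rng.normal(size=(6, n))
        expr = OmicsMatrix(values, [f"g{i}" for i in range(6)], samples, "expression_log")
        loghr = 1.2 if protective_gene else 0.0
        scores = pd.Series(values[0], index=samples)
        clin = _clinical_from_hazard(scores, loghr=loghr, seed=seed)
        return expr, clin

    def test_planted_protective_gene_survives(self):
        expr, clin = self._expr_clinical()
        survivors = prognostic_screen(expr, clin, ["g0", "g1"], alpha=0.01)
        assert "g0" in survivors

    def test_null_survivor_fraction_near_alpha(self):
        rng = np.random.default_rng(9)
        n, n_genes = 120, 150
        samples = [f"p{i}" for i in range(n)]
        expr = OmicsMatrix(
            rng.normal(size=(n_genes, n)),
            [f"g{i}" for i in range(n_genes)],
            samples,
            "expression_log",
        )
        clin = _clinical_from_hazard(pd.Series(np.zeros(n), index=samples), 0.0, seed=9)
        survivors = prognostic_screen(expr, clin, expr.feature_ids, alpha=0.05)
        # one-directional screen at alpha: survivor rate ~ alpha/2
        assert len(survivors) / n_genes < 0.07

    def test_gene_absent_from_validation_excluded(self):
        expr, clin = self._expr_clinical()
        v_expr = OmicsMatrix(
            expr.values[1:], expr.feature_ids[1:], expr.sample_ids, "expression_log"
        )
        validated = prognostic_screen(
            expr,
            clin,
            ["g0"],
            alpha=0.01,
            validation_cohorts=[(v_expr, clin)],
        )
        assert validated == []

    def test_validation_keeps_consistent_gene(self):
        expr, clin = self._expr_clinical()
        validated = prognostic_screen(
            expr, clin, ["g0"], alpha=0.01, validation_cohorts=[(expr, clin)]
        )
        assert validated == ["g0"]
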