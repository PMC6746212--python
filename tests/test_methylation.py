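"""SAM differential methylation, promoter/gene calls and region
enrichment."""

import numpy as np
import pandas as pd
import pytest

from moprog.data_io import OmicsMatrix, RegionAnnotation
from moprog.methylation import (
    DiffMethResult,
    annotate_probes,
    call_dm_genes,
    region_enrichment,
    region_means,
    sam_test,
)


def _meth(values, probe_ids=None):
    values = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"cg{i:04d}" for i in range(values.shape[0])]
    return OmicsMatrix(
        values,
        probe_ids,
        [f"s{j}" for j in range(values.shape[1])],
        "methylation_beta",
    )


def _result(probe_ids, calls, fold=None):
    n = len(probe_ids)
    return DiffMethResult(
        pd.DataFrame(
            {
                "probe_id": probe_ids,
                "fold_change": fold if fold is not None else np.ones(n),
                "d_statistic": np.zeros(n),
                "q_value": np.where(np.asarray(calls) == "ns", 1.0, 0.001),
                "call": calls,
            }
        )
    )


def _annotation(probe_positions, intervals=None, tss=None):
    intervals = (
        intervals
        if intervals is not None
        else pd.DataFrame(columns=["chrom", "start", "end", "region_class"])
    )
    tss = (
        tss
        if tss is not None
        else pd.DataFrame(columns=["gene", "chrom", "strand", "tss_position"])
    )
    return RegionAnnotation(intervals, tss, probe_positions)


class TestSamTest:
    def _groups(self, n_a, n_b):
        return [f"s{j}" for j in range(n_a)], [f"s{j}" for j in range(n_a, n_a + n_b)]

    def test_null_matrix_rarely_called(self, rng):
        beta = rng.beta(2, 3, size=(1500, 40))
        m = _meth(beta)
        a, b = self._groups(20, 20)
        res = sam_test(m, a, b, n_permutations=100, seed=1)
        assert (res.table["q_value"] < 0.01).mean() <= 0.01

    def test_planted_shift_detected(self, rng):
        beta = rng.beta(2, 3, size=(400, 40))
        beta[0, :20] = rng.beta(16, 4, size=20)  # ~0.8 in group a
        beta[0, 20:] = rng.beta(4, 16, size=20)  # ~0.2 in group b
        m = _meth(np.clip(beta, 0, 1))
        a, b = self._groups(20, 20)
        res = sam_test(m, a, b, n_permutations=100, seed=1)
        row = res.table.iloc[0]
        assert row["q_value"] < 0.01
        assert row["call"] == "hypo"
        assert abs(res.table["d_statistic"]).idxmax() == 0

    def test_call_rule_matches_thresholds(self, rng):
        beta = rng.beta(2, 2, size=(300, 24))
        m = _meth(beta)
        a, b = self._groups(12, 12)
        res = sam_test(m, a, b, n_permutations=50, seed=2)
        t = res.table
        expect = np.where(
            (t["fold_change"] > 1.25) & (t["q_value"] < 0.01),
            "hyper",
            np.where((t["fold_change"] < 0.8) & (t["q_value"] < 0.01), "hypo", "ns"),
        )
        assert list(t["call"]) == list(expect)
        assert (t["call"].isin(["hyper", "hypo", "ns"])).all()

    def test_q_monotone_in_abs_d(self, rng):
        beta = rng.beta(2, 2, size=(200, 20))
        m = _meth(beta)
        a, b = self._groups(10, 10)
        res = sam_test(m, a, b, n_permutations=60, seed=3)
        t = res.table.assign(abs_d=lambda x: x["d_statistic"].abs()).sort_values(
            "abs_d", ascending=False
        )
        assert np.all(np.diff(t["q_value"].to_numpy()) >= -1e-12)

    def test_deterministic_given_seed(self, rng):
        beta = rng.beta(2, 2, size=(100, 12))
        m = _meth(beta)
        a, b = self._groups(6, 6)
        r1 = sam_test(m, a, b, n_permutations=40, seed=7)
        r2 = sam_test(m, a, b, n_permutations=40, seed=7)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_small_group_rejected(self, rng):
        m = _meth(rng.beta(2, 2, size=(10, 3)))
        with pytest.raises(ValueError):
            sam_test(m, ["s0"], ["s1", "s2"])


class TestAnnotateProbes:
    def _regions(self):
        intervals = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [5000, 5100],
                "end": [5200, 5300],
                "region_class": ["exon", "enhancer"],
            }
        )
        tss = pd.DataFrame(
            {"gene": ["G1"], "chrom": ["chr1"], "strand": ["+"], "tss_position": [10000]}
        )
        probes = pd.DataFrame(
            {
                "probe_id": ["p_up", "p_low_edge", "p_high_edge", "p_multi", "p_none", "p_chr9"],
                "chrom": ["chr1", "chr1", "chr1", "chr1", "chr1", "chr9"],
                "position": [9900, 8500, 11500, 5150, 300, 5],
            }
        )
        return RegionAnnotation(intervals, tss, probes)

    def test_promoter_window_and_boundaries(self):
        classes = annotate_probes(self._regions())
        assert classes["p_up"] == {"promoter"}  # tss - 100
        assert classes["p_low_edge"] == {"promoter"}  # tss - 1500, included
        assert classes["p_high_edge"] == {"none"}  # tss + 1500, excluded
        assert classes["p_multi"] == {"exon", "enhancer"}
        assert classes["p_none"] == {"none"}
        assert classes["p_chr9"] == {"none"}


class TestCallDMGenes:
    def _annotation(self):
        tss = pd.DataFrame(
            {
                "gene": ["HYPO1", "MIXED", "QUIET"],
                "chrom": ["chr1"] * 3,
                "strand": ["+"] * 3,
                "tss_position": [10_000, 50_000, 90_000],
            }
        )
        probes = pd.DataFrame(
            {
                "probe_id": ["a", "b", "c", "d"],
                "chrom": ["chr1"] * 4,
                "position": [10_100, 50_100, 50_200, 90_100],
            }
        )
        return _annotation(probes, tss=tss)

    def test_gene_calls_and_mixed_exclusion(self):
        result = _result(["a", "b", "c", "d"], ["hypo", "hyper", "hypo", "ns"])
        calls = call_dm_genes(result, self._annotation())
        table = dict(zip(calls["gene"], calls["call"]))
        assert table == {"HYPO1": "hypo"}  # MIXED excluded, QUIET absent


class TestRegionMeans:
    def test_identical_groups_not_significant(self, small_bundle):
        bundle = small_bundle
        # relabel samples at random: group structure destroyed
        rng = np.random.default_rng(0)
        fake = pd.Series(
            rng.permutation(np.repeat(["x", "y"], len(bundle.groups) // 2 + 1))[
                : len(bundle.groups)
            ],
            index=bundle.groups.index,
        )
        summary = region_means(bundle.methylation, fake, bundle.regions)
        assert (summary.tests["p"] > 0.01).mean() > 0.8
        assert ((summary.means >= 0) & (summary.means <= 1)).all().all()

    def test_planted_hypomethylation_lowest_everywhere(self, small_bundle):
        bundle = small_bundle
        summary = region_means(bundle.methylation, bundle.groups, bundle.regions)
        for cls, row in summary.means.iterrows():
            assert row["better"] < row["intermediate"] < row["poorer"], cls


class TestRegionEnrichment:
    def _uniform_annotation(self, n=400):
        # half the probes sit in exons, half nowhere
        probes = pd.DataFrame(
            {
                "probe_id": [f"cg{i:04d}" for i in range(n)],
                "chrom": ["chr1"] * n,
                "position": [100 + 10 * i for i in range(n)],
            }
        )
        intervals = pd.DataFrame(
            {
                "chrom": ["chr1"],
                "start": [0],
                "end": [100 + 10 * (n // 2)],
                "region_class": ["exon"],
            }
        )
        return _annotation(probes, intervals=intervals)

    def test_uniform_calls_near_unit_odds(self, rng):
        n = 400
        ann = self._uniform_annotation(n)
        calls = np.where(rng.random(n) < 0.25, "hypo", "ns")
        res = region_enrichment(_result([f"cg{i:04d}" for i in range(n)], calls), ann, "hypo")
        row = res.enrichment.set_index("region_class").loc["exon"]
        assert 0.6 < row["odds_ratio"] < 1.67
        assert row["p_adjusted"] > 0.001

    def test_planted_concentration_enriched(self):
        n = 400
        ann = self._uniform_annotation(n)
        # hypo calls only among in-class probes
        calls = ["hypo" if i < 80 else "ns" for i in range(n)]
        res = region_enrichment(_result([f"cg{i:04d}" for i in range(n)], calls), ann, "hypo")
        row = res.enrichment.set_index("region_class").loc["exon"]
        assert row["odds_ratio"] > 1.0
        assert row["p_adjusted"] <= 0.001

    def test_empty_call_set_all_null(self):
        n = 50
        ann = self._uniform_annotation(n)
        res = region_enrichment(
            _result([f"cg{i:04d}" for i in range(n)], ["ns"] * n), ann, "hypo"
        )
        assert (res.enrichment["p"] == 1.0).all()

    def test_background_equal_to_call_set_unit_odds(self):
        n = 60
        ann = self._uniform_annotation(n)
        res = region_enrichment(
            _result([f"cg{i:04d}" for i in range(n)], ["hypo"] * n), ann, "hypo"
        )
        assert res.enrichment["odds_ratio"].to_numpy() == pytest.approx(1.0)
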