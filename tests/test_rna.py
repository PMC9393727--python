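"""Quantification, replicate QC and the RNA differential test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dualomics.config import OX_RESPONSE, WT_RESPONSE, SampleSheet
from dualomics.rna import (bh_adjust, cpm, de_test_rna, fpkm,
                           min_replicate_correlation, replicate_correlation)


def _sheet(reps=3):
    return SampleSheet.design(reps)


class TestFpkm:
    def test_formula_arithmetic(self):
        counts = pd.DataFrame({"s1": [10]}, index=["g1"])
        lengths = pd.Series([1000], index=["g1"])
        totals = pd.Series([1_000_000], index=["s1"])
        out = fpkm(counts, lengths, totals)
        assert out.loc["g1", "s1"] == pytest.approx(10.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 100, (20, 4)),
                              index=[f"g{i}" for i in range(20)],
                              columns=list("abcd"))
        lengths = pd.Series(rng.integers(200, 2000, 20), index=counts.index)
        totals = counts.sum(axis=0)
        base = fpkm(counts, lengths, totals)
        scaled = fpkm(counts * 7, lengths, totals * 7)
        pd.testing.assert_frame_equal(base, scaled)

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(0, 500, (50, 6)),
                              index=[f"g{i}" for i in range(50)],
                              columns=[f"s{j}" for j in range(6)])
        lengths = pd.Series(rng.integers(300, 5000, 50), index=counts.index)
        totals = pd.Series(rng.integers(500_000, 2_000_000, 6), index=counts.columns)
        out = fpkm(counts, lengths, totals)
        for g in counts.index:
            for s in counts.columns:
                expected = counts.loc[g, s] * 1e9 / (lengths[g] * totals[s])
                assert out.loc[g, s] == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("bad", ["length", "total"])
    def test_rejects_nonpositive(self, bad):
        counts = pd.DataFrame({"s1": [1]}, index=["g1"])
        lengths = pd.Series([0 if bad == "length" else 100], index=["g1"])
        totals = pd.Series([0 if bad == "total" else 1000], index=["s1"])
        with pytest.raises(ValueError):
            fpkm(counts, lengths, totals)


class TestReplicateCorrelation:
    def test_identical_replicates_give_one(self):
        sheet = _sheet(3)
        rng = np.random.default_rng(2)
        col = rng.random(30)
        matrix = pd.DataFrame({s: col for s in sheet.samples})
        pairs = replicate_correlation(matrix, sheet)
        assert np.allclose(pairs["r"], 1.0)
        assert not pairs["below_threshold"].any()

    def test_centered_negation_gives_minus_one(self):
        sheet = _sheet(2)
        rng = np.random.default_rng(3)
        x = rng.random(20) - 0.5
        matrix = pd.DataFrame({s: (x if s.endswith("r1") else -x)
                               for s in sheet.samples})
        pairs = replicate_correlation(matrix, sheet)
        assert np.allclose(pairs["r"], -1.0)

    def test_constant_column_reported_undefined(self):
        sheet = _sheet(2)
        matrix = pd.DataFrame({s: np.ones(10) for s in sheet.samples})
        matrix[sheet.samples[1]] = np.arange(10)
        pairs = replicate_correlation(matrix, sheet)
        undef = pairs[~pairs["defined"]]
        assert len(undef) >= 1
        # group minima are taken over defined pairs only, no NaN leakage
        minima = min_replicate_correlation(pairs)
        assert minima["min_r"].notna().all() or minima.empty

    def test_matches_direct_pearson(self, default_dataset):
        sheet = default_dataset.samples
        matrix = np.log2(cpm(default_dataset.rna) + 1)
        pairs = replicate_correlation(matrix, sheet)
        for row in pairs.itertuples():
            x = matrix[row.sample_a]
            y = matrix[row.sample_b]
            direct = np.corrcoef(x, y)[0, 1]
            assert row.r == pytest.approx(direct, abs=1e-12)


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_against_independent_step_up_oracle(self):
        rng = np.random.default_rng(4)
        p = rng.random(57)
        # independent BH: sort, p*(m/rank), enforce monotone from the top
        order = np.argsort(p)
        m = len(p)
        scaled = p[order] * m / np.arange(1, m + 1)
        monotone = np.minimum.accumulate(scaled[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.clip(monotone, 0, 1)
        assert np.allclose(bh_adjust(p), expected)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_order_preserving_and_bounded(self, p):
        adj = bh_adjust(p)
        assert adj.min() >= min(p) - 1e-15
        assert (adj >= 0).all() and (adj <= 1).all()
        p_arr = np.asarray(p)
        for i in range(len(p)):
            for j in range(len(p)):
                if p_arr[i] <= p_arr[j]:
                    assert adj[i] <= adj[j] + 1e-15

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestDeTestRna:
    def test_identical_groups_are_ns(self):
        sheet = _sheet(3)
        rng = np.random.default_rng(5)
        col = rng.integers(1, 1000, 50)
        counts = pd.DataFrame({s: col for s in sheet.samples},
                              index=[f"g{i}" for i in range(50)])
        res = de_test_rna(counts, sheet, WT_RESPONSE)
        assert np.allclose(res["log2fc"], 0.0)
        assert (res["status"] == "ns").all()

    def test_threshold_rule_is_strict_on_both_axes(self):
        # log2FC above 1 with small FDR -> up; below 1 -> ns regardless of FDR
        from dualomics import rna
        log2fc = np.array([1.2, 0.9])
        fdr = np.array([0.01, 0.001])
        status = np.where((log2fc > 1) & (fdr < 0.05), "up", "ns")
        assert list(status) == ["up", "ns"]
        # and the pipeline's own rule agrees on constructed data
        res = pd.DataFrame({"log2fc": log2fc, "fdr": fdr})
        up = (res["log2fc"] > 1) & (res["fdr"] < 0.05)
        assert up.tolist() == [True, False]

    def test_pvalues_match_per_gene_welch(self, default_dataset):
        sheet = default_dataset.samples
        counts = default_dataset.rna
        res = de_test_rna(counts, sheet, WT_RESPONSE)
        norm = np.log2(cpm(counts) + 1)
        b = norm[sheet.group("WT", "24h")]
        a = norm[sheet.group("WT", "0h")]
        for g in counts.index[:200]:
            p = stats.ttest_ind(b.loc[g], a.loc[g], equal_var=False).pvalue
            assert res.loc[g, "p"] == pytest.approx(p, abs=1e-12)

    def test_contrast_flip_negates_log2fc_preserves_p(self, default_dataset):
        sheet = default_dataset.samples
        counts = default_dataset.rna.iloc[:300]
        fwd = de_test_rna(counts, sheet, WT_RESPONSE)
        rev = de_test_rna(counts, sheet, WT_RESPONSE.flipped())
        assert np.allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-10)
        assert np.allclose(fwd["p"], rev["p"], atol=1e-12)
        up_fwd = set(fwd.index[fwd["status"] == "up"])
        down_rev = set(rev.index[rev["status"] == "down"])
        assert up_fwd == down_rev

    def test_status_partition_exhaustive_exclusive(self, fitted):
        for res in fitted.rna_de.values():
            assert set(res["status"]) <= {"up", "down", "ns"}
            assert res["status"].notna().all()

    def test_rejects_single_replicate_group(self):
        sheet = SampleSheet.design(3)
        dropped = sheet.frame[sheet.frame["sample"] != "WT_24h_r1"]
        dropped = dropped[dropped["sample"] != "WT_24h_r2"]
        small = SampleSheet(dropped)
        counts = pd.DataFrame(
            np.ones((5, len(small))), index=[f"g{i}" for i in range(5)],
            columns=small.samples)
        with pytest.raises(ValueError, match=">= 2 samples"):
            de_test_rna(counts, small, WT_RESPONSE)
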