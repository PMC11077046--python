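"""Table unification, flank/metagene extraction, row-wise tests, peak calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import txpileup as tp


def table_for(genes_lengths, **value_cols):
    rows = {"chrom": [], "gencoor": [], "strand": [], "gene": [], "txcoor": []}
    g0 = 1
    for g, L in genes_lengths:
        rows["chrom"] += ["chr1"] * L
        rows["gencoor"] += list(range(g0, g0 + L))
        rows["strand"] += ["+"] * L
        rows["gene"] += [g] * L
        rows["txcoor"] += list(range(1, L + 1))
        g0 += L
    t = pd.DataFrame(rows)
    for k, v in value_cols.items():
        t[k] = v
    return t


class TestUnify:
    def test_intersection_and_identity(self):
        a = table_for([("A", 3), ("B", 4)], cov=range(7))
        b = table_for([("B", 4), ("C", 2)], cov=range(6))
        ua, ub = tp.unify_tables([a, b])
        assert list(ua["gene"].unique()) == ["B"] == list(ub["gene"].unique())
        assert list(ua["txcoor"]) == list(ub["txcoor"])
        (same,) = tp.unify_tables([a])
        pd.testing.assert_frame_equal(same, a)

    def test_length_mismatch_raises(self):
        a = table_for([("A", 3)], cov=range(3))
        b = table_for([("A", 4)], cov=range(4))
        with pytest.raises(ValueError, match="differing lengths"):
            tp.unify_tables([a, b])

    def test_empty_intersection_warns(self):
        a = table_for([("A", 3)], cov=range(3))
        b = table_for([("B", 3)], cov=range(3))
        with pytest.warns(UserWarning, match="empty"):
            ua, ub = tp.unify_tables([a, b])
        assert len(ua) == 0 and len(ub) == 0


class TestFlanks:
    def test_edge_padding_and_interior_window(self):
        t = table_for([("g", 10)], v=[float(i) for i in range(1, 11)])
        t["hit"] = [False, True, False, False, True, False, False, False, False, False]
        fm = tp.get_flanks_from_logical(t, "hit", "v", w=2)
        assert fm.shape == (2, 5)
        row1 = fm.iloc[0].to_numpy()
        assert np.isnan(row1[0]) and list(row1[1:]) == [1.0, 2.0, 3.0, 4.0]
        assert list(fm.iloc[1]) == [3.0, 4.0, 5.0, 6.0, 7.0]

    def test_no_true_positions_gives_empty(self):
        t = table_for([("g", 5)], v=range(5))
        t["hit"] = False
        assert len(tp.get_flanks_from_logical(t, "hit", "v", w=2)) == 0


class TestMetagene:
    def coding_table(self):
        m = tp.TranscriptModel("g", "chr1", "+", ((0, 100),), (20, 80))
        t = table_for([("g", 100)], v=[float(i) for i in range(1, 101)])
        tp.add_gene_region(t, [m])
        return t

    def test_equal_width_bin_means(self):
        mm = tp.get_metagene_regions(self.coding_table(), "v", bins=(2, 2, 2))
        assert list(mm.loc["g"]) == [5.5, 15.5, 35.5, 65.5, 85.5, 95.5]

    def test_short_region_yields_missing_bins(self):
        m = tp.TranscriptModel("g", "chr1", "+", ((0, 10),), (1, 9))
        t = table_for([("g", 10)], v=[1.0] * 10)
        tp.add_gene_region(t, [m])
        mm = tp.get_metagene_regions(t, "v", bins=(2, 2, 2))
        row = mm.loc["g"]
        assert row["utr5_1"] == 1.0 and np.isnan(row["utr5_2"])

    def test_site_counts_with_sum_aggregate(self):
        t = self.coding_table()
        t["putative_site"] = t["txcoor"].isin([5, 50, 51, 90])
        mm = tp.get_metagene_regions(t, "putative_site", bins=(1, 1, 1), aggregate="sum")
        assert list(mm.loc["g"]) == [1.0, 2.0, 1.0]

    def test_noncoding_gene_skipped(self):
        t = self.coding_table()
        nc = table_for([("nc", 10)], v=[0.0] * 10)
        nc["region"] = None
        mm = tp.get_metagene_regions(pd.concat([t, nc], ignore_index=True), "v",
                                     bins=(2, 2, 2))
        assert list(mm.index) == ["g"]


class TestPfm:
    def test_counts_by_offset(self):
        t = table_for([("a", 3), ("b", 3)])
        t["refSeq"] = list("ACG") + list("ACT")
        pfm = tp.pfm_from_sites(t, [("a", 2), ("b", 2)], w=1)
        assert pfm.loc["A", -1] == 2
        assert pfm.loc["C", 0] == 2
        assert pfm.loc["G", 1] == 1 and pfm.loc["T", 1] == 1

    def test_single_site_one_hot(self):
        t = table_for([("a", 3)])
        t["refSeq"] = list("ACG")
        pfm = tp.pfm_from_sites(t, [("a", 2)], w=1)
        assert (pfm.sum(axis=0) == 1).all()

    def test_out_of_range_offsets_uncounted(self):
        t = table_for([("a", 3)])
        t["refSeq"] = list("ACG")
        pfm = tp.pfm_from_sites(t, [("a", 1)], w=1)
        assert pfm[-1].sum() == 0 and pfm[0].sum() == 1


class TestRowTtests:
    def make_groups(self, vals1, vals2, n_rows=1):
        g1 = [table_for([("g", n_rows)], x=[v] * n_rows) for v in vals1]
        g2 = [table_for([("g", n_rows)], x=[v] * n_rows) for v in vals2]
        return g1, g2

    def test_textbook_pooled_example(self):
        g1, g2 = self.make_groups([0.8, 0.7, 0.9], [0.1, 0.2, 0.0])
        res = tp.row_ttests(g1, g2, "x")
        assert res["mean_diff"][0] == pytest.approx(0.7)
        assert res["statistic"][0] == pytest.approx(8.5732, abs=1e-4)
        assert res["df"][0] == 4

    def test_identical_groups(self):
        g1, g2 = self.make_groups([0.5, 0.6], [0.5, 0.6])
        res = tp.row_ttests(g1, g2, "x")
        assert res["statistic"][0] == 0 and res["p_value"][0] == 1

    def test_zero_variance_nonzero_diff(self):
        g1, g2 = self.make_groups([0.9, 0.9], [0.1, 0.1])
        res = tp.row_ttests(g1, g2, "x")
        assert np.isinf(res["statistic"][0]) and res["p_value"][0] == 0

    def test_group_too_small_raises(self):
        g1, g2 = self.make_groups([0.5], [0.1, 0.2])
        with pytest.raises(ValueError):
            tp.row_ttests(g1, g2, "x")

    @pytest.mark.parametrize("variance,equal_var", [("pooled", True), ("welch", False)])
    def test_agrees_with_scipy_on_random_rows(self, variance, equal_var):
        rng = np.random.default_rng(7)
        n = 1000
        x1 = rng.normal(0, 1, size=(3, n))
        x2 = rng.normal(0.2, 1.5, size=(4, n))
        g1 = [table_for([("g", n)], x=row) for row in x1]
        g2 = [table_for([("g", n)], x=row) for row in x2]
        res = tp.row_ttests(g1, g2, "x", variance=variance)
        oracle = sps.ttest_ind(x1, x2, axis=0, equal_var=equal_var)
        np.testing.assert_allclose(res["statistic"], oracle.statistic, atol=1e-10)
        np.testing.assert_allclose(res["p_value"], oracle.pvalue, atol=1e-10)

    def test_missing_replicate_value_blanks_row(self):
        g1, g2 = self.make_groups([0.8, 0.7], [0.1, 0.2], n_rows=2)
        g1[0].loc[1, "x"] = np.nan
        res = tp.row_ttests(g1, g2, "x")
        assert not np.isnan(res["p_value"][0]) and np.isnan(res["p_value"][1])


def lrt_oracle(k1, n1, k2, n2):
    """Brute-force binomial log-likelihood ratio via scipy pmfs."""
    def ll(k, n, p):
        p = min(max(p, 1e-12), 1 - 1e-12)
        return sps.binom.logpmf(k, n, p)
    p1, p2, p0 = k1 / n1, k2 / n2, (k1 + k2) / (n1 + n2)
    return 2 * (ll(k1, n1, p1) + ll(k2, n2, p2) - ll(k1, n1, p0) - ll(k2, n2, p0))


class TestBinomialLrt:
    def tables(self, k1, n1, k2, n2):
        g1 = [table_for([("g", 1)], k=[k1 / 2], n=[n1 / 2]) for _ in range(2)]
        g2 = [table_for([("g", 1)], k=[k2 / 2], n=[n2 / 2]) for _ in range(2)]
        return g1, g2

    def test_frozen_example(self):
        g1, g2 = self.tables(80, 100, 5, 100)
        res = tp.row_binomial_lrt(g1, g2, "k", "n")
        assert res["statistic"][0] == pytest.approx(132.958, abs=0.01)

    def test_equal_proportions_zero(self):
        g1, g2 = self.tables(30, 100, 30, 100)
        assert tp.row_binomial_lrt(g1, g2, "k", "n")["statistic"][0] == 0

    def test_boundary_proportions_finite(self):
        g1, g2 = self.tables(1000, 1000, 0, 1000)
        stat = tp.row_binomial_lrt(g1, g2, "k", "n")["statistic"][0]
        assert np.isfinite(stat) and stat > 1000

    def test_agrees_with_logpmf_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            n1, n2 = int(rng.integers(2, 300)), int(rng.integers(2, 300))
            k1, k2 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
            g1, g2 = self.tables(k1, n1, k2, n2)
            stat = tp.row_binomial_lrt(g1, g2, "k", "n")["statistic"][0]
            assert stat >= 0
            assert stat == pytest.approx(lrt_oracle(k1, n1, k2, n2), abs=1e-8)

    def test_zero_trials_missing(self):
        g1, g2 = self.tables(0, 0, 5, 100)
        assert np.isnan(tp.row_binomial_lrt(g1, g2, "k", "n")["p_value"][0])


class TestPeaks:
    def test_single_peak(self):
        t = table_for([("g", 8)], cov=[0, 1, 5, 9, 5, 1, 0, 0])
        res = tp.call_peaks(t, smooth_w=1, min_cov=2)
        assert len(res) == 1
        assert res["txcoor"][0] == 4 and res["height"][0] == 9

    def test_flat_coverage_no_peaks(self):
        t = table_for([("g", 10)], cov=[3] * 10)
        assert len(tp.call_peaks(t, smooth_w=1, min_cov=1)) == 0

    def test_merge_keeps_highest_leftmost(self):
        t = table_for([("g", 11)], cov=[0, 5, 1, 7, 1, 5, 0, 0, 0, 4, 0])
        res = tp.call_peaks(t, smooth_w=1, min_cov=2, min_gap=4)
        assert list(res["txcoor"]) == [4, 10]

    def test_bimodal_vs_bridged_coverage(self):
        """Two single-end mates make two peaks; the bridged fragment makes one."""
        m = tp.TranscriptModel("g", "chr1", "+", ((0, 200),))
        bridged = {"g": [tp.TxFragment("g", 20, 169) for _ in range(30)]}
        single = {"g": [tp.TxFragment("g", 20, 59) for _ in range(30)]
                  + [tp.TxFragment("g", 130, 169) for _ in range(30)]}
        jitter = np.random.default_rng(3).integers(-5, 6, size=30)
        bridged["g"] = [tp.TxFragment("g", 20 + int(j), 169 + int(j)) for j in jitter]
        single["g"] = [tp.TxFragment("g", 20 + int(j), 59 + int(j)) for j in jitter] + [
            tp.TxFragment("g", 130 + int(j), 169 + int(j)) for j in jitter]
        tb = tp.make_table(bridged, [m], mode="cov")
        ts = tp.make_table(single, [m], mode="cov")
        pb = tp.call_peaks(tb, smooth_w=11, min_cov=5, min_gap=30)
        ps = tp.call_peaks(ts, smooth_w=11, min_cov=5, min_gap=30)
        assert len(pb) == 1 and len(ps) == 2


class TestSampleGenes:
    def test_deterministic_subsample(self):
        t = table_for([(f"g{i}", 3) for i in range(10)], cov=range(30))
        a = tp.sample_genes(t, 3, seed=5)
        b = tp.sample_genes(t, 3, seed=5)
        pd.testing.assert_frame_equal(a, b)
        assert a["gene"].nunique() == 3

    def test_full_sample_keeps_everything(self):
        t = table_for([("a", 2), ("b", 2)], cov=range(4))
        pd.testing.assert_frame_equal(tp.sample_genes(t, 2, seed=1), t)

    def test_zero_and_overflow(self):
        t = table_for([("a", 2)], cov=range(2))
        assert len(tp.sample_genes(t, 0, seed=1)) == 0
        with pytest.raises(ValueError):
            tp.sample_genes(t, 5, seed=1)
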