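"""Interval algebra, exact tests, motif screening and network construction."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from ependymics.regulatory import (
    DAConfig, MotifTestConfig, build_tf_network, differential_accessibility,
    enhancer_concordance, filter_peak_widths, fisher_exact_two_sided,
    gene_activity, joint_emt_screen, merge_peak_sets, motif_deviation_test,
)


def bed(*intervals, chrom="chr1"):
    return pd.DataFrame([(chrom, s, e) for s, e in intervals],
                        columns=["chrom", "start", "end"])


def rational_fisher_oracle(a, b, c, d):
    """Exact two-sided Fisher p by integer hypergeometric enumeration."""
    n1, n2, k = a + b, c + d, a + c
    denom = math.comb(n1 + n2, k)
    obs = math.comb(n1, a) * math.comb(n2, c)
    tot = sum(w for x in range(max(0, k - n2), min(k, n1) + 1)
              if (w := math.comb(n1, x) * math.comb(n2, k - x)) <= obs)
    return tot / denom


class TestMergePeaks:
    def test_overlapping_intervals_merge(self):
        out = merge_peak_sets([bed((10, 20)), bed((15, 30))])
        assert list(zip(out["start"], out["end"])) == [(10, 30)]

    def test_abutting_halfopen_intervals_stay_separate(self):
        out = merge_peak_sets([bed((10, 20)), bed((20, 30))])
        assert list(zip(out["start"], out["end"])) == [(10, 20), (20, 30)]

    def test_staggered_transitive_merge(self):
        out = merge_peak_sets([bed((0, 5)), bed((4, 9)), bed((8, 12))])
        assert list(zip(out["start"], out["end"])) == [(0, 12)]

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(3)
        sets = [bed(*[(s, s + rng.integers(1, 50)) for s in
                      rng.integers(0, 500, 20)]) for _ in range(3)]
        out1 = merge_peak_sets(sets)
        out2 = merge_peak_sets(sets[::-1])
        pd.testing.assert_frame_equal(
            out1[["start", "end"]], out2[["start", "end"]])
        again = merge_peak_sets([out1])
        pd.testing.assert_frame_equal(
            out1[["start", "end"]], again[["start", "end"]])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.tuples(st.integers(0, 300), st.integers(1, 40)),
                    min_size=1, max_size=25))
    def test_agrees_with_per_basepair_oracle(self, raw):
        intervals = [(s, s + w) for s, w in raw]
        covered = np.zeros(400, dtype=bool)
        for s, e in intervals:
            covered[s:e] = True
        out = merge_peak_sets([bed(*intervals)])
        from_merge = np.zeros(400, dtype=bool)
        for s, e in zip(out["start"], out["end"]):
            from_merge[s:e] = True
        assert (covered == from_merge).all()
        # disjointness under the half-open convention
        assert (out["start"].to_numpy()[1:] >= out["end"].to_numpy()[:-1]).all()

    def test_malformed_interval_reports_record_index(self):
        with pytest.raises(ValueError, match="index 1"):
            merge_peak_sets([bed((0, 5), (9, 9))])


class TestWidthFilter:
    def test_equal_widths_nothing_removed(self):
        peaks = bed((0, 100), (200, 300), (400, 500))
        assert len(filter_peak_widths(peaks)) == 3

    def test_extreme_outlier_removed_iff_beyond_cutoff(self):
        widths = [100] * 10 + [10000]
        peaks = bed(*[(i * 20000, i * 20000 + w) for i, w in enumerate(widths)])
        arr = np.array(widths, dtype=float)
        expect_removed = 10000 > arr.mean() + 3 * arr.std(ddof=1)
        out = filter_peak_widths(peaks)
        assert (len(out) == 10) == expect_removed

    def test_output_subset_order_preserved(self):
        rng = np.random.default_rng(5)
        peaks = bed(*[(s, s + rng.integers(50, 5000))
                      for s in rng.integers(0, 10**6, 30)])
        out = filter_peak_widths(peaks)
        assert list(out.index) == sorted(out.index)
        assert set(out.index) <= set(peaks.index)


class TestGeneActivity:
    loci = pd.DataFrame([{"gene": "GX", "chrom": "chr1", "start": 5000,
                          "end": 8000, "strand": "+", "tss": 5000}])

    def frags(self, *ivals):
        return pd.DataFrame([("chr1", s, e, "cell1") for s, e in ivals],
                            columns=["chrom", "start", "end", "cell"])

    def test_fragment_in_body_counted_once(self):
        act = gene_activity(self.frags((6000, 6100)), self.loci)
        assert act.loc["GX", "cell1"] == 1

    def test_fragment_spanning_body_and_promoter_counted_once(self):
        act = gene_activity(self.frags((4900, 5100)), self.loci)
        assert act.loc["GX", "cell1"] == 1

    def test_halfopen_boundaries(self):
        # promoter extends the scored region to [3000, 8000)
        act = gene_activity(self.frags((2999, 3001), (2000, 3000), (8000, 8100)),
                            self.loci)
        assert act.loc["GX", "cell1"] == 1

    def test_minus_strand_promoter_downstream_of_end(self):
        loci = pd.DataFrame([{"gene": "GY", "chrom": "chr1", "start": 5000,
                              "end": 8000, "strand": "-", "tss": 8000}])
        act = gene_activity(self.frags((8500, 8600), (10001, 10100)), loci)
        assert act.loc["GY", "cell1"] == 1  # [5000, 10000) scored

    def test_missing_strand_rejected(self):
        loci = self.loci.assign(strand=".")
        with pytest.raises(ValueError, match="strand"):
            gene_activity(self.frags((6000, 6100)), loci)


class TestFisherExact:
    def test_worked_example_is_exact_fraction(self):
        assert fisher_exact_two_sided(8, 2, 2, 8) == \
            pytest.approx(4252 / 184756, abs=1e-12)

    def test_balanced_table_gives_one(self):
        assert fisher_exact_two_sided(5, 5, 5, 5) == pytest.approx(1.0)

    def test_matches_rational_oracle_on_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 11, 4)
            assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(
                rational_fisher_oracle(a, b, c, d), abs=1e-10)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 40, 4)
            assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(
                scipy_fisher([[a, b], [c, d]])[1], abs=1e-9)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(-1, 2, 3, 4)


class TestDifferentialAccessibility:
    def test_peak_below_30pct_excluded_and_planted_recovered(
            self, accessibility_cohort):
        matrices, labels, _, truth = accessibility_cohort
        da = differential_accessibility(matrices, labels, "P2")
        planted = da.index.intersection(truth.da_peaks["P2"])
        assert (da.loc[planted, "fdr"] < 0.1).mean() >= 0.9
        assert (da.loc[planted, "direction"] == "up").all()

    def test_30pct_filter_semantics(self):
        cells = [f"c{i}" for i in range(100)]
        labels = pd.Series(["T"] * 10 + ["rest"] * 90, index=cells)
        mat = pd.DataFrame(0, index=["pk_low", "pk_hi"], columns=cells)
        mat.loc["pk_low", cells[:2]] = 1    # 20% of population cells
        mat.loc["pk_hi", cells[:8]] = 1     # 80%
        labels2 = labels.copy()
        matrices = {"s1": mat, "s2": mat}
        da = differential_accessibility(
            {"s1": mat, "s2": mat}, {"s1": labels, "s2": labels2}, "T")
        assert "pk_low" not in da.index
        assert "pk_hi" in da.index

    def test_population_absent_everywhere_raises(self, accessibility_cohort):
        matrices, labels, _, _ = accessibility_cohort
        with pytest.raises(ValueError, match="absent"):
            differential_accessibility(matrices, labels, "P99")


class TestEnhancerConcordance:
    def _enh(self, genes):
        return pd.DataFrame({"chrom": "chr1",
                             "start": [i * 1000 for i in range(len(genes))],
                             "end": [i * 1000 + 100 for i in range(len(genes))],
                             "gene": genes})

    def test_worked_overlap_example(self):
        universe = {f"G{i}" for i in range(20)}
        enh = self._enh([f"G{i}" for i in range(10)])
        da = bed(*[(i * 1000, i * 1000 + 50) for i in range(10)])
        degs = {f"G{i}" for i in range(8)} | {"G15", "G16"}
        counts, p = enhancer_concordance(da, enh, degs, universe)
        assert counts["both"] == 8
        assert p == pytest.approx(4252 / 184756, abs=1e-10)

    def test_overlap_at_expectation_not_significant(self):
        universe = {f"G{i}" for i in range(100)}
        enh = self._enh([f"G{i}" for i in range(10)])
        da = bed(*[(i * 1000, i * 1000 + 50) for i in range(10)])
        degs = {"G0"} | {f"G{i}" for i in range(50, 59)}
        counts, p = enhancer_concordance(da, enh, degs, universe)
        assert counts["both"] == 1
        assert p > 0.5

    def test_empty_da_set(self):
        universe = {f"G{i}" for i in range(10)}
        counts, p = enhancer_concordance(
            bed(), self._enh(["G0"]), {"G1"}, universe)
        assert counts["both"] == 0 and p == 1.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            enhancer_concordance(bed(), self._enh(["G0"]), set(), set())


class TestMotifDeviation:
    def _cohort(self, shift=0.0, n_in=50, n_out=200, seed=0):
        rng = np.random.default_rng(seed)
        scores = {}
        labels = {}
        for s in ("s1", "s2"):
            cells = [f"{s}c{i}" for i in range(n_in + n_out)]
            lab = pd.Series(["T"] * n_in + ["rest"] * n_out, index=cells)
            x = rng.normal(0, 1, (3, len(cells)))
            x[0, :n_in] += shift
            scores[s] = pd.DataFrame(x, index=["TFa", "TFb", "TFc"],
                                     columns=cells)
            labels[s] = lab
        return scores, labels

    def test_identical_distributions_not_significant(self):
        scores, labels = self._cohort(shift=0.0)
        out = motif_deviation_test(scores, labels, "T")
        assert out.loc["TFb", "combined_p"] > 0.05
        assert abs(out.loc["TFb", "delta_z"]) < 0.5

    def test_two_sd_shift_detected(self):
        scores, labels = self._cohort(shift=2.0)
        out = motif_deviation_test(scores, labels, "T")
        assert out.loc["TFa", "combined_p"] < 1e-6
        assert out.loc["TFa", "flagged"]

    def test_delta_z_display_rule(self):
        # significant but small shift: FDR passes, delta_z < 1 -> not flagged
        scores, labels = self._cohort(shift=0.4, n_in=400, n_out=400, seed=3)
        out = motif_deviation_test(scores, labels, "T")
        assert out.loc["TFa", "fdr"] < 0.01
        assert out.loc["TFa", "delta_z"] < 1
        assert not out.loc["TFa", "flagged"]


class TestJointScreen:
    expr = pd.DataFrame(
        [[1.0, 2, 3, 4, 5, 6], [6, 5, 4, 3, 2, 1], [2, 4, 6, 1, 3, 5]],
        index=["TFup", "TFdown", "TFnoisy"],
        columns=[f"s{i}" for i in range(6)])
    abundance = pd.Series(np.arange(6.0), index=[f"s{i}" for i in range(6)])

    def test_monotone_correlations(self):
        fdr = pd.Series(0.01, index=self.expr.index)
        out = joint_emt_screen(self.expr, self.abundance, fdr)
        assert out.loc["TFup", "spearman_r"] == pytest.approx(1.0)
        assert out.loc["TFdown", "spearman_r"] == pytest.approx(-1.0)
        assert out.loc["TFup", "selected"] and out.loc["TFdown", "selected"]
        assert out.loc["TFdown", "direction"] == "negative"

    def test_and_rule_requires_both_conditions(self):
        fdr = pd.Series({"TFup": 0.5, "TFdown": 0.01, "TFnoisy": 0.01})
        out = joint_emt_screen(self.expr, self.abundance, fdr)
        assert not out.loc["TFup", "selected"]      # motif FDR fails
        assert not out.loc["TFnoisy", "selected"]   # correlation p fails
        assert out.loc["TFdown", "selected"]

    def test_too_few_paired_samples_rejected(self):
        with pytest.raises(ValueError, match="4 paired"):
            joint_emt_screen(self.expr.iloc[:, :3], self.abundance,
                             pd.Series(0.01, index=self.expr.index))


class TestNetwork:
    loci = pd.DataFrame([
        {"gene": "TFA", "chrom": "chr1", "start": 100_000, "end": 102_000,
         "strand": "+", "tss": 100_000},
        {"gene": "TFB", "chrom": "chr1", "start": 500_000, "end": 502_000,
         "strand": "-", "tss": 502_000},
    ])

    def sites(self, rows):
        return pd.DataFrame(rows, columns=["tf", "chrom", "start", "end", "p"])

    def test_no_significant_sites_no_edges(self):
        sites = self.sites([("TFA", "chr1", 499_000, 499_010, 0.2)])
        g = build_tf_network(sites, self.loci)
        assert g.number_of_edges() == 0
        assert set(g.nodes) == {"TFA", "TFB"}

    def test_window_boundary_halfopen(self):
        at_edge = self.sites([("TFA", "chr1", 490_000, 490_001, 0.04)])
        g = build_tf_network(at_edge, self.loci)
        assert g.has_edge("TFA", "TFB")
        past_edge = self.sites([("TFA", "chr1", 489_999, 490_000, 0.04)])
        g2 = build_tf_network(past_edge, self.loci)
        assert not g2.has_edge("TFA", "TFB")

    def test_self_loops_permitted(self):
        sites = self.sites([("TFA", "chr1", 101_000, 101_010, 0.01)])
        g = build_tf_network(sites, self.loci)
        assert g.has_edge("TFA", "TFA")

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            build_tf_network(self.sites([]), self.loci, window=-1)

    def test_planted_network_recovered_exactly(self, annotation):
        loci, _, sites, truth = annotation
        g = build_tf_network(sites, loci)
        edges = set(g.edges())
        planted = set(truth.planted_edges)
        assert edges == planted  # precision and recall both 1
        for a, b in planted:
            assert g.edges[a, b]["min_p"] < 0.05
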