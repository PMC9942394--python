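import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from sweepscan.sweep_caller import (
    OutlierThresholds, allele_frequency_trajectory, annotate_genes,
    call_joint_outliers, compute_thresholds, contrast_overlap,
    cross_method_concordance, empirical_quantile_threshold,
    merge_windows_to_segments, recovered_loci,
)
from sweepscan.variants_io import GeneAnnotation, PopulationMap, ValidationError
from conftest import make_table
import oracles


def window_frame(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "fst",
                                     "log2_pi_ratio"])
    df["masked"] = False
    df["n_snps"] = 50
    return df


class TestQuantileThreshold:
    def test_two_hundred_distinct_values(self):
        assert empirical_quantile_threshold(np.arange(1, 201), 0.01) == 199

    def test_minimum_one_rule(self):
        assert empirical_quantile_threshold(np.arange(50), 0.01) == 49

    def test_normal_quantile_recovered(self):
        draws = np.random.default_rng(12).standard_normal(10_000)
        thr = empirical_quantile_threshold(draws, 0.01)
        assert abs(thr - norm.ppf(0.99)) < 0.1

    def test_all_masked_is_an_error(self):
        with pytest.raises(ValidationError):
            empirical_quantile_threshold([np.nan, np.inf], 0.01)


class TestJointOutliers:
    THR = OutlierThresholds(fst_threshold=0.44,
                            pi_ratio_threshold=np.log2(2.27))

    def test_joint_requirement(self):
        df = window_frame([("c1", 0, 40_000, 0.9, 3.0),
                          ("c1", 20_000, 60_000, 0.9, 0.1),
                          ("c1", 40_000, 80_000, 0.1, 3.0)])
        out = call_joint_outliers(df, self.THR)
        assert list(out.start) == [0]

    def test_masked_windows_never_qualify(self):
        df = window_frame([("c1", 0, 40_000, 0.9, 3.0)])
        df["masked"] = True
        assert len(call_joint_outliers(df, self.THR)) == 0

    def test_constructed_exceedances_returned_exactly(self, rng):
        n = 1000
        fst = rng.uniform(0, 0.4, n)
        ratio = rng.uniform(-1, 1, n)
        chosen = rng.choice(n, 12, replace=False)
        fst[chosen] = rng.uniform(0.5, 0.9, 12)
        ratio[chosen] = rng.uniform(1.5, 4.0, 12)
        df = window_frame([("c1", i * 20_000, i * 20_000 + 40_000, f, r)
                           for i, (f, r) in enumerate(zip(fst, ratio))])
        out = call_joint_outliers(df, OutlierThresholds(0.5, 1.5))
        assert sorted(out.index_col if hasattr(out, "index_col") else
                      (out.start // 20_000)) == sorted(chosen)

    def test_thresholds_monotone(self, rng):
        df = window_frame([("c1", i * 20_000, i * 20_000 + 40_000,
                            rng.uniform(0, 1), rng.uniform(-2, 4))
                           for i in range(300)])
        base = call_joint_outliers(df, OutlierThresholds(0.5, 1.0))
        tighter = call_joint_outliers(df, OutlierThresholds(0.6, 1.5))
        assert set(tighter.start) <= set(base.start)


class TestSegmentMerging:
    def test_overlap_and_separate_chromosomes(self):
        df = window_frame([("chr1", 0, 40_000, 0.5, 2.0),
                          ("chr1", 20_000, 60_000, 0.7, 1.8),
                          ("chr2", 0, 40_000, 0.6, 2.5)])
        seg = merge_windows_to_segments(df)
        assert len(seg) == 2
        chr1 = seg[seg.chrom == "chr1"].iloc[0]
        assert (chr1.start, chr1.end, chr1.n_windows) == (0, 60_000, 2)
        assert chr1.peak_fst == 0.7 and chr1.peak_log2_pi_ratio == 2.0

    def test_single_window_identity(self):
        df = window_frame([("chr1", 40_000, 80_000, 0.5, 2.0)])
        seg = merge_windows_to_segments(df)
        assert (seg.iloc[0].start, seg.iloc[0].end) == (40_000, 80_000)

    def test_book_ended_windows_merge(self):
        df = window_frame([("chr1", 0, 40_000, 0.5, 2.0),
                          ("chr1", 40_000, 80_000, 0.6, 1.0)])
        seg = merge_windows_to_segments(df)
        assert len(seg) == 1 and seg.iloc[0].end == 80_000

    def test_segment_count_bounded_by_windows(self, rng):
        starts = np.sort(rng.choice(200, 40, replace=False)) * 20_000
        df = window_frame([("chr1", s, s + 40_000, 0.5, 2.0) for s in starts])
        seg = merge_windows_to_segments(df)
        assert len(seg) <= len(df)
        assert (seg.end - seg.start >= 40_000).all()


class TestGeneAnnotation:
    def _genes(self, rows):
        return GeneAnnotation(pd.DataFrame(
            rows, columns=["chrom", "start", "end", "strand", "gene_id",
                           "gene_name"]))

    def test_one_bp_overlap_counts(self):
        seg = pd.DataFrame([{"chrom": "c", "start": 0, "end": 60_000}])
        genes = self._genes([("c", 10_000, 20_000, "+", "gA", "gA"),
                             ("c", 59_999, 70_000, "+", "gB", "gB")])
        out, ids = annotate_genes(seg, genes)
        assert ids == {"gA", "gB"}

    def test_half_open_boundary_excluded(self):
        seg = pd.DataFrame([{"chrom": "c", "start": 0, "end": 60_000}])
        genes = self._genes([("c", 60_000, 70_000, "+", "gC", "gC")])
        _, ids = annotate_genes(seg, genes)
        assert ids == set()

    def test_matches_quadratic_oracle(self, rng):
        segs = [("c%d" % rng.integers(3), int(s), int(s) + int(rng.integers(1, 50_000)))
                for s in rng.integers(0, 10**6, 100)]
        genes = [("c%d" % rng.integers(3), int(s), int(s) + int(rng.integers(1, 30_000)),
                  f"g{i}") for i, s in enumerate(rng.integers(0, 10**6, 500))]
        seg_df = pd.DataFrame(segs, columns=["chrom", "start", "end"])
        gene_df = self._genes([(c, s, e, "+", g, g) for c, s, e, g in genes])
        out, _ = annotate_genes(seg_df, gene_df)
        expected = oracles.interval_overlaps_literal(segs, genes)
        got = [sorted(x.split(",")) if x else [] for x in out.genes]
        assert got == expected


class TestConcordanceAndOverlap:
    def test_fraction_examples(self):
        frac, inter = cross_method_concordance({"g1", "g2", "g3", "g4"},
                                               {"g2", "g3", "g5"})
        assert frac == 0.5 and inter == ["g2", "g3"]
        assert cross_method_concordance({"a"}, {"a"})[0] == 1.0
        assert cross_method_concordance({"a"}, {"b"})[0] == 0.0

    def test_empty_candidate_set_is_error(self):
        with pytest.raises(ValidationError):
            cross_method_concordance(set(), {"a"})

    def test_venn_cells(self):
        cells = contrast_overlap({"NMG": {"a", "b"}, "GS": {"b", "c"},
                                  "QH": {"c", "d"}})
        pair = cells[(cells.NMG == 1) & (cells.GS == 1) & (cells.QH == 0)]
        assert pair.iloc[0]["count"] == 1 and pair.iloc[0]["genes"] == "b"
        triple = cells[(cells.NMG == 1) & (cells.GS == 1) & (cells.QH == 1)]
        assert triple.iloc[0]["count"] == 0

    def test_cells_sum_to_union(self, rng):
        sets = {f"s{i}": set(rng.choice(40, rng.integers(5, 20),
                                        replace=False).tolist())
                for i in range(3)}
        cells = contrast_overlap(sets)
        assert cells["count"].sum() == len(set().union(*sets.values()))


class TestTrajectory:
    def _setup(self, freqs_per_pop):
        # six populations, 5 diploids each, constructed to hit the target
        # alt-allele frequency at a single site
        n_pops = len(freqs_per_pop)
        geno = []
        for f in freqs_per_pop:
            alt = int(round(f * 10))
            g = [2] * (alt // 2) + [1] * (alt % 2)
            g += [0] * (5 - len(g))
            geno.extend(g)
        table = make_table(np.array([geno], dtype=np.int8), positions=[100])
        assignments = {}
        altitudes = {}
        for p in range(n_pops):
            for i in range(5):
                assignments[f"s{p * 5 + i}"] = f"P{p}"
            altitudes[f"P{p}"] = 100.0 + 500 * p
        return table, PopulationMap(assignments, altitudes)

    def test_strict_monotone_flagged(self):
        table, pm = self._setup([0.1, 0.2, 0.4, 0.5, 0.7, 0.9])
        out = allele_frequency_trajectory(table, pm, [("chr1", 100)])
        assert bool(out.iloc[0].altitude_increasing)
        assert out.iloc[0].rank_correlation == pytest.approx(1.0)

    def test_non_monotone_not_flagged(self):
        table, pm = self._setup([0.5, 0.4, 0.6, 0.3, 0.7, 0.2])
        out = allele_frequency_trajectory(table, pm, [("chr1", 100)])
        assert not bool(out.iloc[0].altitude_increasing)

    def test_rise_below_default_threshold_not_flagged(self):
        table, pm = self._setup([0.1, 0.1, 0.1, 0.1, 0.1, 0.3])
        # non-decreasing with total rise 0.2 -> flagged at the default...
        out = allele_frequency_trajectory(table, pm, [("chr1", 100)])
        assert bool(out.iloc[0].altitude_increasing)
        table, pm = self._setup([0.1, 0.1, 0.1, 0.1, 0.1, 0.2])
        # ...but a 0.1 rise is below min_rise=0.2
        out = allele_frequency_trajectory(table, pm, [("chr1", 100)])
        assert not bool(out.iloc[0].altitude_increasing)

    def test_missing_population_reported_incomplete(self):
        table, pm = self._setup([0.1, 0.2, 0.4, 0.5, 0.7, 0.9])
        table.genotypes[0, 5:10] = -1  # second population all missing
        out = allele_frequency_trajectory(table, pm, [("chr1", 100)])
        assert bool(out.iloc[0].incomplete)
        assert not bool(out.iloc[0].altitude_increasing)


class TestRecoveredLoci:
    def test_tolerance_and_misses(self):
        seg = pd.DataFrame([{"chrom": "chr2", "start": 430_000, "end": 470_000}])
        truth = {"chr1": None, "chr2": 500_000, "chr3": 500_000}
        rec = recovered_loci(seg, truth, tolerance=100_000)
        assert rec == {"chr2": 500_000}
        assert recovered_loci(seg, truth, tolerance=10_000) == {}
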