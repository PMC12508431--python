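"""rpk quantification, low-signal filtering, fold changes, tornado matrices."""

import numpy as np
import pandas as pd
import pytest

from enhquant.quant import (
    SignalTable,
    build_signal_table,
    count_overlaps,
    filter_low_signal,
    fold_change,
    rpk,
    signal_matrix,
)
from enhquant.regions import EnhancerLocus, GenomicInterval

from conftest import make_readset, random_reads


def brute_force_overlap_count(triples, locus):
    """Per-base scan: a read counts iff it shares >= 1 base with the locus."""
    locus_bases = set(range(locus.interval.start, locus.interval.end))
    n = 0
    for chrom, start, end in triples:
        if chrom == locus.chrom and set(range(start, end)) & locus_bases:
            n += 1
    return n


class TestCountOverlaps:
    def test_partial_overlap_counts(self, simple_locus):
        rs = make_readset("s", [("chr1", 100, 200)])
        assert count_overlaps(rs, simple_locus) == 1

    def test_half_open_abutment_does_not_count(self, simple_locus):
        rs = make_readset("s", [("chr1", 700, 800)])
        assert count_overlaps(rs, simple_locus) == 0

    def test_contained_reads_count(self, simple_locus):
        rs = make_readset("s", [("chr1", 200, 250)] * 3)
        assert count_overlaps(rs, simple_locus) == 3

    def test_spike_reads_never_counted(self, simple_locus):
        rs = make_readset("s", [("dm6_chr1", 200, 250), ("chr1", 200, 250)])
        assert count_overlaps(rs, simple_locus) == 1

    def test_matches_per_base_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            triples = random_reads(rng, int(rng.integers(0, 100)))
            rs = make_readset("s", triples)
            for _ in range(int(rng.integers(1, 10))):
                s = int(rng.integers(0, 9_500))
                locus = EnhancerLocus(
                    "L", GenomicInterval("chr1", s, s + int(rng.integers(1, 500)))
                )
                assert count_overlaps(rs, locus) == brute_force_overlap_count(
                    triples, locus
                )


class TestRpk:
    @pytest.mark.parametrize(
        "count,width,expected", [(300, 600, 500.0), (0, 600, 0.0), (50, 2500, 20.0)]
    )
    def test_examples(self, count, width, expected):
        assert rpk(count, width) == pytest.approx(expected)

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            rpk(10, 0)

    def test_additive_over_disjoint_read_subsets(self, simple_locus):
        rng = np.random.default_rng(3)
        triples = random_reads(rng, 60, max_coord=1000)
        merged = make_readset("s", triples)
        a = make_readset("s", triples[:25])
        b = make_readset("s", triples[25:])
        total = rpk(count_overlaps(merged, simple_locus), simple_locus.width)
        parts = rpk(count_overlaps(a, simple_locus), simple_locus.width) + rpk(
            count_overlaps(b, simple_locus), simple_locus.width
        )
        assert total == pytest.approx(parts)


def table_from_dict(data, assay="chip"):
    return SignalTable(values=pd.DataFrame(data), assay=assay)


class TestBuildSignalTable:
    def test_rpk_values(self):
        locus = EnhancerLocus("E1", GenomicInterval("chr1", 0, 600))
        rs = make_readset("s1", [("chr1", 10, 85)] * 60)
        table = build_signal_table([rs], [locus])
        assert table.values.loc["E1", "s1"] == pytest.approx(100.0)

    def test_zero_coverage_row(self):
        loci = [
            EnhancerLocus("E1", GenomicInterval("chr1", 0, 600)),
            EnhancerLocus("E2", GenomicInterval("chr1", 5000, 5600)),
        ]
        rs = make_readset("s1", [("chr1", 10, 85)])
        table = build_signal_table([rs], loci)
        assert table.values.loc["E2", "s1"] == 0.0

    def test_sample_order_permutes_columns_only(self):
        locus = EnhancerLocus("E1", GenomicInterval("chr1", 0, 600))
        a = make_readset("a", [("chr1", 10, 85)] * 3)
        b = make_readset("b", [("chr1", 10, 85)] * 7)
        t1 = build_signal_table([a, b], [locus])
        t2 = build_signal_table([b, a], [locus])
        assert t1.samples == ["a", "b"] and t2.samples == ["b", "a"]
        pd.testing.assert_frame_equal(t1.values, t2.values[["a", "b"]])

    def test_duplicate_sample_ids_rejected(self):
        locus = EnhancerLocus("E1", GenomicInterval("chr1", 0, 600))
        rs = make_readset("a", [("chr1", 10, 85)])
        with pytest.raises(ValueError, match="duplicate"):
            build_signal_table([rs, rs], [locus])


class TestFilterLowSignal:
    @pytest.mark.parametrize(
        "ctrl,treat,assay,kept",
        [
            (25.0, 28.0, "chip", False),  # both below 30
            (25.0, 35.0, "chip", True),  # one side clears the floor
            (5.0, 8.0, "rna", False),  # both below 10
            (5.0, 12.0, "rna", True),
            (30.0, 0.0, "chip", True),  # threshold is >= (not strict)
        ],
    )
    def test_or_rule(self, ctrl, treat, assay, kept):
        table = table_from_dict({"c": [ctrl], "t": [treat]}, assay)
        out = filter_low_signal(table, "c", "t")
        assert (len(out.values) == 1) is kept

    def test_unknown_sample_rejected(self):
        table = table_from_dict({"c": [1.0], "t": [2.0]})
        with pytest.raises(KeyError):
            filter_low_signal(table, "c", "missing")

    def test_raising_threshold_shrinks_retained_set(self):
        rng = np.random.default_rng(5)
        table = table_from_dict(
            {"c": rng.uniform(0, 60, 100), "t": rng.uniform(0, 60, 100)}
        )
        previous = None
        for threshold in [0, 10, 20, 30, 50, 100]:
            kept = set(filter_low_signal(table, "c", "t", threshold).values.index)
            if previous is not None:
                assert kept <= previous
            previous = kept


class TestFoldChange:
    def test_equal_signal_gives_zero(self):
        table = table_from_dict({"c": [100.0], "t": [100.0]})
        fc = fold_change(table, "c", "t")
        assert fc["log2fc"].iloc[0] == pytest.approx(0.0)

    def test_halved_signal_with_pseudocount(self):
        table = table_from_dict({"c": [100.0], "t": [50.0]})
        fc = fold_change(table, "c", "t", pseudocount=1.0)
        assert fc["log2fc"].iloc[0] == pytest.approx(np.log2(51 / 101), abs=1e-9)
        assert fc["log2fc"].iloc[0] == pytest.approx(-0.9858, abs=1e-4)

    def test_excluded_locus_has_no_log2fc(self):
        table = table_from_dict({"c": [0.0], "t": [0.0]})
        fc = fold_change(table, "c", "t")
        assert not fc["passed_filter"].iloc[0]
        assert np.isnan(fc["log2fc"].iloc[0])

    def test_negative_pseudocount_rejected(self):
        table = table_from_dict({"c": [1.0], "t": [1.0]})
        with pytest.raises(ValueError):
            fold_change(table, "c", "t", pseudocount=-1)

    def test_log2fc_finite_wherever_filter_passed(self):
        rng = np.random.default_rng(6)
        table = table_from_dict(
            {"c": rng.uniform(0, 100, 200), "t": rng.uniform(0, 100, 200)}
        )
        fc = fold_change(table, "c", "t")
        assert np.isfinite(fc.loc[fc["passed_filter"], "log2fc"]).all()


class TestSignalMatrix:
    def test_bin_count(self):
        locus = EnhancerLocus("E", GenomicInterval("chr1", 99_000, 101_000))
        rs = make_readset("s", [("chr1", 100_000, 100_075)])
        matrix = signal_matrix(rs, [locus], window=3000, bin_size=50)
        assert matrix.values.shape == (1, 120)

    def test_single_read_at_anchor_hits_central_bins_only(self):
        locus = EnhancerLocus("E", GenomicInterval("chr1", 99_000, 101_000))
        rs = make_readset("s", [("chr1", 100_000, 100_075)])
        matrix = signal_matrix(rs, [locus], window=3000, bin_size=50)
        nonzero = matrix.values.columns[(matrix.values.iloc[0] > 0).to_numpy()]
        assert list(nonzero) == [0, 50]  # 75 bp read spans two 50 bp bins

    def test_uniform_coverage_gives_equal_bins(self):
        locus = EnhancerLocus("E", GenomicInterval("chr1", 50_000, 50_600))
        reads = [("chr1", s, s + 50) for s in range(40_000, 60_000, 50)]
        rs = make_readset("s", reads)
        matrix = signal_matrix(rs, [locus], window=3000, bin_size=50)
        assert len(set(matrix.values.iloc[0])) == 1

    def test_window_past_chromosome_start_is_zero(self):
        locus = EnhancerLocus("E", GenomicInterval("chr1", 0, 600))
        rs = make_readset("s", [("chr1", 100, 175)])
        matrix = signal_matrix(rs, [locus], window=3000, bin_size=50)
        left_bins = matrix.values.iloc[0][matrix.values.columns < -300]
        assert (left_bins == 0).all()

    def test_indivisible_window_rejected(self):
        locus = EnhancerLocus("E", GenomicInterval("chr1", 0, 600))
        with pytest.raises(ValueError, match="divisible"):
            signal_matrix(make_readset("s", []), [locus], window=3000, bin_size=70)

    def test_rows_orderable_by_sum(self):
        loci = [
            EnhancerLocus("HIGH", GenomicInterval("chr1", 99_000, 101_000)),
            EnhancerLocus("LOW", GenomicInterval("chr1", 199_000, 201_000)),
        ]
        reads = [("chr1", 100_000, 100_075)] * 5 + [("chr1", 200_000, 200_075)]
        matrix = signal_matrix(make_readset("s", reads), loci)
        assert list(matrix.ordered_by_sum().index) == ["HIGH", "LOW"]
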