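"""Locus ingestion, minimum-width extension, nearest-TSS linkage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enhquant.regions import (
    BedParseError,
    EnhancerLocus,
    GenomicInterval,
    TSSRecord,
    ValidationError,
    extend_to_min_width,
    link_to_nearest_tss,
    read_bed,
    read_chrom_sizes,
    read_tss_bed,
    write_linked_bed,
)


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadBed:
    def test_bed4_line_parses_with_midpoint_anchor(self, tmp_path):
        path = _write(tmp_path, "a.bed", "chr1\t100\t700\tE1\n")
        (locus,) = read_bed(path)
        assert locus.id == "E1"
        assert (locus.interval.start, locus.interval.end) == (100, 700)
        assert locus.anchor == 400

    def test_bed3_id_defaults_to_coordinates(self, tmp_path):
        path = _write(tmp_path, "a.bed", "chr2\t10\t20\n")
        (locus,) = read_bed(path)
        assert locus.id == "chr2:10-20"

    def test_inverted_interval_is_parse_error_naming_line(self, tmp_path):
        path = _write(tmp_path, "a.bed", "chr1\t0\t5\n" + "chr1\t700\t100\n")
        with pytest.raises(BedParseError, match=":2"):
            read_bed(path)

    def test_non_integer_coordinate_rejected(self, tmp_path):
        path = _write(tmp_path, "a.bed", "chr1\tx\t700\n")
        with pytest.raises(BedParseError):
            read_bed(path)

    def test_order_preserved_and_track_lines_skipped(self, tmp_path):
        path = _write(
            tmp_path,
            "a.bed",
            "track name=x\nchr1\t0\t10\tA\nchr1\t20\t30\tB\nchr1\t40\t50\tC\n",
        )
        assert [l.id for l in read_bed(path)] == ["A", "B", "C"]

    def test_interval_beyond_chrom_sizes_rejected(self, tmp_path):
        path = _write(tmp_path, "a.bed", "chr1\t100\t700\n")
        with pytest.raises(ValidationError, match="exceeds"):
            read_bed(path, chrom_sizes={"chr1": 500})


class TestExtend:
    def test_deficit_split_symmetrically(self):
        locus = EnhancerLocus("E", GenomicInterval("chr1", 1000, 1400))
        (out,) = extend_to_min_width([locus], 600)
        assert (out.interval.start, out.interval.end) == (900, 1500)
        assert out.anchor == locus.anchor  # anchors never move

    def test_left_clip_moves_lost_bases_right(self):
        locus = EnhancerLocus("E", GenomicInterval("chr1", 0, 100))
        (out,) = extend_to_min_width([locus], 600)
        assert (out.interval.start, out.interval.end) == (0, 600)

    def test_right_clip_moves_lost_bases_left(self):
        locus = EnhancerLocus("E", GenomicInterval("chr1", 900, 1000))
        (out,) = extend_to_min_width([locus], 600, {"chr1": 1100})
        assert (out.interval.start, out.interval.end) == (500, 1100)

    def test_wide_locus_unchanged(self):
        locus = EnhancerLocus("E", GenomicInterval("chr1", 1000, 1601))
        (out,) = extend_to_min_width([locus], 600)
        assert out is locus

    def test_odd_deficit_floor_left_ceil_right(self):
        locus = EnhancerLocus("E", GenomicInterval("chr1", 1000, 1001))
        (out,) = extend_to_min_width([locus], 600)
        # deficit 599: 299 left, 300 right
        assert (out.interval.start, out.interval.end) == (701, 1301)

    @settings(derandomize=True, max_examples=200)
    @given(
        start=st.integers(min_value=600, max_value=10**6),
        width=st.integers(min_value=1, max_value=2000),
        min_width=st.integers(min_value=1, max_value=600),
    )
    def test_width_is_max_of_input_and_minimum(self, start, width, min_width):
        """Away from chromosome edges the output width is exactly
        max(input width, min_width), and extension is idempotent."""
        locus = EnhancerLocus("L", GenomicInterval("chr1", start, start + width))
        (out,) = extend_to_min_width([locus], min_width)
        assert out.width == max(width, min_width)
        assert out.anchor == locus.anchor
        assert extend_to_min_width([out], min_width) == [out]

    def test_chromosome_shorter_than_min_width_errors(self):
        locus = EnhancerLocus("E", GenomicInterval("chr1", 0, 100))
        with pytest.raises(ValidationError, match="shorter"):
            extend_to_min_width([locus], 600, {"chr1": 400})

    def test_idempotent_and_width_exact(self):
        rng = np.random.default_rng(0)
        loci = []
        for i in range(200):
            start = int(rng.integers(1000, 100_000))
            width = int(rng.integers(1, 1500))
            loci.append(EnhancerLocus(f"L{i}", GenomicInterval("chr1", start, start + width)))
        once = extend_to_min_width(loci, 600)
        twice = extend_to_min_width(once, 600)
        assert once == twice
        for before, after in zip(loci, once):
            assert after.width == max(before.width, 600)


class TestLinkage:
    def test_nearest_tss_wins(self):
        locus = EnhancerLocus("E", GenomicInterval("chr1", 5500, 6500))
        tss = [TSSRecord("GENEA", "chr1", 5000), TSSRecord("GENEB", "chr1", 20000)]
        (out,) = link_to_nearest_tss([locus], tss)
        assert out.linked_gene == "GENEA"
        assert out.linked_distance == 1000

    def test_exact_tie_goes_to_smallest_gene_id(self):
        locus = EnhancerLocus("E", GenomicInterval("chr1", 9500, 10500))
        tss = [TSSRecord("Z", "chr1", 9000), TSSRecord("A", "chr1", 11000)]
        (out,) = link_to_nearest_tss([locus], tss)
        assert out.linked_gene == "A"

    def test_no_tss_on_chromosome_leaves_unlinked(self, caplog):
        locus = EnhancerLocus("E", GenomicInterval("chr1", 100, 800))
        tss = [TSSRecord("G", "chr9", 5000)]
        with caplog.at_level("WARNING"):
            (out,) = link_to_nearest_tss([locus], tss)
        assert out.linked_gene is None
        assert "unlinked" in caplog.text

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n_loci = int(rng.integers(1, 50))
            n_tss = int(rng.integers(1, 50))
            loci = []
            for i in range(n_loci):
                s = int(rng.integers(0, 100_000))
                loci.append(EnhancerLocus(f"L{i}", GenomicInterval("chr1", s, s + 100)))
            tss = [
                TSSRecord(f"G{j:03d}", "chr1", int(rng.integers(0, 100_000)))
                for j in range(n_tss)
            ]
            linked = link_to_nearest_tss(loci, tss)
            for locus, out in zip(loci, linked):
                # brute force: all-pairs distance scan with the same tie rule
                best = min((abs(t.tss - locus.anchor), t.gene_id) for t in tss)
                assert out.linked_gene == best[1]
                assert out.linked_distance == best[0]


class TestIO:
    def test_tss_bed_strand_semantics(self, tmp_path):
        path = _write(
            tmp_path,
            "tss.bed",
            "chr1\t100\t200\tGPLUS\t0\t+\nchr1\t300\t400\tGMINUS\t0\t-\n",
        )
        plus, minus = read_tss_bed(path)
        assert plus.tss == 100
        assert minus.tss == 399

    def test_chrom_sizes_roundtrip(self, tmp_path):
        path = _write(tmp_path, "c.sizes", "chr1\t1000\ndm6_chr2L\t500\n")
        assert read_chrom_sizes(path) == {"chr1": 1000, "dm6_chr2L": 500}

    def test_linked_bed_writer(self, tmp_path):
        locus = EnhancerLocus(
            "E1", GenomicInterval("chr1", 100, 700), linked_gene="G", linked_distance=5
        )
        out = tmp_path / "linked.bed"
        write_linked_bed([locus], out)
        assert out.read_text() == "chr1\t100\t700\tE1\t0\t.\tG\t5\n"
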