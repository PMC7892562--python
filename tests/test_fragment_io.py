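"""Fragment/gene/signal I-O, size classification and dyad conventions."""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucspacer.fragment_io import (
    FragmentRecord,
    GeneRecord,
    SignalTrack,
    SizeClassConfig,
    classify_by_size,
    fragment_dyad,
    read_fragments,
    read_genes,
    read_signal_track,
    write_fragments_bed,
)


class TestFragmentRecords:
    def test_invariants(self):
        with pytest.raises(ValueError):
            FragmentRecord("chrI", 250, 100)
        with pytest.raises(ValueError):
            FragmentRecord("", 0, 10)
        assert FragmentRecord("chrI", 100, 250).length == 150

    @pytest.mark.parametrize(
        "start,end,dyad", [(100, 250, 175), (0, 147, 73), (10, 11, 10)]
    )
    def test_dyad_midpoint(self, start, end, dyad):
        f = FragmentRecord("chrI", start, end)
        assert fragment_dyad(f) == dyad
        assert start <= fragment_dyad(f) < end

    @settings(derandomize=True, max_examples=50)
    @given(
        start=st.integers(0, 10**6),
        length=st.integers(1, 500),
        shift=st.integers(0, 10**4),
    )
    def test_dyad_translation_invariant(self, start, length, shift):
        f = FragmentRecord("chrI", start, start + length)
        g = FragmentRecord("chrI", start + shift, start + shift + length)
        assert fragment_dyad(g) == fragment_dyad(f) + shift


class TestSizeClassification:
    @pytest.mark.parametrize(
        "length,expected",
        [
            (119, "other"), (120, "mono"), (150, "mono"), (180, "mono"),
            (181, "other"), (250, "di"), (300, "di"), (350, "di"), (351, "other"),
        ],
    )
    def test_inclusive_bounds(self, length, expected):
        assert SizeClassConfig().classify_length(length) == expected

    def test_partition_total(self):
        frags = [FragmentRecord("c", 0, L) for L in range(1, 500)]
        mono, di, other = classify_by_size(frags)
        assert len(mono) + len(di) + len(other) == len(frags)
        assert {f.length for f in mono} == set(range(120, 181))
        assert {f.length for f in di} == set(range(250, 351))

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            SizeClassConfig(mono_min=120, mono_max=260, di_min=250, di_max=350)

    @settings(derandomize=True, max_examples=30)
    @given(length=st.integers(1, 500), k=st.integers(-50, 50))
    def test_bound_shift_equivalence(self, length, k):
        """Shifting all bounds by +k classifies length L as L-k did originally."""
        base = SizeClassConfig()
        shifted = SizeClassConfig(120 + k, 180 + k, 250 + k, 350 + k)
        assert shifted.classify_length(length) == base.classify_length(length - k)


class TestFragmentIO:
    def test_bed_roundtrip(self, tmp_path):
        frags = [FragmentRecord("chrI", 100, 250), FragmentRecord("chrII", 0, 147)]
        path = tmp_path / "f.bed"
        write_fragments_bed(frags, path)
        assert read_fragments(path, "bed") == frags

    def test_bed_errors_name_line(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chrI\t100\t250\nchrI\t250\t100\n")
        with pytest.raises(ValueError, match="line 2"):
            read_fragments(path, "bed")

    def test_empty_file_warns(self, tmp_path, caplog):
        path = tmp_path / "empty.bed"
        path.write_text("")
        with caplog.at_level("WARNING"):
            assert read_fragments(path, "bed") == []
        assert "no fragments" in caplog.text

    def test_unknown_format(self, tmp_path):
        path = tmp_path / "f.bed"
        path.write_text("chrI\t1\t2\n")
        with pytest.raises(ValueError, match="unknown fragment format"):
            read_fragments(path, "cram")

    def test_paired_alignments_sam(self, tmp_path):
        sam = tmp_path / "pairs.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:queryname\n"
            "@SQ\tSN:chrI\tLN:10000\n"
            "r1\t99\tchrI\t101\t60\t50M\t=\t201\t150\t" + "A" * 50 + "\t*\n"
            "r1\t147\tchrI\t201\t60\t50M\t=\t101\t-150\t" + "A" * 50 + "\t*\n"
        )
        frags = read_fragments(sam, "paired-alignments")
        assert frags == [FragmentRecord("chrI", 100, 250)]


class TestGeneIO:
    def test_bed6_plus(self, tmp_path):
        path = tmp_path / "g.bed"
        path.write_text("chrI\t1000\t3500\tYAL001C\t0\t+\n")
        (g,) = read_genes(path, "bed6")
        assert (g.tss, g.tts, g.strand) == (1000, 3500, "+")
        assert g.gene_length == 2500

    def test_bed6_minus_convention(self, tmp_path):
        """Minus-strand TSS is the rightmost transcribed base (end - 1)."""
        path = tmp_path / "g.bed"
        path.write_text("chrI\t1000\t3500\tYAL001C\t0\t-\n")
        (g,) = read_genes(path, "bed6")
        assert (g.tss, g.tts) == (3499, 1000)
        assert g.tss > g.tts

    def test_gff3_and_strand_required(self, tmp_path):
        path = tmp_path / "g.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chrI\tsrc\tgene\t1001\t3500\t.\t+\t.\tID=YAL001C\n"
            "chrI\tsrc\tmRNA\t1001\t3500\t.\t+\t.\tID=t1;Parent=YAL001C\n"
        )
        (g,) = read_genes(path, "gff3")
        assert (g.gene_id, g.tss, g.tts) == ("YAL001C", 1000, 3500)
        bad = tmp_path / "bad.gff3"
        bad.write_text("chrI\tsrc\tgene\t1001\t3500\t.\t.\t.\tID=x\n")
        with pytest.raises(ValueError, match="strand"):
            read_genes(bad, "gff3")

    def test_tsv_roundtrip_and_duplicates(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text(
            "gene_id\tchrom\ttss\ttts\tstrand\tplus1_dyad\n"
            "g1\tchrI\t1000\t3500\t+\t1073\n"
            "g2\tchrI\t8000\t5000\t-\t7927\n"
        )
        genes = read_genes(path, "tsv")
        assert genes[0].plus1_dyad == 1073
        assert genes[1].strand == "-"
        dup = tmp_path / "dup.tsv"
        dup.write_text(
            "gene_id\tchrom\ttss\ttts\tstrand\n"
            "g1\tchrI\t1000\t3500\t+\ng1\tchrI\t4000\t6000\t+\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_genes(dup, "tsv")

    def test_gene_record_strand_invariants(self):
        with pytest.raises(ValueError):
            GeneRecord("g", "chrI", 3000, 1000, "+")
        with pytest.raises(ValueError):
            GeneRecord("g", "chrI", 1000, 3000, "-")


class TestSignalTrack:
    def test_genomic_mean(self, tmp_path):
        path = tmp_path / "t.bedgraph"
        path.write_text("chrI\t0\t100\t2\nchrI\t200\t300\t4\n")
        track = read_signal_track(path)
        assert track.genomic_mean == pytest.approx(3.0)

    def test_errors(self, tmp_path):
        empty = tmp_path / "e.bedgraph"
        empty.write_text("")
        with pytest.raises((ValueError, pd.errors.EmptyDataError)):
            read_signal_track(empty)
        neg = pd.DataFrame(
            {"chrom": ["chrI"], "start": [0], "end": [10], "value": [-1.0]}
        )
        with pytest.raises(ValueError, match=">= 0"):
            SignalTrack(neg)
        overlap = pd.DataFrame(
            {
                "chrom": ["chrI", "chrI"],
                "start": [0, 50],
                "end": [100, 150],
                "value": [1.0, 2.0],
            }
        )
        with pytest.raises(ValueError, match="overlap"):
            SignalTrack(overlap)

    def test_zero_signal_warns(self, caplog):
        df = pd.DataFrame({"chrom": ["chrI"], "start": [0], "end": [10], "value": [0.0]})
        with caplog.at_level("WARNING"):
            track = SignalTrack(df)
        assert track.genomic_mean == 0.0

    def test_mean_over_interval(self):
        df = pd.DataFrame(
            {"chrom": ["chrI", "chrI"], "start": [0, 100], "end": [100, 200],
             "value": [2.0, 6.0]}
        )
        track = SignalTrack(df)
        mean, covered = track.mean_over("chrI", 50, 150)
        assert (mean, covered) == (4.0, 100)
        assert track.mean_over("chrX", 0, 10) == (0.0, 0)
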