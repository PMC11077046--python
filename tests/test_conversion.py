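"""Alignment filtering, transcript-space conversion and mate bridging."""

import pytest

import txpileup as tp
from txpileup.conversion import AlignedSegmentView, ConversionOptions


def seg(pos, cigar, seq=None, strand="+", name="r", read1=False, read2=False,
        paired=False, chrom="chr1"):
    return AlignedSegmentView(
        query_name=name, chrom=chrom, strand=strand, pos=pos, cigar=cigar, seq=seq,
        is_read1=read1, is_read2=read2, is_paired=paired,
    )


class TestSegmentToTx:
    def test_simple_match_inside_exon(self, two_exon_plus):
        res = tp.segment_to_tx(seg(101, [("M", 10)], "ACGTACGTAC"), two_exon_plus)
        assert res is not None
        s, e, calls = res
        assert (s, e) == (1, 10)
        assert calls == {i + 1: "ACGTACGTAC"[i] for i in range(10)}

    def test_junction_concordant_spliced_read(self, two_exon_plus):
        # 50M exactly fills exon 1; 50N is exactly the intron (150,200)
        res = tp.segment_to_tx(seg(101, [("M", 50), ("N", 50), ("M", 10)], "A" * 60),
                               two_exon_plus)
        assert res is not None
        s, e, _ = res
        assert (s, e) == (1, 60)

    def test_junction_mismatch_rejected(self, two_exon_plus):
        assert tp.segment_to_tx(seg(101, [("M", 50), ("N", 40), ("M", 10)], "A" * 60),
                                two_exon_plus) is None

    def test_soft_clip_ignored(self, two_exon_plus):
        clipped = tp.segment_to_tx(seg(101, [("S", 5), ("M", 10)], "NNNNNACGTACGTAC"),
                                   two_exon_plus)
        plain = tp.segment_to_tx(seg(101, [("M", 10)], "ACGTACGTAC"), two_exon_plus)
        assert clipped == plain

    def test_deletion_occupies_reference_positions(self, two_exon_plus):
        res = tp.segment_to_tx(seg(101, [("M", 3), ("D", 2), ("M", 2)], "AAACC"), two_exon_plus)
        s, e, calls = res
        assert (s, e) == (1, 7)
        assert calls[4] == "-" and calls[5] == "-" and calls[6] == "C"

    def test_insertion_contributes_no_positions(self, two_exon_plus):
        res = tp.segment_to_tx(seg(101, [("M", 3), ("I", 4), ("M", 2)], "AAAGGGGCC"),
                               two_exon_plus)
        s, e, calls = res
        assert (s, e) == (1, 5) and calls[4] == "C"

    def test_read_outside_exons_rejected(self, two_exon_plus):
        assert tp.segment_to_tx(seg(155, [("M", 10)], "A" * 10), two_exon_plus) is None

    def test_minus_model_complements_calls(self):
        model = tp.TranscriptModel("g", "chr1", "-", ((0, 4),))
        res = tp.segment_to_tx(seg(1, [("M", 4)], "ACGT"), model)
        s, e, calls = res
        # genomic 1..4 map to tx 4..1; calls complemented into transcript orientation
        assert (s, e) == (1, 4)
        assert calls == {4: "T", 3: "G", 2: "C", 1: "A"}


class TestFragmentFromPair:
    def test_bridging_gap_has_no_calls(self):
        model = tp.TranscriptModel("g", "chr1", "+", ((0, 200),))
        s1 = seg(1, [("M", 40)], "A" * 40, read1=True, paired=True)
        s2 = seg(111, [("M", 40)], "A" * 40, strand="-", read2=True, paired=True)
        frag = tp.fragment_from_pair(s1, s2, model)
        assert frag is not None
        assert (frag.tx_start, frag.tx_end) == (1, 150)
        assert all(p not in frag.calls for p in range(41, 111))
        assert len(frag.calls) == 80

    def test_overlapping_mates_agree(self):
        model = tp.TranscriptModel("g", "chr1", "+", ((0, 200),))
        s1 = seg(1, [("M", 60)], "A" * 60, read1=True, paired=True)
        s2 = seg(41, [("M", 60)], "A" * 60, strand="-", read2=True, paired=True)
        frag = tp.fragment_from_pair(s1, s2, model)
        assert (frag.tx_start, frag.tx_end) == (1, 100)
        assert all(frag.calls[p] == "A" for p in range(1, 101))

    def test_overlapping_mates_disagree_becomes_n(self):
        model = tp.TranscriptModel("g", "chr1", "+", ((0, 200),))
        s1 = seg(1, [("M", 60)], "A" * 60, read1=True, paired=True)
        s2 = seg(50, [("M", 11)], "A" * 9 + "CA", strand="-", read2=True, paired=True)
        frag = tp.fragment_from_pair(s1, s2, model)
        assert frag.calls[59] == "N" and frag.calls[58] == "A" and frag.calls[60] == "A"

    def test_mates_on_different_chroms_rejected(self):
        model = tp.TranscriptModel("g", "chr1", "+", ((0, 200),))
        s1 = seg(1, [("M", 10)], "A" * 10, read1=True, paired=True)
        s2 = seg(1, [("M", 10)], "A" * 10, read2=True, paired=True, chrom="chr2")
        assert tp.fragment_from_pair(s1, s2, model) is None

    def test_span_exceeding_max_fragment_rejected(self):
        model = tp.TranscriptModel("g", "chr1", "+", ((0, 2000),))
        s1 = seg(1, [("M", 40)], "A" * 40, read1=True, paired=True)
        s2 = seg(1500, [("M", 40)], "A" * 40, strand="-", read2=True, paired=True)
        assert tp.fragment_from_pair(s1, s2, model, ConversionOptions(max_fragment=1000)) is None
        assert tp.fragment_from_pair(s1, s2, model, ConversionOptions(max_fragment=2000)) is not None

    def test_antisense_pair_rejected_under_same_strand_mode(self):
        model = tp.TranscriptModel("g", "chr1", "+", ((0, 200),))
        s1 = seg(41, [("M", 40)], "A" * 40, strand="-", read1=True, paired=True)
        s2 = seg(1, [("M", 40)], "A" * 40, strand="+", read2=True, paired=True)
        assert tp.fragment_from_pair(s1, s2, model) is None
        assert tp.fragment_from_pair(
            s1, s2, model, ConversionOptions(strand_mode="opposite")) is not None


SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:1000\n"


def write_sam(tmp_path, body, name="t.sam"):
    p = tmp_path / name
    p.write_text(SAM_HEADER + body)
    return p


class TestLoadAlignments:
    def test_two_proper_pairs(self, tmp_path):
        body = (
            "q1\t99\tchr1\t1\t60\t10M\t=\t51\t60\tAAAAAAAAAA\tIIIIIIIIII\n"
            "q1\t147\tchr1\t51\t60\t10M\t=\t1\t-60\tAAAAAAAAAA\tIIIIIIIIII\n"
            "q2\t99\tchr1\t5\t60\t10M\t=\t55\t60\tAAAAAAAAAA\tIIIIIIIIII\n"
            "q2\t147\tchr1\t55\t60\t10M\t=\t5\t-60\tAAAAAAAAAA\tIIIIIIIIII\n"
        )
        groups = tp.load_alignments(write_sam(tmp_path, body))
        assert len(groups) == 2 and all(len(v) == 2 for v in groups.values())

    def test_unmapped_mate_excluded(self, tmp_path):
        body = (
            "q1\t73\tchr1\t1\t60\t10M\t=\t1\t0\tAAAAAAAAAA\tIIIIIIIIII\n"
            "q1\t133\tchr1\t1\t0\t*\t=\t1\t0\tAAAAAAAAAA\tIIIIIIIIII\n"
        )
        groups = tp.load_alignments(write_sam(tmp_path, body))
        assert len(groups) == 1 and len(groups["q1"]) == 1

    def test_header_only_sam(self, tmp_path):
        assert tp.load_alignments(write_sam(tmp_path, "")) == {}


class TestAssign:
    def test_pair_assigned_to_both_overlapping_isoforms(self, tmp_path):
        iso1 = tp.TranscriptModel("isoA", "chr1", "+", ((0, 200),))
        iso2 = tp.TranscriptModel("isoB", "chr1", "+", ((0, 300),))
        body = (
            "q1\t99\tchr1\t1\t60\t10M\t=\t101\t110\tAAAAAAAAAA\tIIIIIIIIII\n"
            "q1\t147\tchr1\t101\t60\t10M\t=\t1\t-110\tAAAAAAAAAA\tIIIIIIIIII\n"
        )
        groups = tp.load_alignments(write_sam(tmp_path, body))
        frags, report = tp.assign_to_transcripts(groups, [iso1, iso2])
        assert len(frags["isoA"]) == 1 and len(frags["isoB"]) == 1
        assert report.assigned == 1

    def test_antisense_pair_counted_in_strand_discards(self, tmp_path):
        model = tp.TranscriptModel("g", "chr1", "-", ((0, 300),))
        body = (
            "q1\t99\tchr1\t1\t60\t10M\t=\t101\t110\tAAAAAAAAAA\tIIIIIIIIII\n"
            "q1\t147\tchr1\t101\t60\t10M\t=\t1\t-110\tAAAAAAAAAA\tIIIIIIIIII\n"
        )
        groups = tp.load_alignments(write_sam(tmp_path, body))
        frags, report = tp.assign_to_transcripts(groups, [model])
        assert frags["g"] == [] and report.strand == 1

    def test_empty_model_list_raises(self):
        with pytest.raises(ValueError):
            tp.assign_to_transcripts({}, [])

    def test_bookkeeping_on_simulated_library(self, sim_library):
        groups = tp.load_alignments(sim_library["sam"])
        frags, report = tp.assign_to_transcripts(groups, sim_library["models"])
        pairs_in = len(groups)
        assert report.assigned + report.total_discarded == pairs_in
        # a simulated read library reconstructs the truth record exactly
        from collections import Counter
        truth = Counter(
            (r.gene, r.tx_start, r.tx_end) for r in sim_library["truth"].itertuples())
        got = Counter(
            (g, f.tx_start, f.tx_end) for g, fl in frags.items() for f in fl)
        assert truth == got
        for g, fl in frags.items():
            model = next(m for m in sim_library["models"] if m.gene_id == g)
            for f in fl:
                f.validate(model)

    def test_single_end_processing_counts_each_mate(self, sim_library):
        groups = tp.load_alignments(sim_library["sam"])
        frags, _ = tp.assign_to_transcripts(
            groups, sim_library["models"], ConversionOptions(paired=False))
        n_single = sum(len(v) for v in frags.values())
        assert n_single == 2 * len(sim_library["truth"])
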