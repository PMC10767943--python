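"""ORF prediction, the 50-nt NMD rule, and TSS/TTS feature annotation."""

import numpy as np
import pytest
from Bio.Seq import Seq

from flicurate.annotate import (
    last_junction_position,
    polya_motif_scan,
    predict_nmd,
    predict_orf,
    transcript_range_to_genomic,
    transcript_sequence,
    tss_feature_overlap,
)
from flicurate.model import AnnotationTrack, FlicurateError, GenomicInterval
from flicurate.simulate import embed_orf, transcript_genomic_positions
from helpers import make_transcript

CODING_FREE = "C"  # sequence of C's carries no ATG and no stop codon


def flat_genome(length=5000, chrom="chr1"):
    return {chrom: CODING_FREE * length}


def spliced_transcript(exon_lens, intron_len=100, strand="+", start=50):
    intervals, pos = [], start
    for L in exon_lens:
        intervals.append((pos, pos + L))
        pos += L + intron_len
    return make_transcript("t", intervals, strand=strand)


class TestSequence:
    def test_minus_strand_is_reverse_complement(self):
        genome = {"chr1": "AACCGGTTAACCGGTT"}
        plus = make_transcript("p", [(0, 4), (8, 12)], strand="+")
        minus = make_transcript("m", [(0, 4), (8, 12)], strand="-")
        fwd = transcript_sequence(plus, genome)
        rev = transcript_sequence(minus, genome)
        assert rev == str(Seq(fwd).reverse_complement())

    def test_missing_contig_is_error(self):
        with pytest.raises(FlicurateError, match="chr9"):
            transcript_sequence(make_transcript("t", [(0, 10)], chrom="chr9"), flat_genome())

    def test_exon_past_contig_end_is_error(self):
        with pytest.raises(FlicurateError, match="extends past"):
            transcript_sequence(make_transcript("t", [(0, 10)]), {"chr1": "ACGT"})


class TestOrf:
    def test_constructed_303nt_orf(self):
        """ATG + 99 sense codons + TAA (303 nt) gives a 100-aa protein."""
        t = spliced_transcript([200, 200])
        genome = embed_orf(flat_genome(), t, orf_len_nt=303, tstart=10)
        orf = predict_orf(t, genome, min_len_nt=300)
        assert orf is not None
        assert (orf.start, orf.end) == (10, 313)
        assert orf.length_nt == 303 and orf.protein_length == 100

    def test_no_atg_means_noncoding(self):
        t = spliced_transcript([200, 200])
        assert predict_orf(t, flat_genome(), min_len_nt=30) is None

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_longest_orf_wins_against_exhaustive_scan(self, strand):
        """With ORFs of 399 and 351 nt embedded, the longer is reported;
        an exhaustive scan over all ATG positions agrees."""
        t = spliced_transcript([300, 300, 300], strand=strand)
        genome = embed_orf(flat_genome(), t, orf_len_nt=351, tstart=20)
        genome = embed_orf(genome, t, orf_len_nt=399, tstart=420)
        orf = predict_orf(t, genome, min_len_nt=300)
        assert (orf.start, orf.end) == (420, 819)

        seq = transcript_sequence(t, genome)
        candidates = []
        for i in range(len(seq) - 2):
            if seq[i : i + 3] != "ATG":
                continue
            for j in range(i + 3, len(seq) - 2, 3):
                codon = seq[j : j + 3]
                if codon in ("TAA", "TAG", "TGA"):
                    candidates.append((j + 3 - i, -i))
                    break
        best_len, neg_start = max(candidates)
        assert (orf.start, orf.end) == (-neg_start, -neg_start + best_len)

    def test_reported_orf_translates_cleanly(self):
        """The reported ORF begins with Met, ends with a stop, and has no
        internal stop codons (frame invariance; Biopython as oracle)."""
        rng = np.random.default_rng(3)
        t = spliced_transcript([250, 250], strand="-")
        genome = embed_orf(flat_genome(), t, orf_len_nt=330, tstart=40, rng=rng)
        orf = predict_orf(t, genome, min_len_nt=300)
        seq = transcript_sequence(t, genome)[orf.start : orf.end]
        protein = str(Seq(seq).translate())
        assert protein.startswith("M") and protein.endswith("*")
        assert "*" not in protein[:-1]
        assert len(protein) - 1 == orf.protein_length

    def test_genomic_blocks_consistent_with_exons(self):
        t = spliced_transcript([100, 100, 100])
        blocks = transcript_range_to_genomic(t, 50, 250)
        assert sum(b.length for b in blocks) == 200
        positions = transcript_genomic_positions(t)
        covered = sorted(p for b in blocks for p in range(b.start, b.end))
        assert covered == sorted(positions[50:250])


class TestNmd:
    @staticmethod
    def transcript_with_stop_distance(d: int):
        """Two-exon transcript whose ORF's stop codon ends d nt upstream of
        the last exon-exon junction."""
        L1 = 420
        t = spliced_transcript([L1, 120])
        genome = embed_orf(flat_genome(), t, orf_len_nt=300, tstart=L1 - d - 300)
        orf = predict_orf(t, genome, min_len_nt=300)
        assert orf is not None and orf.end == L1 - d
        assert last_junction_position(t) == L1
        return t, orf

    def test_boundary_sweep_strictly_greater_than_50(self):
        """Distances 0..100 nt: NMD is predicted exactly for 51..100."""
        for d in range(0, 101):
            t, orf = self.transcript_with_stop_distance(d)
            assert predict_nmd(t, orf) is (d > 50), f"distance {d}"

    def test_stop_in_last_exon_is_not_nmd(self):
        t = spliced_transcript([120, 420])
        genome = embed_orf(flat_genome(), t, orf_len_nt=300, tstart=200)
        orf = predict_orf(t, genome, min_len_nt=300)
        assert orf.end > last_junction_position(t)
        assert predict_nmd(t, orf) is False

    def test_noncoding_is_contract_violation(self):
        t = spliced_transcript([200, 200])
        with pytest.raises(FlicurateError):
            predict_nmd(t, None)


class TestTssFeatures:
    def test_te_at_exactly_100bp_hits_and_101_misses(self):
        t = make_transcript("t", [(1000, 1200), (1300, 1500)])
        at_100 = AnnotationTrack("TE", [GenomicInterval("chr1", 880, 901, "+", "AluY")])
        at_101 = AnnotationTrack("TE", [GenomicInterval("chr1", 880, 900, "+", "AluY")])
        assert tss_feature_overlap(t, at_100, window=100)[0] is True
        assert tss_feature_overlap(t, at_101, window=100)[0] is False

    def test_tss_inside_te_reports_label(self):
        t = make_transcript("t", [(1000, 1200), (1300, 1500)])
        track = AnnotationTrack("TE", [GenomicInterval("chr1", 900, 1100, "+", "L1PA2")])
        hit, label = tss_feature_overlap(t, track, window=100)
        assert hit and label == "L1PA2"

    def test_minus_strand_anchors(self):
        """On the − strand the TSS is the rightmost coordinate and the TTS
        the leftmost."""
        t = make_transcript("t", [(1000, 1200), (1300, 1500)], strand="-")
        near_right = AnnotationTrack("TE", [GenomicInterval("chr1", 1550, 1580, "+", "x")])
        near_left = AnnotationTrack("pA", [GenomicInterval("chr1", 950, 980, "+", "y")])
        assert tss_feature_overlap(t, near_right, window=100, anchor="TSS")[0]
        assert not tss_feature_overlap(t, near_left, window=100, anchor="TSS")[0]
        assert tss_feature_overlap(t, near_left, window=100, anchor="TTS")[0]

    def test_window_matches_brute_force_interval_arithmetic(self):
        rng = np.random.default_rng(11)
        intervals = [
            GenomicInterval("chr1", int(s), int(s) + int(l) + 1, "+", f"te{i}")
            for i, (s, l) in enumerate(
                zip(rng.integers(0, 3000, 60), rng.integers(1, 80, 60))
            )
        ]
        track = AnnotationTrack("TE", intervals)
        for start in range(0, 3000, 97):
            t = make_transcript("t", [(start + 1, start + 51), (start + 151, start + 200)])
            hit, _ = tss_feature_overlap(t, track, window=100)
            point = t.tss
            brute = any(
                iv.start <= point + 100 and iv.end - 1 >= point - 100 for iv in intervals
            )
            assert hit == brute


class TestPolyaMotif:
    def test_motif_in_tail_found(self):
        t = make_transcript("t", [(0, 60)])
        genome = {"chr1": "C" * 34 + "AATAAA" + "C" * 20}
        assert polya_motif_scan(t, genome) == "AATAAA"

    def test_no_motif_in_last_50nt(self):
        t = make_transcript("t", [(0, 100)])
        genome = {"chr1": "AATAAA" + "C" * 94}
        assert polya_motif_scan(t, genome) is None

    def test_three_prime_most_occurrence_wins(self):
        t = make_transcript("t", [(0, 60)])
        genome = {"chr1": "C" * 14 + "AATAAA" + "C" * 10 + "ATTAAA" + "C" * 24}
        assert polya_motif_scan(t, genome) == "ATTAAA"
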