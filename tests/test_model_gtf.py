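"""Data model and GTF/BED/junction-table I/O."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flicurate.gtf import GtfReadReport, read_gtf, read_query_gtfs, write_gtf
from flicurate.junctions import read_junction_tables
from flicurate.model import (
    GtfParseError,
    Intron,
    JunctionEvidenceSet,
    ModelValidationError,
    TranscriptModel,
)
from helpers import make_transcript


def write_lines(path, lines):
    path.write_text("".join(line + "\n" for line in lines))


def gtf_exon(chrom, start1, end1, strand, tid, gid="G1"):
    return (
        f'{chrom}\tsrc\texon\t{start1}\t{end1}\t.\t{strand}\t.\t'
        f'gene_id "{gid}"; transcript_id "{tid}";'
    )


class TestGtfReading:
    def test_coordinate_convention_and_intron_key(self, tmp_path):
        """GTF 1-based exons (100,200) and (301,400) become a single intron
        with half-open internal key (200, 300)."""
        p = tmp_path / "q.gtf"
        write_lines(p, [gtf_exon("chr1", 100, 200, "+", "t1"),
                        gtf_exon("chr1", 301, 400, "+", "t1")])
        (t,) = read_gtf(p, kind="query")
        assert (t.start, t.end) == (99, 400)
        (intron,) = t.intron_chain()
        assert (intron.start, intron.end) == (200, 300)
        assert (intron.donor, intron.acceptor) == (200, 300)

    def test_minus_strand_reverses_ranks_and_donor(self, tmp_path):
        p = tmp_path / "q.gtf"
        write_lines(p, [gtf_exon("chr1", 100, 200, "-", "t1"),
                        gtf_exon("chr1", 301, 400, "-", "t1")])
        (t,) = read_gtf(p, kind="query")
        assert [e.rank for e in t.exons] == [2, 1]
        assert t.exons[-1].rank == 1  # rank 1 is the (301,400) exon
        (intron,) = t.intron_chain()
        assert (intron.donor, intron.acceptor) == (300, 200)

    def test_round_trip_is_identity(self, tmp_path, small_reference):
        p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
        write_gtf(small_reference.transcripts, p1)
        first = read_gtf(p1, kind="query")
        write_gtf(first, p2)
        second = read_gtf(p2, kind="query")
        assert [t.transcript_id for t in first] == [t.transcript_id for t in second]
        for a, b in zip(first, second):
            assert a == b

    def test_missing_transcript_id_names_line(self, tmp_path):
        p = tmp_path / "q.gtf"
        write_lines(p, [gtf_exon("chr1", 100, 200, "+", "t1"),
                        'chr1\tsrc\texon\t300\t400\t.\t+\t.\tgene_id "G1";'])
        with pytest.raises(GtfParseError, match=r":2:"):
            read_gtf(p)

    def test_unstranded_transcript_rejected_and_counted(self, tmp_path):
        p = tmp_path / "q.gtf"
        write_lines(p, [gtf_exon("chr1", 100, 200, ".", "t0"),
                        gtf_exon("chr1", 100, 200, "+", "t1"),
                        gtf_exon("chr1", 301, 400, "+", "t1")])
        report = GtfReadReport()
        out = read_gtf(p, report=report)
        assert [t.transcript_id for t in out] == ["t1"]
        assert report.n_rejected_unstranded == 1

    def test_strand_conflict_within_transcript_is_error(self, tmp_path):
        p = tmp_path / "q.gtf"
        write_lines(p, [gtf_exon("chr1", 100, 200, "+", "t1"),
                        gtf_exon("chr1", 301, 400, "-", "t1")])
        with pytest.raises(GtfParseError, match="conflict"):
            read_gtf(p)

    def test_duplicate_ids_across_files_suffixed(self, tmp_path):
        p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
        for p in (p1, p2):
            write_lines(p, [gtf_exon("chr1", 100, 200, "+", "t1"),
                            gtf_exon("chr1", 301, 400, "+", "t1")])
        out = read_query_gtfs([p1, p2])
        assert [t.transcript_id for t in out] == ["t1", "t1_dup2"]

    def test_gzip_round_trip(self, tmp_path):
        p = tmp_path / "q.gtf.gz"
        t = make_transcript("t1", [(100, 200), (300, 400)])
        write_gtf([t], p)
        (back,) = read_gtf(p)
        assert back == t

    def test_written_attributes_parse_back(self, tmp_path):
        p = tmp_path / "c.gtf"
        t = make_transcript("t1", [(100, 200), (300, 400)])
        write_gtf([t], p, extra_attributes={"t1": {"category": "NNC", "coding": "true"}})
        text = p.read_text()
        assert 'category "NNC";' in text and 'coding "true";' in text


class TestTranscriptModel:
    def test_three_exons_two_introns(self):
        t = make_transcript("t", [(100, 200), (300, 400), (500, 600)])
        chain = t.intron_chain()
        assert [(j.start, j.end) for j in chain] == [(200, 300), (400, 500)]
        assert t.length == 300

    def test_mono_exonic_has_empty_chain(self):
        assert make_transcript("t", [(100, 200)]).intron_chain() == ()

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ModelValidationError):
            make_transcript("t", [(100, 250), (200, 400)])

    @given(
        st.lists(
            st.tuples(st.integers(10, 400), st.integers(20, 500)),
            min_size=1,
            max_size=8,
        ),
        st.sampled_from(["+", "-"]),
    )
    @settings(max_examples=100, deadline=None)
    def test_chain_length_and_containment(self, pieces, strand):
        """n exons give n-1 introns, all strictly inside the span."""
        pos, intervals = 10, []
        for gap, length in pieces:
            intervals.append((pos, pos + length))
            pos += length + gap
        t = make_transcript("t", intervals, strand=strand)
        chain = t.intron_chain()
        assert len(chain) == t.n_exons - 1
        for j in chain:
            assert t.start < j.start < j.end < t.end


class TestJunctionTables:
    @staticmethod
    def sj_line(chrom, start1, end1, code, unique):
        return f"{chrom}\t{start1}\t{end1}\t{code}\t1\t0\t{unique}\t0\t30"

    def test_aggregate_counts_samples(self, tmp_path):
        paths = []
        for i in range(3):
            p = tmp_path / f"s{i}.tab"
            write_lines(p, [self.sj_line("chr1", 201, 300, 1, 4)])
            paths.append(p)
        ev = read_junction_tables(paths)
        j = Intron("chr1", "+", 200, 300)
        assert ev.aggregate()[j] == 3

    def test_zero_unique_reads_do_not_count(self, tmp_path):
        p1, p2 = tmp_path / "a.tab", tmp_path / "b.tab"
        write_lines(p1, [self.sj_line("chr1", 201, 300, 1, 0)])
        write_lines(p2, [self.sj_line("chr1", 201, 300, 1, 2)])
        ev = read_junction_tables([p1, p2])
        assert ev.aggregate().get(Intron("chr1", "+", 200, 300)) == 1

    def test_strand_code_zero_registers_both_strands(self, tmp_path):
        """An undefined-strand junction supports a −-strand transcript
        intron at the same coordinates."""
        p = tmp_path / "a.tab"
        write_lines(p, [self.sj_line("chr1", 201, 300, 0, 5)])
        ev = read_junction_tables([p])
        agg = ev.aggregate()
        assert agg[Intron("chr1", "-", 200, 300)] == 1
        assert agg[Intron("chr1", "+", 200, 300)] == 1

    def test_sj_coordinates_match_gtf_intron(self, tmp_path):
        """STAR's 1-based intron 201..300 equals the intron of GTF exons
        ending at 200 and starting at 301."""
        g = tmp_path / "q.gtf"
        write_lines(g, [gtf_exon("chr1", 100, 200, "+", "t1"),
                        gtf_exon("chr1", 301, 400, "+", "t1")])
        (t,) = read_gtf(g)
        s = tmp_path / "a.tab"
        write_lines(s, [self.sj_line("chr1", 201, 300, 1, 5)])
        ev = read_junction_tables([s])
        (intron,) = t.intron_chain()
        assert ev.aggregate()[intron] == 1

    def test_aggregate_invariant_under_file_order(self, tmp_path):
        lines = {
            "a": [self.sj_line("chr1", 201, 300, 1, 3)],
            "b": [self.sj_line("chr1", 201, 300, 1, 1),
                  self.sj_line("chr1", 401, 500, 2, 2)],
            "c": [self.sj_line("chr2", 11, 90, 1, 9)],
        }
        paths = {}
        for name, ls in lines.items():
            paths[name] = tmp_path / f"{name}.tab"
            write_lines(paths[name], ls)
        fwd = read_junction_tables([paths["a"], paths["b"], paths["c"]])
        rev = read_junction_tables([paths["c"], paths["b"], paths["a"]])
        assert fwd.aggregate() == rev.aggregate()

    def test_malformed_row_names_file_and_line(self, tmp_path):
        from flicurate.model import JunctionTableError

        p = tmp_path / "bad.tab"
        write_lines(p, [self.sj_line("chr1", 201, 300, 1, 5), "chr1\tnope"])
        with pytest.raises(JunctionTableError, match=r"bad.tab:2"):
            read_junction_tables([p])

    def test_negative_counts_rejected(self):
        ev = JunctionEvidenceSet()
        with pytest.raises(ModelValidationError):
            ev.add_sample("s", {Intron("chr1", "+", 1, 10): -1})
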