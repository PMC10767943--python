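"""Functional annotation: ORF, coding/NMD status, and TSS/TTS features.

Coding potential is assessed with a longest-ORF finder on the spliced
transcript sequence (ATG to stop, three forward frames, minimum 300 nt by
default); externally predicted ORFs can be supplied instead, and all
downstream logic (NMD, ORF-identity during consolidation) is agnostic to
the ORF's provenance.

NMD is predicted by the 50-nt rule: a transcript is a predicted
nonsense-mediated-decay target when its stop codon lies strictly more than
50 nt upstream of the last exon–exon junction.

TSS/TTS features (transposable-element overlap, CAGE peaks, polyA sites)
use a symmetric ±100 bp window around the strand-aware end coordinate;
polyA motifs (AATAAA, ATTAAA by default) are scanned in the terminal 50 nt
of the transcript sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .model import AnnotationTrack, FlicurateError, GenomicInterval, TranscriptModel

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
STOP_CODONS = ("TAA", "TAG", "TGA")
DEFAULT_POLYA_MOTIFS = ("AATAAA", "ATTAAA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def transcript_sequence(t: TranscriptModel, genome) -> str:
    """Assemble the spliced transcript sequence, strand-aware.

    ``genome`` is any mapping of chromosome name to a sliceable sequence —
    a ``pyfaidx.Fasta``, a ``dict[str, str]``, or a Biopython ``SeqRecord``
    dict all work.
    """
    try:
        contig = genome[t.chrom]
    except KeyError:
        raise FlicurateError(f"{t.transcript_id}: contig {t.chrom!r} absent from FASTA")
    parts = []
    for exon in t.exons:
        piece = str(contig[exon.start : exon.end]).upper()
        if len(piece) != exon.length:
            raise FlicurateError(
                f"{t.transcript_id}: exon [{exon.start},{exon.end}) extends past "
                f"the end of contig {t.chrom!r}"
            )
        parts.append(piece)
    seq = "".join(parts)
    return reverse_complement(seq) if t.strand == "-" else seq


@dataclass(frozen=True)
class ORF:
    """An open reading frame in transcript coordinates (0-based half-open,
    stop codon included). ``genomic_blocks`` are the corresponding genomic
    intervals, used for ORF-identity checks during consolidation."""

    transcript_id: str
    start: int
    end: int
    genomic_blocks: tuple[GenomicInterval, ...]
    protein_length: int

    @property
    def length_nt(self) -> int:
        return self.end - self.start


def transcript_range_to_genomic(
    t: TranscriptModel, tstart: int, tend: int
) -> tuple[GenomicInterval, ...]:
    """Map a transcript-coordinate interval onto genomic blocks.

    Blocks are returned in genomic order, consistent with the exon
    structure; on the − strand the transcript runs right-to-left across
    the exons.
    """
    if not (0 <= tstart < tend <= t.length):
        raise FlicurateError(
            f"{t.transcript_id}: transcript range [{tstart},{tend}) outside 0..{t.length}"
        )
    blocks: list[GenomicInterval] = []
    offset = 0
    for exon in t.exons_in_transcription_order():
        lo = max(tstart, offset)
        hi = min(tend, offset + exon.length)
        if lo < hi:
            if t.strand == "+":
                g_lo = exon.start + (lo - offset)
                g_hi = exon.start + (hi - offset)
            else:
                g_hi = exon.end - (lo - offset)
                g_lo = exon.end - (hi - offset)
            blocks.append(GenomicInterval(t.chrom, g_lo, g_hi, t.strand))
        offset += exon.length
    return tuple(sorted(blocks, key=lambda b: b.start))


def _orfs_in_frame(seq: str, frame: int) -> Iterable[tuple[int, int]]:
    """All maximal ATG→stop ORFs in one frame as (start, end) including the
    stop codon; the start is the 5'-most ATG before the stop."""
    start = None
    for pos in range(frame, len(seq) - 2, 3):
        codon = seq[pos : pos + 3]
        if codon in STOP_CODONS:
            if start is not None:
                yield start, pos + 3
            start = None
        elif codon == "ATG" and start is None:
            start = pos
    # an ORF without a stop codon is not reported: the model requires a
    # complete coding sequence ending in a stop


def predict_orf(
    t: TranscriptModel, genome, min_len_nt: int = 300
) -> ORF | None:
    """Longest ATG→stop ORF (three forward frames) of length >= min_len_nt.

    Ties on length are broken toward the 5'-most start. Returns None when
    no qualifying ORF exists; the transcript is then non-coding.
    """
    seq = transcript_sequence(t, genome)
    best: tuple[int, int] | None = None
    for frame in range(3):
        for start, end in _orfs_in_frame(seq, frame):
            if end - start < min_len_nt:
                continue
            if best is None or (end - start, -start) > (best[1] - best[0], -best[0]):
                best = (start, end)
    if best is None:
        return None
    start, end = best
    return ORF(
        transcript_id=t.transcript_id,
        start=start,
        end=end,
        genomic_blocks=transcript_range_to_genomic(t, start, end),
        protein_length=(end - start) // 3 - 1,
    )


def last_junction_position(t: TranscriptModel) -> int:
    """Transcript-coordinate position of the last exon–exon junction
    (distance from the 5' end to the start of the last exon)."""
    if not t.is_spliced:
        raise FlicurateError(f"{t.transcript_id}: unspliced transcript has no junction")
    return t.length - t.exons_in_transcription_order()[-1].length


def predict_nmd(t: TranscriptModel, orf: ORF, rule_nt: int = 50) -> bool:
    """50-nt rule: NMD is predicted when the stop codon ends strictly more
    than ``rule_nt`` nucleotides upstream of the last exon–exon junction."""
    if orf is None:
        raise FlicurateError(f"{t.transcript_id}: NMD prediction needs a coding ORF")
    return (last_junction_position(t) - orf.end) > rule_nt


def tss_feature_overlap(
    t: TranscriptModel,
    track: AnnotationTrack,
    window: int = 100,
    anchor: str = "TSS",
) -> tuple[bool, str | None]:
    """Does any track interval fall within ±window bp of the transcript end?

    ``anchor`` selects the strand-aware TSS or TTS coordinate; the window
    is closed on both sides (an interval ending exactly ``window`` bp away
    still counts). Returns (hit, label of the first overlapping interval
    in genomic order).
    """
    if anchor not in ("TSS", "TTS"):
        raise ValueError("anchor must be 'TSS' or 'TTS'")
    point = t.tss if anchor == "TSS" else t.tts
    lo = max(0, point - window)
    hi = point + window + 1  # closed window in half-open arithmetic
    hits = track.query(t.chrom, lo, hi, strand=t.strand if track.stranded else None)
    if not hits:
        return False, None
    first = hits[0]
    return True, first.label or track.name


def polya_motif_scan(
    t: TranscriptModel,
    genome,
    motifs: Sequence[str] = DEFAULT_POLYA_MOTIFS,
    search_len: int = 50,
) -> str | None:
    """Scan the 3'-terminal ``search_len`` nt for a polyadenylation motif.

    When several motif occurrences exist, the 3'-most one wins. Returns the
    motif string or None.
    """
    seq = transcript_sequence(t, genome)
    tail = seq[-search_len:]
    best_pos, best_motif = -1, None
    for motif in motifs:
        pos = tail.rfind(motif.upper())
        if pos > best_pos:
            best_pos, best_motif = pos, motif.upper()
    return best_motif


@dataclass
class FunctionalFlags:
    """Per-transcript functional annotation record."""

    coding: bool = False
    nmd: bool = False
    te_tss: bool = False
    te_label: str | None = None
    cage_tss: bool = False
    polya_site: bool = False
    polya_motif: str | None = None

    def __post_init__(self) -> None:
        if self.nmd and not self.coding:
            raise FlicurateError("NMD flag requires a coding transcript")
        if self.te_tss and not self.te_label:
            raise FlicurateError("TE overlap requires a TE label")


def annotate_transcript(
    t: TranscriptModel,
    genome=None,
    orf: ORF | None = None,
    te_track: AnnotationTrack | None = None,
    cage_track: AnnotationTrack | None = None,
    polya_track: AnnotationTrack | None = None,
    window: int = 100,
    min_orf_nt: int = 300,
    polya_motifs: Sequence[str] = DEFAULT_POLYA_MOTIFS,
) -> tuple[FunctionalFlags, ORF | None]:
    """Full functional annotation of one transcript.

    An externally predicted ``orf`` takes precedence over the built-in
    finder; without a genome and without an external ORF the transcript is
    annotated as non-coding and sequence-level features are skipped.
    """
    if orf is None and genome is not None:
        orf = predict_orf(t, genome, min_len_nt=min_orf_nt)
    coding = orf is not None
    nmd = bool(coding and t.is_spliced and predict_nmd(t, orf))
    te_hit, te_label = (False, None)
    if te_track is not None:
        te_hit, te_label = tss_feature_overlap(t, te_track, window=window, anchor="TSS")
    cage_hit = False
    if cage_track is not None:
        cage_hit, _ = tss_feature_overlap(t, cage_track, window=window, anchor="TSS")
    polya_hit = False
    if polya_track is not None:
        polya_hit, _ = tss_feature_overlap(t, polya_track, window=window, anchor="TTS")
    motif = polya_motif_scan(t, genome, motifs=polya_motifs) if genome is not None else None
    return (
        FunctionalFlags(
            coding=coding,
            nmd=nmd,
            te_tss=te_hit,
            te_label=te_label,
            cage_tss=cage_hit,
            polya_site=polya_hit,
            polya_motif=motif,
        ),
        orf,
    )


def write_annotation_tsv(
    rows: Iterable[tuple[TranscriptModel, str, FunctionalFlags, ORF | None]],
    path: str | Path,
) -> None:
    """Annotation table: one row per transcript with category and flags."""
    with open(path, "wt") as out:
        out.write(
            "transcript_id\tlength\tn_exons\tcategory\tcoding\tnmd\tcage_tss\t"
            "polya_site\tpolya_motif\tte_tss\tte_label\torf_protein_length\n"
        )
        for t, category, flags, orf in rows:
            out.write(
                "\t".join(
                    [
                        t.transcript_id,
                        str(t.length),
                        str(t.n_exons),
                        category,
                        str(flags.coding).lower(),
                        str(flags.nmd).lower(),
                        str(flags.cage_tss).lower(),
                        str(flags.polya_site).lower(),
                        flags.polya_motif or ".",
                        str(flags.te_tss).lower(),
                        flags.te_label or ".",
                        str(orf.protein_length) if orf else ".",
                    ]
                )
                + "\n"
            )
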