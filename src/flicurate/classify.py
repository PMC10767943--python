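"""Structural classification of long-read transcripts against a reference.

Each spliced transcript gets exactly one of six categories:

* **FSM** (full-splice match): intron chain exactly equals a reference
  transcript's chain.
* **ISM** (incomplete splice match): intron chain is a contiguous sub-chain
  of some reference chain — a likely truncation artifact from RNA
  degradation or incomplete reverse transcription; removed from the
  curated catalog.
* **antisense**: overlaps reference gene(s) only on the opposite strand.
* **intergenic**: overlaps no reference gene at all.
* **NIC** (novel in catalog): every splice site is known to the reference,
  but the junction combination is novel.
* **NNC** (novel not in catalog): at least one splice site is absent from
  the reference.

The decision cascade evaluates in that order, so a transcript overlapping
no same-strand gene is never called NIC/NNC (those categories are defined
relative to a gene's known sites).
"""

from __future__ import annotations

import collections
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .model import FlicurateError, Intron, ReferenceIndex, TranscriptModel


class StructuralCategory(str, enum.Enum):
    FSM = "FSM"
    ISM = "ISM"
    NIC = "NIC"
    NNC = "NNC"
    ANTISENSE = "antisense"
    INTERGENIC = "intergenic"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class ClassificationResult:
    transcript_id: str
    category: StructuralCategory
    assigned_gene: str | None = None
    matched_reference_transcript: str | None = None
    novel_splice_sites: list[tuple[str, str, int]] = field(default_factory=list)
    novel_junctions: list[Intron] = field(default_factory=list)


def assign_locus(t: TranscriptModel, ref: ReferenceIndex) -> str:
    """Assign a transcript to a reference gene, or call it antisense/intergenic.

    Returns a gene id when any same-strand reference gene's exons overlap
    the transcript's exons (ties broken by exonic-overlap bp, then
    gene-span overlap, then lexicographic gene id); ``"antisense"`` when
    only an opposite-strand gene span overlaps the transcript span;
    ``"intergenic"`` otherwise.
    """
    exonic_bp: dict[str, int] = collections.Counter()
    for exon in t.exons:
        for begin, end, gid in ref.exonic_overlaps(t.chrom, t.strand, exon.start, exon.end):
            exonic_bp[gid] += min(end, exon.end) - max(begin, exon.start)
    if exonic_bp:
        def span_overlap(gid: str) -> int:
            span = ref.genes[gid]
            return max(0, min(span.end, t.end) - max(span.start, t.start))

        best = min(exonic_bp, key=lambda g: (-exonic_bp[g], -span_overlap(g), g))
        return best
    if any(
        span.strand != t.strand
        for _gid, span in ref.gene_span_overlaps(t.chrom, t.start, t.end)
    ):
        return "antisense"
    return "intergenic"


def _is_contiguous_subchain(
    chain: tuple[Intron, ...], ref: ReferenceIndex
) -> str | None:
    """Return a reference transcript id containing ``chain`` as a contiguous
    sub-chain of its intron chain, or None."""
    first = chain[0]
    hits = ref.intron_occurrences.get(first, ())
    matches = []
    for tid, idx in hits:
        ref_chain = ref.transcripts[tid].intron_chain()
        if ref_chain[idx : idx + len(chain)] == chain:
            matches.append(tid)
    return min(matches) if matches else None


def classify_transcript(t: TranscriptModel, ref: ReferenceIndex) -> ClassificationResult:
    """Classify one spliced transcript with the six-category cascade."""
    if not t.is_spliced:
        raise FlicurateError(
            f"{t.transcript_id}: classification requires a spliced transcript "
            "(mono-exonic models are filtered upstream)"
        )
    chain = t.intron_chain()

    ref_tids = ref.intron_chains.get(chain)
    if ref_tids:
        matched = min(ref_tids)
        return ClassificationResult(
            t.transcript_id,
            StructuralCategory.FSM,
            assigned_gene=ref.transcripts[matched].gene_id or matched,
            matched_reference_transcript=matched,
        )

    sub_match = _is_contiguous_subchain(chain, ref)
    if sub_match is not None:
        return ClassificationResult(
            t.transcript_id,
            StructuralCategory.ISM,
            assigned_gene=ref.transcripts[sub_match].gene_id or sub_match,
            matched_reference_transcript=sub_match,
        )

    locus = assign_locus(t, ref)
    if locus == "antisense":
        return ClassificationResult(t.transcript_id, StructuralCategory.ANTISENSE)
    if locus == "intergenic":
        return ClassificationResult(t.transcript_id, StructuralCategory.INTERGENIC)

    sites = sorted(t.splice_sites())
    novel_sites = [s for s in sites if s not in ref.splice_sites]
    if not novel_sites:
        novel_junctions = [j for j in chain if j not in ref.junctions]
        return ClassificationResult(
            t.transcript_id,
            StructuralCategory.NIC,
            assigned_gene=locus,
            novel_junctions=novel_junctions,
        )
    return ClassificationResult(
        t.transcript_id,
        StructuralCategory.NNC,
        assigned_gene=locus,
        novel_splice_sites=novel_sites,
    )


def classify_and_prune(
    transcripts: Iterable[TranscriptModel],
    ref: ReferenceIndex,
    remove: Sequence[StructuralCategory] = (StructuralCategory.ISM,),
) -> tuple[list[tuple[TranscriptModel, ClassificationResult]], dict[str, int]]:
    """Classify every transcript and drop the removal categories (ISM by
    default — truncation artifacts). Returns the surviving (transcript,
    result) pairs in input order and the full category tally including the
    removed transcripts."""
    tally: dict[str, int] = collections.Counter()
    kept: list[tuple[TranscriptModel, ClassificationResult]] = []
    for t in transcripts:
        res = classify_transcript(t, ref)
        tally[res.category.value] += 1
        if res.category not in remove:
            kept.append((t, res))
    return kept, dict(tally)


def write_classification_tsv(
    results: Iterable[ClassificationResult], path: str | Path
) -> None:
    """Per-transcript classification table (one row per transcript)."""
    with open(path, "wt") as out:
        out.write(
            "transcript_id\tcategory\tassigned_gene\t"
            "matched_reference_transcript\tn_novel_sites\tn_novel_junctions\n"
        )
        for r in results:
            out.write(
                f"{r.transcript_id}\t{r.category.value}\t"
                f"{r.assigned_gene or '.'}\t{r.matched_reference_transcript or '.'}\t"
                f"{len(r.novel_splice_sites)}\t{len(r.novel_junctions)}\n"
            )
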