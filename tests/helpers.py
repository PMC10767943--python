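"""Independent oracles and small builders shared across the test suite.

The brute-force classifier here deliberately avoids the package's
ReferenceIndex lookups: it enumerates reference chains, sites and exons
directly, so agreement with the cascade classifier is a genuine
cross-check rather than the same code twice.
"""

from __future__ import annotations

from flicurate.model import TranscriptModel


def make_transcript(
    tid: str,
    intervals,
    strand: str = "+",
    chrom: str = "chr1",
    gene_id: str | None = None,
    samples=(),
) -> TranscriptModel:
    return TranscriptModel.from_intervals(
        tid, chrom, strand, intervals, gene_id=gene_id, source_samples=samples
    )


def brute_force_classify(t: TranscriptModel, reference: list[TranscriptModel]) -> str:
    """Six-category classification by exhaustive enumeration.

    Checks, in order: exact chain equality (FSM); contiguous sub-chain at
    every possible offset of every reference chain (ISM); direct
    exon-by-exon overlap scan for locus assignment (antisense /
    intergenic); exhaustive set membership of every splice site (NIC vs
    NNC).
    """
    chain = t.intron_chain()
    ref_chains = {r.transcript_id: r.intron_chain() for r in reference}

    for rc in ref_chains.values():
        if chain == rc:
            return "FSM"
    k = len(chain)
    for rc in ref_chains.values():
        for off in range(0, len(rc) - k + 1):
            if tuple(rc[off : off + k]) == chain:
                return "ISM"

    # locus: same-strand exonic overlap with any reference gene
    same_strand_overlap = False
    opposite_span_overlap = False
    for r in reference:
        if r.chrom != t.chrom:
            continue
        span_hit = min(r.end, t.end) > max(r.start, t.start)
        if r.strand == t.strand:
            for re_ in r.exons:
                for te in t.exons:
                    if min(re_.end, te.end) > max(re_.start, te.start):
                        same_strand_overlap = True
        elif span_hit:
            opposite_span_overlap = True
    if not same_strand_overlap:
        return "antisense" if opposite_span_overlap else "intergenic"

    all_sites = set()
    all_junctions = set()
    for r in reference:
        for j in r.intron_chain():
            all_junctions.add(j)
            all_sites.update(j.sites)
    t_sites = set()
    for j in chain:
        t_sites.update(j.sites)
    if t_sites <= all_sites:
        return "NIC"
    return "NNC"
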