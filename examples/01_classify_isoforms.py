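"""Classify long-read isoforms against a reference annotation.

Builds a two-gene reference in memory, constructs query isoforms with
known relationships to it, and prints the structural category the
classifier assigns to each.
"""

from flicurate import ReferenceIndex, TranscriptModel, classify_transcript

# reference: one 4-exon gene on +, one 2-exon gene on -
ref = ReferenceIndex(
    [
        TranscriptModel.from_intervals(
            "GENE1.t1", "chr1", "+",
            [(1000, 1200), (1400, 1600), (1800, 2000), (2200, 2400)],
            gene_id="GENE1",
        ),
        TranscriptModel.from_intervals(
            "GENE2.t1", "chr1", "-", [(9000, 9300), (9500, 9800)], gene_id="GENE2"
        ),
    ]
)

queries = {
    "same chain, shorter ends": TranscriptModel.from_intervals(
        "q1", "chr1", "+",
        [(1050, 1200), (1400, 1600), (1800, 2000), (2200, 2300)]
    ),
    "truncated to the last 2 introns": TranscriptModel.from_intervals(
        "q2", "chr1", "+", [(1450, 1600), (1800, 2000), (2200, 2400)]
    ),
    "exon 2 skipped (known sites, new junction)": TranscriptModel.from_intervals(
        "q3", "chr1", "+", [(1000, 1200), (1800, 2000), (2200, 2400)]
    ),
    "splice donor shifted 7 bp (new site)": TranscriptModel.from_intervals(
        "q4", "chr1", "+",
        [(1000, 1193), (1400, 1600), (1800, 2000), (2200, 2400)]
    ),
    "opposite strand of GENE1": TranscriptModel.from_intervals(
        "q5", "chr1", "-", [(1100, 1300), (1500, 1700)]
    ),
    "empty region": TranscriptModel.from_intervals(
        "q6", "chr1", "+", [(50000, 50200), (50400, 50600)]
    ),
}

for description, t in queries.items():
    res = classify_transcript(t, ref)
    gene = res.assigned_gene or "-"
    print(f"{t.transcript_id}  {res.category.value:<10s} gene={gene:<6s} ({description})")

# FSM = full-splice match (kept), ISM = truncation artifact (removed from
# the catalog), NIC/NNC = novel junction combinations / novel splice sites,
# antisense/intergenic = outside any same-strand annotated gene.
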