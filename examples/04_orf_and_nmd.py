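"""Predict an ORF and apply the 50-nt NMD rule.

Builds a two-exon transcript and embeds a 300-nt ORF at several positions
so the stop codon lands at controlled distances upstream of the last
exon-exon junction. NMD (nonsense-mediated decay) is predicted only when
that distance strictly exceeds 50 nt.
"""

from flicurate import TranscriptModel, predict_nmd, predict_orf
from flicurate.annotate import last_junction_position
from flicurate.simulate import embed_orf

L1 = 420  # first exon length; the last junction sits at transcript position 420
t = TranscriptModel.from_intervals("t", "chr1", "+", [(50, 50 + L1), (600, 720)])

for distance in (0, 50, 51, 100):
    genome = embed_orf({"chr1": "C" * 1000}, t, orf_len_nt=300,
                       tstart=L1 - distance - 300)
    orf = predict_orf(t, genome, min_len_nt=300)
    nmd = predict_nmd(t, orf)
    print(
        f"stop ends {last_junction_position(t) - orf.end:3d} nt upstream of the "
        f"last junction: protein {orf.protein_length} aa, NMD predicted: {nmd}"
    )

# 50 nt is not enough (the rule is strictly greater than 50); 51 nt is.
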