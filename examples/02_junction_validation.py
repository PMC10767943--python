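"""Validate transcript models with short-read splice-junction support.

A transcript survives only if each of its introns was detected in at least
five short-read samples. The example builds evidence in which one of two
junctions falls short, and shows the boundary at exactly five samples.
"""

from flicurate import (
    JunctionEvidenceSet,
    TranscriptModel,
    ValidationParams,
    filter_by_junction_support,
)

t = TranscriptModel.from_intervals(
    "iso1", "chr1", "+", [(100, 200), (300, 400), (500, 600)]
)
j1, j2 = t.intron_chain()

for support_j2 in (5, 4):
    evidence = JunctionEvidenceSet()
    for i in range(7):
        counts = {j1: 12}  # j1 seen in all 7 samples
        if i < support_j2:
            counts[j2] = 3
        evidence.add_sample(f"sample{i}", counts)
    kept, report = filter_by_junction_support(
        [t], evidence, ValidationParams(min_samples=5)
    )
    status = "kept" if kept else f"dropped (weak junction {j2.start}-{j2.end})"
    print(f"junction 2 in {support_j2} samples -> {status}")

# "at least five samples" is inclusive: support of 5 keeps the transcript,
# 4 drops it and the report names the failing junction.
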