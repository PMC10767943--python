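"""Consolidate near-duplicate isoforms.

Three transcripts share an intron chain but their transcript ends wobble.
A and B are within the 100-bp end tolerance, as are B and C — but A and C
are not. The greedy longest-first rule resolves the non-transitive chain:
the longest transcript seeds the group and absorbs what is comparable to
it, so the catalog retains the transcript of extended length.
"""

from flicurate import TranscriptModel, comparable, consolidate


def isoform(tid, d_tss, d_tts, samples):
    return TranscriptModel.from_intervals(
        tid, "chr1", "+",
        [(1000 + d_tss, 1300), (1500, 1800), (2000, 2500 + d_tts)],
        source_samples=samples,
    )


a = isoform("A", -60, +60, {"patient1"})   # longest: extended at both ends
b = isoform("B", 0, 0, {"patient2"})
c = isoform("C", +60, -60, {"patient3"})   # shortest

for x, y in [(a, b), (b, c), (a, c)]:
    ok, reason = comparable(x, y)
    verdict = "comparable" if ok else f"not comparable ({reason})"
    print(f"{x.transcript_id} vs {y.transcript_id}: {verdict}")

representatives, groups = consolidate([a, b, c])
for g in groups:
    print(f"group: representative={g.representative} members={sorted(g.members)} "
          f"samples={sorted(g.merged_source_samples)}")

# A (1900+120 bp) absorbs B; C stays alone because its start is 120 bp from
# A's. The representative inherits the union of the members' source samples.
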