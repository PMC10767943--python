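# Methods

This note records the models, thresholds and design choices behind
`flicurate`, and what the synthetic fixtures do and do not demonstrate.

## Coordinates and the data model

All internal coordinates are 0-based half-open; GTF and STAR junction
tables (1-based inclusive) are converted at the I/O boundary and nowhere
else. A splice junction (intron) is keyed by `(chrom, strand, start,
end)`: donor/acceptor roles are derived from strand, but equality uses the
coordinate pair, so junctions at identical coordinates on opposite strands
are distinct. Transcripts with strand `.` are rejected at parse time
(counted and logged) because the antisense/intergenic calls are
strand-dependent. Duplicate transcript ids across query GTFs are suffixed
with an occurrence index; true structural duplicates are resolved later by
consolidation, not at parse time.

## Junction validation

A transcript is retained iff every intron in its chain was detected in at
least `min_samples = 5` distinct short-read samples, with at least
`min_unique_reads = 1` uniquely mapping reads per sample. The read
threshold is exposed because "detected" is the only stated requirement;
≥ 1 unique read is the weakest non-trivial reading. All provided junction
tables are pooled regardless of cohort — the criterion counts samples, not
cohorts. STAR's strand code 0 (undefined) registers a junction on both
strands, since such evidence can support a transcript intron on either
strand. Mono-exonic transcripts are dropped by policy (reason
`unspliced`): the curated product is a catalog of spliced isoforms and the
junction criterion is vacuous for them; `keep_monoexonic` passes them
through for other uses.

## Structural classification

The cascade is: FSM (exact chain match) → ISM (contiguous sub-chain) →
antisense/intergenic (locus assignment) → NIC (all sites known) → NNC.
Decisions embedded in it:

* **ISM is any contiguous sub-chain**, not only 3′-anchored ones, because
  the artifacts it models (RNA degradation, incomplete reverse
  transcription) truncate transcripts from either end.
* **Splice-site novelty is positional and strand-specific**; donors and
  acceptors share one site set — a query donor matching a reference
  acceptor coordinate counts as known.
* **Locus assignment precedes NIC/NNC**: a transcript with no same-strand
  exonic overlap with any reference gene is antisense (opposite-strand
  span overlap) or intergenic, never NIC/NNC, because junction/site
  novelty is only meaningful relative to a gene's known sites. Gene ties
  are broken by exonic-overlap bp, then gene-span overlap, then
  lexicographic gene id, so runs are reproducible.
* ISM transcripts are tallied and then removed from the catalog.

## Consolidation

Two spliced transcripts are *comparable* iff all of: same chrom/strand;
same exon count; for each exon, the summed absolute shift of its internal
(splice-site) boundaries is ≤ 4 bp (a switch applies the cap per boundary
instead — the prose the thresholds come from does not disambiguate); the
number of exons with any boundary shift is ≤ 3; the strand-aware TSS and
TTS each differ by ≤ 100 bp; and, when both transcripts are coding, the
ORF genomic coordinates are identical. "An exonic variation" is read as
"an exon whose boundaries differ between the two transcripts"; the per-exon
4-bp cap governs internal boundaries and the 100-bp cap the two outer
ends — the one reading under which the three numbers (3, 4, 100) act on
disjoint parts of the structure.

Comparability is not transitive, so clustering is greedy and
deterministic: sort by (length desc, start, transcript id); the first
unassigned transcript seeds a group and absorbs every remaining comparable
transcript. The seed — longest by construction — is the representative,
implementing the preference for retaining transcripts of extended length,
and inherits the union of the members' source samples. Consolidation runs
within (assigned locus, category) bins so FSM and NNC structures are never
merged. The pipeline predicts ORFs before consolidating because the
ORF-identity clause needs them; full annotation still happens afterwards
on the representatives only.

## Functional annotation

* **ORF**: longest ATG→stop reading frame across the three forward frames
  of the spliced, strand-aware transcript sequence, minimum 300 nt
  (100 codons) including the stop; ties go to the 5′-most start. An ORF
  without a stop codon is not called. This is a deliberate longest-ORF
  model — externally predicted ORFs (e.g. from a dedicated gene predictor)
  can be supplied per transcript and flow through NMD and consolidation
  identically.
* **NMD**: predicted iff `(last-junction position − ORF end) > 50` nt,
  strictly; a stop exactly 50 nt upstream, or in the last exon, is not an
  NMD target.
* **TSS/TTS features**: a TE or CAGE peak counts if it intersects the
  closed window ±100 bp around the strand-aware TSS (polyA sites: around
  the TTS). The ±100 bp window is stated for TEs; CAGE and polyA reuse it
  as the package's own default, and all windows are configurable.
* **polyA motif**: 3′-most occurrence of AATAAA/ATTAAA in the terminal
  50 nt of the transcript sequence — list and window follow common
  long-read QC practice and are configurable. Motif scan and polyA-site
  overlap are reported independently, not conjoined.

## Specific RNA transcripts

Tissue specificity is scored on one value per (transcript, tissue type) —
the median TPM over that type's samples, aggregation statistic
configurable. With ratios `p_it = x_it / Σ_i x_it`,
`S_t = log2(N) − H(p)` in bits, so `0 ≤ S_t ≤ log2(N)`, 0 for uniform
expression and `log2(N)` for a point mass; zero terms contribute 0 to the
entropy, and the ratio vector must sum to 1 within 1e−9. A transcript is
tissue-specific iff `p_(1) > 2·p_(2)` (passing when `p_(2) = 0 <
p_(1)`) and `S_t > 1`. All-zero transcripts get an undefined (NaN) score
and are flagged unexpressed rather than scored 0, to avoid fake
specificity.

Tumor-SRTs per cancer type `c`: (A) median tumor TPM over samples of `c`
≥ 10 × the maximum TPM over all normal samples — normal tissues excluding
testis, *pooled* with tumor-adjacent normals (the stricter of the two
readings of the criterion; a flag checks adjacent normals separately) —
with `median > 0` required when the normal maximum is 0; (B) TPM > 0.5 in
strictly more than 5 % of the tumor samples of `c`. "At least 10-fold" is
≥; the TPM floor and the 5 % prevalence are strict, read literally from
their comparators. Long-read tumor specificity (a transcript observed
exclusively in tumor long-read samples) is a simple set difference over
source-sample cohort labels.

## Synthetic fixtures

The generator plants truth *by construction* and never invokes the
classifier or the SRT callers, so tests against the truth are not
circular. Defaults: 30 genes of 4–8 exons (80–300 bp exons, 60–400 bp
introns) on one toy chromosome; 5 planted transcripts per category;
junction support drawn from 5–8 samples (supported) or 1–4 (unsupported,
one private intron of each of 3 designated transcripts); expression over
3 cancer types × 40 tumor + 10 adjacent-normal samples and 22 normal
tissue types × 5 samples, background ~5 TPM log-normal, with 3 tumor-SRTs
planted at 20 TPM in 70 % of one cancer type's tumors against ~0.1 TPM
normals (testis 0.3) and 3 tissue-SRTs confined to one tissue at 30 TPM;
multiplicative log-normal noise σ = 0.5 and 5 % dropout. The planted
prevalence is 0.7 because the median-based fold criterion cannot hold for
a transcript expressed in under half the tumor samples; prevalence near
the 5 % threshold is exercised separately in unit tests. Genome sequence
is uniform random; coding fixtures embed ORFs explicitly (a CTG-repeat
codon body guarantees the embedded ORF is the only one the payload can
create).

What the fixtures do **not** model: realistic splice-site motifs, GC
structure or repeat content; correlated noise, batch or library-size
effects in TPM; overlapping genes and multi-isoform loci; long-read
error profiles. Passing tests therefore demonstrate the correctness of
the decision logic under its stated definitions, not performance on real
cohorts.

## Problem sizes and numerical choices

Tests and the acceptance script use fixtures of 12–30 genes and
30–40-transcript expression matrices, with 100 seeded fixtures for the
classification cross-check and 5 replicates for noisy SRT recovery —
sizes chosen so the whole suite replays in seconds while every code path
is exercised. The ratio-normalization tolerance is 1e−9; TPM values are
float64 throughout; all randomness flows from a single integer seed
through named `numpy` generator streams, and pipeline outputs are written
with sorted keys so reruns are byte-identical.

## Known limitations

* Classification implements one coherent cascade; tools built on the same
  category names differ in corner cases (e.g. mono-exonic handling,
  ISM anchoring, genic-intron transcripts), so counts are not
  bug-for-bug comparable with any particular external tool.
* The longest-ORF model ignores Kozak context and selects a single ORF;
  upstream ORFs and non-AUG starts are out of scope.
* `comparable()` requires equal exon counts; merging across different
  exon numbers (e.g. an unspliced retained intron variant) is never
  attempted.
* Survival/differential statistics on SRTs, read-level processing
  (alignment, collapse, quantification) and database/web layers are out
  of scope; the pipeline starts from a merged GTF and TPM matrices.
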