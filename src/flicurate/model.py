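"""Coordinate-aware data model for spliced transcript curation.

All internal coordinates are 0-based, half-open ``[start, end)``. GTF and
STAR junction files use 1-based inclusive coordinates; the readers in
:mod:`flicurate.gtf` and :mod:`flicurate.junctions` convert on the way in
and out, so arithmetic on intron keys and overlaps is unambiguous
everywhere else.

The central objects are:

* :class:`TranscriptModel` — one spliced isoform as an ordered exon list,
  with its intron chain derivable on demand.
* :class:`ReferenceIndex` — a reference annotation indexed for the lookups
  structural classification needs: splice-site set, junction set, intron
  chains, and interval trees for gene-overlap queries.
* :class:`JunctionEvidenceSet` — short-read splice-junction support,
  per sample and aggregated to per-junction sample counts.
* :class:`AnnotationTrack` — a named interval track (TE, CAGE peaks,
  polyA sites) indexed for window queries.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

from intervaltree import IntervalTree

STRANDS = ("+", "-")


class FlicurateError(Exception):
    """Base class for errors raised by this package."""


class GtfParseError(FlicurateError):
    """A GTF record could not be parsed; the message names file and line."""


class JunctionTableError(FlicurateError):
    """A junction table row could not be parsed."""


class ModelValidationError(FlicurateError):
    """A domain-object invariant was violated."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open.

    ``label`` carries an optional annotation name (e.g. a TE family such
    as L1PA2) when the interval belongs to an :class:`AnnotationTrack`.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"
    label: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ModelValidationError(
                f"interval requires 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ModelValidationError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Exon:
    """One exon of a transcript; ``rank`` is 1-based in transcription order
    (rank 1 is the 5'-most exon, i.e. the rightmost exon on the − strand)."""

    interval: GenomicInterval
    rank: int

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True, order=True)
class Intron:
    """A splice junction keyed by (chrom, strand, start, end).

    ``start``/``end`` are the genomic half-open bounds of the intron.
    Donor and acceptor are derived from strand, but equality and hashing
    use the coordinate pair, so + and − introns at identical coordinates
    are distinct junctions.
    """

    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ModelValidationError(
                f"intron requires start < end, got ({self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ModelValidationError(f"intron strand must be +/-, got {self.strand!r}")

    @property
    def donor(self) -> int:
        """Genomic coordinate of the exon/intron boundary on the intron's 5' side."""
        return self.start if self.strand == "+" else self.end

    @property
    def acceptor(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def sites(self) -> tuple[tuple[str, str, int], ...]:
        """The two splice sites as (chrom, strand, position) keys."""
        return (
            (self.chrom, self.strand, self.start),
            (self.chrom, self.strand, self.end),
        )


@dataclass(frozen=True)
class TranscriptModel:
    """One spliced transcript: ordered exons on a single chrom/strand.

    Exons are stored in genomic order; ranks encode transcription order.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[Exon, ...]
    gene_id: str | None = None
    source_samples: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.exons:
            raise ModelValidationError(f"{self.transcript_id}: transcript needs >=1 exon")
        if self.strand not in STRANDS:
            raise ModelValidationError(
                f"{self.transcript_id}: strand must be +/-, got {self.strand!r}"
            )
        prev_end = -1
        for exon in self.exons:
            if exon.interval.chrom != self.chrom or exon.interval.strand != self.strand:
                raise ModelValidationError(
                    f"{self.transcript_id}: exon chrom/strand conflicts with transcript"
                )
            if exon.start < prev_end:
                raise ModelValidationError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = exon.end
        n = len(self.exons)
        expected = range(1, n + 1) if self.strand == "+" else range(n, 0, -1)
        if tuple(e.rank for e in self.exons) != tuple(expected):
            raise ModelValidationError(
                f"{self.transcript_id}: exon ranks do not follow 5'->3' order"
            )

    @classmethod
    def from_intervals(
        cls,
        transcript_id: str,
        chrom: str,
        strand: str,
        intervals: Sequence[tuple[int, int]],
        gene_id: str | None = None,
        source_samples: Iterable[str] = (),
    ) -> "TranscriptModel":
        """Build a transcript from (start, end) pairs in any order."""
        ivs = sorted(intervals)
        n = len(ivs)
        exons = tuple(
            Exon(
                GenomicInterval(chrom, s, e, strand),
                rank=(i + 1) if strand == "+" else (n - i),
            )
            for i, (s, e) in enumerate(ivs)
        )
        return cls(
            transcript_id=transcript_id,
            chrom=chrom,
            strand=strand,
            exons=exons,
            gene_id=gene_id,
            source_samples=frozenset(source_samples),
        )

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def is_spliced(self) -> bool:
        return len(self.exons) > 1

    @property
    def tss(self) -> int:
        """Strand-aware transcription start site (single 0-based coordinate)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        """Strand-aware transcription termination site."""
        return self.end - 1 if self.strand == "+" else self.start

    def intron_chain(self) -> tuple[Intron, ...]:
        """The n−1 introns of an n-exon transcript, in genomic order."""
        return tuple(
            Intron(self.chrom, self.strand, a.end, b.start)
            for a, b in zip(self.exons, self.exons[1:])
        )

    def splice_sites(self) -> set[tuple[str, str, int]]:
        sites: set[tuple[str, str, int]] = set()
        for intron in self.intron_chain():
            sites.update(intron.sites)
        return sites

    def exons_in_transcription_order(self) -> tuple[Exon, ...]:
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    def with_samples(self, samples: Iterable[str]) -> "TranscriptModel":
        return replace(self, source_samples=frozenset(samples))


def chain_key(transcript: TranscriptModel) -> tuple[Intron, ...]:
    """The identity key for structural comparison: the full intron chain."""
    return transcript.intron_chain()


class ReferenceIndex:
    """Reference annotation indexed for structural classification.

    Exposes:

    * ``splice_sites`` — set of (chrom, strand, position) over all reference
      donors and acceptors;
    * ``junctions`` — set of reference :class:`Intron` keys;
    * ``intron_chains`` — full chain key → reference transcript ids;
    * exonic and gene-span interval trees for locus assignment.
    """

    def __init__(
        self,
        transcripts: Iterable[TranscriptModel],
        gene_spans: Mapping[str, GenomicInterval] | None = None,
    ) -> None:
        self.transcripts: dict[str, TranscriptModel] = {}
        self.splice_sites: set[tuple[str, str, int]] = set()
        self.junctions: set[Intron] = set()
        self.intron_chains: dict[tuple[Intron, ...], list[str]] = {}
        #: intron key -> list of (transcript_id, index within that chain)
        self.intron_occurrences: dict[Intron, list[tuple[str, int]]] = (
            collections.defaultdict(list)
        )
        self._exon_trees: dict[tuple[str, str], IntervalTree] = (
            collections.defaultdict(IntervalTree)
        )
        self._gene_trees: dict[str, IntervalTree] = collections.defaultdict(IntervalTree)
        self.genes: dict[str, GenomicInterval] = {}

        gene_bounds: dict[str, list] = {}
        for t in transcripts:
            if t.transcript_id in self.transcripts:
                raise ModelValidationError(
                    f"duplicate reference transcript id {t.transcript_id!r}"
                )
            self.transcripts[t.transcript_id] = t
            chain = t.intron_chain()
            if chain:
                self.intron_chains.setdefault(chain, []).append(t.transcript_id)
            for i, intron in enumerate(chain):
                self.junctions.add(intron)
                self.splice_sites.update(intron.sites)
                self.intron_occurrences[intron].append((t.transcript_id, i))
            gid = t.gene_id or t.transcript_id
            for exon in t.exons:
                self._exon_trees[(t.chrom, t.strand)].addi(exon.start, exon.end, gid)
            b = gene_bounds.setdefault(gid, [t.chrom, t.strand, t.start, t.end])
            b[2] = min(b[2], t.start)
            b[3] = max(b[3], t.end)

        for gid, (chrom, strand, start, end) in gene_bounds.items():
            span = GenomicInterval(chrom, start, end, strand)
            self.genes[gid] = span
        if gene_spans:
            # explicit gene records (e.g. GTF "gene" features) widen the
            # spans inferred from transcripts
            for gid, span in gene_spans.items():
                old = self.genes.get(gid)
                if old is None:
                    self.genes[gid] = span
                else:
                    self.genes[gid] = GenomicInterval(
                        span.chrom,
                        min(span.start, old.start),
                        max(span.end, old.end),
                        span.strand,
                    )
        for gid, span in self.genes.items():
            self._gene_trees[span.chrom].addi(span.start, span.end, (gid, span.strand))

    def __len__(self) -> int:
        return len(self.transcripts)

    def exonic_overlaps(
        self, chrom: str, strand: str, start: int, end: int
    ) -> list[tuple[int, int, str]]:
        """Same-strand reference exon intervals overlapping [start, end)."""
        tree = self._exon_trees.get((chrom, strand))
        if tree is None:
            return []
        return [(iv.begin, iv.end, iv.data) for iv in tree.overlap(start, end)]

    def gene_span_overlaps(
        self, chrom: str, start: int, end: int
    ) -> list[tuple[str, GenomicInterval]]:
        tree = self._gene_trees.get(chrom)
        if tree is None:
            return []
        return [(iv.data[0], self.genes[iv.data[0]]) for iv in tree.overlap(start, end)]


class JunctionEvidenceSet:
    """Short-read splice-junction evidence.

    Holds one map ``Intron -> unique-read count`` per sample, and computes
    the aggregate number of samples supporting each junction at a given
    per-sample minimum unique-read count.
    """

    def __init__(self) -> None:
        self.per_sample: dict[str, dict[Intron, int]] = {}

    @property
    def n_samples(self) -> int:
        return len(self.per_sample)

    def add_sample(self, sample: str, counts: Mapping[Intron, int]) -> None:
        if sample in self.per_sample:
            raise ModelValidationError(f"sample {sample!r} already present")
        for c in counts.values():
            if c < 0:
                raise ModelValidationError("unique-read counts must be non-negative")
        self.per_sample[sample] = dict(counts)

    def aggregate(self, min_unique_reads: int = 1) -> dict[Intron, int]:
        """Per-junction count of samples with >= min_unique_reads unique reads.

        A threshold of 0 counts every sample in which the junction was
        reported at all (detection only).
        """
        agg: dict[Intron, int] = collections.Counter()
        for counts in self.per_sample.values():
            for intron, c in counts.items():
                if c >= min_unique_reads:
                    agg[intron] += 1
        return dict(agg)

    def support(self, intron: Intron, min_unique_reads: int = 1) -> int:
        return sum(
            1
            for counts in self.per_sample.values()
            if counts.get(intron, -1) >= min_unique_reads
        )


class AnnotationTrack:
    """A named interval track (TE, CAGE peak, polyA site) with overlap queries."""

    def __init__(
        self, name: str, intervals: Iterable[GenomicInterval], stranded: bool = False
    ) -> None:
        self.name = name
        self.stranded = stranded
        self.intervals = sorted(intervals)
        self._trees: dict[str, IntervalTree] = collections.defaultdict(IntervalTree)
        for iv in self.intervals:
            key = f"{iv.chrom}:{iv.strand}" if stranded else iv.chrom
            self._trees[key].addi(iv.start, iv.end, iv)

    def __len__(self) -> int:
        return len(self.intervals)

    def query(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> list[GenomicInterval]:
        """Intervals overlapping [start, end), sorted by genomic order."""
        if self.stranded:
            if strand is None:
                raise ModelValidationError(f"track {self.name!r} is stranded; pass strand")
            key = f"{chrom}:{strand}"
        else:
            key = chrom
        tree = self._trees.get(key)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.overlap(start, end))


def intron_chain(transcript: TranscriptModel) -> tuple[Intron, ...]:
    """Functional alias for :meth:`TranscriptModel.intron_chain`."""
    return transcript.intron_chain()
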