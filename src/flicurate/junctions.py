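"""Short-read splice-junction evidence and the junction-support filter.

A long-read transcript model survives curation only if every intron in its
chain was observed in short-read RNA-seq data in enough samples (default:
at least five). The evidence comes from STAR ``SJ.out.tab`` files, one per
short-read sample.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .model import (
    Intron,
    JunctionEvidenceSet,
    JunctionTableError,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

_STRAND_CODE = {"0": None, "1": "+", "2": "-"}


def read_junction_tables(
    paths: Sequence[str | Path], sample_names: Sequence[str] | None = None
) -> JunctionEvidenceSet:
    """Read STAR ``SJ.out.tab`` files, one per sample.

    Columns (tab-separated, no header): chrom, intron start (1-based, first
    base of intron), intron end (1-based, last base of intron), strand code
    (0 undefined / 1 + / 2 −), motif, annotated flag, unique reads,
    multi-mapping reads, max overhang.

    Junctions with strand code 0 are registered on both strands, since an
    undefined-strand short-read junction can support a transcript intron on
    either strand. Duplicate junctions within one file have their
    unique-read counts summed (with a warning).
    """
    if sample_names is None:
        sample_names = [Path(p).stem for p in paths]
    if len(sample_names) != len(paths):
        raise ValueError("sample_names must match paths")
    evidence = JunctionEvidenceSet()
    for sample, path in zip(sample_names, paths):
        counts: dict[Intron, int] = {}
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as handle:
            for lineno, line in enumerate(handle, start=1):
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9:
                    raise JunctionTableError(
                        f"{path}:{lineno}: expected 9 columns, got {len(fields)}"
                    )
                chrom = fields[0]
                try:
                    start = int(fields[1]) - 1  # 1-based first intron base
                    end = int(fields[2])  # 1-based last intron base -> half-open end
                    unique = int(fields[6])
                except ValueError:
                    raise JunctionTableError(f"{path}:{lineno}: non-integer field")
                if start < 0 or start >= end or unique < 0:
                    raise JunctionTableError(f"{path}:{lineno}: invalid junction row")
                strand = _STRAND_CODE.get(fields[3])
                if fields[3] not in _STRAND_CODE:
                    raise JunctionTableError(
                        f"{path}:{lineno}: unknown strand code {fields[3]!r}"
                    )
                strands = ("+", "-") if strand is None else (strand,)
                for s in strands:
                    key = Intron(chrom, s, start, end)
                    if key in counts:
                        logger.warning(
                            "%s:%d: duplicate junction %s; summing counts",
                            path,
                            lineno,
                            key,
                        )
                        counts[key] += unique
                    else:
                        counts[key] = unique
        evidence.add_sample(sample, counts)
    return evidence


@dataclass
class ValidationParams:
    """Thresholds for the junction-support filter.

    ``min_samples`` is the number of distinct short-read samples in which
    every junction of a transcript must be detected (default 5);
    ``min_unique_reads`` is the per-sample unique-read count required for a
    junction to count as detected in that sample (default 1).
    """

    min_samples: int = 5
    min_unique_reads: int = 1
    keep_monoexonic: bool = False

    def __post_init__(self) -> None:
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        if self.min_unique_reads < 0:
            raise ValueError("min_unique_reads must be >= 0")


@dataclass
class ValidationReport:
    """Outcome of the junction filter: kept ids and per-transcript reasons."""

    kept: list[str] = field(default_factory=list)
    #: transcript id -> list of unsupported Intron keys, or the string
    #: "unspliced" for mono-exonic transcripts dropped by policy
    dropped: dict[str, list[Intron] | str] = field(default_factory=dict)
    aggregate_counts: dict[Intron, int] = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)

    def summary(self) -> dict:
        return {
            "n_in": self.n_kept + self.n_dropped,
            "n_kept": self.n_kept,
            "n_dropped": self.n_dropped,
        }

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "wt") as out:
            out.write("transcript_id\tstatus\tfailing_junctions\n")
            for tid in self.kept:
                out.write(f"{tid}\tkept\t.\n")
            for tid, why in self.dropped.items():
                if isinstance(why, str):
                    out.write(f"{tid}\tdropped\t{why}\n")
                else:
                    keys = ",".join(f"{j.chrom}:{j.start}-{j.end}({j.strand})" for j in why)
                    out.write(f"{tid}\tdropped\t{keys}\n")


def filter_by_junction_support(
    transcripts: Iterable[TranscriptModel],
    evidence: JunctionEvidenceSet,
    params: ValidationParams | None = None,
) -> tuple[list[TranscriptModel], ValidationReport]:
    """Keep transcripts whose every intron is supported in enough samples.

    A transcript survives iff every intron in its chain was detected (with
    at least ``min_unique_reads`` unique reads) in at least ``min_samples``
    distinct samples. Mono-exonic transcripts are dropped with reason
    "unspliced" unless ``keep_monoexonic`` is set: the curated catalog is
    restricted to spliced isoforms and the junction criterion is vacuous
    for them.

    Output order is input order restricted to kept transcripts.
    """
    params = params or ValidationParams()
    transcripts = list(transcripts)
    agg = evidence.aggregate(min_unique_reads=params.min_unique_reads)
    if not agg and any(t.is_spliced for t in transcripts):
        logger.warning(
            "junction evidence is empty but %d spliced transcript(s) were "
            "given; all will be dropped (possible misconfiguration)",
            sum(t.is_spliced for t in transcripts),
        )
    report = ValidationReport(aggregate_counts=agg)
    kept: list[TranscriptModel] = []
    for t in transcripts:
        if not t.is_spliced:
            if params.keep_monoexonic:
                kept.append(t)
                report.kept.append(t.transcript_id)
            else:
                report.dropped[t.transcript_id] = "unspliced"
            continue
        failing = [j for j in t.intron_chain() if agg.get(j, 0) < params.min_samples]
        if failing:
            report.dropped[t.transcript_id] = failing
        else:
            kept.append(t)
            report.kept.append(t.transcript_id)
    return kept, report
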