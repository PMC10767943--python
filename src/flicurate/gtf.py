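"""GTF reading and writing.

GTF coordinates are 1-based inclusive; everything inside the package is
0-based half-open. The conversion happens here and nowhere else.

The reader accepts the Ensembl/GENCODE attribute dialect (``key "value";``
pairs), plain or gzip-compressed files, and enforces the contracts the
pipeline needs: a parse error names the offending file and line, transcripts
with strand "." are rejected (and counted) because antisense/intergenic
classification is strand-dependent, and duplicate transcript ids are
suffixed with an occurrence index so downstream consolidation can resolve
true duplicates.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

from .model import (
    GenomicInterval,
    GtfParseError,
    ReferenceIndex,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"\s*;')


@dataclass
class GtfReadReport:
    """Side information from a GTF read: rejected and renamed records."""

    n_transcripts: int = 0
    n_rejected_unstranded: int = 0
    renamed: dict[str, str] = field(default_factory=dict)


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def parse_attributes(attr_field: str) -> dict[str, str]:
    """Parse a GTF attribute column into a dict (last value wins on repeats)."""
    return {k: v for k, v in _ATTR_RE.findall(attr_field)}


def read_gtf(
    path: str | Path,
    kind: str = "query",
    report: GtfReadReport | None = None,
) -> list[TranscriptModel] | ReferenceIndex:
    """Read transcript models from a GTF file.

    Parameters
    ----------
    path:
        GTF file, optionally gzip-compressed. Exon features must carry a
        ``transcript_id`` attribute; ``gene_id`` is optional for queries.
    kind:
        ``"query"`` returns a list of :class:`TranscriptModel` in file
        order. ``"reference"`` additionally builds every classification
        index and returns a :class:`ReferenceIndex`.
    report:
        Optional accumulator for rejection/renaming side information.

    Raises
    ------
    GtfParseError
        On a malformed exon record (missing transcript_id, bad
        coordinates) or an exon strand conflict within one transcript;
        the message names the file and line.
    """
    if kind not in ("query", "reference"):
        raise ValueError(f"kind must be 'query' or 'reference', got {kind!r}")
    report = report if report is not None else GtfReadReport()

    # transcript_id -> [chrom, strand, [(start, end)...], gene_id]
    order: list[str] = []
    records: dict[str, list] = {}
    unstranded: set[str] = set()
    gene_spans: dict[str, GenomicInterval] = {}

    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GtfParseError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
            if feature == "gene" and kind == "reference" and strand in ("+", "-"):
                a = parse_attributes(attrs)
                gid = a.get("gene_id")
                if gid:
                    try:
                        gene_spans[gid] = GenomicInterval(
                            chrom, int(start_s) - 1, int(end_s), strand
                        )
                    except ValueError:
                        raise GtfParseError(f"{path}:{lineno}: bad gene coordinates")
                continue
            if feature != "exon":
                continue
            attributes = parse_attributes(attrs)
            tid = attributes.get("transcript_id")
            if not tid:
                raise GtfParseError(f"{path}:{lineno}: exon lacks transcript_id attribute")
            try:
                start = int(start_s) - 1  # GTF 1-based inclusive -> half-open
                end = int(end_s)
            except ValueError:
                raise GtfParseError(f"{path}:{lineno}: non-integer coordinates")
            if start < 0 or start >= end:
                raise GtfParseError(f"{path}:{lineno}: invalid exon interval {start_s}-{end_s}")
            if strand == ".":
                unstranded.add(tid)
                continue
            if strand not in ("+", "-"):
                raise GtfParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            gene_id = attributes.get("gene_id")
            if gene_id == "NA":  # writer's placeholder for unassigned genes
                gene_id = None
            rec = records.get(tid)
            if rec is None:
                records[tid] = [chrom, strand, [(start, end)], gene_id]
                order.append(tid)
            else:
                if rec[0] != chrom or rec[1] != strand:
                    raise GtfParseError(
                        f"{path}:{lineno}: exon strand/chrom conflict within "
                        f"transcript {tid!r}"
                    )
                rec[2].append((start, end))

    for tid in unstranded:
        records.pop(tid, None)
        if tid in order:
            order.remove(tid)
    if unstranded:
        report.n_rejected_unstranded += len(unstranded)
        logger.warning(
            "%s: rejected %d transcript(s) with strand '.'", path, len(unstranded)
        )

    transcripts = [
        TranscriptModel.from_intervals(
            tid,
            records[tid][0],
            records[tid][1],
            records[tid][2],
            gene_id=records[tid][3],
        )
        for tid in order
    ]
    report.n_transcripts += len(transcripts)
    if kind == "reference":
        return ReferenceIndex(transcripts, gene_spans=gene_spans or None)
    return transcripts


def read_query_gtfs(
    paths: Sequence[str | Path], report: GtfReadReport | None = None
) -> list[TranscriptModel]:
    """Read and concatenate several query GTFs.

    A transcript id seen more than once (across or within files) is
    suffixed ``_dupK`` with its occurrence index and logged.
    """
    report = report if report is not None else GtfReadReport()
    seen: dict[str, int] = {}
    out: list[TranscriptModel] = []
    for path in paths:
        for t in read_gtf(path, kind="query", report=report):
            n = seen.get(t.transcript_id, 0)
            seen[t.transcript_id] = n + 1
            if n:
                new_id = f"{t.transcript_id}_dup{n + 1}"
                report.renamed[new_id] = t.transcript_id
                logger.warning(
                    "duplicate transcript_id %s renamed to %s", t.transcript_id, new_id
                )
                t = TranscriptModel.from_intervals(
                    new_id,
                    t.chrom,
                    t.strand,
                    [(e.start, e.end) for e in t.exons],
                    gene_id=t.gene_id,
                    source_samples=t.source_samples,
                )
            out.append(t)
    return out


def _fmt_attrs(attrs: dict[str, str]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in attrs.items())


def write_gtf(
    transcripts: Iterable[TranscriptModel],
    path: str | Path,
    extra_attributes: dict[str, dict[str, str]] | None = None,
    source: str = "flicurate",
) -> None:
    """Write transcripts as GTF (transcript + exon features, 1-based inclusive).

    ``extra_attributes`` maps transcript_id to additional attribute
    key/value pairs (e.g. structural category, coding/NMD flags, TE/CAGE/
    polyA annotations) emitted on the transcript feature line.
    """
    extra_attributes = extra_attributes or {}
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as out:
        out.write("##provider: flicurate\n")
        for t in transcripts:
            attrs = {"gene_id": t.gene_id or "NA", "transcript_id": t.transcript_id}
            attrs.update(
                {k: str(v) for k, v in extra_attributes.get(t.transcript_id, {}).items()}
            )
            out.write(
                "\t".join(
                    [
                        t.chrom,
                        source,
                        "transcript",
                        str(t.start + 1),
                        str(t.end),
                        ".",
                        t.strand,
                        ".",
                        _fmt_attrs(attrs),
                    ]
                )
                + "\n"
            )
            base = {"gene_id": t.gene_id or "NA", "transcript_id": t.transcript_id}
            for exon in t.exons:
                exon_attrs = dict(base)
                exon_attrs["exon_number"] = str(exon.rank)
                out.write(
                    "\t".join(
                        [
                            t.chrom,
                            source,
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            t.strand,
                            ".",
                            _fmt_attrs(exon_attrs),
                        ]
                    )
                    + "\n"
                )


def read_bed_track(
    path: str | Path, name: str, stranded: bool = False
) -> "AnnotationTrack":
    """Read a BED file (3-6 columns) into an :class:`AnnotationTrack`.

    BED is already 0-based half-open. Column 4 (name), if present, becomes
    the interval label; column 6 the strand (defaulting to '+' when the
    track is unstranded and no strand column exists).
    """
    from .model import AnnotationTrack

    intervals = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise GtfParseError(f"{path}:{lineno}: BED needs >=3 columns")
            chrom, start_s, end_s = fields[:3]
            label = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "+"
            try:
                intervals.append(
                    GenomicInterval(chrom, int(start_s), int(end_s), strand, label)
                )
            except ValueError:
                raise GtfParseError(f"{path}:{lineno}: bad BED coordinates")
    return AnnotationTrack(name, intervals, stranded=stranded)


def write_bed_track(track, path: str | Path) -> None:
    """Write an AnnotationTrack as BED6."""
    with open(path, "wt") as out:
        for iv in track.intervals:
            out.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\t0\t{iv.strand}\n"
            )
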