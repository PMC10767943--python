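"""End-to-end curation pipeline.

Stage order: junction validation → structural classification (+ ISM
removal) → consolidation of comparable isoforms → functional annotation →
specific-transcript calling. Each stage writes its report into the output
directory, and a machine-readable ``summary.json`` records per-stage
counts and the category tally; counts are conserved at every stage
(input = kept + dropped). The run is fully deterministic given its
configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import annotate as _annotate
from .annotate import DEFAULT_POLYA_MOTIFS, FunctionalFlags, ORF
from .classify import (
    ClassificationResult,
    StructuralCategory,
    write_classification_tsv,
)
from .consolidate import (
    ConsolidationGroup,
    ConsolidationParams,
    consolidate,
    write_groups_tsv,
)
from .gtf import read_bed_track, read_gtf, read_query_gtfs, write_gtf
from .junctions import ValidationParams, filter_by_junction_support, read_junction_tables
from .model import FlicurateError, TranscriptModel
from .srt import (
    ExpressionMatrix,
    TumorSrtParams,
    call_tissue_srt,
    call_tumor_srt,
    write_tissue_srt_tsv,
    write_tumor_srt_tsv,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs, thresholds and output location for one curation run.

    Defaults mirror the curation criteria throughout: 5-sample junction
    support, 3 exonic variations / 4 bp per exon / 100 bp end
    dissimilarity for consolidation, the 50-nt NMD rule, ±100 bp TSS/TTS
    feature windows, and 10-fold / 0.5 TPM / 5% tumor-SRT thresholds.
    """

    query_gtf: list[str] = field(default_factory=list)
    reference_gtf: str = ""
    sj_tables: list[str] = field(default_factory=list)
    genome_fasta: str | None = None
    te_bed: str | None = None
    cage_bed: str | None = None
    polya_bed: str | None = None
    tpm_tsv: str | None = None
    samples_tsv: str | None = None
    outdir: str = "flicurate_out"
    validation: ValidationParams = field(default_factory=ValidationParams)
    consolidation: ConsolidationParams = field(default_factory=ConsolidationParams)
    tumor_srt: TumorSrtParams = field(default_factory=TumorSrtParams)
    feature_window: int = 100
    min_orf_nt: int = 300
    nmd_rule_nt: int = 50
    polya_motifs: tuple[str, ...] = DEFAULT_POLYA_MOTIFS
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        for key, sub in (
            ("validation", ValidationParams),
            ("consolidation", ConsolidationParams),
            ("tumor_srt", TumorSrtParams),
        ):
            if key in raw and isinstance(raw[key], dict):
                if key == "tumor_srt" and "excluded_normals" in raw[key]:
                    raw[key]["excluded_normals"] = frozenset(raw[key]["excluded_normals"])
                raw[key] = sub(**raw[key])
        if "query_gtf" in raw and isinstance(raw["query_gtf"], str):
            raw["query_gtf"] = [raw["query_gtf"]]
        if "polya_motifs" in raw:
            raw["polya_motifs"] = tuple(raw["polya_motifs"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["tumor_srt"]["excluded_normals"] = sorted(
            raw["tumor_srt"]["excluded_normals"]
        )
        raw["polya_motifs"] = list(self.polya_motifs)
        with open(path, "wt") as out:
            yaml.safe_dump(raw, out, sort_keys=True)


@dataclass
class CatalogEntry:
    """One curated transcript with everything the pipeline learned about it."""

    transcript: TranscriptModel
    classification: ClassificationResult
    group: ConsolidationGroup
    flags: FunctionalFlags
    orf: ORF | None = None
    tumor_srt_types: tuple[str, ...] = ()
    is_tissue_srt: bool = False

    @property
    def category(self) -> str:
        return self.classification.category.value


@dataclass
class CuratedCatalog:
    entries: list[CatalogEntry]
    summary: dict

    def __len__(self) -> int:
        return len(self.entries)

    def transcript_ids(self) -> list[str]:
        return [e.transcript.transcript_id for e in self.entries]


def _load_genome(path: str | Path):
    from pyfaidx import Fasta

    return Fasta(str(path))


def run_curation(config: RunConfig) -> CuratedCatalog:
    """Run the full curation pipeline and write all stage outputs.

    Returns the curated catalog; ``summary.json`` in the output directory
    holds the per-stage counts.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    if not config.query_gtf or not config.reference_gtf:
        raise FlicurateError("query_gtf and reference_gtf are required")

    queries = read_query_gtfs(config.query_gtf)
    ref = read_gtf(config.reference_gtf, kind="reference")
    logger.info("stage=input n_query=%d n_reference=%d", len(queries), len(ref))

    # --- junction validation ----------------------------------------
    evidence = read_junction_tables(config.sj_tables)
    validated, report = filter_by_junction_support(queries, evidence, config.validation)
    report.to_tsv(outdir / "validation.tsv")
    (outdir / "validation.json").write_text(json.dumps(report.summary(), sort_keys=True))
    logger.info("stage=validate %s", report.summary())

    # --- structural classification + ISM removal --------------------
    from .classify import classify_transcript

    all_results = [classify_transcript(t, ref) for t in validated]
    tally: dict[str, int] = {}
    for r in all_results:
        tally[r.category.value] = tally.get(r.category.value, 0) + 1
    kept_pairs = [
        (t, r)
        for t, r in zip(validated, all_results)
        if r.category is not StructuralCategory.ISM
    ]
    write_classification_tsv(all_results, outdir / "classification.tsv")
    results_by_id = {r.transcript_id: r for r in all_results}
    logger.info("stage=classify tally=%s", tally)

    # --- ORF prediction (needed for ORF-identity in consolidation) ---
    genome = _load_genome(config.genome_fasta) if config.genome_fasta else None
    orfs: dict[str, ORF | None] = {}
    if genome is not None:
        for t, _res in kept_pairs:
            orfs[t.transcript_id] = _annotate.predict_orf(
                t, genome, min_len_nt=config.min_orf_nt
            )

    # --- consolidation within (locus, category) bins ------------------
    def bin_key(t: TranscriptModel):
        res = results_by_id[t.transcript_id]
        locus = res.assigned_gene or f"{t.chrom}:{t.strand}"
        return (locus, res.category.value)

    reps, groups = consolidate(
        [t for t, _res in kept_pairs],
        config.consolidation,
        orfs=orfs,
        bin_key=bin_key,
    )
    write_groups_tsv(groups, outdir / "groups.tsv")
    logger.info("stage=consolidate n_in=%d n_groups=%d", len(kept_pairs), len(groups))

    # --- functional annotation ---------------------------------------
    te_track = read_bed_track(config.te_bed, "TE") if config.te_bed else None
    cage_track = read_bed_track(config.cage_bed, "CAGE") if config.cage_bed else None
    polya_track = read_bed_track(config.polya_bed, "polyA") if config.polya_bed else None
    rep_groups = {g.representative: g for g in groups}
    entries: list[CatalogEntry] = []
    annotation_rows = []
    for t in reps:
        flags, orf = _annotate.annotate_transcript(
            t,
            genome=genome,
            orf=orfs.get(t.transcript_id),
            te_track=te_track,
            cage_track=cage_track,
            polya_track=polya_track,
            window=config.feature_window,
            min_orf_nt=config.min_orf_nt,
        )
        res = results_by_id[t.transcript_id]
        entries.append(
            CatalogEntry(
                transcript=t,
                classification=res,
                group=rep_groups[t.transcript_id],
                flags=flags,
                orf=orf,
            )
        )
        annotation_rows.append((t, res.category.value, flags, orf))
    _annotate.write_annotation_tsv(annotation_rows, outdir / "annotation.tsv")

    # --- specific RNA transcripts -------------------------------------
    n_tumor_srt = n_tissue_srt = 0
    if config.tpm_tsv and config.samples_tsv:
        matrix = ExpressionMatrix.read_tsv(config.tpm_tsv, config.samples_tsv)
        tumor = matrix.subset_cohort("tumor")
        gtex = matrix.subset_cohort("normal")
        adjacent = matrix.subset_cohort("adjacent_normal")
        hits, calls = call_tumor_srt(
            tumor, gtex, adjacent if adjacent.values.shape[1] else None, config.tumor_srt
        )
        write_tumor_srt_tsv(calls, outdir / "tumor_srt.tsv")
        tissue_results = call_tissue_srt(gtex.aggregate_by_group())
        write_tissue_srt_tsv(tissue_results, outdir / "tissue_srt.tsv")
        tumor_by_tid: dict[str, list[str]] = {}
        for tid, ct in sorted(hits):
            tumor_by_tid.setdefault(tid, []).append(ct)
        tissue_flags = {r.transcript_id: r.is_tissue_srt for r in tissue_results}
        for entry in entries:
            tid = entry.transcript.transcript_id
            entry.tumor_srt_types = tuple(tumor_by_tid.get(tid, ()))
            entry.is_tissue_srt = bool(tissue_flags.get(tid, False))
        n_tumor_srt = sum(1 for e in entries if e.tumor_srt_types)
        n_tissue_srt = sum(1 for e in entries if e.is_tissue_srt)

    # --- catalog GTF + summary ----------------------------------------
    attrs = {}
    for e in entries:
        a = {
            "category": e.category,
            "coding": str(e.flags.coding).lower(),
            "nmd": str(e.flags.nmd).lower(),
            "te_tss": str(e.flags.te_tss).lower(),
            "cage_tss": str(e.flags.cage_tss).lower(),
            "polya_site": str(e.flags.polya_site).lower(),
        }
        if e.flags.te_label:
            a["te_label"] = e.flags.te_label
        if e.flags.polya_motif:
            a["polya_motif"] = e.flags.polya_motif
        attrs[e.transcript.transcript_id] = a
    write_gtf([e.transcript for e in entries], outdir / "catalog.gtf", attrs)

    summary = {
        "n_query": len(queries),
        "validation": report.summary(),
        "category_tally": dict(sorted(tally.items())),
        "n_ism_removed": tally.get("ISM", 0),
        "n_after_classification": len(kept_pairs),
        "n_consolidation_groups": len(groups),
        "n_catalog": len(entries),
        "n_coding": sum(1 for e in entries if e.flags.coding),
        "n_nmd": sum(1 for e in entries if e.flags.nmd),
        "n_te_tss": sum(1 for e in entries if e.flags.te_tss),
        "n_cage_tss": sum(1 for e in entries if e.flags.cage_tss),
        "n_polya_site": sum(1 for e in entries if e.flags.polya_site),
        "n_tumor_srt": n_tumor_srt,
        "n_tissue_srt": n_tissue_srt,
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=2) + "\n"
    )
    logger.info("stage=done n_catalog=%d", len(entries))
    return CuratedCatalog(entries=entries, summary=summary)
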