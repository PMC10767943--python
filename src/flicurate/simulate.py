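"""Deterministic synthetic fixtures with known truth labels.

Generates toy genomes, reference annotations, long-read query transcripts
planted with known structural categories, short-read junction evidence
with planted supported/unsupported junctions, and TPM matrices with
planted tumor- and tissue-specific transcripts.

Truth labels are guaranteed *by construction* — the generator never runs
the classifier or the SRT callers — so generator and pipeline stay
independent and tests against the truth are not circular:

* FSM: copy a reference intron chain (outer ends jittered).
* ISM: drop a terminal exon, leaving a contiguous sub-chain.
* NIC: skip an internal exon, pairing two known sites into a junction the
  reference lacks.
* NNC: shift one internal splice site into the adjacent exon body, where
  no reference site can exist.
* antisense: mirror a reference transcript onto the opposite strand (gene
  loci are disjoint, so no same-strand exonic overlap is possible).
* intergenic: place a transcript in a region free of genes.

All randomness flows from ``FixtureSpec.seed`` through named
``numpy.random.default_rng`` streams, so an identical spec yields
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import Intron, JunctionEvidenceSet, ReferenceIndex, TranscriptModel
from .srt import ExpressionMatrix

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass
class FixtureSpec:
    """All knobs of the synthetic fixture, with deterministic defaults.

    The defaults define the study conditions the pipeline is exercised
    under: multi-exon genes on a single toy chromosome, six planted
    structural categories, junction support straddling the five-sample
    validation threshold, and expression matrices with tumor-SRTs planted
    at 20-fold over normal with 70% prevalence under log-normal noise
    (sigma = 0.5) and 5% dropout.
    """

    seed: int = 0
    chrom: str = "chr1"
    n_genes: int = 30
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_len: tuple[int, int] = (80, 300)
    intron_len: tuple[int, int] = (60, 400)
    intergene_gap: tuple[int, int] = (500, 1500)
    planted: dict[str, int] = field(
        default_factory=lambda: {
            "FSM": 5,
            "ISM": 5,
            "NIC": 5,
            "NNC": 5,
            "antisense": 5,
            "intergenic": 5,
        }
    )
    # junction evidence
    n_sj_samples: int = 8
    supported_samples: tuple[int, int] = (5, 8)
    unsupported_samples: tuple[int, int] = (1, 4)
    n_unsupported: int = 3
    # expression
    n_cancer_types: int = 3
    tumor_samples_per_type: int = 40
    adjacent_per_type: int = 10
    n_tissue_types: int = 22
    samples_per_tissue: int = 5
    n_tumor_srt: int = 3
    n_tissue_srt: int = 3
    tumor_srt_fold: float = 20.0
    tumor_srt_prevalence: float = 0.7
    background_tpm: float = 5.0
    noise_sigma: float = 0.5
    dropout: float = 0.05

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class SyntheticReference:
    transcripts: list[TranscriptModel]
    chrom_lengths: dict[str, int]
    free_region: tuple[str, int, int]  # guaranteed gene-free

    def index(self) -> ReferenceIndex:
        return ReferenceIndex(self.transcripts)


def make_reference(spec: FixtureSpec) -> SyntheticReference:
    """Random multi-exon genes laid out non-overlapping along one chromosome,
    alternating strand assignment, one transcript per gene."""
    rng = spec.rng(0)
    cursor = 1000
    transcripts: list[TranscriptModel] = []
    for g in range(spec.n_genes):
        n_exons = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        exons: list[tuple[int, int]] = []
        pos = cursor
        for i in range(n_exons):
            length = int(rng.integers(spec.exon_len[0], spec.exon_len[1] + 1))
            exons.append((pos, pos + length))
            pos += length
            if i < n_exons - 1:
                pos += int(rng.integers(spec.intron_len[0], spec.intron_len[1] + 1))
        gid = f"G{g + 1:03d}"
        transcripts.append(
            TranscriptModel.from_intervals(
                f"{gid}.t1", spec.chrom, strand, exons, gene_id=gid
            )
        )
        cursor = pos + int(rng.integers(spec.intergene_gap[0], spec.intergene_gap[1] + 1))
    free_start = cursor + 2000
    free_end = free_start + 20000
    chrom_len = free_end + 1000
    return SyntheticReference(
        transcripts=transcripts,
        chrom_lengths={spec.chrom: chrom_len},
        free_region=(spec.chrom, free_start, free_end),
    )


def make_genome(spec: FixtureSpec, reference: SyntheticReference) -> dict[str, str]:
    """Random genome sequence for the reference's chromosomes."""
    rng = spec.rng(1)
    genome = {}
    for chrom, length in reference.chrom_lengths.items():
        genome[chrom] = bytes(_BASES[rng.integers(0, 4, size=length)]).decode()
    return genome


def _jitter_ends(
    exons: list[tuple[int, int]], rng: np.random.Generator, max_shift: int = 20
) -> list[tuple[int, int]]:
    """Shift the two outer transcript ends without touching splice sites."""
    exons = list(exons)
    s, e = exons[0]
    shift = int(rng.integers(-max_shift, max_shift + 1))
    if 0 < s + shift < e - 10:
        exons[0] = (s + shift, e)
    s, e = exons[-1]
    shift = int(rng.integers(-max_shift, max_shift + 1))
    if e + shift > s + 10:
        exons[-1] = (s, e + shift)
    return exons


def make_query_set(
    spec: FixtureSpec, reference: SyntheticReference
) -> tuple[list[TranscriptModel], dict[str, str]]:
    """Plant query transcripts with guaranteed structural categories.

    Returns the query transcripts and a truth map transcript_id -> category.
    """
    rng = spec.rng(2)
    chrom = spec.chrom
    truth: dict[str, str] = {}
    queries: list[TranscriptModel] = []
    # genes with >=3 introns can host every gene-derived construction
    eligible = [t for t in reference.transcripts if t.n_exons >= 4]
    if not eligible:
        raise ValueError("fixture needs genes with >=4 exons; widen exons_per_gene")
    lr_samples = [f"LR_tumor_{i}" for i in (1, 2, 3)] + [f"LR_normal_{i}" for i in (1, 2)]

    def pick_gene() -> TranscriptModel:
        return eligible[int(rng.integers(len(eligible)))]

    def samples() -> list[str]:
        k = int(rng.integers(1, 4))
        return [lr_samples[i] for i in rng.choice(len(lr_samples), size=k, replace=False)]

    free_cursor = reference.free_region[1]
    for category, count in spec.planted.items():
        for i in range(count):
            tid = f"LR.{category}.{i + 1}"
            src = pick_gene()
            exons = [(e.start, e.end) for e in src.exons]
            if category == "FSM":
                q = TranscriptModel.from_intervals(
                    tid, chrom, src.strand, _jitter_ends(exons, rng),
                    source_samples=samples(),
                )
            elif category == "ISM":
                # drop a terminal exon -> proper contiguous sub-chain
                kept = exons[1:] if rng.random() < 0.5 else exons[:-1]
                q = TranscriptModel.from_intervals(
                    tid, chrom, src.strand, kept, source_samples=samples()
                )
            elif category == "NIC":
                # skip one internal exon: all sites known, one junction novel
                skip = int(rng.integers(1, len(exons) - 1))
                kept = exons[:skip] + exons[skip + 1 :]
                q = TranscriptModel.from_intervals(
                    tid, chrom, src.strand, kept, source_samples=samples()
                )
            elif category == "NNC":
                # move one internal donor 6 bp into the exon body: that
                # coordinate cannot be a reference splice site
                j = int(rng.integers(0, len(exons) - 1))
                s, e = exons[j]
                shifted = list(exons)
                shifted[j] = (s, e - 6)
                q = TranscriptModel.from_intervals(
                    tid, chrom, src.strand, shifted, source_samples=samples()
                )
            elif category == "antisense":
                flipped = "-" if src.strand == "+" else "+"
                q = TranscriptModel.from_intervals(
                    tid, chrom, flipped, exons, source_samples=samples()
                )
            elif category == "intergenic":
                n_ex = int(rng.integers(2, 5))
                pos = free_cursor
                iv = []
                for k in range(n_ex):
                    length = int(rng.integers(spec.exon_len[0], spec.exon_len[1] + 1))
                    iv.append((pos, pos + length))
                    pos += length + int(
                        rng.integers(spec.intron_len[0], spec.intron_len[1] + 1)
                    )
                free_cursor = pos + 200
                strand = "+" if rng.random() < 0.5 else "-"
                q = TranscriptModel.from_intervals(
                    tid, chrom, strand, iv, source_samples=samples()
                )
            else:
                raise ValueError(f"unknown planted category {category!r}")
            queries.append(q)
            truth[tid] = category
    return queries, truth


def make_junction_evidence(
    spec: FixtureSpec, queries: Sequence[TranscriptModel]
) -> tuple[dict[str, dict[Intron, int]], set[str]]:
    """Assign per-junction sample support and distribute it over samples.

    A few transcripts owning at least one *private* intron (an intron no
    other query shares) are designated unsupported: that intron appears in
    fewer samples than the validation threshold. Returns the per-sample
    junction count maps and the set of transcripts planted to be dropped.
    """
    rng = spec.rng(3)
    owners: dict[Intron, set[str]] = {}
    for q in queries:
        for j in q.intron_chain():
            owners.setdefault(j, set()).add(q.transcript_id)
    private: dict[str, list[Intron]] = {}
    for j, tids in owners.items():
        if len(tids) == 1:
            private.setdefault(next(iter(tids)), []).append(j)
    candidates = sorted(private)
    n_drop = min(spec.n_unsupported, len(candidates))
    dropped = set(
        candidates[i] for i in rng.choice(len(candidates), size=n_drop, replace=False)
    )
    weak: set[Intron] = set()
    for tid in sorted(dropped):
        introns = sorted(private[tid])
        weak.add(introns[int(rng.integers(len(introns)))])

    support: dict[Intron, int] = {}
    for j in sorted(owners):
        lo, hi = (
            spec.unsupported_samples if j in weak else spec.supported_samples
        )
        support[j] = int(rng.integers(lo, hi + 1))

    sample_names = [f"SJ_{i + 1:02d}" for i in range(spec.n_sj_samples)]
    per_sample: dict[str, dict[Intron, int]] = {s: {} for s in sample_names}
    for j in sorted(support):
        k = min(support[j], spec.n_sj_samples)
        chosen = rng.choice(spec.n_sj_samples, size=k, replace=False)
        for idx in chosen:
            per_sample[sample_names[idx]][j] = int(rng.integers(1, 51))
    return per_sample, dropped


def evidence_from_maps(per_sample: dict[str, dict[Intron, int]]) -> JunctionEvidenceSet:
    ev = JunctionEvidenceSet()
    for sample in sorted(per_sample):
        ev.add_sample(sample, per_sample[sample])
    return ev


def make_expression(
    spec: FixtureSpec, transcript_ids: Sequence[str]
) -> tuple[ExpressionMatrix, dict[str, dict[str, str]]]:
    """TPM matrix over tumor, adjacent-normal and normal-tissue samples,
    with planted tumor-SRTs and tissue-SRTs.

    Background transcripts express log-normally around ``background_tpm``
    in every sample. Planted tumor-SRTs are near-silent in normals
    (testis slightly higher, at 0.3 TPM) and expressed at
    ``tumor_srt_fold`` TPM in a ``tumor_srt_prevalence`` fraction of one
    cancer type's tumor samples. Planted tissue-SRTs express in exactly
    one normal tissue type. Multiplicative log-normal noise (sigma) and
    dropout apply to every nonzero value.

    Returns the matrix and a truth dict with "tumor_srt" and "tissue_srt"
    maps (transcript_id -> cancer type / tissue).
    """
    rng = spec.rng(4)
    ids = list(transcript_ids)
    need = spec.n_tumor_srt + spec.n_tissue_srt
    if len(ids) < need:
        raise ValueError(f"need >= {need} transcripts to plant SRTs, got {len(ids)}")
    cancer_types = [f"CT{i + 1}" for i in range(spec.n_cancer_types)]
    tissues = ["testis"] + [f"tissue{i + 2:02d}" for i in range(spec.n_tissue_types - 1)]

    columns: list[str] = []
    meta_rows: list[tuple[str, str, str]] = []
    for ct in cancer_types:
        for i in range(spec.tumor_samples_per_type):
            columns.append(f"{ct}_T{i + 1:03d}")
            meta_rows.append((columns[-1], ct, "tumor"))
        for i in range(spec.adjacent_per_type):
            columns.append(f"{ct}_N{i + 1:03d}")
            meta_rows.append((columns[-1], ct, "adjacent_normal"))
    for tis in tissues:
        for i in range(spec.samples_per_tissue):
            columns.append(f"{tis}_G{i + 1:02d}")
            meta_rows.append((columns[-1], tis, "normal"))

    chosen = [ids[i] for i in rng.choice(len(ids), size=need, replace=False)]
    tumor_srts = {
        tid: cancer_types[i % len(cancer_types)]
        for i, tid in enumerate(chosen[: spec.n_tumor_srt])
    }
    tissue_srts = {
        tid: tissues[1 + i % (len(tissues) - 1)]
        for i, tid in enumerate(chosen[spec.n_tumor_srt :])
    }

    def noisy(value: float, n: int) -> np.ndarray:
        out = value * np.exp(rng.normal(0.0, spec.noise_sigma, size=n))
        if spec.dropout > 0:
            out[rng.random(n) < spec.dropout] = 0.0
        return out

    data = np.zeros((len(ids), len(columns)))
    col_group = {c: g for c, g, _ in meta_rows}
    col_cohort = {c: co for c, _, co in meta_rows}
    for r, tid in enumerate(ids):
        if tid in tumor_srts:
            ct = tumor_srts[tid]
            row = np.zeros(len(columns))
            for c, col in enumerate(columns):
                cohort = col_cohort[col]
                group = col_group[col]
                if cohort == "tumor" and group == ct:
                    if rng.random() < spec.tumor_srt_prevalence:
                        row[c] = noisy(spec.tumor_srt_fold, 1)[0]
                elif cohort == "normal" and group == "testis":
                    row[c] = noisy(0.3, 1)[0]
                elif cohort in ("normal", "adjacent_normal"):
                    row[c] = noisy(0.1, 1)[0]
            data[r] = row
        elif tid in tissue_srts:
            tis = tissue_srts[tid]
            row = np.zeros(len(columns))
            for c, col in enumerate(columns):
                if col_cohort[col] == "normal" and col_group[col] == tis:
                    row[c] = noisy(30.0, 1)[0]
            data[r] = row
        else:
            base = spec.background_tpm * float(np.exp(rng.normal(0.0, 0.5)))
            data[r] = noisy(base, len(columns))

    values = pd.DataFrame(data, index=ids, columns=columns)
    meta = pd.DataFrame(
        [(g, co) for _, g, co in meta_rows],
        index=pd.Index(columns, name="sample_id"),
        columns=["group", "cohort"],
    )
    matrix = ExpressionMatrix(values, meta)
    return matrix, {"tumor_srt": tumor_srts, "tissue_srt": tissue_srts}


def transcript_genomic_positions(t: TranscriptModel) -> list[int]:
    """Genomic position of every transcript base, 5'->3'."""
    positions: list[int] = []
    for exon in t.exons_in_transcription_order():
        if t.strand == "+":
            positions.extend(range(exon.start, exon.end))
        else:
            positions.extend(range(exon.end - 1, exon.start - 1, -1))
    return positions


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def embed_orf(
    genome: dict[str, str],
    t: TranscriptModel,
    orf_len_nt: int,
    tstart: int = 0,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Write an ATG…stop ORF into the genome so that the spliced transcript
    sequence carries it at transcript coordinate ``tstart``.

    ``orf_len_nt`` includes the stop codon and must be a multiple of 3.
    Returns a new genome dict. Intended for constructing coding-test
    fixtures; clobbers whatever sequence was there. Without an ``rng`` the
    codon body is a CTG repeat, which introduces no ATG and no stop codon
    in any reading frame — the embedded ORF is then the only one the
    payload can create; with an ``rng`` the body is random non-stop
    codons.
    """
    if orf_len_nt % 3 or orf_len_nt < 6:
        raise ValueError("orf_len_nt must be a multiple of 3, >= 6")
    if tstart + orf_len_nt > t.length:
        raise ValueError("ORF does not fit in the transcript")
    n_codons = orf_len_nt // 3 - 2
    if rng is None:
        middle = "CTG" * n_codons
    else:
        middle = "".join(
            _NONSTOP_CODONS[int(rng.integers(len(_NONSTOP_CODONS)))]
            for _ in range(n_codons)
        )
    payload = "ATG" + middle + "TAA"
    positions = transcript_genomic_positions(t)
    seq = list(genome[t.chrom])
    for offset, base in enumerate(payload):
        gpos = positions[tstart + offset]
        seq[gpos] = base if t.strand == "+" else base.translate(_COMPLEMENT)
    new_genome = dict(genome)
    new_genome[t.chrom] = "".join(seq)
    return new_genome


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "wt") as out:
        for chrom in genome:
            out.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def write_sj_tables(
    per_sample: dict[str, dict[Intron, int]], outdir: str | Path
) -> list[Path]:
    """Write one STAR-dialect ``SJ.out.tab`` per sample; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for sample in sorted(per_sample):
        path = outdir / f"{sample}.SJ.out.tab"
        with open(path, "wt") as out:
            for j in sorted(per_sample[sample]):
                code = "1" if j.strand == "+" else "2"
                out.write(
                    f"{j.chrom}\t{j.start + 1}\t{j.end}\t{code}\t1\t0\t"
                    f"{per_sample[sample][j]}\t0\t30\n"
                )
        paths.append(path)
    return paths


def write_fixture(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the complete fixture to ``outdir``.

    Emits genome.fa, reference.gtf, query.gtf, truth.tsv (category and
    junction-support truth per transcript), sj/*.SJ.out.tab, tpm.tsv,
    samples.tsv and srt_truth.tsv. Returns the paths keyed by role.
    """
    from .gtf import write_gtf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = make_reference(spec)
    genome = make_genome(spec, reference)
    queries, truth = make_query_set(spec, reference)
    per_sample, planted_dropped = make_junction_evidence(spec, queries)
    matrix, srt_truth = make_expression(spec, [q.transcript_id for q in queries])

    paths = {
        "genome": outdir / "genome.fa",
        "reference_gtf": outdir / "reference.gtf",
        "query_gtf": outdir / "query.gtf",
        "truth": outdir / "truth.tsv",
        "sj_dir": outdir / "sj",
        "tpm": outdir / "tpm.tsv",
        "samples": outdir / "samples.tsv",
        "srt_truth": outdir / "srt_truth.tsv",
    }
    write_fasta(genome, paths["genome"])
    write_gtf(reference.transcripts, paths["reference_gtf"])
    write_gtf(queries, paths["query_gtf"])
    with open(paths["truth"], "wt") as out:
        out.write("transcript_id\tcategory\tjunction_status\n")
        for q in queries:
            status = "dropped" if q.transcript_id in planted_dropped else "kept"
            out.write(f"{q.transcript_id}\t{truth[q.transcript_id]}\t{status}\n")
    write_sj_tables(per_sample, paths["sj_dir"])
    matrix.write_tsv(paths["tpm"], paths["samples"])
    with open(paths["srt_truth"], "wt") as out:
        out.write("transcript_id\tkind\tgroup\n")
        for tid in sorted(srt_truth["tumor_srt"]):
            out.write(f"{tid}\ttumor_srt\t{srt_truth['tumor_srt'][tid]}\n")
        for tid in sorted(srt_truth["tissue_srt"]):
            out.write(f"{tid}\ttissue_srt\t{srt_truth['tissue_srt'][tid]}\n")
    return paths
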