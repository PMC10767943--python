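"""Specific RNA transcript (SRT) calling from TPM expression matrices.

Two callers operate on transcript × sample TPM matrices:

* **tissue-SRTs** use an entropy-based specificity score. With x_it the
  expression of transcript t in tissue type i (one value per type,
  aggregated by the median over samples), the expression ratios are
  p_it = x_it / Σ_i x_it and the specificity score is

      S_t = log2(N) − ( −Σ_i p_it · log2 p_it ),

  i.e. log2(N) minus the Shannon entropy of the ratio vector, ranging from
  0 (uniform expression) to log2(N) (expression confined to one of the N
  tissue types). A transcript is tissue-specific when the largest ratio is
  more than twice the second largest AND S_t > 1.

* **tumor-SRTs** require, for at least one cancer type, (A) a median tumor
  TPM at least 10-fold above the maximum TPM seen in any normal sample —
  normal tissues (excluding testis, whose transcriptome is permissive)
  pooled with tumor-adjacent normals — and (B) expression above 0.5 TPM in
  strictly more than 5% of that cancer type's tumor samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import FlicurateError

RATIO_TOL = 1e-9


@dataclass
class ExpressionMatrix:
    """TPM values (rows = transcripts, columns = samples) plus sample
    metadata with ``group`` (cancer type / tissue type) and ``cohort``
    (tumor, adjacent_normal, normal) per sample."""

    values: pd.DataFrame
    meta: pd.DataFrame  # index = sample_id; columns: group, cohort

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise FlicurateError("TPM values must be non-negative")
        missing = [c for c in ("group", "cohort") if c not in self.meta.columns]
        if missing:
            raise FlicurateError(f"sample metadata lacks column(s): {missing}")
        unknown = [s for s in self.values.columns if s not in self.meta.index]
        if unknown:
            raise FlicurateError(f"samples without metadata: {unknown[:5]}")

    @classmethod
    def read_tsv(cls, matrix_path: str | Path, meta_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(values, meta)

    def write_tsv(self, matrix_path: str | Path, meta_path: str | Path) -> None:
        self.values.to_csv(matrix_path, sep="\t")
        self.meta.to_csv(meta_path, sep="\t")

    def subset_cohort(self, cohort: str) -> "ExpressionMatrix":
        samples = self.meta.index[self.meta["cohort"] == cohort]
        cols = [s for s in self.values.columns if s in set(samples)]
        return ExpressionMatrix(self.values[cols], self.meta.loc[cols])

    def groups(self) -> pd.Series:
        """group label per matrix column, in column order."""
        return self.meta.loc[self.values.columns, "group"]

    def aggregate_by_group(self, statistic: str = "median") -> pd.DataFrame:
        """Aggregate samples to one value per (transcript, group) —
        the per-tissue-type matrix the specificity score is defined on."""
        return self.values.T.groupby(self.groups()).agg(statistic).T


def expression_ratios(x: Sequence[float] | np.ndarray) -> np.ndarray:
    """p_i = x_i / Σx. An all-zero vector returns all zeros (the caller
    flags such transcripts as unexpressed; they are excluded from scoring)."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise FlicurateError("expression values must be non-negative")
    total = x.sum()
    if total == 0:
        return np.zeros_like(x)
    return x / total


def specificity_score(p: Sequence[float] | np.ndarray, n_types: int | None = None) -> float:
    """S = log2(N) − H(p) with H the Shannon entropy in bits.

    Terms with p_i = 0 contribute 0 to the entropy. ``p`` must sum to 1
    within 1e−9.
    """
    p = np.asarray(p, dtype=float)
    if n_types is None:
        n_types = len(p)
    if abs(p.sum() - 1.0) > RATIO_TOL:
        raise FlicurateError(f"ratio vector sums to {p.sum()!r}, not 1")
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return float(np.log2(n_types) - entropy)


@dataclass
class SpecificityResult:
    transcript_id: str
    n_types: int
    p: np.ndarray
    score: float  # NaN for unexpressed transcripts
    top_tissue: str | None
    p_top: float
    p_second: float
    is_tissue_srt: bool
    expressed: bool


@dataclass
class TumorSrtParams:
    """Thresholds for tumor-SRT calling: fold on the tumor median vs the
    normal maximum (>= 10 by default), the TPM floor counting a sample as
    expressing (> 0.5, strict), the fraction of tumor samples that must
    express (> 5%, strict), and normal tissues excluded from the maximum
    (testis by default)."""

    fold: float = 10.0
    tpm_min: float = 0.5
    frac_expressed: float = 0.05
    excluded_normals: frozenset[str] = frozenset({"testis"})
    pool_adjacent_normals: bool = True

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ValueError("fold must be > 1")
        if not (0 < self.frac_expressed < 1):
            raise ValueError("frac_expressed must be in (0, 1)")


def call_tissue_srt(tissue_matrix: pd.DataFrame) -> list[SpecificityResult]:
    """Score tissue specificity on a transcript × tissue-type matrix.

    One expression value per (transcript, tissue type) is expected —
    aggregate samples with :meth:`ExpressionMatrix.aggregate_by_group`
    first. A transcript is a tissue-SRT when p_(1) > 2·p_(2) (passing when
    p_(2) = 0 and p_(1) > 0) and S_t > 1. Unexpressed transcripts get an
    undefined (NaN) score and are never tissue-specific.
    """
    n_types = tissue_matrix.shape[1]
    if n_types < 2:
        raise FlicurateError("tissue-specificity needs >= 2 tissue types")
    results: list[SpecificityResult] = []
    tissues = list(tissue_matrix.columns)
    for tid, row in tissue_matrix.iterrows():
        x = row.to_numpy(dtype=float)
        p = expression_ratios(x)
        if p.sum() == 0:
            results.append(
                SpecificityResult(tid, n_types, p, float("nan"), None, 0.0, 0.0, False, False)
            )
            continue
        s = specificity_score(p, n_types)
        order = np.argsort(-p, kind="stable")
        p_top, p_second = float(p[order[0]]), float(p[order[1]])
        ratio_ok = p_top > 2 * p_second  # holds automatically when p_second == 0
        results.append(
            SpecificityResult(
                transcript_id=tid,
                n_types=n_types,
                p=p,
                score=s,
                top_tissue=tissues[order[0]],
                p_top=p_top,
                p_second=p_second,
                is_tissue_srt=bool(ratio_ok and s > 1),
                expressed=True,
            )
        )
    return results


@dataclass
class TumorSrtCall:
    transcript_id: str
    cancer_type: str
    median_tumor: float
    max_normal: float
    fold: float  # inf when max_normal == 0 and median_tumor > 0
    frac_expressed: float
    passes: bool


def call_tumor_srt(
    tumor: ExpressionMatrix,
    gtex_normal: ExpressionMatrix,
    tcga_adjacent: ExpressionMatrix | None = None,
    params: TumorSrtParams | None = None,
) -> tuple[set[tuple[str, str]], list[TumorSrtCall]]:
    """Call tumor-specific transcripts per cancer type.

    Returns the set of (transcript_id, cancer_type) pairs passing both
    criteria, plus the full per-(transcript, type) evaluation table.
    Transcript ids are intersected across matrices; the normal maximum
    pools GTEx tissues (minus the excluded ones) with tumor-adjacent
    normals when provided.
    """
    params = params or TumorSrtParams()
    normal_cols = gtex_normal.values[
        [
            s
            for s in gtex_normal.values.columns
            if gtex_normal.meta.loc[s, "group"] not in params.excluded_normals
        ]
    ]
    normal_blocks = [normal_cols]
    if tcga_adjacent is not None and params.pool_adjacent_normals:
        normal_blocks.append(tcga_adjacent.values)
    if sum(b.shape[1] for b in normal_blocks) == 0:
        raise FlicurateError("no normal samples available: tumor-SRT fold is undefined")

    tids = tumor.values.index
    for block in normal_blocks:
        tids = tids.intersection(block.index)
    if tcga_adjacent is not None and not params.pool_adjacent_normals:
        tids = tids.intersection(tcga_adjacent.values.index)

    max_normal = pd.concat(
        [b.loc[tids] for b in normal_blocks], axis=1
    ).max(axis=1)
    if tcga_adjacent is not None and not params.pool_adjacent_normals:
        max_adjacent = tcga_adjacent.values.loc[tids].max(axis=1)

    calls: list[TumorSrtCall] = []
    hits: set[tuple[str, str]] = set()
    tumor_groups = tumor.groups()
    for cancer_type in sorted(tumor_groups.unique()):
        cols = [s for s in tumor.values.columns if tumor_groups[s] == cancer_type]
        block = tumor.values.loc[tids, cols]
        med = block.median(axis=1)
        frac = (block > params.tpm_min).mean(axis=1)
        for tid in tids:
            mn = float(max_normal[tid])
            mt = float(med[tid])
            if mn == 0:
                a_ok = mt > 0
                fold = float("inf") if mt > 0 else 0.0
            else:
                fold = mt / mn
                a_ok = mt >= params.fold * mn
            if a_ok and tcga_adjacent is not None and not params.pool_adjacent_normals:
                ma = float(max_adjacent[tid])
                a_ok = (mt > 0) if ma == 0 else (mt >= params.fold * ma)
            b_ok = float(frac[tid]) > params.frac_expressed
            passes = bool(a_ok and b_ok)
            calls.append(
                TumorSrtCall(tid, cancer_type, mt, mn, fold, float(frac[tid]), passes)
            )
            if passes:
                hits.add((tid, cancer_type))
    return hits, calls


def lr_tumor_specific(
    transcripts: Iterable, sample_cohorts: dict[str, str]
) -> set[str]:
    """Long-read tumor specificity: transcripts whose source samples are
    exclusively tumor samples (set difference over cohort labels)."""
    out: set[str] = set()
    for t in transcripts:
        cohorts = {sample_cohorts.get(s, "unknown") for s in t.source_samples}
        if cohorts and cohorts <= {"tumor"}:
            out.add(t.transcript_id)
    return out


def write_tissue_srt_tsv(results: Sequence[SpecificityResult], path: str | Path) -> None:
    with open(path, "wt") as out:
        out.write("transcript_id\tN\tS_t\ttop_tissue\tp_top\tp_second\tis_tissue_srt\n")
        for r in results:
            score = "NA" if np.isnan(r.score) else f"{r.score:.6g}"
            out.write(
                f"{r.transcript_id}\t{r.n_types}\t{score}\t{r.top_tissue or '.'}\t"
                f"{r.p_top:.6g}\t{r.p_second:.6g}\t{str(r.is_tissue_srt).lower()}\n"
            )


def write_tumor_srt_tsv(calls: Sequence[TumorSrtCall], path: str | Path) -> None:
    with open(path, "wt") as out:
        out.write(
            "transcript_id\tcancer_type\tmedian_tumor\tmax_normal\tfold\t"
            "frac_expressed\tis_tumor_srt\n"
        )
        for c in calls:
            out.write(
                f"{c.transcript_id}\t{c.cancer_type}\t{c.median_tumor:.6g}\t"
                f"{c.max_normal:.6g}\t{c.fold:.6g}\t{c.frac_expressed:.6g}\t"
                f"{str(c.passes).lower()}\n"
            )
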