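"""Consolidation of comparable isoforms.

Long-read catalogs contain near-duplicate transcript models whose exon
boundaries wobble by a few base pairs. Two transcripts are *comparable*
when they have the same exon count, their splice-site boundaries differ by
at most a small per-exon budget (default 4 bp, with at most 3 exons varied
at all), their transcription start and termination sites differ by at most
100 bp, and — for coding transcripts — their predicted ORFs are identical.
Comparable transcripts are clustered greedily, longest first, keeping the
longest member as the group representative and merging the members'
source-sample sets.

Comparability is not transitive; the deterministic greedy order (length
descending, then start, then transcript id) makes the clustering
reproducible and implements the preference for retaining the transcript of
extended length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Hashable, Iterable, Mapping, Sequence

from .model import TranscriptModel

# ORF identity is compared on genomic block coordinates; anything with a
# `genomic_blocks` attribute (or a plain tuple of intervals) works.


@dataclass
class ConsolidationParams:
    """Tolerances for calling two isoforms comparable.

    ``max_exonic_variations``: maximum number of exons allowed to differ at
    any boundary (default 3). ``max_bp_per_exon``: maximum summed absolute
    shift of an exon's internal (splice-site) boundaries (default 4 bp);
    set ``bp_cap_per_boundary`` to apply the cap to each boundary
    separately instead. ``max_end_dissimilarity``: maximum TSS and TTS
    offset (default 100 bp). ``require_identical_orf``: when both
    transcripts are coding, their predicted ORFs must coincide.
    """

    max_exonic_variations: int = 3
    max_bp_per_exon: int = 4
    max_end_dissimilarity: int = 100
    require_identical_orf: bool = True
    bp_cap_per_boundary: bool = False

    def __post_init__(self) -> None:
        if min(self.max_exonic_variations, self.max_bp_per_exon, self.max_end_dissimilarity) < 0:
            raise ValueError("consolidation thresholds must be >= 0")


@dataclass
class ConsolidationGroup:
    representative: str
    members: list[str]
    merged_source_samples: frozenset[str] = frozenset()

    @property
    def n_members(self) -> int:
        return len(self.members)


def comparable(
    a: TranscriptModel,
    b: TranscriptModel,
    params: ConsolidationParams | None = None,
    orf_a=None,
    orf_b=None,
) -> tuple[bool, str | None]:
    """Decide whether two spliced isoforms are near-identical.

    Returns ``(True, None)`` or ``(False, reason)`` where the reason names
    the first failed clause: "locus", "exon count", "bp per exon",
    "exonic variations", "end dissimilarity", or "orf".
    """
    params = params or ConsolidationParams()
    if a.chrom != b.chrom or a.strand != b.strand:
        return False, "locus"
    if a.n_exons != b.n_exons:
        return False, "exon count"

    n = a.n_exons
    varied = 0
    for i, (ea, eb) in enumerate(zip(a.exons, b.exons)):
        d_start = abs(ea.start - eb.start)
        d_end = abs(ea.end - eb.end)
        # internal boundaries = splice sites: the first exon's start and
        # last exon's end are transcript ends, governed by the 100 bp cap
        internal = []
        if i > 0:
            internal.append(d_start)
        if i < n - 1:
            internal.append(d_end)
        if params.bp_cap_per_boundary:
            if any(d > params.max_bp_per_exon for d in internal):
                return False, "bp per exon"
        elif sum(internal) > params.max_bp_per_exon:
            return False, "bp per exon"
        if d_start or d_end:
            varied += 1
    if varied > params.max_exonic_variations:
        return False, "exonic variations"

    if abs(a.tss - b.tss) > params.max_end_dissimilarity:
        return False, "end dissimilarity"
    if abs(a.tts - b.tts) > params.max_end_dissimilarity:
        return False, "end dissimilarity"

    if params.require_identical_orf and orf_a is not None and orf_b is not None:
        blocks_a = getattr(orf_a, "genomic_blocks", orf_a)
        blocks_b = getattr(orf_b, "genomic_blocks", orf_b)
        if tuple(blocks_a) != tuple(blocks_b):
            return False, "orf"
    return True, None


def _sort_key(t: TranscriptModel) -> tuple:
    return (-t.length, t.start, t.transcript_id)


def consolidate(
    transcripts: Iterable[TranscriptModel],
    params: ConsolidationParams | None = None,
    orfs: Mapping[str, object] | None = None,
    bin_key: Callable[[TranscriptModel], Hashable] | None = None,
) -> tuple[list[TranscriptModel], list[ConsolidationGroup]]:
    """Greedy longest-first clustering of comparable isoforms.

    Candidates are sorted by (length descending, start, transcript id); the
    first unassigned transcript seeds a group and absorbs every remaining
    transcript comparable to it. The seed — the longest member by
    construction — is kept as the representative, inheriting the union of
    the members' source samples.

    ``bin_key`` restricts comparison to transcripts in the same bin
    (typically the assigned locus and structural category); transcripts in
    different bins are never merged.

    Returns the representatives (sorted by genomic position then id) and
    the groups, which partition the input ids.
    """
    params = params or ConsolidationParams()
    orfs = orfs or {}
    items = sorted(transcripts, key=_sort_key)
    ids = [t.transcript_id for t in items]
    if len(set(ids)) != len(ids):
        raise ValueError("transcript ids must be unique for consolidation")

    bins: dict[Hashable, list[TranscriptModel]] = {}
    for t in items:
        key = bin_key(t) if bin_key is not None else (t.chrom, t.strand)
        bins.setdefault(key, []).append(t)

    groups: list[ConsolidationGroup] = []
    representatives: list[TranscriptModel] = []
    for key in sorted(bins, key=repr):
        pool = bins[key]  # already in greedy order
        assigned = [False] * len(pool)
        for i, seed in enumerate(pool):
            if assigned[i]:
                continue
            assigned[i] = True
            members = [seed]
            for j in range(i + 1, len(pool)):
                if assigned[j]:
                    continue
                ok, _ = comparable(
                    seed,
                    pool[j],
                    params,
                    orfs.get(seed.transcript_id),
                    orfs.get(pool[j].transcript_id),
                )
                if ok:
                    assigned[j] = True
                    members.append(pool[j])
            samples: set[str] = set()
            for m in members:
                samples.update(m.source_samples)
            rep = replace(seed, source_samples=frozenset(samples))
            representatives.append(rep)
            groups.append(
                ConsolidationGroup(
                    representative=seed.transcript_id,
                    members=[m.transcript_id for m in members],
                    merged_source_samples=frozenset(samples),
                )
            )
    order = sorted(
        range(len(representatives)),
        key=lambda k: (
            representatives[k].chrom,
            representatives[k].start,
            representatives[k].transcript_id,
        ),
    )
    return [representatives[k] for k in order], [groups[k] for k in order]


def write_groups_tsv(groups: Sequence[ConsolidationGroup], path: str | Path) -> None:
    with open(path, "wt") as out:
        out.write("representative_id\tmember_ids\tn_members\n")
        for g in groups:
            out.write(f"{g.representative}\t{','.join(g.members)}\t{g.n_members}\n")
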