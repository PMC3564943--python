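"""Potential mature Transcript Extremes (PTEs) from EST end clustering.

An EST library samples transcript fragments; the two genomic termini of
each alignment ("extremes") pile up at genuine transcript ends.  This
module turns raw extremes into classified PTEs through five steps:

1. single-linkage clustering of extremes at <=1 nt distance,
2. a minimum-support filter (>=4 member ESTs),
3. removal of clusters inside annotated exons (intronic ones are kept:
   they may be ends of alternative first/last exons),
4. removal of clusters within 25 nt of a splice site of a spliced EST
   (likely internal exon edges, not transcript ends),
5. merging of clusters closer than 25 nt (PAS positions wobble by a few
   nucleotides), keeping the most distal one, and classification of
   each survivor as a putative PAS or putative TSS by the orientation
   of the nearest reference gene: a gene transcribed *towards* the PTE
   makes it a putative PAS, a gene transcribed away makes it a putative
   TSS.

EST orientations are never consulted: only positions count.
"""

from __future__ import annotations

import bisect
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from intervaltree import IntervalTree

from .genomic_io import EstAlignment, TranscriptModel

__all__ = [
    "PteConfig",
    "PteCluster",
    "ClassifiedPte",
    "cluster_est_ends",
    "merge_proximal_clusters",
    "filter_ptes",
    "classify_pte",
    "classify_ptes",
    "est_extremes",
]

Identity = Literal["putative_PAS", "putative_TSS", "undetermined"]


@dataclass(frozen=True)
class PteConfig:
    """Distance and support constants of the PTE pipeline (all in nt)."""

    linkage_distance: int = 1
    merge_distance: int = 25
    min_support: int = 4
    splice_site_exclusion: int = 25
    max_gene_distance: int = 1_000_000

    def __post_init__(self) -> None:
        for name in (
            "linkage_distance",
            "merge_distance",
            "min_support",
            "splice_site_exclusion",
            "max_gene_distance",
        ):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")


@dataclass(frozen=True)
class PteCluster:
    """A cluster of EST extremes.

    ``position`` is the representative base: the modal member position,
    with ties broken towards the larger coordinate.  ``support`` is the
    number of member extremes.
    """

    chrom: str
    position: int
    support: int
    min_position: int
    max_position: int

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("support must be >= 1")
        if not self.min_position <= self.position <= self.max_position:
            raise ValueError("representative outside member span")


@dataclass(frozen=True)
class ClassifiedPte:
    cluster: PteCluster
    identity: Identity
    nearest_transcript_id: str | None
    distance_bp: int | None
    inferred_strand: Literal["+", "-", "."]


def est_extremes(ests: Iterable[EstAlignment]) -> list[tuple[str, int]]:
    """All alignment termini as (chrom, position) pairs, both ends of every EST."""
    out: list[tuple[str, int]] = []
    for est in ests:
        left, right = est.extremes()
        out.append((est.chrom, left))
        out.append((est.chrom, right))
    return out


def cluster_est_ends(
    extremes: Sequence[tuple[str, int]], config: PteConfig = PteConfig()
) -> list[PteCluster]:
    """Single-linkage clustering of extremes.

    Two extremes join if they are at most ``linkage_distance`` apart;
    linkage is transitive, so 100,101,102 form one cluster even though
    the outer pair is 2 apart.  Clusters are returned sorted by
    (chrom, position).
    """
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in extremes:
        by_chrom.setdefault(chrom, []).append(pos)
    clusters: list[PteCluster] = []
    for chrom in sorted(by_chrom):
        positions = sorted(by_chrom[chrom])
        run: list[int] = [positions[0]]
        for pos in positions[1:]:
            if pos - run[-1] <= config.linkage_distance:
                run.append(pos)
            else:
                clusters.append(_make_cluster(chrom, run))
                run = [pos]
        clusters.append(_make_cluster(chrom, run))
    return clusters


def _make_cluster(chrom: str, members: list[int]) -> PteCluster:
    counts = Counter(members)
    best = max(counts.items(), key=lambda kv: (kv[1], kv[0]))[0]
    return PteCluster(
        chrom=chrom,
        position=best,
        support=len(members),
        min_position=members[0],
        max_position=members[-1],
    )


# ---------------------------------------------------------------------------
# reference index


class _RefIndex:
    """Per-chromosome lookup structures over a reference transcript list."""

    def __init__(self, transcripts: Sequence[TranscriptModel]):
        self.by_chrom: dict[str, list[TranscriptModel]] = {}
        self.exon_trees: dict[str, IntervalTree] = {}
        self.span_trees: dict[str, IntervalTree] = {}
        for t in transcripts:
            self.by_chrom.setdefault(t.chrom, []).append(t)
        for chrom, ts in self.by_chrom.items():
            ts.sort(key=lambda t: (t.start, t.end, t.transcript_id))
            self.exon_trees[chrom] = IntervalTree.from_tuples(
                (e.start, e.end, t.transcript_id) for t in ts for e in t.exons
            )
            self.span_trees[chrom] = IntervalTree.from_tuples(
                (t.start, t.end, t) for t in ts
            )

    def in_exon(self, chrom: str, position: int) -> bool:
        tree = self.exon_trees.get(chrom)
        return bool(tree is not None and tree.at(position))

    def containing(self, chrom: str, position: int) -> list[TranscriptModel]:
        tree = self.span_trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.at(position)]
        hits.sort(key=lambda t: (t.start, t.end, t.transcript_id))
        return hits

    def nearest(self, chrom: str, position: int) -> tuple[int, list[TranscriptModel]]:
        """Minimum edge distance to any transcript and all transcripts at it."""
        ts = self.by_chrom.get(chrom, [])
        if not ts:
            return -1, []
        best = None
        hits: list[TranscriptModel] = []
        for t in ts:
            if t.start <= position < t.end:
                d = 0
            elif position < t.start:
                d = t.start - position
            else:
                d = position - (t.end - 1)
            if best is None or d < best:
                best, hits = d, [t]
            elif d == best:
                hits.append(t)
        hits.sort(key=lambda t: (t.start, t.end, t.transcript_id))
        return int(best), hits


# ---------------------------------------------------------------------------
# merge / filter / classify


def merge_proximal_clusters(
    clusters: Sequence[PteCluster],
    reference: Sequence[TranscriptModel],
    config: PteConfig = PteConfig(),
) -> list[PteCluster]:
    """Collapse runs of clusters closer than ``merge_distance``.

    PAS positions wobble by a few nucleotides, so clusters chained at
    pairwise distance < 25 nt are taken as one site and only the most
    distal cluster survives.  "Distal" is resolved in the transcription
    direction of the nearest reference transcript (within 1 Mb); when no
    transcript is near, or the nearest transcripts disagree on strand,
    the highest-support cluster wins (ties towards the larger
    coordinate).  Survivors are pairwise >= merge_distance apart.
    """
    index = _RefIndex(reference)
    out: list[PteCluster] = []
    by_chrom: dict[str, list[PteCluster]] = {}
    for c in sorted(clusters, key=lambda c: (c.chrom, c.position)):
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom in sorted(by_chrom):
        cs = by_chrom[chrom]
        run: list[PteCluster] = [cs[0]]
        for c in cs[1:]:
            if c.position - run[-1].position < config.merge_distance:
                run.append(c)
            else:
                out.append(_pick_survivor(run, index, config))
                run = [c]
        out.append(_pick_survivor(run, index, config))
    return out


def _pick_survivor(
    run: list[PteCluster], index: _RefIndex, config: PteConfig
) -> PteCluster:
    if len(run) == 1:
        return run[0]
    anchor = run[0].position
    dist, hits = index.nearest(run[0].chrom, anchor)
    strands = {t.strand for t in hits}
    if hits and dist <= config.max_gene_distance and len(strands) == 1:
        strand = strands.pop()
        # most distal = farthest along the direction of transcription
        if strand == "+":
            return max(run, key=lambda c: c.position)
        return min(run, key=lambda c: c.position)
    return max(run, key=lambda c: (c.support, c.position))


def filter_ptes(
    clusters: Sequence[PteCluster],
    reference: Sequence[TranscriptModel],
    ests: Sequence[EstAlignment],
    config: PteConfig = PteConfig(),
) -> list[PteCluster]:
    """Apply the support, exon and splice-site filters.

    Removes clusters (a) with support below ``min_support``, (b) whose
    representative position falls inside any reference exon (intronic
    positions are retained), and (c) within ``splice_site_exclusion``
    nt (inclusive) of any splice site of a spliced EST — such ends are
    likely unannotated internal exon boundaries, not transcript ends.
    """
    index = _RefIndex(reference)
    sites: dict[str, list[int]] = {}
    for est in ests:
        if est.spliced:
            sites.setdefault(est.chrom, []).extend(est.splice_sites())
    for chrom in sites:
        sites[chrom].sort()
    out = []
    for c in clusters:
        if c.support < config.min_support:
            continue
        if index.in_exon(c.chrom, c.position):
            continue
        if _near_site(sites.get(c.chrom, []), c.position, config.splice_site_exclusion):
            continue
        out.append(c)
    return out


def _near_site(sorted_sites: list[int], position: int, radius: int) -> bool:
    i = bisect.bisect_left(sorted_sites, position)
    for j in (i - 1, i):
        if 0 <= j < len(sorted_sites) and abs(sorted_sites[j] - position) <= radius:
            return True
    return False


def classify_pte(
    cluster: PteCluster,
    reference: Sequence[TranscriptModel],
    config: PteConfig = PteConfig(),
) -> ClassifiedPte:
    """Classify one PTE by the orientation of the nearest reference gene."""
    return _classify(cluster, _RefIndex(reference), config)


def classify_ptes(
    clusters: Sequence[PteCluster],
    reference: Sequence[TranscriptModel],
    config: PteConfig = PteConfig(),
) -> list[ClassifiedPte]:
    """Classify many PTEs, building the reference index once."""
    index = _RefIndex(reference)
    return [_classify(c, index, config) for c in clusters]


def _classify(
    cluster: PteCluster, index: _RefIndex, config: PteConfig
) -> ClassifiedPte:
    pos = cluster.position
    containing = index.containing(cluster.chrom, pos)
    if containing:
        strands = {t.strand for t in containing}
        if len(strands) > 1:
            # overlapping genes in opposite directions: identity undecidable
            return ClassifiedPte(cluster, "undetermined", containing[0].transcript_id, 0, ".")
        # inside an intron (exonic clusters were filtered): the containing
        # gene is transcribed towards the PTE, so it reads as a PAS of an
        # alternative last exon on that gene's strand
        return ClassifiedPte(
            cluster, "putative_PAS", containing[0].transcript_id, 0, strands.pop()
        )
    dist, hits = index.nearest(cluster.chrom, pos)
    if not hits or dist > config.max_gene_distance:
        return ClassifiedPte(cluster, "undetermined", None, None, ".")
    labels = set()
    for t in hits:
        towards = (t.strand == "+" and pos >= t.end) or (
            t.strand == "-" and pos < t.start
        )
        labels.add("putative_PAS" if towards else "putative_TSS")
    if len(labels) > 1:
        return ClassifiedPte(cluster, "undetermined", hits[0].transcript_id, dist, ".")
    return ClassifiedPte(cluster, labels.pop(), hits[0].transcript_id, dist, hits[0].strand)
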