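"""Cross-database support decisions and cutoff-ranked FDR curves.

A putative PAS found against one annotation database (the "examined"
database) can be checked against an independent one (the "validating"
database: another annotation set, or orthologous transcripts projected
onto the same genome).  A putative PAS is *supported* when some
validating transcript (i) ends at the same position, within a small
positional tolerance that absorbs the natural wobble of cleavage sites,
and (ii) shares its last intron with any intron of any gene in the
examined database — evidence that the two models describe the same gene
rather than coincidentally adjacent loci.

Ranking putative PASs by their score (CDI or CD) and treating every
observed score as a cutoff gives an empirical FDR curve:

    FDR(c) = #(unsupported with score >= c) / #(score >= c).

These FDRs are conservative overestimates: a genuinely used PAS that no
database has annotated yet counts as a false discovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genomic_io import TranscriptModel

__all__ = [
    "SupportDecision",
    "FdrPoint",
    "is_supported",
    "support_decisions",
    "fdr_curve",
    "fdr_frame",
]


@dataclass(frozen=True)
class SupportDecision:
    pas_id: str
    chrom: str
    pas_position: int
    supported: bool
    supporting_transcript_id: str | None
    validating_db_name: str

    def __post_init__(self) -> None:
        if self.supported != (self.supporting_transcript_id is not None):
            raise ValueError("supported flag must match presence of a supporting transcript")


@dataclass(frozen=True)
class FdrPoint:
    cutoff: float
    n: int
    n_unsupported: int
    fdr: float


class _ValidatingIndex:
    """PAS positions of validating transcripts whose last intron occurs
    among the introns of the examined database."""

    def __init__(
        self,
        validating: Sequence[TranscriptModel],
        examined: Sequence[TranscriptModel],
        db_name: str,
    ):
        self.db_name = db_name
        examined_introns = {
            (t.chrom, t.strand, i.start, i.end) for t in examined for i in t.introns()
        }
        self.by_chrom: dict[str, list[tuple[int, str]]] = {}
        for v in validating:
            li = v.last_intron()
            if li is None:
                continue
            if (v.chrom, v.strand, li.start, li.end) not in examined_introns:
                continue
            self.by_chrom.setdefault(v.chrom, []).append(
                (v.pas_position(), v.transcript_id)
            )
        for lst in self.by_chrom.values():
            lst.sort()

    def find(self, chrom: str, position: int, tolerance: int) -> str | None:
        best: tuple[int, str] | None = None
        for pas, tid in self.by_chrom.get(chrom, []):
            d = abs(pas - position)
            if d <= tolerance and (best is None or (d, tid) < best):
                best = (d, tid)
        return best[1] if best else None


def is_supported(
    chrom: str,
    pas_position: int,
    validating: Sequence[TranscriptModel],
    examined: Sequence[TranscriptModel],
    pas_tolerance: int = 25,
    pas_id: str | None = None,
    db_name: str = "validating",
) -> SupportDecision:
    """Decide support for one putative PAS.

    Supported iff some validating transcript has its PAS within
    ``pas_tolerance`` nt of ``pas_position`` *and* that transcript's
    last intron is coordinate-identical (chrom, strand, donor,
    acceptor) to an intron of some examined-database transcript.
    ``pas_tolerance=0`` gives the literal same-position reading.
    """
    index = _ValidatingIndex(validating, examined, db_name)
    tid = index.find(chrom, pas_position, pas_tolerance)
    return SupportDecision(
        pas_id=pas_id or f"{chrom}:{pas_position}",
        chrom=chrom,
        pas_position=pas_position,
        supported=tid is not None,
        supporting_transcript_id=tid,
        validating_db_name=db_name,
    )


def support_decisions(
    positions: Sequence[tuple[str, str, int]],
    validating_dbs: Mapping[str, Sequence[TranscriptModel]],
    examined: Sequence[TranscriptModel],
    pas_tolerance: int = 25,
) -> list[SupportDecision]:
    """Batch decisions for (pas_id, chrom, position) triples.

    Multiple validating databases are OR-combined: a PAS is supported if
    any of them supports it (the first matching database, in mapping
    order, is credited).
    """
    indexes = [
        _ValidatingIndex(db, examined, name) for name, db in validating_dbs.items()
    ]
    out: list[SupportDecision] = []
    for pas_id, chrom, position in positions:
        decision = None
        for index in indexes:
            tid = index.find(chrom, position, pas_tolerance)
            if tid is not None:
                decision = SupportDecision(
                    pas_id, chrom, position, True, tid, index.db_name
                )
                break
        if decision is None:
            name = "+".join(i.db_name for i in indexes) if indexes else "none"
            decision = SupportDecision(pas_id, chrom, position, False, None, name)
        out.append(decision)
    return out


def fdr_curve(
    scores: Iterable[tuple[str, float]],
    support: Sequence[SupportDecision] | Mapping[str, bool],
) -> list[FdrPoint]:
    """Empirical FDR at every distinct observed score used as a cutoff.

    ``scores`` are (pas_id, score) pairs; undefined scores (NaN/None)
    are excluded.  Each distinct score becomes one cutoff (ties collapse
    to a single point), points are sorted by descending cutoff, and at
    each cutoff FDR = unsupported fraction among PASs with score >=
    cutoff.
    """
    if isinstance(support, Mapping):
        supported = dict(support)
    else:
        supported = {d.pas_id: d.supported for d in support}
    items: list[tuple[float, bool]] = []
    for pas_id, score in scores:
        if score is None or (isinstance(score, float) and math.isnan(score)):
            continue
        if pas_id not in supported:
            raise KeyError(f"no support decision for scored PAS {pas_id!r}")
        items.append((float(score), supported[pas_id]))
    items.sort(key=lambda x: -x[0])
    points: list[FdrPoint] = []
    n = n_unsup = 0
    for i, (score, is_sup) in enumerate(items):
        n += 1
        n_unsup += not is_sup
        last_of_tie = i + 1 == len(items) or items[i + 1][0] != score
        if last_of_tie:
            points.append(FdrPoint(score, n, n_unsup, n_unsup / n))
    return points


def fdr_frame(points: Sequence[FdrPoint]) -> pd.DataFrame:
    """FDR curve as a table with a 1-based rank column.

    The rank scale spaces contiguous cutoffs evenly regardless of the
    absolute score differences, which is how these curves are usually
    plotted.
    """
    return pd.DataFrame(
        {
            "rank": range(1, len(points) + 1),
            "cutoff": [p.cutoff for p in points],
            "n": [p.n for p in points],
            "n_unsupported": [p.n_unsupported for p in points],
            "fdr": [p.fdr for p in points],
        }
    )
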