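"""3'UTR extension candidates from orthologous models, scored by the
Coverage Difference (CD).

Orthologous transcripts projected onto the reference genome (e.g. by
TransMap) sometimes end farther downstream than the annotated model of
the same gene.  When a projected transcript shares the annotated
transcript's *last intron* exactly — same chromosome, strand, donor and
acceptor — but has a more distal PAS, its last exon proposes a 3'UTR
extension.  RNA-seq then arbitrates: if transcription really continues
to the proposed PAS, the extension interval ("Up", from the annotated
PAS to the proposed one) is covered by reads while the equal-length
interval immediately beyond ("Down") is not.  The score is

    CD = %covered(Up) - %covered(Down)

with a base counted as covered iff its depth is >= 1 (read orientation
and depth beyond 1 are deliberately ignored).  CD = 100 means a fully
covered extension with a silent flank — a strong PAS; CD = 0 means no
transcriptional change across the proposed end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd

from .genomic_io import GenomicInterval, ScoreTrack, TranscriptModel

__all__ = [
    "ExtensionCandidate",
    "CdResult",
    "find_extension_candidates",
    "compute_cd",
    "compute_cd_table",
    "merge_tissue_coverage",
    "cd_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExtensionCandidate:
    """A proposed 3'UTR extension of one reference transcript.

    ``up`` spans from the base after the annotated PAS through the
    proposed PAS (in transcription direction); ``down`` is the interval
    of the same length immediately beyond the proposed PAS, possibly
    truncated at a chromosome bound (flagged).
    """

    reference_transcript_id: str
    ortho_transcript_id: str
    chrom: str
    strand: Literal["+", "-"]
    annotated_pas: int
    putative_pas: int
    up: GenomicInterval
    down: GenomicInterval
    down_truncated: bool = False

    @property
    def extension_length(self) -> int:
        return self.up.length()


@dataclass(frozen=True)
class CdResult:
    candidate: ExtensionCandidate
    up_pct: float
    down_pct: float
    cd: float
    valid: bool = True


def find_extension_candidates(
    reference: Sequence[TranscriptModel],
    ortho: Sequence[TranscriptModel],
    min_extension: int = 1,
    collapse: Literal["most-distal"] | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> list[ExtensionCandidate]:
    """Pair reference and orthologous transcripts that share a last intron.

    A candidate is emitted for every (reference, ortho) pair on the same
    chromosome and strand whose last introns are coordinate-identical
    and where the ortho PAS is strictly more distal (by at least
    ``min_extension`` nt) in the transcription direction.  Single-exon
    transcripts have no last intron and are skipped with a log notice.
    ``collapse='most-distal'`` keeps only the farthest-reaching
    candidate per reference transcript.
    """
    by_intron: dict[tuple[str, str, int, int], list[TranscriptModel]] = {}
    for r in reference:
        li = r.last_intron()
        if li is None:
            logger.info("skipping single-exon reference transcript %s", r.transcript_id)
            continue
        by_intron.setdefault((r.chrom, r.strand, li.start, li.end), []).append(r)

    candidates: list[ExtensionCandidate] = []
    for o in ortho:
        li = o.last_intron()
        if li is None:
            logger.info("skipping single-exon ortho transcript %s", o.transcript_id)
            continue
        for r in by_intron.get((o.chrom, o.strand, li.start, li.end), []):
            cand = _make_candidate(r, o, min_extension, chrom_lengths)
            if cand is not None:
                candidates.append(cand)

    if collapse == "most-distal":
        best: dict[str, ExtensionCandidate] = {}
        for c in candidates:
            cur = best.get(c.reference_transcript_id)
            if (
                cur is None
                or c.extension_length > cur.extension_length
                or (
                    c.extension_length == cur.extension_length
                    and c.ortho_transcript_id < cur.ortho_transcript_id
                )
            ):
                best[c.reference_transcript_id] = c
        candidates = list(best.values())
    candidates.sort(
        key=lambda c: (c.chrom, c.annotated_pas, c.reference_transcript_id, c.ortho_transcript_id)
    )
    return candidates


def _make_candidate(
    r: TranscriptModel,
    o: TranscriptModel,
    min_extension: int,
    chrom_lengths: dict[str, int] | None,
) -> ExtensionCandidate | None:
    ref_pas, ortho_pas = r.pas_position(), o.pas_position()
    if r.strand == "+":
        ext = ortho_pas - ref_pas
    else:
        ext = ref_pas - ortho_pas
    if ext < min_extension:
        return None
    chrom_len = (chrom_lengths or {}).get(r.chrom)
    if r.strand == "+":
        up = GenomicInterval(r.chrom, ref_pas + 1, ortho_pas + 1, "+")
        down_end = ortho_pas + 1 + ext
        truncated = chrom_len is not None and down_end > chrom_len
        if truncated:
            down_end = chrom_len
        if down_end <= ortho_pas + 1:
            return None
        down = GenomicInterval(r.chrom, ortho_pas + 1, down_end, "+")
    else:
        up = GenomicInterval(r.chrom, ortho_pas, ref_pas, "-")
        down_start = ortho_pas - ext
        truncated = down_start < 0
        if truncated:
            down_start = 0
        if down_start >= ortho_pas:
            return None
        down = GenomicInterval(r.chrom, down_start, ortho_pas, "-")
    return ExtensionCandidate(
        reference_transcript_id=r.transcript_id,
        ortho_transcript_id=o.transcript_id,
        chrom=r.chrom,
        strand=r.strand,
        annotated_pas=ref_pas,
        putative_pas=ortho_pas,
        up=up,
        down=down,
        down_truncated=truncated,
    )


def compute_cd(candidate: ExtensionCandidate, coverage: ScoreTrack) -> CdResult:
    """CD for one candidate: percent-covered(Up) minus percent-covered(Down).

    A base is covered iff its depth is >= 1; each percentage is taken
    over its own interval's (possibly truncated) length.
    """
    if coverage.role != "coverage":
        raise ValueError("compute_cd requires a coverage-role track")
    up_len, down_len = candidate.up.length(), candidate.down.length()
    if up_len == 0 or down_len == 0:
        return CdResult(candidate, float("nan"), float("nan"), float("nan"), valid=False)
    up_pct = 100.0 * coverage.covered_count(candidate.up) / up_len
    down_pct = 100.0 * coverage.covered_count(candidate.down) / down_len
    return CdResult(candidate, up_pct, down_pct, up_pct - down_pct)


def compute_cd_table(
    candidates: Iterable[ExtensionCandidate], coverage: ScoreTrack
) -> list[CdResult]:
    return [compute_cd(c, coverage) for c in candidates]


def merge_tissue_coverage(tracks: Sequence[ScoreTrack]) -> ScoreTrack:
    """Pool per-tissue coverage by per-base depth summation.

    A base is covered in the pooled track iff it is covered in any
    tissue, matching the binary covered/uncovered definition of the CD.
    """
    if not tracks:
        raise ValueError("need at least one coverage track")
    merged = tracks[0]
    for t in tracks[1:]:
        merged = merged.add(t)
    return merged


def cd_frame(results: Sequence[CdResult]) -> pd.DataFrame:
    """CD results as a table, sorted by CD descending."""
    df = pd.DataFrame(
        {
            "reference_transcript": [r.candidate.reference_transcript_id for r in results],
            "ortho_transcript": [r.candidate.ortho_transcript_id for r in results],
            "chrom": [r.candidate.chrom for r in results],
            "strand": [r.candidate.strand for r in results],
            "annotated_pas": [r.candidate.annotated_pas for r in results],
            "putative_pas": [r.candidate.putative_pas for r in results],
            "extension_length": [r.candidate.extension_length for r in results],
            "up_pct": [r.up_pct for r in results],
            "down_pct": [r.down_pct for r in results],
            "cd": [r.cd for r in results],
            "valid": [r.valid for r in results],
        }
    )
    return df.sort_values("cd", ascending=False, kind="stable").reset_index(drop=True)
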