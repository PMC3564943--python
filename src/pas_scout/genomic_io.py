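"""Genomic coordinate model and text-format I/O.

Everything downstream of the readers works in a single coordinate
convention: 0-based, half-open intervals, as in BED.  GTF exon features
(1-based inclusive) and fixedStep wiggle tracks (1-based starts) are
converted at the boundary and never leak their native conventions into
the rest of the package.  This matters because the method is built on
small fixed windows (50-nt conservation windows, 25-nt exclusion radii)
where off-by-one drift silently changes every statistic.

Formats handled: BED12 (UCSC dialect) for transcript models and EST
alignments, GTF2.2 exon features, fixedStep WIG and bedGraph score
tracks.  Binary formats (BAM, bigWig) are out of scope; depth should be
converted to bedGraph with e.g. ``bedtools genomecov -bga`` upstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import gffutils
import numpy as np

Strand = Literal["+", "-", "."]

__all__ = [
    "FormatError",
    "GenomicInterval",
    "TranscriptModel",
    "EstAlignment",
    "ScoreTrack",
    "TrackStats",
    "read_bed12",
    "write_bed12",
    "read_gtf",
    "write_gtf",
    "read_track",
    "write_fixedstep_wig",
    "write_bedgraph",
    "read_table",
    "write_table",
    "mirror_position",
    "mirror_interval",
    "mirror_transcript",
    "mirror_est",
    "mirror_track",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def _flip(strand: Strand) -> Strand:
    return {"+": "-", "-": "+", ".": "."}[strand]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: Strand = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded, multi-exon gene model.

    Exons are stored in ascending genomic order regardless of strand;
    strand only enters through the derived accessors (``tss``,
    ``pas_position``, ``last_intron``), which report the transcript's
    5'/3' geometry.  Positions returned by the accessors are base
    coordinates (the offset of a single base), not half-open bounds.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: Strand
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript {self.transcript_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: needs >=1 exon")
        object.__setattr__(self, "exons", tuple(self.exons))
        for a, b in itertools.pairwise(self.exons):
            if a.chrom != b.chrom:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons on multiple chromosomes"
                )
            if b.start < a.end + 1:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons must be ascending and "
                    "separated by >=1 base"
                )
        if any(e.chrom != self.chrom for e in self.exons):
            raise ValueError(f"transcript {self.transcript_id}: exon chrom mismatch")

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    def tss(self) -> int:
        """First transcribed base (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1

    def pas_position(self) -> int:
        """Last transcribed base — the cleavage/polyadenylation site."""
        return self.end - 1 if self.strand == "+" else self.start

    def introns(self) -> tuple[GenomicInterval, ...]:
        return tuple(
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in itertools.pairwise(self.exons)
        )

    def last_intron(self) -> GenomicInterval | None:
        """The intron nearest the 3' end, or None for single-exon models."""
        introns = self.introns()
        if not introns:
            return None
        return introns[-1] if self.strand == "+" else introns[0]


@dataclass(frozen=True)
class EstAlignment:
    """A (possibly spliced) EST alignment.

    The alignment orientation is carried through from the input but is
    deliberately ignored by all downstream logic: EST libraries mix
    orientations, so only the two genomic termini are evidence.
    """

    est_id: str
    chrom: str
    blocks: tuple[GenomicInterval, ...]
    strand: Strand = "."

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"EST {self.est_id}: needs >=1 block")
        object.__setattr__(self, "blocks", tuple(self.blocks))
        for a, b in itertools.pairwise(self.blocks):
            if b.start < a.end + 1:
                raise ValueError(f"EST {self.est_id}: blocks must be ascending")

    @property
    def spliced(self) -> bool:
        return len(self.blocks) >= 2

    def extremes(self) -> tuple[int, int]:
        """The two outermost aligned bases (leftmost, rightmost)."""
        return self.blocks[0].start, self.blocks[-1].end - 1

    def splice_sites(self) -> tuple[int, ...]:
        """Exon-edge bases flanking each internal gap.

        For each junction this yields the last base of the upstream
        block and the first base of the downstream block.  Empty for
        single-block alignments.
        """
        sites: list[int] = []
        for a, b in itertools.pairwise(self.blocks):
            sites.extend((a.end - 1, b.start))
        return tuple(sites)


# ---------------------------------------------------------------------------
# score tracks


@dataclass(frozen=True)
class TrackStats:
    """Summary of a track over one interval."""

    mean: float
    value_fraction: float
    n_values: int


class ScoreTrack:
    """Sparse per-base numeric signal (conservation score or read depth).

    The missing-data semantics are declared at construction via ``role``:

    * ``conservation`` — bases without an entry are *missing* (PhyloP is
      undefined where the alignment has gaps); means are taken over the
      present bases only and the fraction of present bases is reported.
    * ``coverage`` — bases without an entry have depth 0; depths must be
      non-negative.
    """

    def __init__(
        self,
        role: Literal["conservation", "coverage"],
        data: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
    ) -> None:
        if role not in ("conservation", "coverage"):
            raise ValueError(f"unknown track role {role!r}")
        self.role = role
        self._pos: dict[str, np.ndarray] = {}
        self._val: dict[str, np.ndarray] = {}
        if data:
            for chrom, (pos, val) in data.items():
                self._set_chrom(chrom, pos, val)

    def _set_chrom(self, chrom: str, pos: np.ndarray, val: np.ndarray) -> None:
        pos = np.asarray(pos, dtype=np.int64)
        val = np.asarray(val, dtype=np.float64)
        if pos.shape != val.shape:
            raise ValueError("positions and values must align")
        order = np.argsort(pos, kind="stable")
        pos, val = pos[order], val[order]
        if pos.size and np.any(np.diff(pos) == 0):
            raise FormatError(f"duplicate positions on {chrom}")
        if self.role == "coverage" and np.any(val < 0):
            raise FormatError(f"negative depth on {chrom}")
        self._pos[chrom] = pos
        self._val[chrom] = val

    @classmethod
    def from_dict(
        cls,
        role: Literal["conservation", "coverage"],
        values: dict[str, dict[int, float]],
    ) -> "ScoreTrack":
        data = {
            chrom: (
                np.fromiter(d.keys(), dtype=np.int64, count=len(d)),
                np.fromiter(d.values(), dtype=np.float64, count=len(d)),
            )
            for chrom, d in values.items()
        }
        return cls(role, data)

    def chroms(self) -> list[str]:
        return sorted(self._pos)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        return self._pos.get(chrom, np.empty(0, np.int64)), self._val.get(
            chrom, np.empty(0, np.float64)
        )

    def _window(self, interval: GenomicInterval) -> tuple[np.ndarray, np.ndarray]:
        pos, val = self.arrays(interval.chrom)
        lo = np.searchsorted(pos, interval.start, side="left")
        hi = np.searchsorted(pos, interval.end, side="left")
        return pos[lo:hi], val[lo:hi]

    def mean_over(self, interval: GenomicInterval) -> TrackStats:
        """Average the track over ``interval`` under the role's semantics."""
        _, val = self._window(interval)
        n = interval.length()
        if self.role == "coverage":
            return TrackStats(mean=float(val.sum()) / n, value_fraction=1.0, n_values=n)
        if val.size == 0:
            return TrackStats(mean=float("nan"), value_fraction=0.0, n_values=0)
        return TrackStats(
            mean=float(val.mean()),
            value_fraction=val.size / n,
            n_values=int(val.size),
        )

    def covered_count(self, interval: GenomicInterval) -> int:
        """Number of bases in ``interval`` with depth >= 1 (coverage role)."""
        if self.role != "coverage":
            raise ValueError("covered_count requires a coverage-role track")
        _, val = self._window(interval)
        return int(np.count_nonzero(val >= 1))

    def values_over(self, interval: GenomicInterval) -> np.ndarray:
        """Dense per-base values; NaN where missing (conservation) or 0 (coverage)."""
        fill = 0.0 if self.role == "coverage" else float("nan")
        out = np.full(interval.length(), fill)
        pos, val = self._window(interval)
        out[pos - interval.start] = val
        return out

    def add(self, other: "ScoreTrack") -> "ScoreTrack":
        """Per-base sum of two tracks of the same role."""
        if other.role != self.role:
            raise ValueError("cannot add tracks of different roles")
        merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in set(self._pos) | set(other._pos):
            p1, v1 = self.arrays(chrom)
            p2, v2 = other.arrays(chrom)
            pos = np.concatenate([p1, p2])
            val = np.concatenate([v1, v2])
            upos, inv = np.unique(pos, return_inverse=True)
            uval = np.zeros(upos.size)
            np.add.at(uval, inv, val)
            merged[chrom] = (upos, uval)
        return ScoreTrack(self.role, merged)


# ---------------------------------------------------------------------------
# BED12


_BED12_N = 12


def _parse_bed12_line(line: str, lineno: int) -> tuple[str, int, int, str, Strand, list[GenomicInterval]]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < _BED12_N:
        raise FormatError(f"line {lineno}: BED12 needs >=12 tab-separated fields, got {len(fields)}")
    chrom, name, strand = fields[0], fields[3], fields[5]
    try:
        chrom_start, chrom_end = int(fields[1]), int(fields[2])
        block_count = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise FormatError(f"line {lineno}: {exc}") from None
    if strand not in ("+", "-", "."):
        raise FormatError(f"line {lineno}: bad strand {strand!r}")
    if len(sizes) != block_count or len(starts) != block_count:
        raise FormatError(
            f"line {lineno}: blockCount {block_count} does not match "
            f"{len(sizes)} sizes / {len(starts)} starts"
        )
    if block_count < 1:
        raise FormatError(f"line {lineno}: blockCount must be >=1")
    if starts[0] != 0:
        raise FormatError(f"line {lineno}: first blockStart must be 0")
    blocks: list[GenomicInterval] = []
    prev_end = -1
    for size, rel in zip(sizes, starts):
        if size < 1:
            raise FormatError(f"line {lineno}: block size must be >=1")
        s = chrom_start + rel
        if s <= prev_end:
            raise FormatError(f"line {lineno}: blocks overlap or touch")
        blocks.append(GenomicInterval(chrom, s, s + size, strand))
        prev_end = s + size
    if blocks[-1].end != chrom_end:
        raise FormatError(
            f"line {lineno}: last block ends at {blocks[-1].end}, expected chromEnd {chrom_end}"
        )
    return chrom, chrom_start, chrom_end, name, strand, blocks


def read_bed12(
    path: str | Path, kind: Literal["transcript", "est"] = "transcript"
) -> list[TranscriptModel] | list[EstAlignment]:
    """Read a BED12 file as transcript models or EST alignments.

    BED12 carries no gene identifier, so ``gene_id`` defaults to the
    record name.  Record order is preserved.
    """
    out: list = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, _, _, name, strand, blocks = _parse_bed12_line(line, lineno)
            if kind == "transcript":
                if strand == ".":
                    raise FormatError(f"line {lineno}: transcript models need a strand")
                out.append(
                    TranscriptModel(
                        transcript_id=name,
                        gene_id=name,
                        chrom=chrom,
                        strand=strand,
                        exons=tuple(blocks),
                    )
                )
            else:
                out.append(
                    EstAlignment(est_id=name, chrom=chrom, blocks=tuple(blocks), strand=strand)
                )
    return out


def write_bed12(path: str | Path, records: Iterable[TranscriptModel | EstAlignment]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, TranscriptModel):
                name, blocks, strand = rec.transcript_id, rec.exons, rec.strand
            else:
                name, blocks, strand = rec.est_id, rec.blocks, rec.strand
            chrom_start = blocks[0].start
            chrom_end = blocks[-1].end
            sizes = ",".join(str(b.length()) for b in blocks)
            starts = ",".join(str(b.start - chrom_start) for b in blocks)
            fh.write(
                "\t".join(
                    (
                        blocks[0].chrom,
                        str(chrom_start),
                        str(chrom_end),
                        name,
                        "0",
                        strand,
                        str(chrom_start),
                        str(chrom_end),
                        "0",
                        str(len(blocks)),
                        sizes,
                        starts,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GTF


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read GTF2.2 exon features into transcript models.

    Exon coordinates (1-based inclusive) are converted to internal
    0-based half-open intervals; exons are sorted ascending per
    transcript.  Transcripts appear in order of first occurrence.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene_id, chrom, strand)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                feat = gffutils.feature.feature_from_line(line, dialect=None)
            except Exception as exc:
                raise FormatError(f"line {lineno}: {exc}") from None
            if feat.featuretype != "exon":
                continue
            tids = feat.attributes.get("transcript_id")
            if not tids:
                raise FormatError(f"line {lineno}: exon feature without transcript_id")
            tid = tids[0]
            gids = feat.attributes.get("gene_id")
            gid = gids[0] if gids else tid
            if feat.strand not in ("+", "-"):
                raise FormatError(f"line {lineno}: exon needs an explicit strand")
            iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            if tid in meta:
                _, chrom0, strand0 = meta[tid]
                if feat.strand != strand0:
                    raise FormatError(f"line {lineno}: mixed strands within transcript {tid}")
                if feat.seqid != chrom0:
                    raise FormatError(f"line {lineno}: mixed chromosomes within transcript {tid}")
            else:
                meta[tid] = (gid, feat.seqid, feat.strand)
            exons.setdefault(tid, []).append(iv)
    out = []
    for tid, ivs in exons.items():
        gid, chrom, strand = meta[tid]
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                exons=tuple(sorted(ivs, key=lambda e: e.start)),
            )
        )
    return out


def write_gtf(path: str | Path, transcripts: Iterable[TranscriptModel], source: str = "pas_scout") -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            for exon in t.exons:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    "\t".join(
                        (
                            t.chrom,
                            source,
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            t.strand,
                            ".",
                            attrs,
                        )
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# score-track I/O (fixedStep WIG + bedGraph)


def _parse_fixedstep_header(line: str, lineno: int) -> tuple[str, int, int]:
    kv = dict(part.split("=", 1) for part in line.split()[1:] if "=" in part)
    try:
        chrom = kv["chrom"]
        start = int(kv["start"])
    except KeyError as exc:
        raise FormatError(f"line {lineno}: fixedStep header missing {exc}") from None
    step = int(kv.get("step", 1))
    if step != 1:
        raise FormatError(f"line {lineno}: only step=1 fixedStep tracks are supported")
    if start < 1:
        raise FormatError(f"line {lineno}: fixedStep start is 1-based and must be >=1")
    return chrom, start, step


def read_track(
    path: str | Path, role: Literal["conservation", "coverage"]
) -> ScoreTrack:
    """Read a per-base score track (fixedStep WIG or bedGraph).

    The dialect is auto-detected: ``fixedStep`` headers introduce WIG
    blocks (1-based starts, converted internally), while 4-column
    numeric lines are bedGraph records (already 0-based half-open) whose
    intervals are expanded to per-base values.  Overlapping bedGraph
    records are an error, as are negative depths in the coverage role.
    """
    per_chrom_pos: dict[str, list[np.ndarray]] = {}
    per_chrom_val: dict[str, list[np.ndarray]] = {}
    bedgraph_spans: dict[str, list[tuple[int, int]]] = {}

    def flush_block(chrom: str, start0: int, values: list[str], lineno: int) -> None:
        if not values:
            return
        try:
            arr = np.asarray(values, dtype=np.float64)
        except ValueError as exc:
            raise FormatError(f"near line {lineno}: bad wiggle value ({exc})") from None
        per_chrom_pos.setdefault(chrom, []).append(
            np.arange(start0, start0 + arr.size, dtype=np.int64)
        )
        per_chrom_val.setdefault(chrom, []).append(arr)

    block_chrom: str | None = None
    block_start0 = 0
    block_values: list[str] = []
    lineno = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                if block_chrom is not None:
                    flush_block(block_chrom, block_start0, block_values, lineno)
                chrom, start1, _ = _parse_fixedstep_header(line, lineno)
                block_chrom, block_start0, block_values = chrom, start1 - 1, []
                continue
            if line.startswith("variableStep"):
                raise FormatError(f"line {lineno}: unknown track header (variableStep unsupported)")
            fields = line.split()
            if len(fields) == 1:
                if block_chrom is None:
                    raise FormatError(f"line {lineno}: wiggle value outside a fixedStep block")
                block_values.append(fields[0])
                continue
            if len(fields) == 4:
                if block_chrom is not None:
                    flush_block(block_chrom, block_start0, block_values, lineno)
                    block_chrom, block_values = None, []
                chrom = fields[0]
                try:
                    start, end = int(fields[1]), int(fields[2])
                    value = float(fields[3])
                except ValueError as exc:
                    raise FormatError(f"line {lineno}: {exc}") from None
                if not 0 <= start < end:
                    raise FormatError(f"line {lineno}: bad bedGraph interval {start}-{end}")
                if role == "coverage" and value < 0:
                    raise FormatError(f"line {lineno}: negative depth {value}")
                bedgraph_spans.setdefault(chrom, []).append((start, end))
                per_chrom_pos.setdefault(chrom, []).append(
                    np.arange(start, end, dtype=np.int64)
                )
                per_chrom_val.setdefault(chrom, []).append(np.full(end - start, value))
                continue
            raise FormatError(f"line {lineno}: unrecognized track line {line!r}")
    if block_chrom is not None:
        flush_block(block_chrom, block_start0, block_values, lineno)

    for chrom, spans in bedgraph_spans.items():
        spans.sort()
        for (s1, e1), (s2, _) in itertools.pairwise(spans):
            if s2 < e1:
                raise FormatError(f"overlapping bedGraph records on {chrom} at {s2}")

    data = {
        chrom: (np.concatenate(per_chrom_pos[chrom]), np.concatenate(per_chrom_val[chrom]))
        for chrom in per_chrom_pos
    }
    return ScoreTrack(role, data)


def write_fixedstep_wig(
    path: str | Path, chrom: str, start: int, values: Sequence[float] | np.ndarray
) -> None:
    """Write one contiguous fixedStep block; ``start`` is 0-based internal."""
    with open(path, "w") as fh:
        fh.write(f"fixedStep chrom={chrom} start={start + 1} step=1\n")
        np.savetxt(fh, np.asarray(values, dtype=np.float64), fmt="%.4f")


def write_bedgraph(
    path: str | Path, records: Iterable[tuple[str, int, int, float]]
) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in records:
            val = int(value) if float(value).is_integer() else value
            fh.write(f"{chrom}\t{start}\t{end}\t{val}\n")


# ---------------------------------------------------------------------------
# TSV tables (commented header line)


def write_table(df, path: str | Path) -> None:
    """Write a DataFrame as TSV with a commented header line."""
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_table(path: str | Path):
    import pandas as pd

    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise FormatError(f"{path}: expected a commented header line")
        columns = header.lstrip("#").strip().split("\t")
        try:
            df = pd.read_csv(fh, sep="\t", header=None, names=columns)
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(columns=columns)
    return df


# ---------------------------------------------------------------------------
# genome-mirror transform (P -> L-1-P with strand flip)
#
# Used by tests and by users who want to verify orientation handling:
# every statistic in the package is invariant under this reflection.


def mirror_position(position: int, chrom_length: int) -> int:
    return chrom_length - 1 - position


def mirror_interval(iv: GenomicInterval, chrom_length: int) -> GenomicInterval:
    return GenomicInterval(
        iv.chrom, chrom_length - iv.end, chrom_length - iv.start, _flip(iv.strand)
    )


def mirror_transcript(t: TranscriptModel, chrom_length: int) -> TranscriptModel:
    exons = tuple(
        sorted(
            (mirror_interval(e, chrom_length) for e in t.exons), key=lambda e: e.start
        )
    )
    return TranscriptModel(
        transcript_id=t.transcript_id,
        gene_id=t.gene_id,
        chrom=t.chrom,
        strand=_flip(t.strand),
        exons=exons,
    )


def mirror_est(est: EstAlignment, chrom_length: int) -> EstAlignment:
    blocks = tuple(
        sorted(
            (mirror_interval(b, chrom_length) for b in est.blocks), key=lambda b: b.start
        )
    )
    return EstAlignment(est.est_id, est.chrom, blocks, _flip(est.strand))


def mirror_track(track: ScoreTrack, chrom_length: int) -> ScoreTrack:
    data = {}
    for chrom in track.chroms():
        pos, val = track.arrays(chrom)
        data[chrom] = (chrom_length - 1 - pos, val)
    return ScoreTrack(track.role, data)
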