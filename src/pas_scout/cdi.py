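"""Conservation Drop Index (CDI) at transcript extremes.

Genomic conservation of a 3'UTR typically collapses just downstream of
the cleavage/polyadenylation site, because selection acts on the mature
transcript but not on the adjacent intergenic sequence.  The CDI
quantifies that drop at a candidate end: take the mean per-base
conservation (e.g. PhyloP) of the 50-nt window *inside* the mature
transcript that finishes at the end ("T"), the mean of the 50-nt window
starting 50 nt *outside* the end ("NT"), and report

    CDI = mean(T) - mean(NT).

The 50-nt gap between the two windows skips the downstream sequence
element (DSE), a moderately conserved G/GU-rich region ~25 nt past the
cleavage site that would otherwise contaminate the outside window.  A
strongly positive CDI at a putative PAS is the signature of a genuine,
evolutionarily maintained 3' end; TSSs show no comparable drop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .genomic_io import GenomicInterval, ScoreTrack
from .pte import ClassifiedPte

__all__ = [
    "CdiConfig",
    "Anchor",
    "WindowPair",
    "CdiResult",
    "cdi_windows",
    "compute_cdi",
    "cdi_table",
    "anchors_from_classified",
    "cdi_frame",
    "cdi_histogram",
]

EndType = Literal["three_prime", "five_prime"]


@dataclass(frozen=True)
class CdiConfig:
    """Window geometry and usability threshold for the CDI.

    ``window``: length (nt) of each of the T and NT windows.
    ``gap``: bases skipped between the transcript end and the NT window
    (accounts for the DSE).  ``min_value_fraction``: minimum fraction of
    bases with a defined conservation value each window must have for
    the CDI to be considered defined.
    """

    window: int = 50
    gap: int = 50
    min_value_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.gap < 0:
            raise ValueError("gap must be >= 0")
        if not 0 < self.min_value_fraction <= 1:
            raise ValueError("min_value_fraction must be in (0, 1]")


@dataclass(frozen=True)
class Anchor:
    """A transcript extreme to score: a base position, strand and end type.

    ``position`` is the first (five_prime) or last (three_prime)
    transcribed base itself; the anchor base belongs to the T window.
    """

    chrom: str
    position: int
    strand: Literal["+", "-"]
    end_type: EndType
    name: str = ""


@dataclass(frozen=True)
class WindowPair:
    t: GenomicInterval | None
    nt: GenomicInterval | None
    t_truncated: bool = False
    nt_truncated: bool = False


@dataclass(frozen=True)
class CdiResult:
    anchor: Anchor
    t_mean: float
    nt_mean: float
    cdi: float
    t_value_fraction: float
    nt_value_fraction: float
    defined: bool
    truncated: bool = False


def _clamp(
    chrom: str, start: int, end: int, strand: str, chrom_length: int | None
) -> tuple[GenomicInterval | None, bool]:
    lo, hi = max(start, 0), end if chrom_length is None else min(end, chrom_length)
    if lo >= hi:
        return None, True
    return GenomicInterval(chrom, lo, hi, strand), (lo != start or hi != end)


def cdi_windows(
    anchor: Anchor, config: CdiConfig = CdiConfig(), chrom_length: int | None = None
) -> WindowPair:
    """The T (inside) and NT (outside) windows for an anchor.

    The outside direction points away from the transcript body: rightward
    for a + strand 3' end or a - strand 5' end, leftward otherwise.  With
    window w, gap g and anchor base p (outside pointing right):
    T = [p-w+1, p+1) and NT = [p+g+1, p+g+1+w).  Windows are truncated at
    chromosome bounds and flagged, never raised.
    """
    w, g, p = config.window, config.gap, anchor.position
    outside_right = (anchor.strand == "+") == (anchor.end_type == "three_prime")
    if outside_right:
        t_raw = (p - w + 1, p + 1)
        nt_raw = (p + g + 1, p + g + 1 + w)
    else:
        t_raw = (p, p + w)
        nt_raw = (p - g - w, p - g)
    t, t_trunc = _clamp(anchor.chrom, *t_raw, anchor.strand, chrom_length)
    nt, nt_trunc = _clamp(anchor.chrom, *nt_raw, anchor.strand, chrom_length)
    return WindowPair(t, nt, t_trunc, nt_trunc)


def compute_cdi(
    anchor: Anchor,
    track: ScoreTrack,
    config: CdiConfig = CdiConfig(),
    chrom_length: int | None = None,
) -> CdiResult:
    """CDI at one anchor from a conservation track.

    Means are taken over non-missing bases only; the result is flagged
    undefined when either window has fewer than ``min_value_fraction``
    of its bases defined (or vanished entirely after truncation).
    """
    if track.role != "conservation":
        raise ValueError("compute_cdi requires a conservation-role track")
    pair = cdi_windows(anchor, config, chrom_length)
    stats = [
        track.mean_over(iv) if iv is not None else None for iv in (pair.t, pair.nt)
    ]
    t_stats, nt_stats = stats
    t_mean = t_stats.mean if t_stats else float("nan")
    nt_mean = nt_stats.mean if nt_stats else float("nan")
    t_frac = t_stats.value_fraction if t_stats else 0.0
    nt_frac = nt_stats.value_fraction if nt_stats else 0.0
    defined = (
        t_frac >= config.min_value_fraction and nt_frac >= config.min_value_fraction
    )
    cdi = t_mean - nt_mean if defined else float("nan")
    return CdiResult(
        anchor=anchor,
        t_mean=t_mean,
        nt_mean=nt_mean,
        cdi=cdi,
        t_value_fraction=t_frac,
        nt_value_fraction=nt_frac,
        defined=defined,
        truncated=pair.t_truncated or pair.nt_truncated,
    )


def cdi_table(
    anchors: Iterable[Anchor],
    track: ScoreTrack,
    config: CdiConfig = CdiConfig(),
    chrom_length: int | None = None,
) -> list[CdiResult]:
    """One CdiResult per anchor, order preserving."""
    return [compute_cdi(a, track, config, chrom_length) for a in anchors]


def anchors_from_classified(ptes: Iterable[ClassifiedPte]) -> list[Anchor]:
    """Anchors for classified PTEs.

    A putative PAS is scored as a 3' end on the classifying gene's
    strand, a putative TSS as a 5' end.  An undetermined PTE has no
    resolved polarity, so both orientations are emitted as a pair
    (suffixes ``|fwd`` and ``|rev``: inside-left and inside-right).
    """
    anchors: list[Anchor] = []
    for p in ptes:
        c = p.cluster
        name = f"{c.chrom}:{c.position}"
        if p.identity == "putative_PAS":
            anchors.append(Anchor(c.chrom, c.position, p.inferred_strand, "three_prime", name))
        elif p.identity == "putative_TSS":
            anchors.append(Anchor(c.chrom, c.position, p.inferred_strand, "five_prime", name))
        else:
            anchors.append(Anchor(c.chrom, c.position, "+", "three_prime", name + "|fwd"))
            anchors.append(Anchor(c.chrom, c.position, "-", "three_prime", name + "|rev"))
    return anchors


def cdi_frame(results: Sequence[CdiResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [r.anchor.name for r in results],
            "chrom": [r.anchor.chrom for r in results],
            "position": [r.anchor.position for r in results],
            "strand": [r.anchor.strand for r in results],
            "end_type": [r.anchor.end_type for r in results],
            "t_mean": [r.t_mean for r in results],
            "nt_mean": [r.nt_mean for r in results],
            "cdi": [r.cdi for r in results],
            "t_value_fraction": [r.t_value_fraction for r in results],
            "nt_value_fraction": [r.nt_value_fraction for r in results],
            "defined": [r.defined for r in results],
            "truncated": [r.truncated for r in results],
        }
    )


def cdi_histogram(
    results: Sequence[CdiResult],
    bin_width: float = 0.25,
    exclude_band: float | None = None,
) -> pd.DataFrame:
    """Bin defined CDI values for plotting.

    ``exclude_band`` drops values with |CDI| < band from the histogram
    (a presentation device that de-clutters the uninformative centre);
    the underlying result table always keeps every value.
    """
    values = np.array([r.cdi for r in results if r.defined and np.isfinite(r.cdi)])
    if exclude_band is not None:
        values = values[np.abs(values) >= exclude_band]
    if values.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if edges.size < 2:
        edges = np.array([lo, lo + bin_width])
    counts, edges = np.histogram(values, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
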