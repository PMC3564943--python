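"""Truth-labelled synthetic scenarios for the whole pipeline.

The generator lays multi-exon genes along one artificial chromosome and
plants, for a subset of them, a *true distal PAS* beyond the annotated
one.  Around this truth it emulates the three evidence channels the
method consumes, with the signal structure seen in real data:

* a per-base conservation track drawn Normal(mu_in, sigma) over the
  transcribed region (gene body plus any true extension) and
  Normal(mu_out, sigma) elsewhere — conservation collapses exactly at
  the true PAS;
* EST extremes: a Poisson(lambda_true) cloud of ends within +-1 nt of
  every planted site, plus uniform decoy ends along the chromosome
  (each EST also contributes its second, uninformative terminus, and a
  few spliced ESTs per gene exercise the splice-site filter);
* RNA-seq coverage: each transcribed base covered with probability
  p_in, everything else with probability p_out, so coverage is dense up
  to the true PAS and near-zero beyond it;
* orthologous transcript models echoing the true extensions (sharing
  the annotated last intron but ending at the true PAS) plus decoy
  ortho extensions of non-extended genes.

Decoy EST-end clouds are additionally planted just downstream and just
upstream of every gene (in its transcription direction) so that the
classifier's putative-PAS / putative-TSS branches are both exercised
with known truth, and intergenic spacing guarantees each planted decoy
is nearest to its own gene.

Everything is deterministic given the seed; what the generator does
*not* model is sequence content (no polyA hexamers), phylogeny, or
read-level noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genomic_io import (
    EstAlignment,
    GenomicInterval,
    ScoreTrack,
    TranscriptModel,
    write_bed12,
    write_bedgraph,
    write_fixedstep_wig,
    write_gtf,
    write_table,
)

__all__ = [
    "ScenarioConfig",
    "TruthTable",
    "Scenario",
    "RecoveryMetrics",
    "build_scenario",
    "generate_scenario",
    "evaluate_recovery",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of a synthetic scenario.

    Length ranges are inclusive-low/exclusive-high integer ranges.
    ``mu_in``/``mu_out`` are the per-base conservation means inside and
    outside transcribed regions; ``p_in``/``p_out`` the per-base
    coverage probabilities.  ``lambda_true`` is the expected number of
    EST ends at each planted site and must keep the expected cluster
    support at or above ``min_support`` so planted sites are
    recoverable in principle.
    """

    seed: int = 0
    chrom: str = "chrSim"
    n_genes: int = 30
    n_true_extended: int = 20
    n_exons: int = 3
    exon_length: tuple[int, int] = (150, 400)
    intron_length: tuple[int, int] = (500, 1500)
    extension_length: tuple[int, int] = (500, 2000)
    # conservation model
    mu_in: float = 1.5
    mu_out: float = -0.5
    sigma: float = 0.5
    # EST model
    lambda_true: float = 8.0
    est_jitter: int = 1
    est_length: tuple[int, int] = (200, 400)
    decoy_rate_per_kb: float = 0.5
    n_spliced_ests_per_gene: int = 2
    plant_flank_decoys: bool = True
    # coverage model
    p_in: float = 0.9
    p_out: float = 0.02
    # ortho model
    ortho_true_fraction: float = 1.0
    ortho_decoy_fraction: float = 0.3
    min_support: int = 4

    def __post_init__(self) -> None:
        for name in ("p_in", "p_out", "ortho_true_fraction", "ortho_decoy_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.n_true_extended <= self.n_genes:
            raise ValueError("n_true_extended must be in [0, n_genes]")
        if self.lambda_true < self.min_support:
            raise ValueError(
                "lambda_true must be >= min_support so planted sites have "
                "recoverable expected support"
            )
        for name in ("exon_length", "intron_length", "extension_length", "est_length"):
            lo, hi = getattr(self, name)
            if not 1 <= lo < hi:
                raise ValueError(f"{name} must be an increasing positive range")
        if self.n_exons < 2:
            raise ValueError("genes need >=2 exons so every model has a last intron")


@dataclass(frozen=True)
class TruthTable:
    """Planted truth: one row per gene and one row per planted site."""

    genes: pd.DataFrame
    sites: pd.DataFrame

    def true_pas_positions(self) -> list[int]:
        return self.sites.loc[self.sites["kind"] == "true_pas", "position"].tolist()


@dataclass(frozen=True)
class Scenario:
    config: ScenarioConfig
    chrom_length: int
    genes: list[TranscriptModel]
    ortho: list[TranscriptModel]
    ests: list[EstAlignment]
    conservation: ScoreTrack
    coverage: ScoreTrack
    truth: TruthTable


# flank-decoy placement constants (nt); chosen so each planted decoy is
# strictly nearest to its own gene and clear of every CDI/CD window
_PAD_BASE = 4500
_DOWN_OFFSET = (2500, 3500)
_UP_OFFSET = (1000, 2000)


def build_scenario(config: ScenarioConfig = ScenarioConfig()) -> Scenario:
    """Generate a scenario in memory.  Deterministic given config.seed."""
    rng = np.random.default_rng(config.seed)
    chrom = config.chrom

    extended_flags = np.zeros(config.n_genes, dtype=bool)
    extended_flags[
        rng.choice(config.n_genes, size=config.n_true_extended, replace=False)
    ] = True

    genes: list[TranscriptModel] = []
    gene_rows = []
    site_rows = []
    tx_spans: list[tuple[int, int]] = []  # transcribed region incl. extension
    cursor = 1000
    for i in range(config.n_genes):
        gid = f"g{i:03d}"
        extended = bool(extended_flags[i])
        ext_len = int(rng.integers(*config.extension_length)) if extended else 0
        pad = _PAD_BASE + ext_len
        exon_lens = rng.integers(*config.exon_length, size=config.n_exons)
        intron_lens = rng.integers(*config.intron_length, size=config.n_exons - 1)
        strand = "+" if rng.random() < 0.5 else "-"

        gene_start = cursor + pad
        exons = []
        at = gene_start
        for j in range(config.n_exons):
            exons.append(GenomicInterval(chrom, at, at + int(exon_lens[j]), strand))
            at += int(exon_lens[j])
            if j < config.n_exons - 1:
                at += int(intron_lens[j])
        gene_end = at
        genes.append(
            TranscriptModel(
                transcript_id=f"{gid}.t1",
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                exons=tuple(exons),
            )
        )

        if strand == "+":
            annotated_pas = gene_end - 1
            true_pas = annotated_pas + ext_len
            tx_lo, tx_hi = gene_start, gene_end + ext_len
        else:
            annotated_pas = gene_start
            true_pas = annotated_pas - ext_len
            tx_lo, tx_hi = gene_start - ext_len, gene_end
        tx_spans.append((tx_lo, tx_hi))

        gene_rows.append(
            {
                "gene_id": gid,
                "transcript_id": f"{gid}.t1",
                "strand": strand,
                "start": gene_start,
                "end": gene_end,
                "annotated_pas": annotated_pas,
                "extended": extended,
                "true_pas": true_pas if extended else -1,
                "extension_length": ext_len,
            }
        )
        if extended:
            site_rows.append(
                {
                    "site_id": f"{gid}.true_pas",
                    "gene_id": gid,
                    "kind": "true_pas",
                    "position": true_pas,
                    "strand": strand,
                    "expected_identity": "putative_PAS",
                }
            )
        if config.plant_flank_decoys:
            d = int(rng.integers(*_DOWN_OFFSET))
            u = int(rng.integers(*_UP_OFFSET))
            if strand == "+":
                down_pos, up_pos = true_pas + d, gene_start - u
            else:
                down_pos, up_pos = true_pas - d, gene_end - 1 + u
            site_rows.append(
                {
                    "site_id": f"{gid}.decoy_down",
                    "gene_id": gid,
                    "kind": "decoy_downstream",
                    "position": down_pos,
                    "strand": strand,
                    "expected_identity": "putative_PAS",
                }
            )
            site_rows.append(
                {
                    "site_id": f"{gid}.decoy_up",
                    "gene_id": gid,
                    "kind": "decoy_upstream",
                    "position": up_pos,
                    "strand": strand,
                    "expected_identity": "putative_TSS",
                }
            )
        cursor = gene_end + pad
    chrom_length = cursor + 1000

    for lo, hi in tx_spans:
        if lo < 0 or hi > chrom_length:
            raise ValueError("infeasible geometry: transcribed span exceeds chromosome")

    # ortho transcripts: echo true extensions, plus decoy extensions
    ortho: list[TranscriptModel] = []
    for gene, row in zip(genes, gene_rows):
        gid = row["gene_id"]
        if row["extended"]:
            if rng.random() < config.ortho_true_fraction:
                ortho.append(_extend_model(gene, f"ortho_{gid}", row["true_pas"]))
        elif config.ortho_decoy_fraction > 0 and rng.random() < config.ortho_decoy_fraction:
            ext = int(rng.integers(*config.extension_length))
            target = (
                row["annotated_pas"] + ext
                if gene.strand == "+"
                else row["annotated_pas"] - ext
            )
            ortho.append(_extend_model(gene, f"ortho_decoy_{gid}", target))

    # ESTs
    ests: list[EstAlignment] = []
    counter = 0
    for site in site_rows:
        n_ends = int(rng.poisson(config.lambda_true))
        for _ in range(n_ends):
            jitter = int(rng.integers(-config.est_jitter, config.est_jitter + 1))
            pos = site["position"] + jitter
            length = int(rng.integers(*config.est_length))
            leftward = site["strand"] == "+" if site["kind"] != "decoy_upstream" else (
                site["strand"] == "-"
            )
            ests.append(_single_block_est(f"est{counter:05d}", chrom, pos, length, leftward, rng))
            counter += 1
    n_uniform = int(rng.poisson(config.decoy_rate_per_kb * chrom_length / 1000))
    for _ in range(n_uniform):
        pos = int(rng.integers(500, chrom_length - 500))
        length = int(rng.integers(*config.est_length))
        ests.append(
            _single_block_est(f"est{counter:05d}", chrom, pos, length, bool(rng.random() < 0.5), rng)
        )
        counter += 1
    for gene in genes:
        for _ in range(config.n_spliced_ests_per_gene):
            ests.append(
                EstAlignment(
                    est_id=f"est{counter:05d}",
                    chrom=chrom,
                    blocks=gene.exons,
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
            counter += 1

    # conservation
    cons = rng.normal(config.mu_out, config.sigma, chrom_length)
    for lo, hi in tx_spans:
        cons[lo:hi] = rng.normal(config.mu_in, config.sigma, hi - lo)
    conservation = ScoreTrack(
        "conservation",
        {chrom: (np.arange(chrom_length, dtype=np.int64), cons)},
    )

    # coverage
    covered = rng.random(chrom_length) < config.p_out
    for lo, hi in tx_spans:
        covered[lo:hi] = rng.random(hi - lo) < config.p_in
    pos = np.nonzero(covered)[0].astype(np.int64)
    coverage = ScoreTrack("coverage", {chrom: (pos, np.ones(pos.size))})

    truth = TruthTable(
        genes=pd.DataFrame(gene_rows),
        sites=pd.DataFrame(
            site_rows,
            columns=["site_id", "gene_id", "kind", "position", "strand", "expected_identity"],
        ),
    )
    return Scenario(
        config=config,
        chrom_length=chrom_length,
        genes=genes,
        ortho=ortho,
        ests=ests,
        conservation=conservation,
        coverage=coverage,
        truth=truth,
    )


def _extend_model(gene: TranscriptModel, new_id: str, target_pas: int) -> TranscriptModel:
    """Copy of ``gene`` whose terminal exon is extended so its PAS is
    ``target_pas``; the last intron is untouched."""
    exons = list(gene.exons)
    if gene.strand == "+":
        last = exons[-1]
        exons[-1] = GenomicInterval(last.chrom, last.start, target_pas + 1, last.strand)
    else:
        first = exons[0]
        exons[0] = GenomicInterval(first.chrom, target_pas, first.end, first.strand)
    return TranscriptModel(
        transcript_id=new_id,
        gene_id=new_id,
        chrom=gene.chrom,
        strand=gene.strand,
        exons=tuple(exons),
    )


def _single_block_est(
    est_id: str, chrom: str, end_pos: int, length: int, leftward: bool, rng
) -> EstAlignment:
    """A single-block EST with one terminus at ``end_pos``, extending
    leftward (body upstream of a + strand end) or rightward."""
    if leftward:
        block = GenomicInterval(chrom, end_pos - length + 1, end_pos + 1)
    else:
        block = GenomicInterval(chrom, end_pos, end_pos + length)
    return EstAlignment(
        est_id=est_id,
        chrom=chrom,
        blocks=(block,),
        strand="+" if rng.random() < 0.5 else "-",
    )


def generate_scenario(
    config: ScenarioConfig = ScenarioConfig(), out_dir: str | Path = "."
) -> dict[str, Path]:
    """Generate a scenario and write it as standard-format files.

    Emits ``ref.gtf``, ``ortho.bed12``, ``ests.bed12``, ``cons.wig``,
    ``cov.bedgraph`` and ``truth.tsv`` in ``out_dir`` and returns their
    paths.  Byte-identical across runs with the same config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenario = build_scenario(config)
    paths = {
        "ref": out / "ref.gtf",
        "ortho": out / "ortho.bed12",
        "ests": out / "ests.bed12",
        "conservation": out / "cons.wig",
        "coverage": out / "cov.bedgraph",
        "truth": out / "truth.tsv",
    }
    write_gtf(paths["ref"], scenario.genes)
    write_bed12(paths["ortho"], scenario.ortho)
    write_bed12(paths["ests"], scenario.ests)
    _, cons_values = scenario.conservation.arrays(config.chrom)
    write_fixedstep_wig(paths["conservation"], config.chrom, 0, cons_values)
    write_bedgraph(paths["coverage"], _rle_covered(scenario.coverage, config.chrom))
    write_table(scenario.truth.sites, paths["truth"])
    return paths


def _rle_covered(coverage: ScoreTrack, chrom: str):
    pos, _ = coverage.arrays(chrom)
    if pos.size == 0:
        return
    breaks = np.nonzero(np.diff(pos) > 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [pos.size - 1]])
    for s, e in zip(starts, ends):
        yield chrom, int(pos[s]), int(pos[e]) + 1, 1


@dataclass(frozen=True)
class RecoveryMetrics:
    sensitivity: float
    empirical_fdr: float | None
    n_truth: int
    n_predictions: int
    n_matched_truth: int
    n_matched_predictions: int


def evaluate_recovery(
    predictions: Sequence[int],
    truth: TruthTable | Sequence[int],
    match_tolerance: int = 2,
) -> RecoveryMetrics:
    """Score predicted PAS positions against planted truth.

    A truth site is recovered if any prediction lies within
    ``match_tolerance`` nt of it; a prediction is a false discovery if
    no truth site lies within tolerance.  With no predictions the
    empirical FDR is undefined (None).
    """
    truth_positions = (
        truth.true_pas_positions() if isinstance(truth, TruthTable) else list(truth)
    )
    t = np.sort(np.asarray(truth_positions, dtype=np.int64))
    p = np.sort(np.asarray(list(predictions), dtype=np.int64))

    def _matched(queries: np.ndarray, targets: np.ndarray) -> int:
        if queries.size == 0 or targets.size == 0:
            return 0
        idx = np.searchsorted(targets, queries)
        left = np.abs(queries - targets[np.clip(idx - 1, 0, targets.size - 1)])
        right = np.abs(queries - targets[np.clip(idx, 0, targets.size - 1)])
        return int(np.count_nonzero(np.minimum(left, right) <= match_tolerance))

    n_matched_truth = _matched(t, p)
    n_matched_pred = _matched(p, t)
    sensitivity = n_matched_truth / t.size if t.size else float("nan")
    empirical_fdr = (p.size - n_matched_pred) / p.size if p.size else None
    return RecoveryMetrics(
        sensitivity=sensitivity,
        empirical_fdr=empirical_fdr,
        n_truth=int(t.size),
        n_predictions=int(p.size),
        n_matched_truth=n_matched_truth,
        n_matched_predictions=n_matched_pred,
    )
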