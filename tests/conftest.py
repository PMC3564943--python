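import numpy as np
import pytest

from pas_scout.cli import run_all
from pas_scout.genomic_io import GenomicInterval, ScoreTrack, TranscriptModel
from pas_scout.synthetic import ScenarioConfig, build_scenario, generate_scenario

SCENARIO_SEED = 1


def make_transcript(
    tid: str,
    exons: list[tuple[int, int]],
    strand: str = "+",
    chrom: str = "chr1",
    gene_id: str | None = None,
) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene_id or tid,
        chrom=chrom,
        strand=strand,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
    )


def conservation_track(values: dict[int, float], chrom: str = "chr1") -> ScoreTrack:
    return ScoreTrack.from_dict("conservation", {chrom: values})


def coverage_track(covered, chrom: str = "chr1", depth: float = 1.0) -> ScoreTrack:
    pos = np.asarray(sorted(set(covered)), dtype=np.int64)
    return ScoreTrack("coverage", {chrom: (pos, np.full(pos.size, depth))})


@pytest.fixture(scope="session")
def default_scenario():
    return build_scenario(ScenarioConfig(seed=SCENARIO_SEED))


@pytest.fixture(scope="session")
def scenario_run(tmp_path_factory, default_scenario):
    """Default scenario written to disk and pushed through the full
    pipeline via files, as a user would run it."""
    root = tmp_path_factory.mktemp("scenario")
    paths = generate_scenario(ScenarioConfig(seed=SCENARIO_SEED), root / "data")
    out_dir = root / "out"
    manifest = run_all(
        ests_path=str(paths["ests"]),
        reference_path=str(paths["ref"]),
        out_dir=str(out_dir),
        ortho_path=str(paths["ortho"]),
        conservation_path=str(paths["conservation"]),
        coverage_paths=(str(paths["coverage"]),),
    )
    return {
        "scenario": default_scenario,
        "paths": paths,
        "out_dir": out_dir,
        "manifest": manifest,
    }
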