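import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pas_scout.cd_extend import (
    compute_cd,
    compute_cd_table,
    find_extension_candidates,
    merge_tissue_coverage,
)
from pas_scout.genomic_io import GenomicInterval, ScoreTrack, mirror_track, mirror_transcript

from conftest import coverage_track, make_transcript
from oracles import brute_cd

REF = lambda: make_transcript("ref", [(1000, 1200), (1500, 2001)], "+")


class TestCandidates:
    def test_shared_last_intron_more_distal_pas(self):
        ortho = make_transcript("ortho", [(1000, 1200), (1500, 4001)], "+")
        (c,) = find_extension_candidates([REF()], [ortho])
        assert c.annotated_pas == 2000 and c.putative_pas == 4000
        assert (c.up.start, c.up.end) == (2001, 4001)
        assert (c.down.start, c.down.end) == (4001, 6001)
        assert c.up.length() == c.down.length() == 2000

    def test_different_last_intron_no_candidate(self):
        ortho = make_transcript("ortho", [(1000, 1200), (1510, 4001)], "+")
        assert find_extension_candidates([REF()], [ortho]) == []

    def test_equal_or_upstream_pas_no_candidate(self):
        same = make_transcript("o1", [(1000, 1200), (1500, 2001)], "+")
        upstream = make_transcript("o2", [(1000, 1200), (1500, 1900)], "+")
        assert find_extension_candidates([REF()], [same, upstream]) == []

    def test_strand_mismatch_no_candidate(self):
        ortho = make_transcript("ortho", [(1000, 1200), (1500, 4001)], "-")
        assert find_extension_candidates([REF()], [ortho]) == []

    def test_minus_strand_geometry(self):
        ref = make_transcript("ref", [(5000, 5300), (5600, 5800)], "-")
        ortho = make_transcript("ortho", [(4000, 5300), (5600, 5800)], "-")
        (c,) = find_extension_candidates([ref], [ortho])
        assert c.annotated_pas == 5000 and c.putative_pas == 4000
        assert (c.up.start, c.up.end) == (4000, 5000)
        assert (c.down.start, c.down.end) == (3000, 4000)

    def test_single_exon_models_skipped(self):
        assert find_extension_candidates(
            [make_transcript("r", [(100, 200)])], [make_transcript("o", [(100, 300)])]
        ) == []

    def test_collapse_most_distal(self):
        o1 = make_transcript("o1", [(1000, 1200), (1500, 3001)], "+")
        o2 = make_transcript("o2", [(1000, 1200), (1500, 4001)], "+")
        cands = find_extension_candidates([REF()], [o1, o2], collapse="most-distal")
        assert len(cands) == 1 and cands[0].ortho_transcript_id == "o2"

    def test_min_extension(self):
        ortho = make_transcript("ortho", [(1000, 1200), (1500, 2011)], "+")
        assert find_extension_candidates([REF()], [ortho], min_extension=11) == []
        assert len(find_extension_candidates([REF()], [ortho], min_extension=10)) == 1


def _candidate(up=(2001, 4001), down=(4001, 6001)):
    ortho = make_transcript("ortho", [(1000, 1200), (1500, 4001)], "+")
    (c,) = find_extension_candidates([REF()], [ortho])
    return c


class TestComputeCd:
    def test_full_up_empty_down_is_100(self):
        c = _candidate()
        track = coverage_track(range(2001, 4001))
        r = compute_cd(c, track)
        assert r.cd == pytest.approx(100.0) and r.up_pct == 100.0 and r.down_pct == 0.0

    def test_identical_profiles_is_0(self):
        c = _candidate()
        covered = [p for p in range(2001, 6001) if (p - 2001) % 3 == 0]
        r = compute_cd(c, coverage_track(covered))
        assert r.cd == pytest.approx(0.0)

    def test_hand_counted_partial_coverage(self):
        ref = make_transcript("ref", [(0, 40), (60, 101)], "+")
        ortho = make_transcript("ortho", [(0, 40), (60, 151)], "+")
        (c,) = find_extension_candidates([ref], [ortho])
        assert c.up.length() == c.down.length() == 50
        covered = list(range(101, 131)) + list(range(151, 161))  # 30 in Up, 10 in Down
        r = compute_cd(c, coverage_track(covered))
        assert (r.up_pct, r.down_pct, r.cd) == (60.0, 20.0, 40.0)

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(5)
        c = _candidate()
        covered = set(
            int(p) for p in rng.choice(np.arange(2001, 6001), size=1500, replace=False)
        )
        r = compute_cd(c, coverage_track(covered))
        up_pct, down_pct, cd = brute_cd(covered, (2001, 4001), (4001, 6001))
        assert r.up_pct == pytest.approx(up_pct) and r.cd == pytest.approx(cd)

    def test_depth_binarization_invariance_and_bounds(self):
        rng = np.random.default_rng(9)
        c = _candidate()
        covered = sorted(
            int(p) for p in rng.choice(np.arange(2001, 6001), size=800, replace=False)
        )
        depth1 = coverage_track(covered, depth=1.0)
        depth7 = coverage_track(covered, depth=7.0)
        r1, r7 = compute_cd(c, depth1), compute_cd(c, depth7)
        assert r1.cd == r7.cd
        assert -100.0 <= r1.cd <= 100.0
        assert 0.0 <= r1.up_pct <= 100.0 and 0.0 <= r1.down_pct <= 100.0

    @given(st.sets(st.integers(2001, 6000), max_size=60))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotonicity(self, covered):
        c = _candidate()
        base = compute_cd(c, coverage_track(covered) if covered else ScoreTrack("coverage", {}))
        up_extra = covered | {2500}
        down_extra = covered | {4500}
        assert compute_cd(c, coverage_track(up_extra)).cd >= base.cd
        assert compute_cd(c, coverage_track(down_extra)).cd <= base.cd

    def test_mirror_invariance(self):
        L = 10_000
        rng = np.random.default_rng(17)
        ref, ortho = REF(), make_transcript("ortho", [(1000, 1200), (1500, 4001)], "+")
        covered = sorted(int(p) for p in rng.choice(np.arange(L), size=3000, replace=False))
        track = coverage_track(covered)
        (c,) = find_extension_candidates([ref], [ortho])
        (cm,) = find_extension_candidates(
            [mirror_transcript(ref, L)], [mirror_transcript(ortho, L)]
        )
        r = compute_cd(c, track)
        rm = compute_cd(cm, mirror_track(track, L))
        assert rm.cd == pytest.approx(r.cd)
        assert rm.up_pct == pytest.approx(r.up_pct)


class TestTissuePooling:
    def test_single_track_identity(self):
        t = coverage_track([1, 2, 3])
        m = merge_tissue_coverage([t])
        assert np.array_equal(m.arrays("chr1")[0], t.arrays("chr1")[0])

    def test_disjoint_union(self):
        a = coverage_track(range(0, 10))
        b = coverage_track(range(10, 20))
        m = merge_tissue_coverage([a, b])
        assert m.covered_count(GenomicInterval("chr1", 0, 20)) == 20

    def test_depth_sum_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        tracks = []
        expected = {}
        for _ in range(4):
            pos = sorted(int(p) for p in rng.choice(100, size=30, replace=False))
            depth = rng.integers(1, 5, size=len(pos))
            tracks.append(
                ScoreTrack("coverage", {"chr1": (np.array(pos), depth.astype(float))})
            )
            for p, d in zip(pos, depth):
                expected[p] = expected.get(p, 0) + int(d)
        merged = merge_tissue_coverage(tracks)
        pos, val = merged.arrays("chr1")
        assert {int(p): int(v) for p, v in zip(pos, val)} == expected


def test_mean_cd_recovers_coverage_probability_gap(default_scenario):
    """Where transcription stops at the planted distal PAS, the mean CD of
    true candidates estimates 100*(p_in - p_out) to within binomial error."""
    sc = default_scenario
    cands = find_extension_candidates(sc.genes, sc.ortho)
    true_pas = set(sc.truth.true_pas_positions())
    results = [
        r
        for r in compute_cd_table(cands, sc.coverage)
        if r.candidate.putative_pas in true_pas
    ]
    assert results
    expected = 100.0 * (sc.config.p_in - sc.config.p_out)
    lengths = np.array([r.candidate.up.length() for r in results], dtype=float)
    # binomial SE of each CD, combined across candidates
    per_site_var = 100.0**2 * (
        sc.config.p_in * (1 - sc.config.p_in) + sc.config.p_out * (1 - sc.config.p_out)
    ) / lengths
    se = np.sqrt(per_site_var.sum()) / len(results)
    observed = np.mean([r.cd for r in results])
    assert abs(observed - expected) < 4 * se
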