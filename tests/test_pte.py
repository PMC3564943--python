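import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pas_scout.genomic_io import EstAlignment, GenomicInterval, mirror_transcript
from pas_scout.pte import (
    PteCluster,
    PteConfig,
    classify_pte,
    classify_ptes,
    cluster_est_ends,
    filter_ptes,
    merge_proximal_clusters,
)

from conftest import make_transcript
from oracles import brute_single_linkage

CFG = PteConfig()


def clusters_at(*positions_supports, chrom="chr1"):
    return [
        PteCluster(chrom, p, s, p, p) for p, s in positions_supports
    ]


class TestClustering:
    def test_adjacent_ends_join(self):
        (c,) = cluster_est_ends([("chr1", 100), ("chr1", 100), ("chr1", 101)])
        assert (c.position, c.support) == (100, 3)

    def test_gap_of_two_splits(self):
        cs = cluster_est_ends([("chr1", 100), ("chr1", 102)])
        assert [(c.position, c.support) for c in cs] == [(100, 1), (102, 1)]

    def test_transitive_chaining(self):
        (c,) = cluster_est_ends([("chr1", 100), ("chr1", 101), ("chr1", 102)])
        assert c.support == 3 and c.min_position == 100 and c.max_position == 102

    def test_modal_representative_tie_takes_larger(self):
        (c,) = cluster_est_ends([("chr1", 100), ("chr1", 100), ("chr1", 101), ("chr1", 101)])
        assert c.position == 101

    def test_chroms_kept_separate(self):
        cs = cluster_est_ends([("chr1", 100), ("chr2", 100)])
        assert len(cs) == 2

    def test_empty_input(self):
        assert cluster_est_ends([]) == []

    def test_matches_pairwise_linkage_oracle(self):
        rng = np.random.default_rng(42)
        positions = rng.integers(0, 1000, size=500).tolist()
        got = cluster_est_ends([("chr1", p) for p in positions])
        expected = brute_single_linkage(positions, CFG.linkage_distance)
        assert [(c.position, c.support, c.min_position, c.max_position) for c in got] == [
            (c["position"], c["support"], c["min"], c["max"]) for c in expected
        ]


class TestMerge:
    def test_keeps_distal_for_plus_strand_gene(self):
        gene = make_transcript("g", [(0, 30), (60, 90)], "+")
        merged = merge_proximal_clusters(clusters_at((100, 5), (110, 5)), [gene], CFG)
        assert [c.position for c in merged] == [110]

    def test_keeps_distal_for_minus_strand_gene(self):
        gene = make_transcript("g", [(200, 230), (260, 290)], "-")
        merged = merge_proximal_clusters(clusters_at((100, 5), (110, 5)), [gene], CFG)
        assert [c.position for c in merged] == [100]

    def test_no_gene_falls_back_to_support(self):
        # 100-120-140 chain pairwise at <25 nt; no reference gene nearby,
        # so the highest-support member survives
        merged = merge_proximal_clusters(
            clusters_at((100, 5), (120, 9), (140, 4)), [], CFG
        )
        assert [(c.position, c.support) for c in merged] == [(120, 9)]

    def test_exactly_merge_distance_apart_not_merged(self):
        merged = merge_proximal_clusters(clusters_at((100, 5), (125, 5)), [], CFG)
        assert len(merged) == 2

    @given(st.lists(st.integers(0, 2000), min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_idempotent_and_separated(self, positions):
        clusters = cluster_est_ends([("chr1", p) for p in positions])
        once = merge_proximal_clusters(clusters, [], CFG)
        twice = merge_proximal_clusters(once, [], CFG)
        assert once == twice
        gaps = np.diff([c.position for c in once])
        assert (gaps >= CFG.merge_distance).all()


class TestFilters:
    GENE = staticmethod(lambda: make_transcript("g", [(1000, 1200), (1500, 1700)], "+"))

    def test_low_support_removed(self):
        kept = filter_ptes(clusters_at((5000, 3), (6000, 4)), [self.GENE()], [], CFG)
        assert [c.position for c in kept] == [6000]

    def test_exonic_removed_intronic_kept(self):
        kept = filter_ptes(clusters_at((1100, 8), (1300, 8)), [self.GENE()], [], CFG)
        assert [c.position for c in kept] == [1300]

    def test_splice_site_exclusion_radius_is_inclusive(self):
        est = EstAlignment(
            "e",
            "chr1",
            (GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 300, 400)),
        )
        # splice-site bases are 199 and 300
        near = clusters_at((199 - 25, 8))
        far = clusters_at((199 - 26, 8))
        assert filter_ptes(near, [], [est], CFG) == []
        assert [c.position for c in filter_ptes(far, [], [est], CFG)] == [199 - 26]

    def test_unspliced_est_creates_no_exclusion(self):
        est = EstAlignment("e", "chr1", (GenomicInterval("chr1", 100, 200),))
        kept = filter_ptes(clusters_at((199, 8)), [], [est], CFG)
        assert len(kept) == 1


class TestClassification:
    def test_gene_transcribed_towards_pte_gives_pas(self):
        gene = make_transcript("g", [(0, 500), (800, 1000)], "+")
        c = classify_pte(PteCluster("chr1", 3000, 5, 3000, 3000), [gene], CFG)
        assert c.identity == "putative_PAS"
        assert c.distance_bp == 3000 - 999 and c.inferred_strand == "+"

    def test_gene_transcribed_away_gives_tss(self):
        gene = make_transcript("g", [(5000, 6000), (7000, 8000)], "+")
        c = classify_pte(PteCluster("chr1", 3000, 5, 3000, 3000), [gene], CFG)
        assert c.identity == "putative_TSS" and c.distance_bp == 2000

    def test_opposite_strand_intron_overlap_undetermined(self):
        a = make_transcript("a", [(0, 100), (900, 1000)], "+")
        b = make_transcript("b", [(100, 200), (800, 900)], "-")
        c = classify_pte(PteCluster("chr1", 500, 5, 500, 500), [a, b], CFG)
        assert c.identity == "undetermined" and c.distance_bp == 0

    def test_intron_containment_classified_on_gene_strand(self):
        gene = make_transcript("g", [(0, 100), (900, 1000)], "-")
        c = classify_pte(PteCluster("chr1", 500, 5, 500, 500), [gene], CFG)
        assert c.identity == "putative_PAS" and c.inferred_strand == "-"

    def test_beyond_max_distance_undetermined(self):
        gene = make_transcript("g", [(0, 100), (200, 300)], "+")
        c = classify_pte(PteCluster("chr1", 2_000_000, 5, 2_000_000, 2_000_000), [gene], CFG)
        assert c.identity == "undetermined" and c.nearest_transcript_id is None

    def test_invariant_to_transcript_order(self):
        genes = [
            make_transcript("a", [(0, 100), (200, 300)], "+"),
            make_transcript("b", [(5000, 5100), (5200, 5300)], "-"),
            make_transcript("c", [(9000, 9100), (9200, 9300)], "+"),
        ]
        cluster = PteCluster("chr1", 4000, 6, 4000, 4000)
        forward = classify_pte(cluster, genes, CFG)
        backward = classify_pte(cluster, genes[::-1], CFG)
        assert forward == backward

    def test_mirror_preserves_labels(self):
        L = 20_000
        genes = [
            make_transcript("a", [(1000, 1200), (1400, 1600)], "+"),
            make_transcript("b", [(8000, 8200), (8400, 8600)], "-"),
        ]
        clusters = clusters_at((3000, 6), (7000, 6), (500, 6))
        mirrored_genes = [mirror_transcript(g, L) for g in genes]
        for c in clusters:
            direct = classify_pte(c, genes, CFG)
            mc = PteCluster(c.chrom, L - 1 - c.position, c.support, L - 1 - c.max_position, L - 1 - c.min_position)
            mirrored = classify_pte(mc, mirrored_genes, CFG)
            assert direct.identity == mirrored.identity
            assert direct.distance_bp == mirrored.distance_bp


def test_planted_sites_yield_single_cluster_near_truth(default_scenario):
    """Every planted site with enough surviving EST support produces
    exactly one surviving PTE within jitter distance of the truth."""
    sc = default_scenario
    from pas_scout.pte import est_extremes

    clusters = cluster_est_ends(est_extremes(sc.ests), CFG)
    filtered = filter_ptes(clusters, sc.genes, sc.ests, CFG)
    merged = merge_proximal_clusters(filtered, sc.genes, CFG)
    jitter = sc.config.est_jitter
    for _, site in sc.truth.sites.iterrows():
        raw_support = sum(
            1
            for c in clusters
            if abs(c.position - site.position) <= jitter and c.support >= CFG.min_support
        )
        nearby = [c for c in merged if abs(c.position - site.position) <= jitter]
        if raw_support:
            assert len(nearby) == 1
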