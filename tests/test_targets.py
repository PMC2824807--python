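import numpy as np
import pytest

from chipscope import (
    BindingSite,
    GenomeAnnotation,
    Transcript,
    assign_all,
    assign_targets,
    filter_targets_go_rule,
    site_transcript_relation,
    target_gene_census,
)
from chipscope.targets import GENE_DOWNSTREAM, GENE_UPSTREAM, INTERNAL, assignments_to_frame

from conftest import make_annotation, make_transcript, random_annotation
from oracles import brute_force_go_filter, brute_force_relation, brute_force_targets


def site_at(midpoint, chrom="chrI", width=200):
    return BindingSite(chrom, midpoint - width // 2, midpoint + width // 2,
                       p_value=1e-9, signal=5.0)


class TestSiteTranscriptRelation:
    def test_internal_midpoint(self):
        t = make_transcript(strand="+", tss=4000, tes=5999)
        assert site_transcript_relation(5000, t) == (INTERNAL, 0)

    def test_gene_downstream_of_site(self):
        t = make_transcript(strand="+", tss=4000, tes=5999)
        assert site_transcript_relation(3500, t) == (GENE_DOWNSTREAM, 500)

    def test_gene_upstream_of_site(self):
        t = make_transcript(strand="+", tss=4000, tes=6000)
        assert site_transcript_relation(6800, t) == (GENE_UPSTREAM, 800)

    def test_midpoint_exactly_at_tss_is_internal(self):
        t = make_transcript(strand="+", tss=4000, tes=5999)
        assert site_transcript_relation(4000, t) == (INTERNAL, 0)
        minus = make_transcript(strand="-", tss=5999, tes=4000)
        assert site_transcript_relation(5999, minus) == (INTERNAL, 0)

    def test_agrees_with_mirrored_oracle_on_random_cases(self):
        L = 100_000
        rng = np.random.default_rng(42)
        for _ in range(10_000):
            strand = "+" if rng.random() < 0.5 else "-"
            a = int(rng.integers(0, L - 5000))
            b = a + int(rng.integers(100, 5000))
            tss, tes = (a, b) if strand == "+" else (b, a)
            t = make_transcript(strand=strand, tss=tss, tes=tes)
            mid = int(rng.integers(0, L))
            rel, dist = site_transcript_relation(mid, t)
            assert (rel, dist) == brute_force_relation(mid, tss, tes, strand)
            # mirror the genome: relation and distance are preserved
            mstrand = "-" if strand == "+" else "+"
            mt = make_transcript(
                strand=mstrand, tss=L - 1 - tss, tes=L - 1 - tes
            )
            assert site_transcript_relation(L - 1 - mid, mt) == (rel, dist)


class TestAssignTargets:
    def test_first_bin_takes_internal_and_near_downstream(self, toy_annotation):
        # midpoint internal to g1 and 1 kb 5' of nothing else nearby
        assignment = assign_targets(site_at(3000), toy_annotation)
        assert {r.gene_id for r in assignment.targets} == {"g1"}
        assert all(r.bin == 1 for r in assignment.targets)

    def test_far_transcript_gives_empty_targets(self):
        ann = make_annotation([make_transcript(tss=20000, tes=22000)])
        assignment = assign_targets(site_at(14000 - 100), ann)
        assert assignment.targets == []
        assert assignment.all_candidates == []

    def test_isoform_grouping_takes_closest_isoform(self):
        ann = make_annotation(
            [
                make_transcript("g1.1", "g1", tss=10000, tes=14000),
                make_transcript("g1.2", "g1", tss=8000, tes=14000),
            ]
        )
        assignment = assign_targets(site_at(7500), ann)
        (rel,) = assignment.targets
        assert rel.gene_id == "g1"
        assert rel.relation == GENE_DOWNSTREAM
        assert rel.distance == 500

    def test_candidates_ranked_internal_then_downstream_then_upstream(self):
        ann = make_annotation(
            [
                make_transcript("gin.1", "gin", tss=4000, tes=6000),
                make_transcript("gd1.1", "gd1", tss=6500, tes=9000),
                make_transcript("gd2.1", "gd2", tss=9500, tes=11000),
                # '-' gene whose 3' end faces the site from the right:
                # the site is 3'-ward of its TES -> gene upstream of site
                make_transcript("gu.1", "gu", strand="-", tss=14000, tes=9900),
            ]
        )
        assignment = assign_targets(site_at(5000), ann)
        assert [r.gene_id for r in assignment.all_candidates] == [
            "gin", "gd1", "gd2", "gu"
        ]

    def test_bin_boundaries_follow_strict_and_inclusive_rules(self):
        # 2000 exactly -> bin 2; 5000 exactly retained; 5001 dropped
        ann = make_annotation(
            [
                make_transcript("a.1", "a", tss=12000, tes=14000),
                make_transcript("b.1", "b", tss=15000, tes=17000),
                make_transcript("c.1", "c", tss=15001, tes=17001),
            ]
        )
        assignment = assign_targets(site_at(10000), ann)
        by_gene = {r.gene_id: r for r in assignment.all_candidates}
        assert by_gene["a"].bin == 2 and by_gene["a"].distance == 2000
        assert by_gene["b"].bin == 2 and by_gene["b"].distance == 5000
        assert "c" not in by_gene

    def test_matches_brute_force_on_random_dense_annotations(self):
        rng = np.random.default_rng(0)
        checked = 0
        for _ in range(50):
            ann = random_annotation(rng)
            tuples = [
                (t.gene_id, t.tss, t.tes, t.strand) for t in ann.transcripts
            ]
            for _ in range(20):
                mid = int(rng.integers(0, 60000))
                assignment = assign_targets(site_at(mid), ann)
                expected, bins = brute_force_targets(mid, tuples)
                got = {r.gene_id for r in assignment.targets}
                assert got == expected, (mid, tuples)
                for r in assignment.all_candidates:
                    assert bins[r.gene_id] == r.bin
                checked += 1
        assert checked == 1000

    def test_exhaustive_small_world_grid_matches_oracle(self):
        rng = np.random.default_rng(1)
        for n_genes in (1, 2, 3, 4):
            for _layout in range(5):
                ann = random_annotation(
                    rng, n_genes=n_genes, chrom_len=30000
                )
                tuples = [
                    (t.gene_id, t.tss, t.tes, t.strand) for t in ann.transcripts
                ]
                for mid in range(0, 30000, 100):
                    got = {
                        r.gene_id
                        for r in assign_targets(site_at(mid), ann).targets
                    }
                    assert got == brute_force_targets(mid, tuples)[0]

    def test_targets_never_mix_bins(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            ann = random_annotation(rng)
            assignment = assign_targets(
                site_at(int(rng.integers(0, 60000))), ann
            )
            assert len({r.bin for r in assignment.targets}) <= 1
            seen = [r.gene_id for r in assignment.all_candidates]
            assert len(seen) == len(set(seen))

    def test_translation_invariance(self):
        offset = 1377
        txs = [
            make_transcript("a.1", "a", tss=4000, tes=6000),
            make_transcript("b.1", "b", strand="-", tss=11000, tes=9000),
        ]
        shifted = [
            make_transcript(
                t.id, t.gene_id, strand=t.strand,
                tss=t.tss + offset, tes=t.tes + offset,
            )
            for t in txs
        ]
        ann = make_annotation(txs, {"chrI": 50000})
        ann2 = make_annotation(shifted, {"chrI": 50000 + offset})
        for mid in range(1000, 14000, 250):
            a = assign_targets(site_at(mid), ann)
            b = assign_targets(site_at(mid + offset), ann2)
            assert [(r.gene_id, r.relation, r.distance, r.bin)
                    for r in a.all_candidates] == [
                (r.gene_id, r.relation, r.distance, r.bin)
                for r in b.all_candidates
            ]


class TestGoRuleFilter:
    def test_upstream_only_gene_excluded_internal_retained(self):
        ann = make_annotation(
            [
                make_transcript("up.1", "up", tss=2000, tes=4000),
                make_transcript("inn.1", "inn", tss=20000, tes=24000),
            ]
        )
        # site downstream of up's TES -> bin 3; site internal to inn -> bin 1
        assignments = assign_all([site_at(4600), site_at(21000)], ann)
        assert filter_targets_go_rule(assignments) == {"inn"}

    def test_matches_brute_force_refilter(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            ann = random_annotation(rng)
            tuples = [
                (t.gene_id, t.tss, t.tes, t.strand) for t in ann.transcripts
            ]
            mids = [int(rng.integers(0, 60000)) for _ in range(5)]
            assignments = assign_all([site_at(m) for m in mids], ann)
            expected = set()
            for m in mids:
                expected |= brute_force_go_filter(m, tuples)
            assert filter_targets_go_rule(assignments) == expected


class TestCensus:
    def test_empty_assignment_list_gives_zero_census(self):
        census = target_gene_census([])
        assert census["n_sites"] == 0
        assert census["n_target_genes"] == 0
        assert census["frac_assigned"] == 0.0

    def test_all_internal_sites_fully_assigned(self, toy_annotation):
        sites = [site_at(3000), site_at(7000), site_at(13000)]
        census = target_gene_census(assign_all(sites, toy_annotation))
        assert census["frac_assigned"] == 1.0

    def test_census_equals_recount_from_table(self):
        rng = np.random.default_rng(8)
        ann = random_annotation(rng, n_genes=10)
        sites = [site_at(int(rng.integers(0, 60000))) for _ in range(30)]
        assignments = assign_all(sites, ann)
        census = target_gene_census(assignments)
        frame = assignments_to_frame(assignments)
        tgt = frame[frame["is_target"]]
        assert census["n_assigned"] == tgt["site_index"].nunique()
        assert census["n_target_genes"] == tgt["gene_id"].nunique()
        assert sorted(census["distances"]) == sorted(tgt["distance"])
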