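import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chipscope import (
    CoverageTrack,
    GenomeAnnotation,
    Pwm,
    Transcript,
    derive_tss,
    read_annotation,
    read_pwm,
    read_sites,
    read_track,
    write_annotation,
    write_pwm,
    write_sites,
    write_track,
)
from chipscope.core_io import BindingSite, FormatError

from conftest import make_transcript


class TestTranscript:
    def test_strand_orientation_invariant_enforced(self):
        with pytest.raises(ValueError, match="TSS"):
            make_transcript(strand="+", tss=5000, tes=1000)
        with pytest.raises(ValueError, match="TSS"):
            make_transcript(strand="-", tss=1000, tes=5000)

    def test_span_is_tss_to_tes_inclusive(self):
        plus = make_transcript(strand="+", tss=100, tes=299)
        assert (plus.start, plus.end, plus.length) == (100, 300, 200)
        minus = make_transcript(strand="-", tss=299, tes=100)
        assert (minus.start, minus.end, minus.length) == (100, 300, 200)

    def test_needs_tss_or_atg(self):
        with pytest.raises(ValueError, match="neither TSS nor ATG"):
            Transcript(id="x", gene_id="x", chrom="chrI", strand="+",
                       tss=None, tes=100)


class TestDeriveTss:
    def test_atg_fallback_places_tss_150_bases_five_prime(self):
        plus = make_transcript(strand="+", tss=None, atg=10000, tes=12000)
        assert derive_tss(plus) == 9850
        minus = make_transcript(strand="-", tss=None, atg=10000, tes=8000)
        assert derive_tss(minus) == 10150

    def test_annotated_tss_returned_unchanged(self):
        t = make_transcript(tss=5000, tes=7000, atg=5200)
        assert derive_tss(t) == 5000

    @settings(max_examples=100, derandomize=True)
    @given(atg=st.integers(1000, 50000), L=st.integers(60000, 80000))
    def test_strand_antisymmetry_under_genome_mirror(self, atg, L):
        plus = make_transcript(strand="+", tss=None, atg=atg, tes=atg + 3000)
        mirrored = make_transcript(
            strand="-", tss=None, atg=L - 1 - atg, tes=L - 1 - (atg + 3000)
        )
        assert derive_tss(mirrored) == L - 1 - derive_tss(plus)


class TestAnnotationIO:
    def test_gff3_groups_isoforms_by_gene(self, tmp_path):
        path = tmp_path / "two_iso.gff3"
        path.write_text(
            "##gff-version 3\n"
            "##sequence-region chrI 1 50000\n"
            "chrI\tsrc\tgene\t1001\t5000\t.\t+\t.\tID=geneA\n"
            "chrI\tsrc\tmRNA\t1001\t5000\t.\t+\t.\tID=geneA.1;Parent=geneA\n"
            "chrI\tsrc\tmRNA\t1201\t4800\t.\t+\t.\tID=geneA.2;Parent=geneA\n"
        )
        ann = read_annotation(path)
        assert ann.n_genes == 1
        assert ann.n_transcripts == 2
        assert ann.transcript("geneA.1").tss == 1000  # 1-based -> 0-based

    def test_malformed_gff3_names_line_number(self, tmp_path):
        path = tmp_path / "bad.gff3"
        path.write_text(
            "##gff-version 3\n"
            "##sequence-region chrI 1 50000\n"
            "chrI\tsrc\tmRNA\tnot_a_number\t5000\t.\t+\t.\tID=t\n"
        )
        with pytest.raises(FormatError, match="line 3"):
            read_annotation(path)

    def test_transcript_outside_chromosome_rejected(self, tmp_path):
        path = tmp_path / "oob.gff3"
        path.write_text(
            "##gff-version 3\n"
            "##sequence-region chrI 1 2000\n"
            "chrI\tsrc\tmRNA\t1001\t5000\t.\t+\t.\tID=t\n"
        )
        with pytest.raises(ValueError, match="outside"):
            read_annotation(path)

    def test_bed12_minus_strand_tss_is_end_side(self, tmp_path):
        path = tmp_path / "minus.bed"
        path.write_text("chrI\t100\t600\tgeneB|geneB.1\t0\t-\t100\t100\n")
        ann = read_annotation(path, chrom_sizes={"chrI": 1000})
        t = ann.transcript("geneB.1")
        assert t.tss == 599
        assert t.tes == 100

    def test_gff3_round_trip_preserves_coordinates(self, tmp_path):
        rng = np.random.default_rng(7)
        for i in range(100):
            txs = []
            for g in range(int(rng.integers(1, 5))):
                strand = "+" if rng.random() < 0.5 else "-"
                start = int(rng.integers(0, 40000))
                end = start + int(rng.integers(200, 5000))
                tss, tes = (start, end - 1) if strand == "+" else (end - 1, start)
                atg = None
                if rng.random() < 0.4:
                    atg = tss + 150 if strand == "+" else tss - 150
                no_tss = atg is not None and rng.random() < 0.5
                txs.append(
                    Transcript(
                        id=f"g{g}.1", gene_id=f"g{g}", chrom="chrI",
                        strand=strand, tss=None if no_tss else tss,
                        tes=tes, atg=atg,
                    )
                )
            ann = GenomeAnnotation(chromosomes={"chrI": 60000}, transcripts=txs)
            path = tmp_path / f"rt{i}.gff3"
            write_annotation(ann, path)
            back = read_annotation(path)
            assert back.chromosomes == ann.chromosomes
            assert sorted(back.transcripts, key=lambda t: t.id) == sorted(
                ann.transcripts, key=lambda t: t.id
            )


class TestTrackIO:
    def test_bedgraph_expands_per_base(self, tmp_path):
        path = tmp_path / "t.bedgraph"
        path.write_text(
            "track type=bedGraph name=x total_mapped_reads=100\n"
            "#chrom_sizes chrI=20\n"
            "chrI\t0\t10\t3\n"
        )
        track = read_track(path)
        assert track.total_mapped_reads == 100
        np.testing.assert_array_equal(
            track.data["chrI"], [3.0] * 10 + [0.0] * 10
        )

    def test_empty_body_gives_zero_track(self, tmp_path):
        path = tmp_path / "empty.bedgraph"
        path.write_text(
            "track type=bedGraph total_mapped_reads=5\n#chrom_sizes chrI=15\n"
        )
        track = read_track(path)
        assert track.data["chrI"].sum() == 0

    def test_overlapping_intervals_rejected(self, tmp_path):
        path = tmp_path / "ov.bedgraph"
        path.write_text(
            "track type=bedGraph total_mapped_reads=5\n#chrom_sizes chrI=30\n"
            "chrI\t0\t10\t1\nchrI\t5\t15\t2\n"
        )
        with pytest.raises(FormatError, match="overlap"):
            read_track(path)

    def test_negative_value_rejected(self, tmp_path):
        path = tmp_path / "neg.bedgraph"
        path.write_text(
            "track type=bedGraph total_mapped_reads=5\n#chrom_sizes chrI=30\n"
            "chrI\t0\t10\t-1\n"
        )
        with pytest.raises(FormatError, match="negative"):
            read_track(path)

    def test_missing_total_rejected(self, tmp_path):
        path = tmp_path / "nt.bedgraph"
        path.write_text("track type=bedGraph\nchrI\t0\t10\t1\n")
        with pytest.raises(FormatError, match="total_mapped_reads"):
            read_track(path)

    def test_round_trip_random_sparse_tracks(self, tmp_path):
        rng = np.random.default_rng(11)
        for i in range(20):
            arr = np.zeros(int(rng.integers(50, 500)))
            for _ in range(int(rng.integers(0, 8))):
                s = int(rng.integers(0, arr.size - 5))
                arr[s : s + int(rng.integers(1, 40))] = int(rng.integers(1, 9))
            track = CoverageTrack(
                data={"chrI": arr, "chrII": np.zeros(30)},
                total_mapped_reads=int(rng.integers(1, 10**7)),
                label="rt",
            )
            path = tmp_path / f"rt{i}.bedgraph"
            write_track(track, path)
            back = read_track(path)
            assert back.total_mapped_reads == track.total_mapped_reads
            for chrom in track.data:
                np.testing.assert_array_equal(back.data[chrom], track.data[chrom])


class TestSiteAndPwmIO:
    def test_site_table_round_trip(self, tmp_path):
        sites = [
            BindingSite("chrI", 100, 500, 1e-8, 5.5),
            BindingSite("chrII", 0, 50, 0.02, 1.0),
        ]
        path = tmp_path / "sites.tsv"
        write_sites(sites, path)
        assert read_sites(path) == sites

    def test_pwm_round_trip_and_count_normalization(self, tmp_path):
        rng = np.random.default_rng(3)
        pwm = Pwm(
            matrix=rng.dirichlet([1] * 4, size=6).T,
            background=np.array([0.3, 0.2, 0.2, 0.3]),
            name="m1",
        )
        path = tmp_path / "m.pwm"
        write_pwm(pwm, path)
        back = read_pwm(path)
        np.testing.assert_allclose(back.matrix, pwm.matrix, atol=1e-12)
        np.testing.assert_allclose(back.background, pwm.background)
        # count matrices are accepted and floored away from zero
        counts = tmp_path / "counts.pwm"
        counts.write_text(
            "A\t8\t0\nC\t0\t2\nG\t2\t8\nT\t0\t0\n"
        )
        loaded = read_pwm(counts)
        np.testing.assert_allclose(loaded.matrix.sum(axis=0), 1.0)
        assert loaded.matrix.min() > 0

    def test_pwm_columns_must_sum_to_one(self):
        bad = np.full((4, 3), 0.3)
        with pytest.raises(ValueError, match="sum to 1"):
            Pwm(matrix=bad)


class TestCoverageTrack:
    def test_rejects_negative_coverage(self):
        with pytest.raises(ValueError, match="negative"):
            CoverageTrack(data={"chrI": np.array([1.0, -1.0])},
                          total_mapped_reads=10)

    def test_rejects_nonpositive_total(self):
        with pytest.raises(ValueError, match="positive"):
            CoverageTrack(data={"chrI": np.ones(5)}, total_mapped_reads=0)

    def test_region_sum_clips_to_chromosome(self):
        track = CoverageTrack(data={"chrI": np.arange(10.0)},
                              total_mapped_reads=10)
        assert track.region_sum("chrI", -5, 3) == 0 + 1 + 2
        assert track.region_sum("chrI", 8, 99) == 8 + 9
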