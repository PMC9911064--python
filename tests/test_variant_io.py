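"""I/O, QC, window tiling and ancestry classification."""
import numpy as np
import pytest

from domscan.simulate import SimulationConfig, simulate_cohort
from domscan.types import GenotypeMatrix, VariantSite
from domscan.variant_io import (
    classify_accessions,
    missingness_filter,
    n50,
    read_gff_genes,
    read_vcf,
    select_biallelic_snps,
    site_qc_flag,
    tile_windows,
    write_vcf,
)

from conftest import build_matrix


class TestSiteQC:
    @pytest.mark.parametrize(
        "qual,depth,expected",
        [
            (19, 10, "LowQual"),  # quality clause, strict
            (20, 32, "PASS"),  # both at the boundary: strict inequalities
            (50, 33, "LowQual"),  # excess-depth clause
            (19.99, 32, "LowQual"),
            (None, 10, "PASS"),  # missing QUAL cannot fail the clause
            (50, None, "PASS"),  # missing DP passes the depth clause
        ],
    )
    def test_flagging(self, qual, depth, expected):
        site = VariantSite("chr1", 100, "A", ("T",), qual=qual, depth=depth)
        assert site_qc_flag(site).filter_flag == expected

    def test_negative_depth_rejected(self):
        site = VariantSite("chr1", 100, "A", ("T",), qual=30, depth=-1)
        with pytest.raises(ValueError):
            site_qc_flag(site)


class TestBiallelicSelection:
    def make(self):
        sites = [
            VariantSite("chr1", 10, "A", ("T",)),  # biallelic SNP
            VariantSite("chr1", 20, "AT", ("A",)),  # indel
            VariantSite("chr1", 30, "G", ("A", "C")),  # triallelic
            VariantSite("chr1", 40, "C", ("G",), filter_flag="LowQual"),
        ]
        hap = np.zeros((4, 4), dtype=np.int8)
        return GenotypeMatrix(hap, ["a", "b"], ["pop", "pop"], sites)

    def test_definition(self):
        kept = select_biallelic_snps(self.make())
        assert kept.n_sites == 1 and kept.sites[0].pos == 10

    def test_idempotent(self):
        once = select_biallelic_snps(self.make())
        twice = select_biallelic_snps(once)
        assert [s.pos for s in once.sites] == [s.pos for s in twice.sites]

    def test_all_lowqual_gives_empty(self):
        m = self.make()
        for s in m.sites:
            s.filter_flag = "LowQual"
        assert select_biallelic_snps(m).n_sites == 0


class TestMissingness:
    def test_thresholds_are_strict(self):
        # s0 (ingroup) at exactly 50% missing -> removed; s2 (outgroup) at
        # exactly 75% -> removed; complete samples kept.
        cols = [
            [-1, -1, 0, 0, -1, -1, 0, 0],
            [-1, -1, 0, 0, -1, -1, 0, 0],
            [0, 0, 0, 0, -1, -1, 0, 0],
            [0, 0, 0, 0, 0, 0, 0, 0],
        ]
        m = build_matrix(cols, populations=["pop", "pop", "outgroup", "pop"])
        kept = missingness_filter(m)
        assert kept.samples == ["s1", "s3"]

    def test_outgroup_below_threshold_kept(self):
        cols = [[-1, -1, 0, 0]] * 7 + [[0, 0, 0, 0]] * 3  # 70% missing for s0
        m = build_matrix(cols, populations=["outgroup", "pop"])
        assert "s0" in missingness_filter(m).samples

    def test_empty_matrix_rejected(self):
        m = build_matrix([[0, 0]])
        with pytest.raises(ValueError):
            missingness_filter(m.subset_sites([]))


class TestTileWindows:
    def test_partial_terminal_window_kept(self):
        track = tile_windows({"chr1": 25_000}, 10_000)
        assert [(w.start, w.end) for w in track] == [
            (0, 10_000),
            (10_000, 20_000),
            (20_000, 25_000),
        ]

    def test_fully_gapped_window_removed(self):
        track = tile_windows(
            {"chr1": 25_000}, 10_000, {"chr1": [(10_000, 20_000)]}
        )
        assert [(w.start, w.end) for w in track] == [(0, 10_000), (20_000, 25_000)]

    def test_overlapping_gaps_merged_and_fraction_set(self):
        track = tile_windows(
            {"chr1": 10_000}, 10_000, {"chr1": [(0, 3000), (2000, 5000)]}
        )
        assert track[0].gap_fraction == pytest.approx(0.5)

    def test_coverage_matches_arithmetic_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            lengths = {
                f"c{i}": int(rng.integers(1, 12) * 7919) for i in range(3)
            }
            w = int(rng.integers(1000, 20_000))
            track = tile_windows(lengths, w)
            expected = sum(-(-L // w) for L in lengths.values())
            assert len(track) == expected
            # windows cover every base exactly once
            for chrom, L in lengths.items():
                wins = track.on_chrom(chrom)
                assert wins[0].start == 0 and wins[-1].end == L
                for a, b in zip(wins, wins[1:]):
                    assert a.end == b.start

    def test_bad_width_rejected(self):
        with pytest.raises(ValueError):
            tile_windows({"chr1": 100}, 0)


class TestClassifyAccessions:
    def test_published_cohort_assignments(self, accession_table):
        rows = [(name, q) for name, q, _ in accession_table]
        result = classify_accessions(rows)
        for (name, _, expected), profile in zip(accession_table, result):
            assert profile.assigned_group == expected, name

    def test_exact_threshold_is_admixed(self):
        rows = [("x", {"Guatemalan": 0.80, "Mexican": 0.20, "Lowland": 0.0})]
        assert classify_accessions(rows)[0].assigned_group == "admixed"

    def test_exclusion_list(self):
        rows = [("Gwen", {"Guatemalan": 1.0, "Mexican": 0.0, "Lowland": 0.0})]
        out = classify_accessions(rows, exclusions=["Gwen"])
        assert out[0].assigned_group == "excluded"

    def test_bad_row_sum_rejected(self):
        with pytest.raises(ValueError):
            classify_accessions([("x", {"Guatemalan": 0.5, "Mexican": 0.1, "Lowland": 0.0})])

    def test_percent_and_fraction_rows_mix(self):
        rows = [
            ("pct", {"Guatemalan": 90.0, "Mexican": 10.0, "Lowland": 0.0}),
            ("frac", {"Guatemalan": 0.9, "Mexican": 0.1, "Lowland": 0.0}),
        ]
        out = classify_accessions(rows)
        assert [p.assigned_group for p in out] == ["Guatemalan", "Guatemalan"]
        assert out[0].proportions["Guatemalan"] == pytest.approx(0.9)


class TestGFF:
    GFF = """##gff-version 3
chr1\tsrc\tgene\t100\t200\t.\t+\t.\tID=g1
chr1\tsrc\tmRNA\t100\t200\t.\t+\t.\tID=g1.t1;Parent=g1
chr1\tsrc\tCDS\t100\t150\t.\t+\t0\tID=g1.c1;Parent=g1.t1
chr1\tsrc\tCDS\t140\t180\t.\t+\t0\tID=g1.c2;Parent=g1.t1
chr2\tsrc\tCDS\t5\t20\t.\t+\t0\tID=orphan
"""

    def test_coordinates_and_cds_merge(self, tmp_path):
        path = tmp_path / "x.gff3"
        path.write_text(self.GFF)
        genes = read_gff_genes(path)
        assert len(genes) == 1
        g = genes[0]
        assert (g.start, g.end) == (99, 200)  # 1-based inclusive -> half-open
        assert g.cds == [(99, 180)]  # overlapping CDS merged
        assert g.cds_length == 81

    def test_cds_length_matches_base_count(self, tmp_path):
        rng = np.random.default_rng(1)
        for trial in range(5):
            ivs = sorted(rng.integers(1, 500, size=6))
            cds = [(int(ivs[0]), int(ivs[1]) + 1), (int(ivs[2]), int(ivs[3]) + 1), (int(ivs[4]), int(ivs[5]) + 1)]
            lines = ["##gff-version 3", f"chr1\ts\tgene\t1\t600\t.\t+\t.\tID=g"]
            lines.append("chr1\ts\tmRNA\t1\t600\t.\t+\t.\tID=t;Parent=g")
            for i, (s, e) in enumerate(cds):
                lines.append(f"chr1\ts\tCDS\t{s}\t{e}\t.\t+\t0\tID=c{i};Parent=t")
            path = tmp_path / f"r{trial}.gff3"
            path.write_text("\n".join(lines) + "\n")
            (gene,) = read_gff_genes(path)
            base_set = set()
            for s, e in cds:
                base_set |= set(range(s - 1, e))
            assert gene.cds_length == len(base_set)


class TestVCFRoundTrip:
    def test_cohort_round_trip_preserves_fields(self, tmp_path, cohort):
        matrix, _ = cohort
        small = matrix.subset_sites(range(0, min(300, matrix.n_sites)))
        p1 = tmp_path / "a.vcf"
        write_vcf(p1, small)
        _, back = read_vcf(p1)
        assert back.samples == small.samples
        assert np.array_equal(back.haplotypes, small.haplotypes)
        for s1, s2 in zip(small.sites, back.sites):
            assert (s1.chrom, s1.pos, s1.ref, s1.alt) == (s2.chrom, s2.pos, s2.ref, s2.alt)
        p2 = tmp_path / "b.vcf"
        write_vcf(p2, back)
        assert p1.read_text().splitlines()[5:] == p2.read_text().splitlines()[5:]

    def test_missing_genotype_maps_to_both_haplotypes(self, tmp_path):
        vcf = tmp_path / "m.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
            "chr1\t5\t.\tA\tG\t50\tPASS\t.\tGT\t./.\t0/1\t1/1\n"
        )
        _, m = read_vcf(vcf)
        assert m.n_haplotypes == 6 and m.n_sites == 1
        assert list(m.haplotypes[:, 0]) == [-1, -1, 0, 1, 1, 1]

    def test_dimension_bookkeeping(self, tmp_path):
        header = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc\n"
        )
        body = "".join(
            f"chr1\t{p}\t.\tA\tC\t50\tPASS\t.\tGT\t0/0\t0/1\t1/1\n" for p in range(10, 60, 10)
        )
        vcf = tmp_path / "d.vcf"
        vcf.write_text(header + body)
        _, m = read_vcf(vcf)
        assert (m.n_haplotypes, m.n_sites) == (6, 5)

    def test_unknown_sample_in_subset_rejected(self, tmp_path):
        vcf = tmp_path / "d.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\n"
            "chr1\t5\t.\tA\tG\t50\tPASS\t.\tGT\t0/1\n"
        )
        with pytest.raises(ValueError, match="nope"):
            read_vcf(vcf, sample_subset=["nope"])


def test_n50_definition():
    # 10 contigs: the length at which the cumulative sorted sum passes half
    assert n50([100, 90, 50, 40, 30]) == 90
    assert n50([10] * 10) == 10
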