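"""Gene-model parsing, region derivation, CpG assignment and NAT pairing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hoxscape.annotation import (
    AnnotationError,
    GeneModel,
    GenomicInterval,
    NATPair,
    RegionIndex,
    RegionKey,
    assign_cpg,
    cluster_of_symbol,
    derive_regions,
    find_nat_pairs,
    parse_annotation,
    parse_bed12,
    parse_gtf,
    promoter_interval,
    write_bed12,
    write_gtf,
)


def make_gene(gene_id, exons, strand="+", chrom="chr1", biotype="coding"):
    return GeneModel(
        gene_id=gene_id, symbol=gene_id, chrom=chrom, strand=strand,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        biotype=biotype,
    )


def random_gene(rng, gene_id="G", strand=None, chrom="chr1"):
    strand = strand or rng.choice(["+", "-"])
    n_exons = int(rng.integers(1, 6))
    start = int(rng.integers(0, 5000)) + 2000
    exons, cursor = [], start
    for _ in range(n_exons):
        length = int(rng.integers(50, 500))
        exons.append((cursor, cursor + length))
        cursor += length + int(rng.integers(50, 400))
    return make_gene(gene_id, exons, strand=strand, chrom=chrom)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

class TestParsing:
    def test_packaged_fixture_has_39_coding_genes_in_4_clusters(self, hox_genes):
        coding = [g for g in hox_genes if g.biotype == "coding"]
        assert len(coding) == 39
        assert {g.cluster for g in coding} == {"A", "B", "C", "D"}
        assert all(g.cluster != "none" for g in coding)

    def test_lncrnas_parsed_with_biotype(self, hox_genes):
        lncs = {g.gene_id for g in hox_genes if g.biotype == "lncRNA"}
        assert "HOTAIRM1" in lncs and len(lncs) == 6

    def test_gtf_bed12_round_trip(self, hox_genes, tmp_path):
        write_gtf(hox_genes, tmp_path / "rt.gtf")
        write_bed12(hox_genes, tmp_path / "rt.bed")
        via_gtf = parse_annotation(tmp_path / "rt.gtf")
        via_bed = parse_annotation(tmp_path / "rt.bed")
        for parsed in (via_gtf, via_bed):
            assert {g.gene_id for g in parsed} == {g.gene_id for g in hox_genes}
            by_id = {g.gene_id: g for g in parsed}
            for g in hox_genes:
                assert by_id[g.gene_id].exons == g.exons
                assert by_id[g.gene_id].strand == g.strand
                assert by_id[g.gene_id].biotype == g.biotype

    def test_malformed_gtf_names_line_number(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text(
            'chr1\tx\texon\t100\t200\t.\t+\t.\tgene_id "A";\n'
            "chr1\tx\texon\tnot_a_number\n"
        )
        with pytest.raises(AnnotationError, match=":2"):
            parse_gtf(path)

    def test_strandless_record_rejected(self, tmp_path):
        path = tmp_path / "strandless.gtf"
        path.write_text('chr1\tx\texon\t100\t200\t.\t.\t.\tgene_id "A";\n')
        with pytest.raises(AnnotationError, match="strandless"):
            parse_gtf(path)

    def test_bed12_block_mismatch_rejected(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t100\t400\tA\t0\t+\t100\t100\t0\t2\t50\t0,200\n")
        with pytest.raises(AnnotationError, match="block"):
            parse_bed12(path)

    def test_cluster_inference_case_insensitive_with_decoys(self):
        assert cluster_of_symbol("hoxa1") == "A"
        assert cluster_of_symbol("HOXD13") == "D"
        assert cluster_of_symbol("GAPDH") == "none"

    def test_single_exon_plus_gene_tss_and_no_introns(self):
        g = make_gene("G", [(100, 200)], strand="+")
        assert g.tss == 101
        assert g.introns_transcript_order() == ()

    def test_minus_strand_exon_intron_orientation_mirror(self):
        g = make_gene("G", [(100, 200), (300, 400)], strand="-")
        assert g.tss == 400
        assert g.exons_transcript_order()[0] == GenomicInterval("chr1", 300, 400, "-")
        assert g.introns_transcript_order() == (GenomicInterval("chr1", 200, 300, "-"),)


# ---------------------------------------------------------------------------
# promoter
# ---------------------------------------------------------------------------

class TestPromoter:
    @pytest.mark.parametrize(
        "strand,exons,expected",
        [
            ("+", [(10000, 12000)], (9000, 10100)),  # tss=10001
            ("-", [(8000, 10000)], (9900, 11000)),  # tss=10000
            ("+", [(500, 900)], (0, 600)),  # clamped at chromosome start
        ],
    )
    def test_promoter_arithmetic(self, strand, exons, expected):
        iv = promoter_interval(make_gene("G", exons, strand=strand))
        assert (iv.start, iv.end) == expected

    @given(tss0=st.integers(2000, 10_000_000), length=st.integers(200, 50_000))
    @settings(max_examples=50, deadline=None)
    def test_strand_mirror_preserves_promoter_length(self, tss0, length):
        plus = make_gene("G", [(tss0, tss0 + length)], strand="+")
        minus = make_gene("G", [(tss0, tss0 + length)], strand="-")
        assert promoter_interval(plus).length == promoter_interval(minus).length


# ---------------------------------------------------------------------------
# region derivation
# ---------------------------------------------------------------------------

class TestRegions:
    def test_three_exon_gene_region_census(self):
        g = make_gene("G", [(1000, 1200), (1400, 1600), (1800, 2000)])
        regions = derive_regions(g)
        kinds = [k.region_type for k, _ in regions]
        assert kinds.count("promoter") == 1
        assert kinds.count("exon") == 3
        assert kinds.count("intron") == 2
        assert len(regions) == 6

    def test_single_exon_gene_has_no_introns(self):
        regions = derive_regions(make_gene("G", [(1000, 1500)]))
        assert [k.region_type for k, _ in regions] == ["promoter", "exon"]

    def test_exons_and_introns_tile_gene_span(self):
        rng = np.random.default_rng(11)
        for i in range(100):
            g = random_gene(rng, f"G{i}")
            regions = dict(derive_regions(g))
            body_len = sum(
                iv.length for k, iv in regions.items() if k.region_type in {"exon", "intron"}
            )
            assert body_len == g.end - g.start

    def test_introns_match_brute_force_complement(self):
        """Oracle: introns are the complement of exons within the gene span."""
        rng = np.random.default_rng(7)
        for i in range(100):
            g = random_gene(rng, f"G{i}")
            covered = np.zeros(g.end - g.start, dtype=bool)
            for e in g.exons:
                covered[e.start - g.start : e.end - g.start] = True
            expected_intron_bp = int((~covered).sum())
            got = sum(iv.length for iv in g.introns_transcript_order())
            assert got == expected_intron_bp

    def test_utr_regions_only_with_cds(self, tmp_path):
        gtf = tmp_path / "cds.gtf"
        attrs = 'gene_id "G"; gene_name "G";'
        gtf.write_text(
            f"chr1\tx\texon\t1001\t1400\t.\t+\t.\t{attrs}\n"
            f"chr1\tx\texon\t1601\t2000\t.\t+\t.\t{attrs}\n"
            f"chr1\tx\tCDS\t1101\t1400\t.\t+\t.\t{attrs}\n"
            f"chr1\tx\tCDS\t1601\t1900\t.\t+\t.\t{attrs}\n"
        )
        (g,) = parse_gtf(gtf)
        regions = dict(derive_regions(g))
        assert regions[RegionKey("G", "utr5", 1)] == GenomicInterval("chr1", 1000, 1100, "+")
        assert regions[RegionKey("G", "utr3", 1)] == GenomicInterval("chr1", 1900, 2000, "+")
        plain = derive_regions(make_gene("G", [(1000, 1400), (1600, 2000)]))
        assert not any(k.region_type.startswith("utr") for k, _ in plain)


# ---------------------------------------------------------------------------
# CpG assignment
# ---------------------------------------------------------------------------

class TestAssignCpg:
    def test_site_in_intron_gets_single_key(self):
        g = make_gene("G", [(1000, 1200), (1400, 1600)])
        assert assign_cpg(1301, "chr1", [g]) == [RegionKey("G", "intron", 1)]

    def test_post_tss_window_assigned_to_promoter_and_exon1(self):
        g = make_gene("G", [(10000, 12000)], strand="+")
        keys = assign_cpg(10051, "chr1", [g])
        assert RegionKey("G", "promoter", 0) in keys
        assert RegionKey("G", "exon", 1) in keys

    def test_intergenic_site_returns_empty(self):
        g = make_gene("G", [(10000, 12000)])
        assert assign_cpg(500_000, "chr1", [g]) == []

    def test_agrees_with_brute_force_containment_oracle(self):
        rng = np.random.default_rng(3)
        genes = [random_gene(rng, f"G{i}") for i in range(12)]
        index = RegionIndex(genes)
        all_regions = [
            (key, iv) for g in genes for key, iv in derive_regions(g)
        ]
        for pos in rng.integers(1, 12000, size=1000):
            expected = sorted(
                key for key, iv in all_regions if iv.contains(int(pos) - 1)
            )
            assert index.assign("chr1", int(pos)) == expected


# ---------------------------------------------------------------------------
# NAT pairing
# ---------------------------------------------------------------------------

class TestNATPairs:
    def test_opposite_strand_exonic_overlap_counts_bp(self):
        gene = make_gene("G", [(200, 300)], strand="+")
        lnc = make_gene("L", [(150, 250)], strand="-", biotype="lncRNA")
        (pair,) = find_nat_pairs([gene, lnc])
        assert pair == NATPair("L", "G", (1,), 50)

    def test_same_strand_overlap_is_not_a_pair(self):
        gene = make_gene("G", [(200, 300)], strand="+")
        lnc = make_gene("L", [(150, 250)], strand="+", biotype="lncRNA")
        assert find_nat_pairs([gene, lnc]) == []

    def test_intronic_only_overlap_is_not_a_pair(self):
        gene = make_gene("G", [(100, 200), (500, 600)], strand="+")
        lnc = make_gene("L", [(300, 400)], strand="-", biotype="lncRNA")
        assert find_nat_pairs([gene, lnc]) == []

    def test_fixture_contains_hotairm1_hoxa1_pair(self, hox_genes):
        pairs = {(p.lncrna_id, p.gene_id) for p in find_nat_pairs(hox_genes)}
        assert ("HOTAIRM1", "HOXA1") in pairs

    def test_invariant_to_input_order_and_exon_permutation(self, hox_genes):
        rng = np.random.default_rng(5)
        shuffled = list(hox_genes)
        rng.shuffle(shuffled)
        assert find_nat_pairs(shuffled) == find_nat_pairs(hox_genes)

    def test_coordinate_reflection_preserves_overlap_bp(self):
        """Mirroring the locus and flipping strands leaves NAT overlaps intact."""
        gene = make_gene("G", [(200, 300), (400, 500)], strand="+")
        lnc = make_gene("L", [(250, 450)], strand="-", biotype="lncRNA")
        (orig,) = find_nat_pairs([gene, lnc])

        m = 1_000_000

        def mirror(g):
            flipped = "-" if g.strand == "+" else "+"
            exons = [(m - e.end, m - e.start) for e in g.exons]
            return make_gene(g.gene_id, sorted(exons), strand=flipped, biotype=g.biotype)

        (refl,) = find_nat_pairs([mirror(gene), mirror(lnc)])
        assert refl.overlap_bp == orig.overlap_bp
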