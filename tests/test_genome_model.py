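import pytest

from ipactools.errors import (
    AnnotationParseError,
    LookupError_,
    MissingAnchorError,
    ValidationError,
)
from ipactools.genome_model import (
    ExtendedAnnotation,
    GeneModel,
    gene_boundary,
    load_annotation,
)

from .conftest import make_gene


class TestExtension:
    def test_plus_strand_end_extended(self):
        g = make_gene("g", "c", "+", 0, 1000, cds=[(100, 900)])
        ann = ExtendedAnnotation([g], {"c": 5000}, extension_nt=50)
        assert ann.genes["g"].ext_end == 1050
        assert ann.genes["g"].ext_start == 0

    def test_minus_strand_mirror(self):
        g = make_gene("g", "c", "-", 500, 1000, cds=[(550, 950)])
        ann = ExtendedAnnotation([g], {"c": 5000}, extension_nt=50)
        # transcription-direction end moves 50 nt toward lower coordinates
        assert ann.genes["g"].ext_start == 450
        assert ann.genes["g"].cut3_extended == 450

    def test_zero_extension_is_identity(self):
        g = make_gene("g", "c", "+", 100, 1000)
        ann = ExtendedAnnotation([g], {"c": 5000}, extension_nt=0)
        assert ann.genes["g"].span_extended == (100, 1000)

    def test_extension_clipped_to_chrom(self):
        g = make_gene("g", "c", "+", 100, 990)
        ann = ExtendedAnnotation([g], {"c": 1000}, extension_nt=50)
        assert ann.genes["g"].ext_end == 1000


class TestIntergenicIntervals:
    def test_complement_of_two_spans(self):
        g1 = make_gene("g1", "c", "+", 0, 100)
        g2 = make_gene("g2", "c", "+", 200, 300)
        ann = ExtendedAnnotation([g1, g2], {"c": 400}, extension_nt=0)
        assert ann.intergenic_intervals("c", "+") == [(100, 200), (300, 400)]

    def test_overlapping_genes_emit_no_gap(self):
        g1 = make_gene("g1", "c", "+", 0, 150)
        g2 = make_gene("g2", "c", "+", 100, 300)
        ann = ExtendedAnnotation([g1, g2], {"c": 400}, extension_nt=0)
        assert ann.intergenic_intervals("c", "+") == [(300, 400)]

    def test_empty_strand_is_whole_chrom(self):
        g1 = make_gene("g1", "c", "+", 0, 100)
        ann = ExtendedAnnotation([g1], {"c": 500}, extension_nt=0)
        assert ann.intergenic_intervals("c", "-") == [(0, 500)]

    def test_unknown_chrom_raises(self, toy_ann):
        with pytest.raises(LookupError_):
            toy_ann.intergenic_intervals("nope", "+")

    def test_tiling_invariant(self, toy_ann):
        # extended spans + intergenic gaps tile each strand exactly once
        for strand in "+-":
            pieces = [
                g.span_extended for g in toy_ann.genes_on("c", strand)
            ] + toy_ann.intergenic_intervals("c", strand)
            pieces.sort()
            assert pieces[0][0] == 0
            assert pieces[-1][1] == 20000
            for (s1, e1), (s2, e2) in zip(pieces, pieces[1:]):
                assert e1 == s2


class TestGeneBoundary:
    def test_plus_stop_codon(self):
        g = make_gene("g", "c", "+", 0, 1000, cds=[(100, 900)])
        assert gene_boundary(g, "stop_codon") == 900

    def test_minus_stop_codon_mirror(self):
        g = make_gene("g", "c", "-", 100, 1000, cds=[(400, 900)])
        assert gene_boundary(g, "stop_codon") == 400

    def test_noncoding_missing_anchor(self):
        g = make_gene("g", "c", "+", 0, 1000, biotype="ncRNA")
        with pytest.raises(MissingAnchorError):
            gene_boundary(g, "stop_codon")

    def test_tx_start_and_extended(self, toy_ann):
        a, b = toy_ann.genes["A"], toy_ann.genes["B"]
        assert gene_boundary(a, "tx_start") == 1000
        assert gene_boundary(a, "tx_end_extended") == 3050
        assert gene_boundary(b, "tx_start") == 8000
        assert gene_boundary(b, "tx_end_extended") == 5950


class TestValidation:
    def test_end_before_start_rejected(self):
        with pytest.raises(ValidationError):
            make_gene("bad", "c", "+", 1000, 1000)

    def test_exon_outside_bounds_rejected(self):
        with pytest.raises(ValidationError):
            GeneModel("g", "c", "+", 100, 200, exons=[(50, 150)])

    def test_malformed_gff3_raises(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("##gff-version 3\nnot a gff line at all\n")
        with pytest.raises(AnnotationParseError):
            load_annotation(str(p))

    def test_introns_derived(self):
        g = GeneModel("g", "c", "+", 0, 1000, exons=[(0, 300), (500, 1000)])
        assert g.introns == [(300, 500)]


class TestGFF3RoundTrip:
    def test_round_trip_identical(self, toy_ann, tmp_path):
        p = tmp_path / "out.gff3"
        toy_ann.to_gff3(str(p))
        re = load_annotation(str(p), extension_nt=50)
        assert set(re.genes) == set(toy_ann.genes)
        for gid, g in toy_ann.genes.items():
            h = re.genes[gid]
            assert (h.tx_start, h.tx_end, h.strand, h.chrom) == (
                g.tx_start,
                g.tx_end,
                g.strand,
                g.chrom,
            )
            assert h.exons == g.exons
            assert h.cds == g.cds
            assert h.span_extended == g.span_extended

    def test_simulated_round_trip(self, sim_paths):
        ann = load_annotation(sim_paths["gff3"], extension_nt=50)
        assert len(ann.genes) == 80
        # every gene has a stop codon anchor in the simulated genome
        assert all(g.stop_codon_cut is not None for g in ann.genes.values())


class TestStrandMirror:
    def test_mirrored_annotation_mirrors_intergenic(self):
        L = 10000
        genes = [
            make_gene("g1", "c", "+", 1000, 3000),
            make_gene("g2", "c", "-", 5000, 7000),
        ]
        ann = ExtendedAnnotation(genes, {"c": L}, extension_nt=50)
        flipped = [
            make_gene(g.gene_id, "c", "-" if g.strand == "+" else "+",
                      L - g.tx_end, L - g.tx_start)
            for g in genes
        ]
        mirror = ExtendedAnnotation(flipped, {"c": L}, extension_nt=50)
        for strand, mstrand in (("+", "-"), ("-", "+")):
            got = sorted((L - e, L - s) for s, e in mirror.intergenic_intervals("c", mstrand))
            assert got == ann.intergenic_intervals("c", strand)


class TestCollapse:
    def test_multi_isoform_distal_stop(self, tmp_path):
        gff = tmp_path / "iso.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "##sequence-region c 1 10000\n"
            "c\t.\tgene\t101\t2000\t.\t+\t.\tID=g1\n"
            "c\t.\tmRNA\t101\t1500\t.\t+\t.\tID=g1.1;Parent=g1\n"
            "c\t.\texon\t101\t1500\t.\t+\t.\tParent=g1.1\n"
            "c\t.\tCDS\t201\t1200\t.\t+\t0\tParent=g1.1\n"
            "c\t.\tmRNA\t101\t2000\t.\t+\t.\tID=g1.2;Parent=g1\n"
            "c\t.\texon\t101\t2000\t.\t+\t.\tParent=g1.2\n"
            "c\t.\tCDS\t201\t1800\t.\t+\t0\tParent=g1.2\n"
        )
        ann = load_annotation(str(gff), extension_nt=50)
        g = ann.genes["g1"]
        assert (g.tx_start, g.tx_end) == (100, 2000)  # outermost bounds
        assert g.stop_codon_cut == 1800  # distal stop codon
        assert len(g.isoforms) == 2
        assert g.biotype == "protein_coding"
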