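"""Annotation parsing and non-overlapping region-index construction."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from hapscreen.annotation import (
    AnnotationError,
    GeneModel,
    build_region_index,
    index_to_gene_models,
    locate,
    read_annotation,
    write_index_bed,
)
from helpers import per_base_membership


def write_lines(path, lines):
    path.write_text("".join(line + "\n" for line in lines))
    return path


class TestReadAnnotation:
    def test_bed_field_mapping(self, tmp_path):
        p = write_lines(tmp_path / "a.bed", ["chr1\t100\t500\tGENEA\t0\t+"])
        (gene,) = read_annotation(p, format="bed12")
        assert gene == GeneModel("GENEA", "chr1", "+", ((100, 500),))

    def test_empty_file(self, tmp_path):
        p = write_lines(tmp_path / "a.bed", [])
        assert read_annotation(p) == []

    def test_unknown_strand_rejected_with_line_number(self, tmp_path):
        p = write_lines(
            tmp_path / "a.bed",
            ["chr1\t100\t500\tGENEA\t0\t+", "chr1\t600\t700\tGENEB\t0\t."],
        )
        with pytest.raises(AnnotationError, match="line 2"):
            read_annotation(p)

    def test_malformed_coordinate_names_line(self, tmp_path):
        p = write_lines(tmp_path / "a.bed", ["chr1\tabc\t500\tGENEA\t0\t+"])
        with pytest.raises(AnnotationError, match="line 1"):
            read_annotation(p)

    def test_bed12_exon_mode(self, tmp_path):
        line = "chr1\t100\t500\tGENEA\t0\t+\t100\t500\t0\t2\t50,100\t0,300"
        p = write_lines(tmp_path / "a.bed", [line])
        (whole,) = read_annotation(p)
        (exonic,) = read_annotation(p, exons_only=True)
        assert whole.intervals == ((100, 500),)
        assert exonic.intervals == ((100, 150), (400, 500))

    def test_refflat_converts_to_half_open_span(self, tmp_path):
        line = "GENEA\tNM_1\tchr1\t-\t100\t500\t120\t480\t2\t100,400,\t150,500,"
        p = write_lines(tmp_path / "a.flat", [line])
        (whole,) = read_annotation(p, format="refflat")
        (exonic,) = read_annotation(p, format="refflat", exons_only=True)
        assert whole.intervals == ((100, 500),)
        assert whole.strand == "-"
        assert exonic.intervals == ((100, 150), (400, 500))

    def test_biotype_column_flagged_and_excluded_from_index(self, tmp_path):
        lines = [
            "chr1\t100\t500\tGENEA\t0\t+\t100\t500\t0\t1\t400\t0\tprotein_coding",
            "chr1\t600\t900\tLNC1\t0\t+\t600\t900\t0\t1\t300\t0\tlincRNA",
        ]
        p = write_lines(tmp_path / "a.bed", lines)
        genes = read_annotation(p)
        assert [g.biotype for g in genes] == ["protein_coding", "lincRNA"]
        index = build_region_index(genes)
        assert {r[3] for r in index.regions} == {"GENEA"}


class TestBuildRegionIndex:
    def test_disjoint_genes_intact(self):
        genes = [
            GeneModel("A", "chr1", "+", ((100, 200),)),
            GeneModel("B", "chr1", "+", ((300, 400),)),
        ]
        index = build_region_index(genes)
        assert index.regions == [
            ("chr1", 100, 200, "A", "+"),
            ("chr1", 300, 400, "B", "+"),
        ]

    def test_partial_overlap_excised_from_both(self):
        genes = [
            GeneModel("A", "chr1", "+", ((100, 300),)),
            GeneModel("B", "chr1", "-", ((200, 400),)),
        ]
        index = build_region_index(genes)
        # per-base oracle over 100..399 gives A on [100,200), B on [300,400)
        for pos in range(100, 400):
            expected = per_base_membership(genes, "chr1", pos)
            got = index.locate("chr1", pos)
            assert (got[0] if got else None) == expected
        assert index.regions == [
            ("chr1", 100, 200, "A", "+"),
            ("chr1", 300, 400, "B", "-"),
        ]

    def test_nested_gene_dropped_outer_keeps_flanks(self):
        genes = [
            GeneModel("OUTER", "chr1", "+", ((100, 500),)),
            GeneModel("INNER", "chr1", "+", ((200, 300),)),
        ]
        index = build_region_index(genes)
        assert index.regions == [
            ("chr1", 100, 200, "OUTER", "+"),
            ("chr1", 300, 500, "OUTER", "+"),
        ]
        for pos in range(100, 500):
            expected = per_base_membership(genes, "chr1", pos)
            got = index.locate("chr1", pos)
            assert (got[0] if got else None) == expected

    def test_multi_record_gene_merged_but_conflict_rejected(self):
        records = [
            GeneModel("A", "chr1", "+", ((100, 200),)),
            GeneModel("A", "chr1", "+", ((150, 300),)),
        ]
        index = build_region_index(records)
        assert index.regions == [("chr1", 100, 300, "A", "+")]
        with pytest.raises(AnnotationError, match="conflicting"):
            build_region_index(
                [
                    GeneModel("A", "chr1", "+", ((100, 200),)),
                    GeneModel("A", "chr2", "+", ((100, 200),)),
                ]
            )

    def test_same_strand_policy_keeps_opposite_strand_overlap(self):
        genes = [
            GeneModel("A", "chr1", "+", ((100, 300),)),
            GeneModel("B", "chr1", "-", ((200, 400),)),
        ]
        index = build_region_index(genes, policy="same_strand")
        # both genes keep their full span, per strand
        assert ("chr1", 100, 300, "A", "+") in index.regions
        assert ("chr1", 200, 400, "B", "-") in index.regions
        # without a strand hint, the shared zone is ambiguous
        assert index.locate("chr1", 250) is None
        assert index.locate("chr1", 250, strand="+") == ("A", "+")
        assert index.locate("chr1", 150) == ("A", "+")
        # same-strand overlap is still excised
        genes2 = [
            GeneModel("A", "chr1", "+", ((100, 300),)),
            GeneModel("B", "chr1", "+", ((200, 400),)),
        ]
        index2 = build_region_index(genes2, policy="same_strand")
        assert index2.regions == build_region_index(genes2).regions


@st.composite
def gene_sets(draw):
    n = draw(st.integers(1, 6))
    genes = []
    for i in range(n):
        start = draw(st.integers(0, 400))
        length = draw(st.integers(1, 200))
        strand = draw(st.sampled_from("+-"))
        genes.append(GeneModel(f"G{i}", "chr1", strand, ((start, start + length),)))
    return genes


class TestIndexProperties:
    @given(gene_sets())
    def test_locate_agrees_with_per_base_scan(self, genes):
        index = build_region_index(genes)
        for pos in range(0, 650):
            expected = per_base_membership(genes, "chr1", pos)
            got = index.locate("chr1", pos)
            assert (got[0] if got else None) == expected

    @given(gene_sets())
    def test_rebuild_from_own_regions_is_identity(self, genes):
        index = build_region_index(genes)
        rebuilt = build_region_index(index_to_gene_models(index))
        assert rebuilt.regions == index.regions

    @given(gene_sets())
    def test_indexed_bases_bounded_by_annotated_bases(self, genes):
        index = build_region_index(genes)
        assert index.total_bases() <= sum(g.length for g in genes)


class TestLocateBoundaries:
    def test_half_open_convention(self, toy_index):
        assert toy_index.locate("chr1", 100) == ("GENEA", "+")  # start inclusive
        assert toy_index.locate("chr1", 499) == ("GENEA", "+")
        assert toy_index.locate("chr1", 500) is None  # end exclusive
        assert toy_index.locate("chr3", 100) is None
        assert locate(toy_index, "chr2", 0) == ("GENEC", "+")

    def test_negative_position_rejected(self, toy_index):
        with pytest.raises(ValueError):
            toy_index.locate("chr1", -1)


def test_index_bed_roundtrip(tmp_path, toy_genes):
    index = build_region_index(toy_genes)
    out = tmp_path / "index.bed"
    write_index_bed(index, out)
    reread = build_region_index(read_annotation(out, format="bed12"))
    assert reread.regions == index.regions
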