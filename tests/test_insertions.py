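"""Insertion parsing, deduplication and per-gene orientation counting."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from hapscreen.annotation import GeneModel, build_region_index
from hapscreen.insertions import (
    GeneCountTable,
    Insertion,
    InsertionParseError,
    assign_and_count,
    deduplicate,
    read_insertions,
    write_insertions,
)
from helpers import brute_force_counts


class TestReadInsertions:
    def test_field_mapping_with_sample_column(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr2\t1500\t1501\t+\tpopHigh\n")
        assert read_insertions(p) == [Insertion("chr2", 1500, "+", "popHigh")]

    def test_sample_defaults_to_file_stem(self, tmp_path):
        p = tmp_path / "screenA.bed"
        p.write_text("chr1\t10\t11\t-\n")
        assert read_insertions(p) == [Insertion("chr1", 10, "-", "screenA")]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("")
        assert read_insertions(p) == []

    @pytest.mark.parametrize(
        "line", ["chr1\t10\t11\t*", "chr1\tten\t11\t+", "chr1\t10\t11"]
    )
    def test_malformed_records_rejected(self, tmp_path, line):
        p = tmp_path / "x.bed"
        p.write_text(line + "\n")
        with pytest.raises(InsertionParseError, match=":1"):
            read_insertions(p)

    def test_roundtrip_through_writer(self, tmp_path):
        ins = [Insertion("chr1", 5, "+", "s"), Insertion("chr2", 9, "-", "s")]
        p = tmp_path / "x.bed"
        write_insertions(ins, p)
        assert read_insertions(p) == ins


class TestDeduplicate:
    def test_uniqueness_key_is_position_strand_sample(self):
        triple = [Insertion("chr1", 100, "+", "S")] * 3
        assert deduplicate(triple) == [Insertion("chr1", 100, "+", "S")]
        both_strands = [
            Insertion("chr1", 100, "+", "S"),
            Insertion("chr1", 100, "-", "S"),
        ]
        assert len(deduplicate(both_strands)) == 2
        two_samples = [
            Insertion("chr1", 100, "+", "S1"),
            Insertion("chr1", 100, "+", "S2"),
        ]
        assert len(deduplicate(two_samples)) == 2

    def test_output_order_deterministic(self):
        ins = [
            Insertion("chr2", 5, "+", "S"),
            Insertion("chr1", 9, "-", "S"),
            Insertion("chr1", 9, "+", "S"),
        ]
        assert deduplicate(ins) == deduplicate(list(reversed(ins)))


class TestAssignAndCount:
    def test_orientation_classification(self, toy_index):
        table = assign_and_count(
            [
                Insertion("chr1", 150, "+", "S"),  # + cassette in + gene: sense
                Insertion("chr1", 900, "+", "S"),  # + cassette in - gene: antisense
                Insertion("chr1", 901, "-", "S"),  # - cassette in - gene: sense
            ],
            toy_index,
        )
        counts = table.counts.set_index("gene_id")
        assert counts.loc["GENEA", ["sense", "antisense"]].tolist() == [1, 0]
        assert counts.loc["GENEB", ["sense", "antisense"]].tolist() == [1, 1]

    def test_unknown_chromosome_counts_as_unassigned(self, toy_index):
        table = assign_and_count([Insertion("chrM", 5, "+", "S")], toy_index)
        assert table.totals.loc["S", "total_unassigned"] == 1
        assert table.counts.empty

    def test_counts_match_brute_force_scan(self, toy_genes, toy_index):
        import numpy as np

        rng = np.random.default_rng(7)
        ins = [
            Insertion(
                str(rng.choice(["chr1", "chr2"])),
                int(rng.integers(0, 1400)),
                str(rng.choice(["+", "-"])),
                str(rng.choice(["high", "low"])),
            )
            for _ in range(100)
        ]
        table = assign_and_count(ins, toy_index)
        expected, expected_unassigned = brute_force_counts(ins, toy_genes)
        got = {
            (r.gene_id, r.sample): {"sense": r.sense, "antisense": r.antisense}
            for r in table.counts.itertuples()
        }
        assert got == expected
        for sample, n in expected_unassigned.items():
            assert table.totals.loc[sample, "total_unassigned"] == n

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 1400),
                st.sampled_from("+-"),
                st.sampled_from(["a", "b"]),
            ),
            max_size=60,
        )
    )
    def test_conservation_and_permutation_invariance(self, raw):
        genes = [
            GeneModel("GENEA", "chr1", "+", ((100, 500),)),
            GeneModel("GENEB", "chr1", "-", ((800, 1200),)),
        ]
        index = build_region_index(genes)
        ins = [Insertion("chr1", p, s, smp) for p, s, smp in raw]
        if not ins:
            return
        table = assign_and_count(ins, index)
        unique_per_sample = {}
        for i in set(ins):
            unique_per_sample[i.sample] = unique_per_sample.get(i.sample, 0) + 1
        for sample, n_unique in unique_per_sample.items():
            row = table.totals.loc[sample]
            assert (
                row["total_sense"] + row["total_antisense"] + row["total_unassigned"]
                == n_unique
            )
        shuffled = assign_and_count(list(reversed(ins)), index)
        assert shuffled.counts.equals(table.counts)
        assert shuffled.totals.equals(table.totals)

    def test_strand_flip_symmetry(self, toy_genes):
        """Flipping all gene AND insertion strands leaves counts unchanged."""
        flip = {"+": "-", "-": "+"}
        ins = [
            Insertion("chr1", 150, "+", "S"),
            Insertion("chr1", 900, "+", "S"),
            Insertion("chr2", 10, "-", "S"),
            Insertion("chr2", 299, "+", "S"),
        ]
        flipped_genes = [
            GeneModel(g.gene_id, g.chrom, flip[g.strand], g.intervals)
            for g in toy_genes
        ]
        flipped_ins = [
            Insertion(i.chrom, i.pos, flip[i.strand], i.sample) for i in ins
        ]
        t1 = assign_and_count(ins, build_region_index(toy_genes))
        t2 = assign_and_count(flipped_ins, build_region_index(flipped_genes))
        assert t1.counts.equals(t2.counts)
        assert t1.totals.equals(t2.totals)


class TestGeneCountTableIO:
    def test_tsv_roundtrip_preserves_counts_and_totals(self, tmp_path, toy_index):
        ins = [
            Insertion("chr1", 150, "+", "high"),
            Insertion("chr1", 151, "-", "high"),
            Insertion("chr1", 900, "+", "low"),
            Insertion("chr9", 5, "+", "low"),
        ]
        table = assign_and_count(ins, toy_index)
        p = tmp_path / "counts.tsv"
        table.to_tsv(p)
        back = GeneCountTable.from_tsv(p)
        assert back.counts.equals(table.counts)
        assert back.totals.astype(int).equals(table.totals.astype(int))

    def test_pretabulated_table_without_totals_header(self, tmp_path):
        p = tmp_path / "counts.tsv"
        p.write_text("gene_id\tsample\tsense\tantisense\nA\ts1\t3\t5\n")
        table = GeneCountTable.from_tsv(p)
        assert table.totals.loc["s1", "total_sense"] == 3
        assert table.totals.loc["s1", "total_unassigned"] == 0

    def test_pooling_sums_counts(self, toy_index):
        ins = [
            Insertion("chr1", 150, "+", "r1"),
            Insertion("chr1", 160, "+", "r2"),
            Insertion("chr1", 170, "-", "r2"),
        ]
        pooled = assign_and_count(ins, toy_index).pooled()
        row = pooled.counts.set_index("gene_id").loc["GENEA"]
        assert row["sense"] == 2 and row["antisense"] == 1
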