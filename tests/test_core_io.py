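"""Readers/writers: FASTA, gene tables, GFF3, Newick, and domain invariants."""

import io

import dendropy
import pytest

from vqfam.core_io import (
    GeneModel,
    LocusGroup,
    read_fasta,
    read_gene_table,
    read_gff3,
    read_newick,
    write_fasta,
    write_newick,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestFasta:
    @pytest.mark.parametrize(
        "text,expected",
        [
            (">a\nMKV\n", [("a", "MKV")]),
            (">a\nMK\nVQ\n>b\nFF\n", [("a", "MKVQ"), ("b", "FF")]),
            (">a desc here\nmkv\n", [("a", "MKV")]),  # first token id, uppercased
        ],
    )
    def test_parse(self, tmp_path, text, expected):
        assert read_fasta(_write(tmp_path, "x.faa", text)) == expected

    def test_duplicate_id_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="duplicate.*'a'"):
            read_fasta(_write(tmp_path, "x.faa", ">a\nMK\n>a\nVV\n"))

    def test_illegal_character_reported_with_line(self, tmp_path):
        with pytest.raises(ValueError, match="line 2"):
            read_fasta(_write(tmp_path, "x.faa", ">a\nM7K\n"))

    def test_empty_file_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="no records"):
            read_fasta(_write(tmp_path, "x.faa", ""))

    def test_round_trip(self, tmp_path):
        recs = [("p1", "MKVQLL" * 30), ("p2", "FFAAX")]
        write_fasta(recs, tmp_path / "out.faa")
        assert read_fasta(tmp_path / "out.faa") == recs


class TestGeneTable:
    HEADER = "gene_name\tlocus_id\tchrom\tstrand\tlocation\tcds_length\n"

    def test_catalogue_style_row(self, tmp_path):
        row = "BrVQ1-1\tBra025998\tA06\t-\t6,588,703–6,588,999\t297\n"
        (g,) = read_gene_table(_write(tmp_path, "g.tsv", self.HEADER + row))
        assert (g.start, g.end, g.cds_length) == (6588703, 6588999, 297)
        assert g.span == 297

    def test_misplaced_thousands_separators(self, tmp_path):
        row = "BrVQ8\tBra033934\tA02\t-\t108,00,121–10,800,534\t414\n"
        (g,) = read_gene_table(_write(tmp_path, "g.tsv", self.HEADER + row))
        assert (g.start, g.end) == (10800121, 10800534)

    def test_reversed_range_rejected(self, tmp_path):
        row = "x\ty\tA01\t+\t10-5\t297\n"
        with pytest.raises(ValueError, match="start.*end"):
            read_gene_table(_write(tmp_path, "g.tsv", self.HEADER + row))

    def test_span_exceeding_cds_kept(self, tmp_path):
        row = "BrVQ35\tBra006328\tA03\t-\t3,034,196–3,038,533\t1707\n"
        (g,) = read_gene_table(_write(tmp_path, "g.tsv", self.HEADER + row))
        assert g.span == 4338 and g.cds_length == 1707

    def test_non_triplet_cds_warns_but_keeps_row(self, tmp_path):
        row = "x\ty\tA01\t+\t1-100\t100\n"
        with pytest.warns(UserWarning, match="multiple of 3"):
            genes = read_gene_table(_write(tmp_path, "g.tsv", self.HEADER + row))
        assert len(genes) == 1


class TestGff3:
    GFF = (
        "##gff-version 3\n"
        "chr1\tsrc\tmRNA\t101\t400\t.\t+\t.\tID=m1;Name=g1\n"
        "chr1\tsrc\tCDS\t101\t400\t.\t+\t0\tParent=m1\n"
    )

    def test_single_exon(self, tmp_path):
        (g,) = read_gff3(_write(tmp_path, "a.gff3", self.GFF))
        assert g.exons == [(101, 400)] and g.cds_length == 300

    def test_two_exons_one_intron(self, tmp_path):
        text = (
            "chr1\tsrc\tmRNA\t101\t400\t.\t+\t.\tID=m1\n"
            "chr1\tsrc\tCDS\t301\t400\t.\t+\t0\tParent=m1\n"
            "chr1\tsrc\tCDS\t101\t200\t.\t+\t0\tParent=m1\n"
        )
        (g,) = read_gff3(_write(tmp_path, "a.gff3", text))
        assert g.exons == [(101, 200), (301, 400)] and g.cds_length == 200

    def test_cds_without_parent_rejected(self, tmp_path):
        text = "chr1\tsrc\tCDS\t101\t200\t.\t+\t0\tID=c1\n"
        with pytest.raises(ValueError, match="Parent"):
            read_gff3(_write(tmp_path, "a.gff3", text))

    def test_overlapping_cds_rejected(self, tmp_path):
        text = (
            "chr1\tsrc\tmRNA\t101\t400\t.\t+\t.\tID=m1\n"
            "chr1\tsrc\tCDS\t101\t250\t.\t+\t0\tParent=m1\n"
            "chr1\tsrc\tCDS\t200\t400\t.\t+\t0\tParent=m1\n"
        )
        with pytest.raises(ValueError, match="overlapping"):
            read_gff3(_write(tmp_path, "a.gff3", text))


class TestNewick:
    @pytest.mark.parametrize("text", ["(A:1,B:1,C:3);", "((A:1,B:1)95:0.5,C:1);"])
    def test_round_trip_preserves_labels_lengths_supports(self, text):
        tree = read_newick(text)
        again = read_newick(write_newick(tree))
        assert sorted(t.name for t in again.tips()) == sorted(t.name for t in tree.tips())
        d1 = {t.name: t.length for t in tree.tips()}
        d2 = {t.name: t.length for t in again.tips()}
        assert d1 == pytest.approx(d2)
        sup1 = sorted(n.name for n in tree.non_tips() if n.name)
        sup2 = sorted(n.name for n in again.non_tips() if n.name)
        assert sup1 == sup2

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(ValueError, match="[Nn]ewick"):
            read_newick("((A,B")

    def test_dendropy_agrees_on_round_trip(self):
        text = "((A:1.5,B:0.25)80:0.5,(C:2,D:1)60:0.125,E:3);"
        out = write_newick(read_newick(text))
        t = dendropy.Tree.get(data=out, schema="newick")
        assert sorted(l.taxon.label for l in t.leaf_node_iter()) == list("ABCDE")
        assert t.length() == pytest.approx(read_newick(text).descending_branch_length())


class TestDomainTypes:
    def test_gene_model_rejects_bad_coordinates(self):
        with pytest.raises(ValueError):
            GeneModel("g", "l", "A01", "+", 100, 50, 30)

    def test_exon_sum_must_match_cds(self):
        with pytest.raises(ValueError, match="sum"):
            GeneModel("g", "l", "A01", "+", 1, 400, 300, exons=[(1, 100)])

    def test_locus_group_rejects_duplicates_and_bad_labels(self):
        with pytest.raises(ValueError, match="duplicate"):
            LocusGroup("A", "tPCK1", "RefVQ1", members=[("g1", "LF"), ("g1", "MF1")])
        with pytest.raises(ValueError, match="subgenome"):
            LocusGroup("A", "tPCK1", "RefVQ1", members=[("g1", "LF2")])


def test_catalogue_span_never_below_cds(catalogue_genes):
    """Genomic span can only exceed CDS length via introns, never undercut it."""
    assert len(catalogue_genes) == 57
    assert all(g.span >= g.cds_length for g in catalogue_genes)
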