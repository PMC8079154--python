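"""Parsers, writers and the shared data model: validation and round-trips."""

import math

import pytest

from kleptoscreen import core_io
from kleptoscreen.core_io import (DEGRecord, DEGTable, FormatError, GeneCatalog,
                                  GeneModel, Scaffold, ScaffoldSet,
                                  ScreenConfig, TaxonomyTree, ValidationError)
from kleptoscreen.synthetic_data import simulate_taxonomy


BLAST6_ROW = "g1\tsubj1\t85.5\t250\t30\t2\t1\t250\t10\t260\t1e-50\t250\n"


class TestHitTable:
    def test_blast6_row_maps_fields(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(BLAST6_ROW)
        table = core_io.read_hit_table(p, "blast6")
        assert len(table) == 1
        r = table[0]
        assert r.bit_score == 250.0
        assert r.e_value == 1e-50
        assert r.subject_taxon_id == "subj1"  # falls back to subject id
        assert r.query_length is None

    def test_empty_file_gives_empty_table(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("")
        assert len(core_io.read_hit_table(p, "blast6")) == 0

    def test_tiny_evalue_does_not_underflow(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(BLAST6_ROW.replace("1e-50", "1e-180"))
        r = core_io.read_hit_table(p, "blast6")[0]
        # Oracle: decimal string parsing.
        assert r.e_value == float("1e-180") > 0.0

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(BLAST6_ROW + "g2\tonly\tthree\n")
        with pytest.raises(FormatError, match=r":2:"):
            core_io.read_hit_table(p, "blast6")

    def test_unparseable_number_names_line(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(BLAST6_ROW.replace("250\n", "not_a_number\n"))
        with pytest.raises(FormatError, match="bitscore"):
            core_io.read_hit_table(p, "blast6")

    def test_unknown_dialect_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="dialect"):
            core_io.read_hit_table(tmp_path / "x", "blast7")

    def test_qlen_dialect_and_taxid(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(BLAST6_ROW.rstrip("\n") + "\t300\tAplysia\n")
        r = core_io.read_hit_table(p, "blast6+qlen", with_taxid=True)[0]
        assert r.query_length == 300
        assert r.subject_taxon_id == "Aplysia"
        assert r.query_coverage == pytest.approx(250 / 300)

    @pytest.mark.parametrize("dialect", ["blast6", "blast6+qlen", "mmseq2"])
    def test_round_trip_exact(self, tmp_path, dialect, hit_factory):
        recs = [hit_factory(query=f"g{i}", bits=100.0 + i / 7.0,
                            evalue=10.0 ** -(3 * i + 4), qlen=300 + i,
                            raw=(371.0 + i) / 3.0)
                for i in range(5)]
        table = core_io.HitTable(recs)
        p = tmp_path / "out.tsv"
        core_io.write_hit_table(table, p, dialect)
        back = core_io.read_hit_table(p, dialect)
        for a, b in zip(table, back):
            assert a.query_id == b.query_id
            assert a.bit_score == b.bit_score  # repr round-trip, bit exact
            assert a.e_value == b.e_value
            if dialect != "blast6":
                assert a.query_length == b.query_length
            if dialect == "mmseq2":
                assert a.raw_score == b.raw_score

    def test_invalid_record_rejected(self, hit_factory):
        with pytest.raises(ValidationError):
            core_io.HitRecord("g", "s", "t", 50.0, 10, -1.0, 1e-5, 1, 10).validate()
        with pytest.raises(ValidationError):
            core_io.HitRecord("g", "s", "t", 50.0, 10, 5.0, 1e-5, 11, 10).validate()


class TestTaxonomy:
    def test_three_node_chain_depth(self, tmp_path):
        p = tmp_path / "tax.tsv"
        p.write_text(
            "root\t-\troot\tprokaryote\n"
            "A\troot\tA\teukaryote\n"
            "B\tA\tB\talgae\n"
            "C\tA\tC\tlophotrochozoa\n")
        tree = core_io.read_taxonomy(p)
        assert tree.depth("B") == 2
        assert tree.path_to_root("B") == ["B", "A", "root"]

    def test_self_parent_is_cycle_error(self, tmp_path):
        p = tmp_path / "tax.tsv"
        p.write_text("root\t-\troot\t\nA\tA\tA\t\n")
        with pytest.raises(FormatError, match="cycle"):
            core_io.read_taxonomy(p)

    def test_orphan_parent_error(self):
        with pytest.raises(ValidationError, match="orphan"):
            TaxonomyTree({"root": None, "A": "ghost"},
                         groups={g: {"root"} for g in core_io.REQUIRED_GROUPS})

    def test_two_roots_rejected(self):
        with pytest.raises(ValidationError, match="root"):
            TaxonomyTree({"r1": None, "r2": None},
                         groups={g: {"r1"} for g in core_io.REQUIRED_GROUPS})

    def test_algae_lophotrochozoa_overlap_rejected(self):
        parents = {"root": None, "Euk": "root", "X": "Euk"}
        groups = {"prokaryote": {"root"}, "eukaryote": {"Euk"},
                  "algae": {"X"}, "lophotrochozoa": {"X"}}
        with pytest.raises(ValidationError, match="overlap"):
            TaxonomyTree(parents, groups=groups)

    def test_algae_outside_eukaryote_rejected(self):
        parents = {"root": None, "Euk": "root", "Alga": "root", "Loph": "Euk"}
        groups = {"prokaryote": {"root"}, "eukaryote": {"Euk"},
                  "algae": {"Alga"}, "lophotrochozoa": {"Loph"}}
        with pytest.raises(ValidationError, match="algae"):
            TaxonomyTree(parents, groups=groups)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_tree_paths_terminate_at_root(self, seed, tmp_path):
        tree = simulate_taxonomy(n_taxa=50, seed=seed)
        for taxon in tree.parents:
            path = tree.path_to_root(taxon)  # would raise on a cycle
            assert path[-1] == tree.root
        # Round-trip through the TSV format.
        p = tmp_path / "tax.tsv"
        core_io.write_taxonomy(tree, p)
        back = core_io.read_taxonomy(p)
        assert back.parents == tree.parents
        assert back.groups == tree.groups

    def test_lca_and_groups(self, tiny_tree):
        assert tiny_tree.lca(["Chlorella", "Aplysia"]) == "Eukaryota"
        assert tiny_tree.lca(["Aplysia", "Plakobranchus"]) == "Lophotrochozoa"
        assert tiny_tree.in_group("Caulerpa", "algae")
        assert tiny_tree.in_group("Caulerpa", "eukaryote")
        assert not tiny_tree.in_group("Caulerpa", "lophotrochozoa")
        assert tiny_tree.in_group("Ecoli", "prokaryote")


class TestGenesAndScaffolds:
    def test_gff_gene_is_half_open_internally(self, tmp_path):
        p = tmp_path / "genes.gff3"
        p.write_text("##gff-version 3\n"
                     "scaf1\tsrc\tgene\t100\t400\t.\t+\t.\tID=g1\n"
                     "scaf1\tsrc\texon\t100\t200\t.\t+\t.\tID=g1.e1\n")
        cat = core_io.read_gff_genes(p)
        assert len(cat) == 1  # exon row skipped
        g = cat["g1"]
        assert (g.start, g.end) == (99, 400)
        assert g.length == 301  # 1-based inclusive span

    def test_gff_round_trip(self, tmp_path):
        cat = GeneCatalog([GeneModel("g1", "s1", 0, 300, "+"),
                           GeneModel("g2", "s1", 500, 1400, "-")])
        p = tmp_path / "genes.gff3"
        core_io.write_gff_genes(cat, p)
        back = core_io.read_gff_genes(p)
        for gid in ("g1", "g2"):
            assert (back[gid].start, back[gid].end, back[gid].strand) == \
                   (cat[gid].start, cat[gid].end, cat[gid].strand)

    def test_gff_bad_strand_located(self, tmp_path):
        p = tmp_path / "genes.gff3"
        p.write_text("scaf1\tsrc\tgene\t100\t400\t.\t?\t.\tID=g1\n")
        with pytest.raises(FormatError, match=r":1:"):
            core_io.read_gff_genes(p)

    def test_fasta_round_trip_lengths(self, tmp_path):
        p = tmp_path / "asm.fasta"
        p.write_text(">s1 desc\nACGTACGT\n>s2\nACGT\nAC\n")
        scafs = core_io.read_fasta(p)
        assert len(scafs) == 2
        assert scafs["s1"].length == 8
        assert scafs["s2"].length == 6

    def test_gene_off_scaffold_end_rejected(self):
        scafs = ScaffoldSet([Scaffold("s1", 100)])
        cat = GeneCatalog([GeneModel("g1", "s1", 50, 150)])
        with pytest.raises(ValidationError, match="past scaffold end"):
            cat.validate_against(scafs)

    def test_depth_table_round_trip(self, tmp_path):
        depths = {"s1": {"libA": 31.5, "libB": 28.0}, "s2": {"libA": 540.0}}
        p = tmp_path / "depths.tsv"
        core_io.write_depth_table(depths, p)
        assert core_io.read_depth_table(p) == depths

    def test_negative_depth_located(self, tmp_path):
        p = tmp_path / "depths.tsv"
        p.write_text("s1\tlibA\t-3\n")
        with pytest.raises(FormatError, match="negative"):
            core_io.read_depth_table(p)


class TestMatricesAndDegs:
    def test_count_matrix_round_trip(self, tmp_path):
        import pandas as pd
        m = pd.DataFrame([[10, 2, 3], [0, 1, 5]],
                         index=["OG1", "OG2"], columns=["PoB", "sp1", "sp2"])
        p = tmp_path / "counts.tsv"
        core_io.write_count_matrix(m, p)
        back = core_io.read_count_matrix(p)
        assert (back == m).all().all()

    def test_non_integer_cell_rejected(self, tmp_path):
        p = tmp_path / "counts.tsv"
        p.write_text("orthogroup\tPoB\tsp1\nOG1\t1.5\t2\n")
        with pytest.raises(FormatError, match="non-integer"):
            core_io.read_count_matrix(p)

    def test_deg_table_round_trip_and_sets(self, tmp_path):
        table = DEGTable([
            DEGRecord("g1", 2.5, 1e-6, "up"),
            DEGRecord("g2", -1.5, 0.005, "down"),
            DEGRecord("g3", 0.1, 0.8, "ns"),
        ])
        p = tmp_path / "deg.tsv"
        core_io.write_deg_table(table, p)
        back = core_io.read_deg_table(p)
        assert back.up_genes() == {"g1"}
        assert back.down_genes() == {"g2"}

    def test_deg_direction_fdr_invariant(self):
        with pytest.raises(ValidationError, match="FDR"):
            DEGRecord("g1", 2.0, 0.5, "up").validate(fdr_cutoff=0.01)


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = ScreenConfig()
        cfg.lca.top_percent = 10.0
        cfg.hgt_index.threshold = 150.0
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        back = ScreenConfig.from_yaml(p)
        assert back.lca.top_percent == 10.0
        assert back.hgt_index.threshold == 150.0
        assert back.decontam.organelle_min_bitscore == 1000.0

    def test_defaults_are_published_values(self, cfg):
        assert cfg.lca.min_score == 50
        assert cfg.lca.max_expected == 1e-4
        assert cfg.lca.top_percent == 20
        assert cfg.lca.lca_percent == 90
        assert cfg.align_screen.min_query_coverage == 0.60
        assert cfg.align_screen.min_norm_score == 2.0
        assert cfg.hgt_index.threshold == 100
        assert cfg.decontam.min_bacterial_genes == 2
        assert cfg.read_screen.flag_tpm == 100

    def test_invalid_values_rejected(self):
        cfg = ScreenConfig()
        cfg.lca.top_percent = 0.0
        with pytest.raises(ValidationError):
            cfg.validate()
        with pytest.raises(ValidationError, match="unknown"):
            ScreenConfig.from_dict({"lca": {"bogus_option": 1}})
        cfg2 = ScreenConfig()
        cfg2.hgt_index.threshold = math.inf
        with pytest.raises(ValidationError):
            cfg2.validate()
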