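"""LCA assignment: filter rules, oracle equivalence, monotonicity, content counts."""

import random

import pytest

from kleptoscreen.core_io import (UNASSIGNED, GeneCatalog, GeneModel, HitTable,
                                  ScreenConfig, TaxonomyTree)
from kleptoscreen.synthetic_data import simulate_taxonomy
from kleptoscreen.taxonomy_lca import (assign_lca, classify_scaffold_gene_content,
                                       lca_scan, retain_hits)


from _oracles import exhaustive_lca_oracle


class TestRetainHits:
    def test_top_percent_band(self, cfg, hit_factory):
        hits = HitTable([hit_factory(bits=b) for b in (200, 190, 90)])
        kept = retain_hits(hits, cfg)
        assert sorted(r.bit_score for r in kept) == [190, 200]  # cutoff 160

    def test_min_score_boundary(self, cfg, hit_factory):
        hits = HitTable([hit_factory(bits=b) for b in (49.9, 30, 10)])
        assert len(retain_hits(hits, cfg)) == 0
        # exactly 50 is retained (>= Min Score)
        assert len(retain_hits(HitTable([hit_factory(bits=50.0)]), cfg)) == 1

    def test_single_modest_hit_retained(self, cfg, hit_factory):
        hits = HitTable([hit_factory(bits=60.0, evalue=1e-5)])
        assert len(retain_hits(hits, cfg)) == 1

    def test_evalue_filter(self, cfg, hit_factory):
        hits = HitTable([hit_factory(bits=200, evalue=1e-3),
                         hit_factory(bits=80, evalue=1e-9)])
        kept = retain_hits(hits, cfg)
        assert [r.bit_score for r in kept] == [80]

    def test_mixed_queries_rejected(self, cfg, hit_factory):
        hits = HitTable([hit_factory(query="a"), hit_factory(query="b")])
        with pytest.raises(ValueError, match="single query"):
            retain_hits(hits, cfg)

    def test_brute_force_filter_equivalence(self, cfg, hit_factory):
        rng = random.Random(7)
        for _ in range(50):
            hits = HitTable([hit_factory(bits=rng.uniform(10, 400),
                                         evalue=10 ** -rng.uniform(0, 30))
                             for _ in range(rng.randint(1, 20))])
            kept = {id(r) for r in retain_hits(hits, cfg)}
            # Oracle: literal re-statement of the three rules.
            surv = [r for r in hits if r.bit_score >= 50 and r.e_value <= 1e-4]
            if surv:
                best = max(r.bit_score for r in surv)
                oracle = {id(r) for r in surv if r.bit_score >= 0.8 * best}
            else:
                oracle = set()
            assert kept == oracle


class TestAssignLca:
    def test_two_taxa_assigns_their_lca(self, tiny_tree, cfg, hit_factory):
        hits = HitTable([hit_factory(taxon="Aplysia"),
                         hit_factory(taxon="Plakobranchus")])
        a = assign_lca(hits, tiny_tree, cfg)
        assert a.assigned_taxon_id == "Lophotrochozoa"
        assert a.support_fraction == 1.0

    def test_no_retained_hits_unassigned(self, tiny_tree, cfg, hit_factory):
        a = assign_lca(HitTable([hit_factory(bits=20.0)]), tiny_tree, cfg)
        assert a.assigned_taxon_id == UNASSIGNED
        assert a.n_hits_retained == 0

    def test_nine_of_ten_supports_majority_node(self, cfg, hit_factory):
        # Node Y holds 9 distinct species; 1 hit falls elsewhere.  At
        # lca_percent=90 the assignment is Y itself (support 9/10).
        parents = {"root": None, "Bact": "root", "Euk": "root",
                   "Alga": "Euk", "Loph": "Euk", "Y": "Loph"}
        parents.update({f"sp{i}": "Y" for i in range(9)})
        tree = TaxonomyTree(parents, groups={
            "prokaryote": {"Bact"}, "eukaryote": {"Euk"},
            "algae": {"Alga"}, "lophotrochozoa": {"Loph"}})
        hits = [hit_factory(taxon=f"sp{i}", subject=f"s{i}") for i in range(9)]
        hits.append(hit_factory(taxon="Bact", subject="s9"))
        a = assign_lca(HitTable(hits), tree, cfg)
        assert a.assigned_taxon_id == "Y"
        assert a.support_fraction == 0.9

    def test_unknown_taxon_is_error(self, tiny_tree, cfg, hit_factory):
        with pytest.raises(KeyError, match="Martian"):
            assign_lca(HitTable([hit_factory(taxon="Martian")]), tiny_tree, cfg)

    def test_duplicate_taxon_counts_once(self, tiny_tree, cfg, hit_factory):
        # 9 hits to one taxon + 1 to a distant one: per-taxon weighting
        # means support is 1/2 each, so the assignment is their LCA.
        hits = [hit_factory(taxon="Aplysia", subject=f"s{i}") for i in range(9)]
        hits.append(hit_factory(taxon="Ecoli", subject="s9"))
        a = assign_lca(HitTable(hits), tiny_tree, cfg)
        assert a.assigned_taxon_id == "root"

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_scan_on_random_instances(self, seed, cfg, hit_factory):
        """Oracle equivalence on random (tree, hit set) instances."""
        rng = random.Random(seed)
        tree = simulate_taxonomy(n_taxa=rng.randint(8, 60), seed=seed)
        taxa_pool = list(tree.parents)
        for _ in range(20):
            chosen = rng.sample(taxa_pool, rng.randint(1, min(40, len(taxa_pool))))
            hits = HitTable([hit_factory(taxon=t, subject=f"s{i}", bits=200.0)
                             for i, t in enumerate(chosen)])
            a = assign_lca(hits, tree, cfg)
            assert a.assigned_taxon_id == exhaustive_lca_oracle(
                tree, chosen, cfg.lca.lca_percent)

    def test_raising_lca_percent_never_deepens(self, cfg, hit_factory):
        rng = random.Random(11)
        tree = simulate_taxonomy(n_taxa=40, seed=11)
        taxa_pool = list(tree.parents)
        for _ in range(20):
            chosen = rng.sample(taxa_pool, rng.randint(2, 20))
            hits = HitTable([hit_factory(taxon=t, subject=f"s{i}")
                             for i, t in enumerate(chosen)])
            prev = None
            for pct in (50, 70, 90, 100):
                cfg.lca.lca_percent = pct
                node = assign_lca(hits, tree, cfg).assigned_taxon_id
                if prev is not None:
                    assert tree.is_ancestor_or_self(node, prev)
                prev = node
        cfg.lca.lca_percent = 90

    def test_hit_order_independence(self, cfg, hit_factory):
        rng = random.Random(5)
        tree = simulate_taxonomy(n_taxa=30, seed=5)
        taxa = rng.sample(list(tree.parents), 12)
        hits = [hit_factory(taxon=t, subject=f"s{i}") for i, t in enumerate(taxa)]
        base = assign_lca(HitTable(hits), tree, cfg).assigned_taxon_id
        for _ in range(5):
            rng.shuffle(hits)
            assert assign_lca(HitTable(hits), tree, cfg).assigned_taxon_id == base


class TestLcaScan:
    def test_hitless_genes_reported_unassigned(self, tiny_tree, cfg, hit_factory):
        hits = HitTable([hit_factory(query="g1", taxon="Aplysia")])
        out = lca_scan(hits, tiny_tree, cfg, gene_ids=["g1", "g2"])
        assert out["g2"].assigned_taxon_id == UNASSIGNED
        assert out["g1"].assigned_taxon_id == "Aplysia"

    def test_min_support_percent_pushes_up(self, tiny_tree, hit_factory):
        """A taxon holding under the support floor moves genes to an ancestor."""
        cfg = ScreenConfig()
        cfg.lca.min_support_percent = 30.0  # floor = 1.5 genes of 5
        hits = []
        for i in range(4):
            hits.append(hit_factory(query=f"g{i}", taxon="Aplysia"))
        hits.append(hit_factory(query="g4", taxon="Chlorella"))
        out = lca_scan(HitTable(hits), tiny_tree, cfg)
        # Chlorella holds 1 < 1.5 genes: pushed to an ancestor, not dropped.
        node = out["g4"].assigned_taxon_id
        assert node != "Chlorella" and node != UNASSIGNED
        assert tiny_tree.is_ancestor_or_self(node, "Chlorella")
        assert out["g0"].assigned_taxon_id == "Aplysia"

    def test_low_complexity_mask_skips_gene(self, tiny_tree, cfg, hit_factory):
        hits = HitTable([hit_factory(query="g1", taxon="Aplysia")])
        out = lca_scan(hits, tiny_tree, cfg, low_complexity={"g1": True})
        assert out["g1"].assigned_taxon_id == UNASSIGNED


class TestScaffoldGeneContent:
    def _assignments(self, mapping, cfg, tiny_tree, hit_factory):
        hits = HitTable([hit_factory(query=g, taxon=t) for g, t in mapping.items()])
        return lca_scan(hits, tiny_tree, cfg)

    def test_counts_mixed_scaffold(self, tiny_tree, cfg, hit_factory):
        cat = GeneCatalog([GeneModel(g, "s1", i * 1000, i * 1000 + 300)
                           for i, g in enumerate(["g1", "g2", "g3"])])
        assigns = self._assignments(
            {"g1": "Ecoli", "g2": "Bsubtilis", "g3": "Aplysia"},
            cfg, tiny_tree, hit_factory)
        counts = classify_scaffold_gene_content(assigns, cat, tiny_tree)
        assert counts["s1"].as_tuple() == (2, 1, 0)

    def test_all_unassigned_counts_nothing(self, tiny_tree, cfg):
        cat = GeneCatalog([GeneModel("g1", "s1", 0, 300)])
        counts = classify_scaffold_gene_content({}, cat, tiny_tree)
        assert counts["s1"].as_tuple() == (0, 0, 0)

    def test_counts_match_membership_recount(self, cfg, hit_factory):
        """20-gene scaffold: counts equal a per-gene set-membership recount."""
        rng = random.Random(9)
        tree = simulate_taxonomy(n_taxa=30, seed=9)
        leaves = [t for t in tree.parents if not tree.children(t)]
        mapping = {f"g{i}": rng.choice(leaves) for i in range(20)}
        cat = GeneCatalog([GeneModel(g, "s1", i * 1000, i * 1000 + 300)
                           for i, g in enumerate(mapping)])
        cfg2 = ScreenConfig()
        cfg2.lca.min_support_percent = 0.0  # direct leaf assignments
        assigns = self._assignments(mapping, cfg2, tree, hit_factory)
        counts = classify_scaffold_gene_content(assigns, cat, tree)
        bact = tree.group_taxa("bacteria")
        loph = tree.group_taxa("lophotrochozoa")
        exp_b = sum(1 for t in mapping.values() if t in bact)
        exp_l = sum(1 for t in mapping.values() if t in loph)
        assert counts["s1"].n_bacterial == exp_b
        assert counts["s1"].n_lophotrochozoan == exp_l
        assert sum(counts["s1"].as_tuple()) == 20
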