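"""Taxonomy tree, LCA and taxon-assignment strategies."""

import numpy as np
import pytest

from virofit.config import PipelineConfig
from virofit.errors import FormatError, StructureError
from virofit.hits import HitRecord
from virofit.taxonomy import (
    UNASSIGNED,
    HostGroupMap,
    TaxonomyNode,
    TaxonomyTree,
    assign_taxon,
    load_taxonomy,
)

from _oracles import brute_force_lca


def _hit(taxid, bitscore, evalue=1e-20, qid="q1"):
    return HitRecord(qid, 1000, f"s{taxid}", taxid, 90.0, 500, 10, 1,
                     1, 500, 1, 500, evalue, bitscore)


class TestLoadTaxonomy:
    def test_minimal_three_node_tree(self, tmp_path):
        p = tmp_path / "tax.tsv"
        p.write_text(
            "tax_id\tparent_id\trank\tname\n"
            "1\t1\troot\troot\n2\t1\tspecies\ta\n3\t1\tspecies\tb\n"
        )
        tree = load_taxonomy(p)
        assert len(tree) == 3 and tree.root == 1

    def test_absent_parent_is_structure_error(self, tmp_path):
        p = tmp_path / "tax.tsv"
        p.write_text(
            "tax_id\tparent_id\trank\tname\n1\t1\troot\troot\n2\t99\tspecies\ta\n"
        )
        with pytest.raises(StructureError):
            load_taxonomy(p)

    def test_duplicate_tax_id_is_format_error(self, tmp_path):
        p = tmp_path / "tax.tsv"
        p.write_text(
            "tax_id\tparent_id\trank\tname\n"
            "1\t1\troot\troot\n2\t1\tspecies\ta\n2\t1\tspecies\tb\n"
        )
        with pytest.raises(FormatError):
            load_taxonomy(p)

    def test_cycle_detected(self):
        with pytest.raises(StructureError):
            TaxonomyTree(
                [
                    TaxonomyNode(1, 1, "root", "root"),
                    TaxonomyNode(2, 3, "no_rank", "a"),
                    TaxonomyNode(3, 2, "no_rank", "b"),
                ]
            )

    def test_leaf_depths_by_parent_walk(self, seven_node_tree):
        for leaf in (11, 12, 21, 22):
            walked = 0
            t = leaf
            while t != seven_node_tree.root:
                t = seven_node_tree.parent(t)
                walked += 1
            assert walked == 2 == seven_node_tree.depth(leaf)

    def test_round_trip(self, seven_node_tree, tmp_path):
        p = tmp_path / "t.tsv"
        seven_node_tree.write(p)
        again = load_taxonomy(p)
        assert again.nodes == seven_node_tree.nodes


class TestLCA:
    def test_singleton(self, seven_node_tree):
        assert seven_node_tree.lca({11}) == 11

    def test_siblings_collapse_to_parent(self, seven_node_tree):
        assert seven_node_tree.lca({11, 12}) == 10
        assert seven_node_tree.lca({11, 21}) == 1

    def test_empty_set_rejected(self, seven_node_tree):
        with pytest.raises(ValueError):
            seven_node_tree.lca(set())

    def test_unknown_taxon_rejected(self, seven_node_tree):
        with pytest.raises(KeyError):
            seven_node_tree.lca({11, 999})

    def test_matches_brute_force_on_random_trees(self):
        from conftest import random_tree

        rng = np.random.default_rng(123)
        for _ in range(20):
            tree = random_tree(rng, 50)
            parent = {t: n.parent_id for t, n in tree.nodes.items()}
            for _ in range(10):
                taxa = set(rng.choice(range(1, 51), size=5, replace=False).tolist())
                assert tree.lca(taxa) == brute_force_lca(parent, taxa)

    def test_idempotent_and_order_invariant(self):
        from conftest import random_tree

        rng = np.random.default_rng(7)
        tree = random_tree(rng, 40)
        taxa = {5, 17, 33}
        anc = tree.lca(taxa)
        assert tree.lca({anc}) == anc
        assert tree.lca(set(reversed(sorted(taxa)))) == anc
        # result is ancestor-or-self of every input
        for t in taxa:
            assert anc in tree.path_to_root(t)


class TestAssignTaxon:
    def test_single_hit_both_modes(self, seven_node_tree):
        hits = [_hit(11, 100.0)]
        for mode in ("best_hit", "lca"):
            assert assign_taxon(hits, seven_node_tree, mode) == 11

    def test_equal_score_siblings_lca_gives_genus(self, seven_node_tree):
        hits = [_hit(11, 100.0), _hit(12, 100.0)]
        assert assign_taxon(hits, seven_node_tree, "lca") == 10

    def test_empty_hits_give_unassigned(self, seven_node_tree):
        assert assign_taxon([], seven_node_tree) == UNASSIGNED

    def test_best_hit_tie_breaks(self, seven_node_tree):
        hits = [_hit(21, 100.0, evalue=1e-30), _hit(12, 100.0, evalue=1e-40)]
        assert assign_taxon(hits, seven_node_tree, "best_hit") == 12
        hits = [_hit(21, 100.0), _hit(12, 100.0)]
        assert assign_taxon(hits, seven_node_tree, "best_hit") == 12

    def test_window_filters_then_lca(self, seven_node_tree):
        rng = np.random.default_rng(5)
        taxa_pool = [11, 12, 21, 22]
        cfg = PipelineConfig(lca_score_window=0.10)
        for _ in range(25):
            hits = [
                _hit(int(rng.choice(taxa_pool)), float(rng.uniform(50, 150)))
                for _ in range(10)
            ]
            top = max(h.bitscore for h in hits)
            expect_taxa = {
                h.subject_taxid for h in hits if h.bitscore >= 0.9 * top
            }
            parent = {
                t: n.parent_id for t, n in seven_node_tree.nodes.items()
            }
            expected = brute_force_lca(parent, expect_taxa)
            assert assign_taxon(hits, seven_node_tree, "lca", cfg) == expected

    def test_zero_window_equals_best_hit_when_top_unique(self, seven_node_tree):
        cfg = PipelineConfig(lca_score_window=0.0)
        hits = [_hit(11, 120.0), _hit(21, 100.0), _hit(22, 90.0)]
        assert assign_taxon(hits, seven_node_tree, "lca", cfg) == assign_taxon(
            hits, seven_node_tree, "best_hit"
        )


class TestHostGroupMap:
    def test_unmapped_resolves_to_unassigned(self):
        m = HostGroupMap({5: "mosquito"})
        assert m.group(5) == "mosquito"
        assert m.group(6) == "unassigned"

    def test_unknown_label_rejected(self):
        with pytest.raises(FormatError):
            HostGroupMap({5: "dragon"})

    def test_round_trip(self, tmp_path):
        m = HostGroupMap({5: "mosquito", 7: "bat"})
        p = tmp_path / "hg.tsv"
        m.write(p)
        assert HostGroupMap.load(p).entries == m.entries
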