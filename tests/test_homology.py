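"""Orthologue/paralogue classification and synteny QC."""

import numpy as np
import pandas as pd
import pytest

from ncrphylo.homology import (
    CLASS_MANY2MANY,
    CLASS_ONE2MANY,
    CLASS_ONE2ONE,
    CLASS_WITHIN_PARALOG,
    HomologyPair,
    homology_table,
    infer_homologies,
    pair_counts,
    synteny_support,
)
from ncrphylo.reconciliation import annotate_tree, reconcile
from ncrphylo.synthetic import SimulationConfig, simulate_synteny_fixture


def _annotated(make_gene_tree, species, newick, dcs_threshold=0.25):
    tree = make_gene_tree(newick)
    recon = reconcile(tree, species)
    annotate_tree(tree, recon, dcs_threshold=dcs_threshold)
    return tree


def _classes(pairs):
    return {frozenset((p.gene1, p.gene2)): p.cls for p in pairs}


class TestInferHomologies:
    def test_simple_one2one(self, species2, make_gene_tree):
        tree = _annotated(make_gene_tree, species2, "(a1_A,b1_B);")
        pairs = infer_homologies(tree)
        assert _classes(pairs) == {frozenset({"a1_A", "b1_B"}): CLASS_ONE2ONE}

    def test_one2many_and_within_paralog(self, species2, make_gene_tree):
        tree = _annotated(make_gene_tree, species2, "(a1_A,(b1_B,b2_B));")
        cls = _classes(infer_homologies(tree))
        assert cls[frozenset({"a1_A", "b1_B"})] == CLASS_ONE2MANY
        assert cls[frozenset({"a1_A", "b2_B"})] == CLASS_ONE2MANY
        assert cls[frozenset({"b1_B", "b2_B"})] == CLASS_WITHIN_PARALOG

    def test_confident_root_duplication_blocks_cross_pairs(
        self, species2, make_gene_tree
    ):
        tree = _annotated(
            make_gene_tree, species2, "((a1_A,b1_B),(a2_A,b2_B));"
        )
        assert tree.root.dcs == 1.0
        cls = _classes(infer_homologies(tree))
        assert cls[frozenset({"a1_A", "b1_B"})] == CLASS_ONE2ONE
        assert cls[frozenset({"a2_A", "b2_B"})] == CLASS_ONE2ONE
        assert cls[frozenset({"a1_A", "a2_A"})] == CLASS_WITHIN_PARALOG
        assert cls[frozenset({"b1_B", "b2_B"})] == CLASS_WITHIN_PARALOG
        assert frozenset({"a1_A", "b2_B"}) not in cls

    def test_dubious_duplication_rescue(self, species5, make_gene_tree):
        # duplication above (A,B) with one side missing its B copy: the
        # dubious node (DCS < 0.25 is impossible with 2 species, so force it)
        tree = make_gene_tree("((a1_A,b1_B),a2_A);")
        recon = reconcile(tree, species5)
        annotate_tree(tree, recon)
        tree.root.dcs = 0.2  # ill-supported duplication
        pairs = infer_homologies(tree, dcs_threshold=0.25)
        cls = _classes(pairs)
        # a2 has no speciation partner in B; b1's only speciation partner is a1
        # (species A) so it has none in... A? it does (a1). Two-sided rule:
        # rescue requires BOTH free; b1 already matches species A via a1.
        assert frozenset({"a2_A", "b1_B"}) not in cls

    def test_rescue_when_both_sides_free(self, species5, make_gene_tree):
        # root duplication over disjoint copies: a1 pairs C-gene, a2 alone
        tree = make_gene_tree("((a1_A,c1_C),a2_A);")
        recon = reconcile(tree, species5)
        annotate_tree(tree, recon)
        tree.root.dcs = 0.0
        cls = _classes(infer_homologies(tree, dcs_threshold=0.25))
        # a2_A and c1_C: a2 has no speciation partner in C, c1 has one in A
        assert frozenset({"a2_A", "c1_C"}) not in cls
        # but with threshold 0 the rescue is off and nothing changes
        cls0 = _classes(infer_homologies(tree, dcs_threshold=0.0))
        assert frozenset({"a2_A", "c1_C"}) not in cls0

    def test_rescue_accepts_isolated_pairs(self, species5, make_gene_tree):
        # both genes lack speciation partners in the other species
        tree = make_gene_tree("(a1_A,b1_B)[&&NHX:D=Y:DCS=0.1];")
        pairs = infer_homologies(tree, dcs_threshold=0.25)
        cls = _classes(pairs)
        assert cls[frozenset({"a1_A", "b1_B"})] == CLASS_ONE2ONE

    def test_unreconciled_tree_errors(self, make_gene_tree):
        tree = make_gene_tree("((a1_A,b1_B),c1_C);")
        with pytest.raises(ValueError, match="reconciled"):
            infer_homologies(tree)

    def test_rescue_never_increases_with_threshold_zero(
        self, species12, config, rng
    ):
        """Disabling the dubious rescue never yields more orthologues."""
        from ncrphylo.synthetic import simulate_gene_tree

        for _ in range(20):
            tree, _ = simulate_gene_tree(species12, config, rng=rng)
            recon = reconcile(tree, species12)
            annotate_tree(tree, recon)
            with_rescue = [
                p
                for p in infer_homologies(tree, dcs_threshold=0.25)
                if p.cls != CLASS_WITHIN_PARALOG
            ]
            without = [
                p
                for p in infer_homologies(tree, dcs_threshold=0.0)
                if p.cls != CLASS_WITHIN_PARALOG
            ]
            assert len(without) <= len(with_rescue)

    def test_one2one_is_a_matching(self, species12, config, rng):
        """No gene appears in two one2one pairs with the same partner species."""
        from ncrphylo.synthetic import simulate_gene_tree

        for _ in range(20):
            tree, _ = simulate_gene_tree(species12, config, rng=rng)
            recon = reconcile(tree, species12)
            annotate_tree(tree, recon)
            seen = set()
            for p in infer_homologies(tree):
                if p.cls != CLASS_ONE2ONE:
                    continue
                k1 = (p.gene1, p.species2)
                k2 = (p.gene2, p.species1)
                assert k1 not in seen and k2 not in seen
                seen.add(k1)
                seen.add(k2)


class TestTables:
    def test_unanimity_counts(self, species5, make_gene_tree):
        tree = _annotated(make_gene_tree, species5, "((a1_A,b1_B),c1_C);")
        counts = pair_counts(infer_homologies(tree))
        assert counts["n_pairs"].sum() == 3
        assert set(counts["class"]) == {CLASS_ONE2ONE}

    def test_empty_listing_keeps_header(self):
        table = homology_table([])
        assert list(table.columns)[:4] == ["gene1", "species1", "gene2", "species2"]
        assert len(table) == 0


class TestSynteny:
    def test_planted_fraction_recovered(self, config):
        ann, prot, nc = simulate_synteny_fixture(20, 0.75, config)
        _flags, summary = synteny_support(nc, ann, prot, window=5000)
        total_supported = summary.intronic_supported + summary.window_supported
        assert total_supported == 15
        assert summary.intronic_fraction == 1.0
        assert summary.window_fraction == pytest.approx(
            summary.window_supported / summary.window_total
        )

    @pytest.mark.parametrize("fraction,expected", [(1.0, 20), (0.0, 0)])
    def test_extreme_fractions(self, config, fraction, expected):
        ann, prot, nc = simulate_synteny_fixture(20, fraction, config)
        _flags, summary = synteny_support(nc, ann, prot)
        assert summary.intronic_supported + summary.window_supported == expected

    def test_window_boundary_exclusive_beyond_5000(self, config):
        """A protein pair at exactly 5000 bp supports; at 5001 bp it does not."""
        ann = {
            "human": pd.DataFrame(
                [
                    ("p1_h", "protein_coding", "chr1", 1, 1000, "+", None),
                    ("n1_h", "ncRNA", "chr1", 6001, 6100, "+", None),
                ],
                columns=["gene_id", "type", "chromosome", "start", "end", "strand", "host_gene"],
            ),
            "mouse": pd.DataFrame(
                [
                    ("p1_m", "protein_coding", "chr1", 1, 1000, "+", None),
                    ("n1_m", "ncRNA", "chr1", 6002, 6100, "+", None),
                ],
                columns=["gene_id", "type", "chromosome", "start", "end", "strand", "host_gene"],
            ),
        }
        prot = [
            HomologyPair("p1_h", "p1_m", "human", "mouse", CLASS_ONE2ONE, 0, "speciation")
        ]
        nc = [
            HomologyPair("n1_h", "n1_m", "human", "mouse", CLASS_ONE2ONE, 0, "speciation")
        ]
        _f, at_5001 = synteny_support(nc, ann, prot, window=5000)
        assert at_5001.window_supported == 0  # mouse gap is 5001
        ann["mouse"].loc[1, "start"] = 6001  # gap exactly 5000
        _f, at_5000 = synteny_support(nc, ann, prot, window=5000)
        assert at_5000.window_supported == 1

    def test_intronic_requires_same_class_hosts(self, config):
        ann, prot, nc = simulate_synteny_fixture(4, 1.0, config)
        # downgrade the protein pair class of the first (intronic) pair
        prot_mut = [
            HomologyPair(
                p.gene1, p.gene2, p.species1, p.species2,
                CLASS_MANY2MANY if i == 0 else p.cls, p.node_id, p.node_event,
            )
            for i, p in enumerate(prot)
        ]
        _f, summary = synteny_support(nc, ann, prot_mut)
        assert summary.intronic_supported == summary.intronic_total - 1

    def test_missing_coordinates_skipped(self, config):
        ann, prot, nc = simulate_synteny_fixture(3, 1.0, config)
        extra = HomologyPair(
            "ghost_h", "ghost_m", "human", "mouse", CLASS_ONE2ONE, 0, "speciation"
        )
        _f, summary = synteny_support(list(nc) + [extra], ann, prot)
        assert summary.skipped == 1
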