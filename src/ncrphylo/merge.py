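"""Multi-tree merging against a species tree (the *mmerge* strategy).

Given several rooted gene trees over the same gene set, a single binary tree
is assembled top-down.  At each recursion over a gene set G the candidate
splits are the bipartitions of G induced by the root of each input tree
restricted to G (every child-versus-rest split when the restricted root is
multifurcating).  Candidates are ranked by

    1. speciation preferred over duplication,
    2. fewer losses on the two branches leaving the split,
    3. larger maximum bootstrap among the supporting input nodes,
    4. lexicographically smallest gene list on the smaller side (determinism).

The identifiers of the input trees inducing the winning split are recorded on
the two branches it creates (``supporters``), which drives the
branch-support summary.
Because only splits present in the inputs are considered, the search is
linear in the total input size at each level.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Optional, Sequence

import pandas as pd

from .tree import (
    EVENT_DUPLICATION,
    EVENT_SPECIATION,
    Bipartition,
    GeneTree,
    SpeciesTree,
    TreeNode,
    restrict,
)

__all__ = ["CandidateSplit", "mmerge", "branch_support_summary", "model_overlap_table"]


@dataclass
class CandidateSplit:
    bipartition: Bipartition
    supporters: set[str]
    max_bootstrap: int
    event: str
    losses: int

    def rank_key(self) -> tuple:
        # smaller key wins
        return (
            0 if self.event == EVENT_SPECIATION else 1,
            self.losses,
            -self.max_bootstrap,
            self.bipartition.sort_key(),
        )


def _species_lca(species_tree: SpeciesTree, genes: Sequence[TreeNode]) -> TreeNode:
    cur = species_tree.leaf(genes[0].species_id)
    for g in genes[1:]:
        cur = species_tree.lca(cur, species_tree.leaf(g.species_id))
    return cur


def _split_event_losses(
    species_tree: SpeciesTree,
    side_a: Sequence[TreeNode],
    side_b: Sequence[TreeNode],
) -> tuple[str, int]:
    """Event label and the loss count on the two branches of a candidate split."""
    from .reconciliation import is_duplication

    ma = _species_lca(species_tree, side_a)
    mb = _species_lca(species_tree, side_b)
    m = species_tree.lca(ma, mb)
    sets = [
        frozenset(g.species_id for g in side_a),
        frozenset(g.species_id for g in side_b),
    ]
    dup = is_duplication(species_tree, m, sets)
    event = EVENT_DUPLICATION if dup else EVENT_SPECIATION
    losses = 0
    for mc in (ma, mb):
        if mc is m:
            continue
        d = species_tree.path_down_length(m, mc)
        losses += max(0, d - 1 + (1 if dup else 0))
    return event, losses


def _root_split_candidates(
    restricted: GeneTree, label: str
) -> list[tuple[Bipartition, int]]:
    """Bipartitions induced by the restricted root, with their bootstrap."""
    root = restricted.root
    if root.is_leaf or len(root.children) < 2:
        return []
    all_genes = frozenset(restricted.gene_ids())
    out = []
    if len(root.children) == 2:
        left = frozenset(leaf.gene_id for leaf in root.children[0].leaves())
        boot = max(
            (c.bootstrap for c in root.children if c.bootstrap is not None),
            default=0,
        )
        out.append((Bipartition(left, all_genes - left), boot))
    else:
        for child in root.children:
            below = frozenset(leaf.gene_id for leaf in child.leaves())
            boot = child.bootstrap if child.bootstrap is not None else 0
            out.append((Bipartition(below, all_genes - below), boot))
    return out


def mmerge(
    input_trees: Sequence[tuple[str, GeneTree]],
    species_tree: SpeciesTree,
) -> GeneTree:
    """Merge rooted input trees over identical gene sets into one binary tree.

    ``input_trees`` is a sequence of (label, tree) pairs; inputs are expected
    to be rooted already (typically by duplication-loss rooting).
    """
    if not input_trees:
        raise ValueError("at least one input tree required")
    gene_sets = [frozenset(t.gene_ids()) for _, t in input_trees]
    if len(set(gene_sets)) != 1:
        raise ValueError("input trees must share the same gene set")
    genes = gene_sets[0]
    species_tree.prepare()

    leaf_species = {}
    leaf_lengths: dict[str, list[float]] = {g: [] for g in genes}
    for _, t in input_trees:
        for leaf in t.leaves():
            leaf_species[leaf.gene_id] = leaf.species_id
            leaf_lengths[leaf.gene_id].append(leaf.length)

    def leaves_of(side: frozenset) -> list[TreeNode]:
        out = []
        for g in sorted(side):
            n = TreeNode(label=g, gene_id=g, species_id=leaf_species[g])
            out.append(n)
        return out

    def branch_length_of(side: frozenset) -> float:
        """Median length, across inputs, of the edge inducing this clade.

        Approximate convenience only: the merged topology is the product of
        this module; lengths are normally recomputed downstream.
        """
        vals = []
        for _, t in input_trees:
            for node in t.postorder():
                if node.parent is None:
                    continue
                below = frozenset(leaf.gene_id for leaf in node.leaves())
                if below == side:
                    vals.append(node.length)
                    break
        return float(median(vals)) if vals else 0.0

    def build(current: frozenset) -> TreeNode:
        if len(current) == 1:
            (g,) = current
            node = TreeNode(label=g, gene_id=g, species_id=leaf_species[g])
            node.length = float(median(leaf_lengths[g]))
            return node
        # gather candidates from all inputs restricted to the current set
        by_bip: dict[Bipartition, CandidateSplit] = {}
        for label, t in input_trees:
            restricted = restrict(t, current)
            for bip, boot in _root_split_candidates(restricted, label):
                if bip in by_bip:
                    cand = by_bip[bip]
                    cand.supporters.add(label)
                    cand.max_bootstrap = max(cand.max_bootstrap, boot)
                else:
                    a, b = bip.sides
                    event, losses = _split_event_losses(
                        species_tree, leaves_of(a), leaves_of(b)
                    )
                    by_bip[bip] = CandidateSplit(bip, {label}, boot, event, losses)
        best = min(by_bip.values(), key=CandidateSplit.rank_key)
        a, b = best.bipartition.sides
        node = TreeNode()
        node.event = best.event
        for side in (a, b):
            child = build(frozenset(side))
            if len(side) > 1:
                child.length = branch_length_of(frozenset(side))
                child.bootstrap = best.max_bootstrap
            # supporters annotate the branches the split creates
            child.supporters = sorted(best.supporters)
            node.add_child(child)
        return node

    root = build(genes)
    root.length = 0.0
    return GeneTree(root)


def branch_support_summary(
    final_trees: Sequence[tuple[object, GeneTree, Sequence[str]]],
) -> pd.DataFrame:
    """Per-input-tree branch support fractions across merged trees.

    ``final_trees`` holds (family_id, merged tree, labels of the inputs that
    were available for that family).  For every input label the fraction of
    final internal branches it supports — and supports uniquely — is computed
    over all families where that input appears.
    """
    supported: dict[str, int] = {}
    unique: dict[str, int] = {}
    branches_seen: dict[str, int] = {}
    for _family, tree, labels in final_trees:
        internal = [
            n for n in tree.postorder() if not n.is_leaf and n.supporters
        ]
        for label in labels:
            branches_seen[label] = branches_seen.get(label, 0) + len(internal)
            supported.setdefault(label, 0)
            unique.setdefault(label, 0)
        for node in internal:
            for label in node.supporters:
                supported[label] = supported.get(label, 0) + 1
            if len(node.supporters) == 1:
                only = node.supporters[0]
                unique[only] = unique.get(only, 0) + 1
    rows = []
    for label in sorted(branches_seen):
        total = branches_seen[label]
        rows.append(
            {
                "tree_label": label,
                "branches_considered": total,
                "supported": supported[label],
                "unique": unique[label],
                "support_fraction": supported[label] / total if total else 0.0,
                "unique_fraction": unique[label] / total if total else 0.0,
            }
        )
    return pd.DataFrame(rows)


def model_overlap_table(
    final_trees: Sequence[tuple[object, GeneTree, Sequence[str]]],
) -> pd.DataFrame:
    """Pairwise overlap of branch support between input-tree labels.

    For two labels the overlap is |branches supported by both| / |branches
    supported by either|, pooled over all final trees.
    """
    sets: dict[str, set[tuple]] = {}
    for family, tree, _labels in final_trees:
        for i, node in enumerate(tree.postorder()):
            if node.is_leaf or not node.supporters:
                continue
            key = (family, i)
            for label in node.supporters:
                sets.setdefault(label, set()).add(key)
    labels = sorted(sets)
    data = []
    for a in labels:
        row = {}
        for b in labels:
            union = sets[a] | sets[b]
            row[b] = len(sets[a] & sets[b]) / len(union) if union else 0.0
        data.append(row)
    return pd.DataFrame(data, index=labels)
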