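"""K tree-score comparison and ranking of trees against a reference.

The K score measures the joint branch-length and topology distance between
two trees over the same leaves: the comparison tree is rescaled by the factor
K that minimises the summed squared branch-length differences over matched
bipartitions (branches present in only one tree pair with length 0), and the
score is the root of the residual sum of squares,

    K = sum(b_ref * b_comp) / sum(b_comp^2),
    score = sqrt( sum( (K * b_comp - b_ref)^2 ) ).

Identical trees give K = 1 and score 0; a copy with all lengths scaled by c
gives K = 1/c and score 0.  Trees are compared on their unrooted bipartition
sets (including the terminal branches).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import math

import pandas as pd

from .tree import GeneTree, SpeciesTree, unrooted_splits
from .reconciliation import root_by_dl

__all__ = ["TreeComparison", "k_score", "rank_trees"]


@dataclass
class TreeComparison:
    k_factor: float
    k_score: float
    n_matched: int
    n_unmatched_ref: int
    n_unmatched_comp: int


def k_score(reference: GeneTree, comparison: GeneTree) -> TreeComparison:
    """Minimum branch-length distance after optimal rescaling of ``comparison``."""
    ref_leaves = frozenset(reference.gene_ids())
    comp_leaves = frozenset(comparison.gene_ids())
    if ref_leaves != comp_leaves:
        raise ValueError("trees must share the same leaf set")

    ref = unrooted_splits(reference, include_trivial=True)
    comp = unrooted_splits(comparison, include_trivial=True)
    keys = set(ref) | set(comp)
    num = 0.0
    den = 0.0
    for bp in keys:
        br = ref.get(bp, 0.0)
        bc = comp.get(bp, 0.0)
        num += br * bc
        den += bc * bc
    if den == 0.0:
        raise ValueError("comparison tree has no branch lengths; K undefined")
    k = num / den
    ss = 0.0
    for bp in keys:
        br = ref.get(bp, 0.0)
        bc = comp.get(bp, 0.0)
        ss += (k * bc - br) ** 2
    matched = sum(1 for bp in keys if bp in ref and bp in comp)
    return TreeComparison(
        k_factor=k,
        k_score=math.sqrt(ss),
        n_matched=matched,
        n_unmatched_ref=len(ref) - matched,
        n_unmatched_comp=len(comp) - matched,
    )


def rank_trees(
    final: GeneTree,
    inputs: Sequence[tuple[str, GeneTree]],
    species_tree: Optional[SpeciesTree] = None,
    family_id: Optional[str] = None,
) -> pd.DataFrame:
    """Rank input trees by similarity (ascending K score) to the final tree.

    When a species tree is given, inputs are first re-rooted by
    duplication-loss parsimony so the comparison does not depend on arbitrary
    input rootings.  Ties keep the label order stable.
    """
    rows = []
    for label, tree in inputs:
        t = root_by_dl(tree, species_tree) if species_tree is not None else tree
        cmp = k_score(final, t)
        rows.append(
            {
                "family_id": family_id,
                "tree_label": label,
                "k_factor": cmp.k_factor,
                "k_score": cmp.k_score,
            }
        )
    rows.sort(key=lambda r: (r["k_score"], r["tree_label"]))
    for i, r in enumerate(rows, start=1):
        r["rank"] = i
    return pd.DataFrame(rows, columns=["family_id", "tree_label", "k_factor", "k_score", "rank"])
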