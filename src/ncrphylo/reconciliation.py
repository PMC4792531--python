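"""Gene-tree / species-tree reconciliation by LCA mapping.

Each gene-tree node is mapped to the most recent species-tree node containing
all its descendant species.  An internal node is a *duplication* when the
split below it does not separate species lineages: two of its children draw
on a common child lineage of the mapped species node (on a binary species
tree this is the classical "mapping equals a child's mapping" criterion;
multifurcations are treated as soft polytomies so that a resolvable split is
still a speciation).  Losses are counted per gene-tree
edge from the number of species-tree levels skipped between the two mappings:

    losses(u -> v) = pathlen(m(u), m(v)) - 1 + [u is duplication and m(v) != m(u)]

with losses = 0 when m(u) = m(v).  ``pathlen`` is the number of species-tree
edges from m(u) down to m(v); a multifurcating (flattened) species node counts
as a single level, so descending through it never charges the uninvolved
sister lineages as losses.

Duplication-loss rooting places the root on the edge of the unrooted topology
that minimises total duplications + losses; only the topology is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .tree import (
    EVENT_DUBIOUS,
    EVENT_DUPLICATION,
    EVENT_SPECIATION,
    GeneTree,
    SpeciesTree,
    TreeNode,
    reroot_above,
)

__all__ = [
    "Reconciliation",
    "reconcile",
    "count_losses",
    "root_by_dl",
    "duplication_confidence",
    "annotate_tree",
    "simplify_species_tree",
    "event_table",
]


@dataclass
class Reconciliation:
    """LCA mapping, event labels and per-edge loss counts for one gene tree."""

    gene_tree: GeneTree
    species_tree: SpeciesTree
    mapping: dict[int, TreeNode]  # id(gene node) -> species node
    events: dict[int, str]  # id(gene node) -> event (internal nodes only)
    losses: dict[int, int] = field(default_factory=dict)  # id(child) -> losses on its edge

    @property
    def total_dup(self) -> int:
        return sum(1 for e in self.events.values() if e == EVENT_DUPLICATION)

    @property
    def total_loss(self) -> int:
        return sum(self.losses.values())

    @property
    def dl_score(self) -> int:
        return self.total_dup + self.total_loss

    def map_of(self, node: TreeNode) -> TreeNode:
        return self.mapping[id(node)]

    def event_of(self, node: TreeNode) -> str:
        return self.events[id(node)]


def is_duplication(
    species_tree: SpeciesTree,
    mapped: TreeNode,
    child_species_sets: list[frozenset],
) -> bool:
    """Duplication test at a node mapped to ``mapped``.

    Multifurcations in the species tree are treated as soft polytomies: the
    node is a duplication only when two of its children draw on a common
    child lineage of ``mapped`` (for a binary species node this reduces to
    the classical "mapping equals a child's mapping" criterion).  A node
    mapped to a species leaf is a within-species duplication.
    """
    if mapped.is_leaf:
        return True
    used: set[int] = set()
    for sset in child_species_sets:
        usage = {
            i
            for i, k in enumerate(mapped.children)
            if sset & species_tree.species_below(k)
        }
        if used & usage:
            return True
        used |= usage
    return False


def reconcile(gene_tree: GeneTree, species_tree: SpeciesTree) -> Reconciliation:
    """Standard LCA reconciliation of a rooted (possibly multifurcating) tree."""
    if species_tree._leaf_by_taxon is None:
        species_tree.prepare()
    missing = sorted(
        {leaf.species_id for leaf in gene_tree.leaves()}
        - set(species_tree.taxa())
    )
    if missing:
        raise KeyError(f"species not in species tree: {missing}")

    mapping: dict[int, TreeNode] = {}
    events: dict[int, str] = {}
    species_sets: dict[int, frozenset] = {}
    for node in gene_tree.postorder():
        if node.is_leaf:
            mapping[id(node)] = species_tree.leaf(node.species_id)
            species_sets[id(node)] = frozenset([node.species_id])
        else:
            m = mapping[id(node.children[0])]
            acc = species_sets[id(node.children[0])]
            for c in node.children[1:]:
                m = species_tree.lca(m, mapping[id(c)])
                acc |= species_sets[id(c)]
            mapping[id(node)] = m
            species_sets[id(node)] = acc
            dup = is_duplication(
                species_tree, m, [species_sets[id(c)] for c in node.children]
            )
            events[id(node)] = EVENT_DUPLICATION if dup else EVENT_SPECIATION

    recon = Reconciliation(gene_tree, species_tree, mapping, events)
    for node in gene_tree.postorder():
        if node.parent is not None:
            recon.losses[id(node)] = count_losses(node, recon)
    return recon


def count_losses(child: TreeNode, recon: Reconciliation) -> int:
    """Losses inferred on the edge from ``child.parent`` down to ``child``."""
    parent = child.parent
    if parent is None:
        raise ValueError("count_losses needs a non-root node")
    mu = recon.mapping[id(parent)]
    mv = recon.mapping[id(child)]
    if mu is mv:
        return 0
    d = recon.species_tree.path_down_length(mu, mv)  # raises if not descendant
    extra = 1 if recon.events[id(parent)] == EVENT_DUPLICATION else 0
    return max(0, d - 1 + extra)


def _rootable_nodes(tree: GeneTree) -> list[TreeNode]:
    """Nodes whose parent edge yields a distinct rooting of the unrooted topology.

    Every non-root node is a candidate; with a binary root, the two child
    edges are the same unrooted edge, so one of them is skipped.
    """
    nodes = [n for n in tree.postorder() if n.parent is not None]
    if len(tree.root.children) == 2:
        skip = tree.root.children[1]
        nodes = [n for n in nodes if n is not skip]
    return nodes


def root_by_dl(tree: GeneTree, species_tree: SpeciesTree) -> GeneTree:
    """Root ``tree`` on the edge minimising duplications + losses.

    Branch lengths are ignored for scoring.  Ties are broken by the root
    bipartition with the lexicographically smallest sorted gene list on its
    smaller side, making the result deterministic.
    """
    if tree.n_leaves < 3:
        return tree.copy()
    best: Optional[tuple] = None
    best_tree: Optional[GeneTree] = None
    for node in _rootable_nodes(tree):
        candidate = reroot_above(tree, node)
        recon = reconcile(candidate, species_tree)
        sides = sorted(
            (sorted(leaf.gene_id for leaf in c.leaves())
             for c in candidate.root.children),
            key=lambda s: (len(s), s),
        )
        key = (recon.dl_score, sides[0], sides[-1])
        if best is None or key < best:
            best = key
            best_tree = candidate
    return best_tree


def duplication_confidence(node: TreeNode, recon: Optional[Reconciliation] = None) -> float:
    """Duplication confidence score of a duplication node.

    The fraction of species in which the duplication is still detectable:
    intersection over union of the children's species sets.  With more than
    two children the intersection generalises to "present in at least two
    children".  Species-specific duplications score exactly 1.0.
    """
    if node.is_leaf or len(node.children) < 2:
        raise ValueError("DCS needs an internal node with >= 2 children")
    event = node.event if recon is None else recon.events.get(id(node))
    if event not in (EVENT_DUPLICATION, EVENT_DUBIOUS):
        raise ValueError("DCS is defined only for duplication nodes")
    sets = [
        {leaf.species_id for leaf in c.leaves()} for c in node.children
    ]
    union = set().union(*sets)
    if len(sets) == 2:
        inter = sets[0] & sets[1]
    else:
        inter = {
            s for s in union if sum(1 for ss in sets if s in ss) >= 2
        }
    return len(inter) / len(union)


def annotate_tree(
    tree: GeneTree,
    recon: Reconciliation,
    dcs_threshold: Optional[float] = None,
) -> None:
    """Write events, taxa and DCS onto the tree nodes in place.

    Duplication nodes with DCS below ``dcs_threshold`` are re-labelled
    ``dubious`` for reporting; reconciliation totals still count them as
    duplications.
    """
    for node in tree.postorder():
        node.taxon = recon.mapping[id(node)]
        if node.is_leaf:
            continue
        node.event = recon.events[id(node)]
        if node.event == EVENT_DUPLICATION:
            node.dcs = duplication_confidence(node, recon)
            if dcs_threshold is not None and node.dcs < dcs_threshold:
                node.event = EVENT_DUBIOUS
        else:
            node.dcs = None


def simplify_species_tree(species_tree: SpeciesTree, clades: Iterable[str]) -> SpeciesTree:
    """Flatten each named clade into one multifurcating node over its leaves.

    Mirrors the species-tree preparation that collapses densely sampled
    clades so that topology disagreements inside them are not over-called as
    duplications.  Leaf branch lengths become root-of-clade-to-leaf path sums.
    """
    out = species_tree.copy()
    for name in clades:
        node = None
        for n in out.preorder():
            if n.label == name:
                node = n
                break
        if node is None:
            raise KeyError(f"clade {name!r} not in species tree")
        if node.is_leaf:
            continue
        leaves = []
        for leaf in node.leaves():
            total = leaf.length
            p = leaf.parent
            while p is not node:
                total += p.length
                p = p.parent
            leaf.length = total
            leaves.append(leaf)
        node.children = []
        for leaf in leaves:
            node.add_child(leaf)
    out.prepare()
    return out


def event_table(tree: GeneTree, recon: Reconciliation) -> list[dict]:
    """Flat per-internal-node event records (node_id, event, taxon, dcs, losses)."""
    rows = []
    for i, node in enumerate(tree.postorder()):
        if node.is_leaf:
            continue
        event = recon.events[id(node)]
        rows.append(
            {
                "node_id": i,
                "event": event,
                "taxon": recon.mapping[id(node)].label,
                "dcs": (
                    duplication_confidence(node, recon)
                    if event == EVENT_DUPLICATION
                    else None
                ),
                "losses": sum(
                    recon.losses.get(id(c), 0) for c in node.children
                ),
            }
        )
    return rows
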