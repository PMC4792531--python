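"""Large-family handling: NJ guide trees, recursive splitting, supertrees.

Families above a size cap are split into groups of at most ``max_size`` genes
(default 400) by cutting a midpoint-rooted neighbour-joining guide tree
top-down; each group gets its own independently inferred subtree, and the
subtrees are re-connected into a supertree following the recorded split
hierarchy.  Families whose total input sequence exceeds 150 kb are flagged
for fast tree-building alternatives.

The NJ implementation follows the classical Q-criterion agglomeration with a
deterministic tie-break (smallest active index pair) and clamps negative
branch-length estimates to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .tree import GeneTree, TreeNode, reroot_above

__all__ = [
    "neighbor_joining",
    "distance_matrix",
    "read_fasta_alignment",
    "midpoint_root",
    "SplitHierarchy",
    "HierarchyNode",
    "split_family",
    "assemble_supertree",
    "needs_fast_mode",
    "FAST_MODE_THRESHOLD",
    "MAX_GROUP_SIZE",
]

FAST_MODE_THRESHOLD = 150_000  # bp of total input sequence
MAX_GROUP_SIZE = 400  # genes per split group


def neighbor_joining(dist: np.ndarray, labels: Sequence[str]) -> GeneTree:
    """Neighbour joining on a symmetric distance matrix.

    Returns an unrooted tree represented with a trifurcating root.  Negative
    branch-length estimates are clamped to 0.  Ties in the Q criterion are
    broken by the smallest (i, j) pair under the stable input ordering (new
    internal nodes are appended after the original genes).
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if n != len(labels):
        raise ValueError("labels do not match matrix size")
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if not np.all(np.isfinite(d)) or np.any(d < 0):
        raise ValueError("distances must be finite and non-negative")

    d = d.copy()
    nodes: list[TreeNode] = [
        TreeNode(label=lab, gene_id=lab) for lab in labels
    ]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))  # first minimum in row-major order = smallest (i,j)
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (totals[ai] - totals[aj]) / (2.0 * (m - 2))
        lj = dij - li
        parent = TreeNode()
        nodes[i].length = max(0.0, li)
        nodes[j].length = max(0.0, lj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # new distances to remaining nodes
        new_row = 0.5 * (d[i, active] + d[j, active] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        k = d.shape[0] - 1
        d[k, active] = new_row
        d[active, k] = new_row
        d[k, k] = 0.0
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [k]

    # join the last three nodes on a central (trifurcating) root
    i, j, k = active
    root = TreeNode()
    nodes[i].length = max(0.0, 0.5 * (d[i, j] + d[i, k] - d[j, k]))
    nodes[j].length = max(0.0, 0.5 * (d[i, j] + d[j, k] - d[i, k]))
    nodes[k].length = max(0.0, 0.5 * (d[i, k] + d[j, k] - d[i, j]))
    for idx in (i, j, k):
        root.add_child(nodes[idx])
    return GeneTree(root)


def read_fasta_alignment(path) -> list[tuple[str, str]]:
    """Read a FASTA multiple alignment as (id, sequence) rows."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def distance_matrix(alignment: Sequence[tuple[str, str]]) -> tuple[np.ndarray, list[str]]:
    """p-distances from a multiple alignment given as (id, sequence) rows.

    Sites where either sequence has a gap (``-`` or ``.``) are ignored; a pair
    with no comparable site gets the matrix maximum (computed afterwards).
    """
    if not alignment:
        raise ValueError("empty alignment")
    labels = [name for name, _ in alignment]
    lengths = {len(seq) for _, seq in alignment}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: sequences differ in length")
    seqs = np.array(
        [list(seq.upper()) for _, seq in alignment], dtype="U1"
    )
    gap = (seqs == "-") | (seqs == ".")
    n = len(labels)
    d = np.zeros((n, n))
    incomparable = []
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            total = int(ok.sum())
            if total == 0:
                incomparable.append((i, j))
                continue
            mism = int((seqs[i][ok] != seqs[j][ok]).sum())
            d[i, j] = d[j, i] = mism / total
    if incomparable:
        fill = d.max()
        for i, j in incomparable:
            d[i, j] = d[j, i] = fill
    return d, labels


def midpoint_root(tree: GeneTree) -> GeneTree:
    """Root a tree at the midpoint of its longest leaf-to-leaf path."""
    leaves = tree.leaves()
    if len(leaves) < 2:
        return tree.copy()

    def distances_from(start: TreeNode) -> dict[int, float]:
        dist = {id(start): 0.0}
        stack = [start]
        while stack:
            node = stack.pop()
            nbrs = list(node.children)
            if node.parent is not None:
                nbrs.append(node.parent)
            for nb in nbrs:
                if id(nb) in dist:
                    continue
                edge = node.length if nb is node.parent else nb.length
                dist[id(nb)] = dist[id(node)] + edge
                stack.append(nb)
        return dist

    by_id = {id(n): n for n in tree.postorder()}
    d0 = distances_from(leaves[0])
    u = max(leaves, key=lambda l: d0[id(l)])
    du = distances_from(u)
    v = max(leaves, key=lambda l: du[id(l)])
    diameter = du[id(v)]

    # walk from v towards u; the midpoint lies on this path
    path = []
    node = v
    seen = {id(v)}
    # reconstruct path via parents/children using distances
    while node is not u:
        nbrs = list(node.children)
        if node.parent is not None:
            nbrs.append(node.parent)
        node = min(
            (nb for nb in nbrs if id(nb) not in seen),
            key=lambda nb: du[id(nb)],
        )
        seen.add(id(node))
        path.append(node)
    # walk edges along the path until the midpoint falls inside one
    half = diameter / 2.0
    walked = 0.0
    prev = v
    for node in path:
        upward = node is prev.parent
        child = prev if upward else node  # lower endpoint of this edge
        edge = child.length
        if walked + edge >= half - 1e-12 or node is u:
            rem = half - walked
            frac = rem / edge if edge > 0 else 0.5
            if not upward:  # entering the edge from its upper end
                frac = 1.0 - frac
            frac = min(max(frac, 0.0), 1.0)
            return reroot_above(tree, child, fraction=frac)
        walked += edge
        prev = node
    return reroot_above(tree, v, fraction=0.5)  # degenerate: zero-length tree


@dataclass
class HierarchyNode:
    """Node of a split hierarchy; leaves carry a gene cluster."""

    cluster: Optional[tuple[str, ...]] = None
    children: list["HierarchyNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return self.cluster is not None


@dataclass
class SplitHierarchy:
    """Record of the recursive guide-tree cuts for one large family."""

    root: HierarchyNode
    max_size: int

    def clusters(self) -> list[tuple[str, ...]]:
        out: list[tuple[str, ...]] = []

        def walk(node: HierarchyNode) -> None:
            if node.is_leaf:
                out.append(node.cluster)
            else:
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out


def split_family(
    guide_tree: GeneTree, max_size: int = MAX_GROUP_SIZE
) -> SplitHierarchy:
    """Split a family into clusters of at most ``max_size`` genes.

    The guide tree is midpoint-rooted and cut top-down: any clade larger than
    the cap is replaced by its root's child clades, recursively.  The
    returned hierarchy records the cut order and partitions the gene set.
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    rooted = midpoint_root(guide_tree)

    def cut(node: TreeNode) -> HierarchyNode:
        genes = tuple(sorted(leaf.gene_id for leaf in node.leaves()))
        if len(genes) <= max_size:
            return HierarchyNode(cluster=genes)
        if node.is_leaf:  # cannot happen with max_size >= 1
            return HierarchyNode(cluster=genes)
        h = HierarchyNode()
        for c in node.children:
            h.children.append(cut(c))
        return h

    return SplitHierarchy(root=cut(rooted.root), max_size=max_size)


def assemble_supertree(
    hierarchy: SplitHierarchy,
    subtrees: dict[tuple[str, ...], GeneTree],
) -> GeneTree:
    """Reconnect per-cluster subtrees following the split hierarchy.

    Each hierarchy leaf is replaced by the rooted subtree inferred for its
    cluster; connecting branches carry no length.
    """
    for cluster in hierarchy.clusters():
        if cluster not in subtrees:
            raise KeyError(f"missing subtree for cluster {cluster[:3]}...")
        got = tuple(sorted(subtrees[cluster].gene_ids()))
        if got != cluster:
            raise ValueError(
                f"subtree leaf set does not match cluster ({len(got)} vs {len(cluster)} genes)"
            )

    def build(h: HierarchyNode) -> TreeNode:
        if h.is_leaf:
            root = subtrees[h.cluster].copy().root
            root.length = 0.0
            return root
        node = TreeNode()
        for c in h.children:
            node.add_child(build(c))
        return node

    return GeneTree(build(hierarchy.root))


def needs_fast_mode(
    total_input_sequence_length: int, threshold: int = FAST_MODE_THRESHOLD
) -> bool:
    """True when a family's total input sequence is strictly above the cap."""
    if total_input_sequence_length < 0:
        raise ValueError("sequence length must be >= 0")
    return total_input_sequence_length > threshold
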