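"""Tree data model and Newick/NHX input/output.

Gene trees carry per-leaf ``gene_id``/``species_id`` and per-node evolutionary
annotations (event label, species-tree mapping, duplication confidence score,
supporting input trees).  Species trees are rooted, possibly multifurcating
taxon trees, optionally ultrametric with branch lengths in millions of years.

Parsing is delegated to dendropy; NHX hot comments (``S=`` species, ``D=Y|N``
duplication, ``B=`` bootstrap, ``DCS=`` duplication confidence, ``T=``
supporting trees) are mapped onto node fields.  Serialization emits the same
tags so a write→parse cycle is the identity on topology and annotations.
"""

from __future__ import annotations

import io
from typing import Callable, Iterable, Iterator, Optional

import dendropy

__all__ = [
    "TreeNode",
    "GeneTree",
    "SpeciesTree",
    "Bipartition",
    "NewickError",
    "parse_newick",
    "parse_gene_tree",
    "parse_species_tree",
    "write_newick",
    "restrict",
    "bipartitions",
    "unrooted_splits",
    "reroot_above",
]

EVENT_SPECIATION = "speciation"
EVENT_DUPLICATION = "duplication"
EVENT_DUBIOUS = "dubious"


class NewickError(ValueError):
    """Raised on malformed Newick/NHX input; message names the position."""


class TreeNode:
    """A node of a gene or species tree.

    Interior nodes have ``children``; leaves have none.  ``length`` is the
    length of the branch above the node (0.0 at an unannotated root).
    """

    __slots__ = (
        "parent",
        "children",
        "length",
        "bootstrap",
        "label",
        "gene_id",
        "species_id",
        "event",
        "taxon",
        "dcs",
        "supporters",
    )

    def __init__(
        self,
        label: Optional[str] = None,
        length: float = 0.0,
        gene_id: Optional[str] = None,
        species_id: Optional[str] = None,
    ):
        self.parent: Optional[TreeNode] = None
        self.children: list[TreeNode] = []
        self.length = float(length)
        self.bootstrap: Optional[int] = None
        self.label = label
        self.gene_id = gene_id
        self.species_id = species_id
        self.event: Optional[str] = None
        self.taxon: Optional[TreeNode] = None
        self.dcs: Optional[float] = None
        self.supporters: Optional[list[str]] = None

    # -- structure ---------------------------------------------------------
    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def copy(self) -> "TreeNode":
        new = TreeNode(self.label, self.length, self.gene_id, self.species_id)
        new.bootstrap = self.bootstrap
        new.event = self.event
        new.taxon = self.taxon
        new.dcs = self.dcs
        new.supporters = list(self.supporters) if self.supporters is not None else None
        for c in self.children:
            new.add_child(c.copy())
        return new

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        name = self.gene_id or self.species_id or self.label or "*"
        return f"<TreeNode {name} ({len(self.children)} children)>"


class _BaseTree:
    def __init__(self, root: TreeNode):
        self.root = root

    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    def preorder(self) -> Iterator[TreeNode]:
        return self.root.preorder()

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.postorder())

    def __len__(self) -> int:
        return sum(1 for _ in self.postorder())


class GeneTree(_BaseTree):
    """Rooted (or arbitrarily rooted) tree over genes of one family."""

    def copy(self) -> "GeneTree":
        return GeneTree(self.root.copy())

    def gene_ids(self) -> list[str]:
        return [leaf.gene_id for leaf in self.leaves()]

    def leaf(self, gene_id: str) -> TreeNode:
        for node in self.leaves():
            if node.gene_id == gene_id:
                return node
        raise KeyError(f"gene {gene_id!r} not in tree")

    def species_ids(self) -> set[str]:
        return {leaf.species_id for leaf in self.leaves()}

    def check(self) -> None:
        """Validate structural invariants; raise ValueError on violation."""
        ids = self.gene_ids()
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene_ids in tree")
        for node in self.postorder():
            if node.length < 0:
                raise ValueError(f"negative branch length at {node!r}")
            for c in node.children:
                if c.parent is not node:
                    raise ValueError("broken parent link")


class SpeciesTree(_BaseTree):
    """Rooted, possibly multifurcating taxon tree.

    ``prepare()`` caches depths and leaf lookups; it is called lazily by the
    accessors, and must be re-run after structural edits.
    """

    def __init__(self, root: TreeNode):
        super().__init__(root)
        self._leaf_by_taxon: Optional[dict[str, TreeNode]] = None
        self._depth: Optional[dict[int, int]] = None
        self._below: Optional[dict[int, frozenset]] = None

    def copy(self) -> "SpeciesTree":
        return SpeciesTree(self.root.copy())

    def prepare(self) -> None:
        self._leaf_by_taxon = {}
        self._depth = {}
        self._below = {}
        for node in self.preorder():
            self._depth[id(node)] = (
                0 if node.parent is None else self._depth[id(node.parent)] + 1
            )
            if node.is_leaf:
                if node.label in self._leaf_by_taxon:
                    raise ValueError(f"duplicate taxon {node.label!r}")
                self._leaf_by_taxon[node.label] = node
        for node in self.postorder():
            if node.is_leaf:
                self._below[id(node)] = frozenset([node.label])
            else:
                acc = frozenset()
                for c in node.children:
                    acc |= self._below[id(c)]
                self._below[id(node)] = acc

    def species_below(self, node: TreeNode) -> frozenset:
        """Set of leaf taxa in the subtree of ``node`` (cached)."""
        if self._below is None:
            self.prepare()
        return self._below[id(node)]

    def leaf(self, taxon_id: str) -> TreeNode:
        if self._leaf_by_taxon is None:
            self.prepare()
        try:
            return self._leaf_by_taxon[taxon_id]
        except KeyError:
            raise KeyError(f"taxon {taxon_id!r} not in species tree") from None

    def taxa(self) -> list[str]:
        return [leaf.label for leaf in self.leaves()]

    def depth(self, node: TreeNode) -> int:
        if self._depth is None:
            self.prepare()
        return self._depth[id(node)]

    def find(self, taxon_id: str) -> TreeNode:
        """Find any node (leaf or internal) with the given taxon label."""
        for node in self.preorder():
            if node.label == taxon_id:
                return node
        raise KeyError(f"taxon {taxon_id!r} not in species tree")

    def lca(self, a: TreeNode, b: TreeNode) -> TreeNode:
        if self._depth is None:
            self.prepare()
        da, db = self._depth[id(a)], self._depth[id(b)]
        while da > db:
            a = a.parent
            da -= 1
        while db > da:
            b = b.parent
            db -= 1
        while a is not b:
            a, b = a.parent, b.parent
        return a

    def lca_of_taxa(self, taxa: Iterable[str]) -> TreeNode:
        nodes = [self.leaf(t) for t in taxa]
        if not nodes:
            raise ValueError("empty taxon set")
        cur = nodes[0]
        for n in nodes[1:]:
            cur = self.lca(cur, n)
        return cur

    def path_down_length(self, ancestor: TreeNode, descendant: TreeNode) -> int:
        """Number of species-tree edges from ancestor down to descendant."""
        if self._depth is None:
            self.prepare()
        d = self._depth[id(descendant)] - self._depth[id(ancestor)]
        node = descendant
        for _ in range(d):
            node = node.parent
        if node is not ancestor:
            raise ValueError("nodes are not ancestor/descendant")
        return d


class Bipartition:
    """An unordered split {A, B} of a gene set; {A,B} == {B,A}."""

    __slots__ = ("_sides", "_hash")

    def __init__(self, side_a: Iterable[str], side_b: Iterable[str]):
        a = frozenset(side_a)
        b = frozenset(side_b)
        if not a or not b:
            raise ValueError("both sides of a bipartition must be non-empty")
        if a & b:
            raise ValueError("bipartition sides must be disjoint")
        self._sides = frozenset((a, b))
        self._hash = hash(self._sides)

    @property
    def sides(self) -> tuple[frozenset, frozenset]:
        a, b = sorted(self._sides, key=lambda s: (len(s), sorted(s)))
        return a, b

    @property
    def smaller_side(self) -> frozenset:
        return self.sides[0]

    def universe(self) -> frozenset:
        a, b = self._sides  # disjoint and non-empty, so always two distinct sets
        return a | b

    def is_trivial(self) -> bool:
        return min(len(s) for s in self._sides) == 1

    def sort_key(self) -> tuple:
        """Deterministic tie-break key: sorted gene list of the smaller side."""
        small = self.smaller_side
        return (sorted(small), sorted(self.sides[1]))

    def __eq__(self, other) -> bool:
        return isinstance(other, Bipartition) and self._sides == other._sides

    def __hash__(self) -> int:
        return self._hash

    def __repr__(self) -> str:
        a, b = self.sides
        return f"Bipartition({sorted(a)} | {sorted(b)})"


# ---------------------------------------------------------------------------
# Newick / NHX input
# ---------------------------------------------------------------------------


def _parse_nhx_comment(comment: str) -> dict[str, str]:
    if not comment.startswith("&&NHX"):
        return {}
    out = {}
    for field in comment[5:].split(":"):
        if not field:
            continue
        if "=" in field:
            key, value = field.split("=", 1)
            out[key] = value
    return out


def _apply_nhx(node: TreeNode, tags: dict[str, str]) -> None:
    if "S" in tags:
        node.species_id = tags["S"]
    if "D" in tags:
        node.event = EVENT_DUPLICATION if tags["D"] == "Y" else EVENT_SPECIATION
    if "E" in tags and tags.get("E") == "dubious":
        node.event = EVENT_DUBIOUS
    if "B" in tags:
        try:
            node.bootstrap = int(tags["B"])
        except ValueError:
            pass
    if "DCS" in tags:
        node.dcs = float(tags["DCS"])
    if "T" in tags and tags["T"]:
        node.supporters = tags["T"].split("+")


def parse_newick(text: str, kind: str = "gene") -> "GeneTree | SpeciesTree":
    """Parse a Newick/NHX string into a :class:`GeneTree` or :class:`SpeciesTree`.

    ``kind`` selects the output type: ``"gene"`` (leaf labels become
    ``gene_id``, species from the NHX ``S=`` tag) or ``"species"`` (labels are
    taxon ids).  Internal plain labels that look like integers are read as
    bootstrap values on gene trees.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            extract_comment_metadata=False,
        )
    except Exception as exc:  # dendropy raises several reader error types
        raise NewickError(f"malformed newick: {exc}") from exc

    def convert(dnode) -> TreeNode:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = TreeNode(label=label, length=dnode.edge.length or 0.0)
        if dnode.is_leaf():
            if kind == "gene":
                node.gene_id = label
            else:
                node.species_id = label
        elif kind == "gene" and label is not None:
            try:
                node.bootstrap = int(label)
            except ValueError:
                pass
        for comment in dnode.comments:
            _apply_nhx(node, _parse_nhx_comment(comment))
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    if kind == "species":
        return SpeciesTree(root)
    return GeneTree(root)


def parse_gene_tree(text: str) -> GeneTree:
    return parse_newick(text, kind="gene")


def parse_species_tree(text: str) -> SpeciesTree:
    return parse_newick(text, kind="species")


# ---------------------------------------------------------------------------
# Newick / NHX output
# ---------------------------------------------------------------------------


def _format_length(x: float) -> str:
    # fixed decimal with trailing-zero trimming; round-trip tolerance 1e-9
    s = f"{x:.9f}".rstrip("0").rstrip(".")
    return s if s else "0"


def _nhx_tags(node: TreeNode, kind: str) -> str:
    tags = []
    if kind == "gene" and node.is_leaf and node.species_id is not None:
        tags.append(f"S={node.species_id}")
    if node.event == EVENT_DUPLICATION:
        tags.append("D=Y")
    elif node.event == EVENT_SPECIATION and not node.is_leaf:
        tags.append("D=N")
    elif node.event == EVENT_DUBIOUS:
        tags.append("D=Y")
        tags.append("E=dubious")
    if node.bootstrap is not None and not node.is_leaf:
        tags.append(f"B={node.bootstrap}")
    if node.dcs is not None:
        tags.append(f"DCS={node.dcs:.6g}")
    if node.supporters:
        tags.append("T=" + "+".join(node.supporters))
    if not tags:
        return ""
    return "[&&NHX:" + ":".join(tags) + "]"


def write_newick(tree: "GeneTree | SpeciesTree", lengths: bool = True) -> str:
    """Serialize a tree to Newick with NHX annotations."""
    kind = "gene" if isinstance(tree, GeneTree) else "species"
    buf = io.StringIO()

    def emit(node: TreeNode) -> None:
        if node.children:
            buf.write("(")
            for i, c in enumerate(node.children):
                if i:
                    buf.write(",")
                emit(c)
            buf.write(")")
            if kind == "species" and node.label is not None:
                buf.write(node.label)
        else:
            name = node.gene_id if kind == "gene" else node.label
            buf.write(name if name is not None else "")
        if lengths and node.parent is not None:
            buf.write(":" + _format_length(node.length))
        buf.write(_nhx_tags(node, kind))

    emit(tree.root)
    buf.write(";")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Basic operations
# ---------------------------------------------------------------------------


def restrict(tree: GeneTree, genes: Iterable[str]) -> GeneTree:
    """Induced subtree on ``genes``; unary nodes suppressed, lengths summed.

    When a unary chain is collapsed the surviving (lower) node keeps its own
    bootstrap, and absorbs the suppressed ancestors' branch lengths.
    """
    wanted = set(genes)
    known = set(tree.gene_ids())
    unknown = wanted - known
    if unknown:
        raise KeyError(f"unknown gene_ids: {sorted(unknown)}")
    if not wanted:
        raise ValueError("cannot restrict to an empty gene set")

    def prune(node: TreeNode) -> Optional[TreeNode]:
        if node.is_leaf:
            if node.gene_id in wanted:
                new = TreeNode(node.label, node.length, node.gene_id, node.species_id)
                new.bootstrap = node.bootstrap
                return new
            return None
        kept = [prune(c) for c in node.children]
        kept = [k for k in kept if k is not None]
        if not kept:
            return None
        if len(kept) == 1:
            # suppress this unary node: child keeps identity, absorbs length
            kept[0].length += node.length
            return kept[0]
        new = TreeNode(node.label, node.length)
        new.bootstrap = node.bootstrap
        new.event = node.event
        new.dcs = node.dcs
        for k in kept:
            new.add_child(k)
        return new

    root = prune(tree.root)
    root.parent = None
    root.length = 0.0
    return GeneTree(root)


def _leafset(node: TreeNode, names: Callable[[TreeNode], str]) -> frozenset:
    return frozenset(names(leaf) for leaf in node.leaves())


def bipartitions(
    tree: "GeneTree | SpeciesTree",
    include_trivial: bool = False,
) -> dict[Bipartition, float]:
    """Bipartitions of the full leaf set, one per internal edge.

    For rooted trees every non-root node contributes the split
    (its leaves | the rest); the two edges at a binary root induce the same
    split and their lengths are summed, matching the unrooted reading.
    Trivial (single-leaf) splits are included only on request.
    """
    if isinstance(tree, GeneTree):
        name = lambda leaf: leaf.gene_id
    else:
        name = lambda leaf: leaf.label
    all_leaves = _leafset(tree.root, name)
    if len(all_leaves) < 2:
        raise ValueError("tree must have at least 2 leaves")
    out: dict[Bipartition, float] = {}
    for node in tree.postorder():
        if node.parent is None:
            continue
        below = _leafset(node, name)
        above = all_leaves - below
        if not above:
            continue
        bp = Bipartition(below, above)
        if bp.is_trivial() and not include_trivial:
            continue
        out[bp] = out.get(bp, 0.0) + node.length
    return out


def unrooted_splits(tree: GeneTree, include_trivial: bool = True) -> dict[Bipartition, float]:
    """Splits of the unrooted version of ``tree`` with branch lengths.

    Used for branch pairing in tree comparison: a binary root's two child
    edges collapse into one unrooted branch whose length is their sum
    (handled by :func:`bipartitions`).
    """
    return bipartitions(tree, include_trivial=include_trivial)


def reroot_above(tree: GeneTree, node: TreeNode, fraction: float = 0.5) -> GeneTree:
    """Return a new tree rooted on the branch above ``node``.

    ``fraction`` places the new root at ``fraction * length`` above the node.
    A former binary root left with a single child is suppressed.  ``node``
    must belong to ``tree``; pass a node of the tree itself, not of a copy.
    """
    if node.parent is None:
        return tree.copy()

    # Work on a copy; locate the matching node by its postorder index.
    index = None
    for i, n in enumerate(tree.postorder()):
        if n is node:
            index = i
            break
    if index is None:
        raise ValueError("node does not belong to tree")
    new_tree = tree.copy()
    target = list(new_tree.postorder())[index]

    old_parent = target.parent
    if old_parent is None:  # pragma: no cover - guarded above
        return new_tree

    new_root = TreeNode()
    dist = target.length
    old_parent.children.remove(target)
    target.parent = None
    target.length = dist * fraction

    # Flip the parent chain old_parent -> ... -> old_root: each former parent
    # becomes a child of its former child; the edge between chain[i] and
    # chain[i+1] keeps its length (which was stored on chain[i]).
    chain = []
    n: Optional[TreeNode] = old_parent
    while n is not None:
        chain.append(n)
        n = n.parent
    old_len = [c.length for c in chain]
    for i in range(len(chain) - 1):
        chain[i + 1].children.remove(chain[i])
    for c in chain:
        c.parent = None
    chain[0].length = dist * (1.0 - fraction)
    for i in range(len(chain) - 1):
        chain[i].add_child(chain[i + 1])
        chain[i + 1].length = old_len[i]

    new_root.add_child(target)
    new_root.add_child(chain[0])

    # The old root may be left unary (it had 2 children and lost one).
    old_root = chain[-1]
    if len(old_root.children) == 1:
        child = old_root.children[0]
        child.length += old_root.length
        parent = old_root.parent
        pos = parent.children.index(old_root)
        parent.children[pos] = child
        child.parent = parent

    return GeneTree(new_root)
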