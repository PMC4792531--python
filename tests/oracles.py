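"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own LCA walking, rerooting and loss
formulas: species mappings are found by scanning for the minimal containing
species subtree, losses are counted by explicitly embedding each gene-tree
edge into the species tree and enumerating the sibling lineages it abandons,
and rootings are enumerated from an undirected adjacency view of the tree.
"""

from __future__ import annotations

from ncrphylo.tree import GeneTree, SpeciesTree, TreeNode


# ---------------------------------------------------------------------------
# exhaustive rooted-topology enumeration (nested 2-tuples; leaves are strings)
# ---------------------------------------------------------------------------


def all_rooted_topologies(leaves):
    """Yield every rooted binary topology over the given leaf names."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], list(leaves[1:])
    for t in all_rooted_topologies(rest):
        yield from _insert_everywhere(t, first)


def _insert_everywhere(t, leaf):
    yield (leaf, t)  # new node above t (covers the root position)
    if isinstance(t, tuple):
        a, b = t
        for na in _insert_everywhere(a, leaf):
            yield (na, b)
        for nb in _insert_everywhere(b, leaf):
            yield (a, nb)


def tuple_to_gene_tree(t, species_of) -> GeneTree:
    def build(node):
        if isinstance(node, tuple):
            n = TreeNode(length=1.0)
            for child in node:
                n.add_child(build(child))
            return n
        return TreeNode(
            label=node, length=1.0, gene_id=node, species_id=species_of[node]
        )

    root = build(t)
    root.length = 0.0
    return GeneTree(root)


# ---------------------------------------------------------------------------
# reconciliation oracle
# ---------------------------------------------------------------------------


def _species_subtree_table(stree: SpeciesTree):
    table = []
    for node in stree.postorder():
        table.append((node, frozenset(l.label for l in node.leaves())))
    return table


def oracle_map(species_set, table):
    """Smallest species subtree containing the set (scan, no LCA walking)."""
    best = None
    for node, below in table:
        if species_set <= below and (best is None or len(below) < len(best[1])):
            best = (node, below)
    return best[0]


def oracle_reconcile(tree: GeneTree, stree: SpeciesTree):
    """Events and per-edge losses by set-scan mapping + explicit embedding.

    Returns (events dict keyed by id(node), losses dict keyed by id(child),
    total_dup, total_loss).
    """
    table = _species_subtree_table(stree)
    species_below = {}
    mapping = {}
    for node in tree.postorder():
        if node.is_leaf:
            species_below[id(node)] = frozenset([node.species_id])
        else:
            acc = frozenset()
            for c in node.children:
                acc |= species_below[id(c)]
            species_below[id(node)] = acc
        mapping[id(node)] = oracle_map(species_below[id(node)], table)

    events = {}
    for node in tree.postorder():
        if node.is_leaf:
            continue
        dup = any(mapping[id(c)] is mapping[id(node)] for c in node.children)
        events[id(node)] = "duplication" if dup else "speciation"

    losses = {}
    for node in tree.postorder():
        if node.parent is None:
            continue
        mu = mapping[id(node.parent)]
        mv = mapping[id(node)]
        if mu is mv:
            losses[id(node)] = 0
            continue
        # walk up from m(v) to m(u), counting abandoned sibling lineages
        path = [mv]
        n = mv
        while n is not mu:
            n = n.parent
            path.append(n)
        lost = 0
        for w in path[1:-1]:  # intermediate species nodes passed through
            lost += len(w.children) - 1
        if events[id(node.parent)] == "duplication":
            lost += len(mu.children) - 1  # the copy also descends out of m(u)
        losses[id(node)] = lost

    total_dup = sum(1 for e in events.values() if e == "duplication")
    total_loss = sum(losses.values())
    return events, losses, total_dup, total_loss


# ---------------------------------------------------------------------------
# rooting oracle: enumerate rootings from an undirected adjacency view
# ---------------------------------------------------------------------------


def _adjacency(tree: GeneTree):
    nodes = list(tree.postorder())
    adj = {id(n): [] for n in nodes}
    info = {}
    for n in nodes:
        info[id(n)] = n
        for c in n.children:
            adj[id(n)].append(id(c))
            adj[id(c)].append(id(n))
    # a binary root is a fake degree-2 vertex of the unrooted topology: splice
    root = tree.root
    if len(root.children) == 2:
        a, b = (id(c) for c in root.children)
        adj[a] = [x for x in adj[a] if x != id(root)] + [b]
        adj[b] = [x for x in adj[b] if x != id(root)] + [a]
        del adj[id(root)]
    return adj, info


def enumerate_rootings(tree: GeneTree):
    """Every rooting of the unrooted topology of ``tree`` as a new GeneTree."""
    adj, info = _adjacency(tree)
    seen_edges = set()
    for u, nbrs in adj.items():
        for v in nbrs:
            edge = frozenset((u, v))
            if edge in seen_edges:
                continue
            seen_edges.add(edge)
            yield _root_on_edge(adj, info, u, v)


def _root_on_edge(adj, info, u, v) -> GeneTree:
    def build(vertex, parent_vertex):
        src = info[vertex]
        node = TreeNode(
            label=src.label,
            length=1.0,
            gene_id=src.gene_id,
            species_id=src.species_id,
        )
        for nb in adj[vertex]:
            if nb != parent_vertex:
                node.add_child(build(nb, vertex))
        return node

    root = TreeNode()
    root.add_child(build(u, v))
    root.add_child(build(v, u))
    return GeneTree(root)


def oracle_best_rooting_score(tree: GeneTree, stree: SpeciesTree) -> int:
    best = None
    for rooted in enumerate_rootings(tree):
        _e, _l, d, l = oracle_reconcile(rooted, stree)
        score = d + l
        if best is None or score < best:
            best = score
    return best


# ---------------------------------------------------------------------------
# exhaustive ancestral-count enumeration for the birth-death likelihood
# ---------------------------------------------------------------------------


def oracle_family_likelihood(profile, tree: SpeciesTree, lam, n_max, root_prior):
    """Sum over all ancestral count assignments (tiny trees only)."""
    from ncrphylo.gainloss import transition_prob

    internals = [n for n in tree.postorder() if not n.is_leaf]
    leaves = tree.leaves()

    def prob_for(assign):
        p = root_prior[assign[id(tree.root)]]
        for node in tree.postorder():
            if node.parent is None:
                continue
            s = assign[id(node.parent)]
            c = (
                profile.counts.get(node.label, 0)
                if node.is_leaf
                else assign[id(node)]
            )
            p *= transition_prob(s, c, node.length, lam)
        return p

    total = 0.0
    counts = [0] * len(internals)
    while True:
        assign = {id(n): counts[i] for i, n in enumerate(internals)}
        total += prob_for(assign)
        i = 0  # odometer over ancestral assignments
        while i < len(counts) and counts[i] == n_max:
            counts[i] = 0
            i += 1
        if i == len(counts):
            break
        counts[i] += 1
    return total
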