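"""Synthetic benchmark generators for every stage of the pipeline.

The generators emulate the study conditions the pipeline is built for:

* gene trees evolved forward in time inside a dated species tree by a
  duplication-loss branching process, with the true event history logged;
* several noisy "intermediate" trees per family (nearest-neighbour
  interchanges plus log-normal branch-length noise), standing in for the
  secondary-structure and genomic input trees;
* family-size profiles drawn from the equal-rate birth-death transition
  kernel at a known λ, for gain/loss parameter-recovery experiments;
* paired annotation tables with planted intronic / 5 kb-window synteny
  support for orthologue QC.

All generators are driven by one integer seed through independent
per-generator substreams (``numpy.random.SeedSequence([seed, stream])``), so
adding a generator never perturbs existing fixtures and every output is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .tree import (
    EVENT_DUPLICATION,
    EVENT_SPECIATION,
    GeneTree,
    SpeciesTree,
    TreeNode,
    parse_species_tree,
)
from .gainloss import FamilyProfile, transition_matrix
from .homology import ANNOTATION_COLUMNS, HomologyPair, CLASS_ONE2ONE

__all__ = [
    "SimulationConfig",
    "default_species_tree",
    "gainloss_species_tree",
    "simulate_gene_tree",
    "perturb_tree",
    "simulate_profiles",
    "simulate_synteny_fixture",
    "random_gene_tree",
]

# Mammal-scale dated species trees (node ages in millions of years).  The
# 12-taxon tree drives the tree-level simulations; the 6-taxon tree is the
# gain/loss benchmark tree (well-annotated genomes spanning the root).
_SPECIES_TREE_12 = (
    "((((((human:6,chimp:6)hominini:2,gorilla:8)homininae:7,orangutan:15)"
    "hominidae:28,marmoset:43)primates:47,(mouse:20,rat:20)murinae:70)"
    "euarchontoglires:70,((dog:55,cat:55)carnivora:40,(cow:60,pig:60)"
    "cetartiodactyla:35)laurasiatheria:65,opossum:160)theria;"
)
_SPECIES_TREE_6 = (
    "(((((human:6,chimp:6)hominini:37,marmoset:43)primates:47,mouse:90)"
    "euarchontoglires:5,dog:95)boreoeutheria:65,opossum:160)theria;"
)


def default_species_tree() -> SpeciesTree:
    """12-taxon dated mammal tree used by the tree-level simulators."""
    tree = parse_species_tree(_SPECIES_TREE_12)
    tree.prepare()
    return tree


def gainloss_species_tree() -> SpeciesTree:
    """6-taxon binary ultrametric tree for birth-death benchmarks."""
    tree = parse_species_tree(_SPECIES_TREE_6)
    tree.prepare()
    return tree


@dataclass
class SimulationConfig:
    """Knobs of the synthetic benchmark; defaults are the study conditions."""

    seed: int = 0
    dup_rate: float = 0.002  # duplications per gene lineage per My
    loss_rate: float = 0.001  # losses per gene lineage per My
    nni_moves: int = 1  # perturbation strength of intermediate trees
    length_noise_sd: float = 0.1  # log-normal sd on branch lengths
    n_families: int = 50
    lambda_true: float = 0.002  # birth-death rate for profile simulation
    n_intermediate_trees: int = 5  # noisy input trees per family
    root_lineages: int = 1  # >1 plants duplications at the root
    max_root_count: int = 5  # uniform root prior cap for profiles
    retry_limit: int = 100

    def rng(self, stream: str) -> np.random.Generator:
        digest = sum((i + 1) * b for i, b in enumerate(stream.encode())) % (2**16)
        return np.random.default_rng(np.random.SeedSequence([self.seed, digest]))


@dataclass
class GeneTreeLog:
    """Ground truth recorded while simulating one gene family."""

    n_duplications: int = 0
    n_losses: int = 0
    duplication_clades: list[frozenset] = field(default_factory=list)
    losses_per_species_branch: dict[str, int] = field(default_factory=dict)


def simulate_gene_tree(
    species_tree: SpeciesTree,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[GeneTree, GeneTreeLog]:
    """Evolve a gene family inside the species tree by duplication and loss.

    Lineages duplicate at ``dup_rate`` and die at ``loss_rate`` along each
    species branch and split at speciations; surviving leaves are named
    ``g<k>_<species>``.  The returned log holds the surviving true
    duplication nodes (as leaf clades) and loss counts.  Extinct simulations
    are resampled up to ``retry_limit`` times.
    """
    rng = rng if rng is not None else config.rng("gene_tree")

    for _attempt in range(config.retry_limit):
        log = GeneTreeLog()
        counter = [0]

        def evolve_branch(snode: TreeNode, t_remaining: float) -> Optional[TreeNode]:
            """One gene lineage along the species branch above ``snode``."""
            total = config.dup_rate + config.loss_rate
            t = rng.exponential(1.0 / total) if total > 0 else np.inf
            if t >= t_remaining:
                return at_species_node(snode, pendant=t_remaining)
            if rng.random() < config.loss_rate / total:
                label = snode.label or "?"
                log.losses_per_species_branch[label] = (
                    log.losses_per_species_branch.get(label, 0) + 1
                )
                log.n_losses += 1
                return None
            node = TreeNode(length=0.0)
            node.event = EVENT_DUPLICATION
            log.n_duplications += 1
            kids = [evolve_branch(snode, t_remaining - t) for _ in range(2)]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                kids[0].length += t
                return kids[0]
            node.length = t  # placed t My into the branch segment
            for k in kids:
                node.add_child(k)
            # lengths of children measured from this node
            return node

        def at_species_node(snode: TreeNode, pendant: float) -> Optional[TreeNode]:
            if snode.is_leaf:
                counter[0] += 1
                leaf = TreeNode(
                    length=pendant,
                    gene_id=f"g{counter[0]}_{snode.label}",
                    species_id=snode.label,
                )
                leaf.label = leaf.gene_id
                return leaf
            node = TreeNode(length=pendant)
            node.event = EVENT_SPECIATION
            kids = []
            for schild in snode.children:
                k = evolve_branch(schild, schild.length)
                if k is not None:
                    kids.append(k)
            if not kids:
                return None
            if len(kids) == 1:
                kids[0].length += pendant
                return kids[0]
            for k in kids:
                node.add_child(k)
            return node

        root = at_species_node(species_tree.root, pendant=0.0)
        if root is None or root.is_leaf:
            continue
        if config.root_lineages > 1:
            top = TreeNode(length=0.0)
            top.event = EVENT_DUPLICATION
            log.n_duplications += 1
            top.add_child(root)
            for _ in range(config.root_lineages - 1):
                extra = at_species_node(species_tree.root, pendant=0.0)
                if extra is not None:
                    top.add_child(extra)
            if len(top.children) > 1:
                root = top
        root.length = 0.0
        root.parent = None
        tree = GeneTree(root)
        for node in tree.postorder():
            if not node.is_leaf and node.event == EVENT_DUPLICATION:
                log.duplication_clades.append(
                    frozenset(leaf.gene_id for leaf in node.leaves())
                )
        return tree, log
    raise RuntimeError("all gene lineages went extinct in every retry")


def _internal_edges(tree: GeneTree) -> list[TreeNode]:
    return [
        n
        for n in tree.postorder()
        if n.parent is not None and not n.is_leaf
    ]


def perturb_tree(
    tree: GeneTree,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> GeneTree:
    """A noisy copy: NNI moves, branch-length noise, synthetic bootstraps.

    Each NNI picks an internal edge (u, v) and swaps one child of v with a
    sibling of v.  Branch lengths are multiplied by log-normal noise.
    Bootstraps reflect local perturbation: clades also present in the source
    tree get high values, rearranged clades low ones.
    """
    rng = rng if rng is not None else config.rng("perturb")
    out = tree.copy()
    for node in out.postorder():
        node.event = None
        node.dcs = None
        node.supporters = None

    for _ in range(config.nni_moves):
        # proper internal edges of the *unrooted* topology: across a binary
        # root the NNI partner is a child of the other root child, otherwise
        # a sibling of v — swapping with the whole sibling subtree across the
        # root would only rotate the rooted tree.
        candidates = []
        for v in _internal_edges(out):
            u = v.parent
            if u.parent is None and len(u.children) == 2:
                w = u.children[0] if u.children[1] is v else u.children[1]
                if not w.is_leaf:
                    candidates.append((v, w, True))
            else:
                candidates.append((v, u, False))
        if not candidates:
            break
        v, other, across_root = candidates[rng.integers(len(candidates))]
        c = v.children[rng.integers(len(v.children))]
        if across_root:
            s = other.children[rng.integers(len(other.children))]
            oi = other.children.index(s)
        else:
            siblings = [x for x in other.children if x is not v]
            s = siblings[rng.integers(len(siblings))]
            oi = other.children.index(s)
        vi = v.children.index(c)
        other.children[oi], v.children[vi] = c, s
        c.parent, s.parent = other, v

    if config.length_noise_sd > 0:
        for node in out.postorder():
            if node.parent is None:
                continue
            node.length = max(
                0.0, node.length * rng.lognormal(0.0, config.length_noise_sd)
            )

    original = {
        frozenset(leaf.gene_id for leaf in n.leaves())
        for n in tree.postorder()
        if not n.is_leaf
    }
    for node in out.postorder():
        if node.is_leaf or node.parent is None:
            continue
        clade = frozenset(leaf.gene_id for leaf in node.leaves())
        if clade in original:
            node.bootstrap = int(rng.integers(85, 101))
        else:
            node.bootstrap = int(rng.integers(20, 61))
    return out


def simulate_profiles(
    tree: SpeciesTree,
    config: SimulationConfig,
    n_families: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    n_max: int = 60,
) -> tuple[list[FamilyProfile], list[dict[str, int]]]:
    """Family-size profiles under the equal-rate birth-death kernel.

    Root counts are uniform on 1..``max_root_count``; counts then evolve down
    every branch by exact sampling from the transition kernel at
    ``lambda_true``.  Returns the extant profiles and, per family, the full
    (true) ancestral count map keyed by node label.
    """
    rng = rng if rng is not None else config.rng("profiles")
    nf = n_families if n_families is not None else config.n_families
    matrices: dict[float, np.ndarray] = {}
    for node in tree.postorder():
        if node.parent is not None and node.length not in matrices:
            m = transition_matrix(n_max, node.length, config.lambda_true)
            matrices[node.length] = m / m.sum(axis=1, keepdims=True)

    profiles = []
    truths = []
    for i in range(nf):
        counts: dict[str, int] = {}
        truth: dict[str, int] = {}
        root_count = int(rng.integers(1, config.max_root_count + 1))
        assign = {id(tree.root): root_count}
        truth[tree.root.label or "root"] = root_count
        for node in tree.preorder():
            if node.parent is None:
                continue
            s = assign[id(node.parent)]
            pmf = matrices[node.length][s]
            c = int(rng.choice(n_max + 1, p=pmf))
            assign[id(node)] = c
            truth[node.label or "?"] = c
            if node.is_leaf:
                counts[node.label] = c
        if not any(counts.values()):
            continue  # extinct at the tips: never observed as a family
        profiles.append(FamilyProfile(f"fam{i}", counts))
        truths.append(truth)
    return profiles, truths


def simulate_synteny_fixture(
    n_pairs: int,
    planted_support_fraction: float,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, pd.DataFrame], list[HomologyPair], list[HomologyPair]]:
    """Two-species annotation tables with planted synteny support.

    A deterministic ``round(fraction * n_pairs)`` of the ncRNA orthologue
    pairs are placed either inside orthologous host genes (intronic) or
    within 5 kb of a protein orthologue pair; the remainder land at least
    20 kb away from any protein.  Returns (annotations per species, protein
    pairs, ncRNA pairs).
    """
    if not 0.0 <= planted_support_fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = rng if rng is not None else config.rng("synteny")
    species = ("human", "mouse")
    n_planted = round(planted_support_fraction * n_pairs)

    rows: dict[str, list[dict]] = {sp: [] for sp in species}
    protein_pairs: list[HomologyPair] = []
    nc_pairs: list[HomologyPair] = []
    slot = 100_000  # one genomic slot per pair, comfortably > 2x 20 kb

    for i in range(n_pairs):
        base = 1 + i * slot
        supported = i < n_planted
        intronic = supported and (i % 2 == 0)
        prot = {sp: f"prot{i}_{sp}" for sp in species}
        nc = {sp: f"nc{i}_{sp}" for sp in species}
        for sp in species:
            prot_start = base + int(rng.integers(0, 1000))
            prot_end = prot_start + 20_000
            rows[sp].append(
                {
                    "gene_id": prot[sp],
                    "type": "protein_coding",
                    "chromosome": "chr1",
                    "start": prot_start,
                    "end": prot_end,
                    "strand": "+",
                    "host_gene": None,
                }
            )
            if intronic:
                nc_start = prot_start + 5_000
                host = prot[sp]
            elif supported:
                nc_start = prot_end + int(rng.integers(1000, 5000 - 200))
                host = None
            else:
                nc_start = prot_end + 25_000 + int(rng.integers(0, 5_000))
                host = None
            rows[sp].append(
                {
                    "gene_id": nc[sp],
                    "type": "ncRNA",
                    "chromosome": "chr1",
                    "start": nc_start,
                    "end": nc_start + 120,
                    "strand": "+",
                    "host_gene": host,
                }
            )
        protein_pairs.append(
            HomologyPair(
                gene1=prot[species[0]],
                gene2=prot[species[1]],
                species1=species[0],
                species2=species[1],
                cls=CLASS_ONE2ONE,
                node_id=-1,
                node_event="speciation",
            )
        )
        nc_pairs.append(
            HomologyPair(
                gene1=nc[species[0]],
                gene2=nc[species[1]],
                species1=species[0],
                species2=species[1],
                cls=CLASS_ONE2ONE,
                node_id=-1,
                node_event="speciation",
            )
        )
    annotations = {
        sp: pd.DataFrame(rows[sp], columns=ANNOTATION_COLUMNS) for sp in species
    }
    return annotations, protein_pairs, nc_pairs


def random_gene_tree(
    gene_ids: Sequence[str],
    species_of: dict[str, str],
    rng: np.random.Generator,
) -> GeneTree:
    """Uniform random rooted binary tree over the given genes (test helper)."""
    nodes = []
    for g in gene_ids:
        n = TreeNode(label=g, gene_id=g, species_id=species_of[g], length=1.0)
        nodes.append(n)
    if len(nodes) == 1:
        return GeneTree(nodes[0])
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=1.0)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    nodes[0].length = 0.0
    return GeneTree(nodes[0])
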