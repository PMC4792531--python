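"""Orthologue/paralogue inference from a reconciled gene tree, plus synteny QC.

Following Fitch, two genes are orthologues when their last common ancestor in
the gene tree is a speciation node, and paralogues when it is a duplication.
Within-species paralogues (same species, duplication LCA) are reported; pairs
from different species whose LCA is a *dubious* duplication (duplication
confidence score below a threshold, default 0.25) are rescued as orthologues
when neither gene has a better (speciation-mediated) match in the other
species.  Accepted orthologues are sub-classified by the number of
co-orthologous copies in each species: one-to-one, one-to-many, many-to-many.

Synteny QC checks each cross-species ncRNA orthologue pair against protein
orthologue pairs of the same class: a pair is *intronic-supported* when both
ncRNAs sit inside host protein-coding genes that are themselves orthologues
of the same class, and *window-supported* when a same-class protein
orthologue pair lies within 5 kb upstream or downstream of both ncRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .tree import (
    EVENT_DUBIOUS,
    EVENT_DUPLICATION,
    EVENT_SPECIATION,
    GeneTree,
    TreeNode,
)

__all__ = [
    "HomologyPair",
    "infer_homologies",
    "homology_table",
    "pair_counts",
    "read_annotation_table",
    "synteny_support",
    "SyntenySummary",
]

CLASS_ONE2ONE = "ortholog_one2one"
CLASS_ONE2MANY = "ortholog_one2many"
CLASS_MANY2MANY = "ortholog_many2many"
CLASS_WITHIN_PARALOG = "within_species_paralog"

DEFAULT_DCS_THRESHOLD = 0.25


@dataclass(frozen=True)
class HomologyPair:
    gene1: str
    gene2: str
    species1: str
    species2: str
    cls: str
    node_id: int
    node_event: str
    dcs: Optional[float] = None

    def key(self) -> frozenset:
        return frozenset((self.gene1, self.gene2))


def _lca_table(tree: GeneTree) -> tuple[list[TreeNode], dict[tuple[int, int], TreeNode]]:
    """All-pairs leaf LCA via per-leaf ancestor sets (families are small)."""
    leaves = tree.leaves()
    anc: dict[int, list[TreeNode]] = {}
    for leaf in leaves:
        path = []
        node: Optional[TreeNode] = leaf
        while node is not None:
            path.append(node)
            node = node.parent
        anc[id(leaf)] = path
    lca: dict[tuple[int, int], TreeNode] = {}
    for i, a in enumerate(leaves):
        for b in leaves[i + 1 :]:
            sa = set(id(n) for n in anc[id(a)])
            for node in anc[id(b)]:
                if id(node) in sa:
                    lca[(id(a), id(b))] = lca[(id(b), id(a))] = node
                    break
    return leaves, lca


def infer_homologies(
    tree: GeneTree, dcs_threshold: float = DEFAULT_DCS_THRESHOLD
) -> list[HomologyPair]:
    """Infer homology pairs from a reconciled, annotated gene tree.

    Requires ``event`` set on internal nodes (and ``dcs`` on duplication
    nodes when the dubious-duplication rescue is active,
    ``dcs_threshold > 0``).  Rescue accepts a cross-species pair below a
    dubious duplication only when *both* genes lack any speciation-mediated
    partner in the other species.
    """
    for node in tree.postorder():
        if not node.is_leaf and node.event is None:
            raise ValueError("tree is not reconciled: internal node without event")

    leaves, lca = _lca_table(tree)
    node_index = {id(n): i for i, n in enumerate(tree.postorder())}

    def effective_event(node: TreeNode) -> str:
        if node.event == EVENT_DUBIOUS:
            return EVENT_DUPLICATION
        return node.event

    def is_dubious(node: TreeNode) -> bool:
        if node.event == EVENT_DUBIOUS:
            return True
        if node.event == EVENT_DUPLICATION and node.dcs is not None:
            return node.dcs < dcs_threshold
        return False

    # speciation partners: species -> per gene, species of speciation-mediated matches
    speciation_partner_species: dict[str, set[str]] = {
        leaf.gene_id: set() for leaf in leaves
    }
    raw_pairs: list[tuple[TreeNode, TreeNode, TreeNode, str]] = []
    for i, a in enumerate(leaves):
        for b in leaves[i + 1 :]:
            node = lca[(id(a), id(b))]
            event = effective_event(node)
            if a.species_id != b.species_id and event == EVENT_SPECIATION:
                speciation_partner_species[a.gene_id].add(b.species_id)
                speciation_partner_species[b.gene_id].add(a.species_id)
            raw_pairs.append((a, b, node, event))

    accepted: list[tuple[TreeNode, TreeNode, TreeNode, str]] = []
    within: list[tuple[TreeNode, TreeNode, TreeNode]] = []
    for a, b, node, event in raw_pairs:
        if a.species_id == b.species_id:
            if event == EVENT_DUPLICATION:
                within.append((a, b, node))
            continue
        if event == EVENT_SPECIATION:
            accepted.append((a, b, node, "speciation"))
        elif dcs_threshold > 0 and is_dubious(node):
            a_free = b.species_id not in speciation_partner_species[a.gene_id]
            b_free = a.species_id not in speciation_partner_species[b.gene_id]
            if a_free and b_free:
                accepted.append((a, b, node, "dubious_duplication"))

    # cross-species degree over accepted orthologues (rescued pairs included)
    degree: dict[tuple[str, str], int] = {}
    for a, b, _node, _kind in accepted:
        degree[(a.gene_id, b.species_id)] = degree.get((a.gene_id, b.species_id), 0) + 1
        degree[(b.gene_id, a.species_id)] = degree.get((b.gene_id, a.species_id), 0) + 1

    pairs: list[HomologyPair] = []
    for a, b, node, kind in accepted:
        da = degree[(a.gene_id, b.species_id)]
        db = degree[(b.gene_id, a.species_id)]
        if da == 1 and db == 1:
            cls = CLASS_ONE2ONE
        elif da == 1 or db == 1:
            cls = CLASS_ONE2MANY
        else:
            cls = CLASS_MANY2MANY
        pairs.append(
            HomologyPair(
                gene1=a.gene_id,
                gene2=b.gene_id,
                species1=a.species_id,
                species2=b.species_id,
                cls=cls,
                node_id=node_index[id(node)],
                node_event=kind,
                dcs=node.dcs,
            )
        )
    for a, b, node in within:
        pairs.append(
            HomologyPair(
                gene1=a.gene_id,
                gene2=b.gene_id,
                species1=a.species_id,
                species2=b.species_id,
                cls=CLASS_WITHIN_PARALOG,
                node_id=node_index[id(node)],
                node_event="duplication",
                dcs=node.dcs,
            )
        )
    pairs.sort(key=lambda p: (p.gene1, p.gene2))
    return pairs


def homology_table(pairs: Sequence[HomologyPair]) -> pd.DataFrame:
    """Full pair listing as a DataFrame (TSV-ready)."""
    cols = ["gene1", "species1", "gene2", "species2", "class", "node_id", "node_event", "dcs"]
    rows = [
        (p.gene1, p.species1, p.gene2, p.species2, p.cls, p.node_id, p.node_event, p.dcs)
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=cols)


def pair_counts(pairs: Sequence[HomologyPair]) -> pd.DataFrame:
    """Per species-pair counts of each homology class."""
    counts: dict[tuple[str, str, str], int] = {}
    for p in pairs:
        s1, s2 = sorted((p.species1, p.species2))
        key = (s1, s2, p.cls)
        counts[key] = counts.get(key, 0) + 1
    rows = [
        {"species1": s1, "species2": s2, "class": cls, "n_pairs": n}
        for (s1, s2, cls), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["species1", "species2", "class", "n_pairs"])


# ---------------------------------------------------------------------------
# Synteny-based QC
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "gene_id",
    "type",
    "chromosome",
    "start",
    "end",
    "strand",
    "host_gene",
]


def read_annotation_table(path) -> pd.DataFrame:
    """Read a BED-like TSV annotation table (1-based inclusive coordinates)."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table misses columns {sorted(missing)}")
    bad = df[df["start"] > df["end"]]
    if len(bad):
        raise ValueError("annotation table has start > end rows")
    return df


def _interval_gap(s1: int, e1: int, s2: int, e2: int) -> int:
    """Gap in bp between two 1-based inclusive intervals; 0 when overlapping."""
    if e1 < s2:
        return s2 - e1 - 1
    if e2 < s1:
        return s1 - e2 - 1
    return 0


@dataclass
class SyntenySummary:
    intronic_supported: int
    intronic_total: int
    window_supported: int
    window_total: int
    skipped: int

    @property
    def intronic_fraction(self) -> float:
        return self.intronic_supported / self.intronic_total if self.intronic_total else 0.0

    @property
    def window_fraction(self) -> float:
        return self.window_supported / self.window_total if self.window_total else 0.0


def synteny_support(
    pairs: Sequence[HomologyPair],
    annotations: dict[str, pd.DataFrame],
    protein_pairs: Sequence[HomologyPair],
    window: int = 5000,
) -> tuple[pd.DataFrame, SyntenySummary]:
    """Synteny QC of ncRNA orthologue calls against protein orthologues.

    Returns a per-pair flag table and summary fractions.  Pairs whose genes
    lack coordinates are skipped and counted.  Distance is measured between
    gene boundaries, strand-agnostic; a pair at exactly ``window`` bp is
    still supported, one at ``window + 1`` is not.
    """
    ann_by_gene: dict[str, dict] = {}
    for species, table in annotations.items():
        for row in table.itertuples(index=False):
            ann_by_gene[row.gene_id] = {
                "species": species,
                "chromosome": row.chromosome,
                "start": int(row.start),
                "end": int(row.end),
                "host_gene": None if pd.isna(row.host_gene) else row.host_gene,
            }

    protein_by_class: dict[str, set[frozenset]] = {}
    protein_members: dict[str, list[tuple[str, str]]] = {}
    for p in protein_pairs:
        if p.cls == CLASS_WITHIN_PARALOG:
            continue
        protein_by_class.setdefault(p.cls, set()).add(frozenset((p.gene1, p.gene2)))
        protein_members.setdefault(p.cls, []).append((p.gene1, p.gene2))

    rows = []
    intronic_supported = intronic_total = 0
    window_supported = window_total = 0
    skipped = 0
    for p in pairs:
        if p.cls == CLASS_WITHIN_PARALOG:
            continue
        a1 = ann_by_gene.get(p.gene1)
        a2 = ann_by_gene.get(p.gene2)
        if a1 is None or a2 is None:
            skipped += 1
            continue
        intronic = False
        near = False
        host1, host2 = a1["host_gene"], a2["host_gene"]
        same_class_pairs = protein_by_class.get(p.cls, set())
        if host1 and host2:
            intronic_total += 1
            intronic = frozenset((host1, host2)) in same_class_pairs
            intronic_supported += int(intronic)
        else:
            window_total += 1
            for g1, g2 in protein_members.get(p.cls, []):
                for pg1, pg2 in ((g1, g2), (g2, g1)):
                    b1 = ann_by_gene.get(pg1)
                    b2 = ann_by_gene.get(pg2)
                    if b1 is None or b2 is None:
                        continue
                    if b1["species"] != a1["species"] or b2["species"] != a2["species"]:
                        continue
                    if (
                        b1["chromosome"] == a1["chromosome"]
                        and b2["chromosome"] == a2["chromosome"]
                        and _interval_gap(
                            a1["start"], a1["end"], b1["start"], b1["end"]
                        )
                        <= window
                        and _interval_gap(
                            a2["start"], a2["end"], b2["start"], b2["end"]
                        )
                        <= window
                    ):
                        near = True
                        break
                if near:
                    break
            window_supported += int(near)
        rows.append(
            {
                "gene1": p.gene1,
                "gene2": p.gene2,
                "class": p.cls,
                "intronic": bool(host1 and host2),
                "supported": intronic if (host1 and host2) else near,
            }
        )
    summary = SyntenySummary(
        intronic_supported, intronic_total, window_supported, window_total, skipped
    )
    return pd.DataFrame(rows), summary
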