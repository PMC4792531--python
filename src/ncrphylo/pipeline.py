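"""Per-family orchestration and the pipeline's scalar filtering rules.

``run_family`` drives one gene family end to end: size filter, optional
splitting of very large families, duplication-loss rooting of every input
tree, multi-tree merging, reconciliation with duplication confidence
scoring, orthologue/paralogue inference and K-score ranking of the inputs.
Stage outputs are collected in a JSON-serialisable report; a failure in one
family never affects the others.

Scalar rules (defaults follow the production pipeline): families need at
least 3 genes; split groups are capped at 400 genes; fast mode triggers
strictly above 150 kb of input sequence; duplications with confidence below
0.25 are dubious; the synteny window is 5 kb; genomic flanks extend a gene
by twice its length on both sides (a 5L window in total).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

from .tree import GeneTree, SpeciesTree, write_newick
from .reconciliation import annotate_tree, reconcile, root_by_dl
from .merge import mmerge
from .homology import infer_homologies, pair_counts
from .supertree import assemble_supertree, needs_fast_mode, split_family
from .treedist import rank_trees

__all__ = [
    "PipelineConfig",
    "FamilyInput",
    "filter_family",
    "select_best_copy",
    "flank_region",
    "run_family",
]


@dataclass
class PipelineConfig:
    min_family_size: int = 3
    max_group_size: int = 400
    fast_mode_threshold: int = 150_000  # bp
    dcs_threshold: float = 0.25
    synteny_window: int = 5_000  # bp
    flank_factor: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_family_size",
            "max_group_size",
            "fast_mode_threshold",
            "dcs_threshold",
            "synteny_window",
            "flank_factor",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class FamilyInput:
    family_id: str
    intermediate_trees: list[tuple[str, GeneTree]]
    total_sequence_length: int = 0


def filter_family(genes: Sequence[str], min_family_size: int = 3) -> bool:
    """True when the family is large enough to proceed (>= 3 genes)."""
    return len(genes) >= min_family_size


def select_best_copy(copies: Sequence[tuple[str, float]]) -> str:
    """Pick the copy at the locus with the highest sequence identity.

    Used to deduplicate redundant annotations in fragmented assemblies.
    Ties go to the lexicographically smallest gene id.
    """
    if not copies:
        raise ValueError("no copies to choose from")
    return min(copies, key=lambda c: (-c[1], c[0]))[0]


def flank_region(
    gene: tuple[str, int, int, str],
    chrom_length: int,
    factor: float = 2.0,
) -> tuple[str, int, int]:
    """Extend a gene by ``factor`` times its length on both sides.

    Coordinates are 1-based inclusive; the extension is strand-agnostic and
    clipped to the chromosome, giving a 5L window for the default factor 2.
    """
    chrom, start, end, _strand = gene
    if start > end:
        raise ValueError("start must be <= end")
    if start < 1 or end > chrom_length:
        raise ValueError("gene lies outside the chromosome")
    length = end - start + 1
    ext = int(round(factor * length))
    return chrom, max(1, start - ext), min(chrom_length, end + ext)


def run_family(
    family: FamilyInput,
    species_tree: SpeciesTree,
    config: Optional[PipelineConfig] = None,
) -> dict:
    """Run filter -> (split) -> root -> merge -> reconcile -> homologies -> ranking.

    Returns a JSON-serialisable report; on a stage failure the report records
    the stage and diagnostic instead of raising.
    """
    config = config or PipelineConfig()
    report: dict = {"family_id": family.family_id, "status": "ok", "stages": []}

    try:
        if not family.intermediate_trees:
            raise ValueError("no intermediate trees supplied")
        genes = sorted(family.intermediate_trees[0][1].gene_ids())
        report["n_genes"] = len(genes)
        if not filter_family(genes, config.min_family_size):
            report["status"] = "filtered"
            report["stages"].append(
                {"stage": "filter", "detail": f"{len(genes)} genes < {config.min_family_size}"}
            )
            return report
        report["stages"].append({"stage": "filter", "detail": "passed"})

        report["fast_mode"] = needs_fast_mode(
            family.total_sequence_length, config.fast_mode_threshold
        )

        rooted = [
            (label, root_by_dl(tree, species_tree))
            for label, tree in family.intermediate_trees
        ]
        report["stages"].append({"stage": "rooting", "detail": f"{len(rooted)} trees"})

        if len(genes) > config.max_group_size:
            guide = rooted[0][1]
            hierarchy = split_family(guide, config.max_group_size)
            subtrees = {}
            for cluster in hierarchy.clusters():
                cluster_inputs = [
                    (label, _restricted(tree, cluster)) for label, tree in rooted
                ]
                subtrees[cluster] = mmerge(cluster_inputs, species_tree)
            merged = assemble_supertree(hierarchy, subtrees)
            report["stages"].append(
                {"stage": "split", "detail": f"{len(hierarchy.clusters())} clusters"}
            )
        else:
            merged = mmerge(rooted, species_tree)
        report["stages"].append({"stage": "merge", "detail": "done"})

        recon = reconcile(merged, species_tree)
        annotate_tree(merged, recon, dcs_threshold=config.dcs_threshold)
        report["tree"] = write_newick(merged)
        report["n_duplications"] = recon.total_dup
        report["n_losses"] = recon.total_loss
        report["n_dubious"] = sum(
            1 for n in merged.postorder() if n.event == "dubious"
        )
        report["stages"].append({"stage": "reconcile", "detail": "done"})

        pairs = infer_homologies(merged, dcs_threshold=config.dcs_threshold)
        counts = pair_counts(pairs)
        report["homologies"] = {
            "pairs": [
                [p.gene1, p.gene2, p.cls] for p in pairs
            ],
            "class_counts": {
                cls: int(n)
                for cls, n in counts.groupby("class")["n_pairs"].sum().items()
            },
        }
        report["stages"].append({"stage": "homology", "detail": f"{len(pairs)} pairs"})

        ranking = rank_trees(
            merged, rooted, species_tree=None, family_id=family.family_id
        )
        report["ranking"] = [
            {
                "tree_label": r.tree_label,
                "k_factor": float(r.k_factor),
                "k_score": float(r.k_score),
                "rank": int(r.rank),
            }
            for r in ranking.itertuples(index=False)
        ]
        report["stages"].append({"stage": "kscore", "detail": "done"})
    except Exception as exc:  # per-family isolation
        report["status"] = "error"
        report["error"] = f"{type(exc).__name__}: {exc}"
    return report


def _restricted(tree: GeneTree, cluster: tuple[str, ...]) -> GeneTree:
    from .tree import restrict

    return restrict(tree, cluster)
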