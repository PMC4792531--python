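"""Birth-death gene gain/loss analysis of family-size profiles.

Gene family evolution is modelled as a linear birth-death process with equal
per-gene gain and loss rate λ (per gene per million years) along an
ultrametric species tree with integer branch lengths in millions of years.
The transition kernel for a parent count s evolving for time t is

    alpha = λt / (1 + λt)
    P(c | s, t) = sum_{j=0}^{min(s,c)} C(s, j) C(s+c-j-1, s-1)
                  alpha^(s+c-2j) (1 - 2 alpha)^j

with P(c | 0, t) = [c == 0] (an extinct family stays extinct).  The
parameterisation requires alpha < 1/2, i.e. it is valid for all finite λt.

Family likelihoods are evaluated by the pruning algorithm with ancestral
counts truncated at ``n_max``; the global λ is estimated by bounded 1-D
maximum likelihood over all families whose species span the root of the
tree, with an iterative exclusion of outlier families when the likelihood is
maximised at the search boundary.  Per-branch expansions and contractions
are called from the most probable (max-product) ancestral counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, log
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .tree import GeneTree, SpeciesTree, TreeNode

__all__ = [
    "FamilyProfile",
    "GainLossModel",
    "make_ultrametric",
    "transition_prob",
    "transition_matrix",
    "family_loglik",
    "profiles_loglik",
    "root_presence_filter",
    "estimate_lambda",
    "expansions_contractions",
    "gain_loss_summary",
    "read_profile_table",
]


@dataclass
class FamilyProfile:
    """Gene counts per extant species for one family."""

    family_id: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")
        if not any(c > 0 for c in self.counts.values()):
            raise ValueError("profile needs at least one positive count")

    def max_count(self) -> int:
        return max(self.counts.values())

    def present_species(self) -> set[str]:
        return {s for s, c in self.counts.items() if c > 0}


@dataclass
class GainLossModel:
    """A fitted (or fixed) equal-rate birth-death model on a species tree."""

    lam: float  # rate per gene per million years
    tree: SpeciesTree
    n_max: int
    root_prior: Optional[np.ndarray] = None  # over counts 0..n_max; default uniform 1..n_max
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.root_prior is None:
            prior = np.zeros(self.n_max + 1)
            prior[1:] = 1.0 / self.n_max
            self.root_prior = prior

    def matrix(self, t: float) -> np.ndarray:
        key = (round(t, 9), self.n_max)
        if key not in self._cache:
            self._cache[key] = transition_matrix(self.n_max, t, self.lam)
        return self._cache[key]


def make_ultrametric(
    species_tree: SpeciesTree, node_ages: dict[str, float]
) -> SpeciesTree:
    """Set branch lengths from node ages (millions of years).

    Each branch gets ``parent age - child age`` rounded to the nearest
    integer, floored at 1 My; pre-rounding root-to-leaf sums are equal by
    construction when leaf ages are equal.  Leaves missing from
    ``node_ages`` default to age 0.
    """
    out = species_tree.copy()
    for node in out.preorder():
        if node.parent is None:
            continue
        child_age = node_ages.get(node.label, 0.0 if node.is_leaf else None)
        parent_age = node_ages.get(node.parent.label)
        if child_age is None or parent_age is None:
            raise KeyError(f"missing age for {node.label!r} or its parent")
        if parent_age <= child_age:
            raise ValueError(
                f"non-positive branch implied at {node.label!r}: "
                f"parent age {parent_age} <= child age {child_age}"
            )
        node.length = max(1, round(parent_age - child_age))
    out.prepare()
    return out


def _alpha(t: float, lam: float) -> float:
    if t < 0:
        raise ValueError("time must be non-negative")
    a = lam * t / (1.0 + lam * t)
    if a >= 0.5:
        raise ValueError("lambda * t too large: alpha >= 0.5")
    return a


def transition_prob(s: int, c: int, t: float, lam: float) -> float:
    """P(child count = c | parent count = s) after time t at rate ``lam``."""
    if s < 0 or c < 0:
        raise ValueError("counts must be non-negative")
    if s == 0:
        return 1.0 if c == 0 else 0.0
    a = _alpha(t, lam)
    if a == 0.0:
        return 1.0 if c == s else 0.0
    total = 0.0
    for j in range(min(s, c) + 1):
        total += (
            comb(s, j)
            * comb(s + c - j - 1, s - 1)
            * a ** (s + c - 2 * j)
            * (1.0 - 2.0 * a) ** j
        )
    return total


# The binomial prefactors of the kernel do not depend on t or lambda; they
# are cached per truncation size (bounded cache: the tensors are O(n_max^3)).
_BINOM_CACHE: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _binomial_tensor(n_max: int):
    if n_max in _BINOM_CACHE:
        return _BINOM_CACHE[n_max]
    from scipy.special import gammaln

    lg = gammaln(np.arange(3 * n_max + 2) + 1.0)  # log k!
    idx = np.arange(n_max + 1)
    s = idx[1:, None, None]
    c = idx[None, :, None]
    j = idx[None, None, :]
    valid = j <= np.minimum(s, c)
    js = np.where(valid, j, 0)
    # log C(s, j) + log C(s+c-j-1, s-1)
    logbin = (
        lg[s] - lg[js] - lg[s - js]
        + lg[s + c - js - 1] - lg[s - 1] - lg[c - js]
    )
    exponent = (s + c - 2 * j).astype(float)
    if len(_BINOM_CACHE) >= 2:
        _BINOM_CACHE.pop(next(iter(_BINOM_CACHE)))
    _BINOM_CACHE[n_max] = (logbin, exponent, valid)
    return _BINOM_CACHE[n_max]


def transition_matrix(n_max: int, t: float, lam: float) -> np.ndarray:
    """Dense kernel P[s, c] for s, c in 0..n_max.

    Vectorised evaluation of the same sum as :func:`transition_prob`
    (log-binomials, with t/lambda-independent factors cached); agreement
    with the scalar form is at machine precision.
    """
    a = _alpha(t, lam)
    if a == 0.0:
        return np.eye(n_max + 1)
    logbin, exponent, valid = _binomial_tensor(n_max)
    j = np.arange(n_max + 1)[None, None, :].astype(float)
    logterm = np.where(
        valid, logbin + exponent * log(a) + j * np.log1p(-2 * a), -np.inf
    )
    terms = np.exp(logterm)
    m = np.zeros((n_max + 1, n_max + 1))
    m[1:, :] = terms.sum(axis=2)
    m[0, 0] = 1.0
    return m


def _leaf_order(tree: SpeciesTree) -> list[str]:
    return tree.taxa()


def profiles_loglik(
    profiles: Sequence[FamilyProfile], model: GainLossModel
) -> np.ndarray:
    """Vectorised pruning log-likelihood for many families at once.

    All families share the species tree; the dynamic-programming vectors are
    stacked so each species-tree node is visited once.  Species missing from
    a profile count as 0 genes.
    """
    n_max = model.n_max
    for p in profiles:
        if p.max_count() > n_max:
            raise ValueError(
                f"n_max={n_max} below maximum observed count for {p.family_id}"
            )
    nf = len(profiles)
    partial: dict[int, np.ndarray] = {}
    for node in model.tree.postorder():
        if node.is_leaf:
            vec = np.zeros((nf, n_max + 1))
            for i, p in enumerate(profiles):
                vec[i, p.counts.get(node.label, 0)] = 1.0
            partial[id(node)] = vec
        else:
            acc = np.ones((nf, n_max + 1))
            for child in node.children:
                m = model.matrix(child.length)  # (s, c)
                acc *= partial.pop(id(child)) @ m.T
            partial[id(node)] = acc
    root_vec = partial[id(model.tree.root)]
    lik = root_vec @ model.root_prior
    with np.errstate(divide="ignore"):
        return np.log(lik)


def family_loglik(
    profile: FamilyProfile,
    model: GainLossModel,
    root_prior: Optional[np.ndarray] = None,
) -> float:
    """Pruning log-likelihood of one family profile under the model."""
    if root_prior is not None:
        model = GainLossModel(
            lam=model.lam, tree=model.tree, n_max=model.n_max, root_prior=root_prior
        )
    return float(profiles_loglik([profile], model)[0])


def root_presence_filter(
    profiles: Iterable[FamilyProfile], tree: SpeciesTree
) -> list[FamilyProfile]:
    """Keep families whose present species span the species-tree root."""
    tree.prepare()
    kept = []
    for p in profiles:
        present = p.present_species() & set(tree.taxa())
        if not present:
            continue
        if tree.lca_of_taxa(present) is tree.root:
            kept.append(p)
    return kept


def default_n_max(profiles: Sequence[FamilyProfile]) -> int:
    observed = max((p.max_count() for p in profiles), default=1)
    return max(10, 4 * observed)


def _lambda_upper_bound(tree: SpeciesTree, alpha_cap: float = 0.45) -> float:
    t_max = max(n.length for n in tree.postorder() if n.parent is not None)
    # alpha < cap  <=>  lam < cap / ((1 - cap) t)
    return alpha_cap / ((1.0 - alpha_cap) * t_max)


def estimate_lambda(
    profiles: Sequence[FamilyProfile],
    tree: SpeciesTree,
    n_max: Optional[int] = None,
    lam_bounds: Optional[tuple[float, float]] = None,
    max_excluded_fraction: float = 0.2,
) -> tuple[float, list[str], GainLossModel, np.ndarray]:
    """Maximum-likelihood global λ with iterative outlier exclusion.

    Maximises the summed pruning log-likelihood over a bounded interval.
    When the maximum sits at a boundary (no interior optimum) the family with
    the lowest per-family log-likelihood at that boundary is excluded and the
    search repeats; exclusions stop at 20% of the input families.  The final
    model scores *all* root-present input families at the estimated λ.

    Returns (lambda_hat, excluded family ids, fitted model, per-family
    log-likelihoods for all input profiles at lambda_hat).
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to fit")
    if n_max is None:
        n_max = default_n_max(profiles)
    lo, hi = lam_bounds if lam_bounds is not None else (1e-8, _lambda_upper_bound(tree))

    def total_ll(lam: float, prof: Sequence[FamilyProfile]) -> float:
        model = GainLossModel(lam=lam, tree=tree, n_max=n_max)
        ll = profiles_loglik(prof, model)
        return float(np.sum(ll))

    working = list(profiles)
    excluded: list[str] = []
    max_excl = int(max_excluded_fraction * len(profiles))
    lam_hat: Optional[float] = None
    while True:
        res = minimize_scalar(
            lambda lam: -total_ll(lam, working),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        lam_hat = float(res.x)
        span = hi - lo
        interior = lo + 1e-3 * span < lam_hat < hi - 1e-3 * span
        if interior:
            break
        if len(excluded) >= max_excl:
            raise RuntimeError(
                "lambda not maximised in the interior after excluding "
                f"{len(excluded)} families"
            )
        boundary_lam = lam_hat
        model = GainLossModel(lam=boundary_lam, tree=tree, n_max=n_max)
        per_family = profiles_loglik(working, model)
        worst = int(np.argmin(per_family))
        excluded.append(working[worst].family_id)
        working.pop(worst)

    model = GainLossModel(lam=lam_hat, tree=tree, n_max=n_max)
    all_ll = profiles_loglik(profiles, model)
    return lam_hat, excluded, model, all_ll


def expansions_contractions(
    profile: FamilyProfile, model: GainLossModel
) -> tuple[dict[str, int], dict[str, str]]:
    """Most probable ancestral counts and per-branch expansion labels.

    Max-product dynamic programming over ancestral counts, ties broken
    towards the smallest count.  Returns (node label -> count, child node
    label -> 'expanded' | 'contracted' | 'unchanged').  Internal nodes
    without labels are named by their postorder index.
    """
    n_max = model.n_max
    tree = model.tree
    names: dict[int, str] = {}
    for i, node in enumerate(tree.postorder()):
        names[id(node)] = node.label if node.label is not None else f"node{i}"

    up: dict[int, np.ndarray] = {}
    back: dict[int, np.ndarray] = {}  # per child: argmax c for each parent s
    for node in tree.postorder():
        if node.is_leaf:
            vec = np.full(n_max + 1, -np.inf)
            vec[profile.counts.get(node.label, 0)] = 0.0
            up[id(node)] = vec
        else:
            acc = np.zeros(n_max + 1)
            for child in node.children:
                with np.errstate(divide="ignore"):
                    logm = np.log(model.matrix(child.length))
                scores = logm + up[id(child)][None, :]  # (s, c)
                best_c = np.argmax(scores, axis=1)  # first max = smallest count
                back[id(child)] = best_c
                acc += scores[np.arange(n_max + 1), best_c]
            up[id(node)] = acc

    with np.errstate(divide="ignore"):
        root_scores = np.log(model.root_prior) + up[id(tree.root)]
    counts: dict[str, int] = {}
    assign: dict[int, int] = {}
    root_count = int(np.argmax(root_scores))
    assign[id(tree.root)] = root_count
    counts[names[id(tree.root)]] = root_count
    labels: dict[str, str] = {}
    for node in tree.preorder():
        if node.parent is None:
            continue
        s = assign[id(node.parent)]
        if node.is_leaf:
            c = profile.counts.get(node.label, 0)
        else:
            c = int(back[id(node)][s])
        assign[id(node)] = c
        counts[names[id(node)]] = c
        if c > s:
            labels[names[id(node)]] = "expanded"
        elif c < s:
            labels[names[id(node)]] = "contracted"
        else:
            labels[names[id(node)]] = "unchanged"
    return counts, labels


def gain_loss_summary(
    profiles: Sequence[FamilyProfile], model: GainLossModel
) -> pd.DataFrame:
    """Per-branch counts of expanded / contracted / unchanged families."""
    tally: dict[str, dict[str, int]] = {}
    for p in profiles:
        _counts, labels = expansions_contractions(p, model)
        for branch, label in labels.items():
            rec = tally.setdefault(
                branch, {"expanded": 0, "contracted": 0, "unchanged": 0}
            )
            rec[label] += 1
    rows = [
        {"branch": b, **rec}
        for b, rec in sorted(tally.items())
    ]
    return pd.DataFrame(rows, columns=["branch", "expanded", "contracted", "unchanged"])


def read_profile_table(path) -> list[FamilyProfile]:
    """Read a family x species count table (TSV, first column family_id)."""
    df = pd.read_csv(path, sep="\t")
    fam_col = df.columns[0]
    species = list(df.columns[1:])
    out = []
    for _, row in df.iterrows():
        counts = {sp: int(row[sp]) for sp in species}
        out.append(FamilyProfile(family_id=str(row[fam_col]), counts=counts))
    return out
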