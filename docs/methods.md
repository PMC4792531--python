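# Methods

This note documents the models and algorithmic choices behind `ncrphylo`,
the defaults that matter, and what the synthetic benchmark does and does not
show. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Reconciliation model

Gene trees are reconciled against a rooted species tree by LCA mapping:
`m(v)` is the most recent species-tree node containing every species below
`v`. Event labelling follows duplication–loss parsimony with one deliberate
refinement: multifurcating species-tree nodes are treated as **soft
polytomies**. A node is labelled a duplication only when two of its children
draw on a common child lineage of `m(v)`; on a binary species tree (with
binary gene trees) this is provably equivalent to the classical criterion
"`m(v)` equals the mapping of some child". The refinement matters because
the pipeline deliberately flattens densely sampled clades of the species
tree (see below): under the naive criterion *any* resolved structure inside
a flattened clade would map to the polytomy itself and be mis-called a
duplication with confidence 0, which is precisely what flattening is meant
to prevent.

Losses on an edge `u → v` are `pathlen(m(u), m(v)) − 1`, plus one if `u` is
a duplication whose mapping differs from `m(v)`, and zero when the mappings
coincide. A multifurcation counts as a single level: descending through it
charges one path step and never bills the uninvolved sister lineages as
losses. When a duplication lies above a flattened clade we do not re-expand
the clade to count interior losses at finer resolution; this is one
consistent reading of the flattening contract and is applied uniformly.

**Rooting** evaluates every edge of the unrooted topology, reconciles, and
keeps the rooting with the smallest duplications + losses total. Branch
lengths are ignored. Ties are broken by the lexicographically smallest
sorted gene list on the smaller side of the root split, so rooting is
deterministic and order-independent.

**Duplication confidence (DCS)** is the intersection over union of the two
child species sets. For a multifurcating duplication node the intersection
generalises to "species present in at least two children", which reduces to
the usual definition for two children and keeps species-specific
duplications at exactly 1.0. Duplications with DCS below the configurable
threshold (default 0.25) are re-labelled *dubious* for reporting and for the
homology rescue rule; reconciliation totals still count them as
duplications.

**Species-tree simplification** replaces a named clade by one multifurcating
node over its leaves (leaf branch lengths become clade-root-to-leaf path
sums). The regression property checked by the tests is that flattening never
increases the number of DCS = 0 duplication calls on simulated families.

## Merging

`mmerge` builds one binary tree from up to 17 rooted inputs over the same
gene set by recursive bipartitioning. At each gene set G the candidates are
exactly the splits of G induced by the root of each input restricted to G
(each child-versus-rest split when the restricted root is multifurcating) —
never splits absent from every input. Ranking: speciation before
duplication, then fewer losses on the two branches leaving the split (not
whole-subtree losses), then larger maximum bootstrap among supporting nodes
(absent bootstraps count 0), then the lexicographic tie-break used
everywhere else. Supporters of the winning split are recorded on the two
branches it creates. Inputs are assumed rooted; the pipeline roots them with
the duplication–loss rooter first. Branch lengths of the merged tree are
copied as medians of the supporting inputs' lengths and are explicitly
approximate — consumers needing calibrated lengths should re-estimate them.

## K tree score

Trees are compared on the bipartition sets of their unrooted versions,
terminal branches included; a branch present in one tree only is paired with
length 0. The scale factor `K = Σ b_ref·b_comp / Σ b_comp²` is the exact
least-squares minimiser, and the score is the unnormalised root of the
residual sum of squares. We deliberately skip any division by branch count:
the score's use here is ranking input trees against the merged tree, which
is invariant under a global monotone normalisation. Comparing trees whose
leaf sets differ is out of scope.

## Homology inference

For every unordered gene pair the tree LCA decides: same species +
duplication → within-species paralogue; different species + speciation →
orthologue; different species + dubious duplication → orthologue **only if
both** genes lack a speciation-mediated partner in the other's species (the
strictest symmetric reading of "no better match"; the one-sided alternative
would also accept pairs where only one gene is matchless). Rescued pairs
enter the same degree counts as ordinary orthologues, and classes are
assigned from the cross-species degrees: one2one (both 1), one2many (exactly
one greater than 1), many2many (both greater).

Synteny QC compares ncRNA orthologue pairs with protein orthologue pairs of
the same class: *intronic* support requires both ncRNAs to sit inside host
genes that are themselves a same-class protein pair; otherwise *window*
support requires a same-class protein pair with one member within 5 kb
(boundary-to-boundary gap, strand-agnostic, ≤ 5000 bp inclusive) of each
ncRNA. Coordinates are 1-based inclusive throughout.

## Birth–death gain/loss model

Family sizes evolve by an equal-rate linear birth–death process (rate λ per
gene per million years for gain and for loss). The transition kernel, with
`α = λt/(1+λt)`:

    P(c|s,t) = Σ_{j=0}^{min(s,c)} C(s,j) C(s+c−j−1, s−1) α^(s+c−2j) (1−2α)^j,
    P(c|0,t) = [c = 0].

The tests verify this closed form against the truncated matrix exponential
of the birth–death generator to 1e-6. The matrix evaluator caches the
t/λ-independent log-binomial tensor per truncation size, so likelihood
optimisation rebuilds only the α-dependent factors.

Likelihood uses post-order pruning with ancestral counts truncated at
`n_max` (default `max(10, 4 × max observed count)`; the truncation-stability
test shows log-likelihood changes below 1e-8 past that point) and a uniform
root prior over 1..n_max (configurable; the point is that families absent at
the root are excluded upstream by the root-presence filter, which keeps only
profiles whose present species span the species-tree root).

λ is estimated by bounded 1-D maximum likelihood; the upper bound keeps
`α < 0.45` on the longest branch. If the optimum sits at a boundary, the
family with the lowest per-family log-likelihood at that boundary is
excluded and the search repeats, up to 20% of the input families — an
operationalisation of iterative outlier removal; the final model scores all
root-present families at the estimated λ. Ancestral counts for
expansion/contraction calls come from max-product dynamic programming with
ties resolved towards the smaller count.

The benchmark species tree for gain/loss is a six-taxon dated mammal tree
(human, chimp, marmoset, mouse, dog, opossum; root at 160 My). A
mammal-depth tree keeps `α` comfortably below the kernel's validity bound at
the benchmark rate λ = 0.002 while remaining realistically calibrated;
deeper vertebrate splits would push `λt` outside the parameterisation.

## Synthetic benchmark

The generators emulate the conditions the pipeline is designed for:

* **Gene trees** evolve forward in time inside a dated 12-taxon mammal
  species tree: lineages duplicate at 0.002 and die at 0.001 events per
  lineage per My, and split at speciations. True duplication nodes and loss
  counts are logged, so recovery statistics use planted ground truth rather
  than re-inference.
* **Intermediate trees** are noisy copies: by default 1 nearest-neighbour
  interchange (performed on proper internal edges of the *unrooted*
  topology, so a move always changes the topology) and log-normal
  branch-length noise with sd 0.1; five intermediates per family. Bootstrap
  values are high (85–100) on clades also present in the source tree and low
  (20–60) on rearranged ones, mimicking the signal the merger's tie-break
  consumes.
* **Family-size profiles** draw a root count uniformly from 1–5 and then
  sample the exact transition kernel down each branch at λ = 0.002, so
  estimator recovery is measured against the model's own data-generating
  process.
* **Synteny fixtures** plant an exact, seed-deterministic fraction of
  supported pairs (alternating intronic and 5 kb-window placements) with the
  remainder at least 20 kb from any protein.

One integer seed drives independent per-generator substreams
(`SeedSequence([seed, stream])`), so adding a generator never perturbs
existing fixtures and all outputs are bit-reproducible.

What passing these benchmarks does **not** show: the generator produces
clock-like branch lengths, no alignment-level noise, no annotation bias
across species, no assembly artefacts, and perturbations are uniform NNIs
rather than the correlated errors real tree inference makes. Results on real
ncRNA families depend on those factors; the benchmarks validate the
algorithms, not the upstream inference.

## Problem sizes and verification scales

The test suite checks reconciliation events, losses and optimal rootings
against brute-force oracles exhaustively over **all** rooted topologies with
up to 8 leaves (events/losses; ~147k trees) and up to 6 leaves plus random
7–8-leaf samples (rooting) on a fixed 5-taxon species tree. Merge supporter
claims are re-verified on 200 randomized cases. End-to-end orthologue
recovery uses 50 simulated families; λ recovery uses 20 replicates of 500
families. `scripts/acceptance.py` re-runs the same computations from
scratch at those sizes in a few seconds.

## Numerical and formatting choices

Branch lengths serialize as fixed-point decimals with trailing zeros
trimmed; round-trips are exact to 1e-9. Negative NJ branch estimates are
clamped to zero; NJ ties take the smallest active index pair; the guide tree
for family splitting is midpoint-rooted (deterministic and balanced) and cut
top-down at clade roots until every cluster holds at most 400 genes. All
tie-breaks throughout (rooting, merging, ranking, ancestral counts) are
deterministic, which is what makes the full pipeline byte-identical across
runs with one seed.

## Known limitations

* One global λ; per-branch rates are not estimated.
* No probabilistic reconciliation, transfer events, or rearrangement-based
  tree correction.
* K-score comparison requires identical leaf sets.
* Merged branch lengths are medians of inputs, not re-estimated likelihood
  lengths.
* The "no better match" rescue is the two-sided reading; the one-sided
  alternative is noted above but not implemented.
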