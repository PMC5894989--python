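# Methods

This note records the models, conventions and design choices behind
`edgeprior`, the assumptions they rest on, and what the synthetic fixtures
do and do not establish about real data.

## Fair-proportion ED and PD

A phylogeny is a rooted tree with finite, non-negative branch lengths in
Myr; leaves are species, polytomies are allowed, internal labels ignored.
PD is the sum of all branch lengths, including a root edge when one is
present. ED divides each branch equally among the leaves below it; a root
edge is divided among all leaves, consistent with the per-edge rule. Two
identities follow and are property-tested: Σ ED = PD (to 1e-6 relative),
and ED ≥ terminal branch length for every species.

The implementation accumulates per-edge shares in one level-order sweep
over an array-backed tree view (`IndexedTree`). The same view evaluates ED
on any leaf subset without rebuilding a tree: pruning with degree-2
collapse never changes the partition relative to dividing each surviving
edge among its *retained* descendants, because a collapsed chain of edges
shares one descendant set. The removal experiment relies on this for speed.
Correctness of the subset evaluation is checked against actual
dendropy-pruned trees, and the full evaluation against both a brute-force
per-edge oracle and R `picante`'s fair-proportion implementation.

Over a tree distribution the per-species summary is the median (midpoint of
the central order statistics for even counts), since ED is right-skewed.
ED values are carried at full precision and rounded to 2 decimals only in
reports, so EDGE never compounds rounding error.

## Pruning and name matching

Trees are pruned to valid, extant, recognised species before any ED
computation, collapsing degree-2 nodes with lengths summed so every
retained leaf keeps its root-to-leaf path length (a stem above the retained
crown survives as a root edge). Leaf labels match taxonomy names exactly
after whitespace trimming, trying underscore and space variants both ways;
unmatched labels are treated as unrecognised and are reportable
(`match_leaves`) — the package never guesses synonymy.

## Imputation

A missing species is assigned the genus tier when ≥ 1 congener is sampled,
else the family tier when ≥ 1 confamiliar is, else it is unimputable (the
caller may substitute a published divergence time via
`substitute_terminal`, a deliberate lower bound on the species' ED). For a
group with n present members of total ED S and m missing members:

- `original`: present scores × n/(n+m); each missing species gets
  S/(n+m). The factor n/(n+m) is the unique proportional shrinkage that
  conserves the group total.
- `simple`: each missing species gets the mean ED of present congeners
  (confamiliars at family tier); present scores unchanged.
- `new`: score 1 is the base ED for present species and the `simple` value
  for missing ones; score 2 is the even split S/(n+m) for every group
  member; the final ED is the mean of the two. Untouched groups are the
  identity (both scores coincide).

Two conventions were genuinely open and are resolved as follows. Family-
tier n and S count **all** present confamilial species. A present species
is corrected at the **finest** tier in which it has missing relatives:
genus when its own genus is incomplete; family only when its genus is
complete but the family has wholly-missing genera. This avoids correcting
any species twice. The cost is a corner case: in a family that combines an
incomplete genus with a wholly-missing genus, the `original` method's
family-group total is conserved only approximately (genus groups are always
conserved exactly). The conservation tests therefore use disjoint-group
constructions, which is also the regime the hand-worked contracts cover.

## EDGE scoring and robustness

EDGE = ln(1 + ED) + GE·ln 2 with GE: LC 0, NT 1, VU 2, EN 3, CR 4. DD, NE,
EX and EW species carry ED but no EDGE score; extinct species are removed
before ED is computed at all. An *EDGE species* is strictly above its
clade's median ED — the median is taken over every species with an ED
value, including DD/NE — and in a threatened category (VU/EN/CR).

Ranking sorts by EDGE descending with deterministic tie-breaks (ED
descending, then species name), so ranks are reproducible across the trees
of a distribution; that determinism is what makes the top-k intersection
(`robust_from_distribution`) meaningful. For single incomplete trees, a
top-k species is robust when its whole genus — whole family for monospecific
genera — is sampled, i.e. no score in its group was imputed. Multi-clade
lists pool only flagged EDGE species of independently-flagged clades and
re-rank the pool.

## Removal experiment

Per iteration, every genus of the (already pruned) tree loses a uniform-
random number of species between 1 and its size — singleton genera are
always removed entirely — the removed subset itself uniform. ED is
recomputed on the reduced tree and the removed species are re-imputed by
all three methods. One record is written per species per iteration:

- removed species carry their imputed scores, the tier used, and the
  proportion of their genus (or family) retained;
- retained species carry the score each method leaves them with on the
  reduced tree (recalculated ED under `simple`; corrected under `original`
  and `new`).

Correlation summaries pool **all** records — the methods' outputs are full
score tables, and their agreement with reference scores is a property of
the whole table; degrees of freedom are reported as N − 2. The captured-
proportion diagnostics (mean imputed/reference, and its OLS regression on
the proportion of the group retained, ideally slope 0 / intercept 1) use
the removed records only, since "captured" is defined for estimated
species. Removed species whose entire family was removed are unimputable:
they are recorded with missing values, excluded from summaries, and
counted. Randomness comes from one seed; per-iteration substreams are
spawned deterministically, so identical seeds give bitwise-identical
results.

Plain Pearson correlation on raw ED is leverage-sensitive: a few deep
lineages dominate it. That matches how such comparisons are usually
reported, but rank-based statistics would be the more robust choice; the
records table carries everything needed to compute them.

## Synthetic fixtures

The generator produces what the other modules need to be tested end to
end: a dated phylogeny whose statistical structure resembles published
consensus trees, a nested taxonomy, Red List draws, and a missingness mask.

- **Tree.** Birth–death (dendropy), conditioned on the extant species
  count, with defaults birth 0.1 / death 0.025 per Myr. Three optional
  shape controls, all on by default in `FixtureConfig`: heritable lineage
  rate variation (`birth_rate_sd = 0.02`) giving realistic imbalance
  (max/median ED of order 10, as in tetrapod trees); a fixed crown age of
  80 Myr (dated trees are calibrated to a known root age, and fixed-age
  taxonomy cuts need a stable timescale); and a stemminess exponent 0.7 on
  node ages (age′ = crown·(age/crown)^0.7), pushing splits rootward so
  terminal branches carry ~0.7 of a species' ED. Fully-sampled constant-
  rate trees put only ~0.5 of ED on terminals, which roughly doubles every
  remaining species' ED when half the tree is removed and makes group-mean
  imputation look far worse than it is on real, sparsely-sampled trees;
  the transform restores the pendant-dominated regime of published
  phylogenies. The rate-varying simulator occasionally emits a negative
  terminal stretch; the draw is then retried deterministically.
- **Taxonomy.** Genera and families are the maximal clades whose stems
  cross fixed cut ages (35 and 49 Myr on the transformed timescale),
  making both monophyletic by construction and group sizes naturally
  skewed. A cut just below the root yields one family per crown lineage —
  a crown tree cannot yield a single family under stem-crossing semantics.
- **Red List.** Independent categorical draws; the default composition is
  majority LC with a threatened minority and a sizeable DD/NE slice.
- **Mask.** `n_species` (default 900) is the full checklist; a uniform
  random `missing_fraction` (default 2/3) of species is masked out of the
  tree, leaving a ~300-leaf observed phylogeny — the coverage regime of the
  consensus trees the imputation methods were designed for. The mask is
  constrained (rejection sampling with a deterministic repair step) so that
  every family keeps at least one sampled species; real families are never
  known only from unsequenced species, and the constraint keeps every
  masked species imputable.

What passing tests on these fixtures shows: the estimators' directional
biases, their relative accuracy, and every exact contract hold on trees
with realistic imbalance, stemminess and sampling. What they do not show:
behaviour under clade-specific diversification dynamics, biased (non-
uniform) sampling of missing species, or taxonomies that conflict with the
tree — real checklists contain non-monophyletic genera, which the
generator never produces.

## Numerical conventions and degenerate inputs

Tolerances: conservation 1e-6 relative; oracle agreement 1e-9 absolute on
small trees; printed-value comparisons ±0.005 (2-decimal reports). Zero-
length edges contribute nothing and are legal; a single-leaf tree has no
fair-proportion partition and is an error, as is pruning below two leaves.
Zero-variance inputs to the correlation are an error rather than NaN.
Experiment iterations that would leave fewer than two leaves raise rather
than skip, so a degenerate configuration is loud.

## Problem sizes

Default test and validation sizes — 200 random trees of 10–200 leaves for
the conservation property, 100-iteration experiments on ~300-leaf observed
trees, 100 replicate experiments for the method comparison — were chosen so
the behavioural claims are tested with comfortable statistical margins
while the whole suite stays quick on a single CPU.
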