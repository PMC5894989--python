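"""Synthetic fixtures: dated trees with nested taxonomy, Red List draws,
and missingness masks.

The generator emulates the statistical structure of real inputs — an
ultrametric birth–death phylogeny in Myr, genera and families defined by
time-slicing the tree (so group sizes are naturally skewed, as in real
checklists where speciose genera are the ones with missing species),
independently sampled Red List categories dominated by Least Concern, and a
uniform-random missingness mask — so every other module is testable without
downloading published phylogenies.  Everything is seeded and deterministic.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from dendropy.model import birthdeath

from .exceptions import EdgePriorError, TreeError
from .phylo_io import RED_LIST_CATEGORIES, prune_to_labels

__all__ = [
    "FixtureConfig",
    "FixtureBundle",
    "DEFAULT_CATEGORY_PROBS",
    "simulate_tree",
    "assign_taxonomy",
    "sample_redlist",
    "mask_missing",
    "make_fixture",
]

# Loosely shaped like the tetrapod Red List composition: mostly Least
# Concern, a threatened minority, a sizeable Data Deficient / Not Evaluated
# slice, and a sliver of extinctions.  Structure, not contract.
DEFAULT_CATEGORY_PROBS = {
    "LC": 0.45, "NT": 0.08, "VU": 0.08, "EN": 0.07, "CR": 0.05,
    "DD": 0.15, "NE": 0.10, "EW": 0.005, "EX": 0.015,
}


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for one synthetic bundle.

    ``n_species`` is the size of the full species pool (the checklist); the
    observed phylogeny contains the unmasked ``(1 - missing_fraction)``
    share of it.  Rates are per lineage per Myr; cut ages in Myr before
    present (the family cut must be older than the genus cut).
    ``birth_rate_sd`` introduces heritable lineage rate variation (tree
    imbalance), ``crown_age`` fixes the root age of the dated tree, and
    ``stemminess`` (< 1) pushes splits rootward so that terminal branches
    carry a realistic share (~0.7) of each species' ED, as in published
    sparsely-sampled consensus phylogenies.
    """

    n_species: int = 900
    birth: float = 0.1
    death: float = 0.025
    birth_rate_sd: float = 0.02
    crown_age: float = 80.0
    stemminess: float = 0.7
    genus_cut: float = 35.0
    family_cut: float = 49.0
    category_probs: dict = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROBS)
    )
    missing_fraction: float = 2.0 / 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 4:
            raise EdgePriorError("n_species must be >= 4")
        if not self.family_cut > self.genus_cut > 0:
            raise EdgePriorError("need family_cut > genus_cut > 0")
        if not 0 <= self.missing_fraction < 1:
            raise EdgePriorError("missing_fraction must be in [0, 1)")
        if not 0 < self.stemminess <= 1:
            raise EdgePriorError("stemminess must be in (0, 1]")
        if self.crown_age is not None and not self.crown_age > 0:
            raise EdgePriorError("crown_age must be positive")
        total = sum(self.category_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise EdgePriorError(
                f"category probabilities sum to {total}, not 1"
            )


@dataclass(frozen=True)
class FixtureBundle:
    """One generated study system: the masked (observed) tree, the full tree
    it came from, taxonomy over all species, Red List categories, and the
    masked-out ('missing') species set."""

    tree: dendropy.Tree
    full_tree: dendropy.Tree
    taxonomy: pd.DataFrame
    redlist: pd.DataFrame
    missing: frozenset


def _apply_depth_transform(
    tree: dendropy.Tree, crown_age: float | None, stemminess: float
) -> None:
    """Rescale node ages to a fixed crown age and apply the stemminess
    transform ``age' = crown * (age/crown)**stemminess`` (< 1 pushes splits
    rootward, lengthening terminal branches).  Topology is untouched."""
    depth: dict[int, float] = {}
    for nd in tree.preorder_node_iter():
        depth[id(nd)] = (
            0.0
            if nd.parent_node is None
            else depth[id(nd.parent_node)] + (nd.edge.length or 0.0)
        )
    height = max(depth[id(l)] for l in tree.leaf_node_iter())
    crown = crown_age if crown_age is not None else height
    age = {
        k: crown * (max(height - d, 0.0) / height) ** stemminess
        for k, d in depth.items()
    }
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        own = 0.0 if nd.is_leaf() else age[id(nd)]
        nd.edge.length = max(age[id(nd.parent_node)] - own, 0.0)


def simulate_tree(
    n_species: int,
    birth: float,
    death: float,
    seed: int,
    *,
    birth_rate_sd: float = 0.0,
    crown_age: float | None = None,
    stemminess: float = 1.0,
) -> dendropy.Tree:
    """Birth–death tree conditioned on ``n_species`` extant leaves, extinct
    lineages pruned; ultrametric, branch lengths in Myr, leaves labelled
    ``sp0001``... deterministically from ``seed``.

    With the defaults the process is constant-rate.  ``birth_rate_sd`` adds
    heritable lineage rate variation (imbalance); ``crown_age`` conditions
    the dated tree on a fixed root age; ``stemminess`` < 1 applies the
    rootward node-age transform (see :class:`FixtureConfig`).  The rate-
    varying simulator occasionally emits a negative terminal stretch, in
    which case the draw is deterministically retried.
    """
    if n_species < 4:
        raise EdgePriorError("n_species must be >= 4")
    if not birth > 0 or death < 0 or death >= birth:
        raise EdgePriorError(
            f"need birth > death >= 0, got birth={birth}, death={death}"
        )
    if not 0 < stemminess <= 1:
        raise EdgePriorError("stemminess must be in (0, 1]")
    tree = None
    for child in np.random.SeedSequence(int(seed)).spawn(50):
        sub_seed = int(child.generate_state(1)[0])
        cand = birthdeath.birth_death_tree(
            birth_rate=float(birth),
            death_rate=float(death),
            birth_rate_sd=float(birth_rate_sd),
            death_rate_sd=float(birth_rate_sd),
            num_extant_tips=int(n_species),
            rng=random.Random(sub_seed),
        )
        if all(
            e.length is None or e.length >= 0
            for e in cand.preorder_edge_iter()
        ):
            tree = cand
            break
    if tree is None:
        raise EdgePriorError(
            "simulation repeatedly produced invalid branch lengths; "
            "reduce birth_rate_sd"
        )
    tree.is_rooted = True
    tree.seed_node.edge.length = None
    if crown_age is not None or stemminess != 1.0:
        _apply_depth_transform(tree, crown_age, stemminess)
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i + 1:04d}"
    return tree


def _node_ages(tree: dendropy.Tree) -> tuple[dict, float]:
    dists = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            dists[id(nd)] = 0.0
        else:
            dists[id(nd)] = dists[id(nd.parent_node)] + (nd.edge.length or 0.0)
    height = max(
        dists[id(l)] for l in tree.leaf_node_iter()
    )
    ages = {k: max(height - v, 0.0) for k, v in dists.items()}
    return ages, height


def assign_taxonomy(
    tree: dendropy.Tree,
    genus_cut_age: float,
    family_cut_age: float,
    seed: int | None = None,
) -> pd.DataFrame:
    """Taxonomy by time-slicing: a genus is a maximal clade whose stem
    crosses the genus cut age, a family likewise at the (older) family cut,
    so every genus nests inside exactly one family and both are monophyletic
    by construction.  Naming is deterministic (``seed`` accepted for API
    symmetry; no randomness is involved).
    """
    if not family_cut_age > genus_cut_age > 0:
        raise EdgePriorError("need family_cut_age > genus_cut_age > 0")
    ages, height = _node_ages(tree)
    if family_cut_age >= height:
        raise EdgePriorError(
            f"family cut age {family_cut_age} must be below tree height {height:.3f}"
        )

    def group_node(leaf, cut):
        nd = leaf
        while nd.parent_node is not None and ages[id(nd.parent_node)] < cut:
            nd = nd.parent_node
        return nd

    genus_names: dict[int, str] = {}
    family_names: dict[int, str] = {}
    rows = []
    for leaf in tree.leaf_node_iter():
        gnode, fnode = group_node(leaf, genus_cut_age), group_node(leaf, family_cut_age)
        g = genus_names.setdefault(id(gnode), f"gen{len(genus_names) + 1:03d}")
        f = family_names.setdefault(id(fnode), f"fam{len(family_names) + 1:02d}")
        rows.append((leaf.taxon.label, g, f, "cladeA", True, False))
    return pd.DataFrame(
        rows,
        columns=["species", "genus", "family", "clade", "is_valid", "is_extinct"],
    )


def sample_redlist(
    species, probabilities=None, seed: int = 0
) -> pd.DataFrame:
    """Independent categorical Red List draws, one per species, seeded."""
    probs = dict(DEFAULT_CATEGORY_PROBS if probabilities is None else probabilities)
    unknown = set(probs) - set(RED_LIST_CATEGORIES)
    if unknown:
        raise EdgePriorError(f"unknown categories in probabilities: {unknown}")
    p = np.array([probs.get(c, 0.0) for c in RED_LIST_CATEGORIES], dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise EdgePriorError(f"probabilities sum to {p.sum()}, not 1")
    species = list(species)
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(RED_LIST_CATEGORIES), size=len(species), p=p / p.sum())
    return pd.DataFrame(
        {"species": species,
         "category": [RED_LIST_CATEGORIES[i] for i in draws]}
    )


def mask_missing(
    tree: dendropy.Tree,
    taxonomy: pd.DataFrame,
    missing_fraction: float,
    seed: int = 0,
    max_tries: int = 100,
) -> tuple[dendropy.Tree, frozenset]:
    """Remove a uniform-random fraction of leaves (the taxonomy is left
    untouched, so masked species become 'missing').

    The mask is constrained so that every family keeps at least one present
    species (no masked species is left without any confamiliar), mirroring
    real checklists, where a family is never known *only* from unsequenced
    species: the uniform draw is rejection-sampled, and if a valid draw is
    not found, deterministically repaired by swapping one member of each
    wiped-out family against a species from a well-covered family.
    """
    if not 0 <= missing_fraction < 1:
        raise EdgePriorError("missing_fraction must be in [0, 1)")
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    n = len(labels)
    n_mask = int(round(missing_fraction * n))
    if n - n_mask < 2:
        raise TreeError("mask would leave fewer than 2 leaves")
    if n_mask == 0:
        return tree.clone(depth=1), frozenset()
    family_of = dict(zip(taxonomy["species"], taxonomy["family"]))
    rng = np.random.default_rng(seed)

    def wiped(masked: set) -> list:
        kept = {family_of[lab] for lab in labels if lab not in masked}
        return sorted(
            {family_of[lab] for lab in labels} - kept
        )

    masked: set = set()
    for _ in range(max_tries):
        masked = set(rng.choice(labels, size=n_mask, replace=False).tolist())
        if not wiped(masked):
            break
    for family in wiped(masked):
        members = sorted(lab for lab in labels if family_of[lab] == family)
        release = members[int(rng.integers(len(members)))]
        kept_counts: dict[str, int] = {}
        for lab in labels:
            if lab not in masked:
                kept_counts[family_of[lab]] = kept_counts.get(family_of[lab], 0) + 1
        swappable = sorted(
            lab
            for lab in labels
            if lab not in masked and kept_counts[family_of[lab]] >= 2
        )
        if not swappable:
            raise EdgePriorError(
                "cannot keep every family represented at this missing_fraction"
            )
        masked.remove(release)
        masked.add(swappable[int(rng.integers(len(swappable)))])
    masked = frozenset(masked)
    pruned = prune_to_labels(tree, [lab for lab in labels if lab not in masked])
    return pruned, masked


def make_fixture(config: FixtureConfig | None = None, **overrides) -> FixtureBundle:
    """Full seeded bundle: tree -> taxonomy -> Red List -> mask."""
    config = replace(config, **overrides) if config else FixtureConfig(**overrides)
    sub = np.random.SeedSequence(config.seed).generate_state(3)
    full_tree = simulate_tree(
        config.n_species,
        config.birth,
        config.death,
        seed=int(sub[0]),
        birth_rate_sd=config.birth_rate_sd,
        crown_age=config.crown_age,
        stemminess=config.stemminess,
    )
    taxonomy = assign_taxonomy(full_tree, config.genus_cut, config.family_cut)
    redlist = sample_redlist(
        taxonomy["species"], config.category_probs, seed=int(sub[1])
    )
    tree, missing = mask_missing(
        full_tree, taxonomy, config.missing_fraction, seed=int(sub[2])
    )
    return FixtureBundle(
        tree=tree,
        full_tree=full_tree,
        taxonomy=taxonomy,
        redlist=redlist,
        missing=missing,
    )
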