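"""Fair-proportion Evolutionary Distinctiveness (ED) and total PD.

Phylogenetic Diversity (PD) of a clade is the sum of all branch lengths of
its dated phylogeny, in millions of years (Myr).  ED partitions PD among
species by the *fair proportion* rule: each branch is divided equally among
the species to which it is ancestral, and a species' ED is the sum of its
shares along the root-to-leaf path.  ED therefore sums exactly to PD, and is
bounded below by the terminal branch length — the part of the path shared
with no other species.

Over a distribution of trees (posterior samples, pseudo-replicates) ED is
summarised per species by the median, since ED is typically right-skewed.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from ._tree import IndexedTree
from .exceptions import TreeError

__all__ = [
    "total_pd",
    "fair_proportion",
    "ed_distribution",
    "terminal_branch_length",
    "EDDistribution",
]


def total_pd(tree: dendropy.Tree) -> float:
    """Sum of all edge lengths in Myr (root edge included when present)."""
    return IndexedTree(tree).total_pd()


def fair_proportion(tree: dendropy.Tree) -> pd.DataFrame:
    """Per-species fair-proportion ED for a tree with >= 2 leaves.

    Returns an ED table (columns ``species, ed, provenance``) whose ``ed``
    column sums to :func:`total_pd` of the tree.  A root edge, when present
    with positive length, is divided among all leaves.
    """
    idx = IndexedTree(tree)
    if idx.n_leaves < 2:
        raise TreeError("fair proportion undefined for a single-leaf tree")
    ed = idx.fair_proportion()
    return pd.DataFrame(
        {"species": idx.leaf_labels, "ed": ed, "provenance": "tree"}
    )


@dataclass(frozen=True)
class EDDistribution:
    """Per-species ED across an ordered set of trees.

    ``values``: DataFrame indexed by species, one column per tree (column
    label = tree index).  ``median``: per-species median, the summary used
    downstream (midpoint of the central order statistics for even counts).
    """

    values: pd.DataFrame
    median: pd.Series

    def __len__(self) -> int:
        return self.values.shape[1]


def ed_distribution(trees) -> EDDistribution:
    """Fair-proportion ED of every species in every tree of a tree set.

    All trees must share one leaf set; a mismatch raises :class:`TreeError`
    naming the offending tree index.
    """
    trees = list(trees)
    if not trees:
        raise TreeError("empty tree set")
    columns = {}
    ref_species: frozenset | None = None
    order: list[str] = []
    for i, tree in enumerate(trees):
        tab = fair_proportion(tree)
        sp = frozenset(tab["species"])
        if ref_species is None:
            ref_species = sp
            order = list(tab["species"])
        elif sp != ref_species:
            raise TreeError(
                f"tree {i} leaf set differs from tree 0 "
                f"(e.g. {sorted(sp ^ ref_species)[:5]})"
            )
        columns[i] = tab.set_index("species")["ed"]
    values = pd.DataFrame(columns).loc[order]
    values.index.name = "species"
    median = values.median(axis=1)
    median.name = "ed"
    return EDDistribution(values=values, median=median)


def terminal_branch_length(tree: dendropy.Tree, species: str) -> float:
    """Length of the pendant edge subtending ``species`` — the minimum
    guaranteed contribution to that species' ED."""
    idx = IndexedTree(tree)
    for cand in (species, species.replace("_", " "), species.replace(" ", "_")):
        if cand in idx.leaf_index:
            return float(idx.terminal_lengths()[idx.leaf_index[cand]])
    raise TreeError(f"species {species!r} is not a leaf of the tree")
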