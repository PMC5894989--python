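"""EDGE scoring, ranking, and robust-priority criteria.

EDGE combines Evolutionary Distinctiveness with Global Endangerment (GE),
an integer weighting of the IUCN Red List category::

    EDGE = ln(1 + ED) + GE * ln 2,   GE: LC=0, NT=1, VU=2, EN=3, CR=4

so each step up the threat ladder doubles the implied extinction odds.
Species that are Data Deficient, Not Evaluated, or extinct in the wild or
entirely (DD/NE/EW/EX) carry ED but no EDGE score.

An *EDGE species* is above the median ED of its clade (median taken over all
species with an ED value, assessed or not) and in a threatened category
(VU/EN/CR).  *Robust* priorities are species whose high rank is insensitive
to phylogenetic uncertainty: top-k in every tree of a distribution, or — for
single incomplete trees — top-k species whose whole genus (whole family for
monospecific genera) is sampled in the tree.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .exceptions import EdgePriorError, NotScorableError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "GE_BY_CATEGORY",
    "THREATENED",
    "ge_from_category",
    "edge_score",
    "score_table",
    "rank_table",
    "flag_edge_species",
    "robust_from_distribution",
    "robust_from_single_tree",
    "combine_clades",
]

GE_BY_CATEGORY = {"LC": 0, "NT": 1, "VU": 2, "EN": 3, "CR": 4}
THREATENED = frozenset({"VU", "EN", "CR"})
_NOT_SCORABLE = frozenset({"DD", "NE", "EX", "EW"})

EDGE_COLUMNS = [
    "species", "clade", "ed", "category", "ge", "edge",
    "rank", "is_edge_species", "is_robust",
]


def ge_from_category(category: str) -> int:
    """GE weight for an assessed, extant category; DD/NE/EX/EW raise
    :class:`NotScorableError`."""
    cat = str(category).strip().upper()
    if cat in GE_BY_CATEGORY:
        return GE_BY_CATEGORY[cat]
    if cat in _NOT_SCORABLE:
        raise NotScorableError(
            f"category {cat} carries no GE weight (no EDGE score)"
        )
    raise SchemaError(f"unknown Red List category {category!r}")


def edge_score(ed: float, ge: int) -> float:
    """``ln(1 + ed) + ge * ln 2`` at full precision."""
    ed = float(ed)
    if not ed >= 0:
        raise EdgePriorError(f"ED must be non-negative, got {ed}")
    if int(ge) not in (0, 1, 2, 3, 4):
        raise EdgePriorError(f"GE must be an integer in 0..4, got {ge}")
    return math.log1p(ed) + int(ge) * math.log(2.0)


def score_table(
    ed_table: pd.DataFrame, redlist: pd.DataFrame, clade: str = "all"
) -> pd.DataFrame:
    """Join an ED table with Red List categories and attach GE and EDGE.

    Species without a usable (LC..CR) category are excluded; the exclusion
    count is logged, never written into the output.
    """
    merged = ed_table.merge(redlist, on="species", how="left")
    usable = merged["category"].isin(GE_BY_CATEGORY)
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info(
            "%d species without scorable Red List category excluded "
            "from EDGE scoring (clade %s)", n_excluded, clade,
        )
    out = merged[usable].copy()
    out["clade"] = clade
    out["ge"] = out["category"].map(GE_BY_CATEGORY).astype(int)
    out["edge"] = np.log1p(out["ed"].astype(float)) + out["ge"] * math.log(2.0)
    out["rank"] = pd.NA
    out["is_edge_species"] = False
    out["is_robust"] = False
    return out[EDGE_COLUMNS].reset_index(drop=True)


def rank_table(table: pd.DataFrame) -> pd.DataFrame:
    """Sort by EDGE descending (ties: ED descending, then species name
    ascending) and assign 1-based ranks — deterministic so rankings are
    comparable across trees of a distribution."""
    out = table.sort_values(
        ["edge", "ed", "species"], ascending=[False, False, True]
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def flag_edge_species(
    table: pd.DataFrame, ed_reference: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Set ``is_edge_species``: strictly above the clade's median ED and in a
    threatened category.

    ``ed_reference`` (columns ``species, clade, ed``) supplies the ED
    distribution over which each clade median is taken; it defaults to the
    table itself but should include DD/NE species when available, since the
    median is a property of the clade's full ED distribution.
    """
    ref = table if ed_reference is None else ed_reference
    medians = ref.groupby("clade")["ed"].median()
    out = table.copy()
    missing_clades = set(out["clade"]) - set(medians.index)
    if missing_clades:
        raise EdgePriorError(
            f"no ED values for clade(s): {sorted(missing_clades)}"
        )
    clade_median = out["clade"].map(medians)
    out["is_edge_species"] = (out["ed"] > clade_median) & out[
        "category"
    ].isin(THREATENED)
    return out


def _require_ranked(table: pd.DataFrame) -> None:
    if table["rank"].isna().any():
        raise EdgePriorError("table must be ranked (use rank_table first)")


def robust_from_distribution(tables, k: int) -> set:
    """Species ranked in the top ``k`` of *every* ranked table (one table per
    tree of a distribution)."""
    tables = list(tables)
    if not tables:
        raise EdgePriorError("no tables supplied")
    universe = set(tables[0]["species"])
    robust = None
    for i, tab in enumerate(tables):
        if set(tab["species"]) != universe:
            raise EdgePriorError(f"table {i} species set differs from table 0")
        _require_ranked(tab)
        topk = set(tab.loc[tab["rank"] <= k, "species"])
        robust = topk if robust is None else robust & topk
    return robust


def robust_from_single_tree(
    table: pd.DataFrame, taxonomy: pd.DataFrame, tree_species, k: int
) -> set:
    """For a single incomplete tree: top-``k`` species whose entire genus —
    entire family, for monospecific genera — is present in the tree."""
    _require_ranked(table)
    tree_species = set(tree_species)
    by_genus = taxonomy.groupby("genus")["species"].apply(set)
    by_family = taxonomy.groupby("family")["species"].apply(set)
    genus_of = dict(zip(taxonomy["species"], taxonomy["genus"]))
    family_of = dict(zip(taxonomy["species"], taxonomy["family"]))
    robust = set()
    for sp in table.loc[table["rank"] <= k, "species"]:
        genus_members = by_genus.get(genus_of.get(sp), set())
        if not genus_members or not genus_members <= tree_species:
            continue
        if len(genus_members) == 1:
            if not by_family.get(family_of.get(sp), set()) <= tree_species:
                continue
        robust.add(sp)
    return robust


def combine_clades(tables, k: int) -> pd.DataFrame:
    """Pool the flagged EDGE species of independently-flagged clade tables,
    re-rank the pool by EDGE (same tie rule), and return the top ``k``."""
    tables = list(tables)
    pooled = pd.concat(
        [t[t["is_edge_species"]] for t in tables], ignore_index=True
    ) if tables else pd.DataFrame(columns=EDGE_COLUMNS)
    if pooled.empty:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    ranked = rank_table(pooled)
    return ranked[ranked["rank"] <= k].reset_index(drop=True)
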