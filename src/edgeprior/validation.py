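"""Imputation-accuracy validation by randomized species removal.

The experiment asks: if species we *do* have in the tree are artificially
hidden, how well does each imputation method recover their known ED?  Per
iteration, every genus loses a uniform-random number of its species (from
one up to the whole genus; singletons are therefore always removed), ED is
recomputed on the reduced tree, and the removed species are re-imputed by
all three methods.  Agreement is quantified by pooled Pearson correlation
between imputed and reference ED, and by regressing the captured proportion
(imputed / reference) on the proportion of the genus or family retained —
ideal imputation gives a flat line at 1 (slope 0, intercept 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._tree import IndexedTree
from .exceptions import EdgePriorError, TreeError
from .imputation import ImputationProblem, METHODS, impute_all_scores

__all__ = [
    "run_removal_experiment",
    "summarise_experiment",
    "pearson_r",
    "proportion_regression",
    "compare_rankings",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = [
    "iteration", "species", "removed", "reference_ed",
    "imputed_ed_original", "imputed_ed_simple", "imputed_ed_new",
    "tier", "proportion_retained",
]


def run_removal_experiment(
    tree, taxonomy: pd.DataFrame, iterations: int, seed: int
) -> pd.DataFrame:
    """Removal–reimputation experiment on a single (already pruned) tree.

    Returns one record per iteration x species: removed species carry their
    re-imputed ED under each method, and retained species carry the score
    each method leaves them with on the reduced tree (the original and new
    methods correct present relatives; the simple method leaves the
    recalculated ED untouched).  Correlation summaries pool all records,
    matching the degrees of freedom convention of full-table comparisons;
    captured-proportion diagnostics use the removed records only.

    Removed species with no present relative at either tier get NaN imputed
    values (their count is stored in ``result.attrs["n_unimputable"]``);
    identical seeds give identical results (per-iteration substreams are
    spawned from one seed).
    """
    if iterations < 1:
        raise EdgePriorError("iterations must be >= 1")
    idx = tree if isinstance(tree, IndexedTree) else IndexedTree(tree)
    labels = idx.leaf_labels
    known = set(taxonomy["species"])
    stray = [lab for lab in labels if lab not in known]
    if stray:
        raise EdgePriorError(
            f"tree leaves absent from taxonomy: {stray[:5]}"
        )
    genus_of = dict(zip(taxonomy["species"], taxonomy["genus"]))
    family_of = dict(zip(taxonomy["species"], taxonomy["family"]))
    genus_positions: dict[str, list[int]] = {}
    family_sizes: dict[str, int] = {}
    for j, lab in enumerate(labels):
        genus_positions.setdefault(genus_of[lab], []).append(j)
        family_sizes[family_of[lab]] = family_sizes.get(family_of[lab], 0) + 1
    genera = sorted(genus_positions)
    reference = idx.fair_proportion()

    streams = np.random.SeedSequence(seed).spawn(iterations)
    rows: list[tuple] = []
    n_unimputable = 0
    for it in range(iterations):
        rng = np.random.default_rng(streams[it])
        keep = np.ones(idx.n_leaves, dtype=bool)
        removed: list[int] = []
        for g in genera:
            pos = genus_positions[g]
            k = int(rng.integers(1, len(pos) + 1))
            sel = rng.choice(len(pos), size=k, replace=False)
            for s in sel:
                keep[pos[s]] = False
                removed.append(pos[s])
        if keep.sum() < 2:
            raise TreeError(
                f"iteration {it} would leave fewer than 2 leaves"
            )
        reduced = idx.fair_proportion(keep)
        base = {labels[j]: reduced[j] for j in np.flatnonzero(keep)}
        missing = frozenset(labels[j] for j in removed)
        problem = ImputationProblem(base=base, taxonomy=taxonomy, missing=missing)
        groups, scores = impute_all_scores(problem, strict=False)
        retained_by_genus = {
            g: int(keep[genus_positions[g]].sum()) for g in genera
        }
        retained_by_family: dict[str, int] = {}
        for j in np.flatnonzero(keep):
            fam = family_of[labels[j]]
            retained_by_family[fam] = retained_by_family.get(fam, 0) + 1
        removed_set = set(removed)
        for j in range(idx.n_leaves):
            sp = labels[j]
            was_removed = j in removed_set
            if was_removed:
                tier = groups.tier.get(sp)
                if tier is None:
                    n_unimputable += 1
                    rows.append(
                        (it, sp, True, reference[j],
                         np.nan, np.nan, np.nan, "unimputable", 0.0)
                    )
                    continue
            else:
                # tier at which the methods correct this present species
                tier = (
                    "genus"
                    if genus_of[sp] in groups.genus_missing
                    else "family"
                    if family_of[sp] in groups.family_missing
                    and groups.corrected_at_family(sp)
                    else "none"
                )
            if tier == "family":
                fam = family_of[sp]
                prop = retained_by_family.get(fam, 0) / family_sizes[fam]
            else:
                g = genus_of[sp]
                prop = retained_by_genus[g] / len(genus_positions[g])
            rows.append(
                (it, sp, was_removed, reference[j],
                 scores["original"][sp], scores["simple"][sp],
                 scores["new"][sp], tier, prop)
            )
    result = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    result.attrs["n_unimputable"] = n_unimputable
    result.attrs["seed"] = seed
    return result


def pearson_r(x, y) -> float:
    """Sample Pearson product-moment correlation (pooled vectors)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise EdgePriorError("pearson_r needs two equal vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise EdgePriorError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y)[0])


def _valid_records(
    result: pd.DataFrame,
    method: str,
    tier: str | None,
    removed_only: bool = False,
):
    col = f"imputed_ed_{method}"
    if col not in result.columns:
        raise EdgePriorError(f"unknown method {method!r}; choose from {METHODS}")
    sub = result[result[col].notna() & (result["reference_ed"] > 0)]
    if removed_only and "removed" in sub.columns:
        sub = sub[sub["removed"]]
    if tier is not None:
        sub = sub[sub["tier"] == tier]
    return sub, col


def proportion_regression(
    result: pd.DataFrame, method: str, tier: str
) -> tuple[float, float]:
    """OLS of captured proportion (imputed/reference) on proportion of the
    group retained, over the removed-species records at one tier, pooled
    across iterations.  Returns ``(slope, intercept)``; the ideal
    imputation gives ``(0, 1)``."""
    if tier not in ("genus", "family"):
        raise EdgePriorError("tier must be 'genus' or 'family'")
    sub, col = _valid_records(result, method, tier, removed_only=True)
    if len(sub) < 3:
        raise EdgePriorError(
            f"need >= 3 pooled records at tier {tier!r}, have {len(sub)}"
        )
    ratio = sub[col].to_numpy() / sub["reference_ed"].to_numpy()
    fit = stats.linregress(sub["proportion_retained"].to_numpy(), ratio)
    return float(fit.slope), float(fit.intercept)


def summarise_experiment(result: pd.DataFrame) -> pd.DataFrame:
    """Per-method summary: Pearson r pooled over all records (d.f. = N - 2),
    mean captured proportion per tier over removed species, and per-tier
    regression coefficients of the captured proportion."""
    rows = []
    for method in METHODS:
        sub, col = _valid_records(result, method, tier=None)
        r = pearson_r(sub["reference_ed"], sub[col])
        entry = {
            "method": method,
            "pearson_r": r,
            "df": len(sub) - 2,
        }
        removed, _ = _valid_records(result, method, tier=None, removed_only=True)
        for tier in ("genus", "family"):
            tsub = removed[removed["tier"] == tier]
            ratio = (
                tsub[col].to_numpy() / tsub["reference_ed"].to_numpy()
                if len(tsub)
                else np.array([])
            )
            entry[f"mean_ratio_{tier}"] = (
                float(ratio.mean()) if ratio.size else np.nan
            )
            if len(tsub) >= 3:
                slope, intercept = proportion_regression(result, method, tier)
            else:
                slope = intercept = np.nan
            entry[f"slope_{tier}"] = slope
            entry[f"intercept_{tier}"] = intercept
        rows.append(entry)
    return pd.DataFrame(rows)


def compare_rankings(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    k_a: int,
    k_b: int,
) -> tuple[int, float, float]:
    """Agreement between two ranked EDGE tables.

    Returns ``(overlap, slope, adjusted R^2)``: the size of the intersection
    of A's top ``k_a`` with B's top ``k_b``, and the OLS fit of B's ranks on
    A's ranks over the shared species universe.
    """
    a = table_a.set_index("species")["rank"]
    b = table_b.set_index("species")["rank"]
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise EdgePriorError("ranked tables share no species")
    top_a = set(a[a <= k_a].index)
    top_b = set(b[b <= k_b].index)
    overlap = len(top_a & top_b)
    x = a[shared].to_numpy(dtype=float)
    y = b[shared].to_numpy(dtype=float)
    if len(shared) < 3 or np.std(x) == 0:
        raise EdgePriorError("need >= 3 shared species with varying ranks")
    fit = stats.linregress(x, y)
    n = len(shared)
    r2 = fit.rvalue ** 2
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return overlap, float(fit.slope), float(adj_r2)
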