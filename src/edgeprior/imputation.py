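"""Estimating ED for species absent from the phylogeny.

Three competing estimators, all driven by taxonomy alone (no tree grafting).
A missing species is imputed at *genus tier* when at least one congener is in
the tree, otherwise at *family tier* when at least one confamiliar is; with
neither, it is unimputable (callers may substitute a published divergence
time instead, see :func:`substitute_terminal`).

For an imputation group with ``n`` present species of total ED ``S`` and
``m`` missing species:

``original``
    conserves group ED: every present species' score is multiplied by
    ``n / (n + m)`` and each missing species receives ``S / (n + m)``.  It
    adds no new PD, so it systematically underestimates.

``simple``
    each missing species receives the arithmetic mean ED of its present
    congeners (confamiliars at family tier); present scores are untouched,
    so total ED only grows — it systematically overestimates.

``new``
    every group member gets two scores — score 1 is the base ED for present
    species and the ``simple`` estimate for missing ones; score 2 is the
    even split ``S / (n + m)`` — and the final ED is their mean.  This both
    adds PD for the missing species and shrinks their close relatives.

Present species are corrected (the reduction in ``original``, the score-2
averaging in ``new``) at the finest tier in which they have missing
relatives: at genus tier when their own genus is incomplete, at family tier
only when their genus is complete but the family has wholly-missing genera.
Family-tier ``n`` and ``S`` count all present confamilial species.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import EdgePriorError, SchemaError, UnimputableError

__all__ = [
    "ImputationProblem",
    "impute_original",
    "impute_simple",
    "impute_new",
    "impute",
    "substitute_terminal",
    "group_report",
    "METHODS",
]

METHODS = ("original", "simple", "new")


@dataclass(frozen=True)
class ImputationProblem:
    """Tree-derived ED for present species plus the taxonomy that places the
    missing ones."""

    base: Mapping[str, float]
    taxonomy: pd.DataFrame
    missing: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "missing", frozenset(self.missing))
        overlap = set(self.base) & self.missing
        if overlap:
            raise SchemaError(
                f"species both present and missing: {sorted(overlap)[:5]}"
            )
        known = set(self.taxonomy["species"])
        stray = (set(self.base) | self.missing) - known
        if stray:
            raise SchemaError(
                f"species absent from taxonomy: {sorted(stray)[:5]}"
            )

    @classmethod
    def from_tables(
        cls,
        ed_table: pd.DataFrame,
        taxonomy: pd.DataFrame,
        missing=None,
    ) -> "ImputationProblem":
        """Build a problem from an ED table; by default every valid, extant
        taxonomy species absent from the table is treated as missing."""
        base = dict(zip(ed_table["species"], ed_table["ed"].astype(float)))
        if missing is None:
            recognised = taxonomy.loc[
                taxonomy["is_valid"] & ~taxonomy["is_extinct"], "species"
            ]
            missing = frozenset(recognised) - set(base)
        return cls(base=base, taxonomy=taxonomy, missing=frozenset(missing))


class _Groups:
    """Tier assignment and group bookkeeping shared by the three methods."""

    def __init__(self, problem: ImputationProblem):
        tax = problem.taxonomy
        self.genus_of = dict(zip(tax["species"], tax["genus"]))
        self.family_of = dict(zip(tax["species"], tax["family"]))
        self.present_by_genus = defaultdict(list)
        self.present_by_family = defaultdict(list)
        for sp in problem.base:
            self.present_by_genus[self.genus_of[sp]].append(sp)
            self.present_by_family[self.family_of[sp]].append(sp)
        self.tier: dict[str, str] = {}
        self.genus_missing = defaultdict(list)
        self.family_missing = defaultdict(list)
        self.unimputable: list[str] = []
        for sp in sorted(problem.missing):
            g, f = self.genus_of[sp], self.family_of[sp]
            if self.present_by_genus.get(g):
                self.tier[sp] = "genus"
                self.genus_missing[g].append(sp)
            elif self.present_by_family.get(f):
                self.tier[sp] = "family"
                self.family_missing[f].append(sp)
            else:
                self.unimputable.append(sp)

    def corrected_at_family(self, species: str) -> bool:
        """Present species take the family-tier correction only when their
        own genus is complete (finest-tier rule)."""
        return self.genus_of[species] not in self.genus_missing


def _resolve(problem: ImputationProblem, strict: bool) -> _Groups:
    groups = _Groups(problem)
    if groups.unimputable and strict:
        raise UnimputableError(groups.unimputable)
    return groups


def _original_scores(problem, groups) -> dict[str, float]:
    base = problem.base
    ed = dict(base)
    for g, miss in groups.genus_missing.items():
        present = groups.present_by_genus[g]
        n, m = len(present), len(miss)
        S = sum(base[p] for p in present)
        for p in present:
            ed[p] = base[p] * n / (n + m)
        for sp in miss:
            ed[sp] = S / (n + m)
    for f, miss in groups.family_missing.items():
        present = groups.present_by_family[f]
        n, m = len(present), len(miss)
        S = sum(base[p] for p in present)
        for p in present:
            if groups.corrected_at_family(p):
                ed[p] = base[p] * n / (n + m)
        for sp in miss:
            ed[sp] = S / (n + m)
    return ed


def _simple_missing_scores(problem, groups) -> dict[str, float]:
    base = problem.base
    out: dict[str, float] = {}
    for g, miss in groups.genus_missing.items():
        mean = float(np.mean([base[p] for p in groups.present_by_genus[g]]))
        for sp in miss:
            out[sp] = mean
    for f, miss in groups.family_missing.items():
        mean = float(np.mean([base[p] for p in groups.present_by_family[f]]))
        for sp in miss:
            out[sp] = mean
    return out


def _simple_scores(problem, groups) -> dict[str, float]:
    ed = dict(problem.base)
    ed.update(_simple_missing_scores(problem, groups))
    return ed


def _new_scores(problem, groups) -> dict[str, float]:
    base = problem.base
    s1 = _simple_scores(problem, groups)
    s2 = dict(s1)
    for g, miss in groups.genus_missing.items():
        present = groups.present_by_genus[g]
        v = sum(base[p] for p in present) / (len(present) + len(miss))
        for sp in present:
            s2[sp] = v
        for sp in miss:
            s2[sp] = v
    for f, miss in groups.family_missing.items():
        present = groups.present_by_family[f]
        v = sum(base[p] for p in present) / (len(present) + len(miss))
        for p in present:
            if groups.corrected_at_family(p):
                s2[p] = v
        for sp in miss:
            s2[sp] = v
    return {sp: (s1[sp] + s2[sp]) / 2.0 for sp in s1}


_SCORERS = {
    "original": _original_scores,
    "simple": _simple_scores,
    "new": _new_scores,
}


def _to_table(
    problem: ImputationProblem, groups: _Groups, ed: Mapping[str, float]
) -> pd.DataFrame:
    rows = [(sp, ed[sp], "tree") for sp in problem.base]
    for sp in sorted(problem.missing):
        if sp in groups.tier:
            rows.append((sp, ed[sp], f"imputed_{groups.tier[sp]}"))
    return pd.DataFrame(rows, columns=["species", "ed", "provenance"])


def impute(
    problem: ImputationProblem, method: str, strict: bool = True
) -> pd.DataFrame:
    """Impute with one of :data:`METHODS`; returns an ED table covering the
    present species (corrected where the method requires it) and every
    imputable missing species, with provenance ``imputed_genus`` or
    ``imputed_family``.

    With ``strict`` (default), unimputable species raise
    :class:`UnimputableError`; otherwise they are omitted from the output
    (see :func:`group_report`).
    """
    if method not in _SCORERS:
        raise EdgePriorError(
            f"unknown imputation method {method!r}; choose from {METHODS}"
        )
    groups = _resolve(problem, strict)
    return _to_table(problem, groups, _SCORERS[method](problem, groups))


def impute_original(problem: ImputationProblem, strict: bool = True) -> pd.DataFrame:
    """ED-conserving imputation: shrink present relatives by ``n/(n+m)`` and
    split the freed ED evenly over the missing species."""
    return impute(problem, "original", strict=strict)


def impute_simple(problem: ImputationProblem, strict: bool = True) -> pd.DataFrame:
    """Group-mean imputation: missing species get the mean ED of present
    congeners (confamiliars at family tier); present scores unchanged."""
    return impute(problem, "simple", strict=strict)


def impute_new(problem: ImputationProblem, strict: bool = True) -> pd.DataFrame:
    """Mean of the ``simple`` estimate and the even within-group split —
    adds PD for missing species while correcting present relatives."""
    return impute(problem, "new", strict=strict)


def impute_all_scores(
    problem: ImputationProblem, strict: bool = True
) -> tuple["_Groups", dict[str, dict[str, float]]]:
    """All three methods' score mappings from one group resolution (the fast
    path used by the removal experiment)."""
    groups = _resolve(problem, strict)
    return groups, {
        m: scorer(problem, groups) for m, scorer in _SCORERS.items()
    }


def substitute_terminal(
    table: pd.DataFrame, species: str, divergence: float
) -> pd.DataFrame:
    """Replace one species' ED with a published divergence time (its terminal
    branch length) — a conservative lower bound on true ED, used for highly
    distinct monotypic genera absent from any phylogeny."""
    if not divergence > 0:
        raise EdgePriorError(f"divergence must be positive, got {divergence}")
    hits = table.index[table["species"] == species]
    if hits.empty:
        raise EdgePriorError(f"species {species!r} not in ED table")
    out = table.copy()
    out.loc[hits, "ed"] = float(divergence)
    out.loc[hits, "provenance"] = "terminal_branch"
    return out


def group_report(problem: ImputationProblem, strict: bool = False) -> pd.DataFrame:
    """Per-group diagnostics: tier, group name, n present, m missing, and
    present-species ED total before imputation.  Unimputable species appear
    as their own rows with tier ``unimputable``."""
    groups = _resolve(problem, strict)
    rows = []
    for g, miss in groups.genus_missing.items():
        present = groups.present_by_genus[g]
        rows.append(
            ("genus", g, len(present), len(miss),
             sum(problem.base[p] for p in present))
        )
    for f, miss in groups.family_missing.items():
        present = groups.present_by_family[f]
        rows.append(
            ("family", f, len(present), len(miss),
             sum(problem.base[p] for p in present))
        )
    for sp in groups.unimputable:
        rows.append(("unimputable", sp, 0, 1, float("nan")))
    return pd.DataFrame(
        rows, columns=["tier", "group", "n_present", "m_missing", "ed_present"]
    )
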