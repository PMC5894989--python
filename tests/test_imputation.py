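import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edgeprior import (
    EdgePriorError,
    ImputationProblem,
    SchemaError,
    UnimputableError,
    group_report,
    impute,
    impute_new,
    impute_original,
    impute_simple,
    substitute_terminal,
)

from .conftest import taxonomy_frame


@pytest.fixture
def genus_toy() -> ImputationProblem:
    """The hand-worked instance: genus with present {A: 6, B: 2}, one
    missing congener M."""
    taxonomy = taxonomy_frame(
        [("A", "G", "F"), ("B", "G", "F"), ("M", "G", "F")]
    )
    return ImputationProblem(
        base={"A": 6.0, "B": 2.0}, taxonomy=taxonomy, missing={"M"}
    )


@pytest.fixture
def family_toy() -> ImputationProblem:
    """Wholly missing genus imputed from a confamiliar: {C: 10} present,
    M1 and M2 missing from another genus of the same family."""
    taxonomy = taxonomy_frame(
        [("C", "Gc", "F"), ("M1", "Gm", "F"), ("M2", "Gm", "F")]
    )
    return ImputationProblem(
        base={"C": 10.0}, taxonomy=taxonomy, missing={"M1", "M2"}
    )


def as_series(table: pd.DataFrame) -> pd.Series:
    return table.set_index("species")["ed"]


class TestWorkedExamples:
    def test_original_conserves_and_splits(self, genus_toy):
        ed = as_series(impute_original(genus_toy))
        assert ed["A"] == pytest.approx(4.0, abs=1e-12)
        assert ed["B"] == pytest.approx(4.0 / 3.0, abs=1e-12)
        assert ed["M"] == pytest.approx(8.0 / 3.0, abs=1e-12)
        assert ed.sum() == pytest.approx(8.0, abs=1e-9)

    def test_simple_assigns_group_mean(self, genus_toy):
        ed = as_series(impute_simple(genus_toy))
        assert ed["M"] == pytest.approx(4.0, abs=1e-12)
        assert ed["A"] == 6.0 and ed["B"] == 2.0
        assert ed.sum() == pytest.approx(12.0)

    def test_new_averages_the_two_scores(self, genus_toy):
        ed = as_series(impute_new(genus_toy))
        assert ed["A"] == pytest.approx(13.0 / 3.0, abs=1e-12)
        assert ed["B"] == pytest.approx(7.0 / 3.0, abs=1e-12)
        assert ed["M"] == pytest.approx(10.0 / 3.0, abs=1e-12)
        assert ed.sum() == pytest.approx(10.0, abs=1e-9)

    def test_family_tier_fallback(self, family_toy):
        orig = as_series(impute_original(family_toy))
        assert orig["C"] == pytest.approx(10.0 / 3.0, abs=1e-12)
        assert orig["M1"] == orig["M2"] == pytest.approx(10.0 / 3.0, abs=1e-12)
        new = as_series(impute_new(family_toy))
        assert new["C"] == pytest.approx(20.0 / 3.0, abs=1e-12)
        assert new["M1"] == new["M2"] == pytest.approx(20.0 / 3.0, abs=1e-12)
        simple = as_series(impute_simple(family_toy))
        assert simple["M1"] == simple["M2"] == pytest.approx(10.0)

    def test_provenance_marks_tier(self, genus_toy, family_toy):
        assert (
            impute_new(genus_toy).set_index("species").loc["M", "provenance"]
            == "imputed_genus"
        )
        assert (
            impute_new(family_toy).set_index("species").loc["M1", "provenance"]
            == "imputed_family"
        )


class TestIdentityAndErrors:
    def test_empty_missing_is_identity_for_all_methods(self, toy_taxonomy):
        problem = ImputationProblem(
            base={"A": 1.0, "B": 2.0, "C": 3.0},
            taxonomy=toy_taxonomy,
            missing=frozenset(),
        )
        for method in ("original", "simple", "new"):
            ed = as_series(impute(problem, method))
            assert dict(ed) == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_unimputable_raises_listing_species(self):
        taxonomy = taxonomy_frame(
            [("A", "Ga", "F1"), ("Z", "Gz", "F9")]
        )
        problem = ImputationProblem(
            base={"A": 5.0}, taxonomy=taxonomy, missing={"Z"}
        )
        with pytest.raises(UnimputableError, match="Z"):
            impute_new(problem)
        report = group_report(problem)
        assert (report["tier"] == "unimputable").sum() == 1

    def test_overlap_between_base_and_missing_rejected(self, toy_taxonomy):
        with pytest.raises(SchemaError):
            ImputationProblem(
                base={"A": 1.0, "B": 1.0}, taxonomy=toy_taxonomy, missing={"A"}
            )

    def test_species_outside_taxonomy_rejected(self, toy_taxonomy):
        with pytest.raises(SchemaError):
            ImputationProblem(
                base={"A": 1.0, "Q": 1.0}, taxonomy=toy_taxonomy, missing=set()
            )


def random_problem(seed: int) -> ImputationProblem:
    """Random disjoint-group problem: several genera in distinct families,
    each with at least one present species."""
    rng = np.random.default_rng(seed)
    rows, base, missing = [], {}, set()
    for g in range(rng.integers(2, 6)):
        n_present = int(rng.integers(1, 5))
        n_missing = int(rng.integers(0, 4))
        for i in range(n_present):
            sp = f"g{g}p{i}"
            rows.append((sp, f"G{g}", f"F{g}"))
            base[sp] = float(rng.gamma(2.0, 5.0))
        for i in range(n_missing):
            sp = f"g{g}m{i}"
            rows.append((sp, f"G{g}", f"F{g}"))
            missing.add(sp)
    return ImputationProblem(
        base=base, taxonomy=taxonomy_frame(rows), missing=missing
    )


class TestInvariants:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_original_conserves_total_on_disjoint_groups(self, seed):
        problem = random_problem(seed)
        before = sum(problem.base.values())
        after = as_series(impute_original(problem)).sum()
        assert after == pytest.approx(before, abs=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_simple_and_new_never_lose_total(self, seed):
        problem = random_problem(seed)
        before = sum(problem.base.values())
        for method in ("simple", "new"):
            after = as_series(impute(problem, method)).sum()
            assert after >= before - 1e-9
            if not problem.missing:
                assert after == pytest.approx(before, abs=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_new_scores_lie_between_even_split_and_simple(self, seed):
        problem = random_problem(seed)
        if not problem.missing:
            return
        new = as_series(impute_new(problem))
        simple = as_series(impute_simple(problem))
        original = as_series(impute_original(problem))
        for sp in problem.missing:
            lo, hi = sorted([original[sp], simple[sp]])
            assert lo - 1e-12 <= new[sp] <= hi + 1e-12

    def test_additional_missing_congener_dilutes_even_split(self):
        taxonomy = taxonomy_frame(
            [("A", "G", "F"), ("B", "G", "F"), ("M1", "G", "F"), ("M2", "G", "F")]
        )
        one = ImputationProblem(
            base={"A": 6.0, "B": 2.0}, taxonomy=taxonomy, missing={"M1"}
        )
        two = ImputationProblem(
            base={"A": 6.0, "B": 2.0}, taxonomy=taxonomy, missing={"M1", "M2"}
        )
        assert as_series(impute_original(two))["M1"] < as_series(
            impute_original(one)
        )["M1"]
        assert as_series(impute_new(two))["A"] < as_series(impute_new(one))["A"]

    def test_cross_method_worked_values_differ_as_expected(self, genus_toy):
        values = {
            m: as_series(impute(genus_toy, m))["M"]
            for m in ("original", "simple", "new")
        }
        assert values["original"] == pytest.approx(8.0 / 3.0)
        assert values["simple"] == pytest.approx(4.0)
        assert values["new"] == pytest.approx(10.0 / 3.0)


class TestSubstituteTerminal:
    def test_overwrites_value_and_provenance(self, genus_toy):
        table = impute_new(genus_toy)
        out = substitute_terminal(table, "M", 11.0)
        row = out.set_index("species").loc["M"]
        assert row["ed"] == 11.0
        assert row["provenance"] == "terminal_branch"
        assert out.set_index("species").loc["A", "ed"] == pytest.approx(13 / 3)

    def test_non_positive_divergence_rejected(self, genus_toy):
        table = impute_new(genus_toy)
        with pytest.raises(EdgePriorError):
            substitute_terminal(table, "M", 0.0)

    def test_unknown_species_rejected(self, genus_toy):
        table = impute_new(genus_toy)
        with pytest.raises(EdgePriorError):
            substitute_terminal(table, "nope", 3.0)
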