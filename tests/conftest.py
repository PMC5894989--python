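import dendropy
import pandas as pd
import pytest

from edgeprior.synthetic_data import FixtureConfig, make_fixture

TOY_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def toy_tree() -> dendropy.Tree:
    return dendropy.Tree.get(data=TOY_NEWICK, schema="newick")


@pytest.fixture
def toy_taxonomy() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species": ["A", "B", "C"],
            "genus": ["Ga", "Ga", "Gc"],
            "family": ["F1", "F1", "F2"],
            "clade": ["X", "X", "X"],
            "is_valid": True,
            "is_extinct": False,
        }
    )


def taxonomy_frame(rows) -> pd.DataFrame:
    """rows: (species, genus, family[, clade]) tuples, flags defaulted."""
    recs = []
    for row in rows:
        sp, g, f = row[:3]
        clade = row[3] if len(row) > 3 else "X"
        recs.append((sp, g, f, clade, True, False))
    return pd.DataFrame(
        recs,
        columns=["species", "genus", "family", "clade", "is_valid", "is_extinct"],
    )


@pytest.fixture(scope="session")
def small_bundle():
    """A compact seeded fixture bundle shared by the slower tests."""
    return make_fixture(FixtureConfig(n_species=180, missing_fraction=0.5, seed=42))
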