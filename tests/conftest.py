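import pandas as pd
import pytest
from hypothesis import settings

from seedtraits.trait_data import COLUMNS, TraitDataset

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_dataset(rows):
    """Build a TraitDataset from (accession, year, replicate, trait, value) rows."""
    return TraitDataset(pd.DataFrame(rows, columns=list(COLUMNS)))


@pytest.fixture
def toy_single_year():
    """Three accessions, two replicates, one year: accession means 5, 9, 7.

    One-way ANOVA by hand: SS_between = 16 (df 2, MS 8), SS_within = 6
    (df 3, MS 2), so sigma_g2 = (8 - 2)/2 = 3 and sigma_e2 = 2.
    """
    rows = []
    for acc, (v1, v2) in {"A": (4, 6), "B": (8, 10), "C": (6, 8)}.items():
        rows.append((acc, 2014, 1, "T", v1))
        rows.append((acc, 2014, 2, "T", v2))
    return make_dataset(rows)


@pytest.fixture
def toy_across_years():
    """Purely additive two-year layout: accession effects (-1, 0, +1),
    year effects (+2, -2), zero noise, nr=2.

    Exact expected-mean-squares arithmetic gives sigma_g2 = 1,
    sigma_gy2 = 0, sigma_e2 = 0.
    """
    rows = []
    for i, acc in enumerate(("A", "B", "C")):
        g = i - 1
        for year, yeff in ((2014, 2.0), (2019, -2.0)):
            for rep in (1, 2):
                rows.append((acc, year, rep, "T", 10.0 + g + yeff))
    return make_dataset(rows)


@pytest.fixture(scope="session")
def ref_trial():
    """Reference-shaped demo dataset.

    The seed gives a realisation where every trait keeps a positive
    genotypic variance estimate, so the full multi-trait pipeline
    (correlations, standardization) is defined for all nine traits; the
    boundary case (a trait whose estimate clamps to zero) is exercised
    separately in the variance-component tests.
    """
    from seedtraits.simulate import reference_fixture

    return reference_fixture(seed=1)


@pytest.fixture(scope="session")
def ref_blup(ref_trial):
    from seedtraits.repeatability import build_blup_matrix

    return build_blup_matrix(ref_trial, scope="across_years")
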