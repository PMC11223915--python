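import random

import pytest

from varshare.concordance import build_ledger
from varshare.fixtures import (
    CohortRecipe,
    make_classification_fixture,
    make_reference,
    published_profile,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def repeat_reference() -> str:
    """Repeat-rich sequence for normalization tests."""
    return make_reference(
        seed=11,
        length=400,
        repeat_tracts=[(50, "AT", 6), (120, "A", 9), (200, "CAG", 5), (300, "GC", 4)],
    )


@pytest.fixture(scope="session")
def published_fixture():
    return make_classification_fixture(published_profile(), seed=1)


@pytest.fixture(scope="session")
def published_ledger(published_fixture):
    return build_ledger(published_fixture.submissions)


@pytest.fixture(scope="session")
def qc_cohort():
    """Cohort with one of each injected pathology."""
    recipe = CohortRecipe(
        seed=7,
        n_unrelated=20,
        n_parent_offspring=2,
        n_duplicates=1,
        n_noisy=1,
        n_empty=1,
        n_sites=2000,
    )
    return simulate_cohort(recipe)


@pytest.fixture()
def rng() -> random.Random:
    return random.Random(123)
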