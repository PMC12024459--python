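from pathlib import Path

import pandas as pd
import pytest

from condiv import make_toy_panel

DATA = Path(__file__).parent / "data"


@pytest.fixture
def toy_panel():
    return make_toy_panel()


@pytest.fixture(scope="session")
def toy_expected():
    """Hand-enumerated Ho/He/MAF for the toy panel's three breeds."""
    return pd.read_csv(DATA / "toy_breed_expected.tsv", sep="\t").set_index("breed_code")


@pytest.fixture(scope="session")
def reference_diversity_table():
    """Published per-breed diversity summary for 16 Korean chicken breeds."""
    return pd.read_csv(DATA / "korean_chicken_diversity.tsv", sep="\t")


@pytest.fixture(scope="session")
def reference_census_table():
    """Published breed census (sample counts, FAO class, origin)."""
    return pd.read_csv(DATA / "korean_chicken_breeds.tsv", sep="\t")
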