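import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from fpdiv import ScenarioSpec, TraitTable, simulate_bundle

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_record(**overrides) -> dict:
    """A valid trait record, with optional overrides."""
    base = dict(
        body_size_um=200.0,
        trophi_type="malleate",
        feeding_type="microphagous",
        protection="active",
        lorica_type="illoricate",
        corona_type="euchlanis_brachionus",
        habitat_preference="beta_mesosaprobic",
        tolerance=3,
    )
    base.update(overrides)
    return base


def make_trait_table(records: dict[str, dict]) -> TraitTable:
    df = pd.DataFrame.from_dict(records, orient="index")
    df.index.name = "species"
    return TraitTable(df)


@pytest.fixture(scope="session")
def small_bundle():
    """A compact filtering-scenario dataset shared by slower tests."""
    spec = ScenarioSpec(
        scenario="filtering", n_species=10, n_dates_per_season=1, seed=11
    )
    return simulate_bundle(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
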