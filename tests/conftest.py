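import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import poipanel as pp
from poipanel import simulate

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1() -> pd.DataFrame:
    return pp.load_fixture("table1")


@pytest.fixture(scope="session")
def table2() -> pd.DataFrame:
    return pp.load_fixture("table2")


@pytest.fixture(scope="session")
def table3() -> pd.DataFrame:
    return pp.load_fixture("table3")


@pytest.fixture(scope="session")
def table4() -> pd.DataFrame:
    return pp.load_fixture("table4")


@pytest.fixture(scope="session")
def all_variants(table1, table2) -> pd.DataFrame:
    return pd.concat([table1, table2], ignore_index=True)


@pytest.fixture(scope="session")
def concordant_policy() -> pp.ConflictPolicy:
    return pp.ConflictPolicy(
        mode="paper_concordant", overrides=pp.PAPER_CONCORDANT_OVERRIDES
    )


@pytest.fixture(scope="session")
def classified(all_variants, concordant_policy) -> pd.DataFrame:
    return pp.classify_all(all_variants, concordant_policy)


@pytest.fixture()
def small_sim() -> simulate.SimConfig:
    return simulate.SimConfig(seed=7, n_cases=6, n_controls=6)
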