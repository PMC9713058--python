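import pytest

from germscreen.acmg import classify_table
from germscreen.synthetic_data import (
    SimulationConfig,
    fixture_table1,
    fixture_table1_classified,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def table1_bundle():
    return fixture_table1()


@pytest.fixture(scope="session")
def table1_engine_classified(table1_bundle):
    """Fixture rows classified by the rule engine."""
    return classify_table(
        [(r, table1_bundle.criteria[r.variant_id]) for r in table1_bundle.records]
    )


@pytest.fixture(scope="session")
def table1_printed_classified(table1_bundle):
    """Fixture rows carrying their published tiers verbatim."""
    return fixture_table1_classified(table1_bundle)


@pytest.fixture(scope="session")
def sim_bundle():
    """Default study-condition simulation (128 patients, planted strata)."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture
def small_sim_bundle(tmp_path):
    bundle = simulate_cohort(
        SimulationConfig(seed=5, n_patients=30, n_background=15),
        out_dir=tmp_path / "bundle",
    )
    return bundle, tmp_path / "bundle"
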