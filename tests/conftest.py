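from types import SimpleNamespace

import pytest
from hypothesis import HealthCheck, settings

from nutriwarn.pipeline import run_supply_pipeline
from nutriwarn.regimes import CHILE_DEFAULT_CONFIG, phase_thresholds
from nutriwarn.synthetic import default_scenario, generate_supply

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def final_regime():
    return phase_thresholds("final")


@pytest.fixture(scope="session")
def initial_full_regime():
    """Initial-phase regime completed with liquid limits for nesting tests.

    Initial-phase liquid limits are not part of the shipped defaults, so
    tests that need a complete earlier regime supply a set in which each
    limit is at least the corresponding final-phase limit.
    """
    config = {
        "initial": {
            **CHILE_DEFAULT_CONFIG["initial"],
            "liquids": {"energy_kcal": 100, "sugars_g": 7.5, "satfat_g": 4.5, "sodium_mg": 150},
        }
    }
    return phase_thresholds("initial", config)


@pytest.fixture(scope="session")
def default_run(final_regime):
    """One full generate -> pipeline run of the shipped scenario."""
    config = default_scenario(seed=17)
    records_by_year, sales, truth = generate_supply(config, final_regime)
    sample = run_supply_pipeline(records_by_year, final_regime, sales)
    return SimpleNamespace(
        config=config,
        records_by_year=records_by_year,
        sales=sales,
        truth=truth,
        sample=sample,
        regime=final_regime,
    )
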