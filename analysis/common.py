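"""Shared setup for the numbered analysis scripts.

Every script works from the same deterministic run of the shipped
scenario (seed 17): generate the synthetic supply, push it through the
exclusion cascade under the final-phase regime, and hand back the
classified analytic sample together with the planted truth.
"""

from pathlib import Path
from types import SimpleNamespace

from nutriwarn import (
    default_scenario,
    generate_supply,
    phase_thresholds,
    run_supply_pipeline,
)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def default_run(seed: int = 17) -> SimpleNamespace:
    regime = phase_thresholds("final")
    config = default_scenario(seed=seed)
    records_by_year, sales, truth = generate_supply(config, regime)
    sample = run_supply_pipeline(records_by_year, regime, sales)
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    return SimpleNamespace(
        config=config, regime=regime, records_by_year=records_by_year,
        sales=sales, truth=truth, sample=sample,
    )
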