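"""Threshold regimes: the per-phase nutrient limits of the labelling law.

The Chilean law tightened its cutoffs over three implementation phases.
The limits shipped here are the publicly documented ones:

* final phase, solids (per 100 g): 275 kcal, 10 g sugars, 4 g saturated
  fats, 400 mg sodium;
* final phase, liquids (per 100 mL): 70 kcal, 5 g sugars, 3 g saturated
  fats, 100 mg sodium;
* initial phase, solids (per 100 g): 350 kcal, 22.5 g sugars, 6 g
  saturated fats, 800 mg sodium.

Initial-phase liquid limits and the entire second phase are deliberately
NOT defaulted: a configuration that needs them must supply them
explicitly, and using a regime for a basis it does not cover raises a
:class:`~nutriwarn.errors.ConfigurationError` naming the missing cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import yaml

from .errors import ConfigurationError
from .types import LIQUID, SOLID

LIMIT_FIELDS = ("energy_kcal", "sugars_g", "satfat_g", "sodium_mg")


@dataclass(frozen=True)
class NutrientLimits:
    """Cutoffs for one basis (per 100 g or per 100 mL)."""

    energy_kcal: float
    sugars_g: float
    satfat_g: float
    sodium_mg: float

    def __post_init__(self):
        for name in LIMIT_FIELDS:
            v = getattr(self, name)
            if not v > 0:
                raise ConfigurationError(f"limit {name} must be > 0, got {v}")

    def limit(self, nutrient: str) -> float:
        return getattr(self, {"energy": "energy_kcal", "sugars": "sugars_g",
                              "satfat": "satfat_g", "sodium": "sodium_mg"}[nutrient])


@dataclass(frozen=True)
class ThresholdRegime:
    """Limits in force during one phase, separately for solids and liquids.

    Either basis block may be absent (``None``) when the phase's limits
    for that basis are not configured; attempting to classify a product
    of that basis then fails loudly.
    """

    phase_id: str
    solid_limits: Optional[NutrientLimits] = None
    liquid_limits: Optional[NutrientLimits] = None

    def limits_for(self, basis: str) -> NutrientLimits:
        limits = self.solid_limits if basis == SOLID else self.liquid_limits
        if limits is None:
            block = "solids" if basis == SOLID else "liquids"
            raise ConfigurationError(
                f"regime {self.phase_id!r} has no {block} limits configured"
            )
        return limits


#: Shipped configuration: only publicly documented cells are present.
CHILE_DEFAULT_CONFIG = {
    "final": {
        "solids": {"energy_kcal": 275, "sugars_g": 10, "satfat_g": 4, "sodium_mg": 400},
        "liquids": {"energy_kcal": 70, "sugars_g": 5, "satfat_g": 3, "sodium_mg": 100},
    },
    "initial": {
        "solids": {"energy_kcal": 350, "sugars_g": 22.5, "satfat_g": 6, "sodium_mg": 800},
    },
}


def _parse_limits(phase_id: str, block_name: str, cells) -> NutrientLimits:
    if not isinstance(cells, dict):
        raise ConfigurationError(f"{phase_id}.{block_name} must be a mapping of limits")
    missing = [f for f in LIMIT_FIELDS if f not in cells]
    if missing:
        raise ConfigurationError(
            f"{phase_id}.{block_name} is missing limit cell(s): {', '.join(missing)}"
        )
    unknown = sorted(set(cells) - set(LIMIT_FIELDS))
    if unknown:
        raise ConfigurationError(
            f"{phase_id}.{block_name} has unknown limit cell(s): {', '.join(unknown)}"
        )
    return NutrientLimits(**{f: float(cells[f]) for f in LIMIT_FIELDS})


def phase_thresholds(phase_id: str, config=None) -> ThresholdRegime:
    """Look up the :class:`ThresholdRegime` for one phase.

    Parameters
    ----------
    phase_id:
        Key into the configuration (the shipped one knows ``"final"`` and
        ``"initial"``).
    config:
        Mapping ``phase_id -> {solids: {...}, liquids: {...}}``.  Defaults
        to the shipped Chilean limits.  A declared basis block must be
        complete; an undeclared block simply leaves that basis
        unconfigured (classification of such products will fail).
    """
    if config is None:
        config = CHILE_DEFAULT_CONFIG
    if phase_id not in config:
        raise ConfigurationError(
            f"unknown phase {phase_id!r}; configured phases: {sorted(config)}"
        )
    entry = config[phase_id]
    unknown = sorted(set(entry) - {"solids", "liquids"})
    if unknown:
        raise ConfigurationError(
            f"{phase_id} has unknown block(s): {', '.join(unknown)} (expected solids/liquids)"
        )
    solids = _parse_limits(phase_id, "solids", entry["solids"]) if "solids" in entry else None
    liquids = _parse_limits(phase_id, "liquids", entry["liquids"]) if "liquids" in entry else None
    if solids is None and liquids is None:
        raise ConfigurationError(f"{phase_id} configures neither solids nor liquids")
    return ThresholdRegime(phase_id=phase_id, solid_limits=solids, liquid_limits=liquids)


def load_regime_config(path) -> dict:
    """Load a regime configuration from a YAML (or JSON) document."""
    with open(path, "r", encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigurationError(f"regime config {path} must be a mapping keyed by phase id")
    return config
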