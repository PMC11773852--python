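"""Domain types for packaged-product records.

A :class:`ProductRecord` is one product observed in one collection period.
Nutrient amounts are the label declarations per 100 g (solids) or 100 mL
(liquids); a product sold as a powder/concentrate carries a
``reconstitution_factor`` that converts as-sold amounts to as-consumed
amounts (see :func:`nutriwarn.profile_model.apply_reconstitution`).

Missing label information is represented as ``None`` and handled by the
supply pipeline (imputation, then exclusion); the types here only enforce
hard invariants (non-negative amounts, period/year consistency).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional

from .errors import ValidationError

#: Regulatory periods in analysis order.
PERIODS = ("T0", "T1", "T2", "T3")

#: Collection years consistent with each period.  The pre-law baseline
#: pools two collection waves.
PERIOD_YEARS = {
    "T0": frozenset({2015, 2016}),
    "T1": frozenset({2017}),
    "T2": frozenset({2019}),
    "T3": frozenset({2020}),
}

YEAR_PERIOD = {2015: "T0", 2016: "T0", 2017: "T1", 2019: "T2", 2020: "T3"}

#: Regulated quantities, in the order used throughout the package.
NUTRIENTS = ("energy", "sugars", "satfat", "sodium")

SOLID = "solid"
LIQUID = "liquid"


@dataclass(frozen=True)
class NutrientPanel:
    """Label-declared amounts per 100 g (solids) or 100 mL (liquids).

    ``None`` means the label did not declare the amount.  ``totalfat_g``
    and ``serving_size`` only matter for the saturated-fat imputation
    rule; ``serving_size`` is grams (solids) or millilitres (liquids)
    per declared serving.
    """

    energy_kcal: Optional[float] = None
    sugars_g: Optional[float] = None
    satfat_g: Optional[float] = None
    totalfat_g: Optional[float] = None
    sodium_mg: Optional[float] = None
    serving_size: Optional[float] = None

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if v is not None and v < 0:
                raise ValidationError(f"{f.name} must be >= 0, got {v}")

    def amount(self, nutrient: str) -> Optional[float]:
        """Amount of one regulated quantity (``energy``/``sugars``/``satfat``/``sodium``)."""
        return getattr(self, _PANEL_FIELD[nutrient])

    def scaled(self, factor: float) -> "NutrientPanel":
        """Panel with every declared nutrient amount multiplied by ``factor``.

        Serving size is left untouched: it describes the as-sold package.
        """
        def mul(v):
            return None if v is None else v * factor

        return NutrientPanel(
            energy_kcal=mul(self.energy_kcal),
            sugars_g=mul(self.sugars_g),
            satfat_g=mul(self.satfat_g),
            totalfat_g=mul(self.totalfat_g),
            sodium_mg=mul(self.sodium_mg),
            serving_size=self.serving_size,
        )

    def key(self) -> tuple:
        """Hashable identity of the declared amounts (used for deduplication)."""
        return (
            self.energy_kcal,
            self.sugars_g,
            self.satfat_g,
            self.totalfat_g,
            self.sodium_mg,
        )


_PANEL_FIELD = {
    "energy": "energy_kcal",
    "sugars": "sugars_g",
    "satfat": "satfat_g",
    "sodium": "sodium_mg",
    "totalfat": "totalfat_g",
}


@dataclass(frozen=True)
class ScopeFlags:
    """Ingredient-list-derived indicators of added critical ingredients.

    Derived once per product from its ingredient list and immutable
    thereafter; a product with no added sugars, saturated fats or sodium
    is outside the warning-label scope regardless of its amounts.
    """

    added_sugars: bool
    added_satfat: bool
    added_sodium: bool

    @property
    def any_added(self) -> bool:
        return self.added_sugars or self.added_satfat or self.added_sodium

    def key(self) -> tuple:
        return (self.added_sugars, self.added_satfat, self.added_sodium)


@dataclass(frozen=True)
class WarningProfile:
    """Classifier verdict: one flag per regulated quantity plus their OR."""

    high_energy: bool
    high_sugars: bool
    high_satfat: bool
    high_sodium: bool
    any_high: bool

    def __post_init__(self):
        expected = (
            self.high_energy or self.high_sugars or self.high_satfat or self.high_sodium
        )
        if self.any_high != expected:
            raise ValidationError("any_high must equal the OR of the component flags")

    @classmethod
    def from_flags(cls, energy: bool, sugars: bool, satfat: bool, sodium: bool):
        return cls(
            high_energy=bool(energy),
            high_sugars=bool(sugars),
            high_satfat=bool(satfat),
            high_sodium=bool(sodium),
            any_high=bool(energy or sugars or satfat or sodium),
        )

    def flag(self, name: str) -> bool:
        """Look up a flag by short name: ``any``/``energy``/``sugars``/``satfat``/``sodium``."""
        return getattr(self, "any_high" if name == "any" else f"high_{name}")


@dataclass(frozen=True)
class ProductRecord:
    """One product in one collection period."""

    product_id: str
    period: str
    collection_year: int
    group: str
    basis: str  # SOLID or LIQUID
    panel: NutrientPanel
    scope: Optional[ScopeFlags] = None  # None: ingredient list missing
    regulated_category: bool = True
    requires_reconstitution: bool = False
    reconstitution_factor: Optional[float] = None
    reconstituted: bool = False
    brand_family: Optional[str] = None
    market_group: Optional[str] = None
    sales: Optional[float] = None

    def __post_init__(self):
        if self.period not in PERIOD_YEARS:
            raise ValidationError(f"unknown period {self.period!r}")
        if self.collection_year not in PERIOD_YEARS[self.period]:
            raise ValidationError(
                f"collection_year {self.collection_year} inconsistent with period {self.period}"
            )
        if self.basis not in (SOLID, LIQUID):
            raise ValidationError(f"basis must be 'solid' or 'liquid', got {self.basis!r}")
        if self.reconstitution_factor is not None and self.reconstitution_factor <= 0:
            raise ValidationError("reconstitution_factor must be > 0 when present")

    def identity(self) -> tuple:
        """Identity used to pool baseline years: the product identifier when
        present, else group + brand family + declared panel."""
        if self.product_id:
            return ("id", self.product_id)
        return ("fallback", self.group, self.brand_family, self.panel.key())

    def dedup_key(self) -> tuple:
        """Within-period duplicate key: same nutrition panel, same ingredient
        flags, same group and brand family means the same product in a
        different package size."""
        scope_key = None if self.scope is None else self.scope.key()
        return (self.group, self.brand_family, self.panel.key(), scope_key)

    def with_(self, **changes) -> "ProductRecord":
        return replace(self, **changes)
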