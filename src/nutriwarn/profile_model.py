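"""Classification of products as "high in" critical nutrients.

A packaged product falls under the warning-label scheme only if its
ingredient list shows *added* sugars, saturated fats or sodium.  For a
product in scope, each nutrient flag is raised when the declared amount
per 100 g/mL *strictly exceeds* the regime cutoff for the product's
basis; ties are compliant, because the law speaks of amounts that
"exceed" the limit.  The calories flag has no added-calories analogue,
so it requires at least one added-ingredient flag plus energy above the
energy cutoff (this gate is configurable).

Products sold to be reconstituted (powders, concentrates) are judged as
consumed: their panel is rescaled by the package's reconstitution factor
and they are always compared against liquid limits.

Amounts are compared exactly as declared on the label; no re-rounding is
applied before comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import IncompleteRecordError, ScopeError, ValidationError
from .regimes import ThresholdRegime, phase_thresholds  # noqa: F401  (re-export)
from .types import LIQUID, ProductRecord, WarningProfile


def apply_reconstitution(record: ProductRecord) -> ProductRecord:
    """Convert an as-sold record to as-consumed amounts.

    Every declared panel amount is multiplied by the reconstitution
    factor, the basis becomes liquid (a reconstituted product is drunk or
    spooned as a liquid and is judged against liquid limits) and the
    factor is cleared.  A record without a factor is returned unchanged.
    The input record is never mutated.
    """
    factor = record.reconstitution_factor
    if factor is None:
        return record
    if factor <= 0:  # unreachable through the dataclass, kept for raw callers
        raise ValidationError(f"reconstitution_factor must be > 0, got {factor}")
    return record.with_(
        panel=record.panel.scaled(factor),
        basis=LIQUID,
        reconstitution_factor=None,
        requires_reconstitution=False,
        reconstituted=True,
    )


#: Per-serving total-fat threshold (g) below which an undeclared
#: saturated-fat amount may be read as zero: labelling rules only require
#: fat subtypes to be declared when total fat reaches 3 g per serving.
SATFAT_IMPUTE_LIMIT_G = 3.0


def impute_missing_saturated_fat(record: ProductRecord) -> ProductRecord:
    """Replace a missing saturated-fat amount by 0 when legally undeclarable.

    Applies only when total fat per serving (``totalfat_g * serving_size
    / 100``) is below 3 g; any record still missing saturated fat after
    this rule remains incomplete and is excluded downstream.
    """
    panel = record.panel
    if panel.satfat_g is not None:
        return record
    if panel.totalfat_g is None or panel.serving_size is None:
        return record
    fat_per_serving = panel.totalfat_g * panel.serving_size / 100.0
    if fat_per_serving < SATFAT_IMPUTE_LIMIT_G:
        return record.with_(panel=panel.__class__(
            energy_kcal=panel.energy_kcal,
            sugars_g=panel.sugars_g,
            satfat_g=0.0,
            totalfat_g=panel.totalfat_g,
            sodium_mg=panel.sodium_mg,
            serving_size=panel.serving_size,
        ))
    return record


def classify_high_in(
    record: ProductRecord,
    regime: ThresholdRegime,
    *,
    strict: bool = True,
    energy_requires_scope: bool = True,
) -> WarningProfile:
    """Classify one regulated record under one threshold regime.

    Parameters
    ----------
    record:
        Must already be reconstituted/imputed and in the regulated
        category; out-of-scope records raise :class:`ScopeError` so the
        pipeline's exclusion stage cannot be silently skipped.
    regime:
        Limits are chosen by the record's basis.
    strict:
        Compare with ``>`` (default, ties compliant).  ``False`` switches
        to ``>=`` for sensitivity runs.
    energy_requires_scope:
        Gate the calories flag on having at least one added-ingredient
        flag (default).

    Raises
    ------
    ScopeError
        If ``record.regulated_category`` is false.
    IncompleteRecordError
        If the ingredient flags are missing, or an amount needed by an
        active flag is missing.
    """
    if not record.regulated_category:
        raise ScopeError(
            f"record {record.product_id!r} is outside the regulated category; "
            "exclude it before classification"
        )
    if record.scope is None:
        raise IncompleteRecordError(
            f"record {record.product_id!r} has no ingredient-derived scope flags"
        )
    limits = regime.limits_for(record.basis)
    scope = record.scope
    panel = record.panel

    def exceeds(nutrient: str) -> bool:
        amount = panel.amount(nutrient)
        if amount is None:
            raise IncompleteRecordError(
                f"record {record.product_id!r} is missing the {nutrient} amount "
                "required by an active scope flag"
            )
        limit = limits.limit(nutrient)
        return amount > limit if strict else amount >= limit

    high_sugars = scope.added_sugars and exceeds("sugars")
    high_satfat = scope.added_satfat and exceeds("satfat")
    high_sodium = scope.added_sodium and exceeds("sodium")
    energy_gate = scope.any_added if energy_requires_scope else True
    high_energy = energy_gate and exceeds("energy")
    return WarningProfile.from_flags(high_energy, high_sugars, high_satfat, high_sodium)


FLAG_COLUMNS = ("high_energy", "high_sugars", "high_satfat", "high_sodium", "any_high")


def classify_frame(
    frame: pd.DataFrame,
    regime: ThresholdRegime,
    *,
    strict: bool = True,
    energy_requires_scope: bool = True,
) -> pd.DataFrame:
    """Vectorised batch classification of a product table.

    Expects the delimited schema of :mod:`nutriwarn.io` (columns
    ``basis``, ``energy_kcal`` ... ``sodium_mg``, ``has_added_*``,
    ``regulated_category``) and returns a copy with the five boolean flag
    columns appended.  Semantics match :func:`classify_high_in` row by
    row; rows violating its preconditions raise the same errors.
    """
    if (~frame["regulated_category"].astype(bool)).any():
        bad = frame.loc[~frame["regulated_category"].astype(bool), "product_id"].iloc[0]
        raise ScopeError(f"record {bad!r} is outside the regulated category")
    out = frame.copy()
    is_liquid = out["basis"].eq(LIQUID).to_numpy()
    n = len(out)

    def limit_vector(nutrient: str) -> np.ndarray:
        vals = np.empty(n)
        if (~is_liquid).any():
            vals[~is_liquid] = regime.limits_for("solid").limit(nutrient)
        if is_liquid.any():
            vals[is_liquid] = regime.limits_for("liquid").limit(nutrient)
        return vals

    scope_cols = ["has_added_sugars", "has_added_satfat", "has_added_sodium"]
    if frame[scope_cols].isna().any().any():
        bad = frame.loc[frame[scope_cols].isna().any(axis=1), "product_id"].iloc[0]
        raise IncompleteRecordError(f"record {bad!r} has no ingredient-derived scope flags")
    scope = {c: out[c].astype(bool).to_numpy() for c in scope_cols}
    any_scope = scope["has_added_sugars"] | scope["has_added_satfat"] | scope["has_added_sodium"]

    def flag(nutrient: str, column: str, active: np.ndarray) -> np.ndarray:
        amounts = out[column].to_numpy(dtype=float)
        if np.isnan(amounts[active]).any():
            bad = out.loc[active & np.isnan(amounts), "product_id"].iloc[0]
            raise IncompleteRecordError(
                f"record {bad!r} is missing the {nutrient} amount required by an active scope flag"
            )
        lim = limit_vector(nutrient)
        over = amounts > lim if strict else amounts >= lim
        return active & np.where(np.isnan(amounts), False, over)

    high_sugars = flag("sugars", "sugars_g", scope["has_added_sugars"])
    high_satfat = flag("satfat", "satfat_g", scope["has_added_satfat"])
    high_sodium = flag("sodium", "sodium_mg", scope["has_added_sodium"])
    gate = any_scope if energy_requires_scope else np.ones(n, dtype=bool)
    high_energy = flag("energy", "energy_kcal", gate)

    out["high_energy"] = high_energy
    out["high_sugars"] = high_sugars
    out["high_satfat"] = high_satfat
    out["high_sodium"] = high_sodium
    out["any_high"] = high_energy | high_sugars | high_satfat | high_sodium
    return out
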