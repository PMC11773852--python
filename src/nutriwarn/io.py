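"""Delimited-file schemas for product tables and sales tables.

Product tables are UTF-8 CSV with a header row; missing values are empty
fields.  One file per collection year on input; the analytic sample is
written with the five classification flags appended.

Product columns
---------------
product_id, period, collection_year, group, market_group, brand_family,
basis, energy_kcal, sugars_g, satfat_g, totalfat_g, sodium_mg,
serving_size, has_added_sugars, has_added_satfat, has_added_sodium,
requires_reconstitution, reconstitution_factor, regulated_category

Boolean columns are written as 1/0.  A row whose three ``has_added_*``
cells are all empty has an unknown ingredient list (scope missing).

Sales columns
-------------
id, group, year, sales  -- one row per (id, year); ``group`` is the
market-share (sales taxonomy) group, not the 16-group analysis taxonomy.
"""

from __future__ import annotations

import math
from typing import Iterable, List, Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import NutrientPanel, ProductRecord, ScopeFlags

PRODUCT_COLUMNS = [
    "product_id",
    "period",
    "collection_year",
    "group",
    "market_group",
    "brand_family",
    "basis",
    "energy_kcal",
    "sugars_g",
    "satfat_g",
    "totalfat_g",
    "sodium_mg",
    "serving_size",
    "has_added_sugars",
    "has_added_satfat",
    "has_added_sodium",
    "requires_reconstitution",
    "reconstitution_factor",
    "regulated_category",
]

SALES_COLUMNS = ["id", "group", "year", "sales"]


def _opt(value) -> Optional[float]:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    return float(value)


def _opt_bool(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        return value.strip().lower() in ("1", "true", "yes")
    return bool(value)


def records_to_frame(records: Iterable[ProductRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        scope = r.scope
        rows.append(
            {
                "product_id": r.product_id,
                "period": r.period,
                "collection_year": r.collection_year,
                "group": r.group,
                "market_group": r.market_group,
                "brand_family": r.brand_family,
                "basis": r.basis,
                "energy_kcal": r.panel.energy_kcal,
                "sugars_g": r.panel.sugars_g,
                "satfat_g": r.panel.satfat_g,
                "totalfat_g": r.panel.totalfat_g,
                "sodium_mg": r.panel.sodium_mg,
                "serving_size": r.panel.serving_size,
                "has_added_sugars": None if scope is None else int(scope.added_sugars),
                "has_added_satfat": None if scope is None else int(scope.added_satfat),
                "has_added_sodium": None if scope is None else int(scope.added_sodium),
                "requires_reconstitution": int(r.requires_reconstitution),
                "reconstitution_factor": r.reconstitution_factor,
                "regulated_category": int(r.regulated_category),
            }
        )
    return pd.DataFrame(rows, columns=PRODUCT_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> List[ProductRecord]:
    missing = [c for c in PRODUCT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"product table is missing column(s): {', '.join(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        flags = (
            _opt_bool(row.has_added_sugars),
            _opt_bool(row.has_added_satfat),
            _opt_bool(row.has_added_sodium),
        )
        scope = None if any(f is None for f in flags) else ScopeFlags(*flags)
        records.append(
            ProductRecord(
                product_id=str(row.product_id),
                period=str(row.period),
                collection_year=int(row.collection_year),
                group=str(row.group),
                market_group=None if pd.isna(row.market_group) else str(row.market_group),
                brand_family=None if pd.isna(row.brand_family) else str(row.brand_family),
                basis=str(row.basis),
                panel=NutrientPanel(
                    energy_kcal=_opt(row.energy_kcal),
                    sugars_g=_opt(row.sugars_g),
                    satfat_g=_opt(row.satfat_g),
                    totalfat_g=_opt(row.totalfat_g),
                    sodium_mg=_opt(row.sodium_mg),
                    serving_size=_opt(row.serving_size),
                ),
                scope=scope,
                regulated_category=bool(_opt_bool(row.regulated_category)),
                requires_reconstitution=bool(_opt_bool(row.requires_reconstitution)),
                reconstitution_factor=_opt(row.reconstitution_factor),
            )
        )
    return records


def write_product_table(records: Iterable[ProductRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_product_table(path) -> List[ProductRecord]:
    return frame_to_records(pd.read_csv(path))


def write_sales_table(frame: pd.DataFrame, path) -> None:
    frame.loc[:, SALES_COLUMNS].to_csv(path, index=False)


def read_sales_frame(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in SALES_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"sales table is missing column(s): {', '.join(missing)}")
    return frame
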