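"""Supply-processing cascade: from raw collection waves to the analytic sample.

The stages run in a fixed, documented order — pool the two baseline
years, drop within-period package-size duplicates, reconstitute powders
and concentrates, apply the saturated-fat imputation rule, exclude
incomplete records, exclude products outside the regulated category,
drop non-best-selling products (< 1% market share within their sales
group), and classify the survivors.  Every removal is tallied in an
:class:`ExclusionLedger` whose rows conserve exactly:
``photographed = final + duplicates + incomplete + out_of_scope +
below_share`` per period.

Setting ``min_share=0`` (or ``full_supply=True``) skips the market-share
filter, which is the full-supply sensitivity mode.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd

from . import io as nwio
from .errors import NutriwarnError, UndefinedShareError, ValidationError
from .profile_model import (
    apply_reconstitution,
    classify_high_in,
    impute_missing_saturated_fat,
)
from .regimes import ThresholdRegime
from .types import PERIODS, YEAR_PERIOD, ProductRecord, WarningProfile

logger = logging.getLogger(__name__)

EXCLUSION_STAGES = ("duplicates", "incomplete", "out_of_scope", "below_share")


@dataclass
class LedgerRow:
    photographed: int = 0
    duplicates: int = 0
    incomplete: int = 0
    out_of_scope: int = 0
    below_share: int = 0
    final: int = 0

    def conserved(self) -> bool:
        return self.photographed == (
            self.final + self.duplicates + self.incomplete + self.out_of_scope + self.below_share
        )

    def to_dict(self) -> dict:
        return dict(
            photographed=self.photographed,
            duplicates=self.duplicates,
            incomplete=self.incomplete,
            out_of_scope=self.out_of_scope,
            below_share=self.below_share,
            final=self.final,
        )


@dataclass
class ExclusionLedger:
    """Per-period accounting of every record entering or leaving the cascade."""

    rows: Dict[str, LedgerRow] = field(default_factory=dict)

    def row(self, period: str) -> LedgerRow:
        return self.rows.setdefault(period, LedgerRow())

    def conserved(self) -> bool:
        return all(row.conserved() for row in self.rows.values())

    def to_dict(self) -> dict:
        return {period: row.to_dict() for period, row in self.rows.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"period": p, **row.to_dict()} for p, row in sorted(self.rows.items())]
        )


# ---------------------------------------------------------------------------
# individual stages
# ---------------------------------------------------------------------------

def pool_baseline(
    records_2015: Sequence[ProductRecord], records_2016: Sequence[ProductRecord]
) -> List[ProductRecord]:
    """Pool the two pre-law collection waves into one baseline.

    Identity clashes are resolved in favour of the most recent (2016)
    collection.  Output order: all 2016 records, then 2015-only records,
    all labelled period T0.
    """
    for rec in records_2015:
        if rec.collection_year != 2015:
            raise ValidationError(f"record {rec.product_id!r} is not from 2015")
    for rec in records_2016:
        if rec.collection_year != 2016:
            raise ValidationError(f"record {rec.product_id!r} is not from 2016")
    seen = set()
    pooled: List[ProductRecord] = []
    for rec in records_2016:
        pooled.append(rec.with_(period="T0"))
        seen.add(rec.identity())
    for rec in records_2015:
        if rec.identity() not in seen:
            pooled.append(rec.with_(period="T0"))
            seen.add(rec.identity())
    return pooled


def deduplicate_sizes(records: Sequence[ProductRecord]) -> List[ProductRecord]:
    """Collapse package-size duplicates within one period.

    Records identical on (group, brand family, nutrition panel, scope
    flags) are the same product in different sizes; the one with the
    lexicographically smallest ``product_id`` is kept so the choice is
    deterministic (duplicates agree on every analysed field, so the
    choice is statistically irrelevant).
    """
    periods = {r.period for r in records}
    if len(periods) > 1:
        raise ValidationError(f"deduplicate_sizes expects a single period, got {sorted(periods)}")
    best: Dict[tuple, ProductRecord] = {}
    order: List[tuple] = []
    for rec in records:
        key = rec.dedup_key()
        if key not in best:
            best[key] = rec
            order.append(key)
        elif rec.product_id < best[key].product_id:
            best[key] = rec
    return [best[key] for key in order]


def exclude_incomplete(records: Sequence[ProductRecord]) -> List[ProductRecord]:
    """Drop records lacking information the classifier needs.

    Required: ingredient-derived scope flags, the four regulated
    amounts (saturated fat after the imputation rule), and a
    reconstitution factor for products that need one.
    """
    return [r for r in records if is_complete(r)]


def is_complete(record: ProductRecord) -> bool:
    if record.scope is None:
        return False
    panel = record.panel
    if panel.energy_kcal is None or panel.sugars_g is None or panel.sodium_mg is None:
        return False
    if panel.satfat_g is None:
        return False
    if record.requires_reconstitution and not record.reconstituted:
        # reconstitution instructions were needed but missing
        return False
    return True


def exclude_out_of_scope(records: Sequence[ProductRecord]) -> List[ProductRecord]:
    """Drop unprocessed/minimally processed/exempt products."""
    return [r for r in records if r.regulated_category]


def compute_market_share(sales: pd.DataFrame, id: str, group: str, year: int) -> float:
    """Sales of one product/brand family as a percent of its group total.

    ``sales(id, year) * 100 / sum of sales(group, year)``.  An id absent
    from the table counts as zero sales (with a warning); a group/year
    with zero total raises :class:`UndefinedShareError`.
    """
    in_group = sales[(sales["group"] == group) & (sales["year"] == year)]
    total = float(in_group["sales"].sum())
    if total <= 0:
        raise UndefinedShareError(f"group {group!r} has no sales in {year}")
    own = sales[(sales["id"] == id) & (sales["year"] == year)]
    if own.empty:
        warnings.warn(f"no sales row for id {id!r} in {year}; treating as zero", stacklevel=2)
        return 0.0
    return float(own["sales"].sum()) * 100.0 / total


def _share_lookup(sales: pd.DataFrame) -> dict:
    """Precomputed (id, group, year) -> share%, for bulk filtering."""
    totals = sales.groupby(["group", "year"])["sales"].sum()
    shares = {}
    for row in sales.itertuples(index=False):
        total = totals.loc[(row.group, row.year)]
        if total > 0:
            shares[(row.id, row.group, row.year)] = float(row.sales) * 100.0 / float(total)
    return shares


def record_market_share(record: ProductRecord, shares: dict) -> float:
    sid = record.brand_family or record.product_id
    return shares.get((sid, record.market_group, record.collection_year), 0.0)


def filter_best_selling(
    records: Sequence[ProductRecord],
    sales: pd.DataFrame,
    min_share: float = 1.0,
) -> List[ProductRecord]:
    """Keep records whose market share meets the minimum (percent).

    A record's share is looked up by its brand family (falling back to
    its product id) within its market group and collection year; an
    unknown id has share 0.  ``min_share=0`` keeps everything (the
    full-supply sensitivity mode).
    """
    if min_share < 0:
        raise ValidationError(f"min_share must be >= 0, got {min_share}")
    if min_share == 0:
        return list(records)
    shares = _share_lookup(sales)
    return [r for r in records if record_market_share(r, shares) >= min_share]


# ---------------------------------------------------------------------------
# the full cascade
# ---------------------------------------------------------------------------

@dataclass
class AnalyticSample:
    """Classified survivors of the cascade plus the exclusion ledger."""

    records: List[ProductRecord]
    profiles: List[WarningProfile]
    ledger: ExclusionLedger
    regime: Optional[ThresholdRegime] = None

    def to_frame(self) -> pd.DataFrame:
        frame = nwio.records_to_frame(self.records)
        frame["high_energy"] = [p.high_energy for p in self.profiles]
        frame["high_sugars"] = [p.high_sugars for p in self.profiles]
        frame["high_satfat"] = [p.high_satfat for p in self.profiles]
        frame["high_sodium"] = [p.high_sodium for p in self.profiles]
        frame["any_high"] = [p.any_high for p in self.profiles]
        return frame

    def __len__(self) -> int:
        return len(self.records)


def _records_for_period(raw_by_year, period: str) -> List[ProductRecord]:
    years = sorted(y for y in raw_by_year if YEAR_PERIOD.get(y) == period)
    out: List[ProductRecord] = []
    for y in years:
        out.extend(raw_by_year[y])
    return out


def run_supply_pipeline(
    raw_by_year: Dict[int, Sequence[ProductRecord]],
    regime: ThresholdRegime,
    sales: Optional[pd.DataFrame] = None,
    *,
    min_share: float = 1.0,
    full_supply: bool = False,
    strict: bool = True,
) -> AnalyticSample:
    """Run the whole cascade and classify the survivors.

    Parameters
    ----------
    raw_by_year:
        Mapping collection year -> raw records (years 2015/2016 form the
        pooled baseline T0).
    regime:
        Threshold regime for the final classification.
    sales:
        Sales table (id, group, year, sales) for market shares; may be
        omitted in full-supply mode.
    min_share, full_supply:
        Minimum market share in percent (default 1); ``full_supply=True``
        or ``min_share=0`` skips the filter.
    """
    unknown_years = sorted(y for y in raw_by_year if y not in YEAR_PERIOD)
    if unknown_years:
        raise ValidationError(f"collection year(s) {unknown_years} map to no period")
    use_share_filter = not full_supply and min_share > 0
    if use_share_filter and sales is None:
        raise ValidationError("market-share filtering requires a sales table")

    ledger = ExclusionLedger()
    all_records: List[ProductRecord] = []
    all_profiles: List[WarningProfile] = []

    for period in PERIODS:
        if not any(YEAR_PERIOD.get(y) == period for y in raw_by_year):
            continue
        row = ledger.row(period)
        try:
            if period == "T0":
                r2015 = list(raw_by_year.get(2015, []))
                r2016 = list(raw_by_year.get(2016, []))
                row.photographed = len(r2015) + len(r2016)
                records = pool_baseline(r2015, r2016)
                # identity clashes across the two baseline years are duplicates
                row.duplicates += row.photographed - len(records)
            else:
                records = [r for r in _records_for_period(raw_by_year, period)]
                row.photographed = len(records)

            before = len(records)
            records = deduplicate_sizes(records)
            row.duplicates += before - len(records)

            records = [apply_reconstitution(r) for r in records]
            records = [impute_missing_saturated_fat(r) for r in records]

            before = len(records)
            records = exclude_incomplete(records)
            row.incomplete = before - len(records)

            before = len(records)
            records = exclude_out_of_scope(records)
            row.out_of_scope = before - len(records)

            if use_share_filter:
                before = len(records)
                records = filter_best_selling(records, sales, min_share)
                row.below_share = before - len(records)

            profiles = [classify_high_in(r, regime, strict=strict) for r in records]
        except NutriwarnError as exc:
            raise type(exc)(f"[period {period}] {exc}") from exc

        row.final = len(records)
        logger.info(
            "period %s: photographed=%d duplicates=%d incomplete=%d "
            "out_of_scope=%d below_share=%d final=%d",
            period, row.photographed, row.duplicates, row.incomplete,
            row.out_of_scope, row.below_share, row.final,
        )
        all_records.extend(records)
        all_profiles.extend(profiles)

    assert ledger.conserved(), "exclusion ledger failed to conserve counts"
    return AnalyticSample(records=all_records, profiles=all_profiles, ledger=ledger, regime=regime)
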