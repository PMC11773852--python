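"""Prevalence tables, quartile tables and density-curve data.

Percentages are reported to one decimal, rounded half-up, and the
headline T0-versus-T3 change in percentage points is the difference of
the *rounded* percents (this is how the published tables' difference
column reproduces, including rows where the unrounded difference would
round the other way).  Significance is emitted as machine-readable
p-values and significant-pair lists, not typographic marks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .errors import DegenerateTrendError, ValidationError
from .pipeline import AnalyticSample
from .stats import (
    PeriodCountTable,
    QuartileSummary,
    cochran_armitage_trend,
    emm_pairwise_contrasts,
    firth_logistic_fit,
    quantile_inference,
)
from .types import LIQUID, NUTRIENTS, SOLID

FLAGS = ("any", "energy", "sugars", "satfat", "sodium")

_FLAG_COLUMN = {
    "any": "any_high",
    "energy": "high_energy",
    "sugars": "high_sugars",
    "satfat": "high_satfat",
    "sodium": "high_sodium",
}

_NUTRIENT_COLUMN = {
    "energy": "energy_kcal",
    "sugars": "sugars_g",
    "satfat": "satfat_g",
    "sodium": "sodium_mg",
}


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from the half (2.25 -> 2.3)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PrevalenceRow:
    """One stratum x flag row of a prevalence table."""

    stratum: str
    flag: str
    periods: tuple
    k: tuple
    n: tuple
    percents: tuple            # 100*k/n, 1 decimal, half-up
    difference_pp: Optional[float]   # rounded last-period percent minus rounded first
    p_pairwise: Dict[Tuple[str, str], float] = field(default_factory=dict)
    p_trend: Optional[float] = None
    trend_degenerate: bool = False
    significant_pairs: List[Tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {"stratum": self.stratum, "flag": self.flag}
        for period, k, n, pct in zip(self.periods, self.k, self.n, self.percents):
            out[f"k_{period}"] = k
            out[f"n_{period}"] = n
            out[f"pct_{period}"] = pct
        out["difference_pp"] = self.difference_pp
        first, last = self.periods[0], self.periods[-1]
        out["p_first_vs_last"] = self.p_pairwise.get((first, last))
        out["p_trend"] = self.p_trend
        return out


def prevalence_row_from_counts(
    counts: PeriodCountTable,
    stratum: str = "overall",
    flag: str = "any",
    *,
    adjust: str = "none",
    scores: Optional[Sequence[float]] = None,
    alpha: float = 0.05,
) -> PrevalenceRow:
    """Full prevalence row (percents, difference, contrasts, trend) from counts.

    This is the arithmetic core of the prevalence tables and also works
    directly on printed (k, n) pairs, so published count tables can be
    re-analysed without the underlying product data.
    """
    percents = tuple(round_half_up(100.0 * k / n) for k, n in zip(counts.k, counts.n))
    diff = float(Decimal(repr(percents[-1])) - Decimal(repr(percents[0])))
    row = PrevalenceRow(
        stratum=stratum,
        flag=flag,
        periods=counts.periods,
        k=counts.k,
        n=counts.n,
        percents=percents,
        difference_pp=diff,
    )
    fit = firth_logistic_fit(counts)
    for c in emm_pairwise_contrasts(fit, counts, adjust=adjust):
        idx_a = counts.periods.index(c.period_a)
        idx_b = counts.periods.index(c.period_b)
        if idx_a < idx_b:
            row.p_pairwise[(c.period_a, c.period_b)] = c.p_value
            if c.p_value < alpha:
                row.significant_pairs.append((c.period_a, c.period_b))
    try:
        trend = cochran_armitage_trend(counts, scores)
        row.p_trend = trend.p_value
    except DegenerateTrendError:
        row.trend_degenerate = True
    return row


def _stratum_mask(frame: pd.DataFrame, stratum: str) -> pd.Series:
    if stratum == "overall":
        return pd.Series(True, index=frame.index)
    if stratum == "solids":
        return frame["basis"].eq(SOLID)
    if stratum == "liquids":
        return frame["basis"].eq(LIQUID)
    return frame["group"].eq(stratum)


def build_prevalence_table(
    sample: AnalyticSample,
    strata: Iterable[str] = ("overall", "solids", "liquids"),
    flags: Iterable[str] = FLAGS,
    *,
    adjust: str = "none",
    scores: Optional[Sequence[float]] = None,
) -> List[PrevalenceRow]:
    """One row per stratum x flag from a classified analytic sample.

    Strata are ``overall``, ``solids``, ``liquids`` or any group label.
    A stratum empty in some period yields a row with missing statistics
    and a warning instead of failing the whole table.
    """
    frame = sample.to_frame()
    periods = sorted(frame["period"].unique(), key=lambda p: p)
    rows: List[PrevalenceRow] = []
    for stratum in strata:
        sub = frame[_stratum_mask(frame, stratum)]
        n_by_period = [int((sub["period"] == p).sum()) for p in periods]
        for flag in flags:
            col = _FLAG_COLUMN[flag]
            k_by_period = [int(sub.loc[sub["period"] == p, col].sum()) for p in periods]
            if any(n == 0 for n in n_by_period):
                warnings.warn(
                    f"stratum {stratum!r} has an empty period; emitting row without statistics",
                    stacklevel=2,
                )
                rows.append(
                    PrevalenceRow(
                        stratum=stratum, flag=flag, periods=tuple(periods),
                        k=tuple(k_by_period), n=tuple(n_by_period),
                        percents=tuple(None for _ in periods), difference_pp=None,
                    )
                )
                continue
            counts = PeriodCountTable(tuple(periods), tuple(k_by_period), tuple(n_by_period))
            rows.append(
                prevalence_row_from_counts(counts, stratum, flag, adjust=adjust, scores=scores)
            )
    return rows


def prevalence_table_frame(rows: Iterable[PrevalenceRow]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in rows])


def build_quartile_table(
    sample: AnalyticSample,
    groups: Optional[Iterable[str]] = None,
    nutrients: Iterable[str] = NUTRIENTS,
    *,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> List[QuartileSummary]:
    """Per group x nutrient: quartiles per period plus p-values versus T0."""
    frame = sample.to_frame()
    known = set(frame["group"].unique())
    if groups is None:
        groups = sorted(known)
    summaries: List[QuartileSummary] = []
    for gi, group in enumerate(groups):
        if group not in known:
            raise ValidationError(f"unknown group {group!r}")
        sub = frame[frame["group"] == group]
        for ni, nutrient in enumerate(nutrients):
            col = _NUTRIENT_COLUMN[nutrient]
            values = sub[col].to_numpy(dtype=float)
            periods = sub["period"].to_numpy()
            ok = ~np.isnan(values)
            summary = quantile_inference(
                values[ok], periods[ok], n_boot=n_boot,
                seed=(seed * 1_000_003 + gi * 101 + ni) % (2**31),
            )
            summaries.append(
                QuartileSummary(
                    periods=summary.periods,
                    taus=summary.taus,
                    quantiles=summary.quantiles,
                    p_values=summary.p_values,
                    group=group,
                    nutrient=nutrient,
                    baseline=summary.baseline,
                )
            )
    return summaries


def significant_cells(summary: QuartileSummary, alpha: float = 0.05) -> List[Tuple[str, float]]:
    """(period, tau) cells whose quantile differs from baseline at ``alpha``."""
    out = []
    if summary.p_values is None:
        return out
    for i, period in enumerate(summary.periods):
        for j, tau in enumerate(summary.taus):
            p = summary.p_values[i, j]
            if np.isfinite(p) and p < alpha:
                out.append((period, tau))
    return out


def quartile_table_frame(summaries: Iterable[QuartileSummary]) -> pd.DataFrame:
    return pd.concat([s.to_frame() for s in summaries], ignore_index=True)


def density_curves(
    sample: AnalyticSample,
    group: str,
    nutrient: str,
    bandwidth_rule: str = "scott",
    gridsize: int = 256,
) -> pd.DataFrame:
    """Per-period kernel density estimates of one nutrient on a common grid.

    Returns a frame with column ``x`` plus one density column per
    period.  Each curve integrates to 1 within 0.01 (trapezoid rule) on
    the padded common grid.  A period with fewer than two distinct
    values has no density and raises an error naming it.
    """
    frame = sample.to_frame()
    sub = frame[frame["group"] == group]
    if sub.empty:
        raise ValidationError(f"unknown or empty group {group!r}")
    col = _NUTRIENT_COLUMN[nutrient]
    periods = sorted(sub["period"].unique())
    by_period = {}
    for period in periods:
        vals = sub.loc[sub["period"] == period, col].dropna().to_numpy(dtype=float)
        if len(np.unique(vals)) < 2:
            raise ValidationError(
                f"period {period} of group {group!r} has fewer than two distinct values"
            )
        by_period[period] = vals
    kdes = {p: gaussian_kde(v, bw_method=bandwidth_rule) for p, v in by_period.items()}
    pad = max(float(np.sqrt(k.covariance[0, 0])) for k in kdes.values()) * 4.0
    lo = min(v.min() for v in by_period.values()) - pad
    hi = max(v.max() for v in by_period.values()) + pad
    grid = np.linspace(lo, hi, gridsize)
    out = pd.DataFrame({"x": grid})
    for period in periods:
        out[period] = kdes[period](grid)
    return out
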