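"""Prevalence/quartile tables and density curves."""

import numpy as np
import pytest

from nutriwarn.errors import ValidationError
from nutriwarn.reporting import (
    build_prevalence_table,
    build_quartile_table,
    density_curves,
    prevalence_row_from_counts,
    prevalence_table_frame,
    round_half_up,
    significant_cells,
)
from nutriwarn.stats import PeriodCountTable, quantile_inference


class TestRounding:
    @pytest.mark.parametrize(
        "x, expected",
        [(70.781, 70.8), (76.1499, 76.1), (2.25, 2.3), (-18.25, -18.3),
         (51.94, 51.9), (0.0, 0.0), (33.35, 33.4)],
    )
    def test_half_up_one_decimal(self, x, expected):
        assert round_half_up(x) == expected


class TestPrevalenceRows:
    def test_published_overall_row_reproduced(self):
        counts = PeriodCountTable.from_counts(
            [(2735, 3864), (1536, 2424), (1671, 3065), (1517, 2888)]
        )
        row = prevalence_row_from_counts(counts)
        assert row.percents == (70.8, 63.4, 54.5, 52.5)
        assert row.difference_pp == -18.3
        assert row.p_pairwise[("T0", "T3")] < 0.001
        assert row.p_trend < 0.001

    def test_rounding_sensitive_liquids_row(self):
        """Difference of rounded percents, not rounded difference: the raw
        difference here is -25.88 (rounds to -25.9) but the rounded
        percents 51.9 and 26.1 give -25.8."""
        counts = PeriodCountTable.from_counts(
            [(684, 1317), (246, 730), (237, 1029), (264, 1013)]
        )
        row = prevalence_row_from_counts(counts)
        assert row.percents == (51.9, 33.7, 23.0, 26.1)
        assert row.difference_pp == -25.8

    def test_all_zero_flag_counts(self):
        counts = PeriodCountTable.from_counts(
            [(0, 50), (0, 40), (0, 60), (0, 45)]
        )
        row = prevalence_row_from_counts(counts)
        assert row.difference_pp == 0.0
        assert row.trend_degenerate and row.p_trend is None

    def test_round_trip_from_emitted_counts(self, default_run):
        rows = build_prevalence_table(default_run.sample)
        for row in rows:
            rebuilt = prevalence_row_from_counts(
                PeriodCountTable(row.periods, row.k, row.n), row.stratum, row.flag
            )
            assert rebuilt.percents == row.percents
            assert rebuilt.difference_pp == row.difference_pp
            assert rebuilt.p_trend == row.p_trend

    def test_percent_definition_holds_everywhere(self, default_run):
        rows = build_prevalence_table(
            default_run.sample,
            strata=["overall", "solids", "liquids", "beverages", "sausages"],
        )
        for row in rows:
            for k, n, pct in zip(row.k, row.n, row.percents):
                assert pct == round_half_up(100.0 * k / n)

    def test_empty_period_stratum_warns(self, default_run):
        with pytest.warns(UserWarning, match="empty period"):
            rows = build_prevalence_table(default_run.sample, strata=["no-such-group"])
        assert rows[0].percents == (None,) * 4

    def test_table_frame_has_row_per_stratum_flag(self, default_run):
        rows = build_prevalence_table(default_run.sample)
        frame = prevalence_table_frame(rows)
        assert len(frame) == 3 * 5


class TestQuartileTable:
    def test_interval_convention_example(self):
        fit = quantile_inference([10.0, 20.0, 30.0, 40.0], ["T0"] * 4,
                                 n_boot=200, seed=0)
        assert fit.quantiles[0].tolist() == [10.0, 20.0, 30.0]

    def test_quartiles_monotone_in_every_cell(self, default_run):
        summaries = build_quartile_table(
            default_run.sample, groups=["beverages", "sausages"],
            nutrients=("sugars", "sodium"), n_boot=300, seed=4,
        )
        for s in summaries:
            for i in range(len(s.periods)):
                q = s.quantiles[i]
                assert q[0] <= q[1] <= q[2]

    def test_unknown_group_rejected(self, default_run):
        with pytest.raises(ValidationError, match="unknown group"):
            build_quartile_table(default_run.sample, groups=["not-a-group"])

    def test_false_positive_rate_without_planted_change(self):
        """Identical laws in all periods: marks appear at roughly the
        nominal per-cell rate (9 cells tested per dataset at alpha=0.05)."""
        rng = np.random.default_rng(123)
        total_marks, total_cells = 0, 0
        for seed in range(30):
            y = rng.lognormal(1.5, 0.7, 4 * 120)
            periods = np.repeat(["T0", "T1", "T2", "T3"], 120)
            res = quantile_inference(y, periods, n_boot=300, seed=seed)
            marks = np.sum(res.p_values[1:] < 0.05)
            total_marks += marks
            total_cells += 9
        rate = total_marks / total_cells
        assert rate < 0.10  # near nominal, far from pathological

    def test_planted_left_shift_detected(self, default_run):
        summaries = build_quartile_table(default_run.sample, groups=["beverages"],
                                         nutrients=("sugars",), n_boot=500, seed=1)
        cells = significant_cells(summaries[0])
        assert any(period == "T3" for period, _ in cells)
        # and the shift is downward at the median
        s = summaries[0]
        i3 = s.periods.index("T3")
        i0 = s.periods.index("T0")
        assert s.quantiles[i3, 1] < s.quantiles[i0, 1]


class TestDensityCurves:
    def test_normalisation_and_common_grid(self, default_run):
        curves = density_curves(default_run.sample, "beverages", "sugars")
        x = curves["x"].to_numpy()
        for period in ("T0", "T1", "T2", "T3"):
            area = np.trapezoid(curves[period].to_numpy(), x)
            assert area == pytest.approx(1.0, abs=0.01)

    def test_left_shift_moves_mode_down(self, default_run):
        curves = density_curves(default_run.sample, "beverages", "sugars")
        x = curves["x"].to_numpy()
        mode_t0 = x[np.argmax(curves["T0"].to_numpy())]
        mode_t3 = x[np.argmax(curves["T3"].to_numpy())]
        assert mode_t3 < mode_t0

    def test_degenerate_period_named(self, default_run):
        import pandas as pd

        from nutriwarn.pipeline import AnalyticSample, ExclusionLedger
        from helpers import make_record
        from nutriwarn.profile_model import classify_high_in

        records = [make_record(product_id=f"a{i}", period="T0", year=2016,
                               sugars=float(i + 1)) for i in range(5)]
        records += [make_record(product_id=f"b{i}", period="T3", year=2020,
                                sugars=4.0) for i in range(5)]
        profiles = [classify_high_in(r, default_run.regime) for r in records]
        sample = AnalyticSample(records, profiles, ExclusionLedger())
        with pytest.raises(ValidationError, match="T3"):
            density_curves(sample, "snacks", "sugars")
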