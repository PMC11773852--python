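"""Synthetic-supply generator: determinism, planted truth, calibration."""

import numpy as np
import pytest

from nutriwarn.io import records_to_frame
from nutriwarn.pipeline import run_supply_pipeline
from nutriwarn.regimes import phase_thresholds
from nutriwarn.synthetic import (
    GroupSpec,
    LogNormalSpec,
    ScenarioConfig,
    default_scenario,
    generate_supply,
    planted_prevalence,
    scenario_truth,
)


def small_group(name="snacks", basis="solid", **kw):
    law = LogNormalSpec(median=8.0, sigma=0.8)
    defaults = dict(
        name=name, basis=basis, energy=LogNormalSpec(median=250.0, sigma=0.5),
        sugars=law, satfat=LogNormalSpec(median=3.0, sigma=0.6),
        sodium=LogNormalSpec(median=350.0, sigma=0.7),
        p_added_sugars=0.7, p_added_satfat=0.5, p_added_sodium=0.6,
    )
    defaults.update(kw)
    return GroupSpec(**defaults)


class TestConfigValidation:
    def test_duplicate_group_names(self):
        with pytest.raises(ValueError, match="unique"):
            ScenarioConfig(groups=[small_group(), small_group()])

    def test_bad_shift(self):
        with pytest.raises(ValueError, match="shift"):
            ScenarioConfig(groups=[small_group()], shifts={"T1": {"sugars": 0.0}})

    def test_unknown_period_in_shifts(self):
        with pytest.raises(ValueError, match="period"):
            ScenarioConfig(groups=[small_group()], shifts={"T9": {"sugars": 0.5}})

    def test_reconstitution_requires_liquid_basis(self):
        with pytest.raises(ValueError, match="liquid"):
            small_group(frac_reconstitution=0.2, basis="solid")

    def test_mixture_needs_second_component(self):
        with pytest.raises(ValueError, match="mixture"):
            LogNormalSpec(median=5.0, sigma=0.5, mix_weight=0.6)


class TestLogNormalSpec:
    def test_exceedance_roundtrip(self):
        law = LogNormalSpec.from_exceedance(limit=10.0, p_exceed=0.3, sigma=0.8)
        assert law.sf(10.0) == pytest.approx(0.3, abs=1e-9)

    def test_mixture_sf_ppf_consistent(self):
        law = LogNormalSpec(median=2.0, sigma=0.4, mix_weight=0.6,
                            median2=20.0, sigma2=0.3)
        for q in (0.1, 0.25, 0.5, 0.75, 0.9):
            x = law.ppf(q)
            assert 1.0 - law.sf(x) == pytest.approx(q, abs=1e-9)

    def test_shift_scales_quantiles(self):
        law = LogNormalSpec(median=5.0, sigma=0.8)
        assert law.ppf(0.5, shift=0.6) == pytest.approx(0.6 * law.ppf(0.5))

    def test_sample_matches_exceedance(self):
        law = LogNormalSpec(median=8.0, sigma=0.8)
        x = law.sample(np.random.default_rng(0), 200_000)
        assert np.mean(x > 10.0) == pytest.approx(law.sf(10.0), abs=0.005)


class TestGeneration:
    def config(self, **kw):
        defaults = dict(groups=[small_group()], products_per_group=40,
                        duplicate_rate=0.1, incomplete_rate=0.05, seed=5)
        defaults.update(kw)
        return ScenarioConfig(**defaults)

    def test_seed_determinism(self):
        a = generate_supply(self.config())
        b = generate_supply(self.config())
        for year in a[0]:
            assert records_to_frame(a[0][year]).equals(records_to_frame(b[0][year]))
        assert a[1].equals(b[1])
        assert a[2] == b[2]

    def test_clean_config_plants_nothing(self, final_regime):
        cfg = self.config(duplicate_rate=0.0, incomplete_rate=0.0,
                          groups=[small_group(frac_out_of_scope=0.0)])
        records_by_year, sales, truth = generate_supply(cfg, final_regime)
        sample = run_supply_pipeline(records_by_year, final_regime, sales,
                                     full_supply=True)
        for period, row in sample.ledger.rows.items():
            # only baseline-year overlap may be removed, nothing else
            assert row.incomplete == 0 and row.out_of_scope == 0 and row.below_share == 0
            if period != "T0":
                assert row.duplicates == 0

    def test_group_streams_independent_of_order(self):
        g1, g2 = small_group("alpha"), small_group("beta", basis="liquid",
                                                   serving_range=(200.0, 250.0))
        fwd = generate_supply(ScenarioConfig(groups=[g1, g2], products_per_group=30, seed=9))
        rev = generate_supply(ScenarioConfig(groups=[g2, g1], products_per_group=30, seed=9))
        for year in fwd[0]:
            f = records_to_frame(fwd[0][year])
            r = records_to_frame(rev[0][year])
            fa = f[f.group == "alpha"].reset_index(drop=True)
            ra = r[r.group == "alpha"].reset_index(drop=True)
            assert fa.equals(ra)

    def test_truth_exclusions_match_recount(self):
        """Planted out-of-scope/incomplete counts equal a direct recount."""
        records_by_year, _, truth = generate_supply(self.config())
        t3 = records_by_year[2020]
        originals = [r for r in t3 if not r.product_id.endswith("~dup")]
        n_oos = sum(not r.regulated_category for r in originals)
        n_dup = sum(r.product_id.endswith("~dup") for r in t3)
        assert n_oos == truth["exclusions"]["T3"]["out_of_scope"]
        assert n_dup == truth["exclusions"]["T3"]["duplicates"]

    def test_planted_shift_moves_empirical_median(self):
        """Factor 0.6 on sugars: T3 median about 0.6 x T0 median (n=5000)."""
        cfg = ScenarioConfig(groups=[small_group(frac_out_of_scope=0.0)],
                             products_per_group=5000, seed=11,
                             shifts={"T3": {"sugars": 0.6}})
        records_by_year, _, _ = generate_supply(cfg)
        t0 = [r.panel.sugars_g for r in records_by_year[2016]]
        t3 = [r.panel.sugars_g for r in records_by_year[2020]]
        ratio = np.median(t3) / np.median(t0)
        assert ratio == pytest.approx(0.6, rel=0.05)


class TestDefaultScenario:
    def test_planted_trajectory(self, final_regime):
        truth = scenario_truth(default_scenario(), final_regime)
        overall = truth["overall_prevalence"]
        assert overall["T0"]["any"] == pytest.approx(0.708, abs=0.002)
        assert overall["T3"]["any"] == pytest.approx(0.525, abs=0.002)

    def test_sixteen_groups_with_solids_and_liquids(self):
        cfg = default_scenario()
        assert len(cfg.groups) == 16
        bases = {g.basis for g in cfg.groups}
        assert bases == {"solid", "liquid"}

    def test_stricter_final_regime_flags_more(self, default_run, initial_full_regime):
        from nutriwarn.profile_model import classify_high_in

        final_hits = sum(p.any_high for p in default_run.sample.profiles)
        initial_hits = sum(
            classify_high_in(r, initial_full_regime).any_high
            for r in default_run.sample.records
        )
        assert initial_hits < final_hits

    def test_recovers_planted_prevalence_per_period(self, default_run):
        frame = default_run.sample.to_frame()
        for period in ("T0", "T3"):
            sub = frame[frame.period == period]
            planted = planted_prevalence(default_run.truth, default_run.sample, period)
            se = np.sqrt(planted * (1 - planted) / len(sub))
            assert abs(sub.any_high.mean() - planted) < 3 * se
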