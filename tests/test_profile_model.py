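"""Threshold regimes and the "high in" classifier."""

import dataclasses

import pytest
from hypothesis import given
from hypothesis import strategies as st

from helpers import make_record
from nutriwarn.errors import ConfigurationError, IncompleteRecordError, ScopeError, ValidationError
from nutriwarn.profile_model import (
    apply_reconstitution,
    classify_frame,
    classify_high_in,
    impute_missing_saturated_fat,
)
from nutriwarn.io import records_to_frame
from nutriwarn.regimes import phase_thresholds


class TestPhaseThresholds:
    def test_final_phase_shipped_limits(self):
        regime = phase_thresholds("final")
        s, l = regime.solid_limits, regime.liquid_limits
        assert (s.energy_kcal, s.sugars_g, s.satfat_g, s.sodium_mg) == (275, 10, 4, 400)
        assert (l.energy_kcal, l.sugars_g, l.satfat_g, l.sodium_mg) == (70, 5, 3, 100)

    def test_initial_phase_solid_limits(self):
        regime = phase_thresholds("initial")
        s = regime.solid_limits
        assert (s.energy_kcal, s.sugars_g, s.satfat_g, s.sodium_mg) == (350, 22.5, 6, 800)

    def test_initial_phase_liquids_not_defaulted(self):
        regime = phase_thresholds("initial")
        with pytest.raises(ConfigurationError, match="liquids"):
            regime.limits_for("liquid")

    def test_incomplete_block_names_missing_cell(self):
        config = {"initial": {"liquids": {"energy_kcal": 100, "sugars_g": 7.5}}}
        with pytest.raises(ConfigurationError, match="satfat_g"):
            phase_thresholds("initial", config)

    def test_unknown_phase(self):
        with pytest.raises(ConfigurationError, match="unknown phase"):
            phase_thresholds("fourth")

    def test_final_limits_not_above_initial(self):
        final = phase_thresholds("final").solid_limits
        initial = phase_thresholds("initial").solid_limits
        for nut in ("energy", "sugars", "satfat", "sodium"):
            assert final.limit(nut) <= initial.limit(nut)


class TestReconstitution:
    def test_powder_scaled_to_liquid(self):
        rec = make_record(basis="solid", sugars=60.0, energy=380.0, sodium=500.0,
                          factor=0.1, requires_recon=True)
        out = apply_reconstitution(rec)
        assert out.panel.sugars_g == pytest.approx(6.0)
        assert out.panel.energy_kcal == pytest.approx(38.0)
        assert out.basis == "liquid"
        assert out.reconstitution_factor is None and out.reconstituted
        # original untouched
        assert rec.panel.sugars_g == 60.0 and rec.basis == "solid"

    def test_absent_factor_is_identity(self):
        rec = make_record()
        assert apply_reconstitution(rec) is rec

    def test_zero_factor_rejected(self):
        with pytest.raises(ValidationError):
            make_record(factor=0.0)


class TestSatfatImputation:
    def test_low_fat_missing_satfat_becomes_zero(self):
        rec = make_record(satfat=None, totalfat=2.0, serving=100.0)
        assert impute_missing_saturated_fat(rec).panel.satfat_g == 0.0

    def test_fat_at_or_above_three_grams_stays_missing(self):
        rec = make_record(satfat=None, totalfat=10.0, serving=50.0)  # 5 g / serving
        assert impute_missing_saturated_fat(rec).panel.satfat_g is None

    def test_declared_satfat_unchanged(self):
        rec = make_record(satfat=7.0, totalfat=20.0, serving=100.0)
        assert impute_missing_saturated_fat(rec) is rec


class TestClassifier:
    def test_sugars_above_final_limit(self, final_regime):
        rec = make_record(basis="solid", sugars=22.5, scope=(True, False, False),
                          energy=100.0)
        assert classify_high_in(rec, final_regime).high_sugars

    def test_tie_is_compliant(self, final_regime):
        rec = make_record(basis="solid", sugars=10.0, scope=(True, False, False))
        assert not classify_high_in(rec, final_regime).high_sugars

    def test_scope_gate_blocks_sodium(self, final_regime):
        rec = make_record(basis="liquid", year=2020, sodium=900.0,
                          scope=(False, False, False), energy=10.0)
        profile = classify_high_in(rec, final_regime)
        assert not profile.high_sodium and not profile.any_high

    def test_energy_flag_rides_on_any_scope_flag(self, final_regime):
        rec = make_record(basis="solid", energy=300.0, sodium=100.0,
                          scope=(False, False, True))
        assert classify_high_in(rec, final_regime).high_energy

    def test_out_of_scope_record_rejected(self, final_regime):
        with pytest.raises(ScopeError):
            classify_high_in(make_record(regulated=False), final_regime)

    def test_missing_amount_under_active_flag(self, final_regime):
        rec = make_record(sodium=None, scope=(False, False, True))
        with pytest.raises(IncompleteRecordError, match="sodium"):
            classify_high_in(rec, final_regime)

    def test_missing_amount_under_inactive_flag_is_fine(self, final_regime):
        rec = make_record(sodium=None, scope=(True, False, False), sugars=2.0)
        assert not classify_high_in(rec, final_regime).any_high


def _oracle(scope, amounts, limits, strict=True):
    """Independent truth-table evaluator for one record."""
    def over(nut):
        return amounts[nut] > limits[nut] if strict else amounts[nut] >= limits[nut]

    sugars = scope[0] and over("sugars")
    satfat = scope[1] and over("satfat")
    sodium = scope[2] and over("sodium")
    energy = any(scope) and over("energy")
    return (energy, sugars, satfat, sodium, energy or sugars or satfat or sodium)


def test_classifier_matches_enumeration_oracle(final_regime):
    """Brute-force sweep: all 8 scope combinations x 4 amounts per nutrient."""
    limits = {"energy": 275.0, "sugars": 10.0, "satfat": 4.0, "sodium": 400.0}
    grid = {nut: (0.0, lim / 2, lim, lim * 1.001) for nut, lim in limits.items()}
    for s in range(8):
        scope = (bool(s & 1), bool(s & 2), bool(s & 4))
        for e in grid["energy"]:
            for su in grid["sugars"]:
                for sf in grid["satfat"]:
                    for na in grid["sodium"]:
                        rec = make_record(energy=e, sugars=su, satfat=sf, sodium=na,
                                          scope=scope, basis="solid")
                        p = classify_high_in(rec, final_regime)
                        amounts = {"energy": e, "sugars": su, "satfat": sf, "sodium": na}
                        assert (p.high_energy, p.high_sugars, p.high_satfat,
                                p.high_sodium, p.any_high) == _oracle(scope, amounts, limits)


amount = st.floats(min_value=0, max_value=1200, allow_nan=False)
scope_st = st.tuples(st.booleans(), st.booleans(), st.booleans())


@given(scope=scope_st, energy=amount, sugars=amount, satfat=amount, sodium=amount,
       bump=st.floats(min_value=0.001, max_value=500),
       which=st.sampled_from(["energy", "sugars", "satfat", "sodium"]))
def test_monotone_in_amounts(scope, energy, sugars, satfat, sodium, bump, which):
    """Raising any amount never clears a raised flag (fixed scope and basis)."""
    regime = phase_thresholds("final")
    base = dict(energy=energy, sugars=sugars, satfat=satfat, sodium=sodium)
    rec = make_record(scope=scope, basis="solid", **base)
    before = classify_high_in(rec, regime)
    base[which] += bump
    after = classify_high_in(make_record(scope=scope, basis="solid", **base), regime)
    for flag in ("high_energy", "high_sugars", "high_satfat", "high_sodium", "any_high"):
        assert getattr(after, flag) >= getattr(before, flag)


@given(scope=scope_st, energy=amount, sugars=amount, satfat=amount, sodium=amount,
       basis=st.sampled_from(["solid", "liquid"]))
def test_final_regime_flags_superset_of_initial(scope, energy, sugars, satfat,
                                                sodium, basis):
    """Stricter (final) limits can only add flags relative to looser ones."""
    final = phase_thresholds("final")
    initial = phase_thresholds("initial", {
        "initial": {
            "solids": {"energy_kcal": 350, "sugars_g": 22.5, "satfat_g": 6, "sodium_mg": 800},
            "liquids": {"energy_kcal": 100, "sugars_g": 7.5, "satfat_g": 4.5, "sodium_mg": 150},
        }
    })
    rec = make_record(scope=scope, basis=basis, energy=energy, sugars=sugars,
                      satfat=satfat, sodium=sodium)
    p_final = classify_high_in(rec, final)
    p_initial = classify_high_in(rec, initial)
    for flag in ("high_energy", "high_sugars", "high_satfat", "high_sodium", "any_high"):
        assert getattr(p_final, flag) >= getattr(p_initial, flag)


@given(scope=scope_st, energy=amount, sugars=amount, satfat=amount, sodium=amount)
def test_classification_idempotent_and_pure(scope, energy, sugars, satfat, sodium):
    regime = phase_thresholds("final")
    rec = make_record(scope=scope, energy=energy, sugars=sugars, satfat=satfat,
                      sodium=sodium)
    snapshot = dataclasses.replace(rec)
    assert classify_high_in(rec, regime) == classify_high_in(rec, regime)
    assert rec == snapshot


def test_vectorised_classification_matches_record_level(default_run):
    frame = records_to_frame(default_run.sample.records)
    out = classify_frame(frame, default_run.regime)
    for rec, (_, row) in zip(default_run.sample.records, out.iterrows()):
        p = classify_high_in(rec, default_run.regime)
        assert (row["high_energy"], row["high_sugars"], row["high_satfat"],
                row["high_sodium"], row["any_high"]) == (
            p.high_energy, p.high_sugars, p.high_satfat, p.high_sodium, p.any_high)
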