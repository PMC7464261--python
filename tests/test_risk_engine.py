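"""Unit and property tests for the absolute-risk engine."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from afacs.errors import (
    CalibrationError,
    ChainMismatchError,
    DomainError,
    MissingScoreError,
    UnknownRegimenError,
)
from afacs.regimens import OAC, UNTREATED, get_regimen
from afacs.risk_engine import (
    AcsMultiplier,
    COMPLEX_PCI,
    STANDARD_PCI,
    StrokeRiskTable,
    TreatmentEffect,
    acs_adjusted_risk,
    calibrate_coronary_table,
    coronary_risk_30d,
    dapt_vs_oac_effect,
    monthly_stroke_risk,
    oac_effect,
    risk_under_regimen,
    stroke_risk_30d,
    validate_score,
)


class TestMonthlyStrokeRisk:
    @pytest.mark.parametrize(
        "score, annual, expected",
        [(2, 3.7, 3.7 / 12), (3, 5.9, 5.9 / 12), (5, 12.0, 1.0)],
    )
    def test_division_by_twelve(self, score, annual, expected):
        table = StrokeRiskTable({score: annual})
        assert monthly_stroke_risk(table, score) == pytest.approx(expected, abs=0)

    def test_reported_one_decimal_values(self, stroke_table):
        # monthly risks round to the reported 0.3 and 0.5 per 100
        assert round(monthly_stroke_risk(stroke_table, 2), 1) == 0.3
        assert round(monthly_stroke_risk(stroke_table, 3), 1) == 0.5

    def test_missing_score_raises_not_extrapolates(self, stroke_table):
        with pytest.raises(MissingScoreError):
            monthly_stroke_risk(stroke_table, 7)

    def test_score_domain(self):
        with pytest.raises(DomainError):
            validate_score(10)
        with pytest.raises(DomainError):
            validate_score(-1)
        with pytest.raises(DomainError):
            validate_score(2.5)


class TestStrokeTableInvariants:
    def test_rates_must_be_positive(self):
        with pytest.raises(DomainError):
            StrokeRiskTable({2: 0.0})

    def test_rates_must_be_non_decreasing(self):
        with pytest.raises(DomainError):
            StrokeRiskTable({2: 5.0, 3: 4.0})

    def test_extended_table_covers_all_scores_and_keeps_core_values(self):
        table = StrokeRiskTable.extended()
        assert table.scores == list(range(10))
        assert table.annual_rate(2) == 3.7
        assert table.annual_rate(3) == 5.9
        # score-4 extension consistent with the reported monthly 0.8/100
        assert round(monthly_stroke_risk(table, 4), 1) == 0.8


class TestAcsAdjustment:
    def test_hand_multiplied_value(self):
        assert acs_adjusted_risk(3.7 / 12, AcsMultiplier(3.9)) == pytest.approx(
            1.2025, abs=5e-5
        )

    def test_identity_multiplier(self):
        assert acs_adjusted_risk(0.77, AcsMultiplier(1.0)) == 0.77

    def test_cap_at_certainty_logged(self, caplog):
        with caplog.at_level("WARNING"):
            assert acs_adjusted_risk(40.0, AcsMultiplier(3.9)) == 100.0
        assert any("capped" in r.message for r in caplog.records)

    def test_multiplier_below_one_rejected(self):
        with pytest.raises(DomainError):
            AcsMultiplier(0.9)


class TestRiskUnderRegimen:
    def test_oac_arm(self):
        risk = risk_under_regimen(1.2025, [oac_effect()], reference=UNTREATED)
        assert risk == pytest.approx(0.43290, abs=5e-6)

    def test_dapt_arm_via_oac(self):
        risk = risk_under_regimen(
            1.2025, [oac_effect(), dapt_vs_oac_effect()], reference=UNTREATED
        )
        assert risk == pytest.approx(0.74459, abs=5e-6)

    def test_empty_chain_is_identity(self):
        assert risk_under_regimen(0.5, [], reference=UNTREATED) == 0.5

    def test_broken_chain_names_both_regimens(self):
        with pytest.raises(ChainMismatchError) as exc:
            risk_under_regimen(1.0, [dapt_vs_oac_effect()], reference=UNTREATED)
        assert "UNTREATED" in str(exc.value) and "OAC" in str(exc.value)

    @given(
        untreated=st.floats(0.0, 100.0),
        v1=st.floats(0.01, 0.99),
        v2=st.floats(0.1, 3.0),
    )
    def test_chain_composition_is_associative(self, untreated, v1, v2):
        a = TreatmentEffect("stroke", OAC, UNTREATED, "relative_risk_reduction", v1)
        b = TreatmentEffect(
            "stroke", get_regimen("DAPT-clopidogrel"), OAC, "risk_ratio", v2
        )
        joint = risk_under_regimen(untreated, [a, b], reference=UNTREATED)
        staged = risk_under_regimen(
            risk_under_regimen(untreated, [a], reference=UNTREATED), [b], reference=OAC
        )
        assert joint == staged  # exact: same multiplication order

    @given(rate=st.floats(0.1, 20.0), factor=st.floats(1.0, 5.0))
    def test_stroke_risk_strictly_increasing_in_rate_and_multiplier(self, rate, factor):
        base = acs_adjusted_risk(rate / 12, AcsMultiplier(factor))
        assert acs_adjusted_risk((rate + 1) / 12, AcsMultiplier(factor)) > base
        assert acs_adjusted_risk(rate / 12, AcsMultiplier(factor + 0.5)) > base

    def test_effect_measure_domains(self):
        with pytest.raises(DomainError):
            TreatmentEffect("stroke", OAC, UNTREATED, "relative_risk_reduction", 1.0)
        with pytest.raises(DomainError):
            TreatmentEffect("stroke", OAC, UNTREATED, "risk_ratio", 0.0)


class TestCoronaryCalibration:
    def test_ticagrelor_anchor_inversion(self):
        table = calibrate_coronary_table([(1, "ticagrelor", 179), (9, "ticagrelor", 105)])
        assert table.reference_rate(1) == pytest.approx(4.655, abs=5e-4)
        assert table.reference_rate(9) == pytest.approx(7.937, abs=5e-4)

    def test_prasugrel_anchor_inversion(self):
        table = calibrate_coronary_table([(1, "prasugrel", 97), (9, "prasugrel", 57)])
        assert table.reference_rate(1) == pytest.approx(4.686, abs=5e-4)
        assert table.reference_rate(9) == pytest.approx(7.974, abs=5e-4)

    def test_independent_calibrations_agree_within_two_percent(self):
        tic = calibrate_coronary_table([(1, "ticagrelor", 179), (9, "ticagrelor", 105)])
        pras = calibrate_coronary_table([(1, "prasugrel", 97), (9, "prasugrel", 57)])
        for score in range(1, 10):
            a, b = tic.reference_rate(score), pras.reference_rate(score)
            assert abs(a - b) / b < 0.02

    def test_bundled_table_reproduces_score3_rate(self, coronary_table):
        # interior consistency: the score-3 reference rate ~5.9/100
        assert coronary_table.reference_rate(3) == pytest.approx(5.95, rel=0.05)

    def test_non_monotone_anchors_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_coronary_table([(1, "ticagrelor", 100), (9, "ticagrelor", 500)])

    def test_fewer_than_two_distinct_scores_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_coronary_table([(1, "ticagrelor", 179), (1, "prasugrel", 97)])


class TestCoronaryRisk:
    def test_reference_regimen_returns_table_value(self, coronary_table):
        assert coronary_risk_30d(
            coronary_table, 1, "DAPT-clopidogrel", STANDARD_PCI
        ) == coronary_table.reference_rate(1)

    def test_ticagrelor_applies_rrr(self, coronary_table):
        r1 = coronary_table.reference_rate(1)
        assert coronary_risk_30d(coronary_table, 1, "DAPT-ticagrelor") == pytest.approx(
            r1 * 0.88
        )

    def test_complex_pci_scales_by_risk_ratio(self, coronary_table):
        r1 = coronary_table.reference_rate(1)
        assert coronary_risk_30d(
            coronary_table, 1, "DAPT-clopidogrel", COMPLEX_PCI
        ) == pytest.approx(r1 * 3.4)

    def test_unregistered_regimen_rejected(self, coronary_table):
        with pytest.raises(UnknownRegimenError):
            coronary_risk_30d(coronary_table, 1, "OAC")


class TestStrokeRisk30d:
    def test_regimen_dispatch(self, stroke_table):
        untreated = stroke_risk_30d(stroke_table, 2, "UNTREATED")
        oac = stroke_risk_30d(stroke_table, 2, "OAC")
        dat = stroke_risk_30d(stroke_table, 2, "DAT-rivaroxaban-15")
        dapt = stroke_risk_30d(stroke_table, 2, "DAPT-clopidogrel")
        assert oac == pytest.approx(untreated * 0.36)
        assert dat == oac  # any anticoagulant-containing regimen
        assert dapt == pytest.approx(oac * 1.72)
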