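"""Risk-rate conversions, risk equations, FH adjustment and calibration."""
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

import etpymodel as m
from etpymodel.inputs import InputError
from etpymodel.risk import (
    AnnualEventRates,
    Coefficient,
    RiskAdjustment,
    RiskCoefficientSet,
    calibrate_primary_scalar,
    load_packaged_coefficients,
    profile_covariates,
    secondary_covariates,
)
from etpymodel.states import Flag


class TestRateConversions:
    def test_zero_risk_zero_rate(self):
        assert m.risk_to_annual_rate(0.0, 10.0) == 0.0
        assert m.annual_rate_to_prob(0.0) == 0.0

    def test_55pct_over_10y_annualised(self):
        # the calibration target: -ln(0.45)/10
        assert m.risk_to_annual_rate(0.55, 10.0) == pytest.approx(0.07985, abs=1e-5)

    def test_rate_back_to_prob(self):
        assert m.annual_rate_to_prob(0.07985) == pytest.approx(0.07675, abs=1e-5)

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_invalid_probability_rejected(self, bad):
        with pytest.raises(ValueError):
            m.risk_to_annual_rate(bad, 10.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            m.annual_rate_to_prob(-0.01)

    @given(st.floats(0.0, 0.999), st.floats(0.1, 50.0))
    def test_mutual_inverses(self, p, horizon):
        rate = m.risk_to_annual_rate(p, horizon)
        assert 1.0 - (1.0 - m.annual_rate_to_prob(rate)) ** horizon == pytest.approx(
            p, abs=1e-10
        )

    @given(st.floats(0.0, 5.0), st.floats(0.0, 5.0))
    def test_prob_monotone_in_rate(self, r1, r2):
        lo, hi = sorted([r1, r2])
        assert m.annual_rate_to_prob(lo) <= m.annual_rate_to_prob(hi)


def _toy_primary(intercept=-2.0, age_coef=0.05):
    return RiskCoefficientSet(
        model_id="primary_10y",
        horizon_years=10.0,
        link="logistic",
        intercept=intercept,
        coefficients={"age": Coefficient(age_coef), "sbp": Coefficient(0.01)},
    )


class TestRiskEquations:
    def test_intercept_only_logistic(self):
        coeffs = RiskCoefficientSet(
            "primary_10y", 10.0, "logistic", math.log(0.25 / 0.75), {}
        )
        assert m.primary_prevention_risk(m.default_cohort(), coeffs) == pytest.approx(
            0.25, abs=1e-12
        )

    def test_linear_predictor_matches_hand_evaluation(self):
        coeffs = _toy_primary()
        profile = m.default_cohort()
        lp = -2.0 + 0.05 * profile.age_mean + 0.01 * profile.sbp_mean
        assert coeffs.linear_predictor(profile_covariates(profile)) == pytest.approx(
            lp, abs=1e-12
        )
        assert m.primary_prevention_risk(profile, coeffs) == pytest.approx(
            1.0 / (1.0 + math.exp(-lp)), abs=1e-12
        )

    def test_missing_covariate_named_in_error(self):
        coeffs = _toy_primary()
        coeffs.coefficients["novel_marker"] = Coefficient(1.0)
        with pytest.raises(InputError, match="novel_marker"):
            coeffs.linear_predictor({"age": 50.0, "sbp": 120.0})

    def test_region_flag_with_zero_coefficient_is_inert(self, cfg):
        sec = load_packaged_coefficients("secondary_20mo")
        sec.coefficients["eastern_europe_or_middle_east"] = Coefficient(0.0)
        on = m.secondary_prevention_risk(cfg.cohort, sec, True)
        off = m.secondary_prevention_risk(cfg.cohort, sec, False)
        assert on == off

    def test_positive_region_coefficient_increases_risk(self, cfg):
        sec = load_packaged_coefficients("secondary_20mo")
        assert m.secondary_prevention_risk(cfg.cohort, sec, True) > (
            m.secondary_prevention_risk(cfg.cohort, sec, False)
        )

    def test_prior_event_indicators_follow_memory(self, cfg):
        cov = secondary_covariates(cfg.cohort, {Flag.POST_MI, Flag.POST_HF}, True)
        assert (cov["prior_mi"], cov["prior_is"], cov["prior_hf"], cov["ecvd"]) == (
            1.0,
            0.0,
            1.0,
            0.0,
        )


class TestAgeEffectRemoval:
    def test_fixed_point_at_baseline_age(self):
        coeffs = _toy_primary()
        frozen = m.remove_age_effect(coeffs, 51.16)
        cov = {"age": 51.16, "sbp": 120.0}
        assert frozen.predict(cov) == pytest.approx(coeffs.predict(cov), abs=1e-15)

    def test_age_invariance_after_removal(self):
        frozen = m.remove_age_effect(_toy_primary(), 51.16)
        base = frozen.predict({"age": 51.16, "sbp": 120.0})
        assert frozen.predict({"age": 71.16, "sbp": 120.0}) == base

    def test_age_coefficient_zeroed_and_idempotent(self):
        frozen = m.remove_age_effect(_toy_primary(), 51.16)
        assert frozen.coefficients["age"].value == 0.0
        again = m.remove_age_effect(frozen, 99.0)
        assert again.intercept == frozen.intercept


class TestFhAdjustment:
    def test_default_mode_returns_published_ratio(self):
        assert m.pool_fh_rate_ratio(RiskAdjustment()) == 7.1

    def test_null_odds_ratios_pool_to_one(self):
        adj = RiskAdjustment(
            or_fh_off=1.0, or_fh_on=1.0, treated_share=0.3, reference_risk=0.4,
            pooled_rr=None,
        )
        assert m.pool_fh_rate_ratio(adj) == pytest.approx(1.0, abs=1e-12)

    def test_or_to_rr_hand_calculation(self):
        adj = RiskAdjustment(
            or_fh_off=13.2, treated_share=0.0, reference_risk=0.2, pooled_rr=None
        )
        assert m.pool_fh_rate_ratio(adj) == pytest.approx(3.837, abs=1e-3)

    def test_computed_ratio_between_group_ratios(self):
        adj = RiskAdjustment(treated_share=0.5, reference_risk=0.2, pooled_rr=None)
        pooled = m.pool_fh_rate_ratio(adj)
        lo = m.pool_fh_rate_ratio(
            RiskAdjustment(treated_share=1.0, reference_risk=0.2, pooled_rr=None)
        )
        hi = m.pool_fh_rate_ratio(
            RiskAdjustment(treated_share=0.0, reference_risk=0.2, pooled_rr=None)
        )
        assert min(lo, hi) <= pooled <= max(lo, hi)


class TestBaselineRates:
    def test_calibrated_no_cvd_rate_hits_target(self, cfg):
        rates = m.baseline_rates(cfg)
        assert rates.state_rates["no_cvd"] == pytest.approx(
            -math.log(0.45) / 10.0, abs=1e-12
        )

    def test_homogeneous_in_pooled_rr_with_fixed_calibration(self, cfg):
        c = cfg.copy()
        c.risk_primary.calibration_scalar = 1.0
        c.risk_adjustment.pooled_rr = 1.0
        unit = m.baseline_rates(c)
        c.risk_adjustment.pooled_rr = 7.1
        scaled = m.baseline_rates(c)
        for k in unit.state_rates:
            assert scaled.state_rates[k] == pytest.approx(
                7.1 * unit.state_rates[k], rel=1e-12
            )

    def test_composite_rate_is_max_of_members(self, cfg, space):
        rates = m.baseline_rates(cfg)
        for s in space.composite_states:
            assert rates.any_event_rate(s) == max(
                rates.state_rates[f.value] for f in s.memory
            )

    def test_calibration_scalar_formula(self, cfg):
        scalar = calibrate_primary_scalar(
            cfg.cohort,
            m.remove_age_effect(cfg.risk_primary, cfg.cohort.age_mean),
            7.1,
            0.55,
        )
        assert scalar > 0

    def test_negative_rate_rejected(self):
        with pytest.raises(InputError):
            AnnualEventRates({"no_cvd": -0.1}).validate()


def test_trace_based_calibration_recovery(cfg):
    """A 10-cycle untreated trace reproduces the configured 55% 10-year risk."""
    risk = m.ten_year_first_event_risk(cfg)
    assert risk == pytest.approx(cfg.target_10y_risk, abs=0.005)
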