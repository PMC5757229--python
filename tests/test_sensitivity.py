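"""Distribution fitting, one-way sensitivity analysis and the PSA."""
import math

import numpy as np
import pandas as pd
import pytest

import etpymodel as m
from etpymodel.inputs import InputError
from etpymodel.sensitivity import (
    DsaScenario,
    ParameterSpec,
    apply_parameter,
    ci_to_distribution,
    default_psa_specs,
    distribution_ci,
    run_dsa,
    sample_parameter,
    tornado_table,
)


class TestDistributionFitting:
    def test_gamma_from_ten_percent_se(self):
        spec = ci_to_distribution(
            ParameterSpec("cost_post_ecvd", "gamma", 582.05, se=58.205)
        )
        assert spec.dist_params["shape"] == pytest.approx(100.0, rel=1e-12)
        assert spec.dist_params["scale"] == pytest.approx(5.8205, rel=1e-12)

    def test_lognormal_sigma_from_99pct_ci(self):
        spec = ci_to_distribution(
            ParameterSpec("rr_mi", "lognormal", 0.71, ci=(0.58, 0.87), ci_level=0.99)
        )
        assert spec.dist_params["sigma"] == pytest.approx(0.0787, abs=2e-4)
        lo, hi = distribution_ci(spec, 0.99)
        assert lo == pytest.approx(0.58, abs=0.01)
        assert hi == pytest.approx(0.87, abs=0.01)

    def test_beta_method_of_moments(self):
        spec = ci_to_distribution(
            ParameterSpec(
                "prop_effective_treatment", "beta", 0.7925, ci=(0.7028, 0.8651)
            )
        )
        a, b = spec.dist_params["alpha"], spec.dist_params["beta"]
        assert a == pytest.approx(75.2, abs=0.5)
        assert b == pytest.approx(19.7, abs=0.5)
        assert a / (a + b) == pytest.approx(0.7925, abs=1e-9)

    @pytest.mark.parametrize(
        "family,analytic_mean",
        [
            ("beta", lambda p: p["alpha"] / (p["alpha"] + p["beta"])),
            ("gamma", lambda p: p["shape"] * p["scale"]),
            ("lognormal", lambda p: math.exp(p["mu"] + p["sigma"] ** 2 / 2.0)),
        ],
    )
    def test_fitted_distribution_mean_matches_point_estimate(self, family, analytic_mean):
        mean, ci = {"beta": (0.6131, (0.5782, 0.6480)), "gamma": (5171.5, None),
                    "lognormal": (7.1, (5.7, 8.7))}[family]
        spec = ParameterSpec("x", family, mean, ci=ci, se=0.1 * mean if ci is None else None)
        ci_to_distribution(spec)
        assert analytic_mean(spec.dist_params) == pytest.approx(mean, rel=1e-9)

    @pytest.mark.parametrize(
        "family,mean,kwargs",
        [
            ("beta", 0.5, dict(se=0.05)),
            ("gamma", 500.0, dict(se=50.0)),
            ("lognormal", 0.71, dict(ci=(0.58, 0.87), ci_level=0.99)),
        ],
    )
    def test_sampling_recovers_mean_within_mc_error(self, family, mean, kwargs):
        spec = ci_to_distribution(ParameterSpec("x", family, mean, **kwargs))
        rng = np.random.default_rng(1234)
        n = 200_000
        p = spec.dist_params
        if family == "beta":
            draws = rng.beta(p["alpha"], p["beta"], n)
        elif family == "gamma":
            draws = rng.gamma(p["shape"], p["scale"], n)
        else:
            draws = rng.lognormal(p["mu"], p["sigma"], n)
        se = draws.std(ddof=1) / math.sqrt(n)
        assert abs(draws.mean() - mean) < 3.0 * se

    def test_invalid_means_rejected(self):
        with pytest.raises(InputError):
            ci_to_distribution(ParameterSpec("x", "beta", 1.5, se=0.1))
        with pytest.raises(InputError):
            ci_to_distribution(ParameterSpec("x", "gamma", -1.0, se=0.1))
        with pytest.raises(InputError):
            ci_to_distribution(ParameterSpec("x", "lognormal", -0.5, ci=(0.1, 0.2)))

    def test_fixed_family_always_returns_mean(self):
        spec = ParameterSpec("x", "fixed", 3.14)
        rng = np.random.default_rng(0)
        assert all(sample_parameter(spec, rng) == 3.14 for _ in range(5))

    def test_default_specs_follow_family_assignment(self, cfg):
        families = {s.name: s.family for s in default_psa_specs(cfg)}
        assert families["ldl_reduction_pct"] == "beta"
        assert families["prop_effective_treatment"] == "beta"
        assert families["pooled_rr"] == "lognormal"
        assert families["rr_mi"] == "lognormal"
        assert families["cost_acute_mi"] == "gamma"
        assert "rr_is_death" not in families  # fixed at 1, never sampled


class TestDsa:
    def test_empty_scenario_reproduces_base_case(self, cfg, base_results):
        dsa = run_dsa(cfg, [DsaScenario("base", {})])
        assert dsa.loc[0, "icer"] == pytest.approx(
            base_results.incremental.icer, rel=1e-12
        )

    def test_parameter_at_mean_reproduces_base_case(self, cfg, base_results):
        dsa = run_dsa(
            cfg, [DsaScenario("rr_mi_at_mean", {"rr_mi": cfg.rate_ratios["mi"].rr})]
        )
        assert dsa.loc[0, "icer"] == pytest.approx(
            base_results.incremental.icer, rel=1e-12
        )

    def test_discount_rate_directions(self, cfg, base_results):
        dsa = run_dsa(
            cfg,
            [
                DsaScenario("costs0", {"discount_costs": 0.0}),
                DsaScenario("outcomes0", {"discount_outcomes": 0.0}),
            ],
        ).set_index("scenario")
        base = base_results.incremental.icer
        assert dsa.loc["costs0", "icer"] > base
        assert dsa.loc["outcomes0", "icer"] < base

    def test_lower_attainment_bound_raises_icer(self, cfg):
        spec = ci_to_distribution(
            ParameterSpec(
                "prop_effective_treatment",
                "beta",
                cfg.efficacy.prop_effective_treatment,
                ci=cfg.efficacy.prop_effective_treatment_ci,
            )
        )
        lo, hi = distribution_ci(spec, 0.95)
        dsa = run_dsa(
            cfg,
            [
                DsaScenario("low", {"prop_effective_treatment": lo}),
                DsaScenario("high", {"prop_effective_treatment": hi}),
            ],
        ).set_index("scenario")
        assert dsa.loc["low", "icer"] > dsa.loc["high", "icer"]

    def test_tornado_pairs_low_and_high(self, cfg):
        dsa = run_dsa(
            cfg,
            [
                DsaScenario("rr_mi_low", {"rr_mi": 0.58}),
                DsaScenario("rr_mi_high", {"rr_mi": 0.87}),
            ],
        )
        tor = tornado_table(dsa)
        assert list(tor["parameter"]) == ["rr_mi"]
        assert {"icer_low", "icer_high", "spread"} <= set(tor.columns)

    def test_unknown_parameter_rejected(self, cfg):
        with pytest.raises(InputError):
            apply_parameter(cfg.copy(), "nonexistent", 1.0)


class TestPsa:
    def test_fixed_distributions_reproduce_base_case(self, cfg, base_results):
        specs = [
            ParameterSpec("rr_mi", "fixed", cfg.rate_ratios["mi"].rr),
            ParameterSpec("ldl_reduction_pct", "fixed", cfg.efficacy.ldl_reduction_pct),
        ]
        psa = m.run_psa(cfg, specs, n=4, seed=99)
        assert np.allclose(psa.draws["icer"], base_results.incremental.icer)
        assert psa.icer == pytest.approx(base_results.incremental.icer, rel=1e-12)

    def test_seed_determinism(self, cfg):
        a = m.run_psa(cfg, n=8, seed=42)
        b = m.run_psa(cfg, n=8, seed=42)
        pd.testing.assert_frame_equal(a.draws, b.draws)
        assert a.icer == b.icer

    def test_variance_shrinks_with_parameter_uncertainty(self, cfg):
        """Scaling every SE towards zero monotonically shrinks Var(dETPY)."""
        variances = []
        for scale in (1.0, 0.4, 0.1):
            specs = []
            for s in default_psa_specs(cfg):
                shrunk = ParameterSpec(
                    s.name, s.family, s.mean, se=None, ci=None, ci_level=s.ci_level
                )
                base = ci_to_distribution(
                    ParameterSpec(s.name, s.family, s.mean, se=s.se, ci=s.ci,
                                  ci_level=s.ci_level)
                )
                if s.family == "lognormal":
                    shrunk.dist_params = {
                        "sigma": base.dist_params["sigma"] * scale,
                        "mu": math.log(s.mean) - (base.dist_params["sigma"] * scale) ** 2 / 2,
                    }
                elif s.family == "beta":
                    a0 = base.dist_params["alpha"]
                    b0 = base.dist_params["beta"]
                    shrunk.dist_params = {"alpha": a0 / scale**2, "beta": b0 / scale**2}
                else:
                    shrunk.dist_params = {
                        "shape": base.dist_params["shape"] / scale**2,
                        "scale": base.dist_params["scale"] * scale**2,
                    }
                specs.append(shrunk)
            psa = m.run_psa(cfg, specs, n=60, seed=7)
            variances.append(psa.draws["d_etpy"].var())
        assert variances[0] > variances[1] > variances[2]

    def test_ceac_monotone_between_extremes(self, cfg):
        psa = m.run_psa(cfg, n=30, seed=3)
        ceac = psa.ceac([0.0, 10_000.0, 50_000.0, 1e9])
        probs = ceac["prob_cost_effective"].to_numpy()
        assert probs[0] == 0.0  # intervention always costs more
        assert probs[-1] == 1.0  # and always adds ETPYs
        assert (np.diff(probs) >= 0).all()
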