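"""Transition-matrix construction and the half-cycle-corrected cohort trace."""
import math

import numpy as np
import pytest

import etpymodel as m
from etpymodel.inputs import EventDistributionTable
from etpymodel.markov import apply_mortality, build_cycle_core, run_trace
from etpymodel.pipeline import build_arm_plan, initial_state_vector
from etpymodel.risk import AnnualEventRates
from etpymodel.states import Event, Kind, chronic_state, Flag


def uniform_dist(shares=(0.5, 0.3, 0.1, 0.1), cerebro=0.5):
    keys = [(), ("ecvd",), ("post_mi",), ("post_is",), ("post_hf",)]
    return EventDistributionTable(
        {k: np.asarray(shares, dtype=float) for k in keys},
        {k: cerebro for k in keys},
    )


def flat_rates(rate):
    return AnnualEventRates(
        {k: rate for k in ("no_cvd", "ecvd", "post_mi", "post_is", "post_hf")}
    )


class TestTransitionMatrix:
    def test_null_dynamics_is_identity(self, space):
        model = apply_mortality(
            build_cycle_core(space, flat_rates(0.0), uniform_dist()), 0.0
        )
        # acute states still deposit into their chronic successor
        for i, s in enumerate(space):
            if not s.is_acute:
                assert model.matrix[i, i] == 1.0

    def test_pure_mortality_routes_to_non_cvd_death(self, space):
        q = 0.07
        model = apply_mortality(
            build_cycle_core(space, flat_rates(0.0), uniform_dist()), q
        )
        death_idx = space.idx(m.HealthState(Kind.NON_CVD_DEATH))
        for i, s in enumerate(space):
            if s.is_death:
                continue
            assert model.matrix[i, death_idx] == pytest.approx(q, abs=1e-15)
            succ = (
                space.idx(chronic_state(s.memory)) if s.is_acute else i
            )
            assert model.matrix[i, succ] == pytest.approx(1.0 - q, abs=1e-15)

    def test_hand_computed_row(self, space):
        """Any-event prob 0.10 split 0.5/0.3/0.1/0.1, cerebro 0.5, q=0.02."""
        rate = -math.log(0.9)  # annual prob exactly 0.10
        model = apply_mortality(
            build_cycle_core(space, flat_rates(rate), uniform_dist()), 0.02
        )
        i = space.idx(m.HealthState(Kind.NO_CVD))
        get = lambda s: model.matrix[i, space.idx(s)]
        assert get(m.HealthState(Kind.NON_CVD_DEATH)) == pytest.approx(0.02, abs=1e-12)
        from etpymodel.states import acute_state

        assert get(acute_state(Event.MI, ())) == pytest.approx(0.049, abs=1e-12)
        assert get(acute_state(Event.IS, ())) == pytest.approx(0.0294, abs=1e-12)
        assert get(acute_state(Event.HF, ())) == pytest.approx(0.0098, abs=1e-12)
        assert get(m.HealthState(Kind.CHD_DEATH)) == pytest.approx(0.0049, abs=1e-12)
        assert get(m.HealthState(Kind.IS_DEATH)) == pytest.approx(0.0049, abs=1e-12)
        assert get(m.HealthState(Kind.NO_CVD)) == pytest.approx(0.882, abs=1e-12)
        assert model.matrix[i].sum() == pytest.approx(1.0, abs=1e-12)

    def test_rows_stochastic_for_base_config(self, cfg, space):
        rates = m.baseline_rates(cfg)
        model = m.build_transition_matrix(
            space, rates, cfg.event_distribution, cfg.life_table, 51.16, 0.4225
        )
        assert np.allclose(model.matrix.sum(axis=1), 1.0, atol=1e-12)
        assert (model.matrix >= 0).all()

    def test_invalid_death_probability_rejected(self, space):
        with pytest.raises(Exception):
            apply_mortality(
                build_cycle_core(space, flat_rates(0.0), uniform_dist()), 1.2
            )


class TestTrace:
    def test_identity_dynamics_constant_occupancy(self, cfg, space):
        model = apply_mortality(
            build_cycle_core(space, flat_rates(0.0), uniform_dist()), 0.0
        )
        init = initial_state_vector(cfg, space)
        trace = run_trace([model] * 5, init)
        assert np.allclose(trace.occupancy, np.tile(init, (6, 1)))
        assert np.allclose(trace.person_time, 1.0)

    def test_half_cycle_person_time_hand_example(self, cfg, space):
        """10%/cycle mortality: person-time = (1+0.9)/2 + (0.9+0.81)/2."""
        model = apply_mortality(
            build_cycle_core(space, flat_rates(0.0), uniform_dist()), 0.10
        )
        init = np.zeros(space.n)
        init[space.idx(m.HealthState(Kind.NO_CVD))] = 1.0
        trace = run_trace([model, model], init)
        assert trace.person_time.sum() == pytest.approx(1.805, abs=1e-12)

    def test_trace_is_deterministic(self, cfg):
        t1, r1 = m.run_arm(cfg, "treatment")
        t2, r2 = m.run_arm(cfg, "treatment")
        assert np.array_equal(t1.occupancy, t2.occupancy)
        assert r1.costs == r2.costs and r1.ly == r2.ly

    def test_acute_states_deposit_after_one_cycle(self, cfg, space):
        """Mass entering acute MI moves to the post-MI family next cycle."""
        plan = build_arm_plan(cfg, "control")
        init = np.zeros(space.n)
        from etpymodel.states import acute_state

        i_acute = space.idx(acute_state(Event.MI, ()))
        init[i_acute] = 1.0
        trace = run_trace(plan.models[:1], init)
        model = plan.models[0]
        # everyone either keeps the post-MI memory or has died
        post_family = [
            i for i, s in enumerate(space) if Flag.POST_MI in s.memory or s.is_death
        ]
        assert trace.occupancy[1, post_family].sum() == pytest.approx(1.0, abs=1e-12)
        # the no-event share deposits into the chronic post-MI state, and any
        # mass still in acute MI is exactly the recurrent-MI probability
        i_post = space.idx(chronic_state({Flag.POST_MI}))
        assert trace.occupancy[1, i_post] == pytest.approx(
            model.matrix[i_acute, i_post], abs=1e-15
        )
        assert trace.occupancy[1, i_post] > 0.5
        assert trace.occupancy[1, i_acute] == pytest.approx(
            model.event_probs[i_acute, 0], abs=1e-15
        )

    def test_zero_cvd_rates_reproduce_life_table_expectancy(self, cfg, space):
        """With CVD switched off, discounted LYs equal the cause-deleted
        life-table expectation computed independently."""
        from etpymodel.pipeline import n_cycles, noncvd_death_probs

        cycles = n_cycles(cfg)
        qs = noncvd_death_probs(cfg, cycles)
        core = build_cycle_core(space, flat_rates(0.0), uniform_dist())
        models = [apply_mortality(core, float(q)) for q in qs]
        init = initial_state_vector(cfg, space)
        trace = run_trace(models, init, stop_alive=0.0)
        res = m.accumulate_outcomes(
            trace, cfg.efficacy, cfg.costs, cfg.discount, "control"
        )
        # independent closed-form expectation over the same q sequence
        surv, expect = 1.0, 0.0
        for t, q in enumerate(qs):
            nxt = surv * (1.0 - q)
            expect += 0.5 * (surv + nxt) / (1.0 + cfg.discount.rate_outcomes) ** t
            surv = nxt
        assert res.ly == pytest.approx(expect, abs=1e-6)

    def test_microsimulation_matches_trace_small(self, cfg):
        plan = build_arm_plan(cfg, "control")
        space = plan.models[0].space
        init = initial_state_vector(cfg, space)
        trace = run_trace(plan.models[:5], init, stop_alive=0.0)
        sim = m.microsimulate(plan.models[:5], init, 50_000, seed=11)
        se = np.sqrt(np.clip(trace.occupancy * (1 - trace.occupancy), 0, 1) / 50_000)
        diff = np.abs(sim - trace.occupancy)
        assert (diff[se == 0] == 0).all()
        assert (diff[se > 0] / se[se > 0]).max() < 5.0

    def test_bad_initial_vector_rejected(self, cfg, space):
        model = apply_mortality(
            build_cycle_core(space, flat_rates(0.0), uniform_dist()), 0.0
        )
        with pytest.raises(Exception):
            run_trace([model], np.ones(space.n))
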