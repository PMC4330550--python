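"""Value updates, softmax policy, simulation and deterministic replay."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from revlearn import (
    Model,
    SubjectParameters,
    TaskConfig,
    ValueState,
    compute_rpe,
    compute_rpe_trace,
    simulate_agent,
    softmax_choice_probabilities,
    update_values,
)
from conftest import make_record
from oracles import oracle_replay

ADOLESCENT_MEANS = SubjectParameters(0.62, 0.69, 0.78, 0.63, 1.9)


class TestComputeRPE:
    @pytest.mark.parametrize(
        "outcome,value,expected",
        [(1.0, 0.0, 1.0), (-1.0, -1.0, 0.0), (1.0, 0.6, pytest.approx(0.4))],
    )
    def test_definition(self, outcome, value, expected):
        assert compute_rpe(outcome, value) == expected


class TestUpdateValues:
    def test_rescorla_wagner_single_step(self):
        params = SubjectParameters.rescorla_wagner(0.5, 1.0)
        state = update_values(Model.RESCORLA_WAGNER, params, ValueState(0, 0), "A", 1)
        assert (state.v_a, state.v_b) == (0.5, 0.0)

    def test_rsav_anticorrelated_update(self):
        """Negative RPE: chosen value falls by alpha_c_neg * |RPE|, unchosen
        rises by alpha_u_neg * |RPE| (hand-computed)."""
        params = SubjectParameters(0.62, 0.69, 0.78, 0.63, 1.9)
        state = update_values(Model.RSAV, params, ValueState(0.5, -0.2), "A", -1)
        # RPE = -1 - 0.5 = -1.5
        assert state.v_a == pytest.approx(0.5 + 0.69 * -1.5)  # -0.535
        assert state.v_b == pytest.approx(-0.2 - 0.63 * -1.5)  # +0.745

    @pytest.mark.parametrize("model", list(Model))
    def test_zero_rates_are_identity(self, model):
        params = SubjectParameters(0, 0, 0, 0, 1.0)
        state = ValueState(0.3, -0.4)
        assert update_values(model, params, state, "B", 1) == state

    def test_model_constraints_enforced(self):
        rsav_only = SubjectParameters(0.5, 0.6, 0.1, 0.0, 1.0)
        with pytest.raises(ValueError):
            update_values(Model.RESCORLA_WAGNER, rsav_only, ValueState(), "A", 1)
        with pytest.raises(ValueError):
            update_values(Model.RISK_SENSITIVE, rsav_only, ValueState(), "A", 1)

    def test_parameter_bounds_enforced(self):
        with pytest.raises(ValueError):
            SubjectParameters(1.5, 0, 0, 0, 1.0)
        with pytest.raises(ValueError):
            SubjectParameters(0.5, 0.5, 0, 0, 0.0)


class TestSoftmax:
    def test_equal_values_give_half(self):
        assert softmax_choice_probabilities(ValueState(0.3, 0.3), 2.0) == (0.5, 0.5)

    @pytest.mark.parametrize("tau", [0.1, 1.0, 3.7])
    def test_log3_gap_gives_three_quarters(self, tau):
        """p_A = 0.75 exactly when V_A - V_B = tau * ln 3 (logistic inverse)."""
        p_a, p_b = softmax_choice_probabilities(ValueState(tau * math.log(3), 0.0), tau)
        assert p_a == pytest.approx(0.75, abs=1e-12)
        assert p_a + p_b == pytest.approx(1.0)

    def test_high_temperature_approaches_indifference(self):
        gaps = [
            softmax_choice_probabilities(ValueState(1.0, 0.0), tau)[0] - 0.5
            for tau in (1.0, 10.0, 100.0, 1000.0)
        ]
        assert all(g > 0 for g in gaps)
        assert gaps == sorted(gaps, reverse=True)

    def test_invalid_temperature_rejected(self):
        with pytest.raises(ValueError):
            softmax_choice_probabilities(ValueState(), 0.0)

    @given(
        v_a=st.floats(-5, 5),
        v_b=st.floats(-5, 5),
        tau=st.floats(0.01, 10),
    )
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_probabilities_sum_to_one_and_monotone(self, v_a, v_b, tau):
        p_a, p_b = softmax_choice_probabilities(ValueState(v_a, v_b), tau)
        assert p_a + p_b == pytest.approx(1.0)
        p_a_hi, _ = softmax_choice_probabilities(ValueState(v_a + 0.5, v_b), tau)
        if p_a < 1.0 - 1e-12:  # strictly increasing until float saturation
            assert p_a_hi > p_a
        else:
            assert p_a_hi == pytest.approx(1.0)


@st.composite
def trial_sequences(draw, max_len=40):
    n = draw(st.integers(2, max_len))
    choices = draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
    outcomes = draw(
        st.lists(st.sampled_from([-1, 1]), min_size=n, max_size=n)
    )
    return choices, outcomes


class TestModelNesting:
    @given(
        seq=trial_sequences(),
        alpha=st.floats(0, 1),
        tau=st.floats(0.01, 10),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_risk_sensitive_with_tied_rates_equals_rw(self, seq, alpha, tau):
        choices, outcomes = seq
        record = make_record(choices, outcomes)
        rw = compute_rpe_trace(
            record, Model.RESCORLA_WAGNER, SubjectParameters.rescorla_wagner(alpha, tau)
        )
        rs = compute_rpe_trace(
            record, Model.RISK_SENSITIVE, SubjectParameters.risk_sensitive(alpha, alpha, tau)
        )
        assert np.array_equal(rw.rpe, rs.rpe)
        assert np.array_equal(rw.choice_prob, rs.choice_prob)

    @given(
        seq=trial_sequences(),
        a_pos=st.floats(0, 1),
        a_neg=st.floats(0, 1),
        tau=st.floats(0.01, 10),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_rsav_with_zero_unchosen_rates_equals_risk_sensitive(
        self, seq, a_pos, a_neg, tau
    ):
        choices, outcomes = seq
        record = make_record(choices, outcomes)
        rs = compute_rpe_trace(
            record, Model.RISK_SENSITIVE, SubjectParameters.risk_sensitive(a_pos, a_neg, tau)
        )
        rsav = compute_rpe_trace(
            record, Model.RSAV, SubjectParameters(a_pos, a_neg, 0.0, 0.0, tau)
        )
        assert np.array_equal(rs.rpe, rsav.rpe)
        assert np.array_equal(rs.chosen_value, rsav.chosen_value)
        assert np.array_equal(rs.choice_prob, rsav.choice_prob)


class TestReplay:
    def test_three_trial_rsav_trace_matches_hand_unrolled_values(self):
        """Choices A,A,B with outcomes +1,-1,+1 at the adolescent means,
        V0 = 0: frozen expectations from an independently unrolled recursion."""
        record = make_record([0, 0, 1], [1, -1, 1])
        trace = compute_rpe_trace(record, Model.RSAV, ADOLESCENT_MEANS)
        np.testing.assert_allclose(trace.rpe, [1.0, -1.62, 0.7594], atol=1e-12)
        np.testing.assert_allclose(trace.chosen_value, [0.0, 0.62, 0.2406], atol=1e-12)

    @pytest.mark.parametrize("model", list(Model))
    def test_replay_matches_independent_oracle(self, model):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            choices = rng.integers(0, 2, n)
            outcomes = rng.choice([-1, 1], n)
            a = rng.uniform(0, 1, 4)
            tau = rng.uniform(0.05, 5)
            if model is Model.RESCORLA_WAGNER:
                params = SubjectParameters.rescorla_wagner(a[0], tau)
                rates = (a[0], a[0], 0.0, 0.0)
            elif model is Model.RISK_SENSITIVE:
                params = SubjectParameters.risk_sensitive(a[0], a[1], tau)
                rates = (a[0], a[1], 0.0, 0.0)
            else:
                params = SubjectParameters(*a, tau)
                rates = tuple(a)
            trace = compute_rpe_trace(make_record(choices, outcomes), model, params)
            rpes, v_chosen, p_obs, _, _ = oracle_replay(choices, outcomes, *rates, tau)
            np.testing.assert_allclose(trace.rpe, rpes, atol=1e-12)
            np.testing.assert_allclose(trace.chosen_value, v_chosen, atol=1e-12)
            np.testing.assert_allclose(trace.choice_prob, p_obs, atol=1e-12)

    def test_one_step_convergence_with_unit_learning_rate(self):
        record = make_record([0] * 6, [1] * 6)
        trace = compute_rpe_trace(
            record, Model.RESCORLA_WAGNER, SubjectParameters.rescorla_wagner(1.0, 1.0)
        )
        np.testing.assert_allclose(trace.rpe, [1, 0, 0, 0, 0, 0], atol=1e-15)

    def test_misses_skipped_without_update(self):
        full = make_record([0, 0, 1], [1, -1, 1])
        with_miss = make_record(
            [0, 0, -1, 1], [1, -1, 0, 1], missed=[False, False, True, False]
        )
        t_full = compute_rpe_trace(full, Model.RSAV, ADOLESCENT_MEANS)
        t_miss = compute_rpe_trace(with_miss, Model.RSAV, ADOLESCENT_MEANS)
        assert t_miss.n_trials == 3
        np.testing.assert_array_equal(t_miss.trial, [0, 1, 3])
        np.testing.assert_allclose(t_miss.rpe, t_full.rpe, atol=1e-15)

    def test_reset_between_runs_restarts_values(self):
        record = make_record([0, 0, 0, 0], [1, 1, 1, 1], run=[0, 0, 1, 1])
        params = SubjectParameters.rescorla_wagner(0.5, 1.0)
        cont = compute_rpe_trace(record, Model.RESCORLA_WAGNER, params)
        reset = compute_rpe_trace(
            record, Model.RESCORLA_WAGNER, params, reset_between_runs=True
        )
        assert cont.chosen_value[2] == pytest.approx(0.75)
        assert reset.chosen_value[2] == 0.0  # back to V0 at the run boundary


class TestValueBoundedness:
    def test_chosen_only_models_stay_in_unit_interval(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = 2000
            record = make_record(rng.integers(0, 2, n), rng.choice([-1, 1], n))
            params = SubjectParameters.risk_sensitive(
                rng.uniform(0, 1), rng.uniform(0, 1), 1.0
            )
            trace = compute_rpe_trace(record, Model.RISK_SENSITIVE, params)
            assert np.all(np.abs(trace.chosen_value) <= 1.0 + 1e-12)

    def test_rsav_values_remain_finite_at_session_length(self):
        """The anticorrelated update is not bounded, and on adversarial
        random sequences the values can grow multiplicatively — but over a
        session (120 trials) growth is capped at 3^n, so every replay stays
        finite.  ~1e6 updates across random sequences and rate vectors."""
        rng = np.random.default_rng(8)
        for _ in range(8400):
            n = 120
            record = make_record(rng.integers(0, 2, n), rng.choice([-1, 1], n))
            params = SubjectParameters(*rng.uniform(0, 1, 4), rng.uniform(0.05, 5))
            trace = compute_rpe_trace(record, Model.RSAV, params)
            assert np.all(np.isfinite(trace.rpe))
            assert np.all(np.isfinite(trace.chosen_value))


class TestSimulateAgent:
    def test_no_learning_is_chance_level(self):
        params = SubjectParameters(0, 0, 0, 0, 1.0)
        cfg = TaskConfig(trials_per_run=5000)
        record = simulate_agent(Model.RSAV, params, cfg, np.random.default_rng(9))
        pct = 100 * np.mean(record.choice == record.correct_stimulus)
        assert abs(pct - 50.0) < 3 * 100 * np.sqrt(0.25 / record.n_trials)

    def test_greedy_agent_repeats_rewarded_choice(self):
        """Near-zero temperature: once an initial value edge exists and reward
        is deterministic, the agent perseverates on the same stimulus."""
        cfg = TaskConfig(
            p_reward_correct=1.0,
            p_reward_incorrect=0.0,
            reversal_min_correct=10**6,
            reversal_max_correct=10**6,
        )
        params = SubjectParameters.rescorla_wagner(0.3, 0.01)
        rng = np.random.default_rng(10)
        record = simulate_agent(
            Model.RESCORLA_WAGNER, params, cfg, rng, v_initial=(0.01, 0.0)
        )
        # A starts ahead; if A is correct it is rewarded forever, if not the
        # first punishment flips the ordering and the agent locks onto B
        choices = record.choice
        assert np.all(choices[1:] == choices[-1])

    def test_simulation_reproducible_and_replay_consistent(self):
        params = SubjectParameters(0.62, 0.69, 0.78, 0.63, 1.9)
        rec1 = simulate_agent(Model.RSAV, params, TaskConfig(), np.random.default_rng(11))
        rec2 = simulate_agent(Model.RSAV, params, TaskConfig(), np.random.default_rng(11))
        assert np.array_equal(rec1.choice, rec2.choice)
        assert np.array_equal(rec1.outcome, rec2.outcome)
        # replaying the record reproduces a coherent trace (finite, aligned)
        trace = compute_rpe_trace(rec1, Model.RSAV, params)
        assert trace.n_trials == rec1.n_valid_trials
        np.testing.assert_allclose(
            trace.rpe, rec1.outcome[rec1.valid] - trace.chosen_value, atol=1e-12
        )
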