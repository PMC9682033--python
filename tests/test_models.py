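"""Model family: softmax choice, update rules, likelihoods, nesting, simulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import arrlearn as al
from arrlearn.models import (SubjectArrays, TrialOutcome, prepare_subject_arrays,
                             reset_accumulator)
from conftest import random_native_params, random_trials
from oracles import oracle_nll

ALL_MODELS = list(al.MODEL_NAMES)


def _state_for(pairs=("A",), model="null-a"):
    spec = al.get_model(model)
    from arrlearn.models import AgentState
    n = len(pairs)
    return spec, AgentState(pair_index={p: i for i, p in enumerate(pairs)},
                            q=np.zeros((n, 2)), q_pos=np.zeros((n, 2)),
                            q_neg=np.zeros((n, 2)), mu=0.0)


class TestChoiceProbabilities:
    def test_symmetry_and_zero_weight(self):
        spec, state = _state_for()
        pv = al.make_parameters(spec, alpha=0.5, beta=3.0)
        assert al.choice_probabilities(state, "A", pv, spec) == (0.5, 0.5)
        state.q[0] = [1.0, -1.0]
        pv0 = al.make_parameters(spec, alpha=0.5, beta=0.0)
        assert al.choice_probabilities(state, "A", pv0, spec) == (0.5, 0.5)

    def test_logistic_value(self):
        # softmax of Q=(1,0) at beta=1 is the logistic of 1
        spec, state = _state_for()
        state.q[0] = [1.0, 0.0]
        pv = al.make_parameters(spec, alpha=0.5, beta=1.0)
        pb, pw = al.choice_probabilities(state, "A", pv, spec)
        assert pb == pytest.approx(0.7310585786300049, abs=1e-10)
        assert pb + pw == pytest.approx(1.0, abs=1e-12)

    def test_two_stream_uses_total_value(self):
        spec, state = _state_for(model="null-aR")
        pv = al.make_parameters(spec, alpha=0.3, lambda_pos=1.0, lambda_neg=1.0,
                                w_pos=1.0, w_neg=1.0, beta=1.0)
        state.q_pos[0] = [0.7, 0.0]
        state.q_neg[0] = [0.3, 0.0]
        pb, _ = al.choice_probabilities(state, "A", pv, spec)
        assert pb == pytest.approx(1 / (1 + np.exp(-1.0)), abs=1e-12)

    def test_nonfinite_q_raises(self):
        spec, state = _state_for()
        state.q[0, 0] = np.nan
        pv = al.make_parameters(spec, alpha=0.5, beta=1.0)
        with pytest.raises(FloatingPointError):
            al.choice_probabilities(state, "A", pv, spec)


class TestUpdateRules:
    def test_canonical_one_step(self):
        spec, state = _state_for()
        pv = al.make_parameters(spec, alpha=0.5, beta=1.0)
        al.update_agent_state(state, TrialOutcome("A", 0, 1.0), pv, spec)
        assert state.q[0, 0] == pytest.approx(0.5)
        assert state.q[0, 1] == 0.0  # only the chosen option changes

    def test_feedback_model_adds_mu_to_delta(self):
        spec, state = _state_for(model="FB-R")
        pv = al.make_parameters(spec, alpha=1.0, alpha_mu=0.1, beta=1.0)
        state.q[0, 0] = 0.5
        state.mu = 0.2
        al.update_agent_state(state, TrialOutcome("A", 0, 1.0), pv, spec)
        # delta = R - Q + mu = 1 - 0.5 + 0.2 = 0.7, applied with alpha = 1
        assert state.q[0, 0] == pytest.approx(0.5 + 0.7)
        # reward accumulator: mu' = mu + alpha_mu * (R - mu)
        assert state.mu == pytest.approx(0.2 + 0.1 * (1.0 - 0.2))

    def test_reward_accumulator_one_step(self):
        spec, state = _state_for(model="b-R")
        pv = al.make_parameters(spec, alpha=0.0, alpha_mu=0.1, beta0=1.0)
        al.update_agent_state(state, TrialOutcome("A", 0, 1.0), pv, spec)
        assert state.mu == pytest.approx(0.1)

    def test_alpha_modulated_starts_at_alpha0(self):
        # with mu = 0 the effective learning rate is the constant term alpha0
        spec, state = _state_for(model="a-R")
        pv = al.make_parameters(spec, alpha0=0.3, alpha_mu=0.2, beta=1.0)
        al.update_agent_state(state, TrialOutcome("A", 0, 1.0), pv, spec)
        assert state.q[0, 0] == pytest.approx(0.3)

    def test_effective_rate_clipped_to_unit_interval(self):
        spec, state = _state_for(model="a-R")
        pv = al.make_parameters(spec, alpha0=0.8, alpha_mu=0.2, beta=1.0)
        state.mu = 2.0  # alpha0 * (1 + mu) = 2.4 -> clipped to 1
        al.update_agent_state(state, TrialOutcome("A", 0, 1.0), pv, spec)
        assert state.q[0, 0] == pytest.approx(1.0)

    def test_out_of_bounds_parameter_rejected(self):
        spec, state = _state_for()
        pv = al.make_parameters(spec, alpha=1.5, beta=1.0)
        with pytest.raises(ValueError, match="outside"):
            al.update_agent_state(state, TrialOutcome("A", 0, 1.0), pv, spec)

    def test_block_reset_clears_mu_only(self):
        spec, state = _state_for(model="FB-R")
        state.mu = 0.4
        state.q[0, 0] = 0.9
        reset_accumulator(state)
        assert state.mu == 0.0 and state.q[0, 0] == 0.9

    def test_init_state_zeroes(self, session_exp1):
        spec = al.get_model("null-aR")
        state = al.init_agent_state(session_exp1, spec)
        assert len(state.pair_index) == 32
        assert not state.q.any() and not state.q_pos.any() and not state.q_neg.any()
        assert state.mu == 0.0


class TestParameterTransforms:
    def test_midpoints(self):
        spec = al.get_model("null-a")
        u = al.transform_parameters(spec, [0.5, 1.0], "to_unconstrained")
        assert u == pytest.approx([0.0, 0.0], abs=1e-12)
        back = al.transform_parameters(spec, u, "to_native")
        assert back == pytest.approx([0.5, 1.0], abs=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 10_000))
    def test_round_trip_identity(self, seed):
        rng = np.random.default_rng(seed)
        spec = al.get_model(ALL_MODELS[seed % len(ALL_MODELS)])
        pv = random_native_params(spec, rng)
        u = al.transform_parameters(spec, pv.as_array(), "to_unconstrained")
        back = al.transform_parameters(spec, u, "to_native")
        assert np.max(np.abs(back - pv.as_array())) < 1e-10

    def test_bounds_enforced(self):
        spec = al.get_model("null-a")
        with pytest.raises(ValueError):
            al.transform_parameters(spec, [1.2, 1.0], "to_unconstrained")
        with pytest.raises(ValueError):
            al.transform_parameters(spec, [0.5, -0.1], "to_unconstrained")


class TestLikelihood:
    def test_uniform_policy_nll(self):
        rng = np.random.default_rng(0)
        _, df = random_trials(rng, n_trials=24)
        for name in ("null-a", "FB-R", "null-aR"):
            spec = al.get_model(name)
            values = {n: 0.5 for n in spec.parameter_names}
            for b in ("beta", "beta0"):
                if b in values:
                    values[b] = 0.0
            nll = al.negative_log_likelihood(spec, al.make_parameters(spec, **values), df)
            assert nll == pytest.approx(24 * np.log(2), abs=1e-10)

    @pytest.mark.parametrize("name", ALL_MODELS)
    def test_matches_straight_line_oracle(self, name):
        """100 random small instances per model agree with a naive per-trial
        re-derivation to 1e-10."""
        spec = al.get_model(name)
        rng = np.random.default_rng(hash(name) % 2**31)
        n_cases = 100
        for _ in range(n_cases):
            olist, df = random_trials(rng, n_trials=int(rng.integers(10, 60)))
            pv = random_native_params(spec, rng)
            got = al.negative_log_likelihood(spec, pv, df)
            want = oracle_nll(name, pv.values, olist)
            assert got == pytest.approx(want, abs=1e-10)

    def test_stepwise_state_path_matches_kernel(self):
        """The single-trial update/choice API and the kernel produce the same
        likelihood trajectory."""
        rng = np.random.default_rng(5)
        olist, df = random_trials(rng, n_trials=40)
        spec = al.get_model("FB-PE")
        pv = al.make_parameters(spec, alpha=0.4, alpha_mu=0.3, beta=2.0)
        from arrlearn.models import AgentState
        state = AgentState(pair_index={f"P{i}": i for i in range(4)},
                           q=np.zeros((4, 2)), q_pos=np.zeros((4, 2)),
                           q_neg=np.zeros((4, 2)), mu=0.0)
        nll = 0.0
        prev_block = None
        for tr in olist:
            if tr["block"] != prev_block:
                reset_accumulator(state)
                prev_block = tr["block"]
            pb, pw = al.choice_probabilities(state, f"P{tr['pair']}", pv, spec)
            nll -= np.log(pb if tr["chosen"] == 0 else pw)
            al.update_agent_state(
                state, TrialOutcome(f"P{tr['pair']}", tr["chosen"], tr["reward"]),
                pv, spec)
        assert nll == pytest.approx(al.negative_log_likelihood(spec, pv, df), abs=1e-10)

    def test_missed_trials_skipped(self):
        rng = np.random.default_rng(1)
        _, df = random_trials(rng, n_trials=30)
        spec = al.get_model("FB-R")
        pv = al.make_parameters(spec, alpha=0.3, alpha_mu=0.2, beta=2.0)
        df_miss = df.copy()
        kill = df_miss.index[5:10]
        df_miss.loc[kill, "missed"] = 1
        df_miss.loc[kill, "chosen_option"] = "none"
        df_kept = df.drop(kill).reset_index(drop=True)
        assert al.negative_log_likelihood(spec, pv, df_miss) == pytest.approx(
            al.negative_log_likelihood(spec, pv, df_kept), abs=1e-12)

    def test_out_of_order_trials_rejected(self):
        rng = np.random.default_rng(2)
        _, df = random_trials(rng)
        with pytest.raises(ValueError, match="order"):
            al.negative_log_likelihood(al.get_model("null-a"),
                                       al.make_parameters("null-a", alpha=0.5, beta=1.0),
                                       df.iloc[::-1])


class TestNestingReductions:
    """With the accumulator silenced every ARR model collapses exactly onto
    the canonical model, and the asymmetric/two-stream variants collapse when
    their extra parameters are neutral."""

    @pytest.mark.parametrize("name", ["FB-R", "FB-PE", "a-R", "a-PE", "b-R", "b-PE"])
    def test_arr_models_reduce_when_alpha_mu_zero(self, name):
        rng = np.random.default_rng(11)
        spec = al.get_model(name)
        base = al.get_model("null-a")
        for _ in range(20):
            _, df = random_trials(rng, n_trials=int(rng.integers(20, 60)))
            alpha, beta = rng.uniform(0.05, 0.95), rng.uniform(0.1, 6.0)
            values = dict(alpha_mu=0.0, beta=beta)
            values["alpha0" if "alpha0" in spec.parameter_names else "alpha"] = alpha
            if "beta0" in spec.parameter_names:
                values["beta0"] = values.pop("beta")
            got = al.negative_log_likelihood(spec, al.make_parameters(spec, **values), df)
            want = al.negative_log_likelihood(
                base, al.make_parameters(base, alpha=alpha, beta=beta), df)
            assert got == pytest.approx(want, abs=1e-12)

    def test_asymmetric_reduces_when_rates_equal(self):
        rng = np.random.default_rng(12)
        spec = al.get_model("null-aPE")
        base = al.get_model("null-a")
        for _ in range(20):
            _, df = random_trials(rng, n_trials=40)
            a, b = rng.uniform(0.05, 0.95), rng.uniform(0.1, 6.0)
            got = al.negative_log_likelihood(
                spec, al.make_parameters(spec, alpha_pos=a, alpha_neg=a, beta=b), df)
            want = al.negative_log_likelihood(
                base, al.make_parameters(base, alpha=a, beta=b), df)
            assert got == pytest.approx(want, abs=1e-12)

    def test_two_stream_reduces_with_neutral_weights(self):
        rng = np.random.default_rng(13)
        spec = al.get_model("null-aR")
        base = al.get_model("null-a")
        for _ in range(20):
            _, df = random_trials(rng, n_trials=40)
            a, b = rng.uniform(0.05, 0.95), rng.uniform(0.1, 6.0)
            got = al.negative_log_likelihood(
                spec, al.make_parameters(spec, alpha=a, lambda_pos=1.0, lambda_neg=1.0,
                                         w_pos=1.0, w_neg=1.0, beta=b), df)
            want = al.negative_log_likelihood(
                base, al.make_parameters(base, alpha=a, beta=b), df)
            assert got == pytest.approx(want, abs=1e-10)


class TestSimulation:
    def test_zero_weight_agent_at_chance(self, session_exp1):
        spec = al.get_model("null-a")
        pv = al.make_parameters(spec, alpha=0.3, beta=0.0)
        df = al.simulate_agent(spec, pv, session_exp1, np.random.default_rng(0))
        proper = df[df.block_index >= 1]
        assert abs(proper["correct"].mean() - 0.5) < 0.06  # 3 sigma of binomial(360)

    def test_greedy_learner_approaches_schedule_optimum(self):
        spec = al.get_model("null-a")
        pv = al.make_parameters(spec, alpha=0.3, beta=20.0)
        rng = np.random.default_rng(4)
        late = []
        for _ in range(60):
            s = al.generate_session(al.experiment_config(1), rng)
            df = al.simulate_agent(spec, pv, s, rng)
            proper = df[(df.block_index >= 1) & (df.trial_within_task >= 9)]
            first = df[(df.block_index >= 1) & (df.trial_within_task == 1)]
            late.append((proper["correct"].mean(), first["correct"].mean()))
        late_mean = np.mean([x[0] for x in late])
        first_mean = np.mean([x[1] for x in late])
        assert late_mean > 0.85        # rises toward the 9/12-schedule optimum
        assert first_mean < 0.6        # near chance before any feedback
        assert late_mean > first_mean  # rising learning curve

    def test_simulation_likelihood_self_consistency(self):
        """On simulated data, the generating parameters fit no worse on
        average than a 50%-perturbed copy."""
        spec = al.get_model("FB-R")
        pv = al.make_parameters(spec, alpha=0.4, alpha_mu=0.5, beta=2.5)
        worse = al.make_parameters(spec, alpha=0.6, alpha_mu=0.75, beta=3.75)
        rng = np.random.default_rng(9)
        gaps = []
        for _ in range(30):
            s = al.generate_session(al.experiment_config(1), rng)
            df = al.simulate_agent(spec, pv, s, rng)
            gaps.append(al.negative_log_likelihood(spec, worse, df)
                        - al.negative_log_likelihood(spec, pv, df))
        assert np.mean(gaps) > 0

    def test_mu_monotone_in_reward(self):
        """Holding choices fixed, a richer feedback sequence gives a pointwise
        greater-or-equal reward accumulator trajectory."""
        rng = np.random.default_rng(6)
        olist, df = random_trials(rng, n_trials=48, rewards=(1.0, -1.0))
        richer = df.copy()
        flip = richer["feedback_points"] == -1.0
        richer.loc[richer.index[flip][:10], "feedback_points"] = 1.0
        spec = al.get_model("FB-R")
        pv = al.make_parameters(spec, alpha=0.3, alpha_mu=0.3, beta=2.0)
        mu_a = al.choice_probability_trajectory(spec, pv, df)["mu"]
        mu_b = al.choice_probability_trajectory(spec, pv, richer)["mu"]
        assert (mu_b.to_numpy() >= mu_a.to_numpy() - 1e-12).all()

    def test_reference_hit_rate_lower_under_low_arr(self):
        """The transfer mechanism: with a reward accumulator boosting the
        prediction error, late reference-task hit rates are lower in low than
        in medium condition blocks."""
        spec = al.get_model("FB-R")
        pv = al.make_parameters(spec, alpha=0.4, alpha_mu=0.7, beta=2.5)
        rng = np.random.default_rng(21)
        rates = {"low": [], "medium": []}
        for _ in range(300):
            s = al.generate_session(al.experiment_config(1), rng)
            df = al.simulate_agent(spec, pv, s, rng)
            late = df[(df.block_index >= 1) & (df.task == "reference")
                      & (df.trial_within_task >= 9)]
            for cond in rates:
                rates[cond].append(late[late.condition == cond]["correct"].mean())
        assert np.mean(rates["low"]) < np.mean(rates["medium"])


def test_model_registry_aliases():
    assert al.get_model("ØØ-α").name == "null-a"
    assert al.get_model("fb-r").name == "FB-R"
    assert al.get_model("null-aR").n_params == 6
    assert all(al.get_model(n).n_params == 3 for n in
               ("FB-PE", "a-PE", "b-PE", "FB-R", "a-R", "b-R"))
    assert al.get_model("null-a").n_params == 2 and al.get_model("null-aPE").n_params == 3
    with pytest.raises(KeyError):
        al.get_model("nope")
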