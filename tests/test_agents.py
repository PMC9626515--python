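"""RL models: softmax rule, value updates, likelihoods, simulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from prlkit.agents import (
    EWAParams,
    RPParams,
    ValueState,
    ewa_update,
    loglik_subject,
    rp_update,
    simulate_subject,
    softmax_prob,
)
from prlkit.task import TaskConfig, build_schedule


def make_trials(choices, outcomes, block=0):
    n = len(choices)
    return pd.DataFrame(
        {
            "block": block,
            "trial": np.arange(n),
            "choice": choices,
            "outcome": outcomes,
        }
    )


class TestSoftmax:
    def test_symmetry_and_zero_beta(self):
        assert softmax_prob(ValueState(q=np.zeros(2)), 3.7) == 0.5
        assert softmax_prob(ValueState(q=np.array([0.9, -0.4])), 0.0) == 0.5

    def test_closed_form(self):
        p = softmax_prob(ValueState(q=np.array([-1.0, 1.0])), 1.0)
        assert p == pytest.approx(1 / (1 + np.exp(-2)), abs=1e-12)

    def test_monotone_in_value_gap_and_beta(self):
        gaps = np.linspace(-2, 2, 21)
        ps = [softmax_prob(ValueState(q=np.array([0.0, g])), 1.5) for g in gaps]
        assert np.all(np.diff(ps) > 0)
        betas = np.linspace(0.1, 8, 20)
        ps = [softmax_prob(ValueState(q=np.array([0.0, 0.5])), b) for b in betas]
        assert np.all(np.diff(ps) > 0)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            softmax_prob(ValueState(q=np.zeros(2)), -1.0)
        with pytest.raises(ValueError):
            softmax_prob(ValueState(q=np.array([np.nan, 0.0])), 1.0)


class TestRPUpdate:
    def test_single_step_reward(self):
        p = RPParams(a_rew=0.5, a_pun=0.3, beta=1.0)
        s = rp_update(ValueState(q=np.zeros(2)), 0, 1, p, mirrored=False)
        assert s.q[0] == pytest.approx(0.5)
        assert s.q[1] == 0.0

    def test_full_rate_jump_to_target(self):
        p = RPParams(a_rew=0.5, a_pun=1 - 1e-12, beta=1.0)
        s = rp_update(ValueState(q=np.zeros(2)), 1, -1, p, mirrored=False)
        assert s.q[1] == pytest.approx(-1.0)

    def test_mirrored_update_moves_unchosen_oppositely(self):
        p = RPParams(a_rew=0.4, a_pun=0.2, beta=1.0)
        s = rp_update(ValueState(q=np.zeros(2)), 0, 1, p, mirrored=True)
        assert s.q[0] == pytest.approx(0.4)
        assert s.q[1] == pytest.approx(-0.4)

    def test_equal_rates_reduce_to_single_rate_rw(self):
        # independent oracle: plain single-rate Rescorla-Wagner recursion
        rng = np.random.default_rng(5)
        a = 0.35
        p = RPParams(a_rew=a, a_pun=a, beta=1.0)
        q_oracle = np.zeros(2)
        state = ValueState(q=np.zeros(2))
        for _ in range(50):
            c = int(rng.integers(2))
            o = int(rng.choice([-1, 1]))
            q_oracle[c] += a * (o - q_oracle[c])
            state = rp_update(state, c, o, p, mirrored=False)
            np.testing.assert_allclose(state.q, q_oracle, atol=1e-12)

    def test_rejects_bad_outcome(self):
        p = RPParams(a_rew=0.5, a_pun=0.5, beta=1.0)
        with pytest.raises(ValueError):
            rp_update(ValueState(q=np.zeros(2)), 0, 0, p)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a_rew=st.floats(0.01, 0.99),
        a_pun=st.floats(0.01, 0.99),
        seed=st.integers(0, 10_000),
    )
    def test_values_bounded_in_unit_interval(self, a_rew, a_pun, seed):
        """With +/-1 outcomes and q0 = 0, values never leave [-1, 1]."""
        rng = np.random.default_rng(seed)
        p = RPParams(a_rew=a_rew, a_pun=a_pun, beta=1.0)
        state = ValueState(q=np.zeros(2))
        for _ in range(60):
            state = rp_update(state, int(rng.integers(2)), int(rng.choice([-1, 1])), p)
            assert np.all(np.abs(state.q) <= 1 + 1e-12)


class TestEWAUpdate:
    def test_memoryless_limit(self):
        # rho = 0, a = 0: q tracks the last payoff exactly
        p = EWAParams(a=1e-12, rho=1e-12, beta=1.0)
        s = ValueState(q=np.array([0.5, 0.0]), n=np.array([3.0, 0.0]))
        s = ewa_update(s, 0, -1, p)
        assert s.n[0] == pytest.approx(1.0)
        assert s.q[0] == pytest.approx(-1.0, abs=1e-9)

    def test_first_observation_dominates(self):
        for a in (0.1, 0.5, 0.9):
            p = EWAParams(a=a, rho=0.5, beta=1.0)
            s = ewa_update(ValueState.fresh("ewa"), 1, 1, p)
            assert s.q[1] == pytest.approx(1.0)
            assert s.n[1] == pytest.approx(1.0)

    def test_high_rho_freezes_updates(self):
        # rho -> 1: experience grows without bound, per-trial changes shrink
        p = EWAParams(a=0.2, rho=1 - 1e-9, beta=1.0)
        s = ValueState.fresh("ewa")
        deltas = []
        for t in range(100):
            q_before = s.q[0]
            s = ewa_update(s, 0, 1 if t % 2 == 0 else -1, p)
            deltas.append(abs(s.q[0] - q_before))
        assert s.n[0] > 90
        assert np.mean(deltas[-10:]) < 0.25 * np.mean(deltas[:10])


class TestLoglik:
    def test_zero_beta_is_uniform_policy(self):
        trials = make_trials([0, 1, 1, 0, 1], [1, -1, 1, 1, -1])
        p = RPParams(a_rew=0.5, a_pun=0.5, beta=0.0)
        total, pw = loglik_subject(trials, p)
        assert total == pytest.approx(5 * np.log(0.5), abs=1e-12)
        e = EWAParams(a=0.5, rho=0.5, beta=0.0)
        total, _ = loglik_subject(trials, e)
        assert total == pytest.approx(5 * np.log(0.5), abs=1e-12)

    def test_single_trial_is_log_half(self):
        trials = make_trials([1], [1])
        total, _ = loglik_subject(trials, RPParams(a_rew=0.2, a_pun=0.7, beta=4.0))
        assert total == pytest.approx(np.log(0.5), abs=1e-12)

    def test_three_trial_hand_trace_rp(self):
        """Step-by-step hand computation of the RP likelihood (mirrored)."""
        choices, outcomes = [1, 1, 0], [1, -1, -1]
        a, b = 0.5, 1.0
        p = RPParams(a_rew=a, a_pun=a, beta=b)
        q = np.zeros(2)
        expected = []
        for c, o in zip(choices, outcomes):
            p1 = 1 / (1 + np.exp(-b * (q[1] - q[0])))
            expected.append(np.log(p1 if c == 1 else 1 - p1))
            rate = a  # equal rates
            q[c] += rate * (o - q[c])
            q[1 - c] += rate * (-o - q[1 - c])
        total, pw = loglik_subject(make_trials(choices, outcomes), p)
        np.testing.assert_allclose(pw, expected, atol=1e-12)
        assert total == pytest.approx(sum(expected), abs=1e-12)

    def test_three_trial_hand_trace_ewa(self):
        choices, outcomes = [0, 0, 1], [1, -1, 1]
        a, rho, b = 0.3, 0.6, 2.0
        q = np.zeros(2)
        n = np.zeros(2)
        expected = []
        for c, o in zip(choices, outcomes):
            p1 = 1 / (1 + np.exp(-b * (q[1] - q[0])))
            expected.append(np.log(p1 if c == 1 else 1 - p1))
            n1 = rho * n[c] + 1
            q[c] = (q[c] * (1 - a) * rho * n[c] + o) / n1
            n[c] = n1
        total, pw = loglik_subject(
            make_trials(choices, outcomes), EWAParams(a=a, rho=rho, beta=b)
        )
        np.testing.assert_allclose(pw, expected, atol=1e-12)

    def test_values_reset_at_block_boundary(self):
        one = make_trials([1, 1], [1, 1], block=0)
        two = make_trials([1, 1], [1, 1], block=1)
        both = pd.concat([one, two], ignore_index=True)
        p = RPParams(a_rew=0.8, a_pun=0.2, beta=5.0)
        _, pw = loglik_subject(both, p)
        # first trial of each block starts from q = 0 -> log(0.5)
        assert pw[0] == pytest.approx(np.log(0.5))
        assert pw[2] == pytest.approx(np.log(0.5))
        assert pw[1] != pytest.approx(np.log(0.5))

    def test_rejects_disordered_trials(self):
        trials = make_trials([0, 1], [1, 1]).iloc[::-1]
        with pytest.raises(ValueError):
            loglik_subject(trials, RPParams(a_rew=0.5, a_pun=0.5, beta=1.0))


class TestSimulate:
    def test_determinism_under_fixed_seed(self):
        sched = build_schedule(TaskConfig(n_blocks=1, seed=4))
        p = RPParams(a_rew=0.4, a_pun=0.3, beta=3.0)
        s1 = simulate_subject(p, sched, np.random.default_rng(99))
        s2 = simulate_subject(p, sched, np.random.default_rng(99))
        pd.testing.assert_frame_equal(s1, s2)

    def test_zero_beta_coin_flip_policy(self):
        cfg = TaskConfig(n_blocks=3, max_trials_per_block=400, seed=6)
        sched = build_schedule(cfg)
        p = RPParams(a_rew=0.5, a_pun=0.5, beta=0.0)
        sim = simulate_subject(p, sched, np.random.default_rng(1))
        n = len(sim)
        assert n >= 600
        rate = sim["choice"].mean()
        assert abs(rate - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_high_beta_fast_learner_near_ceiling(self):
        cfg = TaskConfig(n_blocks=1, prob_error_min=0, prob_error_max=0, seed=8)
        sched = build_schedule(cfg)
        p = RPParams(a_rew=1 - 1e-9, a_pun=1 - 1e-9, beta=10.0)
        sim = simulate_subject(p, sched, np.random.default_rng(2))
        # discard the first few trials of each stage; the rest should be
        # almost always correct
        late = sim.groupby("stage", group_keys=False).apply(
            lambda g: g.iloc[3:], include_groups=False
        )
        assert late["correct"].mean() > 0.9

    def test_self_consistency_of_likelihood_and_simulator(self):
        """Data simulated at P is more likely under P than far-away params."""
        sched = build_schedule(TaskConfig(seed=10))
        p_true = RPParams(a_rew=0.4, a_pun=0.3, beta=4.0)
        p_far = RPParams(a_rew=0.05, a_pun=0.9, beta=0.3)
        wins = 0
        for seed in range(5):
            sim = simulate_subject(p_true, sched, np.random.default_rng(seed))
            ll_true, _ = loglik_subject(sim, p_true)
            ll_far, _ = loglik_subject(sim, p_far)
            wins += ll_true > ll_far
        assert wins == 5
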