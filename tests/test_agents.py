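"""Model update rules against straight-loop oracles and limiting cases."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from revalue.agents import (
    AgentState,
    KappaParams,
    RLParamsPolicy,
    RLParamsQ,
    choice_probability,
    sigmoid,
    update_policy,
    update_qlearning,
)
from revalue.task import TrialRecord
from revalue.values import _policy_scan, _q_scan


def _trial(choice, reward, collected=None):
    return TrialRecord(
        trial_index=0, block_side="R", choice=choice,
        outcome="CS+" if reward else "CS-",
        stim_collected=bool(reward if collected is None else collected),
        R=int(reward), t_go=0.0, t_move=0.5, t_outcome=1.0, t_stim=np.nan,
    )


class TestQUpdates:
    def test_first_reward_moves_value_by_learning_rate(self):
        # with the session-mean learning rate 0.24, a first CS+ moves the
        # chosen value from 0 to exactly 0.24
        p = RLParamsQ(0.24, 0.1, 0.1, 1.0, 1.0, 0.0)
        s = update_qlearning(AgentState(), _trial("R", 1), p)
        assert s.q_rew[1] == pytest.approx(0.24)

    def test_uncollected_csplus_still_rewarded_in_model1(self):
        p = RLParamsQ(0.5, 0.1, 0.1, 1.0, 1.0, 0.0)
        s = update_qlearning(AgentState(), _trial("R", 1, collected=False), p)
        assert s.q_rew[1] == pytest.approx(0.5)

    def test_model2_additive_update_and_uncollected_as_unrewarded(self):
        p = RLParamsQ(0.5, 0.1, 0.1, 1.0, 1.0, 0.0, reward_semantics="stim_as_rpe")
        s = AgentState(q_rew=[0.0, 0.8])
        out = update_qlearning(s, _trial("R", 1, collected=True), p)
        assert out.q_rew[1] == pytest.approx(0.8 + 0.5)  # additive, unbounded
        out2 = update_qlearning(s, _trial("R", 1, collected=False), p)
        assert out2.q_rew[1] == pytest.approx(0.8 + 0.5 * (0.0 - 0.8))

    def test_limiting_cases(self):
        p = RLParamsQ(1.0, 0.0, 0.0, 1.0, 1.0, 0.0)
        s = AgentState(q_rew=[0.4, 0.2])
        out = update_qlearning(s, _trial("R", 1), p)
        assert out.q_rew[1] == pytest.approx(1.0)  # alpha=1 jumps to target
        assert out.q_rew[0] == pytest.approx(0.4)  # gamma=0 leaves unchosen

    def test_no_choice_trial_skipped(self):
        p = RLParamsQ(0.5, 0.5, 0.5, 1.0, 1.0, 0.0)
        s = AgentState(q_rew=[0.3, 0.6])
        out = update_qlearning(s, _trial("none", 0), p)
        assert out.q_rew == [0.3, 0.6]

    def test_kappa_target_for_uncollected(self):
        p = KappaParams(base=RLParamsQ(0.5, 0.1, 0.1, 1.0, 1.0, 0.0), kappa=0.4)
        s = update_qlearning(AgentState(), _trial("L", 1, collected=False), p)
        assert s.q_rew[0] == pytest.approx(0.5 * 0.4)
        s2 = update_qlearning(AgentState(), _trial("L", 1, collected=True), p)
        assert s2.q_rew[0] == pytest.approx(0.5)

    def test_literal_eq5_flag_uses_reward_value(self):
        base = dict(alpha_rew=0.0, alpha_stay=0.5, gamma_forget=0.0,
                    beta_rew=1.0, beta_stay=1.0, bias=0.0)
        s = AgentState(q_rew=[0.8, 0.0], q_stay=[0.6, 0.0])
        out = update_qlearning(s, _trial("R", 0), RLParamsQ(**base))
        assert out.q_stay[0] == pytest.approx(0.6 - 0.5 * 0.6)
        out_lit = update_qlearning(s, _trial("R", 0), RLParamsQ(**base, literal_eq5=True))
        assert out_lit.q_stay[0] == pytest.approx(0.6 - 0.5 * 0.8)


class TestPolicyUpdates:
    def test_actor_critic_first_reward(self):
        p = RLParamsPolicy(0.1, 0.1, 1.0, 1.0, 0.0, critic_alpha=0.3, family="actor_critic")
        s = update_policy(AgentState(), _trial("R", 1), p)
        assert s.v == pytest.approx(0.3)  # delta = 1, V moves to critic_alpha

    def test_reinforce_zero_betas_decay(self):
        p = RLParamsPolicy(0.25, 0.25, 0.0, 0.0, 0.0)
        s = AgentState(pi=2.0)
        for _ in range(3):
            s = update_policy(s, _trial("L", 0), p)
        assert s.pi == pytest.approx(2.0 * 0.75**3)


class TestChoiceProbability:
    def test_zero_state_is_half(self):
        assert choice_probability(AgentState(), RLParamsQ(0.1, 0.1, 0.1, 1, 1, 0.0)) == 0.5

    def test_closed_form_sigmoid(self):
        s = AgentState(q_rew=[0.0, 1.0])
        p = RLParamsQ(0.1, 0.1, 0.1, beta_rew=2.0, beta_stay=0.0, bias=0.0)
        assert choice_probability(s, p) == pytest.approx(1 / (1 + math.exp(-2)), abs=1e-9)

    @given(
        st.floats(-3, 3), st.floats(-3, 3), st.floats(-2, 2),
    )
    @settings(max_examples=100, deadline=None)
    def test_binary_normalization(self, qr, ql, bias):
        s = AgentState(q_rew=[ql, qr])
        p = RLParamsQ(0.1, 0.1, 0.1, 1.5, 0.5, bias)
        pr = choice_probability(s, p)
        assert 0.0 < pr < 1.0


def _random_trials(rng, n):
    trials = []
    for i in range(n):
        choice = rng.choice(["L", "R", "none"], p=[0.45, 0.45, 0.1])
        reward = int(rng.random() < 0.5) if choice != "none" else 0
        collected = bool(reward and rng.random() < 0.8)
        trials.append(_trial(choice, reward, collected))
    return trials


@pytest.mark.parametrize("model", ["q_cs", "q_rpe", "reinforce", "actor_critic"])
def test_scan_matches_stepwise_updates(model):
    """The fast trajectory scan agrees with trial-by-trial object updates
    to 1e-12 over a 200-trial random sequence."""
    rng = np.random.default_rng(0)
    trials = _random_trials(rng, 200)
    ch = np.array([-1 if t.choice == "none" else (1 if t.choice == "R" else 0) for t in trials])
    rw = np.array([t.R for t in trials])
    col = np.array([int(t.stim_collected) for t in trials])

    if model in ("q_cs", "q_rpe"):
        params = RLParamsQ(
            0.3, 0.25, 0.15, 2.5, 1.0, 0.2,
            reward_semantics="cs_as_reward" if model == "q_cs" else "stim_as_rpe",
        )
        scan = _q_scan(ch, rw, col, params, None)
        state = AgentState()
        for i, t in enumerate(trials):
            expect = [state.q_rew[0], state.q_rew[1], state.q_stay[0], state.q_stay[1],
                      choice_probability(state, params)]
            np.testing.assert_allclose(scan[i], expect, atol=1e-12)
            state = update_qlearning(state, t, params)
    else:
        params = RLParamsPolicy(
            0.2, 0.3, 1.5, 1.0, -0.1, critic_alpha=0.25, family=model
        )
        scan = _policy_scan(ch, rw, params)
        state = AgentState()
        for i, t in enumerate(trials):
            expect = [state.pi, state.v, t.R - state.v, choice_probability(state, params)]
            np.testing.assert_allclose(scan[i], expect, atol=1e-12)
            state = update_policy(state, t, params)


@given(st.integers(0, 10_000))
@settings(max_examples=30, deadline=None)
def test_model1_values_stay_in_unit_interval(seed):
    """Convex-combination updates keep q_rew, q_stay in [0, 1]."""
    rng = np.random.default_rng(seed)
    trials = _random_trials(rng, 100)
    p = RLParamsQ(
        rng.uniform(0, 1), rng.uniform(0, 1), rng.uniform(0, 1), 1.0, 1.0, 0.0
    )
    state = AgentState()
    for t in trials:
        state = update_qlearning(state, t, p)
        assert all(0.0 <= q <= 1.0 for q in state.q_rew + state.q_stay)


def test_model2_value_unbounded_growth():
    p = RLParamsQ(0.5, 0.1, 0.0, 1, 1, 0, reward_semantics="stim_as_rpe")
    state = AgentState()
    for _ in range(10):
        state = update_qlearning(state, _trial("R", 1, collected=True), p)
    assert state.q_rew[1] == pytest.approx(5.0)  # 10 * 0.5, beyond [0, 1]
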