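"""Independent brute-force oracles shared by the acceptance checks."""

import numpy as np

from revalue.agents import (
    AgentState,
    RLParamsPolicy,
    RLParamsQ,
    choice_probability,
    update_policy,
    update_qlearning,
)
from revalue.neural.design import build_design_matrix
from revalue.neural.timeline import EVENTS, KERNEL_WINDOWS, build_event_timeline
from revalue.task import SessionData, TrialRecord
from revalue.values import _policy_scan, _q_scan


def _toy_session(n_trials=5, seed=0):
    rng = np.random.default_rng(seed)
    trials = []
    t = 0.0
    for i in range(n_trials):
        t_go = t + 0.3
        t_move = t_go + rng.uniform(0.2, 0.6)
        t_out = t_move + 0.2
        rewarded = i % 2 == 0
        trials.append(
            TrialRecord(
                trial_index=i, block_side="R",
                choice="R" if i % 3 else "L",
                outcome="CS+" if rewarded else "CS-",
                stim_collected=rewarded, R=int(rewarded),
                t_go=t_go, t_move=t_move, t_outcome=t_out,
                t_stim=t_out if rewarded else np.nan,
            )
        )
        t = t_out + 4.0
    return SessionData(trials=trials, block_starts=[0])


def design_matrix_max_abs_dev() -> float:
    """Max |design - brute-force convolution| over all event columns."""
    sess = _toy_session()
    tl = build_event_timeline(sess)
    dm = build_design_matrix(tl)
    X = np.asarray(dm.X.todense())
    worst = 0.0
    for e in EVENTS:
        basis = dm.bases[e].matrix
        w0 = int(round(KERNEL_WINDOWS[e][0] / tl.bin_width))
        for j in range(basis.shape[1]):
            expected = np.zeros((tl.n_trials, tl.n_bins))
            for (tr, b) in tl.event_bins[e]:
                for lag in range(basis.shape[0]):
                    bb = b + w0 + lag
                    if 0 <= bb < tl.n_bins:
                        expected[tr, bb] += basis[lag, j]
            worst = max(
                worst,
                float(np.abs(X[:, dm.columns[e].start + j] - expected.ravel()).max()),
            )
    return worst


def trajectory_max_abs_dev(n_trials: int = 200) -> float:
    """Max deviation between the fast scans and step-by-step state updates
    across all four model families."""
    rng = np.random.default_rng(0)
    trials = []
    for i in range(n_trials):
        choice = rng.choice(["L", "R", "none"], p=[0.45, 0.45, 0.1])
        reward = int(rng.random() < 0.5) if choice != "none" else 0
        trials.append(
            TrialRecord(
                trial_index=i, block_side="R", choice=choice,
                outcome="CS+" if reward else "CS-",
                stim_collected=bool(reward and rng.random() < 0.8),
                R=reward, t_go=0.0, t_move=0.5, t_outcome=1.0, t_stim=np.nan,
            )
        )
    ch = np.array([-1 if t.choice == "none" else (1 if t.choice == "R" else 0) for t in trials])
    rw = np.array([t.R for t in trials])
    col = np.array([int(t.stim_collected) for t in trials])
    worst = 0.0
    for model in ("q_cs", "q_rpe"):
        params = RLParamsQ(
            0.3, 0.25, 0.15, 2.5, 1.0, 0.2,
            reward_semantics="cs_as_reward" if model == "q_cs" else "stim_as_rpe",
        )
        scan = _q_scan(ch, rw, col, params, None)
        state = AgentState()
        for i, t in enumerate(trials):
            expect = np.array(
                [state.q_rew[0], state.q_rew[1], state.q_stay[0], state.q_stay[1],
                 choice_probability(state, params)]
            )
            worst = max(worst, float(np.abs(scan[i] - expect).max()))
            state = update_qlearning(state, t, params)
    for family in ("reinforce", "actor_critic"):
        params = RLParamsPolicy(0.2, 0.3, 1.5, 1.0, -0.1, critic_alpha=0.25, family=family)
        scan = _policy_scan(ch, rw, params)
        state = AgentState()
        for i, t in enumerate(trials):
            expect = np.array(
                [state.pi, state.v, t.R - state.v, choice_probability(state, params)]
            )
            worst = max(worst, float(np.abs(scan[i] - expect).max()))
            state = update_policy(state, t, params)
    return worst
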