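"""Trial-by-trial decision-variable extraction and on-policy simulation.

The neural analyses consume *pre-update* value series: for trial t the
emitted values reflect learning from trials 1..t-1 only, so no variable ever
leaks the current trial's outcome.  Laterality follows the recording
convention: for a left-hemisphere site, contralateral = Right choices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agents import (
    AgentState,
    KappaParams,
    RLAgent,
    RLParamsPolicy,
    RLParamsQ,
    choice_probability,
    sigmoid,
    update_state,
)
from .task import NO_CHOICE, RIGHT, SessionData, TaskConfig, simulate_session

__all__ = [
    "session_arrays",
    "predict_choice_probabilities",
    "extract_decision_variables",
    "detrend_trial_variable",
    "simulate_on_policy",
    "calibration_summary",
]


def session_arrays(session: SessionData) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Encode a session as integer arrays: choice (-1 none / 0 L / 1 R),
    reward indicator, and collection flag."""
    ch = np.array(
        [-1 if t.choice == NO_CHOICE else (1 if t.choice == RIGHT else 0) for t in session.trials],
        dtype=np.int64,
    )
    rw = np.array([t.R for t in session.trials], dtype=np.int64)
    col = np.array([int(t.stim_collected) for t in session.trials], dtype=np.int64)
    return ch, rw, col


def _q_scan(ch, rw, col, params: RLParamsQ, kappa: float | None):
    """Scalar loop over trials for the Q family.

    Returns per-trial pre-update (q_rew_L, q_rew_R, q_stay_L, q_stay_R,
    p_right).  Plain-Python floats keep a ~500-trial scan well under a
    millisecond, which matters because the likelihood is evaluated thousands
    of times during fitting.
    """
    a_r, a_s, g = params.alpha_rew, params.alpha_stay, params.gamma_forget
    b_r, b_s, bias = params.beta_rew, params.beta_stay, params.bias
    rpe_mode = params.reward_semantics == "stim_as_rpe"
    literal = params.literal_eq5
    qL = qR = sL = sR = 0.0
    n = len(ch)
    out = np.empty((n, 5))
    for i in range(n):
        x = bias + b_r * (qR - qL) + b_s * (sR - sL)
        if x >= 0:
            p = 1.0 / (1.0 + math.exp(-x))
        else:
            z = math.exp(x)
            p = z / (1.0 + z)
        out[i, 0] = qL
        out[i, 1] = qR
        out[i, 2] = sL
        out[i, 3] = sR
        out[i, 4] = p
        c = ch[i]
        if c < 0:
            continue
        r = rw[i]
        if rpe_mode:
            rewarded_update = bool(r) and bool(col[i])
        else:
            rewarded_update = bool(r)
        if c == 1:
            if rpe_mode and rewarded_update:
                qR += a_r
            elif rewarded_update:
                target = 1.0
                if kappa is not None and not col[i]:
                    target = kappa
                qR += a_r * (target - qR)
            else:
                qR += a_r * (0.0 - qR)
            qL -= g * qL
            sR += a_s * (1.0 - sR)
            sL += a_s * (0.0 - (qL if literal else sL))
        else:
            if rpe_mode and rewarded_update:
                qL += a_r
            elif rewarded_update:
                target = 1.0
                if kappa is not None and not col[i]:
                    target = kappa
                qL += a_r * (target - qL)
            else:
                qL += a_r * (0.0 - qL)
            qR -= g * qR
            sL += a_s * (1.0 - sL)
            sR += a_s * (0.0 - (qR if literal else sR))
    return out


def _policy_scan(ch, rw, params: RLParamsPolicy):
    """Scalar loop for REINFORCE / actor-critic; returns (pi, v, delta,
    p_right) per trial, pre-update."""
    ac = params.family == "actor_critic"
    pi = v = 0.0
    n = len(ch)
    out = np.empty((n, 4))
    for i in range(n):
        x = params.bias + pi
        if x >= 0:
            p = 1.0 / (1.0 + math.exp(-x))
        else:
            z = math.exp(x)
            p = z / (1.0 + z)
        c = ch[i]
        r = float(rw[i])
        delta = r - v
        out[i, 0] = pi
        out[i, 1] = v
        out[i, 2] = delta
        out[i, 3] = p
        if c < 0:
            continue
        sign = 2 * c - 1
        p_a = p if c == 1 else 1.0 - p
        if rw[i]:
            alpha, beta = params.alpha_win, params.beta_win
        else:
            alpha, beta = params.alpha_loss, params.beta_loss
        step = sign * beta * (1.0 - p_a)
        if ac:
            step *= delta
            v += params.critic_alpha * delta
        pi = (1.0 - alpha) * pi + step
    return out


def predict_choice_probabilities(
    session: SessionData, params: RLParamsQ | RLParamsPolicy | KappaParams
) -> np.ndarray:
    """Per-trial pre-update P(Right) under the model, run off-policy."""
    ch, rw, col = session_arrays(session)
    if isinstance(params, KappaParams):
        return _q_scan(ch, rw, col, params.base, params.kappa)[:, 4]
    if isinstance(params, RLParamsQ):
        return _q_scan(ch, rw, col, params, None)[:, 4]
    return _policy_scan(ch, rw, params)[:, 3]


def _v_scan(ch, rw, alpha: float):
    """State-value trajectory: delta_t = R_t - V_t, V <- V + alpha*delta.

    Pre-update V and delta are emitted per trial; no-choice trials do not
    update V."""
    v = 0.0
    n = len(ch)
    out = np.empty((n, 2))
    for i in range(n):
        delta = float(rw[i]) - v
        out[i, 0] = v
        out[i, 1] = delta
        if ch[i] >= 0:
            v += alpha * delta
    return out


def extract_decision_variables(
    session: SessionData, params: RLParamsQ | KappaParams, model: str = "q_cs"
) -> pd.DataFrame:
    """Run the Q-learning model off-policy over observed choices/outcomes.

    Returns one row per trial with pre-update values: component values
    q_rew_*/q_stay_*, composite action values q_L/q_R (beta-weighted sums),
    their contra/ipsi relabeling by ``session.hemisphere``, relative value
    delta_q, state value v with its RPE delta, and P(Right).
    """
    if session.n_completed < 1:
        raise ValueError("session has no completed trials")
    kappa = None
    if isinstance(params, KappaParams):
        kappa = params.kappa
        base = params.base
    else:
        base = params
    ch, rw, col = session_arrays(session)
    scan = _q_scan(ch, rw, col, base, kappa)
    q_rew_L, q_rew_R = scan[:, 0], scan[:, 1]
    q_stay_L, q_stay_R = scan[:, 2], scan[:, 3]
    q_L = base.beta_rew * q_rew_L + base.beta_stay * q_stay_L
    q_R = base.beta_rew * q_rew_R + base.beta_stay * q_stay_R
    delta_q_lr = q_R - q_L
    vscan = _v_scan(ch, rw, base.alpha_rew)

    if session.hemisphere == "left":
        q_contra, q_ipsi = q_R, q_L
        q_rew_contra, q_rew_ipsi = q_rew_R, q_rew_L
        delta_q = delta_q_lr
    elif session.hemisphere == "right":
        q_contra, q_ipsi = q_L, q_R
        q_rew_contra, q_rew_ipsi = q_rew_L, q_rew_R
        delta_q = -delta_q_lr
    else:
        raise ValueError("hemisphere must be 'left' or 'right'")

    return pd.DataFrame(
        dict(
            trial=np.arange(len(ch)),
            q_rew_L=q_rew_L,
            q_rew_R=q_rew_R,
            q_stay_L=q_stay_L,
            q_stay_R=q_stay_R,
            q_L=q_L,
            q_R=q_R,
            q_contra=q_contra,
            q_ipsi=q_ipsi,
            q_rew_contra=q_rew_contra,
            q_rew_ipsi=q_rew_ipsi,
            delta_q=delta_q,
            v=vscan[:, 0],
            delta=vscan[:, 1],
            p_right=scan[:, 4],
        )
    )


def detrend_trial_variable(values: np.ndarray) -> np.ndarray:
    """Residuals of an ordinary least-squares fit on trial index.

    Slowly learned values drift monotonically over a session; regressing out
    trial number removes the component that could alias against slow drift
    in spiking.  Residuals have zero mean and zero correlation with trial
    index.
    """
    y = np.asarray(values, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 trials to detrend")
    x = np.arange(y.size, dtype=float)
    xc = x - x.mean()
    denom = float(xc @ xc)
    slope = float(xc @ (y - y.mean())) / denom if denom > 0 else 0.0
    return y - (y.mean() + slope * xc)


def simulate_on_policy(
    params: RLParamsQ | RLParamsPolicy | KappaParams,
    config: TaskConfig,
    n_trials: int,
    seed: int,
    hemisphere: str = "left",
) -> tuple[SessionData, pd.DataFrame | None]:
    """Couple the model's policy with the task simulator.

    Returns the session and, for Q-family parameters, the off-policy value
    trajectories (identical to the on-policy latents by construction).
    """
    agent = RLAgent(params)
    session = simulate_session(config, agent, n_trials, seed, hemisphere=hemisphere)
    traj = None
    if isinstance(params, (RLParamsQ, KappaParams)):
        traj = extract_decision_variables(session, params)
    return session, traj


def calibration_summary(
    session: SessionData, traj: pd.DataFrame | None = None, n_quantiles: int = 10
) -> dict:
    """Behavioral calibration statistics.

    Win-stay: P(repeat | previous CS+) vs P(repeat | previous CS-);
    P(high-probability choice); and, when trajectories are supplied, mean
    P(Right)-calibration across relative-value quantiles.
    """
    completed = [t for t in session.trials if t.completed]
    rep_after_plus, rep_after_minus = [], []
    for prev, cur in zip(completed[:-1], completed[1:]):
        repeated = float(cur.choice == prev.choice)
        (rep_after_plus if prev.R else rep_after_minus).append(repeated)
    out = {
        "p_repeat_after_csplus": float(np.mean(rep_after_plus)) if rep_after_plus else np.nan,
        "p_repeat_after_csminus": float(np.mean(rep_after_minus)) if rep_after_minus else np.nan,
        "p_high_choice": float(np.mean([t.choice == t.block_side for t in completed])),
        "n_completed": len(completed),
        "n_blocks": len(session.block_starts),
    }
    if traj is not None:
        ch = np.array([1 if t.choice == RIGHT else 0 for t in session.trials])
        ok = np.array([t.completed for t in session.trials])
        dq = (traj["q_R"] - traj["q_L"]).to_numpy()[ok]
        chose_right = ch[ok]
        edges = np.quantile(dq, np.linspace(0, 1, n_quantiles + 1))
        idx = np.clip(np.searchsorted(edges, dq, side="right") - 1, 0, n_quantiles - 1)
        out["p_right_by_dq_quantile"] = np.array(
            [chose_right[idx == q].mean() if np.any(idx == q) else np.nan for q in range(n_quantiles)]
        )
    return out
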