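"""Behavioral model update rules and choice policies.

Four trial-by-trial models of choice on the reversal task:

* ``q_cs`` — extended Q-learning treating the CS+ as the reward: the chosen
  action's reward value moves toward 1 on CS+ trials (collected or not) and
  toward 0 on CS- trials, with forgetting (exponential decay of the unchosen
  value) and perseveration (a leaky average of past choices, Q_stay).
* ``q_rpe`` — extended Q-learning treating the dopamine stimulation itself
  as an RPE: on collected-stimulation trials the chosen value is incremented
  additively by alpha_rew; CS+ trials without collection count as unrewarded.
* ``reinforce`` — policy gradient: a single propensity pi for Right over
  Left is nudged by the action prediction error (1 - P(a)) with win/loss
  specific rates and weights.
* ``actor_critic`` — REINFORCE plus a critic tracking state value V via the
  RPE delta = R - V, which multiplicatively scales the actor's update.

Choice probabilities pass through a sigmoid with an innate side bias.
All latent states start at zero at the beginning of a session.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .task import NO_CHOICE, RIGHT, SessionData, TrialRecord

__all__ = [
    "RLParamsQ",
    "RLParamsPolicy",
    "KappaParams",
    "AgentState",
    "update_qlearning",
    "update_policy",
    "choice_probability",
    "sigmoid",
    "RLAgent",
    "Q_FAMILY",
    "POLICY_FAMILY",
    "MODELS",
]

Q_FAMILY = ("q_cs", "q_rpe", "kappa")
POLICY_FAMILY = ("reinforce", "actor_critic")
MODELS = Q_FAMILY[:2] + POLICY_FAMILY


def sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


@dataclass(frozen=True)
class RLParamsQ:
    """Parameters of the extended Q-learning models.

    ``reward_semantics`` selects between treating the CS+ as the reward
    (``cs_as_reward``) and treating collected stimulation as an RPE
    (``stim_as_rpe``).
    """

    alpha_rew: float
    alpha_stay: float
    gamma_forget: float
    beta_rew: float
    beta_stay: float
    bias: float
    reward_semantics: str = "cs_as_reward"
    #: reproduce the printed (likely erroneous) unchosen-stay update, which
    #: uses the reward value on its right-hand side
    literal_eq5: bool = False

    def __post_init__(self) -> None:
        for name in ("alpha_rew", "alpha_stay", "gamma_forget"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.reward_semantics not in ("cs_as_reward", "stim_as_rpe"):
            raise ValueError("unknown reward_semantics")


@dataclass(frozen=True)
class RLParamsPolicy:
    """Parameters of the REINFORCE and actor-critic models."""

    alpha_win: float
    alpha_loss: float
    beta_win: float
    beta_loss: float
    bias: float
    critic_alpha: float = 0.0
    family: str = "reinforce"

    def __post_init__(self) -> None:
        for name in ("alpha_win", "alpha_loss", "critic_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.family not in POLICY_FAMILY:
            raise ValueError("family must be reinforce or actor_critic")


@dataclass(frozen=True)
class KappaParams:
    """Q-learning variant with a free value kappa for uncollected CS+.

    CS+ with stimulation keeps its preset target of 1; CS+ without
    stimulation moves the chosen value toward kappa; CS- keeps target 0.
    """

    base: RLParamsQ
    kappa: float = 1.0


@dataclass
class AgentState:
    """Latent state of any of the models; all zeros at session start.

    Index 0 is Left, index 1 is Right.
    """

    q_rew: list[float] = field(default_factory=lambda: [0.0, 0.0])
    q_stay: list[float] = field(default_factory=lambda: [0.0, 0.0])
    pi: float = 0.0
    v: float = 0.0

    def copy(self) -> "AgentState":
        return AgentState(list(self.q_rew), list(self.q_stay), self.pi, self.v)


def _choice_index(choice: str) -> int:
    return 1 if choice == RIGHT else 0


def update_qlearning(
    state: AgentState, trial: TrialRecord, params: RLParamsQ | KappaParams
) -> AgentState:
    """One Q-learning update; trials without a choice leave state unchanged."""
    if trial.choice == NO_CHOICE:
        return state
    kappa = None
    if isinstance(params, KappaParams):
        kappa = params.kappa
        params = params.base
    new = state.copy()
    a = _choice_index(trial.choice)
    u = 1 - a
    q = new.q_rew
    if params.reward_semantics == "cs_as_reward":
        if trial.R:
            target = 1.0
            if kappa is not None and not trial.stim_collected:
                target = kappa
            q[a] += params.alpha_rew * (target - q[a])
        else:
            q[a] += params.alpha_rew * (0.0 - q[a])
    else:  # stim_as_rpe: stimulation acts as the prediction error itself
        if trial.R and trial.stim_collected:
            q[a] += params.alpha_rew * 1.0
        else:
            q[a] += params.alpha_rew * (0.0 - q[a])
    q[u] -= params.gamma_forget * q[u]

    s = new.q_stay
    s[a] += params.alpha_stay * (1.0 - s[a])
    if params.literal_eq5:
        s[u] += params.alpha_stay * (0.0 - q[u])
    else:
        s[u] += params.alpha_stay * (0.0 - s[u])
    return new


def update_policy(
    state: AgentState, trial: TrialRecord, params: RLParamsPolicy
) -> AgentState:
    """One REINFORCE / actor-critic update; no-choice trials are skipped."""
    if trial.choice == NO_CHOICE:
        return state
    new = state.copy()
    a = _choice_index(trial.choice)
    sign = 2 * a - 1  # +1 Right, -1 Left
    p_right = sigmoid(params.bias + state.pi)
    p_a = p_right if a == 1 else 1.0 - p_right
    if trial.R:
        alpha, beta = params.alpha_win, params.beta_win
    else:
        alpha, beta = params.alpha_loss, params.beta_loss
    step = sign * beta * (1.0 - p_a)
    if params.family == "actor_critic":
        delta = float(trial.R) - state.v
        new.v = state.v + params.critic_alpha * delta
        step *= delta
    new.pi = (1.0 - alpha) * state.pi + step
    return new


def choice_probability(
    state: AgentState, params: RLParamsQ | RLParamsPolicy | KappaParams
) -> float:
    """Probability of a Right choice given the current latent state."""
    if isinstance(params, KappaParams):
        params = params.base
    if isinstance(params, RLParamsQ):
        dq_rew = state.q_rew[1] - state.q_rew[0]
        dq_stay = state.q_stay[1] - state.q_stay[0]
        return sigmoid(
            params.bias + params.beta_rew * dq_rew + params.beta_stay * dq_stay
        )
    return sigmoid(params.bias + state.pi)


def update_state(
    state: AgentState,
    trial: TrialRecord,
    params: RLParamsQ | RLParamsPolicy | KappaParams,
) -> AgentState:
    """Dispatch to the appropriate family's update rule."""
    if isinstance(params, (RLParamsQ, KappaParams)):
        return update_qlearning(state, trial, params)
    return update_policy(state, trial, params)


class RLAgent:
    """Stateful on-policy agent usable as a ``simulate_session`` callback.

    Maintains its own latent state, updating it incrementally from the last
    trial of the history it is shown.
    """

    def __init__(self, params: RLParamsQ | RLParamsPolicy | KappaParams):
        self.params = params
        self.state = AgentState()
        self._n_seen = 0

    def __call__(self, history: Sequence[TrialRecord]) -> float:
        while self._n_seen < len(history):
            self.state = update_state(self.state, history[self._n_seen], self.params)
            self._n_seen += 1
        return choice_probability(self.state, self.params)
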