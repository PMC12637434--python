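"""Probabilistic reversal-learning task simulator.

The task is a two-alternative (left/right wheel turn) probabilistic reversal
task: within a block one side is rewarded with high probability (default 70%)
and the other with low probability (default 10%).  Blocks have a default
length drawn uniformly from [20, 40] trials, and the high-probability side
flips at every block transition.  A debiasing rule prevents a block from
advancing until the subject has made at least 7 of its last 10 choices toward
the current high-probability side, which can extend blocks past their drawn
length.  Rewarded choices trigger a positive conditioned stimulus (CS+);
collection of the reinforcer (VTA dopamine stimulation in the experiment this
emulates) is modelled as an independent Bernoulli event per CS+ trial.
Unrewarded or timed-out trials produce a CS-.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "TrialRecord",
    "SessionData",
    "simulate_session",
    "apply_debias_rule",
    "draw_block_length",
]

LEFT = "L"
RIGHT = "R"
NO_CHOICE = "none"
CS_PLUS = "CS+"
CS_MINUS = "CS-"

VARIANTS = ("standard", "no_lick_with_cs", "no_lick_without_cs")


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the reversal task.

    Probabilities are per completed choice; times are in seconds.
    ``collection_prob`` is an agent model of licking for the reinforcer on
    CS+ trials (the experiment's subjects occasionally forgo collection).
    """

    p_high: float = 0.7
    p_low: float = 0.1
    block_len_min: int = 20
    block_len_max: int = 40
    debias_required: int = 7
    debias_window: int = 10
    quiescent_range: tuple[float, float] = (0.2, 0.5)
    choice_timeout: float = 60.0
    lick_window: float = 1.0
    collection_prob: float = 1.0
    iti_range: tuple[float, float] = (4.0, 5.0)
    variant: str = "standard"
    # synthetic-session plumbing, not part of the task rules proper
    choice_latency_range: tuple[float, float] = (0.2, 0.8)
    movement_duration_range: tuple[float, float] = (0.15, 0.35)
    timeout_prob: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_low < self.p_high <= 1.0) and not (
            self.p_low == self.p_high
        ):
            # degenerate equal probabilities are allowed for testing
            raise ValueError("require 0 <= p_low <= p_high <= 1")
        if not (0.0 <= self.p_low <= 1.0 and 0.0 <= self.p_high <= 1.0):
            raise ValueError("probabilities must be in [0, 1]")
        if self.block_len_min > self.block_len_max:
            raise ValueError("block_len_min must be <= block_len_max")
        if self.debias_required > self.debias_window:
            raise ValueError("debias_required must be <= debias_window")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")


@dataclass
class TrialRecord:
    """One trial of the task.

    ``block_side`` is the high-reward-probability side.  ``R`` is the binary
    reward indicator seen by the behavioral models (1 on CS+ trials).
    ``t_stim`` is NaN when the reinforcer was not collected.
    """

    trial_index: int
    block_side: str
    choice: str
    outcome: str
    stim_collected: bool
    R: int
    t_go: float
    t_move: float
    t_outcome: float
    t_stim: float

    @property
    def completed(self) -> bool:
        return self.choice != NO_CHOICE


@dataclass
class SessionData:
    """A simulated (or recorded) session: an ordered list of trials."""

    trials: list[TrialRecord]
    hemisphere: str = "left"
    block_starts: list[int] = field(default_factory=list)
    seed: int | None = None
    config: TaskConfig | None = None
    session_id: str = "session0"
    #: False for the task variant where the CS+ tone is omitted (the reward
    #: indicator R is unchanged; only the auditory event is absent).
    cs_plus_cue_present: bool = True

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_completed(self) -> int:
        return sum(t.completed for t in self.trials)

    def completed_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.completed]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            dict(
                session_id=self.session_id,
                trial=t.trial_index,
                block_side=t.block_side,
                choice=t.choice,
                outcome=t.outcome,
                stim_collected=t.stim_collected,
                R=t.R,
                t_go=t.t_go,
                t_move=t.t_move,
                t_outcome=t.t_outcome,
                t_stim=t.t_stim,
            )
            for t in self.trials
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        hemisphere: str = "left",
        config: TaskConfig | None = None,
    ) -> "SessionData":
        trials = [
            TrialRecord(
                trial_index=int(r.trial),
                block_side=str(r.block_side),
                choice=str(r.choice),
                outcome=str(r.outcome),
                stim_collected=bool(r.stim_collected),
                R=int(r.R),
                t_go=float(r.t_go),
                t_move=float(r.t_move),
                t_outcome=float(r.t_outcome),
                t_stim=float(r.t_stim),
            )
            for r in df.itertuples()
        ]
        starts = [0] + [
            i
            for i in range(1, len(trials))
            if trials[i].block_side != trials[i - 1].block_side
        ]
        sid = str(df["session_id"].iloc[0]) if "session_id" in df else "session0"
        return cls(
            trials=trials,
            hemisphere=hemisphere,
            block_starts=starts,
            config=config,
            session_id=sid,
        )


def apply_debias_rule(
    recent_choices: Sequence[str], block_side: str, config: TaskConfig
) -> bool:
    """Return True iff the debias criterion permits the block to advance.

    Within the last ``debias_window`` completed choices, at least
    ``debias_required`` must match ``block_side``.  When fewer than
    ``debias_window`` completed choices exist (in the current block), the
    window is undefined and the rule returns False.
    """
    if len(recent_choices) < config.debias_window:
        return False
    window = list(recent_choices)[-config.debias_window :]
    return sum(c == block_side for c in window) >= config.debias_required


def draw_block_length(config: TaskConfig, rng: np.random.Generator) -> int:
    """Draw a default block length uniformly from [block_len_min, block_len_max]."""
    return int(rng.integers(config.block_len_min, config.block_len_max + 1))


def simulate_session(
    config: TaskConfig,
    agent: Callable[[list[TrialRecord]], float],
    n_trials: int,
    seed: int,
    hemisphere: str = "left",
    session_id: str = "session0",
) -> SessionData:
    """Simulate one session of the reversal task.

    ``agent`` maps the history of past trials to the probability of a Right
    choice on the upcoming trial.  One RNG stream (PCG64, seeded explicitly)
    drives the whole session; per-trial draws consume it in a fixed order:
    quiescent latency, timeout, choice, outcome, collection (standard variant,
    CS+ trials only), choice latency, movement duration, ITI.  Block-length
    draws occur at each block start.

    The session is byte-identical for identical (config, agent, seed).
    """
    if not callable(agent):
        raise TypeError("agent must be callable")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")

    rng = np.random.Generator(np.random.PCG64(seed))
    trials: list[TrialRecord] = []
    block_starts = [0]
    block_side = LEFT if rng.random() < 0.5 else RIGHT
    block_len = draw_block_length(config, rng)
    block_choices: list[str] = []  # completed choices in the current block
    t = 0.0

    for i in range(n_trials):
        quiescent = rng.uniform(*config.quiescent_range)
        t_go = t + quiescent

        timed_out = config.timeout_prob > 0 and rng.random() < config.timeout_prob
        if timed_out:
            choice = NO_CHOICE
            outcome = CS_MINUS
            collected = False
            t_move = np.nan
            t_outcome = t_go + config.choice_timeout
            t_stim = np.nan
            reward = 0
        else:
            p_right = float(agent(trials))
            choice = RIGHT if rng.random() < p_right else LEFT
            p_reward = config.p_high if choice == block_side else config.p_low
            rewarded = rng.random() < p_reward
            outcome = CS_PLUS if rewarded else CS_MINUS
            if config.variant == "standard":
                collected = bool(rewarded and rng.random() < config.collection_prob)
            else:
                collected = bool(rewarded)
            latency = rng.uniform(*config.choice_latency_range)
            movement = rng.uniform(*config.movement_duration_range)
            t_move = t_go + latency
            t_outcome = t_move + movement
            t_stim = t_outcome if collected else np.nan
            reward = int(rewarded)

        trials.append(
            TrialRecord(
                trial_index=i,
                block_side=block_side,
                choice=choice,
                outcome=outcome,
                stim_collected=collected,
                R=reward,
                t_go=t_go,
                t_move=t_move,
                t_outcome=t_outcome,
                t_stim=t_stim,
            )
        )
        if choice != NO_CHOICE:
            block_choices.append(choice)

        iti = rng.uniform(*config.iti_range)
        t = t_outcome if np.isfinite(t_outcome) else t_go
        t += iti

        # block advances only once the drawn length is reached AND the
        # debias criterion holds
        trials_in_block = i - block_starts[-1] + 1
        if trials_in_block >= block_len and apply_debias_rule(
            block_choices, block_side, config
        ):
            block_side = RIGHT if block_side == LEFT else LEFT
            block_len = draw_block_length(config, rng)
            block_starts.append(i + 1)
            block_choices = []

    if block_starts and block_starts[-1] == n_trials:
        block_starts = block_starts[:-1]

    return SessionData(
        trials=trials,
        hemisphere=hemisphere,
        block_starts=block_starts,
        seed=seed,
        config=config,
        session_id=session_id,
        cs_plus_cue_present=config.variant != "no_lick_without_cs",
    )
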