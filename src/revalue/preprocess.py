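"""Behavioral preprocessing: wheel-onset detection, laterality, exclusions.

Movement onsets are detected in two passes: coarse periods where the
200 ms moving-average wheel speed is at least 1 cm/s (adjacent periods
separated by <100 ms merged, periods shorter than 50 ms removed), then a
precise onset per period — the first instant the 5 ms moving-average speed
reaches 0.2 cm/s.  The per-trial onset is the first one between 0.2 s
before the go cue and the outcome; trials without one are excluded, as are
the first and last ten trials of a session and trials without a choice.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .task import LEFT, NO_CHOICE, RIGHT, SessionData

__all__ = [
    "WheelOnsetParams",
    "detect_wheel_onsets",
    "trial_movement_onsets",
    "assign_laterality",
    "apply_trial_exclusions",
]


@dataclass(frozen=True)
class WheelOnsetParams:
    coarse_threshold: float = 1.0  # cm/s over the coarse moving average
    coarse_window: float = 0.2  # s
    merge_gap: float = 0.1  # s
    min_duration: float = 0.05  # s
    precise_threshold: float = 0.2  # cm/s over the precise moving average
    precise_window: float = 0.005  # s
    pre_go_window: float = 0.2  # s before go cue searched for the trial onset

    def __post_init__(self) -> None:
        if self.coarse_threshold <= 0 or self.precise_threshold <= 0:
            raise ValueError("thresholds must be positive")


def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    n = max(int(n), 1)
    kernel = np.ones(n) / n
    return np.convolve(x, kernel, mode="same")


def detect_wheel_onsets(
    times: np.ndarray,
    positions: np.ndarray,
    params: WheelOnsetParams | None = None,
) -> np.ndarray:
    """Movement onset times from a uniformly sampled position trace (cm)."""
    params = params or WheelOnsetParams()
    times = np.asarray(times, dtype=float)
    positions = np.asarray(positions, dtype=float)
    dt = np.diff(times)
    if dt.size == 0:
        return np.array([])
    step = float(np.median(dt))
    if not np.allclose(dt, step, rtol=0, atol=step * 1e-3):
        raise ValueError("trace must be uniformly sampled")
    fs = 1.0 / step
    speed = np.abs(np.gradient(positions, step))
    coarse = _moving_average(speed, round(params.coarse_window * fs))
    precise = _moving_average(speed, round(params.precise_window * fs))

    moving = coarse >= params.coarse_threshold
    # segment the boolean mask
    edges = np.diff(moving.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if moving[0]:
        starts.insert(0, 0)
    if moving[-1]:
        ends.append(moving.size)
    segments = list(zip(starts, ends))
    # merge gaps shorter than merge_gap
    merged: list[list[int]] = []
    max_gap = int(round(params.merge_gap * fs))
    for s, e in segments:
        if merged and s - merged[-1][1] < max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    # drop segments shorter than min_duration
    min_len = int(round(params.min_duration * fs))
    kept = [(s, e) for s, e in merged if e - s >= min_len]

    onsets = []
    back = int(round(params.coarse_window * fs))
    for s, e in kept:
        lo = max(0, s - back)
        idx = np.nonzero(precise[lo:e] >= params.precise_threshold)[0]
        if idx.size:
            onsets.append(times[lo + idx[0]])
    return np.asarray(onsets)


def trial_movement_onsets(
    session: SessionData,
    onset_times: np.ndarray,
    params: WheelOnsetParams | None = None,
) -> np.ndarray:
    """First detected onset per trial within [go - 0.2 s, outcome]; NaN when
    none is found (the trial is then excluded downstream)."""
    params = params or WheelOnsetParams()
    onset_times = np.sort(np.asarray(onset_times, dtype=float))
    out = np.full(len(session.trials), np.nan)
    for i, t in enumerate(session.trials):
        if not t.completed or not np.isfinite(t.t_outcome):
            continue
        lo, hi = t.t_go - params.pre_go_window, t.t_outcome
        j = np.searchsorted(onset_times, lo, side="left")
        if j < onset_times.size and onset_times[j] <= hi:
            out[i] = onset_times[j]
    return out


def assign_laterality(session: SessionData, hemisphere: str | None = None) -> list[str]:
    """Per-trial contra/ipsi labels relative to a recording hemisphere.

    Left hemisphere: contralateral = Right (counterclockwise) choices;
    right hemisphere mirrored.  Trials without a choice get "none".
    """
    hemi = hemisphere or session.hemisphere
    if hemi not in ("left", "right"):
        raise ValueError("hemisphere must be 'left' or 'right'")
    contra = RIGHT if hemi == "left" else LEFT
    out = []
    for t in session.trials:
        if t.choice == NO_CHOICE:
            out.append("none")
        else:
            out.append("contra" if t.choice == contra else "ipsi")
    return out


def apply_trial_exclusions(
    session: SessionData,
    movement_onsets: np.ndarray | None = None,
    n_edge: int = 10,
) -> tuple[SessionData, pd.DataFrame]:
    """Remove edge trials, no-choice trials, and trials missing a movement
    onset; return the filtered session and a per-trial exclusion log."""
    n = len(session.trials)
    if n == 0:
        raise ValueError("session is empty")
    reasons: dict[int, str] = {}
    if n <= 2 * n_edge:
        import warnings

        warnings.warn("session shorter than the edge exclusions; empty result")
    for i in range(min(n_edge, n)):
        reasons[i] = "first_10"
    for i in range(max(n - n_edge, 0), n):
        reasons.setdefault(i, "last_10")
    for i, t in enumerate(session.trials):
        if i in reasons:
            continue
        if not t.completed:
            reasons[i] = "no_choice"
        elif movement_onsets is not None and not np.isfinite(movement_onsets[i]):
            reasons[i] = "no_movement_onset"
    keep = [t for i, t in enumerate(session.trials) if i not in reasons]
    log = pd.DataFrame(
        [dict(trial=i, reason=r) for i, r in sorted(reasons.items())]
    )
    filtered = SessionData(
        trials=keep,
        hemisphere=session.hemisphere,
        block_starts=([0] if keep else [])
        + [
            j
            for j in range(1, len(keep))
            if keep[j].block_side != keep[j - 1].block_side
        ],
        seed=session.seed,
        config=session.config,
        session_id=session.session_id,
        cs_plus_cue_present=session.cs_plus_cue_present,
    )
    return filtered, log
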