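"""Per-trial event timelines on the 10 ms bin grid.

Each trial is laid out on a fixed grid aligned to go-cue onset (default
0.5 s before to 3.5 s after).  Event indicator vectors are 1 at the bin of
the event and 0 elsewhere; kernel windows per event define the coverage
mask used for z-scoring and for selecting fitted bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..task import CS_MINUS, CS_PLUS, LEFT, NO_CHOICE, RIGHT, SessionData

__all__ = ["TimelineConfig", "EventTimeline", "build_event_timeline", "KERNEL_WINDOWS", "EVENTS"]

EVENTS = ("go", "move_L", "move_R", "cs_plus", "stim", "cs_minus")

#: kernel windows in seconds relative to each event
KERNEL_WINDOWS: dict[str, tuple[float, float]] = {
    "go": (0.0, 1.0),
    "move_L": (-0.5, 0.5),
    "move_R": (-0.5, 0.5),
    "cs_plus": (0.0, 2.0),
    "stim": (0.0, 2.0),
    "cs_minus": (0.0, 2.0),
    # merged events used by reduced models (choice- or reward-unspecific)
    "move": (-0.5, 0.5),
    "cs": (0.0, 2.0),
}


@dataclass(frozen=True)
class TimelineConfig:
    bin_width: float = 0.01
    t_pre: float = 0.5  # seconds before go cue
    t_post: float = 3.5  # seconds after go cue


@dataclass
class EventTimeline:
    """Event indicators c_i(t, T) on the per-trial bin grid."""

    indicators: dict[str, np.ndarray]  # each (n_trials, n_bins) uint8
    coverage: np.ndarray  # (n_trials, n_bins) bool — bins covered by kernels
    included: np.ndarray  # (n_trials,) bool — trials with usable timestamps
    config: TimelineConfig
    n_trials: int
    n_bins: int
    event_bins: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def bin_width(self) -> float:
        return self.config.bin_width

    def n_events(self, event: str) -> int:
        return int(self.indicators[event].sum())


def _snap(t_rel: float, t_pre: float, bw: float) -> int:
    """Nearest bin edge; exact ties go to the earlier bin."""
    x = (t_rel + t_pre) / bw
    return int(np.ceil(x - 0.5))


def build_event_timeline(
    session: SessionData, config: TimelineConfig | None = None
) -> EventTimeline:
    """Lay a session's events out on the per-trial grid.

    Completed trials with missing timestamps are flagged excluded.  In the
    task variant without a CS+ tone, CS+ indicators stay empty (the
    stimulation event is still present on collected trials).
    """
    config = config or TimelineConfig()
    bw = config.bin_width
    n_bins = int(round((config.t_pre + config.t_post) / bw))
    n_trials = len(session.trials)
    ind = {e: np.zeros((n_trials, n_bins), dtype=np.uint8) for e in EVENTS}
    coverage = np.zeros((n_trials, n_bins), dtype=bool)
    included = np.ones(n_trials, dtype=bool)
    event_bins: dict[str, list[tuple[int, int]]] = {e: [] for e in EVENTS}

    def place(event: str, trial: int, t_rel: float) -> None:
        b = _snap(t_rel, config.t_pre, bw)
        if not (0 <= b < n_bins):
            return
        ind[event][trial, b] = 1
        event_bins[event].append((trial, b))
        w0, w1 = KERNEL_WINDOWS[event]
        lo = max(0, b + int(round(w0 / bw)))
        hi = min(n_bins, b + int(round(w1 / bw)))
        coverage[trial, lo:hi] = True

    for i, t in enumerate(session.trials):
        if t.choice == NO_CHOICE:
            included[i] = False
            continue
        if not (np.isfinite(t.t_go) and np.isfinite(t.t_move) and np.isfinite(t.t_outcome)):
            included[i] = False
            continue
        place("go", i, 0.0)
        move_event = "move_R" if t.choice == RIGHT else "move_L"
        place(move_event, i, t.t_move - t.t_go)
        if t.outcome == CS_PLUS:
            if session.cs_plus_cue_present:
                place("cs_plus", i, t.t_outcome - t.t_go)
            if t.stim_collected and np.isfinite(t.t_stim):
                place("stim", i, t.t_stim - t.t_go)
        else:
            place("cs_minus", i, t.t_outcome - t.t_go)

    return EventTimeline(
        indicators=ind,
        coverage=coverage,
        included=included,
        config=config,
        n_trials=n_trials,
        n_bins=n_bins,
        event_bins=event_bins,
    )
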