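"""Higher-level glue: trial conditioning, 100 ms re-binning, and the
end-to-end decoding pipeline used by the CLI."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import io as rio
from .behavior import params_from_dict
from .neural.decoding import DecoderSpec, PopulationDecoder
from .neural.timeline import EventTimeline, build_event_timeline
from .preprocess import assign_laterality
from .pseudosession import PseudosessionPool
from .task import CS_PLUS, SessionData, TaskConfig
from .values import simulate_on_policy

__all__ = ["DECODING_WINDOWS", "bin_for_decoding", "decoding_trial_mask", "decode_population"]

#: decoding windows (align event, start, end) per variable
DECODING_WINDOWS = {
    "v": ("outcome", -0.5, 2.0),
    "dq": ("go", -0.5, 0.5),
    "qcontra": ("go", -0.5, 0.5),
    "qipsi": ("go", -0.5, 0.5),
}

VARIABLE_COLUMNS = {"v": "v", "dq": "delta_q", "qcontra": "q_contra", "qipsi": "q_ipsi"}


def decoding_trial_mask(session: SessionData, timeline: EventTimeline, variable: str) -> np.ndarray:
    """Trial-conditioning rules: contralateral choices for relative value
    and the contra action value, ipsilateral for the ipsi action value,
    rewarded trials for state value."""
    lat = assign_laterality(session)
    completed = np.array([t.completed for t in session.trials])
    mask = completed & timeline.included
    if variable in ("dq", "qcontra"):
        mask &= np.array([side == "contra" for side in lat])
    elif variable == "qipsi":
        mask &= np.array([side == "ipsi" for side in lat])
    elif variable == "v":
        mask &= np.array([t.outcome == CS_PLUS for t in session.trials])
    else:
        raise ValueError(f"unknown variable {variable!r}")
    return mask


def bin_for_decoding(
    counts: np.ndarray,
    session: SessionData,
    timeline: EventTimeline,
    variable: str,
    bin_width: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Re-bin 10 ms counts into 100 ms bins in the variable's window.

    Returns (activity (n_neurons, n_kept_trials, n_bins), bin-center times
    relative to the align event, kept-trial mask).  Trials whose window
    falls off the grid are dropped.
    """
    align, w0, w1 = DECODING_WINDOWS[variable]
    bw = timeline.bin_width
    per = int(round(bin_width / bw))
    n_out = int(round((w1 - w0) / bin_width))
    mask = decoding_trial_mask(session, timeline, variable)
    t_pre = timeline.config.t_pre
    align_bins = np.full(timeline.n_trials, -1)
    for i, t in enumerate(session.trials):
        if not mask[i]:
            continue
        t_rel = 0.0 if align == "go" else t.t_outcome - t.t_go
        b = int(np.ceil((t_rel + t_pre) / bw - 0.5))
        start = b + int(round(w0 / bw))
        if start < 0 or start + n_out * per > timeline.n_bins:
            mask[i] = False
            continue
        align_bins[i] = start
    kept = np.nonzero(mask)[0]
    n_neurons = counts.shape[0]
    activity = np.zeros((n_neurons, kept.size, n_out))
    for j, tr in enumerate(kept):
        s = align_bins[tr]
        seg = counts[:, tr, s : s + n_out * per]
        activity[:, j, :] = seg.reshape(n_neurons, n_out, per).sum(axis=2)
    times = w0 + (np.arange(n_out) + 0.5) * bin_width
    return activity, times, mask


def decode_population(
    spikes_path,
    trials_path,
    values_path,
    variable: str,
    group_size: int = 20,
    n_repeats: int = 10,
    n_null: int = 10,
    seed: int = 0,
    spec: DecoderSpec | None = None,
) -> pd.DataFrame:
    """Load inputs, apply conditioning, and run the time-resolved decoder."""
    session = rio.read_trials_csv(trials_path)
    values = rio.read_values_csv(values_path)
    counts, _, meta = rio.read_spikes_h5(spikes_path)
    rio.validate_trial_counts(
        trials=len(session.trials), values=len(values), spikes=counts.shape[1]
    )
    timeline = build_event_timeline(session)
    activity, times, mask = bin_for_decoding(counts, session, timeline, variable)
    col = VARIABLE_COLUMNS[variable]
    targets = values[col].to_numpy()[mask]

    # pseudosession target pool from simulated behavior
    frames = []
    base = params_from_dict(
        "q_cs",
        dict(alpha_rew=0.3, alpha_stay=0.3, gamma_forget=0.2,
             beta_rew=4.0, beta_stay=1.0, bias=0.0),
    )
    for k in range(6):
        _, traj = simulate_on_policy(
            base, session.config or TaskConfig(), len(session.trials), seed=seed + 50 + k
        )
        frames.append(traj[[col]].to_numpy())
    pool = PseudosessionPool(np.concatenate(frames), columns=[col])

    dec = PopulationDecoder(activity, targets, times, spec=spec, variable=variable)
    result = dec.fit(group_size, seed=seed, pool=pool, n_repeats=n_repeats, n_null=n_null)
    table = result.table.copy()
    table.insert(0, "variable", variable)
    table.insert(1, "group_size", group_size)
    return table
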