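"""Spike binning, z-scoring, and encoding-model design matrices.

The design matrix has one row per (trial, bin) on the timeline grid.  Event
predictor columns are the basis functions convolved with the binary event
indicators, with the convolution confined within each trial and truncated at
the grid edges (the coverage mask records truncation).  Spike-history
predictors convolve the log-spaced history basis with the neuron's own
z-scored activity, lagged at least one bin so the current bin never predicts
itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .basis import BasisSet, make_basis
from .timeline import EVENTS, KERNEL_WINDOWS, EventTimeline

__all__ = [
    "BinnedSpikes",
    "zscore_binned_spikes",
    "default_bases",
    "build_design_matrix",
    "DesignMatrix",
    "history_columns",
]


@dataclass
class BinnedSpikes:
    """Raw and z-scored 10 ms binned activity for one neuron.

    Mean and sd are computed over kernel-covered bins only; uncovered bins
    are transformed with the same statistics.  ``usable`` is False for
    degenerate (zero-variance) neurons.
    """

    raw: np.ndarray  # (n_trials, n_bins)
    z: np.ndarray
    mu: float
    sigma: float
    usable: bool


def zscore_binned_spikes(counts: np.ndarray, coverage: np.ndarray) -> BinnedSpikes:
    counts = np.asarray(counts, dtype=float)
    covered = counts[coverage]
    if covered.size < 2:
        raise ValueError("need at least 2 covered bins")
    mu = float(covered.mean())
    sigma = float(covered.std(ddof=0))
    if sigma == 0.0:
        return BinnedSpikes(raw=counts, z=np.zeros_like(counts), mu=mu, sigma=0.0, usable=False)
    return BinnedSpikes(raw=counts, z=(counts - mu) / sigma, mu=mu, sigma=sigma, usable=True)


def default_bases(bin_width: float = 0.01) -> dict[str, BasisSet]:
    """One linear raised-cosine basis per event, sized to its kernel window."""
    out = {}
    for e in EVENTS:
        w0, w1 = KERNEL_WINDOWS[e]
        out[e] = make_basis("linear_cosine", w1 - w0, bin_width)
    return out


@dataclass
class DesignMatrix:
    """Sparse design matrix plus its column map.

    ``columns`` maps predictor-group name (event name or "history") to a
    slice of column indices.  ``trial_of_row`` gives the trial index of each
    row; rows are ordered trial-major.
    """

    X: sparse.csc_matrix
    columns: dict[str, slice]
    trial_of_row: np.ndarray
    n_trials: int
    n_bins: int
    bases: dict[str, BasisSet]

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def event_names(self) -> list[str]:
        return [k for k in self.columns if k != "history"]


def _event_columns(
    timeline: EventTimeline, event: str, basis: BasisSet
) -> sparse.csc_matrix:
    """Columns for one event: basis functions placed at each occurrence."""
    n_rows = timeline.n_trials * timeline.n_bins
    bw = timeline.bin_width
    w0 = int(round(KERNEL_WINDOWS[event][0] / bw))
    occ = timeline.event_bins.get(event, [])
    m = basis.n_bins
    if not occ:
        return sparse.csc_matrix((n_rows, basis.n_dof))
    trials = np.array([t for t, _ in occ])
    onsets = np.array([b for _, b in occ])
    local = np.arange(m)
    abs_bins = onsets[:, None] + w0 + local[None, :]  # (n_occ, m)
    valid = (abs_bins >= 0) & (abs_bins < timeline.n_bins)
    rows_global = trials[:, None] * timeline.n_bins + abs_bins
    rows_flat = rows_global[valid]
    local_flat = np.broadcast_to(local, abs_bins.shape)[valid]
    cols, rows, data = [], [], []
    for j in range(basis.n_dof):
        vals = basis.matrix[local_flat, j]
        nz = vals != 0
        rows.append(rows_flat[nz])
        data.append(vals[nz])
        cols.append(np.full(int(nz.sum()), j))
    mat = sparse.coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_rows, basis.n_dof),
    )
    return mat.tocsc()


def history_columns(
    z: np.ndarray, basis: BasisSet | None = None, bin_width: float = 0.01
) -> np.ndarray:
    """Spike-history predictors from z-scored activity, within-trial, causal.

    Column j at (trial, bin b) is sum_l basis[l, j] * z[trial, b - 1 - l];
    lags start at one bin.
    """
    if basis is None:
        basis = make_basis("log_cosine_history", 1.0, bin_width)
    n_trials, n_bins = z.shape
    n_lags = basis.n_bins
    out = np.zeros((n_trials * n_bins, basis.n_dof))
    # build lagged copies once; each column is a weighted sum of lags
    for j in range(basis.n_dof):
        kern = basis.matrix[:, j]
        nz = np.nonzero(kern)[0]
        col = np.zeros((n_trials, n_bins))
        for l in nz:
            lag = l + 1
            if lag < n_bins:
                col[:, lag:] += kern[l] * z[:, :-lag]
        out[:, j] = col.ravel()
    return out


def build_design_matrix(
    timeline: EventTimeline,
    bases: dict[str, BasisSet] | None = None,
    history_source: np.ndarray | None = None,
    events: dict[str, np.ndarray] | None = None,
    drop_empty: bool = False,
) -> DesignMatrix:
    """Assemble the encoding design matrix.

    ``events`` may remap/merge indicator matrices (e.g., a single
    choice-unspecific movement indicator for reduced models); by default the
    timeline's standard six events are used.  ``history_source`` is the
    neuron's z-scored activity (n_trials, n_bins); omit it to exclude
    history predictors.  All-zero event groups are kept (columns of zeros)
    unless ``drop_empty``.
    """
    bases = bases or default_bases(timeline.bin_width)
    blocks: list[sparse.csc_matrix | np.ndarray] = []
    columns: dict[str, slice] = {}
    start = 0

    if events is None:
        event_items = {e: None for e in EVENTS}
    else:
        event_items = events

    tl = timeline
    for name in event_items:
        basis = bases[name]
        if events is not None and events[name] is not None:
            # custom indicators: wrap into a shallow timeline view
            tl = _retimeline(timeline, name, events[name])
        block = _event_columns(tl, name, basis)
        tl = timeline
        if drop_empty and block.nnz == 0:
            continue
        blocks.append(block)
        columns[name] = slice(start, start + basis.n_dof)
        start += basis.n_dof

    if history_source is not None:
        h = history_columns(history_source, bin_width=timeline.bin_width)
        blocks.append(sparse.csc_matrix(h))
        columns["history"] = slice(start, start + h.shape[1])
        start += h.shape[1]

    X = sparse.hstack(blocks, format="csc")
    trial_of_row = np.repeat(np.arange(timeline.n_trials), timeline.n_bins)
    return DesignMatrix(
        X=X,
        columns=columns,
        trial_of_row=trial_of_row,
        n_trials=timeline.n_trials,
        n_bins=timeline.n_bins,
        bases=bases,
    )


def _retimeline(timeline: EventTimeline, name: str, indicator: np.ndarray) -> EventTimeline:
    """A view of ``timeline`` with one event's indicator replaced."""
    import copy

    tl = copy.copy(timeline)
    tl.indicators = dict(timeline.indicators)
    tl.indicators[name] = indicator
    tl.event_bins = dict(timeline.event_bins)
    trials, bins_ = np.nonzero(indicator)
    tl.event_bins[name] = list(zip(trials.tolist(), bins_.tolist()))
    return tl
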