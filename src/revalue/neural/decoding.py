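"""Time-resolved population decoding of trial-by-trial values.

A separate lasso decoder is trained for each 100 ms bin of neural activity
to predict a value variable (Q_contra, Q_ipsi, dQ, or V) across trials,
using 5-fold nested stratified cross-validation: trials are stratified into
Freedman-Diaconis bins of the target, outer folds estimate performance, and
inner folds select the penalty from a small log-spaced grid.  Reported R²
is corrected by subtracting the mean R² of decoders trained on
pseudosession surrogate targets, which absorbs nonsense correlations from
slow drift.  Trial-conditioning rules: relative-value decoding uses
contralateral-choice trials only, state-value decoding rewarded trials
only, and targets are always the pre-update values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso

from ..pseudosession import PseudosessionPool

__all__ = [
    "DecoderSpec",
    "stratify_folds",
    "nested_cv_decode",
    "PopulationDecoder",
    "DecoderResult",
    "correct_decoder_r2",
]


@dataclass(frozen=True)
class DecoderSpec:
    """Decoding protocol parameters."""

    bin_width: float = 0.1
    group_sizes: tuple[int, ...] = (10, 20, 30, 40)
    n_repeats: int = 100
    n_outer: int = 5
    n_inner: int = 5
    alphas: tuple[float, ...] = (1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1e0, 1e1)
    n_null: int = 20  # desk-scale default; the full protocol uses 200
    lasso_max_iter: int = 2000


def stratify_folds(
    values: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Stratified fold assignment by Freedman-Diaconis value bins.

    Bin width 2*IQR*n^(-1/3); bins with fewer trials than folds are merged
    with their nearest neighbor; within each bin, shuffled round-robin
    assignment keeps per-bin counts across folds within one of each other.
    A zero IQR (constant values) collapses to a single stratum.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < n_folds:
        raise ValueError("need at least n_folds trials")
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        strata = np.zeros(n, dtype=int)
    else:
        width = 2.0 * iqr * n ** (-1.0 / 3.0)
        edges = np.arange(values.min(), values.max() + width, width)
        if edges[-1] <= values.max():
            edges = np.append(edges, values.max() + width)
        strata = np.clip(np.searchsorted(edges, values, side="right") - 1, 0, None)
        strata = _merge_small_strata(strata, n_folds)
    fold = np.empty(n, dtype=int)
    offset = 0
    for s in np.unique(strata):
        idx = np.nonzero(strata == s)[0]
        rng.shuffle(idx)
        fold[idx] = (offset + np.arange(idx.size)) % n_folds
        offset = (offset + idx.size) % n_folds
    return fold


def _merge_small_strata(strata: np.ndarray, min_count: int) -> np.ndarray:
    strata = strata.copy()
    while True:
        labels, counts = np.unique(strata, return_counts=True)
        if len(labels) <= 1:
            return strata
        small = labels[counts < min_count]
        if small.size == 0:
            return strata
        s = small[0]
        others = labels[labels != s]
        nearest = others[np.argmin(np.abs(others - s))]
        strata[strata == s] = nearest


def nested_cv_decode(
    X: np.ndarray,
    y: np.ndarray,
    spec: DecoderSpec,
    rng: np.random.Generator,
) -> float:
    """Mean held-out R² from 5-fold nested stratified cross-validation.

    Negative values are reported as-is (they indicate the decoder does
    worse than the mean of the held-out targets).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("targets must be finite")
    alphas = np.sort(np.asarray(spec.alphas, dtype=float))[::-1]
    outer = stratify_folds(y, spec.n_outer, rng)
    scores = []
    for f in range(spec.n_outer):
        tr = outer != f
        Xtr, ytr = X[tr], y[tr]
        Xte, yte = X[~tr], y[~tr]
        inner = stratify_folds(ytr, spec.n_inner, rng)
        val_r2 = np.zeros((spec.n_inner, alphas.size))
        for g in range(spec.n_inner):
            itr = inner != g
            model = Lasso(warm_start=True, max_iter=spec.lasso_max_iter)
            for ai, a in enumerate(alphas):
                model.set_params(alpha=a)
                model.fit(Xtr[itr], ytr[itr])
                val_r2[g, ai] = _r2(ytr[~itr], model.predict(Xtr[~itr]))
        best_alpha = float(alphas[int(np.argmax(val_r2.mean(axis=0)))])
        model = Lasso(alpha=best_alpha, max_iter=spec.lasso_max_iter)
        model.fit(Xtr, ytr)
        scores.append(_r2(yte, model.predict(Xte)))
    return float(np.mean(scores))


def _r2(y: np.ndarray, pred: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        return 0.0
    return 1.0 - float(np.sum((y - pred) ** 2)) / sst


@dataclass
class DecoderResult:
    """Per-time-bin decoding performance for one neuron-group size."""

    table: pd.DataFrame  # columns: time, raw_r2, null_r2, corrected_r2
    group_size: int
    variable: str
    n_repeats: int
    n_null: int

    def plot(self, ax=None):
        """Corrected decoding R² across time bins."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.axhline(0.0, color="gray", lw=0.8)
        ax.plot(self.table["time"], self.table["raw_r2"], label="raw", alpha=0.5)
        ax.plot(self.table["time"], self.table["corrected_r2"], label="corrected")
        ax.set_xlabel("time from alignment event (s)")
        ax.set_ylabel("held-out $R^2$")
        ax.set_title(f"{self.variable}, {self.group_size} neurons")
        ax.legend(fontsize="small")
        return ax

    def summary(self) -> str:
        t = self.table
        peak = t.loc[t["corrected_r2"].idxmax()]
        return (
            f"Decoder [{self.variable}] group={self.group_size}: "
            f"peak corrected R2 {peak['corrected_r2']:.4f} at t={peak['time']:.2f}s "
            f"({self.n_repeats} repeats, {self.n_null} nulls)"
        )


class PopulationDecoder:
    """Time-resolved decoder over a binned population.

    ``activity`` has shape (n_neurons, n_trials, n_time_bins) — already
    binned at the decoding resolution and restricted to the trials passing
    the variable's conditioning rule.  ``targets`` are the per-trial
    pre-update values for those same trials.
    """

    def __init__(
        self,
        activity: np.ndarray,
        targets: np.ndarray,
        times: np.ndarray,
        spec: DecoderSpec | None = None,
        variable: str = "value",
    ):
        activity = np.asarray(activity, dtype=float)
        if activity.ndim != 3:
            raise ValueError("activity must be (n_neurons, n_trials, n_bins)")
        self.activity = activity
        self.targets = np.asarray(targets, dtype=float)
        self.times = np.asarray(times, dtype=float)
        self.spec = spec or DecoderSpec()
        self.variable = variable
        if self.targets.size != activity.shape[1]:
            raise ValueError("one target per trial required")

    def fit(
        self,
        group_size: int,
        seed: int = 0,
        pool: PseudosessionPool | None = None,
        n_repeats: int | None = None,
        n_null: int | None = None,
    ) -> DecoderResult:
        spec = self.spec
        n_neurons, n_trials, n_bins = self.activity.shape
        if group_size > n_neurons:
            raise ValueError(
                f"group size {group_size} exceeds available neurons {n_neurons}"
            )
        n_repeats = n_repeats if n_repeats is not None else spec.n_repeats
        n_null = n_null if n_null is not None else spec.n_null
        rng = np.random.default_rng(seed)

        null_targets = []
        if pool is not None and n_null > 0:
            pool.require(n_trials, n_null)
            null_targets = [pool.draw(n_trials, rng).ravel() for _ in range(n_null)]

        raw = np.zeros((n_bins, n_repeats))
        null = np.zeros((n_bins, max(n_null, 1)))
        null_counts = 0
        for r in range(n_repeats):
            group = rng.choice(n_neurons, size=group_size, replace=False)
            for b in range(n_bins):
                raw[b, r] = nested_cv_decode(
                    self.activity[group, :, b].T, self.targets, spec, rng
                )
        if null_targets:
            # nulls use the same protocol with a fixed random group per null
            for i, yt in enumerate(null_targets):
                group = rng.choice(n_neurons, size=group_size, replace=False)
                for b in range(n_bins):
                    null[b, i] += nested_cv_decode(
                        self.activity[group, :, b].T, yt, spec, rng
                    )
            null_counts = len(null_targets)
        raw_mean = raw.mean(axis=1)
        null_mean = null[:, :null_counts].mean(axis=1) if null_counts else np.zeros(n_bins)
        table = pd.DataFrame(
            dict(
                time=self.times,
                raw_r2=raw_mean,
                null_r2=null_mean,
                corrected_r2=raw_mean - null_mean,
            )
        )
        return DecoderResult(
            table=table,
            group_size=group_size,
            variable=self.variable,
            n_repeats=n_repeats,
            n_null=null_counts,
        )


def correct_decoder_r2(
    raw_r2: np.ndarray, null_r2: np.ndarray
) -> np.ndarray:
    """Corrected R² series: raw minus the null-ensemble mean per time bin."""
    raw_r2 = np.asarray(raw_r2, dtype=float)
    null_r2 = np.atleast_2d(np.asarray(null_r2, dtype=float))
    return raw_r2 - null_r2.mean(axis=0)
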