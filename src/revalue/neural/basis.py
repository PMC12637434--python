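"""Raised-cosine basis sets for temporal kernels and spike history.

Event kernels use linearly spaced raised cosines, one per 25 ms of kernel
span, tiling the span as a partition of unity (the pointwise sum is constant
away from the edges).  The spike-history kernel uses 10 raised cosines with
log-spaced centers from 10 ms to 1 s in the past, strictly causal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BasisSet", "make_basis"]

DEFAULT_BIN_WIDTH = 0.01
COSINE_SPACING = 0.025  # one basis function per 25 ms of span


@dataclass(frozen=True)
class BasisSet:
    """A matrix of basis functions sampled on the 10 ms bin grid.

    ``matrix`` has shape (n_window_bins, n_dof).  For ``linear_cosine`` the
    window covers the kernel span starting at lag 0 relative to the kernel
    window start; for ``log_cosine_history`` the window covers lags 1..n
    bins strictly in the past.
    """

    matrix: np.ndarray
    kind: str
    span: float
    bin_width: float

    @property
    def n_dof(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]


def _raised_cosine(x: np.ndarray, center: float, half_support: float) -> np.ndarray:
    out = np.zeros_like(x)
    m = np.abs(x - center) <= half_support
    out[m] = 0.5 * (1.0 + np.cos(np.pi * (x[m] - center) / half_support))
    return out


def make_basis(
    kind: str, span: float, bin_width: float = DEFAULT_BIN_WIDTH
) -> BasisSet:
    """Construct a basis set.

    ``linear_cosine``: ceil(span / 25 ms) cosines with centers evenly tiling
    [0, span].  ``log_cosine_history``: 10 cosines, centers log-spaced over
    [10 ms, 1 s]; ``span`` sets the history length (default callers pass 1.0).
    """
    if span <= 0:
        raise ValueError("span must be positive")
    if kind == "linear_cosine":
        n_dof = int(np.ceil(round(span / COSINE_SPACING, 9)))
        n_bins = int(round(span / bin_width))
        t = (np.arange(n_bins) + 0.5) * bin_width
        centers = np.linspace(0.0, span, n_dof)
        spacing = span / (n_dof - 1) if n_dof > 1 else span
        mat = np.column_stack(
            [_raised_cosine(t, c, 2.0 * spacing) for c in centers]
        )
        return BasisSet(matrix=mat, kind=kind, span=span, bin_width=bin_width)
    if kind == "log_cosine_history":
        n_dof = 10
        t_min, t_max = 0.01, span
        n_bins = int(round(t_max / bin_width))
        # lags 1..n_bins (strictly causal, in units of seconds)
        t = np.arange(1, n_bins + 1) * bin_width
        x = np.log(t)
        centers = np.linspace(np.log(t_min), np.log(t_max), n_dof)
        spacing = (centers[-1] - centers[0]) / (n_dof - 1)
        mat = np.column_stack(
            [_raised_cosine(x, c, 2.0 * spacing) for c in centers]
        )
        return BasisSet(matrix=mat, kind=kind, span=span, bin_width=bin_width)
    raise ValueError(f"unknown basis kind {kind!r}")
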