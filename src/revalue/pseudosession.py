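"""Pseudosession null distributions for value variables.

A pseudosession is a surrogate trial-by-trial value series drawn as a
contiguous chunk from a pool built by concatenating the value series of
many (other) sessions.  Chunks preserve the autocorrelation of real value
trajectories while breaking their alignment with the neural data, which is
what makes them an appropriate null for slow-drift confounds.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["PseudosessionPool"]


class PseudosessionPool:
    """A pool of concatenated trial-by-trial value series.

    ``series`` has shape (n_pool_trials, n_vars).
    """

    def __init__(self, series: np.ndarray, columns: Sequence[str] | None = None):
        series = np.atleast_2d(np.asarray(series, dtype=float))
        if series.shape[0] == 1 and series.shape[1] > 1 and columns is None:
            series = series.T
        self.series = series
        self.columns = list(columns) if columns is not None else None

    def __len__(self) -> int:
        return self.series.shape[0]

    @property
    def n_vars(self) -> int:
        return self.series.shape[1]

    def require(self, n: int, n_null: int = 1) -> None:
        needed = n + n_null - 1
        if len(self) < needed:
            raise ValueError(
                f"pseudosession pool has {len(self)} trials; need at least "
                f"{needed} for chunks of {n} trials and {n_null} nulls"
            )

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """One contiguous chunk of ``n`` trials."""
        if len(self) < n:
            raise ValueError(
                f"pseudosession pool has {len(self)} trials; need at least {n}"
            )
        start = int(rng.integers(0, len(self) - n + 1))
        return self.series[start : start + n].copy()

    def draw_starts(self, n: int, n_null: int, rng: np.random.Generator) -> np.ndarray:
        """Chunk start positions, for nulls that must share trial order
        across analyses (e.g., the learning-rate sweep)."""
        self.require(n, n_null)
        return rng.integers(0, len(self) - n + 1, size=n_null)

    def chunk(self, start: int, n: int) -> np.ndarray:
        return self.series[start : start + n].copy()

    @classmethod
    def from_frames(
        cls, frames: Sequence[pd.DataFrame], columns: Sequence[str]
    ) -> "PseudosessionPool":
        """Concatenate value-trajectory tables (one per session)."""
        arrs = [f.loc[:, list(columns)].to_numpy(dtype=float) for f in frames]
        return cls(np.concatenate(arrs, axis=0), columns=columns)
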