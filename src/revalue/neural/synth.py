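"""Synthetic spike trains and wheel traces from the generative encoding model.

Neurons are generated from the same bilinear form the encoding model fits:
a baseline plus event kernels scaled by trial-by-trial gains that are
affine in the value variables.  Kernel shapes are unit-norm raised-cosine
mixtures, so ground truth lies exactly in the fitted model's span, and the
signal is assembled through the identical kernel-placement code path used
to build the encoding design matrix — in the noiseless Gaussian limit the
fit can recover the generative kernels and gains exactly (up to the
norm/gain scale split).

Two noise modes: ``gaussian`` adds iid noise to the latent signal (matching
the Gaussian-error model actually fitted to z-scored counts; used for exact
recovery tests) and ``poisson_log_link`` emits counts with a log-link
intensity (a realism extension).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ..task import SessionData
from .basis import make_basis
from .design import build_design_matrix
from .timeline import EVENTS, EventTimeline, KERNEL_WINDOWS

__all__ = [
    "GroundTruthNeuron",
    "random_kernel",
    "generate_neuron_signal",
    "generate_neuron_spikes",
    "generate_population",
    "synthesize_wheel_trace",
]


@dataclass
class GroundTruthNeuron:
    """Generative parameters of one synthetic neuron.

    ``kernels`` maps event name to a unit-norm kernel on that event's
    window grid; ``gain_offsets``/``gain_coefs`` parameterize the per-trial
    gain G_i(T) = offset_i + sum_k coef_ik * U_k(T).
    """

    kernels: dict[str, np.ndarray]
    gain_offsets: dict[str, float]
    gain_coefs: dict[str, np.ndarray]
    baseline: float = 0.0
    noise_sd: float = 1.0
    noise_mode: str = "gaussian"
    poisson_a: float = 0.5  # log-intensity intercept (per second)
    poisson_b: float = 1.0  # log-intensity slope on the latent signal
    region: str = "CP"
    hemisphere: str = "left"
    value_coding: bool = False

    def __post_init__(self) -> None:
        if self.noise_mode not in ("gaussian", "poisson_log_link"):
            raise ValueError("noise_mode must be gaussian or poisson_log_link")


def random_kernel(event: str, rng: np.random.Generator, bin_width: float = 0.01) -> np.ndarray:
    """A unit-norm random mixture of the event's raised-cosine basis."""
    w0, w1 = KERNEL_WINDOWS[event]
    basis = make_basis("linear_cosine", w1 - w0, bin_width)
    w = rng.normal(size=basis.n_dof)
    k = basis.matrix @ w
    nrm = np.linalg.norm(k)
    return k / nrm if nrm > 0 else k


def generate_neuron_signal(
    neuron: GroundTruthNeuron,
    timeline: EventTimeline,
    values: np.ndarray | None,
) -> np.ndarray:
    """Latent signal(t, T) = baseline + sum_i G_i(T) * (K_i * c_i)(t, T).

    Assembled through the encoding design-matrix code path: each kernel is
    a one-column basis, so generation and fitting share the convolution
    convention exactly.
    """
    from .basis import BasisSet

    n_trials, n_bins = timeline.n_trials, timeline.n_bins
    signal = np.full((n_trials, n_bins), neuron.baseline, dtype=float)
    U = None
    if values is not None:
        U = np.atleast_2d(np.asarray(values, dtype=float))
        if U.shape[0] != n_trials:
            U = U.T
    for event, kernel in neuron.kernels.items():
        basis = BasisSet(
            matrix=np.asarray(kernel, dtype=float)[:, None],
            kind="linear_cosine",
            span=kernel.size * timeline.bin_width,
            bin_width=timeline.bin_width,
        )
        dm = build_design_matrix(
            timeline, bases={event: basis}, events={event: None}
        )
        col = np.asarray(dm.X.todense()).ravel().reshape(n_trials, n_bins)
        g = np.full(n_trials, neuron.gain_offsets.get(event, 1.0))
        coefs = neuron.gain_coefs.get(event)
        if coefs is not None and U is not None and np.any(coefs):
            g = g + U @ np.asarray(coefs, dtype=float)
        signal += g[:, None] * col
    return signal


def generate_neuron_spikes(
    neuron: GroundTruthNeuron,
    timeline: EventTimeline,
    values: np.ndarray | None,
    seed: int,
) -> np.ndarray:
    """Binned activity for one neuron; deterministic given seed.

    Gaussian mode returns signal + iid noise (continuous "activity" on the
    z-score scale); Poisson mode returns integer counts with intensity
    exp(a + b * signal) * bin_width.
    """
    rng = np.random.default_rng(seed)
    signal = generate_neuron_signal(neuron, timeline, values)
    if neuron.noise_mode == "gaussian":
        return signal + neuron.noise_sd * rng.standard_normal(signal.shape)
    rate = np.exp(neuron.poisson_a + neuron.poisson_b * signal) * timeline.bin_width
    if not np.all(np.isfinite(rate)):
        raise ValueError("non-finite Poisson intensity; rescale poisson_a/b")
    return rng.poisson(rate).astype(float)


def generate_population(
    n_neurons: int,
    mixture: tuple[float, float, float],
    timeline: EventTimeline,
    values: np.ndarray | None,
    seed: int,
    noise_sd: float = 1.0,
    gain_scale: float = 0.5,
    noise_mode: str = "gaussian",
    region: str = "CP",
    hemisphere: str = "left",
    events: Sequence[str] = ("go", "move_L", "move_R", "cs_plus", "stim", "cs_minus"),
) -> tuple[np.ndarray, pd.DataFrame, list[GroundTruthNeuron]]:
    """A labeled synthetic population.

    ``mixture`` = (value-coding, event-only, silent) fractions, summing
    to 1.  Value-coding neurons get a nonzero gain coefficient (magnitude
    ``gain_scale``, random sign and variable) on every event kernel they
    express; event-only neurons have kernels with constant unit gains;
    silent neurons are pure noise.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    if not np.isclose(sum(mixture), 1.0):
        raise ValueError("mixture fractions must sum to 1")
    n_value = int(round(mixture[0] * n_neurons))
    n_event = int(round(mixture[1] * n_neurons))
    n_silent = n_neurons - n_value - n_event
    rng = np.random.default_rng(seed)
    n_vars = 0 if values is None else np.atleast_2d(values).shape[-1]

    counts = np.zeros((n_neurons, timeline.n_trials, timeline.n_bins))
    meta_rows = []
    neurons = []
    kinds = ["value"] * n_value + ["event"] * n_event + ["silent"] * n_silent
    for i, kind in enumerate(kinds):
        if kind == "silent":
            kernels, offsets, coefs = {}, {}, {}
        else:
            kernels = {e: random_kernel(e, rng, timeline.bin_width) for e in events}
            offsets = {e: 1.0 for e in events}
            coefs = {e: np.zeros(n_vars) for e in events}
            if kind == "value" and n_vars > 0:
                for e in events:
                    k = int(rng.integers(n_vars))
                    coefs[e][k] = gain_scale * (1 if rng.random() < 0.5 else -1)
        neuron = GroundTruthNeuron(
            kernels=kernels,
            gain_offsets=offsets,
            gain_coefs=coefs,
            noise_sd=noise_sd,
            noise_mode=noise_mode,
            region=region,
            hemisphere=hemisphere,
            value_coding=(kind == "value"),
        )
        neurons.append(neuron)
        counts[i] = generate_neuron_spikes(
            neuron, timeline, values, seed=int(rng.integers(2**31))
        )
        meta_rows.append(
            dict(
                neuron=i,
                kind=kind,
                value_coding=(kind == "value"),
                region=region,
                hemisphere=hemisphere,
            )
        )
    return counts, pd.DataFrame(meta_rows), neurons


@dataclass(frozen=True)
class WheelKinematics:
    """Synthetic wheel-trace parameters (positions in cm, 1 kHz)."""

    sample_rate: float = 1000.0
    amplitude: float = 0.6  # cm of displacement per choice movement
    ramp_duration: float = 0.35  # s
    #: position noise in cm; the default is zero because a rotary encoder
    #: reports quantized positions, not white noise (white noise at 1 kHz
    #: would alias into cm/s-scale speed noise)
    noise_sd: float = 0.0


def synthesize_wheel_trace(
    session: SessionData,
    kinematics: WheelKinematics | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A 1 kHz wheel-position trace with known movement onsets.

    Each completed trial embeds a smooth ramp (minimum-jerk profile)
    starting at the trial's movement time; Left choices move positive,
    Right negative.  Returns (times, positions, ground-truth onset times).
    """
    kin = kinematics or WheelKinematics()
    last = session.trials[-1]
    t_end = (last.t_outcome if np.isfinite(last.t_outcome) else last.t_go) + 2.0
    n = int(t_end * kin.sample_rate) + 1
    t = np.arange(n) / kin.sample_rate
    rng = np.random.default_rng(seed)
    pos = np.zeros(n)
    onsets = []
    for tr in session.trials:
        if not tr.completed or not np.isfinite(tr.t_move):
            continue
        sign = 1.0 if tr.choice == "L" else -1.0
        t0 = tr.t_move
        onsets.append(t0)
        x = np.clip((t - t0) / kin.ramp_duration, 0.0, 1.0)
        # half-cosine ramp: speed rises quickly from onset, so the precise
        # 0.2 cm/s crossing lands within a few ms of t0
        ramp = 0.5 * (1.0 - np.cos(np.pi * x))
        pos += sign * kin.amplitude * ramp
    pos += kin.noise_sd * rng.standard_normal(n)
    return t, pos, np.asarray(onsets)
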