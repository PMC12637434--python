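"""End-to-end synthetic studies exercising the pipeline.

Each function runs one self-contained simulation study at desk scale:
generate behavior from the task simulator, derive value trajectories,
synthesize neural data where needed, run the analysis under test, and
return its measured quantities.  The same functions back the acceptance
test-suite and the ``scripts/acceptance.py`` entry point, so the numbers
reported there are always recomputed from scratch.

Study conditions (defaults):

* task parameters are the task's own defaults (70%/10% reward, 20-40 trial
  blocks, 7-of-10 debiasing);
* the canonical Q-learning generator uses moderate learning
  (alpha_rew = 0.3) with a decisive value weight (beta_rew = 4), giving
  clean value signals for neural recovery studies;
* the behavior-matched generator reproduces the animals' predictability
  (~ -0.48 log-likelihood per choice, ~77% accuracy) and is used where the
  study's outcome depends on how deterministic behavior is (model
  confusion);
* synthetic neurons are Gaussian-mode with unit-norm kernels; noise and
  gain scales are chosen so corrected dR2 falls in the 0-0.05 range
  typical of striatal units.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .behavior import (
    confusion_analysis,
    fit_session_map,
    params_from_dict,
    recovery_analysis,
    recovery_correlations,
)
from .neural.decoding import DecoderSpec
from .neural.design import zscore_binned_spikes
from .neural.encoding import (
    BilinearEncodingModel,
    EncodingConfig,
    encoding_trial_folds,
    sweep_value_timescale,
    value_significance,
)
from .neural.synth import generate_population
from .neural.timeline import TimelineConfig, build_event_timeline
from .preprocess import apply_trial_exclusions
from .pseudosession import PseudosessionPool
from .task import TaskConfig, simulate_session
from .values import detrend_trial_variable, extract_decision_variables, simulate_on_policy

__all__ = [
    "CANONICAL_Q",
    "MATCHED_Q",
    "task_conformance_study",
    "null_calibration_study",
    "behavior_recovery_study",
    "confusion_study",
    "encoding_recovery_study",
    "timescale_sweep_study",
    "decoder_calibration_study",
]

#: canonical Q-learning generator for neural studies
CANONICAL_Q = dict(
    alpha_rew=0.3, alpha_stay=0.3, gamma_forget=0.2,
    beta_rew=4.0, beta_stay=1.0, bias=0.0,
)

#: generator matched to the animals' choice predictability
MATCHED_Q = dict(
    alpha_rew=0.35, alpha_stay=0.25, gamma_forget=0.2,
    beta_rew=2.3, beta_stay=0.7, bias=0.0,
)


def desk_encoding_config() -> EncodingConfig:
    """Encoding-fit settings for desk-scale fixtures: same penalty ranges,
    coarser grids (13 lasso / 51 ridge values) and a capped coordinate-
    descent budget."""
    return EncodingConfig(
        alphas_l1=np.logspace(-5, 5, 13),
        alphas_l2=np.logspace(-5, 5, 51),
        lasso_max_iter=150,
    )


def analyzed_trajectories(session, params) -> tuple:
    """Trial exclusions plus value extraction done in the right order.

    The model runs off-policy over the *full* session (so values carry the
    whole learning history), and the trajectory rows are then restricted to
    the analyzed (non-excluded) trials.  Extracting from an already
    filtered session instead would re-initialize values at zero and give
    every analyzed series a spurious early-learning transient that
    mid-stream pseudosession chunks do not have — which measurably breaks
    the exchangeability of the null.
    """
    sessf, _ = apply_trial_exclusions(session)
    traj_full = extract_decision_variables(session, params)
    kept = [t.trial_index for t in sessf.trials]
    traj = traj_full.iloc[kept].reset_index(drop=True)
    return sessf, traj


def _encoding_session(n_trials: int, seed: int, params: dict = CANONICAL_Q):
    """Simulated session, trial exclusions, trajectories, timeline, folds."""
    p = params_from_dict("q_cs", params)
    sess, _ = simulate_on_policy(p, TaskConfig(), n_trials, seed=seed)
    sessf, traj = analyzed_trajectories(sess, p)
    tl = build_event_timeline(sessf, TimelineConfig(t_post=3.2))
    folds = encoding_trial_folds(sessf, 5, np.random.default_rng(seed + 1))
    return p, sess, sessf, traj, tl, folds


def _value_pool(columns: Sequence[str], n_trials: int, seed: int,
                params: dict = CANONICAL_Q, n_sessions: int = 60) -> PseudosessionPool:
    """Pool of analyzed value series from simulated sessions.

    Pool sessions get the same treatment as the analyzed session
    (full-history extraction, then edge-trial exclusion), so chunks are
    distributed like the real series — a requirement for the null to be
    exchangeable with it.  The pool must also be large relative to
    (chunk length x number of nulls): with a small pool the surrogate
    chunks overlap heavily, the effective null ensemble shrinks, and the
    tail of the null F distribution is under-sampled, which inflates the
    false-positive rate at strict thresholds.
    """
    p = params_from_dict("q_cs", params)
    frames = []
    for k in range(n_sessions):
        sess, _ = simulate_on_policy(p, TaskConfig(), n_trials, seed=seed + k)
        _, traj = analyzed_trajectories(sess, p)
        frames.append(traj.loc[:, list(columns)].to_numpy())
    return PseudosessionPool(np.concatenate(frames), columns=columns)


# ---------------------------------------------------------------------------


def task_conformance_study(n_trials: int = 20_000, seed: int = 0) -> dict:
    """Empirical reward rates on the high/low-probability sides.

    A random agent visits both sides; each completed choice toward the
    block's designated side is a Bernoulli draw at p_high and each choice
    away from it at p_low, so the conditional rates measure the
    generator's outcome rule directly.  Also reports default block-length
    bounds.
    """
    cfg = TaskConfig()
    sess = simulate_session(cfg, lambda h: 0.5, n_trials, seed=seed)
    high = [t for t in sess.trials if t.completed and t.choice == t.block_side]
    low = [t for t in sess.trials if t.completed and t.choice != t.block_side]
    from .task import draw_block_length

    rng = np.random.default_rng(seed + 1)
    draws = np.array([draw_block_length(cfg, rng) for _ in range(10_000)])
    return dict(
        high_rate=float(np.mean([t.R for t in high])),
        low_rate=float(np.mean([t.R for t in low])),
        n_high=len(high),
        n_low=len(low),
        block_draw_min=int(draws.min()),
        block_draw_max=int(draws.max()),
        n_blocks=len(sess.block_starts),
    )


def null_calibration_study(
    n_neurons: int = 40,
    n_null: int = 100,
    n_trials: int = 80,
    seed: int = 0,
    noise_sd: float = 1.0,
    n_sessions: int = 3,
    config: EncodingConfig | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """False-positive calibration of the pseudosession value-gain F-test.

    Value-blind but task-modulated neurons (event kernels, constant gains)
    are generated across ``n_sessions`` independent sessions; per session,
    the bilinear encoding model is fitted per neuron and tested for
    relative/state-value gains against pseudosession nulls shared within
    that session.  Spreading neurons over several sessions decorrelates
    the flags (all neurons of one session share its value series and null
    draws), so the study-level rate concentrates near the per-neuron
    rate.  Returns per-neuron p, corrected dR2, and the significance flag
    at P <= 0.01.
    """
    config = config or desk_encoding_config()
    # the significance comparison depends only on the iteration-1 kernels,
    # so the calibration study caps the bilinear loop at one iteration
    config = EncodingConfig(
        alphas_l1=config.alphas_l1, alphas_l2=config.alphas_l2,
        lasso_max_iter=config.lasso_max_iter, bilinear_max_iter=1,
    )
    per = [n_neurons // n_sessions] * n_sessions
    for i in range(n_neurons - sum(per)):
        per[i] += 1
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s, n_sub in enumerate(per):
            sub_seed = seed + 10_000 * s
            _, sess_full, sessf, traj, tl, folds = _encoding_session(
                n_trials, sub_seed
            )
            U = np.column_stack(
                [
                    detrend_trial_variable(traj["delta_q"].to_numpy()),
                    detrend_trial_variable(traj["v"].to_numpy()),
                ]
            )
            pool = _value_pool(["delta_q", "v"], n_trials, sub_seed + 900)
            rng = np.random.default_rng(sub_seed + 5)
            pool.require(tl.n_trials, n_null)
            shared = [pool.draw(tl.n_trials, rng) for _ in range(n_null)]
            counts, meta, _ = generate_population(
                n_sub, (0.0, 1.0, 0.0), tl, U, seed=sub_seed + 11,
                noise_sd=noise_sd,
            )
            for i in range(n_sub):
                sp = zscore_binned_spikes(counts[i], tl.coverage)
                fit = BilinearEncodingModel(
                    sp, tl, U, folds, var_names=["delta_q", "v"], config=config
                ).fit()
                st = value_significance(
                    fit, pool, null_chunks=shared, seed=sub_seed + i
                )
                rows.append(
                    dict(session=s, neuron=i, p=st.p, f=st.f,
                         delta_r2=st.delta_r2,
                         corrected_delta_r2=st.corrected_delta_r2,
                         significant=bool(st.significant))
                )
                if progress:
                    print(f"session {s} neuron {i}: p={st.p:.3f}", flush=True)
    return pd.DataFrame(rows)


def behavior_recovery_study(
    n_sessions: int = 40, n_trials: int = 500, seed: int = 0, restarts: int = 6
) -> tuple[pd.DataFrame, pd.Series]:
    """Parameter recovery for the extended Q-learning model at dispersed
    parameters; returns the paired table and per-parameter Pearson r."""
    rng = np.random.default_rng(seed)
    true = [
        dict(
            alpha_rew=rng.uniform(0.1, 0.9),
            alpha_stay=rng.uniform(0.1, 0.9),
            gamma_forget=rng.uniform(0.05, 0.8),
            beta_rew=rng.uniform(1.0, 6.0),
            beta_stay=rng.uniform(0.2, 2.5),
            bias=rng.normal(0.0, 0.5),
        )
        for _ in range(n_sessions)
    ]
    table = recovery_analysis(
        "q_cs", true, TaskConfig(), n_trials=n_trials, seed=seed, restarts=restarts
    )
    return table, recovery_correlations(table)


def confusion_study(
    n_sessions: int = 10, n_trials: int = 500, seed: int = 0, restarts: int = 2
) -> pd.DataFrame:
    """Model confusion with generators fitted to a common reference session
    whose predictability matches the animals'."""
    cfg = TaskConfig()
    ref, _ = simulate_on_policy(
        params_from_dict("q_cs", MATCHED_Q), cfg, 600, seed=seed + 77
    )
    gen = {
        m: fit_session_map(ref, m, restarts=6, seed=seed).params
        for m in ("q_cs", "reinforce", "actor_critic")
    }
    return confusion_analysis(
        gen, cfg, n_sessions=n_sessions, n_trials=n_trials, seed=seed,
        restarts=restarts, n_folds=5,
    )


def encoding_recovery_study(
    n_neurons: int = 12,
    n_null: int = 30,
    n_trials: int = 120,
    seed: int = 0,
    noise_sd: float = 0.5,
    gain_scale: float = 0.5,
    config: EncodingConfig | None = None,
) -> pd.DataFrame:
    """Gain recovery on value-coding Gaussian neurons.

    Each neuron carries one nonzero gain coefficient (random event,
    variable, and sign).  Returns per-neuron p, corrected dR2, and whether
    the fitted gain on the planted event/variable has the planted sign
    (after resolving the kernel-sign ambiguity of the unit-norm
    convention).
    """
    if config is None:
        base = desk_encoding_config()
        # a short bilinear loop is enough for stable gain signs; the
        # significance machinery runs on iteration-1 kernels regardless
        config = EncodingConfig(
            alphas_l1=base.alphas_l1, alphas_l2=base.alphas_l2,
            lasso_max_iter=base.lasso_max_iter, bilinear_max_iter=5,
        )
    _, sess_full, sessf, traj, tl, folds = _encoding_session(n_trials, seed)
    U = np.column_stack(
        [
            detrend_trial_variable(traj["delta_q"].to_numpy()),
            detrend_trial_variable(traj["v"].to_numpy()),
        ]
    )
    pool = _value_pool(["delta_q", "v"], n_trials, seed + 900)
    rng = np.random.default_rng(seed + 5)
    shared = [pool.draw(tl.n_trials, rng) for _ in range(n_null)]
    counts, meta, neurons = generate_population(
        n_neurons, (1.0, 0.0, 0.0), tl, U, seed=seed + 21,
        noise_sd=noise_sd, gain_scale=gain_scale,
    )
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_neurons):
            sp = zscore_binned_spikes(counts[i], tl.coverage)
            fit = BilinearEncodingModel(
                sp, tl, U, folds, var_names=["delta_q", "v"], config=config
            ).fit()
            st = value_significance(fit, pool, null_chunks=shared, seed=seed + i)
            n = neurons[i]
            ev, k = next(
                (e, int(np.nonzero(c)[0][0]))
                for e, c in n.gain_coefs.items()
                if np.any(c)
            )
            ksign = float(np.sign(np.dot(fit.kernels[ev], n.kernels[ev])))
            fitted = ksign * fit.gain_coefs[ev][k]
            rows.append(
                dict(
                    neuron=i, p=st.p,
                    corrected_delta_r2=st.corrected_delta_r2,
                    significant=bool(st.significant),
                    planted_event=ev, planted_var=k,
                    planted_gain=n.gain_coefs[ev][k], fitted_gain=fitted,
                    sign_ok=bool(np.sign(fitted) == np.sign(n.gain_coefs[ev][k])),
                )
            )
    return pd.DataFrame(rows)


def timescale_sweep_study(
    n_replicates: int = 30,
    n_trials: int = 130,
    seed: int = 0,
    generative_alpha: float = 0.3,
    parameters: Sequence[str] = ("alpha_rew", "gamma_forget"),
    n_null: int = 2,
    gain_scale: float = 2.0,
    noise_sd: float = 0.4,
    config: EncodingConfig | None = None,
    secondary_replicates: int | None = None,
) -> dict[str, np.ndarray]:
    """Learning/forgetting-rate sweeps on neurons whose gains are tied to
    reward-only action values generated at ``generative_alpha``.

    For each replicate a fresh session and neuron are generated; the 40-
    point corrected-dR2 curve is computed for each swept parameter and
    averaged across replicates.  ``secondary_replicates`` limits how many
    replicates also sweep the parameters beyond the first (they reuse the
    same sessions and neurons, so the comparison is matched).  Returns the
    grid, the mean curve per parameter, and the per-replicate curves.
    """
    if config is None:
        config = EncodingConfig(
            alphas_l1=np.logspace(-5, 5, 13),
            alphas_l2=np.logspace(-5, 5, 21),
            lasso_max_iter=150,
        )
    config = EncodingConfig(
        alphas_l1=config.alphas_l1, alphas_l2=config.alphas_l2,
        lasso_max_iter=config.lasso_max_iter, bilinear_max_iter=1,
    )
    grid = np.linspace(0.025, 1.0, 40)
    gen_params = dict(CANONICAL_Q, alpha_rew=generative_alpha)
    curves: dict[str, list] = {par: [] for par in parameters}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_replicates):
            p, sess_full, sessf, traj, tl, folds = _encoding_session(
                n_trials, seed + 300 + rep, params=gen_params
            )
            Ugen = np.column_stack(
                [
                    detrend_trial_variable(traj["q_rew_contra"].to_numpy()),
                    detrend_trial_variable(traj["q_rew_ipsi"].to_numpy()),
                ]
            )
            counts, _, _ = generate_population(
                1, (1.0, 0.0, 0.0), tl, Ugen, seed=seed + 700 + rep,
                noise_sd=noise_sd, gain_scale=gain_scale,
            )
            sp = zscore_binned_spikes(counts[0], tl.coverage)
            fit = BilinearEncodingModel(
                sp, tl, Ugen, folds, var_names=["q_rew_contra", "q_rew_ipsi"],
                config=config,
            ).fit()
            pool_sessions = []
            for k in range(3):
                s2, _ = simulate_on_policy(
                    p, TaskConfig(), n_trials, seed=seed + 800 + 10 * rep + k
                )
                pool_sessions.append((s2, p))
            for pi, par in enumerate(parameters):
                if pi > 0 and secondary_replicates is not None and rep >= secondary_replicates:
                    continue
                tab = sweep_value_timescale(
                    fit, sess_full, p, par, pool_sessions, grid=grid,
                    n_null=n_null, seed=seed + rep,
                )
                curves[par].append(tab["corrected_delta_r2"].to_numpy())
    out: dict[str, np.ndarray] = {"grid": grid}
    for par in parameters:
        if curves[par]:
            out[par] = np.mean(curves[par], axis=0)
        out[f"{par}_curves"] = np.asarray(curves[par])
    return out


def decoder_calibration_study(
    n_trials: int = 160,
    n_neurons: int = 40,
    group_sizes: Sequence[int] = (10, 40),
    n_repeats: int = 3,
    n_null: int = 20,
    seed: int = 0,
    noise_sd: float = 0.8,
    gain_scale: float = 0.6,
) -> dict:
    """Pseudosession-corrected decoding of relative value.

    A value-coding population decodes detrended dQ from go-cue-aligned
    activity (100 ms bins); exchangeable (pool-drawn) targets check the
    null correction.  Returns mean corrected R2 per group size, plus the
    corrected R2 for exchangeable targets.
    """
    from .neural.decoding import nested_cv_decode
    from .pipelines import bin_for_decoding

    _, sess_full, sessf, traj, tl, folds = _encoding_session(n_trials, seed)
    U = np.column_stack(
        [
            detrend_trial_variable(traj["delta_q"].to_numpy()),
            detrend_trial_variable(traj["v"].to_numpy()),
        ]
    )
    counts, _, _ = generate_population(
        n_neurons, (1.0, 0.0, 0.0), tl, U, seed=seed + 3,
        noise_sd=noise_sd, gain_scale=gain_scale,
    )
    activity, times, mask = bin_for_decoding(counts, sessf, tl, "dq")
    n_kept = int(mask.sum())
    targets = U[mask, 0]
    pool = _value_pool(["delta_q"], n_trials, seed + 900)
    pool = PseudosessionPool(
        np.apply_along_axis(detrend_trial_variable, 0, pool.series)
    )
    spec = DecoderSpec()
    rng = np.random.default_rng(seed + 5)
    n_bins = activity.shape[2]

    def decode_bins(y, group):
        return np.array(
            [
                nested_cv_decode(activity[group, :, b].T, y, spec, rng)
                for b in range(n_bins)
            ]
        )

    out = {"times": times}
    all_neurons = np.arange(n_neurons)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # null decoders per group size (null R2 does not depend on the
        # real targets, so exchangeable checks reuse the largest group's)
        null_curves: dict[int, np.ndarray] = {}
        for g in group_sizes:
            curves = []
            for _ in range(n_null):
                grp = (
                    all_neurons if g >= n_neurons
                    else rng.choice(n_neurons, size=g, replace=False)
                )
                curves.append(decode_bins(pool.draw(n_kept, rng).ravel(), grp))
            null_curves[g] = np.mean(curves, axis=0)
        for g in group_sizes:
            reps = []
            for _ in range(n_repeats if g < n_neurons else 1):
                grp = (
                    all_neurons if g >= n_neurons
                    else rng.choice(n_neurons, size=g, replace=False)
                )
                reps.append(decode_bins(targets, grp))
            corrected = np.mean(reps, axis=0) - null_curves[g]
            out[f"corrected_r2_{g}"] = float(corrected.mean())
            out[f"peak_corrected_r2_{g}"] = float(corrected.max())
        gmax = max(group_sizes)
        grp = all_neurons if gmax >= n_neurons else all_neurons[:gmax]
        exch = [
            (decode_bins(pool.draw(n_kept, rng).ravel(), grp) - null_curves[gmax]).mean()
            for _ in range(6)
        ]
        out["exchangeable_corrected_r2"] = float(np.mean(exch))
    return out
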