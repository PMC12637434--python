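"""Linear and bilinear encoding models of single-neuron activity.

The linear model regresses z-scored 10 ms binned activity on temporal
kernels (raised-cosine bases convolved with event indicators) plus a
spike-history kernel, with lasso (L1) regularization and the penalty chosen
by 5-fold cross-validation over a log-spaced grid.  The bilinear extension
lets a per-trial multiplicative gain scale each event kernel:

    Sp(t,T) = b0 + sum_i G_i(T) * (K_i * c_i)(t,T) + K_sp * Sp + eps
    G_i(T)  = g_i0 + sum_k g_ik U_k(T)

with U_k the (detrended) trial-by-trial value variables.  Kernels and gains
are estimated by alternating lasso (kernels, unit-normalized each
iteration) and ridge (gains; intercept and history enter as fixed offsets),
with both penalties selected on the first iteration and then frozen.

Significance of a predictor set is an F-statistic on cross-validated
predictions, F = (dSSE / dDOF) / MSE_full, compared against either a
circular-shift null (event kernels) or a pseudosession null (value gains);
the empirical p is the fraction of null F exceeding the real F.  Explained
variance gains are reported as corrected dR2: the real dR2 minus the null
ensemble mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import linalg, sparse
from sklearn.linear_model import Lasso

from ..pseudosession import PseudosessionPool
from ..task import SessionData
from ..values import detrend_trial_variable, extract_decision_variables
from .design import BinnedSpikes, DesignMatrix, build_design_matrix, default_bases
from .timeline import EventTimeline, EVENTS

__all__ = [
    "EncodingConfig",
    "encoding_trial_folds",
    "LinearEncodingModel",
    "LinearEncodingResults",
    "BilinearEncodingModel",
    "BilinearEncodingResults",
    "EncodingStats",
    "f_compare",
    "corrected_delta_r2",
    "value_significance",
    "event_significance",
    "sweep_value_timescale",
]


@dataclass(frozen=True)
class EncodingConfig:
    """Fitting choices for the encoding models."""

    alphas_l1: np.ndarray = field(
        default_factory=lambda: np.logspace(-5, 5, 251)
    )
    alphas_l2: np.ndarray = field(
        default_factory=lambda: np.logspace(-5, 5, 251)
    )
    n_folds: int = 5
    lasso_max_iter: int = 1000
    lasso_tol: float = 1e-3
    bilinear_max_iter: int = 100
    bilinear_tol: float = 1e-3
    bilinear_streak: int = 3
    p_threshold: float = 0.01

    @classmethod
    def desk_scale(cls, n_alphas: int = 41) -> "EncodingConfig":
        """A coarser penalty grid over the same range, for small fixtures.

        Selection is still by minimum mean CV error; only the grid
        resolution changes.
        """
        return cls(
            alphas_l1=np.logspace(-5, 5, n_alphas),
            alphas_l2=np.logspace(-5, 5, max(n_alphas, 101)),
        )


def encoding_trial_folds(
    session: SessionData, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Random fold assignment per trial, approximately balancing block side,
    choice, and outcome across folds (round-robin within each stratum)."""
    labels = [
        (t.block_side, t.choice, t.outcome) for t in session.trials
    ]
    return _stratified_assignment(labels, n_folds, rng)


def _stratified_assignment(labels, n_folds, rng) -> np.ndarray:
    n = len(labels)
    fold = np.empty(n, dtype=int)
    order = {}
    for i, lab in enumerate(labels):
        order.setdefault(lab, []).append(i)
    next_fold = 0
    for lab in sorted(order):
        idx = np.array(order[lab])
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            fold[i] = (next_fold + j) % n_folds
        next_fold = (next_fold + len(idx)) % n_folds
    return fold


# ---------------------------------------------------------------------------
# penalized fits
# ---------------------------------------------------------------------------


@dataclass
class _PenalizedFit:
    alpha: float
    coef: np.ndarray
    intercept: float
    cv_pred: np.ndarray  # held-out predictions for every row
    cv_mse: float


def _lasso_cv(
    X, y, row_fold, alphas, max_iter, tol,
    alpha_fixed: float | None = None,
    cv_predictions: bool = True,
    warm_model: Lasso | None = None,
) -> _PenalizedFit:
    """Lasso with 5-fold CV penalty selection (or a frozen penalty).

    ``row_fold`` assigns each row to a fold; the penalty minimizing mean
    validation MSE is selected, then per-fold refits give held-out
    predictions and a final fit on all rows gives the coefficients.
    ``cv_predictions=False`` skips the per-fold refits (used inside the
    bilinear iteration, where only coefficients are needed);
    ``warm_model`` reuses a persistent estimator across calls.
    """
    if sparse.issparse(X):
        X = X.tocsr()
    folds = np.unique(row_fold)
    alphas = np.sort(np.asarray(alphas))[::-1]
    if alpha_fixed is None:
        mse = np.zeros((len(folds), len(alphas)))
        for fi, f in enumerate(folds):
            tr = row_fold != f
            va = ~tr
            model = Lasso(warm_start=True, max_iter=max_iter, tol=tol)
            Xtr, ytr = X[tr], y[tr]
            Xva, yva = X[va], y[va]
            for ai, a in enumerate(alphas):
                model.set_params(alpha=a)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model.fit(Xtr, ytr)
                mse[fi, ai] = float(np.mean((model.predict(Xva) - yva) ** 2))
        best = alphas[int(np.argmin(mse.mean(axis=0)))]
    else:
        best = alpha_fixed
    cv_pred = np.full_like(y, np.nan)
    if cv_predictions:
        for f in folds:
            tr = row_fold != f
            model = Lasso(alpha=best, max_iter=max_iter, tol=tol)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X[tr], y[tr])
            cv_pred[~tr] = model.predict(X[~tr])
    final = warm_model if warm_model is not None else Lasso(max_iter=max_iter, tol=tol)
    final.set_params(alpha=best)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(X, y)
    return _PenalizedFit(
        alpha=float(best),
        coef=np.asarray(final.coef_).copy(),
        intercept=float(final.intercept_),
        cv_pred=cv_pred,
        cv_mse=float(np.mean((cv_pred - y) ** 2)) if cv_predictions else np.nan,
    )


def _ridge_path_cv(
    X: np.ndarray,
    y: np.ndarray,
    row_fold: np.ndarray,
    alphas: np.ndarray,
    alpha_fixed: float | None = None,
) -> _PenalizedFit:
    """Ridge (no intercept) with CV penalty selection via a Gram-matrix
    eigendecomposition, so the whole penalty path costs one decomposition
    per fold.  Equivalent to refitting sklearn Ridge at every alpha."""
    alphas = np.asarray(alphas, dtype=float)
    folds = np.unique(row_fold)
    p = X.shape[1]

    def path_coefs(Xtr, ytr):
        G = Xtr.T @ Xtr
        b = Xtr.T @ ytr
        w, V = linalg.eigh(G)
        c = V.T @ b
        # coef(alpha) = V @ (c / (w + alpha)) for each alpha -> (p, n_alphas)
        return V @ (c[:, None] / (w[:, None] + alphas[None, :]))

    if alpha_fixed is None:
        mse = np.zeros((len(folds), len(alphas)))
        for fi, f in enumerate(folds):
            tr = row_fold != f
            B = path_coefs(X[tr], y[tr])
            resid = X[~tr] @ B - y[~tr][:, None]
            mse[fi] = np.mean(resid**2, axis=0)
        best = float(alphas[int(np.argmin(mse.mean(axis=0)))])
    else:
        best = float(alpha_fixed)

    cv_pred = np.empty_like(y)
    for f in folds:
        tr = row_fold != f
        Xtr = X[tr]
        G = Xtr.T @ Xtr + best * np.eye(p)
        coef_f = linalg.solve(G, Xtr.T @ y[tr], assume_a="pos")
        cv_pred[~tr] = X[~tr] @ coef_f
    G = X.T @ X + best * np.eye(p)
    coef = linalg.solve(G, X.T @ y, assume_a="pos")
    return _PenalizedFit(
        alpha=best,
        coef=coef,
        intercept=0.0,
        cv_pred=cv_pred,
        cv_mse=float(np.mean((cv_pred - y) ** 2)),
    )


# ---------------------------------------------------------------------------
# F statistic and corrected dR2
# ---------------------------------------------------------------------------


@dataclass
class EncodingStats:
    """Nested-model comparison on cross-validated predictions."""

    sse_full: float
    sse_reduced: float
    delta_dof: int
    n: int
    f: float
    p: float | None = None
    delta_r2: float | None = None
    corrected_delta_r2: float | None = None
    significant: bool | None = None
    null_f: np.ndarray | None = None
    null_delta_r2: np.ndarray | None = None


def f_compare(
    y: np.ndarray,
    pred_full: np.ndarray,
    pred_reduced: np.ndarray,
    delta_dof: int,
) -> EncodingStats:
    """F = (dSSE / dDOF) / MSE_full on (held-out) predictions.

    SSEs are pooled over all predictions.  With held-out predictions the
    full model need not win, so F may be negative; it is reported as-is.
    """
    if delta_dof <= 0:
        raise ValueError("delta_dof must be positive")
    sse_f = float(np.sum((y - pred_full) ** 2))
    sse_r = float(np.sum((y - pred_reduced) ** 2))
    n = y.size
    mse_f = sse_f / n
    f = ((sse_r - sse_f) / delta_dof) / mse_f
    sst = float(np.sum((y - y.mean()) ** 2))
    dr2 = (sse_r - sse_f) / sst if sst > 0 else 0.0
    return EncodingStats(
        sse_full=sse_f,
        sse_reduced=sse_r,
        delta_dof=delta_dof,
        n=n,
        f=f,
        delta_r2=dr2,
    )


def corrected_delta_r2(real_dr2: float, null_dr2: Sequence[float]) -> float:
    """Real explained-variance gain minus the null-ensemble mean."""
    null_dr2 = np.asarray(null_dr2, dtype=float)
    if null_dr2.size < 1:
        raise ValueError("need at least one null sample")
    return float(real_dr2 - null_dr2.mean())


# ---------------------------------------------------------------------------
# linear encoding model
# ---------------------------------------------------------------------------


@dataclass
class LinearEncodingResults:
    """Fitted kernels and cross-validated performance of the linear model."""

    kernels: dict[str, np.ndarray]
    history_kernel: np.ndarray | None
    coef: np.ndarray
    intercept: float
    alpha: float
    cv_pred: np.ndarray
    r2_cv: float
    design: DesignMatrix
    rows: np.ndarray
    y: np.ndarray
    row_fold: np.ndarray
    n_predictors: int

    def summary(self) -> str:
        lines = [
            "Linear encoding model",
            f"  predictors: {self.n_predictors}  (lasso alpha {self.alpha:.3g})",
            f"  cross-validated R2: {self.r2_cv:.4f}",
            "  kernel peak |amplitude| per event:",
        ]
        for e, k in self.kernels.items():
            lines.append(f"    {e:>9s}: {np.max(np.abs(k)) if k.size else 0:.3f}")
        return "\n".join(lines)


class LinearEncodingModel:
    """Kernel-only encoding model for one neuron."""

    def __init__(
        self,
        spikes: BinnedSpikes,
        timeline: EventTimeline,
        trial_folds: np.ndarray,
        bases: dict | None = None,
        config: EncodingConfig | None = None,
        include_history: bool = True,
        events: dict[str, np.ndarray] | None = None,
    ):
        if not spikes.usable:
            raise ValueError("neuron flagged unusable (zero variance)")
        self.spikes = spikes
        self.timeline = timeline
        self.trial_folds = np.asarray(trial_folds)
        self.config = config or EncodingConfig()
        self.bases = bases or default_bases(timeline.bin_width)
        self.include_history = include_history
        self.events = events

    def _rows_mask(self) -> np.ndarray:
        tl = self.timeline
        mask = tl.coverage & tl.included[:, None]
        return mask.ravel()

    def fit(self, alpha_fixed: float | None = None) -> LinearEncodingResults:
        tl = self.timeline
        design = build_design_matrix(
            tl,
            bases=self.bases,
            history_source=self.spikes.z if self.include_history else None,
            events=self.events,
        )
        rows = self._rows_mask()
        X = design.X[rows]
        y = self.spikes.z.ravel()[rows]
        row_fold = self.trial_folds[design.trial_of_row[rows]]
        cfg = self.config
        fit = _lasso_cv(
            X, y, row_fold, cfg.alphas_l1, cfg.lasso_max_iter, cfg.lasso_tol,
            alpha_fixed=alpha_fixed,
        )
        kernels = {}
        for e in design.event_names():
            sl = design.columns[e]
            kernels[e] = design.bases[e].matrix @ fit.coef[sl]
        hist = None
        if "history" in design.columns:
            from .basis import make_basis

            hb = make_basis("log_cosine_history", 1.0, tl.bin_width)
            hist = hb.matrix @ fit.coef[design.columns["history"]]
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - fit.cv_mse * y.size / sst if sst > 0 else 0.0
        return LinearEncodingResults(
            kernels=kernels,
            history_kernel=hist,
            coef=fit.coef,
            intercept=fit.intercept,
            alpha=fit.alpha,
            cv_pred=fit.cv_pred,
            r2_cv=r2,
            design=design,
            rows=rows,
            y=y,
            row_fold=row_fold,
            n_predictors=int(design.X.shape[1]),
        )


# ---------------------------------------------------------------------------
# bilinear encoding model
# ---------------------------------------------------------------------------


@dataclass
class GainRefit:
    """A gains-only refit with kernels frozen (used for model comparison,
    nulls, and the learning-rate sweep)."""

    coef: np.ndarray
    alpha: float
    cv_pred: np.ndarray
    sse_cv: float
    r2_cv: float
    n_predictors: int


@dataclass
class BilinearEncodingResults:
    """Converged kernels, gains, and machinery for gain-stage refits."""

    kernels: dict[str, np.ndarray]  # unit-norm event kernels
    history_kernel: np.ndarray | None
    intercept: float
    gain_offsets: dict[str, float]
    gain_coefs: dict[str, np.ndarray]  # per event, one coef per variable
    gains: np.ndarray  # (n_trials, n_events) trial gains G_i(T)
    var_names: list[str]
    alpha_l1: float
    alpha_l2: float
    n_iter: int
    converged: bool
    r2_cv: float
    # frozen state for refits; the "initial" stage holds the iteration-1
    # (value-agnostic, G == 1) kernels used for exchangeable null comparisons
    _model: "BilinearEncodingModel" = None
    _signal_cols: np.ndarray = None  # (n_rows_sub, n_events) kernel signals
    _offset: np.ndarray = None  # intercept + history contribution per row
    _signal_cols_init: np.ndarray = None
    _offset_init: np.ndarray = None
    _y: np.ndarray = None
    _row_fold: np.ndarray = None
    _trial_of_row: np.ndarray = None

    @property
    def event_names(self) -> list[str]:
        return list(self.kernels)

    def plot_kernels(self, ax=None):
        """Plot the fitted event kernels (unit-norm) on their windows."""
        import matplotlib.pyplot as plt

        from .timeline import KERNEL_WINDOWS

        if ax is None:
            _, ax = plt.subplots()
        bw = self._model.timeline.bin_width
        for e, k in self.kernels.items():
            w0 = KERNEL_WINDOWS[e][0]
            t = w0 + (np.arange(k.size) + 0.5) * bw
            ax.plot(t, k, label=e)
        ax.set_xlabel("time from event (s)")
        ax.set_ylabel("kernel amplitude (unit norm)")
        ax.legend(fontsize="small")
        return ax

    def summary(self) -> str:
        lines = [
            "Bilinear encoding model",
            f"  iterations: {self.n_iter}  converged: {self.converged}",
            f"  penalties: lasso {self.alpha_l1:.3g}, ridge {self.alpha_l2:.3g}",
            f"  cross-validated R2 (full gain model): {self.r2_cv:.4f}",
            "  gain coefficients (event x variable):",
        ]
        for e in self.event_names:
            terms = ", ".join(
                f"{v}={c: .3f}" for v, c in zip(self.var_names, self.gain_coefs[e])
            )
            lines.append(f"    {e:>9s}: offset={self.gain_offsets[e]: .3f}  {terms}")
        return "\n".join(lines)

    def _stage(self, stage: str) -> tuple[np.ndarray, np.ndarray]:
        if stage == "initial":
            return self._signal_cols_init, self._offset_init
        if stage == "final":
            return self._signal_cols, self._offset
        raise ValueError("stage must be 'initial' or 'final'")

    def gain_design(
        self, U: np.ndarray, drop: Sequence[int] | None = None, stage: str = "final"
    ) -> np.ndarray:
        """Columns [signal_i, signal_i * U_k ...] per event, for the rows of
        the fitted subset.  ``drop`` removes the listed variable indices
        from every event (offsets always stay)."""
        signal_cols, _ = self._stage(stage)
        keep = [k for k in range(U.shape[1]) if drop is None or k not in drop]
        Ur = U[self._trial_of_row]
        cols = []
        for i in range(signal_cols.shape[1]):
            s = signal_cols[:, i]
            cols.append(s)
            for k in keep:
                cols.append(s * Ur[:, k])
        return np.column_stack(cols)

    def refit_gains(
        self,
        U: np.ndarray,
        drop: Sequence[int] | None = None,
        reselect_alpha: bool = True,
        stage: str = "final",
    ) -> GainRefit:
        """Refit the gain stage (ridge) with kernels frozen.

        ``stage`` picks which frozen kernels to use: "final" (the converged
        bilinear kernels; best estimates) or "initial" (the iteration-1,
        value-agnostic kernels).  Null-calibrated comparisons must use
        "initial": the converged kernels have adapted to gain structure
        aligned with the real value series, which makes real-vs-null
        comparisons on them anticonservative.  The penalty is re-selected
        by CV (the default, applied identically to real and null refits) or
        frozen at the bilinear fit's value.
        """
        X = self.gain_design(U, drop, stage=stage)
        _, offset = self._stage(stage)
        yr = self._y - offset
        cfg = self._model.config
        fit = _ridge_path_cv(
            X, yr, self._row_fold, cfg.alphas_l2,
            alpha_fixed=None if reselect_alpha else self.alpha_l2,
        )
        pred = fit.cv_pred + offset
        sse = float(np.sum((self._y - pred) ** 2))
        sst = float(np.sum((self._y - self._y.mean()) ** 2))
        return GainRefit(
            coef=fit.coef,
            alpha=fit.alpha,
            cv_pred=pred,
            sse_cv=sse,
            r2_cv=1.0 - sse / sst if sst > 0 else 0.0,
            n_predictors=X.shape[1],
        )


class BilinearEncodingModel:
    """Kernel x gain encoding model for one neuron.

    ``values`` is the (n_trials, n_vars) matrix of trial-by-trial variables
    U_k (detrend upstream; see ``values.detrend_trial_variable``).
    """

    def __init__(
        self,
        spikes: BinnedSpikes,
        timeline: EventTimeline,
        values: np.ndarray,
        trial_folds: np.ndarray,
        var_names: Sequence[str] | None = None,
        bases: dict | None = None,
        config: EncodingConfig | None = None,
        include_history: bool = True,
    ):
        if not spikes.usable:
            raise ValueError("neuron flagged unusable (zero variance)")
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if values.shape[0] == timeline.n_trials:
            pass
        elif values.shape[1] == timeline.n_trials:
            values = values.T
        else:
            raise ValueError("values must have one row per trial")
        self.spikes = spikes
        self.timeline = timeline
        self.values = values
        self.trial_folds = np.asarray(trial_folds)
        self.var_names = list(var_names) if var_names else [
            f"u{k}" for k in range(values.shape[1])
        ]
        self.config = config or EncodingConfig()
        self.bases = bases or default_bases(timeline.bin_width)
        self.include_history = include_history

    def fit(self) -> BilinearEncodingResults:
        cfg = self.config
        tl = self.timeline
        design = build_design_matrix(
            tl,
            bases=self.bases,
            history_source=self.spikes.z if self.include_history else None,
        )
        rows = (tl.coverage & tl.included[:, None]).ravel()
        Xfull = design.X.tocsr()[np.nonzero(rows)[0]].tocsc()
        y = self.spikes.z.ravel()[rows]
        trial_of_row = design.trial_of_row[rows]
        row_fold = self.trial_folds[trial_of_row]
        event_names = design.event_names()
        n_events = len(event_names)
        n_trials = tl.n_trials
        U = self.values

        G = np.ones((n_trials, n_events))
        alpha_l1 = alpha_l2 = None
        prev_beta = None
        streak = 0
        n_iter = 0
        converged = False
        kernel_coefs = {e: np.zeros(design.bases[e].n_dof) for e in event_names}
        hist_coef = None
        intercept = 0.0
        gain_coef_vec = None
        last_gain_fit = None

        # per-event column scaling helper: scale event columns by G_i(trial)
        col_event = np.full(Xfull.shape[1], -1)
        for ei, e in enumerate(event_names):
            col_event[design.columns[e]] = ei

        X_csc = Xfull
        indptr, indices, base_data = X_csc.indptr, X_csc.indices, X_csc.data.copy()
        warm = Lasso(max_iter=cfg.lasso_max_iter, tol=cfg.lasso_tol, warm_start=True)

        for n_iter in range(1, cfg.bilinear_max_iter + 1):
            # ---- kernel stage (lasso), gains fixed -----------------------
            data = base_data.copy()
            for ci in range(X_csc.shape[1]):
                ei = col_event[ci]
                if ei < 0:
                    continue
                seg = slice(indptr[ci], indptr[ci + 1])
                data[seg] *= G[trial_of_row[indices[seg]], ei]
            Xk = sparse.csc_matrix((data, indices, indptr), shape=X_csc.shape)
            kfit = _lasso_cv(
                Xk, y, row_fold, cfg.alphas_l1, cfg.lasso_max_iter,
                cfg.lasso_tol, alpha_fixed=alpha_l1,
                cv_predictions=False, warm_model=warm,
            )
            if alpha_l1 is None:
                alpha_l1 = kfit.alpha
            intercept = kfit.intercept
            coef = kfit.coef.copy()
            # normalize kernels to unit Euclidean norm (zero kernels exempt)
            for e in event_names:
                sl = design.columns[e]
                k = design.bases[e].matrix @ coef[sl]
                nrm = float(np.linalg.norm(k))
                if nrm > 0:
                    coef[sl] = coef[sl] / nrm
                kernel_coefs[e] = coef[sl].copy()
            if "history" in design.columns:
                hist_coef = coef[design.columns["history"]].copy()

            # kernel signal columns s_i = (K_i * c_i) at the fitted rows
            signal_cols = np.column_stack(
                [
                    np.asarray(
                        Xfull[:, design.columns[e]] @ kernel_coefs[e]
                    ).ravel()
                    for e in event_names
                ]
            )
            if "history" in design.columns:
                offset = intercept + np.asarray(
                    Xfull[:, design.columns["history"]] @ hist_coef
                ).ravel()
            else:
                offset = np.full(y.shape, intercept)
            if n_iter == 1:
                # iteration-1 kernels were fit with G == 1 and have never
                # seen the value series; frozen for null comparisons
                signal_cols_init = signal_cols.copy()
                offset_init = offset.copy()

            # ---- gain stage (ridge), kernels fixed -----------------------
            Ur = U[trial_of_row]
            cols = []
            for i in range(n_events):
                s = signal_cols[:, i]
                cols.append(s)
                for k in range(U.shape[1]):
                    cols.append(s * Ur[:, k])
            Xg = np.column_stack(cols)
            gfit = _ridge_path_cv(
                Xg, y - offset, row_fold, cfg.alphas_l2, alpha_fixed=alpha_l2
            )
            if alpha_l2 is None:
                alpha_l2 = gfit.alpha
            last_gain_fit = gfit
            stride = 1 + U.shape[1]
            for i in range(n_events):
                g0 = gfit.coef[i * stride]
                gk = gfit.coef[i * stride + 1 : (i + 1) * stride]
                G[:, i] = g0 + U @ gk

            beta = np.concatenate(
                [kernel_coefs[e] for e in event_names]
                + ([hist_coef] if hist_coef is not None else [])
                + [[intercept], gfit.coef]
            )
            if prev_beta is not None and beta.size == prev_beta.size:
                if np.max(np.abs(beta - prev_beta)) <= cfg.bilinear_tol:
                    streak += 1
                    if streak >= cfg.bilinear_streak:
                        converged = True
                        prev_beta = beta
                        break
                else:
                    streak = 0
            prev_beta = beta

        stride = 1 + U.shape[1]
        gain_offsets = {
            e: float(last_gain_fit.coef[i * stride])
            for i, e in enumerate(event_names)
        }
        gain_coefs = {
            e: last_gain_fit.coef[i * stride + 1 : (i + 1) * stride].copy()
            for i, e in enumerate(event_names)
        }
        pred = last_gain_fit.cv_pred + offset
        sse = float(np.sum((y - pred) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        kernels = {
            e: design.bases[e].matrix @ kernel_coefs[e] for e in event_names
        }
        from .basis import make_basis

        hist_kernel = None
        if hist_coef is not None:
            hb = make_basis("log_cosine_history", 1.0, tl.bin_width)
            hist_kernel = hb.matrix @ hist_coef
        return BilinearEncodingResults(
            kernels=kernels,
            history_kernel=hist_kernel,
            intercept=intercept,
            gain_offsets=gain_offsets,
            gain_coefs=gain_coefs,
            gains=G.copy(),
            var_names=list(self.var_names),
            alpha_l1=float(alpha_l1),
            alpha_l2=float(alpha_l2),
            n_iter=n_iter,
            converged=converged,
            r2_cv=1.0 - sse / sst if sst > 0 else 0.0,
            _model=self,
            _signal_cols=signal_cols,
            _offset=offset,
            _signal_cols_init=signal_cols_init,
            _offset_init=offset_init,
            _y=y,
            _row_fold=row_fold,
            _trial_of_row=trial_of_row,
        )


# ---------------------------------------------------------------------------
# significance machinery
# ---------------------------------------------------------------------------


def value_significance(
    fit: BilinearEncodingResults,
    pool: PseudosessionPool,
    n_null: int = 200,
    seed: int = 0,
    drop: Sequence[int] | None = None,
    null_chunks: Sequence[np.ndarray] | None = None,
    p_threshold: float = 0.01,
    stage: str = "initial",
) -> EncodingStats:
    """Pseudosession-null F test for the value gains.

    The full gain model is compared to a reduced model with the ``drop``
    variables (default: all) removed from every kernel; gains are refit with
    kernels frozen, the ridge penalty re-selected per model, and the same
    procedure applied to the real series and to every null.  Null F values
    repeat the comparison with surrogate value series drawn as contiguous
    chunks from ``pool`` (detrended like the real series).  ``null_chunks``
    allows sharing the same surrogates across neurons.

    ``stage="initial"`` (default) freezes the iteration-1 kernels, which
    never saw the value series, so real and null comparisons are
    exchangeable under the null; ``stage="final"`` uses the converged
    bilinear kernels, which is anticonservative (the kernels adapt to gain
    structure aligned with the real series) and is retained only for
    comparison with that protocol.
    """
    U = fit._model.values
    n_trials, n_vars = U.shape
    if drop is None:
        drop = list(range(n_vars))
    rng = np.random.default_rng(seed)
    full = fit.refit_gains(U, drop=None, reselect_alpha=True, stage=stage)
    red = fit.refit_gains(U, drop=drop, reselect_alpha=True, stage=stage)
    ddof = full.n_predictors - red.n_predictors
    real = f_compare(fit._y, full.cv_pred, red.cv_pred, ddof)

    if null_chunks is None:
        pool.require(n_trials, n_null)
        null_chunks = [pool.draw(n_trials, rng) for _ in range(n_null)]
    null_f = np.empty(len(null_chunks))
    null_dr2 = np.empty(len(null_chunks))
    for i, chunk in enumerate(null_chunks):
        Un = np.column_stack(
            [detrend_trial_variable(chunk[:, k]) for k in range(chunk.shape[1])]
        )
        nfull = fit.refit_gains(Un, drop=None, reselect_alpha=True, stage=stage)
        nred = fit.refit_gains(Un, drop=drop, reselect_alpha=True, stage=stage)
        st = f_compare(fit._y, nfull.cv_pred, nred.cv_pred, ddof)
        null_f[i] = st.f
        null_dr2[i] = st.delta_r2
    p = float(np.mean(null_f > real.f))
    return EncodingStats(
        sse_full=real.sse_full,
        sse_reduced=real.sse_reduced,
        delta_dof=ddof,
        n=real.n,
        f=real.f,
        p=p,
        delta_r2=real.delta_r2,
        corrected_delta_r2=corrected_delta_r2(real.delta_r2, null_dr2),
        significant=p <= p_threshold,
        null_f=null_f,
        null_delta_r2=null_dr2,
    )


def event_significance(
    spikes: BinnedSpikes,
    timeline: EventTimeline,
    trial_folds: np.ndarray,
    drop_events: Sequence[str],
    n_null: int = 200,
    seed: int = 0,
    config: EncodingConfig | None = None,
    bases: dict | None = None,
    p_threshold: float = 0.01,
) -> EncodingStats:
    """Circular-shift-null F test for a set of event kernels.

    The full linear model is compared to a reduced model with the listed
    events' predictors removed.  Null spiking is the binned activity
    circularly shifted by a random integer, drawn uniformly from
    [L/10, 9L/10] bins to exclude near-zero shifts; penalties are frozen at
    the real fit's values.
    """
    config = config or EncodingConfig()
    rng = np.random.default_rng(seed)

    def fit_pair(z_arr, alpha_full=None, alpha_red=None):
        sp = replace(spikes, z=z_arr)
        full_m = LinearEncodingModel(
            sp, timeline, trial_folds, bases=bases, config=config
        )
        full = full_m.fit(alpha_fixed=alpha_full)
        events = {
            e: (np.zeros_like(timeline.indicators[e]) if e in drop_events else None)
            for e in EVENTS
        }
        red_m = LinearEncodingModel(
            sp, timeline, trial_folds, bases=bases, config=config, events=events
        )
        red = red_m.fit(alpha_fixed=alpha_red)
        return full, red

    full, red = fit_pair(spikes.z)
    dropped_dof = sum(full.design.bases[e].n_dof for e in drop_events)
    real = f_compare(full.y, full.cv_pred, red.cv_pred, dropped_dof)

    L = spikes.z.size
    lo, hi = L // 10, 9 * L // 10
    null_f = np.empty(n_null)
    flat = spikes.z.ravel()
    for i in range(n_null):
        shift = int(rng.integers(lo, hi + 1))
        z_shift = np.roll(flat, shift).reshape(spikes.z.shape)
        nf, nr = fit_pair(z_shift, alpha_full=full.alpha, alpha_red=red.alpha)
        null_f[i] = f_compare(nf.y, nf.cv_pred, nr.cv_pred, dropped_dof).f
    p = float(np.mean(null_f > real.f))
    return EncodingStats(
        sse_full=real.sse_full,
        sse_reduced=real.sse_reduced,
        delta_dof=dropped_dof,
        n=real.n,
        f=real.f,
        p=p,
        delta_r2=real.delta_r2,
        significant=p <= p_threshold,
        null_f=null_f,
    )


def sweep_value_timescale(
    fit: BilinearEncodingResults,
    session: SessionData,
    behav_params,
    parameter: str,
    pool_sessions: Sequence[tuple[SessionData, object]] | None = None,
    grid: np.ndarray | None = None,
    n_null: int = 20,
    seed: int = 0,
    stage: str = "initial",
) -> "pd.DataFrame":
    """Corrected dR2 of reward-only action values across a learning-rate grid.

    For each of 40 linearly spaced values of ``parameter`` (``alpha_rew`` or
    ``gamma_forget``) in [0.025, 1], the reward-only contra/ipsi value
    series are recomputed, detrended, and the gains refit with kernels
    frozen (ridge penalty re-selected per grid value).  Pseudosession nulls
    share the same chunk positions across the grid; the null pool is
    rebuilt from ``pool_sessions`` at each grid value so surrogates match
    the variable being tested.

    ``session`` and the pool sessions are *full* sessions: values are
    extracted over the whole history and then restricted to the analyzed
    (non-excluded) trials, so real and surrogate series share the same
    mid-session distribution.  When ``session`` already matches the fitted
    timeline's trial count it is used as-is.
    """
    import pandas as pd

    from ..preprocess import apply_trial_exclusions

    if grid is None:
        grid = np.linspace(0.025, 1.0, 40)
    grid = np.asarray(grid, dtype=float)
    if np.any((grid <= 0) | (grid > 1)):
        raise ValueError("grid values must lie in (0, 1]")
    if parameter not in ("alpha_rew", "gamma_forget"):
        raise ValueError("parameter must be alpha_rew or gamma_forget")
    rng = np.random.default_rng(seed)
    n_trials = fit._model.timeline.n_trials

    def analyzed_series(sess, params_g):
        traj = extract_decision_variables(sess, params_g)
        if len(sess.trials) != n_trials:
            kept = [t.trial_index for t in apply_trial_exclusions(sess)[0].trials]
            traj = traj.iloc[kept].reset_index(drop=True)
        return traj[["q_rew_contra", "q_rew_ipsi"]]

    if len(session.trials) != n_trials:
        n_kept = len(apply_trial_exclusions(session)[0].trials)
        if n_kept != n_trials:
            raise ValueError(
                "session does not match the fitted timeline's trials"
            )
    starts = None
    rows = []
    for g in grid:
        p = replace(behav_params, **{parameter: float(g)})
        traj = analyzed_series(session, p)
        U = np.column_stack(
            [
                detrend_trial_variable(traj["q_rew_contra"].to_numpy()),
                detrend_trial_variable(traj["q_rew_ipsi"].to_numpy()),
            ]
        )
        full = fit.refit_gains(U, drop=None, reselect_alpha=True, stage=stage)
        red = fit.refit_gains(U, drop=[0, 1], reselect_alpha=True, stage=stage)
        dr2 = full.r2_cv - red.r2_cv
        null_mean = 0.0
        if pool_sessions and n_null > 0:
            frames = []
            for sess_p, par_p in pool_sessions:
                pp = replace(par_p, **{parameter: float(g)})
                frames.append(analyzed_series(sess_p, pp))
            pool = PseudosessionPool(
                np.concatenate([f.to_numpy() for f in frames]),
                columns=["q_rew_contra", "q_rew_ipsi"],
            )
            if starts is None:
                starts = pool.draw_starts(n_trials, n_null, rng)
            null_dr2 = []
            for s0 in starts:
                chunk = pool.chunk(int(s0), n_trials)
                Un = np.column_stack(
                    [detrend_trial_variable(chunk[:, k]) for k in range(2)]
                )
                nfull = fit.refit_gains(Un, drop=None, reselect_alpha=True, stage=stage)
                nred = fit.refit_gains(Un, drop=[0, 1], reselect_alpha=True, stage=stage)
                null_dr2.append(nfull.r2_cv - nred.r2_cv)
            null_mean = float(np.mean(null_dr2))
        rows.append(
            dict(
                grid_value=float(g),
                delta_r2=dr2,
                null_mean=null_mean,
                corrected_delta_r2=dr2 - null_mean,
            )
        )
    return pd.DataFrame(rows)
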