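"""Bases, timelines, z-scoring, and the design matrix vs brute force."""

import numpy as np
import pytest

from revalue.neural.basis import make_basis
from revalue.neural.design import (
    build_design_matrix,
    history_columns,
    zscore_binned_spikes,
)
from revalue.neural.timeline import (
    EVENTS,
    KERNEL_WINDOWS,
    TimelineConfig,
    build_event_timeline,
)
from revalue.task import CS_MINUS, SessionData, TrialRecord


class TestBasis:
    def test_basis_counts_match_span(self):
        assert make_basis("linear_cosine", 1.0).n_dof == 40
        assert make_basis("linear_cosine", 2.0).n_dof == 80

    def test_partition_of_unity_interior(self):
        b = make_basis("linear_cosine", 1.0)
        total = b.matrix.sum(axis=1)
        interior = total[10:-10]
        assert np.ptp(interior) < 1e-6

    def test_history_basis_is_causal_and_log_spaced(self):
        b = make_basis("log_cosine_history", 1.0)
        assert b.n_dof == 10
        assert b.n_bins == 100
        # earliest basis functions concentrate near short lags
        peak_lags = np.argmax(b.matrix, axis=0)
        assert np.all(np.diff(peak_lags) >= 0)
        assert peak_lags[0] == 0  # first center at 10 ms = lag bin 1

    def test_invalid_span(self):
        with pytest.raises(ValueError):
            make_basis("linear_cosine", 0.0)


def _toy_session(n_trials=5, seed=0):
    rng = np.random.default_rng(seed)
    trials = []
    t = 0.0
    for i in range(n_trials):
        t_go = t + 0.3
        t_move = t_go + rng.uniform(0.2, 0.6)
        t_out = t_move + 0.2
        rewarded = i % 2 == 0
        trials.append(
            TrialRecord(
                trial_index=i, block_side="R",
                choice="R" if i % 3 else "L",
                outcome="CS+" if rewarded else "CS-",
                stim_collected=rewarded, R=int(rewarded),
                t_go=t_go, t_move=t_move, t_outcome=t_out,
                t_stim=t_out if rewarded else np.nan,
            )
        )
        t = t_out + 4.0
    return SessionData(trials=trials, block_starts=[0])


class TestTimeline:
    def test_one_go_indicator_per_completed_trial(self):
        sess = _toy_session()
        tl = build_event_timeline(sess)
        assert np.all(tl.indicators["go"].sum(axis=1) == 1)

    def test_mutually_exclusive_events(self):
        sess = _toy_session()
        tl = build_event_timeline(sess)
        assert np.all(
            tl.indicators["move_L"].sum(axis=1) * tl.indicators["move_R"].sum(axis=1) == 0
        )
        assert np.all(
            tl.indicators["cs_plus"].sum(axis=1) * tl.indicators["cs_minus"].sum(axis=1) == 0
        )

    def test_cs_minus_only_session_has_no_csplus_indicators(self):
        sess = _toy_session()
        for t in sess.trials:
            t.outcome = CS_MINUS
            t.R = 0
            t.stim_collected = False
            t.t_stim = np.nan
        tl = build_event_timeline(sess)
        assert tl.indicators["cs_plus"].sum() == 0
        assert tl.indicators["stim"].sum() == 0

    def test_indicator_counts_match_trial_table(self):
        sess = _toy_session(n_trials=9)
        tl = build_event_timeline(sess)
        n_plus = sum(t.outcome == "CS+" for t in sess.trials)
        assert tl.n_events("cs_plus") == n_plus
        assert tl.n_events("cs_minus") == len(sess.trials) - n_plus
        assert tl.n_events("move_L") + tl.n_events("move_R") == len(sess.trials)

    def test_missing_timestamp_flags_trial(self):
        sess = _toy_session()
        sess.trials[2].t_move = np.nan
        tl = build_event_timeline(sess)
        assert not tl.included[2]
        assert tl.included.sum() == len(sess.trials) - 1


class TestZScore:
    def test_covered_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(2.0, size=(10, 50)).astype(float)
        mask = np.zeros((10, 50), dtype=bool)
        mask[:, 5:30] = True
        sp = zscore_binned_spikes(counts, mask)
        assert sp.usable
        assert sp.z[mask].mean() == pytest.approx(0.0, abs=1e-10)
        assert sp.z[mask].std() == pytest.approx(1.0, abs=1e-10)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(1.0, size=(4, 30)).astype(float)
        mask = np.ones((4, 30), dtype=bool)
        sp = zscore_binned_spikes(counts, mask)
        mu = counts.sum() / counts.size
        sd = np.sqrt(((counts - mu) ** 2).sum() / counts.size)
        np.testing.assert_allclose(sp.z, (counts - mu) / sd, atol=1e-12)

    def test_constant_neuron_flagged(self):
        counts = np.full((3, 20), 2.0)
        sp = zscore_binned_spikes(counts, np.ones((3, 20), dtype=bool))
        assert not sp.usable


class TestDesignMatrix:
    def test_single_event_column_is_translated_basis(self):
        sess = _toy_session(n_trials=1)
        tl = build_event_timeline(sess)
        dm = build_design_matrix(tl)
        b = tl.event_bins["go"][0][1]
        basis = dm.bases["go"].matrix
        col = np.asarray(dm.X[:, dm.columns["go"].start].todense()).ravel()
        expected = np.zeros(tl.n_bins)
        expected[b : b + basis.shape[0]] = basis[: tl.n_bins - b, 0]
        np.testing.assert_allclose(col, expected, atol=1e-12)

    def test_matches_bruteforce_convolution(self):
        """Design matrix equals a double-loop convolution oracle on a
        5-trial toy session, to 1e-12."""
        sess = _toy_session()
        tl = build_event_timeline(sess)
        dm = build_design_matrix(tl)
        X = np.asarray(dm.X.todense())
        for e in EVENTS:
            basis = dm.bases[e].matrix
            w0 = int(round(KERNEL_WINDOWS[e][0] / tl.bin_width))
            for j in range(basis.shape[1]):
                expected = np.zeros((tl.n_trials, tl.n_bins))
                for (tr, b) in tl.event_bins[e]:
                    for l in range(basis.shape[0]):
                        bb = b + w0 + l
                        if 0 <= bb < tl.n_bins:
                            expected[tr, bb] += basis[l, j]
                np.testing.assert_allclose(
                    X[:, dm.columns[e].start + j],
                    expected.ravel(),
                    atol=1e-12,
                )

    def test_no_event_gives_zero_columns(self):
        sess = _toy_session()
        for t in sess.trials:
            t.outcome = CS_MINUS
            t.R = 0
            t.stim_collected = False
        tl = build_event_timeline(sess)
        dm = build_design_matrix(tl)
        assert np.abs(dm.X[:, dm.columns["cs_plus"]].todense()).sum() == 0

    def test_history_is_strictly_causal(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=(3, 60))
        h = history_columns(z)
        # perturbing the current and future bins must not change history
        z2 = z.copy()
        z2[1, 30:] += 5.0
        h2 = history_columns(z2)
        row = 1 * 60 + 30  # trial 1, bin 30
        np.testing.assert_allclose(h[row], h2[row], atol=1e-12)
        # but past bins do
        z3 = z.copy()
        z3[1, 29] += 5.0
        h3 = history_columns(z3)
        assert not np.allclose(h[row], h3[row])

    def test_history_confined_within_trial(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=(2, 60))
        h = history_columns(z)
        # first bin of trial 2 has no lagged data
        np.testing.assert_allclose(h[60], 0.0, atol=1e-12)
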