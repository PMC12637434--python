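"""Likelihoods, MAP fitting, model comparison, and the kappa re-fit."""

import copy

import numpy as np
import pytest
from scipy import special

from revalue.agents import KappaParams, RLParamsQ
from revalue.behavior import (
    BehavioralModel,
    compare_models,
    fit_csplus_value,
    fit_session_map,
    params_from_dict,
    session_log_likelihood,
)
from revalue.task import TaskConfig
from revalue.values import simulate_on_policy


class TestLogLikelihood:
    def test_uniform_policy_is_chance(self, small_session):
        p = RLParamsQ(0.3, 0.3, 0.2, 0.0, 0.0, 0.0)
        _, per_choice = session_log_likelihood(small_session, p)
        assert per_choice == pytest.approx(np.log(0.5), abs=1e-12)

    def test_constant_probability_gives_its_logarithm(self, task_config):
        """A bias-only model predicting the observed choice at P = 0.622
        on every trial yields LL per choice = ln(0.622) ~ -0.475."""
        # all-right session via a deterministic agent
        from revalue.task import simulate_session

        sess = simulate_session(task_config, lambda h: 1.0, 100, seed=0)
        p = RLParamsQ(0.0, 0.0, 0.0, 0.0, 0.0, bias=float(special.logit(0.622)))
        _, per_choice = session_log_likelihood(sess, p)
        assert per_choice == pytest.approx(np.log(0.622), abs=1e-9)
        assert per_choice == pytest.approx(-0.475, abs=0.001)

    def test_relabel_invariance(self, small_session, q_params):
        """Swapping L and R everywhere and negating the bias leaves the
        likelihood unchanged."""
        flipped = copy.deepcopy(small_session)
        swap = {"L": "R", "R": "L"}
        for t in flipped.trials:
            t.choice = swap.get(t.choice, t.choice)
            t.block_side = swap[t.block_side]
        p = RLParamsQ(0.3, 0.3, 0.2, 4.0, 1.0, bias=0.7)
        p_neg = RLParamsQ(0.3, 0.3, 0.2, 4.0, 1.0, bias=-0.7)
        ll_a, _ = session_log_likelihood(small_session, p)
        ll_b, _ = session_log_likelihood(flipped, p_neg)
        assert ll_a == pytest.approx(ll_b, abs=1e-9)

    def test_smoothness_in_beta_rew(self, small_session):
        """The likelihood is smooth in beta_rew: central finite differences
        at two step sizes agree to O(h^2)."""
        def ll(beta):
            p = RLParamsQ(0.3, 0.3, 0.2, beta, 1.0, 0.0)
            return session_log_likelihood(small_session, p)[0]

        g1 = (ll(2.0 + 1e-3) - ll(2.0 - 1e-3)) / 2e-3
        g2 = (ll(2.0 + 1e-5) - ll(2.0 - 1e-5)) / 2e-5
        assert g1 == pytest.approx(g2, rel=1e-4)


class TestMapFit:
    def test_unidentifiable_session_shrinks_to_prior(self, task_config):
        p = RLParamsQ(0.3, 0.3, 0.2, 0.0, 0.0, 0.0)
        sess, _ = simulate_on_policy(p, task_config, 300, seed=21)
        res = fit_session_map(sess, "q_cs", restarts=5, seed=0)
        assert abs(res.params["bias"]) < 0.2
        assert res.ll_per_choice == pytest.approx(np.log(0.5), abs=0.02)

    def test_rates_respect_link_ranges(self, task_config, q_params):
        sess, _ = simulate_on_policy(q_params, task_config, 300, seed=22)
        res = fit_session_map(sess, "q_cs", restarts=5, seed=0)
        for name in ("alpha_rew", "alpha_stay", "gamma_forget"):
            assert 0.0 < res.params[name] < 1.0

    def test_map_beats_coarse_grid_oracle(self, task_config):
        """The MAP fit attains at least the penalized likelihood of the best
        point on a coarse (alpha_rew x beta_rew) grid with the other
        parameters held at truth, and lands near the grid argmax."""
        true = dict(alpha_rew=0.3, alpha_stay=0.3, gamma_forget=0.2,
                    beta_rew=4.0, beta_stay=1.0, bias=0.0)
        sess, _ = simulate_on_policy(
            params_from_dict("q_cs", true), task_config, 1000, seed=33
        )
        bm = BehavioralModel(sess, "q_cs")
        res = bm.fit(restarts=6, seed=0)

        def penalized(vals):
            from revalue.behavior import natural_to_latent

            z = natural_to_latent("q_cs", vals)
            ll, _ = session_log_likelihood(sess, params_from_dict("q_cs", vals))
            return ll - 0.5 * float(z @ z)

        grid_best, argmax = -np.inf, None
        for a in np.linspace(0.05, 0.95, 10):
            for b in np.linspace(0.5, 8.0, 10):
                vals = dict(true, alpha_rew=a, beta_rew=b)
                v = penalized(vals)
                if v > grid_best:
                    grid_best, argmax = v, (a, b)
        map_obj = penalized(res.params)
        assert map_obj >= grid_best - 1e-6
        assert res.params["alpha_rew"] == pytest.approx(argmax[0], abs=0.15)
        assert res.params["beta_rew"] == pytest.approx(argmax[1], abs=1.5)

    def test_accuracy_definitions(self, task_config, q_params):
        sess, _ = simulate_on_policy(q_params, task_config, 400, seed=4)
        res = fit_session_map(sess, "q_cs", restarts=4, seed=0)
        p_right = res.predict()
        manual = np.mean(
            [
                (p_right[i] if t.choice == "R" else 1 - p_right[i]) > 0.5
                for i, t in enumerate(sess.trials)
                if t.completed
            ]
        )
        assert res.accuracy == pytest.approx(manual, abs=1e-12)
        assert 0.0 <= res.accuracy <= 1.0
        assert res.ll_per_choice <= 0.0


class TestComparison:
    def test_compare_models_table(self, task_config, q_params):
        sess, _ = simulate_on_policy(q_params, task_config, 300, seed=6)
        table = compare_models([sess], ["q_cs", "reinforce"], restarts=3, seed=0)
        assert set(table["model"]) == {"q_cs", "reinforce"}
        assert (table["ll_per_choice"] <= 0).all()
        assert table["accuracy"].between(0, 1).all()


class TestKappa:
    @pytest.mark.parametrize("gen_kappa,expected", [(1.0, 1.0), (0.0, 0.0)])
    def test_kappa_recovery(self, task_config, gen_kappa, expected):
        """Sessions where uncollected CS+ updates like collected CS+
        (kappa=1) vs like CS- (kappa=0) yield kappa estimates near the
        generative target."""
        base = RLParamsQ(0.4, 0.2, 0.1, 5.0, 0.5, 0.0)
        gen = KappaParams(base=base, kappa=gen_kappa)
        cfg = TaskConfig(collection_prob=0.5)
        sessions = [
            simulate_on_policy(gen, cfg, 700, seed=40 + i)[0] for i in range(2)
        ]
        table = fit_csplus_value(sessions, seed=0, restarts=5)
        assert table["included"].all()
        # estimates concentrate near the generative target and away from
        # the alternative (1 = collected-CS+ value, 0 = CS- value)
        for est in table["kappa"]:
            assert abs(est - expected) < abs(est - (1.0 - expected))
        assert table["kappa"].mean() == pytest.approx(expected, abs=0.6)

    def test_sessions_without_uncollected_trials_are_excluded(self, task_config, q_params):
        sess, _ = simulate_on_policy(q_params, task_config, 200, seed=50)
        # collection_prob=1 -> no uncollected CS+
        table = fit_csplus_value([sess], seed=0)
        assert not table["included"].iloc[0]
        assert np.isnan(table["kappa"].iloc[0])


class TestHierarchical:
    def test_small_hierarchy_runs_and_summarizes(self, task_config):
        """Desk-scale ensemble MCMC on 2 subjects x 2 sessions: finite
        posterior medians, rates in (0, 1), Rhat reported."""
        from revalue.behavior import fit_hierarchical

        true = dict(alpha_rew=0.4, alpha_stay=0.3, gamma_forget=0.2,
                    beta_rew=3.0, beta_stay=1.0, bias=0.0)
        sessions, subjects = [], []
        for i in range(2):
            for j in range(2):
                s, _ = simulate_on_policy(
                    params_from_dict("q_cs", true), task_config, 150,
                    seed=100 + 10 * i + j,
                )
                sessions.append(s)
                subjects.append(f"m{i}")
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = fit_hierarchical(
                    sessions, subjects, "q_cs", n_steps=150, n_burn=75, seed=0
                )
        assert len(res.session_params) == 4
        for sp in res.session_params:
            for name in ("alpha_rew", "alpha_stay", "gamma_forget"):
                assert 0.0 < sp[name] < 1.0
            assert np.isfinite(sp["beta_rew"])
        assert np.isfinite(res.max_rhat)
        assert "Hierarchical" in res.summary()
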