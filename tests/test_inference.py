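"""Posterior density, NUTS sampler, and convergence diagnostics."""

import arviz as az
import numpy as np
import pandas as pd
import pytest

from pathshade._nuts import sample_nuts
from pathshade._posterior import ChoicePosterior
from pathshade.choice import PathComposition, TrialRecord, choice_probability, cost_difference
from pathshade.model import PathChoiceModel
from pathshade.simulate import (
    SimulationConfig,
    draw_participants,
    generate_choice_set,
    simulate_decisions,
    simulate_study,
    trials_to_frame,
)


def _random_decisions(n=80, J=8, K=2, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "participant_id": [f"P{j:02d}" for j in rng.integers(0, J, n)],
        "trial_id": np.arange(n),
        "choice_set": rng.integers(1, K + 1, n),
        "chose_A": rng.integers(0, 2, n),
        "a_sun_A": rng.uniform(0, 150, n), "a_tree_A": rng.uniform(0, 80, n),
        "a_shade_A": rng.uniform(0, 100, n),
        "a_sun_B": rng.uniform(0, 150, n), "a_tree_B": rng.uniform(0, 80, n),
        "a_shade_B": rng.uniform(0, 100, n),
    })


class TestChoicePosterior:
    def test_gradient_matches_finite_differences(self):
        post, _, _ = ChoicePosterior.from_dataframe(_random_decisions())
        rng = np.random.default_rng(3)
        theta = rng.normal(0, 0.7, post.dim)
        _, grad = post.logp_grad(theta)
        eps = 1e-6
        for i in range(post.dim):
            step = np.zeros(post.dim)
            step[i] = eps
            num = (post.logp_grad(theta + step)[0] - post.logp_grad(theta - step)[0]) / (2 * eps)
            assert grad[i] == pytest.approx(num, rel=1e-4, abs=1e-6)

    def test_beta_prior_mean_is_exp_two_e(self):
        # Gamma(exp(d+e), exp(d-e)) has mean exp(2e); at d=e=0 it is Gamma(1,1)
        cfg = SimulationConfig(n_participants=10, beta_mean=1.0, beta_sd=1.0)
        assert cfg.hyper_e == pytest.approx(0.0)
        assert cfg.hyper_d == pytest.approx(0.0)
        cfg2 = SimulationConfig(beta_mean=np.exp(0.148), beta_sd=0.2)
        assert cfg2.hyper_e == pytest.approx(0.074)

    def test_missing_outcome_and_missing_columns_rejected(self):
        df = _random_decisions()
        with pytest.raises(ValueError, match="missing columns"):
            ChoicePosterior.from_dataframe(df.drop(columns=["a_sun_A"]))
        df.loc[0, "chose_A"] = np.nan
        with pytest.raises(ValueError, match="outcome"):
            ChoicePosterior.from_dataframe(df)

    def test_prior_predictive_choice_rate_for_identical_options(self):
        """Sampling beta_j from the hyperprior and simulating choices between
        identical options gives a marginal choice rate of one half."""
        rng = np.random.default_rng(11)
        d_draw, e_draw = rng.normal(size=2)
        betas = rng.gamma(np.exp(d_draw + e_draw), 1 / np.exp(d_draw - e_draw), size=10000)
        comp = PathComposition(50, 30, 20)
        trial = TrialRecord("P", 1, 1, comp, comp)
        p = np.array([
            choice_probability(cost_difference(trial, b, 0.5) * 0.01, 0.2) for b in betas[:100]
        ])
        assert p == pytest.approx(0.5)
        chosen = rng.uniform(size=10000) < 0.5
        assert chosen.mean() == pytest.approx(0.5, abs=0.02)


class TestNuts:
    def test_recovers_standard_normal_moments(self):
        def lg(theta):
            return -0.5 * float(theta @ theta), -theta

        res = sample_nuts(lg, [np.zeros(3), np.ones(3)], tune=300, draws=800, seed=5)
        flat = res.draws.reshape(-1, 3)
        assert flat.mean(0) == pytest.approx(np.zeros(3), abs=0.1)
        assert flat.var(0) == pytest.approx(np.ones(3), abs=0.15)
        assert res.n_divergent == 0

    def test_metric_adapts_to_anisotropic_scales(self):
        scales = np.array([0.1, 10.0])

        def lg(theta):
            return -0.5 * float((theta / scales) @ (theta / scales)), -theta / scales**2

        res = sample_nuts(lg, [np.zeros(2), np.zeros(2)], tune=600, draws=800, seed=9)
        flat = res.draws.reshape(-1, 2)
        assert flat.std(0) == pytest.approx(scales, rel=0.25)

    def test_identical_seeds_give_identical_draws(self):
        def lg(theta):
            return -0.5 * float(theta @ theta), -theta

        a = sample_nuts(lg, [np.zeros(2)] * 2, tune=100, draws=100, seed=4)
        b = sample_nuts(lg, [np.zeros(2)] * 2, tune=100, draws=100, seed=4)
        assert np.array_equal(a.draws, b.draws)


class TestDiagnostics:
    def test_iid_draws_have_full_effective_sample_size(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal((4, 10000))
        idata = az.from_dict({"x": draws})
        ess = float(az.ess(idata, method="bulk")["x"])
        assert ess == pytest.approx(40000, rel=0.1)
        assert float(az.rhat(idata, method="rank")["x"]) < 1.01

    def test_stuck_chain_flagged_by_rhat(self):
        rng = np.random.default_rng(1)
        draws = rng.standard_normal((4, 1000))
        draws[3, :] = 5.0  # one chain stuck at a constant
        rhat = float(az.rhat(az.from_dict({"x": draws}), method="rank")["x"])
        assert rhat > 1.01

    def test_identical_chains_do_not_blow_up(self):
        draws = np.tile(np.random.default_rng(2).standard_normal(500), (4, 1))
        rhat = float(az.rhat(az.from_dict({"x": draws}), method="rank")["x"])
        assert np.isfinite(rhat)
        assert rhat == pytest.approx(1.0, abs=0.01)

    def test_single_chain_rhat_is_an_error(self, small_fit):
        _, results, _ = small_fit
        single = results.idata.isel(chain=[0])
        from pathshade.model import PathChoiceResults

        broken = PathChoiceResults(model=results.model, idata=single)
        with pytest.raises(ValueError, match="2 chains"):
            broken.diagnostics()


class TestModelFit:
    def test_summary_and_diagnostics_structure(self, small_fit):
        model, results, _ = small_fit
        table = results.summary()
        assert {"mean", "q2.5%", "q97.5%", "rhat", "ess_bulk"} <= set(table.columns)
        assert (table["q2.5%"] <= table["mean"]).all()
        assert (table["mean"] <= table["q97.5%"]).all()
        # bulk ESS can modestly exceed the raw draw count for antithetic
        # NUTS chains, but not by more than a factor ~2
        assert (table["ess_bulk"] <= 2 * (2 * 600)).all()
        assert (table["ess_bulk"] > 0).all()
        assert len([p for p in table.index if p.startswith("beta[")]) == model.n_participants

    def test_moderate_recovery_on_small_cohort(self, small_fit):
        _, results, truth = small_fit
        assert results.population_beta("pooled") == pytest.approx(truth["beta_mean"], abs=0.25)
        tau = results.posterior["tau"].mean(("chain", "draw")).values
        assert tau == pytest.approx(list(truth["tau"].values()), abs=0.1)

    def test_pooled_and_hyper_population_betas_agree_roughly(self, small_fit):
        _, results, _ = small_fit
        assert results.population_beta("pooled") == pytest.approx(
            results.population_beta("hyper"), abs=0.15
        )

    def test_prob_beta_above_bounds(self, small_fit):
        _, results, _ = small_fit
        p = results.prob_beta_above(1.0)
        assert 0.0 <= p <= 1.0
        assert results.prob_beta_above(0.0) == 1.0

    def test_label_swap_symmetry(self):
        """Relabelling A<->B everywhere and flipping outcomes leaves the
        posterior distribution unchanged: the likelihood of every trial is
        invariant, so all summaries agree up to Monte-Carlo error."""
        frame, _ = _label_swap_frames()
        swapped = frame.rename(columns={
            "a_sun_A": "a_sun_B", "a_sun_B": "a_sun_A",
            "a_tree_A": "a_tree_B", "a_tree_B": "a_tree_A",
            "a_shade_A": "a_shade_B", "a_shade_B": "a_shade_A",
        })
        swapped["chose_A"] = 1 - swapped["chose_A"]
        # the log density itself is exactly invariant
        p1, _, _ = ChoicePosterior.from_dataframe(frame)
        p2, _, _ = ChoicePosterior.from_dataframe(swapped)
        theta = np.random.default_rng(12).normal(0, 0.5, p1.dim)
        assert p1.logp_grad(theta)[0] == pytest.approx(p2.logp_grad(theta)[0], rel=1e-12)
        r1 = PathChoiceModel(frame).fit(chains=2, tune=300, draws=800, seed=12)
        r2 = PathChoiceModel(swapped).fit(chains=2, tune=300, draws=800, seed=12)
        # pooled population summaries agree tightly; individual beta_j are
        # noisier (few trials each) so get a wider Monte-Carlo band
        assert r1.population_beta("pooled") == pytest.approx(r2.population_beta("pooled"), abs=0.05)
        b1 = r1.posterior["beta"].mean(("chain", "draw")).values
        b2 = r2.posterior["beta"].mean(("chain", "draw")).values
        assert b1 == pytest.approx(b2, abs=0.25)
        assert float(r1.posterior["rho"].mean()) == pytest.approx(
            float(r2.posterior["rho"].mean()), abs=0.1
        )

    def test_shrinkage_toward_population_for_extreme_participant(self):
        """A participant who always takes the shadier option gets a beta_j
        above the population mean, but finite (pulled back by the pool)."""
        cfg = SimulationConfig(n_participants=20, seed=3)
        frame, _ = simulate_study(cfg)
        frame = frame[~frame["is_test"]].copy()
        pid = "P001"
        mask = frame["participant_id"] == pid
        # force every choice of P001 to the lower-effective-sun option
        sun_A = frame.loc[mask, "a_sun_A"] + 0.5 * frame.loc[mask, "a_tree_A"]
        sun_B = frame.loc[mask, "a_sun_B"] + 0.5 * frame.loc[mask, "a_tree_B"]
        frame.loc[mask, "chose_A"] = (sun_A < sun_B).astype(int)
        res = PathChoiceModel(frame).fit(chains=2, tune=300, draws=400, seed=3)
        extreme = float(res.posterior["beta"].sel(participant=pid).mean())
        population = res.population_beta("pooled")
        assert extreme > population
        assert extreme < 5.0  # no-pooling MLE would diverge; pooling keeps it finite

    def test_zero_length_or_incomplete_tables_rejected(self):
        frame = _random_decisions()
        frame.loc[0, "chose_A"] = np.nan
        with pytest.raises(ValueError):
            PathChoiceModel(frame)


def _label_swap_frames():
    cfg = SimulationConfig(n_participants=12, seed=21)
    rng = np.random.default_rng(21)
    trials = generate_choice_set(cfg, rng)
    betas = draw_participants(cfg, rng)
    done = simulate_decisions(trials, betas, cfg.true_rho, cfg.true_tau, rng)
    frame = trials_to_frame(done)
    return frame[frame["trial_id"] != cfg.test_trial_id], betas
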