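"""Sampler correctness, prior recovery, diagnostics and point estimates."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from hedoseek.choice_models import ChoiceParams, choice_loglik
from hedoseek.inference import (
    PosteriorSamples,
    SamplerConfig,
    build_posterior,
    diagnostics,
    fit_hierarchical,
    point_estimates,
    sample_nuts,
)
from hedoseek.synthetic_cohort import CohortSpec, generate_exp1


def empty_choice_frame():
    return pd.DataFrame(
        columns=["participant_id", "nAccA_c", "nPosA_c", "nAccB_c", "nPosB_c",
                 "EQ", "chose_A"]
    )


class TestGradients:
    """Analytic gradients agree with central finite differences."""

    @pytest.mark.parametrize("model", ["accpos", "acc", "pos", "tiebreak"])
    def test_choice_models(self, model, rng):
        T, n = 30, 3
        df = pd.DataFrame({
            "participant_id": rng.integers(0, n, T),
            "nAccA_c": rng.normal(0, 1, T), "nAccB_c": rng.normal(0, 1, T),
            "nPosA_c": rng.normal(0, 1.5, T), "nPosB_c": rng.normal(0, 1.5, T),
            "EQ": rng.integers(0, 2, T), "chose_A": rng.integers(0, 2, T),
        })
        post = build_posterior(model, df)
        theta = rng.normal(0, 0.7, post.dim)
        _, grad = post.logp_grad(theta)
        eps = 1e-6
        for i in range(post.dim):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            fd = (post.logp_grad(tp)[0] - post.logp_grad(tm)[0]) / (2 * eps)
            assert grad[i] == pytest.approx(fd, abs=2e-5, rel=1e-4)

    @pytest.mark.parametrize("model", ["full", "nopos"])
    def test_belief_models(self, model, rng):
        T, n = 30, 3
        df = pd.DataFrame({
            "participant_id": rng.integers(0, n, T),
            "nAccA_c": rng.normal(0, 0.5, T), "nPosA_c": rng.normal(0, 1.5, T),
            "dir_prediction": rng.integers(0, 2, T),
            "update": rng.normal(8, 10, T),
        })
        post = build_posterior(model, df)
        theta = rng.normal(0, 0.5, post.dim)
        theta[-n:] = np.log(10) + rng.normal(0, 0.2, n)
        _, grad = post.logp_grad(theta)
        eps = 1e-6
        for i in range(post.dim):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            fd = (post.logp_grad(tp)[0] - post.logp_grad(tm)[0]) / (2 * eps)
            assert grad[i] == pytest.approx(fd, abs=2e-5, rel=1e-4)


class TestNuts:
    def test_standard_normal_moments(self):
        rng = np.random.default_rng(1)

        def lg(x):
            return -0.5 * float(x @ x), -x

        draws, stats = sample_nuts(lg, rng.standard_normal(5), 400, 2000, rng)
        assert np.abs(draws.mean(axis=0)).max() < 0.1
        assert np.abs(draws.std(axis=0) - 1.0).max() < 0.1
        assert stats.divergences == 0

    def test_anisotropic_scales_recovered(self):
        rng = np.random.default_rng(2)
        sd = np.array([0.05, 1.0, 20.0])

        def lg(x):
            return -0.5 * float(np.sum((x / sd) ** 2)), -x / sd**2

        draws, _ = sample_nuts(lg, np.zeros(3), 600, 2000, rng)
        assert np.allclose(draws.std(axis=0) / sd, 1.0, atol=0.15)


class TestPriorRecovery:
    """With no observations the posterior must reproduce the hyperpriors."""

    def test_zero_trial_choice_model(self):
        cfg = SamplerConfig(n_chains=2, n_warmup=400, n_draws=1500, seed=3)
        posterior = fit_hierarchical("accpos", empty_choice_frame(), cfg)
        flat = posterior.stacked()
        # direct prior sampling oracle
        rng = np.random.default_rng(10)
        mu_k_direct = rng.normal(0, 1, 20_000)
        mu_b_direct = rng.normal(0, 2, 20_000)
        sig_direct = rng.gamma(1.0, 2.0, 20_000)
        for name, direct in (("mu_kAcc", mu_k_direct), ("mu_kPos", mu_k_direct),
                             ("mu_beta", mu_b_direct)):
            se = direct.std() / np.sqrt(500)  # generous MCMC-ESS allowance
            assert abs(flat[name].mean() - direct.mean()) < 4 * se
        for name in ("sigma_kAcc", "sigma_kPos", "sigma_beta"):
            assert abs(flat[name].mean() - sig_direct.mean()) < 0.3

    def test_flat_data_beta_concentrates_low(self):
        spec = CohortSpec(n_participants=4, experiment=1, model="accpos",
                          random_responder_fraction=1.0, seed=55)
        dataset, _, _ = generate_exp1(spec)
        cfg = SamplerConfig(n_chains=2, n_warmup=300, n_draws=300, seed=4)
        posterior = fit_hierarchical("accpos", dataset, cfg)
        betas = posterior.stacked()["beta"].mean(axis=0)
        assert np.all(betas < 1.5)
        assert betas.mean() < 1.0


class TestDiagnostics:
    def _make(self, draws_by_chain, config=None):
        cfg = config or SamplerConfig(n_chains=2, n_warmup=10, n_draws=draws_by_chain.shape[1], seed=0)
        return PosteriorSamples(
            model="accpos",
            draws={"mu_kAcc": draws_by_chain},
            participant_ids=np.array([]),
            config=cfg,
            dataset_fingerprint="test",
        )

    def test_iid_chains_converged(self):
        rng = np.random.default_rng(5)
        post = self._make(rng.standard_normal((4, 2000)))
        report = diagnostics(post)
        assert report["params"]["mu_kAcc"]["rhat"] <= 1.01
        assert report["converged"]

    def test_shifted_chains_flagged(self):
        rng = np.random.default_rng(6)
        draws = rng.standard_normal((2, 1000))
        draws[1] += 3.0
        report = diagnostics(self._make(draws))
        assert report["params"]["mu_kAcc"]["rhat"] > 1.1
        assert not report["converged"]

    def test_ess_bounded_by_total(self):
        rng = np.random.default_rng(7)
        post = self._make(rng.standard_normal((2, 500)))
        report = diagnostics(post)
        assert report["params"]["mu_kAcc"]["ess"] <= 1000 + 1e-6

    def test_single_chain_errors(self):
        post = PosteriorSamples(
            model="accpos",
            draws={"mu_kAcc": np.zeros((1, 100))},
            participant_ids=np.array([]),
            config=SamplerConfig(n_chains=2, n_warmup=10, n_draws=100, seed=0),
            dataset_fingerprint="x",
        )
        with pytest.raises(ValueError, match="two chains"):
            diagnostics(post)


class TestPointEstimates:
    def test_degenerate_posterior(self):
        c = 1.234
        post = PosteriorSamples(
            model="accpos",
            draws={"mu_kAcc": np.full((2, 50), c),
                   "beta": np.full((2, 50, 3), c)},
            participant_ids=np.array([0, 1, 2]),
            config=SamplerConfig(n_chains=2, n_warmup=10, n_draws=50, seed=0),
            dataset_fingerprint="x",
        )
        table, hyper = point_estimates(post)
        assert np.allclose(table["beta"], c)
        assert hyper.loc[hyper["parameter"] == "mu_kAcc", "estimate"].iloc[0] == pytest.approx(c)

    def test_row_count(self, exp1_posterior):
        table, _ = point_estimates(exp1_posterior)
        assert len(table) == 8

    def test_median_option_and_validation(self, exp1_posterior):
        t_mean, _ = point_estimates(exp1_posterior, stat="mean")
        t_med, _ = point_estimates(exp1_posterior, stat="median")
        assert not np.allclose(t_mean["beta"], t_med["beta"])
        with pytest.raises(ValueError):
            point_estimates(exp1_posterior, stat="mode")

    def test_shrinkage_toward_group_mean(self, exp1_cohort, exp1_posterior):
        """Hierarchical estimates lie closer to the group mean than
        per-participant maximum-likelihood fits (partial pooling)."""
        dataset, _, _ = exp1_cohort
        table, _ = point_estimates(exp1_posterior)
        mles = []
        for pid, df_i in dataset.groupby("participant_id"):
            def nll(x):
                p = ChoiceParams(k_Acc=x[0], k_Pos=x[1],
                                 beta=float(np.clip(x[2], 0, 5)))
                return -choice_loglik("accpos", p, df_i)[0]
            res = minimize(nll, [1.0, 0.5, 1.0], method="Nelder-Mead",
                           options={"maxiter": 600})
            mles.append(res.x)
        mles = np.array(mles)
        post_k = table["k_Acc"].to_numpy()
        spread_post = np.abs(post_k - post_k.mean()).mean()
        spread_mle = np.abs(mles[:, 0] - mles[:, 0].mean()).mean()
        assert spread_post < spread_mle


class TestFitContract:
    def test_convergence_flagged_not_silent(self, exp1_posterior):
        report = diagnostics(exp1_posterior)
        assert "converged" in report and "max_rhat" in report
        assert report["divergences"] == exp1_posterior.divergences

    def test_reproducible_given_seed(self):
        df = empty_choice_frame()
        cfg = SamplerConfig(n_chains=2, n_warmup=100, n_draws=100, seed=42)
        a = fit_hierarchical("acc", df, cfg)
        b = fit_hierarchical("acc", df, cfg)
        for k in a.draws:
            assert np.array_equal(a.draws[k], b.draws[k])

    def test_save_artifacts(self, tmp_path, exp1_posterior):
        exp1_posterior.save(tmp_path / "post")
        assert (tmp_path / "post" / "draws.csv").exists()
        assert (tmp_path / "post" / "diagnostics.json").exists()
        df = pd.read_csv(tmp_path / "post" / "draws.csv")
        assert {"chain", "draw", "mu_kAcc"} <= set(df.columns)
        assert len(df) == exp1_posterior.n_chains * exp1_posterior.n_draws

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SamplerConfig(n_chains=1)
        with pytest.raises(ValueError):
            SamplerConfig(n_draws=0)
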