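"""Variational-Laplace inversion: priors, free energy, ascent behavior."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from rtdcm.inversion import (InversionError, Priors, default_priors,
                             free_energy, invert, invert_callable,
                             summarize_posterior)
from rtdcm.synth import NoiseSpec, simulate_session


def linear_problem(seed=0, N=40, p=3, sigma=0.7):
    """A conjugate linear-Gaussian surrogate with known log evidence."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((N, p))
    theta_true = rng.standard_normal(p)
    y = (X @ theta_true + rng.standard_normal(N) * sigma)[:, None]
    S0 = np.diag(rng.uniform(0.5, 2.0, p))
    mu0 = rng.standard_normal(p) * 0.3
    lam = np.log(1.0 / sigma ** 2)
    priors = Priors(
        theta_names=tuple(f"t{i}" for i in range(p)),
        theta_mean=mu0, theta_cov=S0,
        lambda_mean=np.array([lam]), lambda_var=np.array([0.0]),
        confound_basis="none",
    )

    def predict(Theta):
        return (np.atleast_2d(Theta) @ X.T)[:, :, None]

    logZ = multivariate_normal.logpdf(
        y[:, 0], mean=X @ mu0, cov=sigma ** 2 * np.eye(N) + X @ S0 @ X.T)
    return y, X, priors, predict, float(logZ), sigma


class TestPriors:
    def test_default_priors_are_zero_mean_shrinkage(self, pair_skeletons):
        sk_l, _ = pair_skeletons
        pri = default_priors(sk_l)
        np.testing.assert_array_equal(pri.theta_mean, 0.0)
        assert np.all(np.diag(pri.theta_cov) > 0)

    def test_pair_gets_identical_A_and_C_priors(self, pair_skeletons):
        # two models differing only in B placement share A/C priors
        sk_l, sk_r = pair_skeletons
        pl, pr = default_priors(sk_l), default_priors(sk_r)
        a_l = [v for n, v in zip(pl.theta_names, np.diag(pl.theta_cov))
               if n.startswith("A")]
        a_r = [v for n, v in zip(pr.theta_names, np.diag(pr.theta_cov))
               if n.startswith("A")]
        assert a_l == a_r
        assert len(a_l) == 4

    def test_nonpsd_prior_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            Priors(theta_names=("a",), theta_mean=np.zeros(1),
                   theta_cov=-np.eye(1), lambda_mean=np.zeros(1),
                   lambda_var=np.zeros(1))


class TestFreeEnergy:
    def test_matches_conjugate_closed_form(self):
        y, X, priors, predict, logZ, sigma = linear_problem()
        res = invert_callable(y, predict, priors, max_iter=200, tol=1e-12,
                              damping=1e-6)
        assert abs(res.F - logZ) < 1e-6

    def test_exact_posterior_matches_closed_form(self):
        y, X, priors, predict, logZ, sigma = linear_problem(seed=3)
        S0inv = np.linalg.inv(priors.theta_cov)
        H = S0inv + X.T @ X / sigma ** 2
        Sig = np.linalg.inv(H)
        mu = Sig @ (S0inv @ priors.theta_mean + X.T @ y[:, 0] / sigma ** 2)
        F = free_energy(y, predict, mu, Sig, priors.lambda_mean, priors)
        assert abs(F - logZ) < 1e-6

    def test_duplicated_data_doubles_accuracy(self):
        # with q = prior (KL = 0) and no confounds, F is the pure accuracy
        # term, which is additive over stacked observations
        y, X, priors, predict, logZ, sigma = linear_problem(seed=5)

        def predict2(Theta):
            g = predict(Theta)
            return np.concatenate([g, g], axis=1)

        F1 = invert_callable(y, predict, priors, max_iter=0).F
        F2 = invert_callable(np.vstack([y, y]), predict2, priors,
                             max_iter=0).F
        np.testing.assert_allclose(F2, 2.0 * F1, rtol=1e-9)

    def test_nonpsd_posterior_cov_rejected(self):
        y, X, priors, predict, *_ = linear_problem()
        with pytest.raises(ValueError, match="PSD"):
            free_energy(y, predict, priors.theta_mean, -np.eye(3),
                        priors.lambda_mean, priors)


class TestAscent:
    def test_zero_budget_returns_prior(self, pair_skeletons, trial_design):
        sk_l, _ = pair_skeletons
        series, _ = simulate_session(trial_design, NoiseSpec(), seed=0)
        win = series.values[:90] - 100.0
        wdes = trial_design.window(0, 90).collapse_inputs()
        res = invert(win, wdes, sk_l, max_iter=0)
        pri = default_priors(sk_l)
        np.testing.assert_array_equal(res.posterior_mean, pri.theta_mean)
        np.testing.assert_array_equal(res.posterior_cov, pri.theta_cov)
        assert not res.converged
        assert res.n_iterations == 0

    def test_default_cap_is_44(self):
        from rtdcm.inversion import DEFAULT_MAX_ITER
        assert DEFAULT_MAX_ITER == 44

    def test_trajectory_monotone_and_deterministic(self, pair_skeletons,
                                                   trial_design):
        sk_l, _ = pair_skeletons
        series, _ = simulate_session(trial_design, NoiseSpec(), seed=11)
        win = series.values[:90] - 100.0
        wdes = trial_design.window(0, 90).collapse_inputs()
        r1 = invert(win, wdes, sk_l)
        r2 = invert(win, wdes, sk_l)
        assert r1.F == r2.F  # bit-identical, no internal randomness
        np.testing.assert_array_equal(r1.F_trajectory, r2.F_trajectory)
        assert np.all(np.diff(r1.F_trajectory) >= -0.05)
        assert r1.n_iterations <= 44
        assert np.isfinite(r1.F)

    def test_short_window_warns(self, pair_skeletons, trial_design):
        sk_l, _ = pair_skeletons
        series, _ = simulate_session(trial_design, NoiseSpec(), seed=1)
        wdes = trial_design.window(0, 12).collapse_inputs()
        with pytest.warns(UserWarning, match="short"):
            invert(series.values[:12] - 100.0, wdes, sk_l, max_iter=1)

    def test_nonfinite_data_rejected(self, pair_skeletons, trial_design):
        sk_l, _ = pair_skeletons
        wdes = trial_design.window(0, 90).collapse_inputs()
        bad = np.zeros((90, 4))
        bad[3, 2] = np.nan
        with pytest.raises(InversionError, match="non-finite"):
            invert(bad, wdes, sk_l)


class TestSummarizePosterior:
    def test_symmetric_mass_at_zero_mean(self):
        res = _result(mean=[0.0], var=[1.0])
        assert summarize_posterior(res)["p0"][1] == pytest.approx(0.5)

    def test_gaussian_tail(self):
        res = _result(mean=[1.96], var=[1.0])
        assert summarize_posterior(res)["p0"][1] == pytest.approx(0.975,
                                                                  abs=1e-3)

    def test_degenerate_posterior_is_exact(self):
        res = _result(mean=[0.3, 0.0], var=[0.0, 0.0])
        s = summarize_posterior(res, threshold=0.1)
        assert s["p0"][1] == 1.0
        assert s["p1"][1] == 0.0


def _result(mean, var):
    from rtdcm.inversion import InversionResult
    mean = np.asarray(mean, dtype=float)
    return InversionResult(
        theta_names=tuple(f"p{i}" for i in range(mean.size)),
        posterior_mean=mean,
        posterior_cov=np.diag(var),
        lambda_post=np.zeros(1), lambda_var=np.zeros(1),
        F=0.0, n_iterations=1, converged=True,
        F_trajectory=np.zeros(1),
    )
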