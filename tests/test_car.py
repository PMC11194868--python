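import numpy as np
import pytest
from scipy import stats as sps

from spatialprev.car import (
    CarModelSpec,
    McmcChains,
    _run_leroux,
    compute_waic,
    fit_car_leroux,
    fit_car_localised,
    geweke_diagnostic,
    posterior_summary,
)
from spatialprev.graph import generate_lattice
from spatialprev.synthetic import (
    SyntheticTruth,
    default_truth,
    simulate_counts,
    simulate_covariates,
)
from spatialprev.weights import build_weights

FAST = {"n_iter": 3000, "burn_in": 1000, "thin": 4}


def _simulated(rows=20, cols=20, seed=0, **truth_kwargs):
    g = generate_lattice(rows, cols)
    w = build_weights(g, "binary")
    t = simulate_covariates(g, seed=seed)
    truth = default_truth(t, w, seed=seed, **truth_kwargs)
    return simulate_counts(t, truth, seed=seed + 1), w, truth


class TestLeroux:
    def test_retained_draw_count(self):
        tab, w, _ = _simulated(6, 6, seed=1, rho=0.5, tau2=0.02)
        spec = CarModelSpec(n_iter=900, burn_in=300, thin=3, seed=0)
        ch = fit_car_leroux(tab, w, spec)
        assert ch.beta.shape[0] == 200
        assert ch.phi.shape == (200, 36)
        assert ch.loglik.shape == (200, 36)

    def test_beta_matches_glm_oracle_when_no_random_effects(self):
        """With phi = 0 in the truth, the posterior mean of beta should sit
        within 2 posterior SDs of the Poisson-GLM maximum likelihood
        estimate from statsmodels (an independent IRLS implementation)."""
        import statsmodels.api as sm

        g = generate_lattice(20, 20)
        w = build_weights(g, "binary")
        t = simulate_covariates(g, seed=5)
        truth = default_truth(t, w, seed=5, rho=0.0, tau2=1e-8)
        truth.phi[:] = 0.0
        tab = simulate_counts(t, truth, seed=6)

        spec = CarModelSpec(n_iter=8000, burn_in=3000, thin=5, seed=2)
        ch = fit_car_leroux(tab, w, spec)

        from spatialprev.design import build_design

        X, names = build_design(tab, include_intercept=True)
        glm = sm.GLM(
            tab["asthma_count"].to_numpy(),
            X,
            family=sm.families.Poisson(),
            offset=np.log(tab["child_pop"].to_numpy()),
        ).fit()
        post_mean = ch.beta.mean(axis=0)
        post_sd = ch.beta.std(axis=0)
        # phi soaks a little residual noise, so compare effects (not the
        # intercept, which trades off against the random-effect mean)
        for j in range(1, len(names)):
            assert abs(post_mean[j] - glm.params[j]) < 2 * post_sd[j] + 0.01, names[j]

    def test_deterministic_chains(self):
        tab, w, _ = _simulated(8, 8, seed=3, rho=0.5, tau2=0.02)
        ch1 = fit_car_leroux(tab, w, CarModelSpec(seed=11, **FAST))
        ch2 = fit_car_leroux(tab, w, CarModelSpec(seed=11, **FAST))
        assert np.array_equal(ch1.beta, ch2.beta)
        assert np.array_equal(ch1.phi, ch2.phi)
        assert np.array_equal(ch1.rho, ch2.rho)

    def test_gibbs_matches_exact_joint_on_path3(self, path3):
        """Prior-only Gibbs at fixed (rho, tau2) on a 3-node path must
        reproduce the exact N(0, Q^-1) joint moments."""
        w = build_weights(path3, "binary")
        rho, tau2 = 0.9, 1.0
        spec = CarModelSpec(
            n_iter=60_000,
            burn_in=5_000,
            thin=2,
            prior_only=True,
            fix_rho=rho,
            fix_tau2=tau2,
            seed=8,
        )
        ch = _run_leroux(
            np.zeros(3), np.zeros(3), np.ones((3, 1)), ["intercept"], w, spec
        )
        D = np.diag([1.0, 2.0, 1.0])
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
        C = np.linalg.inv((rho * (D - A) + (1 - rho) * np.eye(3)) / tau2)
        emp = np.cov(ch.phi.T)
        # Gibbs draws are autocorrelated: allow a generous Monte-Carlo band
        n_eff = ch.phi.shape[0] / 10
        se = np.sqrt((np.outer(np.diag(C), np.diag(C)) + C**2) / n_eff)
        assert (np.abs(emp - C) < 4 * se).all()

    def test_prior_only_recovers_stated_priors(self, grid33):
        """Likelihood switched off: tau2 draws match Inverse-Gamma(1, 0.01)
        and rho draws match Uniform(0, 1) (goodness of fit at the 1% level)."""
        w = build_weights(grid33, "binary")
        spec = CarModelSpec(
            n_iter=30_000, burn_in=5_000, thin=10, prior_only=True, seed=3
        )
        ch = _run_leroux(
            np.zeros(9), np.zeros(9), np.ones((9, 1)), ["intercept"], w, spec
        )
        # 1/tau2 ~ Gamma(shape 1, rate 0.01)
        ks_tau = sps.kstest(1.0 / ch.sigma2, sps.gamma(a=1.0, scale=100.0).cdf)
        ks_rho = sps.kstest(ch.rho, "uniform")
        assert ks_tau.pvalue > 0.01
        assert ks_rho.pvalue > 0.01

    def test_rho_zero_matches_iid_random_effect_oracle(self):
        """Leroux with rho fixed at 0 is an iid-random-effect Poisson model;
        its beta posterior must agree with a minimal independent
        Metropolis-within-Gibbs sampler for that model."""
        tab, w, _ = _simulated(10, 10, seed=9, rho=0.0, tau2=0.02)
        spec = CarModelSpec(
            n_iter=10_000, burn_in=3_000, thin=7, fix_rho=0.0, seed=4
        )
        ch = fit_car_leroux(tab, w, spec)

        # ---- oracle: plain iid random-effect sampler, coded independently
        from spatialprev.design import build_design

        y = tab["asthma_count"].to_numpy(float)
        logE = np.log(tab["child_pop"].to_numpy(float))
        X, _ = build_design(tab, include_intercept=True)
        rng = np.random.default_rng(123)
        n, p = X.shape
        beta = np.zeros(p)
        beta[0] = np.log(y.sum() / np.exp(logE).sum())
        u = np.zeros(n)
        s2 = 0.01
        keep = []
        for it in range(13_000):
            for j in range(p):
                prop = beta.copy()
                prop[j] += 0.02 * rng.standard_normal()
                e0 = logE + X @ beta + u
                e1 = logE + X @ prop + u
                d = np.sum(y * (e1 - e0) - (np.exp(e1) - np.exp(e0)))
                d += -0.5 * (prop[j] ** 2 - beta[j] ** 2) / 1e5
                if np.log(rng.random()) < d:
                    beta = prop
            pu = u + 0.1 * rng.standard_normal(n)
            e0 = logE + X @ beta + u
            e1 = logE + X @ beta + pu
            d = y * (e1 - e0) - (np.exp(e1) - np.exp(e0)) - 0.5 * (pu**2 - u**2) / s2
            u = np.where(np.log(rng.random(n)) < d, pu, u)
            m = u.mean()
            u -= m
            beta[0] += m
            s2 = 1.0 / rng.gamma(1.0 + n / 2, 1.0 / (0.01 + 0.5 * u @ u))
            if it >= 3000 and it % 5 == 0:
                keep.append(beta.copy())
        oracle = np.array(keep)
        om, osd = oracle.mean(axis=0), oracle.std(axis=0)
        pm, psd = ch.beta.mean(axis=0), ch.beta.std(axis=0)
        for j in range(1, p):
            tol = 2 * np.sqrt(osd[j] ** 2 + psd[j] ** 2)
            assert abs(pm[j] - om[j]) < tol + 0.01, j


class TestLocalised:
    def test_lambda_ordered_in_every_draw(self):
        tab, w, _ = _simulated(8, 8, seed=2, rho=0.5, tau2=0.02)
        ch = fit_car_localised(tab, w, CarModelSpec(G=3, seed=1, **FAST))
        assert (np.diff(ch.lam, axis=1) > 0).all()
        assert ch.Z.min() >= 1 and ch.Z.max() <= 3

    def test_occupied_classes_bounded_on_homogeneous_data(self):
        tab, w, _ = _simulated(8, 8, seed=4, rho=0.0, tau2=1e-4)
        ch = fit_car_localised(tab, w, CarModelSpec(G=5, seed=2, **FAST))
        occupied = [(np.bincount(z, minlength=6)[1:] > 0).sum() for z in ch.Z]
        assert max(occupied) <= 5

    def test_prior_only_recovers_delta_and_sigma2(self):
        from spatialprev.car import _run_localised

        n = 16
        spec = CarModelSpec(
            n_iter=30_000, burn_in=5_000, thin=10, G=5, prior_only=True, seed=5
        )
        ch = _run_localised(np.zeros(n), np.zeros(n), np.ones((n, 1)), ["x"], spec)
        assert sps.kstest(ch.delta, sps.uniform(1, 9).cdf).pvalue > 0.01
        assert (
            sps.kstest(1.0 / ch.sigma2, sps.gamma(a=1.0, scale=100.0).cdf).pvalue
            > 0.01
        )

    def test_block_recovery_two_well_separated_blocks(self):
        """Two contiguous intensity blocks, fit with G = 3: the modal
        partition should group >= 90% of areas with their true block."""
        from spatialprev.synthetic import sample_localised_structure

        g = generate_lattice(20, 20)
        w = build_weights(g, "binary")
        assign, lam = sample_localised_structure(g, G=2, seed=0, spacing=0.6)
        t = simulate_covariates(g, seed=0)
        truth = default_truth(
            t, w, seed=0, rho=0.0, tau2=1e-4, clusters=(assign, lam)
        )
        tab = simulate_counts(t, truth, seed=100)
        ch = fit_car_localised(
            tab, w, CarModelSpec(n_iter=12_000, burn_in=4_000, thin=8, G=3, seed=1)
        )
        modal = sps.mode(ch.Z, axis=0).mode
        correct = 0
        for c in np.unique(modal):
            members = assign[modal == c]
            correct += (members == sps.mode(members).mode).sum()
        assert correct / len(assign) >= 0.9

    def test_deterministic_chains(self):
        tab, w, _ = _simulated(8, 8, seed=6, rho=0.5, tau2=0.02)
        ch1 = fit_car_localised(tab, w, CarModelSpec(G=3, seed=7, **FAST))
        ch2 = fit_car_localised(tab, w, CarModelSpec(G=3, seed=7, **FAST))
        assert np.array_equal(ch1.beta, ch2.beta)
        assert np.array_equal(ch1.Z, ch2.Z)

    def test_invalid_g(self):
        tab, w, _ = _simulated(6, 6, seed=0, rho=0.5, tau2=0.02)
        with pytest.raises(ValueError):
            fit_car_localised(tab, w, CarModelSpec(G=1, **FAST))


def _chains_from_loglik(ll):
    S = ll.shape[0]
    return McmcChains(
        model="leroux",
        param_names=["intercept"],
        beta=np.zeros((S, 1)),
        phi=np.zeros((S, 1)),
        sigma2=np.ones(S),
        loglik=ll,
    )


class TestWaic:
    def test_identical_draws_have_zero_penalty(self):
        ll = np.tile([-3.0, -4.0, -5.0], (10, 1))
        res = compute_waic(_chains_from_loglik(ll))
        assert res.p_waic == pytest.approx(0.0)
        assert res.waic == pytest.approx(-2 * ll[0].sum())

    def test_stable_for_very_negative_loglik(self):
        ll = np.full((50, 4), -700.0) + np.random.default_rng(0).normal(
            0, 0.1, (50, 4)
        )
        res = compute_waic(_chains_from_loglik(ll))
        assert np.isfinite(res.waic)

    def test_needs_two_draws(self):
        with pytest.raises(ValueError):
            compute_waic(_chains_from_loglik(np.zeros((1, 3))))

    def test_matches_direct_formula(self, rng):
        ll = rng.normal(-10, 1, size=(200, 7))
        res = compute_waic(_chains_from_loglik(ll))
        lppd = np.log(np.exp(ll).mean(axis=0)).sum()
        p = ll.var(axis=0, ddof=1).sum()
        assert res.lppd == pytest.approx(lppd)
        assert res.waic == pytest.approx(-2 * (lppd - p))


class TestGeweke:
    def test_calibrated_on_iid_chains(self):
        rng = np.random.default_rng(77)
        zs = np.array(
            [geweke_diagnostic(rng.standard_normal(10_000)) for _ in range(1000)]
        )
        rate = np.mean(np.abs(zs) > 1.96)
        se = np.sqrt(0.05 * 0.95 / 1000)
        assert abs(rate - 0.05) < 3 * se

    def test_trend_inflates_z(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(5000)
        z_small = abs(geweke_diagnostic(base + np.linspace(0, 0.5, 5000)))
        z_large = abs(geweke_diagnostic(base + np.linspace(0, 5.0, 5000)))
        assert z_large > z_small
        assert z_large > 1.96

    def test_constant_chain_warns_not_silent(self):
        with pytest.warns(UserWarning, match="constant"):
            z = geweke_diagnostic(np.ones(500))
        assert np.isnan(z)

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            geweke_diagnostic(np.arange(50.0))


class TestPosteriorSummary:
    def _chains(self, draws_by_name):
        names = list(draws_by_name)
        beta = np.column_stack([draws_by_name[n] for n in names])
        S = beta.shape[0]
        return McmcChains(
            model="leroux",
            param_names=names,
            beta=beta,
            phi=np.zeros((S, 1)),
            sigma2=np.ones(S),
            loglik=np.zeros((S, 1)),
        )

    def test_constant_coefficient_pr(self):
        with pytest.warns(UserWarning):  # constant chain -> degenerate Geweke
            summ = posterior_summary(
                self._chains({"most_disadvantaged": np.full(200, 0.0953)}),
                include_reference=False,
            )
        row = summ[summ.variable == "most_disadvantaged"].iloc[0]
        assert round(row["PR"], 2) == 1.10

    def test_reference_rows_printed_as_unity(self):
        rng = np.random.default_rng(0)
        summ = posterior_summary(
            self._chains(
                {
                    "advantaged": rng.normal(0, 0.1, 300),
                    "indigenous_high": rng.normal(0.1, 0.1, 300),
                }
            )
        )
        refs = summ[summ.variable.str.contains("ref")]
        assert len(refs) == 2
        assert (refs["PR"] == 1.0).all()
        assert refs["PR_low"].isna().all()

    def test_quantiles_match_interpolation_oracle(self, rng):
        draws = rng.normal(0.05, 0.02, size=501)
        summ = posterior_summary(
            self._chains({"disadvantaged": draws}), include_reference=False
        )
        row = summ.iloc[0]

        def quantile_oracle(x, q):
            # sort-based linear interpolation, coded independently
            s = np.sort(x)
            pos = q * (len(s) - 1)
            lo = int(np.floor(pos))
            hi = int(np.ceil(pos))
            return s[lo] + (pos - lo) * (s[hi] - s[lo])

        assert row["q2.5"] == pytest.approx(quantile_oracle(draws, 0.025))
        assert row["median"] == pytest.approx(quantile_oracle(draws, 0.5))
        assert row["q97.5"] == pytest.approx(quantile_oracle(draws, 0.975))
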