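"""Asymmetric-Laplace primitives, posterior density, sampler, HDI and ROPE."""

import warnings

import numpy as np
import pytest
from scipy import integrate, stats

from frostdrought import simulate, trees
from frostdrought.quantreg import (
    QRData, QRSpec, al_logpdf, al_rvs, check_loss, fit_qr_mcmc,
    group_line_fit, hdi, log_posterior, rhat_ess, rope_decision,
    _prior_scales,
)


class TestCheckLoss:
    @pytest.mark.parametrize("u,tau,want", [
        (1.0, 0.9, 0.9), (-1.0, 0.9, 0.1), (0.0, 0.3, 0.0),
        (2.0, 0.5, 1.0), (-2.0, 0.5, 1.0),
    ])
    def test_values(self, u, tau, want):
        assert check_loss(u, tau) == pytest.approx(want)

    def test_median_case_is_half_abs(self, rng):
        u = rng.normal(size=50)
        np.testing.assert_allclose(check_loss(u, 0.5), np.abs(u) / 2)


class TestAlDensity:
    def test_mode_value(self):
        assert al_logpdf(0.0, 0.0, 1.0, 0.5) == pytest.approx(np.log(0.25))

    def test_integrates_to_one(self):
        # tau = 0.1: the heavy tail is on the right (scale sigma/tau = 20)
        val, _ = integrate.quad(
            lambda y: np.exp(al_logpdf(y, 0.0, 2.0, 0.1)), -100, 400,
            limit=400)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_median_case_matches_laplace(self, rng):
        y = rng.normal(size=20)
        want = stats.laplace.logpdf(y, loc=0.3, scale=2.0)
        np.testing.assert_allclose(al_logpdf(y, 0.3, 1.0, 0.5), want,
                                   rtol=1e-12)

    def test_nonpositive_sigma_errors(self):
        with pytest.raises(ValueError):
            al_logpdf(0.0, 0.0, 0.0, 0.5)

    @pytest.mark.parametrize("tau", [0.1, 0.5, 0.9])
    def test_rvs_quantile_placement(self, tau, rng):
        draws = al_rvs(rng, 200_000, sigma=2.0, tau=tau)
        assert np.mean(draws < 0) == pytest.approx(tau, abs=0.005)


class TestLogPosterior:
    def _tiny_data(self, phylo: bool):
        tree = trees.read_newick(
            "((A:1,B:1):1,(C:0.5,D:0.5):1.5,E:2);")
        C = trees.vcv(tree)
        y = np.array([1.0, 2.0, -1.0, 0.5, 3.0])
        x = np.array([0.2, -0.3, 1.0, 0.0, -1.2])
        g = np.array(["gymnosperm", "gymnosperm", "evergreen_angiosperm",
                      "evergreen_angiosperm", "gymnosperm"])
        return QRData(y=y, x=x, group=g, C=C if phylo else None,
                      species=tuple(C.species) if phylo else None)

    @pytest.mark.parametrize("phylo", [False, True])
    def test_matches_term_by_term_oracle(self, phylo):
        """Literal term-by-term evaluation of likelihood + priors."""
        data = self._tiny_data(phylo)
        spec = QRSpec(tau=0.3, phylo=phylo, iterations=10, warmup=1)
        params = {"alpha": np.array([0.5, -0.2]), "beta": np.array([1.1, 0.3]),
                  "sigma": 0.8}
        if phylo:
            params["sigma_p"] = 0.6
            params["u"] = np.array([0.1, -0.2, 0.05, 0.0, 0.15])
        got = log_posterior(params, data, spec)

        # independent evaluation, written out literally
        tau, sigma = 0.3, 0.8
        gi = {"evergreen_angiosperm": 0, "gymnosperm": 1}
        want = 0.0
        for i in range(5):
            k = gi[data.group[i]]
            mu = params["alpha"][k] + params["beta"][k] * data.x[i]
            if phylo:
                mu += params["u"][i]
            u_res = (data.y[i] - mu) / sigma
            rho = u_res * (tau - (1 if u_res < 0 else 0))
            want += np.log(tau * (1 - tau) / sigma) - rho
        scales = _prior_scales(data.y, data.x, spec)
        for k in range(2):
            want += stats.norm.logpdf(params["alpha"][k], 0, scales["alpha"])
            want += stats.norm.logpdf(params["beta"][k], 0, scales["beta"])
        want += (stats.t.logpdf(sigma / scales["sigma"], df=3)
                 + np.log(2) - np.log(scales["sigma"]))
        if phylo:
            Cs = data.C.standardized().matrix
            want += stats.multivariate_normal.logpdf(
                params["u"], np.zeros(5), params["sigma_p"] ** 2 * Cs)
            want += stats.halfnorm.logpdf(params["sigma_p"],
                                          scale=scales["sigma_p"])
        assert got == pytest.approx(want, abs=1e-10)

    def test_invalid_sigma_is_rejected_not_raised(self):
        data = self._tiny_data(False)
        spec = QRSpec(tau=0.3, iterations=10, warmup=1)
        bad = {"alpha": np.zeros(2), "beta": np.zeros(2), "sigma": -1.0}
        assert log_posterior(bad, data, spec) == -np.inf


class TestHdi:
    def brute_force(self, draws, mass):
        s = np.sort(draws)
        m = int(np.ceil(mass * len(s)))
        best = (np.inf, None)
        for i in range(len(s) - m + 1):
            w = s[i + m - 1] - s[i]
            if w < best[0]:
                best = (w, (s[i], s[i + m - 1]))
        return best[1]

    @pytest.mark.parametrize("dist", ["normal", "exponential", "mixture"])
    def test_matches_brute_force(self, dist, rng):
        draws = {"normal": rng.normal(size=500),
                 "exponential": rng.exponential(size=500),
                 "mixture": np.concatenate([rng.normal(size=300),
                                            rng.normal(5, 0.5, 200)])}[dist]
        assert hdi(draws, 0.9) == pytest.approx(self.brute_force(draws, 0.9))

    def test_normal_large_sample(self, rng):
        lo, hi = hdi(rng.normal(size=100_000), 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_exponential_starts_at_minimum(self, rng):
        draws = rng.exponential(size=5000)
        lo, hi = hdi(draws, 0.95)
        assert lo == pytest.approx(draws.min(), abs=1e-12)

    def test_constant_draws_zero_width(self):
        lo, hi = hdi(np.full(200, 3.3), 0.95)
        assert lo == hi == 3.3

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            hdi(np.arange(50), 0.95)

    def test_matches_arviz(self, rng):
        draws = rng.gamma(2.0, size=4000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            import arviz as az
            want = az.hdi(draws, hdi_prob=0.95)
        # arviz sizes the window with floor(mass*N) rather than ceil, so
        # endpoints may differ by one order statistic
        got = hdi(draws, 0.95)
        assert got[0] == pytest.approx(want[0], abs=0.05)
        assert got[1] == pytest.approx(want[1], abs=0.05)


class TestRope:
    # y with sample SD exactly 10 -> ROPE = [-1, 1]
    y10 = np.array([-10.0, 0.0, 10.0])

    def test_rope_bounds_exact(self, rng):
        res = rope_decision(rng.normal(5, 0.1, 1000), self.y10)
        assert (res.rope_lo, res.rope_hi) == (-1.0, 1.0)

    def test_outside(self, rng):
        res = rope_decision(rng.uniform(-3.0, -1.5, 2000), self.y10)
        assert res.verdict == "outside_rope"

    def test_inside(self, rng):
        res = rope_decision(rng.uniform(-0.5, 0.4, 2000), self.y10)
        assert res.verdict == "inside_rope"

    def test_overlapping(self, rng):
        res = rope_decision(rng.uniform(-1.5, 0.5, 2000), self.y10)
        assert res.verdict == "overlapping"

    def test_constant_y_errors(self, rng):
        with pytest.raises(ValueError):
            rope_decision(rng.normal(size=200), np.ones(5))


class TestRhatEss:
    def test_well_mixed_chains(self, rng):
        chains = rng.normal(size=(4, 1000))
        r, e = rhat_ess(chains)
        assert r < 1.01
        assert e > 400

    def test_shifted_chains_flagged(self, rng):
        chains = rng.normal(size=(4, 500))
        chains[0] += 5.0
        r, _ = rhat_ess(chains)
        assert r > 1.5

    def test_single_chain_errors(self, rng):
        with pytest.raises(ValueError):
            rhat_ess(rng.normal(size=(1, 500)))


class TestGroupLineFit:
    def test_exact_line(self):
        x = np.arange(10.0)
        df = group_line_fit(2 * x + 1, x, np.repeat("gymnosperm", 10))
        assert df["slope"].iloc[0] == pytest.approx(2.0)
        assert df["r2"].iloc[0] == pytest.approx(1.0)

    def test_small_group_skipped_with_warning(self, rng):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        g = np.array(["a", "a", "a", "a", "b"])
        with pytest.warns(RuntimeWarning, match="fewer than 3"):
            df = group_line_fit(x, x, g)
        assert list(df["group"]) == ["a"]

    def test_constant_x_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            group_line_fit(np.arange(4.0), np.ones(4), np.repeat("a", 4))


class TestSampler:
    def test_recovers_slope_and_quantile(self, rng):
        """y = 2 - 1.5 x + AL noise: slope recovered, HDI covers truth,
        and the fitted tau-line leaves the right fraction below it."""
        x = rng.normal(0, 2, 300)
        y = 2.0 - 1.5 * x + al_rvs(rng, 300, 1.0, 0.5)
        g = np.repeat("gymnosperm", 300)
        spec = QRSpec(tau=0.5, chains=2, iterations=1500, warmup=500, seed=3,
                      diagnostics=False)
        post = fit_qr_mcmc(QRData(y=y, x=x, group=g), spec)
        b = post.beta("gymnosperm")
        assert -1.7 < b.mean() < -1.3
        lo, hi = hdi(b)
        assert lo <= -1.5 <= hi

    def test_tau01_residual_fraction(self, rng):
        x = rng.normal(0, 2, 500)
        y = 2.0 - 1.5 * x + al_rvs(rng, 500, 1.0, 0.1)
        g = np.repeat("gymnosperm", 500)
        spec = QRSpec(tau=0.1, chains=2, iterations=1500, warmup=500, seed=4,
                      diagnostics=False)
        data = QRData(y=y, x=x, group=g)
        post = fit_qr_mcmc(data, spec)
        frac = np.mean(y < post.fitted_quantile(data))
        assert frac == pytest.approx(0.1, abs=0.04)

    def test_scale_equivariance(self, rng):
        """Scaling y by c scales slope posterior and ROPE by c; verdicts
        unchanged (checked at MCMC precision)."""
        x = rng.normal(0, 2, 200)
        y = 1.0 + 2.0 * x + al_rvs(rng, 200, 1.0, 0.5)
        g = np.repeat("gymnosperm", 200)
        spec = QRSpec(tau=0.5, chains=2, iterations=1200, warmup=400, seed=5,
                      diagnostics=False)
        p1 = fit_qr_mcmc(QRData(y=y, x=x, group=g), spec)
        p2 = fit_qr_mcmc(QRData(y=10 * y, x=x, group=g), spec)
        b1, b2 = p1.beta("gymnosperm"), p2.beta("gymnosperm")
        assert b2.mean() == pytest.approx(10 * b1.mean(), rel=0.05)
        r1 = rope_decision(b1, y)
        r2 = rope_decision(b2, 10 * y)
        assert r2.rope_hi == pytest.approx(10 * r1.rope_hi)
        assert r1.verdict == r2.verdict

    def test_group_minimum_size_enforced(self, rng):
        y = rng.normal(size=15)
        x = rng.normal(size=15)
        g = np.array(["gymnosperm"] * 12 + ["evergreen_angiosperm"] * 3)
        with pytest.raises(ValueError, match="fewer than 10"):
            fit_qr_mcmc(QRData(y=y, x=x, group=g), QRSpec(iterations=100,
                                                          warmup=10))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            QRSpec(tau=1.2)
        with pytest.raises(ValueError):
            QRSpec(warmup=100, iterations=100)
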