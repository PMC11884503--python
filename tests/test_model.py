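import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, special, stats

import brcapool as bp
from brcapool.model import from_unconstrained, log_jacobian, to_unconstrained

_props = st.floats(0.02, 0.98)
_kappas = st.floats(0.1, 50.0)


class TestBetaProportion:
    def test_uniform_case_is_flat(self):
        # mu=0.5, kappa=2 is Beta(1,1)
        assert bp.beta_proportion_logpdf(0.3, 0.5, 2.0) == pytest.approx(0.0, abs=1e-12)

    def test_beta22_closed_form(self):
        # Beta(2,2) density 6x(1-x); at 0.5 equals 1.5
        assert bp.beta_proportion_logpdf(0.5, 0.5, 4.0) == pytest.approx(np.log(1.5), abs=1e-12)

    @given(x=_props, mu=_props, kappa=_kappas)
    def test_mirror_symmetry(self, x, mu, kappa):
        left = bp.beta_proportion_logpdf(x, mu, kappa)
        right = bp.beta_proportion_logpdf(1.0 - x, 1.0 - mu, kappa)
        assert left == pytest.approx(right, rel=1e-9, abs=1e-9)

    @given(mu=_props, kappa=_kappas)
    def test_integrates_to_one(self, mu, kappa):
        # endpoint singularities (shapes < 1) are handled by QUADPACK's
        # algebraic weight x^(a-1) (1-x)^(b-1); the remaining factor of the
        # density is the constant 1/B(a, b)
        a, b = mu * kappa, (1.0 - mu) * kappa
        const = np.exp(bp.beta_proportion_logpdf(0.5, mu, kappa)) / (
            0.5 ** (a - 1.0) * 0.5 ** (b - 1.0)
        )
        val, _ = integrate.quad(
            lambda x: const, 0.0, 1.0, weight="alg", wvar=(a - 1.0, b - 1.0)
        )
        assert val == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("bad", [(0.0, 0.5, 2.0), (0.3, 1.0, 2.0), (0.3, 0.5, 0.0)])
    def test_domain_violations(self, bad):
        with pytest.raises(ValueError):
            bp.beta_proportion_logpdf(*bad)


class TestLogPrior:
    def test_gamma_term_symbolic_value(self):
        # with a Gamma(0.1, 1) dispersion prior, at kappa=1 the log density is
        # (0.1-1)*log 1 - 1 - log Gamma(0.1) = -1 - log Gamma(0.1)
        prior = bp.PriorSpec(kappa_shape=0.1, kappa_rate=1.0)
        got = bp.log_prior(bp.HyperParams(mu=0.5, kappa=1.0), prior)
        assert got == pytest.approx(-1.0 - special.gammaln(0.1), abs=1e-12)

    @given(mu=_props)
    def test_uniform_mu_prior_contributes_nothing(self, mu):
        prior = bp.PriorSpec()
        base = bp.log_prior(bp.HyperParams(mu=0.5, kappa=3.0), prior)
        assert bp.log_prior(bp.HyperParams(mu=mu, kappa=3.0), prior) == pytest.approx(base)

    @pytest.mark.parametrize("kappa", [1e-8, 1e6])
    def test_finite_over_support(self, kappa):
        assert np.isfinite(bp.log_prior(bp.HyperParams(mu=0.5, kappa=kappa)))

    def test_prior_spec_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            bp.PriorSpec(kappa_rate=0.0)


class TestLogLikelihood:
    def test_single_bernoulli(self):
        table = bp.CohortTable((bp.CohortRecord("A", 1, 1),))
        assert bp.log_likelihood(table, [0.5]) == pytest.approx(np.log(0.5))

    def test_zero_positive_limit(self):
        table = bp.CohortTable((bp.CohortRecord("A", 42, 0),))
        assert bp.log_likelihood(table, [1e-9]) == pytest.approx(0.0, abs=1e-6)

    def test_matches_termwise_binomial_product(self, paper_table):
        thetas = np.array(
            [max(p / n, 1e-6) for n, p in zip(paper_table.n_tested, paper_table.n_positive)]
        )
        brute = sum(
            stats.binom.logpmf(p, n, t)
            for n, p, t in zip(paper_table.n_tested, paper_table.n_positive, thetas)
        )
        assert bp.log_likelihood(paper_table, thetas) == pytest.approx(brute, rel=1e-12)

    def test_length_mismatch(self, paper_table):
        with pytest.raises(ValueError, match="expected 7"):
            bp.log_likelihood(paper_table, [0.1, 0.2])

    def test_increases_toward_observed_rate(self, paper_table):
        # cohort 0: 19/150; the likelihood term rises as theta_0 approaches it
        grid = np.linspace(0.01, 19 / 150, 8)
        base = [0.1] * 7
        vals = []
        for t in grid:
            th = list(base)
            th[0] = t
            vals.append(bp.log_likelihood(paper_table, th))
        assert np.all(np.diff(vals) > 0)


class TestLogJoint:
    @given(mu=_props, kappa=_kappas, data=st.data())
    def test_is_sum_of_parts(self, paper_table, mu, kappa, data):
        thetas = tuple(
            data.draw(_props, label=f"theta{i}") for i in range(len(paper_table))
        )
        params = bp.ParamVector(hyper=bp.HyperParams(mu, kappa), thetas=thetas)
        prior = bp.PriorSpec()
        expected = (
            bp.log_prior(params.hyper, prior)
            + float(np.sum(bp.beta_proportion_logpdf(np.array(thetas), mu, kappa)))
            + bp.log_likelihood(paper_table, thetas)
        )
        assert bp.log_joint(params, paper_table, prior) == pytest.approx(expected, rel=1e-12)

    def test_finite_at_plausible_point(self, paper_table):
        params = bp.ParamVector(hyper=bp.HyperParams(0.1, 20.0), thetas=(0.1,) * 7)
        assert np.isfinite(bp.log_joint(params, paper_table))

    def test_dimension_mismatch(self, paper_table):
        params = bp.ParamVector(hyper=bp.HyperParams(0.1, 20.0), thetas=(0.1, 0.2))
        with pytest.raises(ValueError):
            bp.log_joint(params, paper_table)


class TestTransforms:
    def test_identity_points(self):
        z = to_unconstrained(
            bp.ParamVector(hyper=bp.HyperParams(0.5, 1.0), thetas=(0.5,))
        )
        assert z.z_mu == pytest.approx(0.0)
        assert z.z_kappa == pytest.approx(0.0)
        assert z.z_thetas[0] == pytest.approx(0.0)

    @given(mu=_props, kappa=_kappas, t1=_props, t2=_props, t3=_props)
    def test_roundtrip(self, mu, kappa, t1, t2, t3):
        params = bp.ParamVector(hyper=bp.HyperParams(mu, kappa), thetas=(t1, t2, t3))
        back = from_unconstrained(to_unconstrained(params))
        assert back.hyper.mu == pytest.approx(mu, abs=1e-12)
        assert back.hyper.kappa == pytest.approx(kappa, rel=1e-12)
        assert np.allclose(back.thetas, params.thetas, atol=1e-12)

    def test_jacobian_against_finite_differences(self):
        params = bp.ParamVector(hyper=bp.HyperParams(0.2, 5.0), thetas=(0.1, 0.4, 0.7))
        z = to_unconstrained(params)
        zvec = np.array([z.z_mu, z.z_kappa, *z.z_thetas])

        def inverse(v):
            back = from_unconstrained(
                bp.UnconstrainedVector(z_mu=v[0], z_kappa=v[1], z_thetas=tuple(v[2:]))
            )
            return np.array([back.hyper.mu, back.hyper.kappa, *back.thetas])

        h = 1e-6
        fd_log_det = 0.0
        for k in range(len(zvec)):
            up, dn = zvec.copy(), zvec.copy()
            up[k] += h
            dn[k] -= h
            fd_log_det += np.log((inverse(up)[k] - inverse(dn)[k]) / (2 * h))
        assert log_jacobian(z) == pytest.approx(fd_log_det, abs=1e-6)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            bp.UnconstrainedVector(z_mu=np.inf, z_kappa=0.0, z_thetas=(0.0,))


class TestBetaBinomialMarginal:
    def test_single_trial_uniform(self):
        # uniform theta: P(P=1 | n=1) = E[theta] = 0.5
        assert bp.beta_binomial_log_marginal(1, 1, 0.5, 2.0) == pytest.approx(np.log(0.5))

    def test_against_numerical_integration(self):
        n, p, mu, kappa = 42, 0, 0.116, 19.1
        val, _ = integrate.quad(
            lambda t: stats.binom.pmf(p, n, t)
            * np.exp(bp.beta_proportion_logpdf(t, mu, kappa)),
            0.0,
            1.0,
            epsabs=1e-12,
        )
        assert bp.beta_binomial_log_marginal(n, p, mu, kappa) == pytest.approx(
            np.log(val), abs=1e-8
        )

    @given(mu=_props, kappa=_kappas, n=st.sampled_from([10, 50]))
    def test_pmf_normalizes(self, mu, kappa, n):
        ps = np.arange(n + 1)
        total = np.exp(bp.beta_binomial_log_marginal(n, ps, mu, kappa)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_complete_pooling_limit(self):
        # kappa -> infinity collapses the population distribution to a point
        # at mu, so the marginal tends to the plain binomial pmf
        n, mu = 42, 0.116
        ps = np.arange(n + 1)
        got = bp.beta_binomial_log_marginal(n, ps, mu, 1e9)
        want = stats.binom.logpmf(ps, n, mu)
        assert np.allclose(got, want, atol=1e-4)

    def test_domain_violation(self):
        with pytest.raises(ValueError):
            bp.beta_binomial_log_marginal(5, 6, 0.5, 1.0)


def test_sampler_target_consistent_with_model(paper_table):
    """The MCMC's marginalized target equals prior + beta-binomial marginal
    + transform Jacobian assembled from the public model functions."""
    from brcapool.mcmc import _hyper_log_target

    prior = bp.PriorSpec()
    n = np.asarray(paper_table.n_tested, float)
    p = np.asarray(paper_table.n_positive, float)
    for mu, kappa in [(0.1, 20.0), (0.3, 2.0), (0.05, 300.0)]:
        z = np.array([special.logit(mu), np.log(kappa)])
        expected = (
            bp.log_prior(bp.HyperParams(mu, kappa), prior)
            + float(np.sum(bp.beta_binomial_log_marginal(n, p, mu, kappa)))
            + (z[0] - 2 * np.logaddexp(0, z[0]))
            + z[1]
        )
        # the sampler omits the constant log-combinatorial and Beta-normalizer
        # terms of the prior; compare differences between two points instead
        ref = np.array([special.logit(0.2), np.log(10.0)])
        expected_ref = (
            bp.log_prior(bp.HyperParams(0.2, 10.0), prior)
            + float(np.sum(bp.beta_binomial_log_marginal(n, p, 0.2, 10.0)))
            + (ref[0] - 2 * np.logaddexp(0, ref[0]))
            + ref[1]
        )
        got_diff = _hyper_log_target(z, n, p, prior) - _hyper_log_target(ref, n, p, prior)
        assert got_diff == pytest.approx(expected - expected_ref, rel=1e-9, abs=1e-9)
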