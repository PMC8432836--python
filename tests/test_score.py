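import numpy as np
import pytest
from scipy import optimize, stats

from equigof import (
    expected_information,
    get_model,
    loglik,
    restricted_mle,
    run_score_test,
    sample_lehmann,
    scores,
)
from equigof.score_test import _theta_sd

EPS = 0.5077
T_LO, T_HI = 1 / (1 + EPS), 1 + EPS

# the two boundary variances n/(V^-1)[0,0] at n=100 are data-independent;
# printed to six decimals in the worked example of the source analysis
V2_LOWER_N100 = 1.636889
V2_UPPER_N100 = 0.276968


class TestLoglik:
    def test_reduces_to_plain_location_scale_at_theta_one(self, std_normal, rng):
        x = rng.normal(1.0, 2.0, size=40)
        mu, sigma = 0.7, 1.9
        plain = np.sum(stats.norm.logpdf((x - mu) / sigma) - np.log(sigma))
        assert loglik(x, 1.0, mu, sigma, std_normal) == pytest.approx(plain, rel=1e-12)

    def test_location_equivariance(self, std_normal, rng):
        x = rng.normal(size=30)
        a = loglik(x, 1.3, 0.4, 1.2, std_normal)
        b = loglik(x + 5.5, 1.3, 0.4 + 5.5, 1.2, std_normal)
        assert a == pytest.approx(b, rel=1e-12)

    @pytest.mark.parametrize("model_name", ["standard_normal", "logistic"])
    def test_finite_difference_gradient_matches_scores(self, model_name, rng):
        model = get_model(model_name)
        x = rng.normal(0.3, 1.4, size=25)
        for theta, mu, sigma in [(0.7, 0.1, 1.0), (1.0, -0.5, 2.0), (1.6, 0.4, 0.8)]:
            s = scores(x, theta, mu, sigma, model)
            h = 1e-6
            fd = np.array([
                (loglik(x, theta + h, mu, sigma, model) - loglik(x, theta - h, mu, sigma, model)),
                (loglik(x, theta, mu + h, sigma, model) - loglik(x, theta, mu - h, sigma, model)),
                (loglik(x, theta, mu, sigma + h, model) - loglik(x, theta, mu, sigma - h, model)),
            ]) / (2 * h)
            assert np.allclose(s, fd, rtol=1e-6, atol=1e-6)

    def test_boundary_standardized_point_rejected(self, rng):
        m = get_model("uniform")
        with pytest.raises(ValueError):
            loglik(np.array([0.2, 0.5, 1.7]), 1.0, 0.0, 1.0, m)


class TestScores:
    def test_theta_component_closed_form(self, std_normal, rng):
        x = rng.normal(size=20)
        theta, mu, sigma = 1.4, 0.2, 1.1
        s = scores(x, theta, mu, sigma, std_normal)
        expected = 20 / theta + stats.norm.logcdf((x - mu) / sigma).sum()
        assert s[0] == pytest.approx(expected, rel=1e-12)

    def test_nuisance_scores_vanish_at_restricted_fit(self, example_sample, std_normal):
        x = example_sample.values
        for theta in (T_LO, T_HI):
            fit = restricted_mle(x, theta, std_normal)
            s = scores(x, theta, fit.mu, fit.sigma, std_normal)
            assert np.max(np.abs(s[1:])) < 1e-8 * x.size

    def test_score_is_centered_at_the_truth(self, std_normal):
        theta, n, reps = 1.2, 50, 2000
        rng = np.random.default_rng(4242)
        tot = np.zeros((reps, 3))
        for i in range(reps):
            x = sample_lehmann(std_normal, theta, n, rng).values
            tot[i] = scores(x, theta, 0.0, 1.0, std_normal)
        se = tot.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(tot.mean(axis=0)) < 3 * se)


class TestRestrictedMle:
    def test_gaussian_closed_form_at_theta_one(self, std_normal, rng):
        x = rng.normal(2.0, 3.0, size=80)
        fit = restricted_mle(x, 1.0, std_normal)
        assert fit.mu == pytest.approx(x.mean(), abs=1e-8)
        assert fit.sigma == pytest.approx(x.std(), abs=1e-8)

    @pytest.mark.parametrize("theta", [T_LO, T_HI])
    def test_matches_independent_optimizer(self, theta, example_sample, std_normal):
        x = example_sample.values
        fit = restricted_mle(x, theta, std_normal)

        def nll(p):
            mu, log_sigma = p
            return -loglik(x, theta, mu, np.exp(log_sigma), std_normal)

        ref = optimize.minimize(
            nll, [x.mean(), np.log(x.std())], method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000},
        )
        assert fit.mu == pytest.approx(ref.x[0], abs=5e-7)
        assert fit.sigma == pytest.approx(np.exp(ref.x[1]), abs=5e-7)
        assert fit.converged and fit.grad_norm < 1e-8 * x.size

    def test_direction_of_the_profile_shift(self, example_sample, std_normal):
        # forcing theta < 1 makes F0^theta larger, so mu must move up and
        # sigma shrink to compensate; the opposite at theta > 1
        x = example_sample.values
        lo = restricted_mle(x, T_LO, std_normal)
        hi = restricted_mle(x, T_HI, std_normal)
        assert lo.mu > x.mean() > hi.mu
        assert lo.sigma < hi.sigma

    def test_too_few_observations_rejected(self, std_normal):
        with pytest.raises(ValueError):
            restricted_mle(np.array([0.1, 0.2]), 1.0, std_normal)


class TestExpectedInformation:
    def test_gaussian_closed_form_at_theta_one(self, std_normal):
        V = expected_information(1.0, 0.0, 1.0, std_normal)
        assert V[1, 1] == pytest.approx(1.0, abs=1e-9)   # location information
        assert V[2, 2] == pytest.approx(2.0, abs=1e-9)   # scale information
        assert V[0, 0] == pytest.approx(1.0, abs=1e-9)   # Var(1 + log U) = 1
        assert V[1, 2] == pytest.approx(0.0, abs=1e-9)   # symmetric model
        assert np.allclose(V, V.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(V) > 0)

    def test_scale_transformation_rule(self, std_normal):
        V1 = expected_information(1.3, 0.0, 1.0, std_normal)
        V2 = expected_information(1.3, 0.0, 2.5, std_normal)
        S = np.diag([1.0, 1 / 2.5, 1 / 2.5])
        assert np.allclose(V2, S @ V1 @ S, atol=1e-9)

    @pytest.mark.parametrize("theta", [T_LO, 1.0, T_HI])
    def test_matches_monte_carlo_score_covariance(self, theta, std_normal):
        V = expected_information(theta, 0.0, 1.0, std_normal)
        rng = np.random.default_rng(314159)
        u = rng.random(1_000_000)
        z = stats.norm.ppf(u ** (1 / theta))
        logF = stats.norm.logcdf(z)
        s = np.vstack([
            1 / theta + logF,
            -((theta - 1) * np.exp(stats.norm.logpdf(z) - logF) - z),
            -((theta - 1) * np.exp(stats.norm.logpdf(z) - logF) * z + 1 - z * z),
        ])
        C = np.cov(s)
        # entrywise 3 SE of a covariance estimate from 1e6 draws
        for i in range(3):
            for j in range(3):
                prod = s[i] * s[j]
                se = prod.std() / np.sqrt(s.shape[1])
                assert abs(V[i, j] - C[i, j]) < 3 * se + 1e-10

    def test_node_doubling_self_check_passes(self, std_normal):
        # default call embeds the check; also verify the 64 vs 128 drift directly
        V64 = expected_information(1.5077, model=std_normal, quadrature_nodes=64,
                                   self_check=False)
        V128 = expected_information(1.5077, model=std_normal, quadrature_nodes=128,
                                    self_check=False)
        assert np.max(np.abs(V128 - V64)) < 1e-8


class TestBoundaryVariances:
    def test_partial_information_is_location_scale_invariant(self, std_normal):
        a = np.linalg.inv(expected_information(T_LO, 0.0, 1.0, std_normal))[0, 0]
        b = np.linalg.inv(expected_information(T_LO, 3.0, 0.4, std_normal))[0, 0]
        assert a == pytest.approx(b, rel=1e-9)

    def test_reference_values_at_n_100(self, std_normal):
        assert _theta_sd(T_LO, 100, std_normal, 64) ** 2 == pytest.approx(
            V2_LOWER_N100, abs=5e-7
        )
        assert _theta_sd(T_HI, 100, std_normal, 64) ** 2 == pytest.approx(
            V2_UPPER_N100, abs=5e-7
        )


class TestRunScoreTest:
    def test_tost_decision_structure(self, example_sample, std_normal):
        res = run_score_test(example_sample.values, std_normal, 0.05, EPS)
        assert res.reject_H == (res.reject_lower and res.reject_upper)
        assert res.z_lower == pytest.approx(res.fit_lower.score_theta / res.v_lower)
        assert res.z_upper == pytest.approx(res.fit_upper.score_theta / res.v_upper)
        z = stats.norm.ppf(0.95)
        assert res.reject_lower == (res.z_lower > z)
        assert res.reject_upper == (res.z_upper < -z)

    def test_location_scale_equivariance(self, example_sample, std_normal):
        x = example_sample.values
        a, b = 3.7, 2.2
        r1 = run_score_test(x, std_normal, 0.05, EPS)
        r2 = run_score_test(a + b * x, std_normal, 0.05, EPS)
        assert r2.fit_lower.mu == pytest.approx(a + b * r1.fit_lower.mu, abs=1e-6)
        assert r2.fit_lower.sigma == pytest.approx(b * r1.fit_lower.sigma, abs=1e-6)
        assert r2.z_lower == pytest.approx(r1.z_lower, abs=1e-8)
        assert r2.z_upper == pytest.approx(r1.z_upper, abs=1e-8)

    def test_monotone_in_the_margin(self, example_sample, std_normal):
        x = example_sample.values
        rejected = [
            run_score_test(x, std_normal, 0.05, e).reject_H
            for e in (0.3135, 0.5077, 0.7341, 1.2, 2.0)
        ]
        # once the margin is wide enough to reject, wider margins keep rejecting
        assert rejected == sorted(rejected)

    def test_small_samples_rejected(self, std_normal):
        with pytest.raises(ValueError):
            run_score_test(np.zeros(5) + [0.1, 0.2, 0.3, 0.4, 0.5], std_normal, 0.05, EPS)
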