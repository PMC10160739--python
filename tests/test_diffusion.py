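import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from swindiff.diffusion import (
    DenoiserOutput,
    LossConfig,
    NoisyBatch,
    build_linear_schedule,
    gaussian_cdf_approx,
    hybrid_loss,
    make_noisy_batch,
    mu_from_eps,
    noise_mse_loss,
    posterior_params,
    q_sample,
    sigma_from_v,
    vlb_term,
)
from swindiff.nn.autograd import Tensor


# ----------------------------------------------------------------- schedules
class TestLinearSchedule:
    def test_default_schedule_endpoints(self):
        s = build_linear_schedule(4000, 5e-6)
        assert s.betas[0] == pytest.approx(5e-6)
        assert s.betas[-1] == pytest.approx(0.02)

    def test_hand_computed_t3(self):
        s = build_linear_schedule(3, 0.1)
        np.testing.assert_allclose(s.betas, [0.1, 0.2, 0.3])
        np.testing.assert_allclose(s.alpha_bars, [0.9, 0.72, 0.504])

    def test_single_step_chain(self):
        s = build_linear_schedule(1, 0.25)
        assert s.alpha_bars[0] == pytest.approx(0.75)
        assert s.posterior_variances[0] == 0.0

    def test_rejects_escaping_beta(self):
        with pytest.raises(ValueError):
            build_linear_schedule(10, 0.1)  # slope*T = 1
        with pytest.raises(ValueError):
            build_linear_schedule(0, 0.1)
        with pytest.raises(ValueError):
            build_linear_schedule(10, -0.01)

    @given(
        T=st.integers(min_value=1, max_value=500),
        inv=st.floats(min_value=1.05, max_value=100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariants_hold_for_any_legal_schedule(self, T, inv):
        slope = 1.0 / (inv * T)
        s = build_linear_schedule(T, slope)
        assert np.all(s.betas > 0) and np.all(s.betas < 1)
        assert np.all(np.diff(s.alpha_bars) < 0) or T == 1
        assert s.posterior_variances[0] == 0.0
        if T >= 2:
            # strict inequality can tie in float arithmetic once alpha_bar ~ 0
            assert np.all(s.posterior_variances[1:] <= s.betas[1:])
            assert s.posterior_variances[1] < s.betas[1]
        for arr in (s.betas, s.alphas, s.alpha_bars, s.posterior_variances):
            assert len(arr) == T


# ------------------------------------------------------------------ q_sample
class TestQSample:
    def test_zero_noise(self, small_schedule):
        x0 = np.full((3, 3), 2.0)
        out = q_sample(x0, 3, np.zeros((3, 3)), small_schedule)
        np.testing.assert_allclose(out, np.sqrt(small_schedule.alpha_bars[2]) * x0)

    def test_direct_arithmetic_alpha_bar_quarter(self):
        # find a schedule whose ab hits 0.25 exactly: T=1, slope=0.75
        s = build_linear_schedule(1, 0.75)
        out = q_sample(np.ones((2, 2)), 1, np.ones((2, 2)), s)
        np.testing.assert_allclose(out, 0.5 + np.sqrt(0.75), atol=1e-12)

    def test_t_out_of_range(self, small_schedule):
        with pytest.raises(ValueError):
            q_sample(np.zeros((2, 2)), 6, np.zeros((2, 2)), small_schedule)
        with pytest.raises(ValueError):
            q_sample(np.zeros((2, 2)), 0, np.zeros((2, 2)), small_schedule)

    def test_marginal_matches_iterated_one_step_kernel(self, small_schedule, rng):
        # brute-force oracle: run the single-step kernel t times on a 1-pixel chain
        n, t, x0 = 20_000, 4, 0.7
        s = small_schedule
        x = np.full(n, x0)
        for step in range(1, t + 1):
            x = np.sqrt(1.0 - s.betas[step - 1]) * x + np.sqrt(s.betas[step - 1]) * rng.standard_normal(n)
        closed = q_sample(np.full(n, x0), t, rng.standard_normal(n), s)
        ab = s.alpha_bars[t - 1]
        assert x.mean() == pytest.approx(np.sqrt(ab) * x0, rel=0.02)
        assert x.var() == pytest.approx(1.0 - ab, rel=0.02)
        assert closed.mean() == pytest.approx(x.mean(), abs=0.03)
        assert closed.var() == pytest.approx(x.var(), rel=0.05)


# ----------------------------------------------------------------- posterior
def brute_force_posterior(x0_val, xt_val, t, schedule, n_levels=257):
    """Discretized-Bayes oracle: enumerate the forward kernels on a grid."""
    grid = np.linspace(-1.0, 1.0, n_levels)
    s = schedule
    # p(x_{t-1} | x_0) on the grid (closed-form marginal of the forward chain)
    if t == 1:
        prior = (np.abs(grid - x0_val) == np.min(np.abs(grid - x0_val))).astype(float)
    else:
        ab_prev = s.alpha_bar_prev(t)
        prior = stats.norm.pdf(grid, np.sqrt(ab_prev) * x0_val, np.sqrt(1.0 - ab_prev))
    # likelihood p(x_t | x_{t-1}) for the observed x_t
    like = stats.norm.pdf(xt_val, np.sqrt(1.0 - s.betas[t - 1]) * grid, np.sqrt(s.betas[t - 1]))
    post = prior * like
    post /= post.sum()
    mean = np.sum(grid * post)
    var = np.sum((grid - mean) ** 2 * post)
    return mean, var


class TestPosterior:
    def test_t1_collapses_to_x0(self, small_schedule):
        x0 = np.array([[0.3]])
        xt = np.array([[0.9]])
        mean, var = posterior_params(xt, x0, 1, small_schedule)
        assert var == 0.0
        np.testing.assert_allclose(mean, x0, atol=1e-12)

    @pytest.mark.parametrize("t", [2, 3, 4, 5])
    def test_discretized_bayes_oracle(self, t):
        # gentle noise keeps the chain's mass inside the 257-level [-1,1] grid
        schedule = build_linear_schedule(5, 2e-3)
        x0_val, xt_val = 0.35, 0.3
        bf_mean, bf_var = brute_force_posterior(x0_val, xt_val, t, schedule)
        mean, var = posterior_params(np.array(xt_val), np.array(x0_val), t, schedule)
        assert float(mean) == pytest.approx(bf_mean, abs=1e-3)
        assert var == pytest.approx(bf_var, abs=1e-3)

    def test_monte_carlo_forward_chain_moments(self, small_schedule, rng):
        # sample (x_{t-1}, x_t) jointly from the forward chain, condition on a
        # narrow x_t window, and compare empirical moments with the closed form
        s, t, x0_val, n = small_schedule, 3, 0.5, 400_000
        x_prev = np.full(n, x0_val)
        for step in range(1, t):
            x_prev = np.sqrt(1 - s.betas[step - 1]) * x_prev + np.sqrt(s.betas[step - 1]) * rng.standard_normal(n)
        x_t = np.sqrt(1 - s.betas[t - 1]) * x_prev + np.sqrt(s.betas[t - 1]) * rng.standard_normal(n)
        target = 0.4
        sel = np.abs(x_t - target) < 0.02
        emp_mean, emp_var = x_prev[sel].mean(), x_prev[sel].var()
        mean, var = posterior_params(np.array(target), np.array(x0_val), t, s)
        assert float(mean) == pytest.approx(emp_mean, abs=0.02)
        assert var == pytest.approx(emp_var, rel=0.05)

    def test_sampling_from_posterior_matches_moments(self, small_schedule, rng):
        mean, var = posterior_params(np.array(0.4), np.array(0.5), 3, small_schedule)
        draws = rng.normal(float(mean), np.sqrt(var), 20_000)
        assert draws.mean() == pytest.approx(float(mean), abs=0.02)
        assert draws.var() == pytest.approx(var, rel=0.02)


# ---------------------------------------------------------------- mu_from_eps
class TestMuFromEps:
    def test_zero_noise_prediction(self, small_schedule):
        xt = np.full((2, 2), 0.8)
        out = mu_from_eps(xt, 2, np.zeros((2, 2)), small_schedule)
        np.testing.assert_allclose(out, xt / np.sqrt(small_schedule.alphas[1]))

    def test_direct_arithmetic(self):
        s = build_linear_schedule(3, 0.1)
        out = mu_from_eps(np.ones((2, 2)), 2, np.full((2, 2), 0.5), s)
        expected = (1.0 - 0.2 * 0.5 / np.sqrt(1.0 - 0.72)) / np.sqrt(0.8)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_substitution_identity(self, small_schedule, seed):
        # with the true eps, mu_from_eps must equal the Bayes posterior mean
        rng = np.random.default_rng(seed)
        for _ in range(20):
            t = int(rng.integers(1, small_schedule.T + 1))
            x0 = rng.uniform(-1, 1, (4, 4))
            eps = rng.standard_normal((4, 4))
            xt = q_sample(x0, t, eps, small_schedule)
            mu_sub = mu_from_eps(xt, t, eps, small_schedule)
            mu_bayes, _ = posterior_params(xt, x0, t, small_schedule)
            np.testing.assert_allclose(mu_sub, mu_bayes, atol=1e-6)


# ---------------------------------------------------------------- sigma_from_v
class TestSigmaFromV:
    def test_endpoints(self, small_schedule):
        for t in (2, 4):
            v0 = sigma_from_v(t, np.zeros((2, 2)), small_schedule)
            v1 = sigma_from_v(t, np.ones((2, 2)), small_schedule)
            np.testing.assert_allclose(v0, small_schedule.posterior_variances[t - 1], rtol=1e-12)
            np.testing.assert_allclose(v1, small_schedule.betas[t - 1], rtol=1e-12)

    def test_midpoint_geometric_mean(self, small_schedule):
        t = 3
        out = sigma_from_v(t, np.full((2, 2), 0.5), small_schedule)
        expected = np.sqrt(small_schedule.betas[t - 1] * small_schedule.posterior_variances[t - 1])
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_bounded_by_endpoints(self, small_schedule, rng):
        for t in range(2, small_schedule.T + 1):
            v = rng.uniform(0, 1, (8, 8))
            out = sigma_from_v(t, v, small_schedule)
            assert np.all(out >= small_schedule.posterior_variances[t - 1] - 1e-15)
            assert np.all(out <= small_schedule.betas[t - 1] + 1e-15)

    def test_rejects_v_outside_unit_interval(self, small_schedule):
        with pytest.raises(ValueError):
            sigma_from_v(2, np.full((2, 2), 1.5), small_schedule)
        with pytest.raises(ValueError):
            sigma_from_v(2, np.full((2, 2), -0.1), small_schedule)


# -------------------------------------------------------------------- losses
class TestNoiseMse:
    def test_perfect_prediction(self):
        a = np.random.default_rng(0).standard_normal((2, 4, 4))
        assert noise_mse_loss(a, a.copy()) == 0.0

    def test_unit_offset(self):
        assert noise_mse_loss(np.zeros((3, 3)), np.ones((3, 3))) == pytest.approx(1.0)

    def test_matches_naive_loop(self, rng):
        a = rng.standard_normal((2, 3, 3))
        b = rng.standard_normal((2, 3, 3))
        total = sum(
            (a[i, j, k] - b[i, j, k]) ** 2
            for i in range(2) for j in range(3) for k in range(3)
        )
        assert noise_mse_loss(a, b) == pytest.approx(total / 18)

    def test_empty_batch(self):
        with pytest.raises(ValueError):
            noise_mse_loss(np.zeros((0, 3, 3)), np.zeros((0, 3, 3)))


def _perfect_output(x0, xt, t, schedule, shape):
    """DenoiserOutput whose mean is exact and whose variance equals beta_tilde."""
    ab = schedule.alpha_bars[t - 1]
    eps_true = (xt - np.sqrt(ab) * x0) / np.sqrt(1.0 - ab)
    return DenoiserOutput(eps_pred=eps_true, v_raw=None, v=np.zeros(shape))


class TestVlbTerm:
    def test_zero_kl_at_perfect_prediction(self, small_schedule, rng):
        t = 3
        x0 = rng.uniform(-1, 1, (4, 4))
        eps = rng.standard_normal((4, 4))
        xt = q_sample(x0, t, eps, small_schedule)
        out = _perfect_output(x0, xt, t, small_schedule, x0.shape)
        val = vlb_term(x0, xt, t, out, small_schedule, LossConfig())
        assert abs(float(val)) < 1e-9

    def test_textbook_half_nat_anchor(self):
        # KL( N(0,1) || N(1,1) ) = 0.5 via the same closed form used at t >= 2
        from swindiff.diffusion import _gaussian_kl

        assert float(_gaussian_kl(0.0, 1.0, 1.0, np.array(1.0))) == pytest.approx(0.5)
        # Monte-Carlo confirmation of the anchor
        rng = np.random.default_rng(5)
        z = rng.normal(0.0, 1.0, 200_000)
        logratio = stats.norm.logpdf(z, 0, 1) - stats.norm.logpdf(z, 1, 1)
        assert logratio.mean() == pytest.approx(0.5, abs=0.01)

    def test_kl_nonnegative_for_random_outputs(self, small_schedule, rng):
        for t in range(2, 6):
            x0 = rng.uniform(-1, 1, (4, 4))
            eps = rng.standard_normal((4, 4))
            xt = q_sample(x0, t, eps, small_schedule)
            out = DenoiserOutput(
                eps_pred=rng.standard_normal((4, 4)), v_raw=None, v=rng.uniform(0, 1, (4, 4))
            )
            assert float(vlb_term(x0, xt, t, out, small_schedule, LossConfig())) >= 0.0

    @pytest.mark.parametrize("x0_val", [0.0, 0.37, -0.9995, 0.9995])
    def test_t1_discretized_likelihood_vs_quadrature(self, small_schedule, x0_val):
        cfg = LossConfig()
        x0 = np.array([[x0_val]])
        xt = np.array([[0.1]])
        out = DenoiserOutput(eps_pred=np.array([[0.2]]), v_raw=None, v=np.array([[1.0]]))
        val = float(vlb_term(x0, xt, 1, out, small_schedule, cfg))

        mu = mu_from_eps(xt, 1, out.eps_pred, small_schedule)[0, 0]
        var = small_schedule.betas[0]  # v = 1 endpoint
        lo, hi = cfg.data_range
        d = cfg.delta

        def cdf(z):
            return float(gaussian_cdf_approx(np.array(z)))

        if x0_val <= lo + d:
            prob = cdf((x0_val + d - mu) / np.sqrt(var))
        elif x0_val >= hi - d:
            prob = 1.0 - cdf((x0_val - d - mu) / np.sqrt(var))
        else:
            # quadrature oracle: integrate the density (derivative of the
            # approximate CDF) over the bin [x0 - d, x0 + d]
            a, b = (x0_val - d - mu) / np.sqrt(var), (x0_val + d - mu) / np.sqrt(var)
            prob, _ = integrate.quad(_cdf_derivative, a, b, epsabs=1e-12)
        assert val == pytest.approx(-np.log(prob + 1e-12), abs=1e-4)


def _cdf_derivative(z):
    c = np.sqrt(2.0 / np.pi)
    u = c * (z + 0.044715 * z**3)
    return 0.5 * (1 - np.tanh(u) ** 2) * c * (1 + 3 * 0.044715 * z**2)


class TestHybridLoss:
    def test_reduces_to_mse_when_vlb_zero(self, small_schedule, rng):
        x0 = rng.uniform(-1, 1, (2, 4, 4))
        t = np.array([3, 4])
        eps = rng.standard_normal((2, 4, 4))
        xt = np.stack([q_sample(x0[i], int(t[i]), eps[i], small_schedule) for i in range(2)])
        batch = NoisyBatch(x0=x0, t=t, eps=eps, xt=xt)
        out = DenoiserOutput(eps_pred=eps.copy(), v_raw=None, v=np.zeros_like(eps))
        total, l_mean, l_var = hybrid_loss(batch, out, small_schedule, LossConfig())
        assert float(l_var) == pytest.approx(0.0, abs=1e-9)
        assert float(total) == pytest.approx(float(l_mean), abs=1e-9)

    def test_default_gamma_is_0p01(self):
        assert LossConfig().gamma == 0.01

    def test_weighting_arithmetic(self):
        # L_mean = 0.5, mean vlb = 2.0, gamma = 0.01 -> 0.52 (checked on the formula)
        assert 0.5 + 0.01 * 2.0 == pytest.approx(0.52)

    def test_gradient_reaches_variance_head_only_through_vlb(self, small_schedule, rng):
        x0 = rng.uniform(-1, 1, (1, 4, 4))
        t = np.array([3])
        eps = rng.standard_normal((1, 4, 4))
        xt = np.stack([q_sample(x0[0], 3, eps[0], small_schedule)])
        eps_pred = Tensor(rng.standard_normal((1, 4, 4)), requires_grad=True)
        v = Tensor(rng.uniform(0.1, 0.9, (1, 4, 4)), requires_grad=True)
        batch = NoisyBatch(x0=x0, t=t, eps=eps, xt=xt)
        total, _, l_var = hybrid_loss(batch, DenoiserOutput(eps_pred, None, v), small_schedule, LossConfig())
        l_var.backward()
        # the mean inside the KL is detached: eps_pred gets no gradient from L_var
        assert eps_pred.grad is None or np.allclose(eps_pred.grad, 0.0)
        assert v.grad is not None and np.any(v.grad != 0.0)


class TestMakeNoisyBatch:
    def test_shapes_and_range(self, small_schedule, rng):
        x0 = rng.uniform(-1, 1, (6, 1, 8, 8))
        batch = make_noisy_batch(x0, small_schedule, rng)
        assert batch.xt.shape == batch.eps.shape == x0.shape
        assert np.all((batch.t >= 1) & (batch.t <= small_schedule.T))
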