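"""Forward/reverse diffusion mathematics and the hybrid training objective.

The forward chain corrupts an image ``x0`` over ``T`` steps with per-step
Gaussian variance ``beta_t`` growing linearly in ``t``.  The reverse process is
parameterized by a predicted noise field (which yields the posterior mean in
closed form) and a per-pixel interpolation coefficient ``v`` placing the
reverse variance between the posterior variance ``beta_tilde_t`` and
``beta_t`` on a log scale.  Training minimizes a pixel MSE on the noise plus a
down-weighted variational term that trains the variance head alone.

Timesteps are 1-indexed: ``t`` runs over ``1..T`` and ``alpha_bar_0 = 1``.
All operations accept plain numpy arrays or autograd :class:`~swindiff.nn.autograd.Tensor`
objects interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor

__all__ = [
    "NoiseSchedule",
    "NoisyBatch",
    "DenoiserOutput",
    "LossConfig",
    "build_linear_schedule",
    "q_sample",
    "posterior_params",
    "mu_from_eps",
    "sigma_from_v",
    "noise_mse_loss",
    "vlb_term",
    "hybrid_loss",
    "make_noisy_batch",
    "gaussian_cdf_approx",
]

#: numerical floor for the t=1 posterior variance inside log-interpolation
VARIANCE_FLOOR = 1e-20


@dataclass(frozen=True)
class NoiseSchedule:
    """Per-timestep quantities of a ``T``-step forward chain.

    Arrays are indexed ``[t-1]`` for timestep ``t``.
    """

    T: int
    betas: np.ndarray
    alphas: np.ndarray
    alpha_bars: np.ndarray
    posterior_variances: np.ndarray

    def alpha_bar_prev(self, t: int) -> float:
        """``alpha_bar_{t-1}`` with the convention ``alpha_bar_0 = 1``."""
        return 1.0 if t == 1 else float(self.alpha_bars[t - 2])

    def check_t(self, t: int) -> int:
        t = int(t)
        if not 1 <= t <= self.T:
            raise ValueError(f"timestep {t} outside 1..{self.T}")
        return t


@dataclass
class NoisyBatch:
    """A forward-corrupted batch: ``xt = sqrt(ab_t) x0 + sqrt(1-ab_t) eps``."""

    x0: np.ndarray
    t: np.ndarray
    eps: np.ndarray
    xt: np.ndarray


@dataclass
class DenoiserOutput:
    """Raw network outputs plus the mapped interpolation coefficient ``v``."""

    eps_pred: object
    v_raw: object
    v: object


@dataclass(frozen=True)
class LossConfig:
    gamma: float = 0.01
    delta: float = 1.0 / 256.0
    data_range: tuple = (-1.0, 1.0)

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")


def build_linear_schedule(T: int, slope: float) -> NoiseSchedule:
    """Build the linear variance schedule ``beta_t = slope * t``.

    Requires ``slope * T < 1`` so every ``beta_t`` stays inside (0, 1).
    """
    T = int(T)
    if T < 1:
        raise ValueError("T must be >= 1")
    if slope <= 0:
        raise ValueError("slope must be > 0")
    if slope * T >= 1.0:
        raise ValueError(f"slope*T = {slope * T} >= 1: beta_T would leave (0,1)")
    t = np.arange(1, T + 1, dtype=np.float64)
    betas = slope * t
    alphas = 1.0 - betas
    alpha_bars = np.cumprod(alphas)
    alpha_bars_prev = np.concatenate([[1.0], alpha_bars[:-1]])
    posterior_variances = (1.0 - alpha_bars_prev) / (1.0 - alpha_bars) * betas
    return NoiseSchedule(T, betas, alphas, alpha_bars, posterior_variances)


def q_sample(x0, t: int, eps, schedule: NoiseSchedule):
    """Closed-form forward corruption to timestep ``t``."""
    t = schedule.check_t(t)
    ab = schedule.alpha_bars[t - 1]
    if np.shape(x0) != np.shape(eps) and getattr(x0, "shape", None) != getattr(eps, "shape", None):
        raise ValueError("x0 and eps shapes differ")
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps


def posterior_coeffs(beta: float, alpha: float, alpha_bar: float, alpha_bar_prev: float):
    """Bayes posterior q(x_{t-1} | x_t, x0) coefficients and variance."""
    c0 = np.sqrt(alpha_bar_prev) * beta / (1.0 - alpha_bar)
    ct = np.sqrt(alpha) * (1.0 - alpha_bar_prev) / (1.0 - alpha_bar)
    var = (1.0 - alpha_bar_prev) / (1.0 - alpha_bar) * beta
    return c0, ct, var


def posterior_params(xt, x0, t: int, schedule: NoiseSchedule):
    """Mean and variance of the forward chain's Bayes posterior at ``t``."""
    t = schedule.check_t(t)
    c0, ct, var = posterior_coeffs(
        schedule.betas[t - 1],
        schedule.alphas[t - 1],
        schedule.alpha_bars[t - 1],
        schedule.alpha_bar_prev(t),
    )
    return c0 * x0 + ct * xt, float(var)


def mean_from_noise(xt, eps_pred, beta: float, alpha: float, alpha_bar: float):
    """Reverse-process mean from a noise estimate (any per-step quantities)."""
    return (xt - (beta / np.sqrt(1.0 - alpha_bar)) * eps_pred) * (1.0 / np.sqrt(alpha))


def mu_from_eps(xt, t: int, eps_pred, schedule: NoiseSchedule):
    """Posterior-mean estimate implied by predicted noise at timestep ``t``."""
    t = schedule.check_t(t)
    return mean_from_noise(
        xt, eps_pred, schedule.betas[t - 1], schedule.alphas[t - 1], schedule.alpha_bars[t - 1]
    )


def log_var_interp(v, beta: float, beta_tilde: float):
    """``exp(v log beta + (1-v) log beta_tilde)`` with the variance floor."""
    beta_tilde = max(float(beta_tilde), VARIANCE_FLOOR)
    return ag.exp(v * np.log(beta) + (1.0 - v) * np.log(beta_tilde))


def sigma_from_v(t: int, v, schedule: NoiseSchedule):
    """Learned reverse variance: log-linear interpolation between
    ``beta_tilde_t`` (v=0) and ``beta_t`` (v=1), elementwise."""
    t = schedule.check_t(t)
    vdata = v.data if isinstance(v, Tensor) else np.asarray(v)
    if np.any(vdata < 0) or np.any(vdata > 1):
        raise ValueError("v must lie in [0, 1]")
    return log_var_interp(v, schedule.betas[t - 1], schedule.posterior_variances[t - 1])


def noise_mse_loss(eps_true, eps_pred):
    """Mean squared error over every pixel, image and timestep in the batch."""
    if np.size(eps_true if not isinstance(eps_true, Tensor) else eps_true.data) == 0:
        raise ValueError("empty batch")
    diff = eps_pred - eps_true
    return (diff * diff).mean()


def gaussian_cdf_approx(z):
    """Fast tanh-based approximation of the standard normal CDF."""
    return 0.5 * (1.0 + ag.tanh(np.sqrt(2.0 / np.pi) * (z + 0.044715 * z**3)))


def _gaussian_kl(mu_q, var_q, mu_p, var_p):
    # KL( N(mu_q, var_q) || N(mu_p, var_p) ), var_p may be a Tensor
    return 0.5 * (
        ag.log(var_p) - np.log(var_q) + (var_q + (mu_q - mu_p) ** 2) / var_p - 1.0
    )


def vlb_term(x0, xt, t: int, out: DenoiserOutput, schedule: NoiseSchedule, cfg: LossConfig):
    """Per-timestep variational term, averaged over pixels.

    For ``t >= 2`` this is the closed-form KL between the true posterior
    ``N(mu, beta_tilde_t)`` and the model's ``N(mu_theta, Sigma_theta)``; both
    means are detached so only the variance head receives gradient.  For
    ``t = 1`` it is the negative log-likelihood of ``x0`` under a per-pixel
    Gaussian discretized into bins of half-width ``delta``, edge bins
    open-ended.
    """
    t = schedule.check_t(t)
    mu_true, var_true = posterior_params(xt, x0, t, schedule)
    mu_theta = ag.detach(mu_from_eps(xt, t, ag.detach(out.eps_pred), schedule))
    sigma_theta = sigma_from_v(t, out.v, schedule)

    if t >= 2:
        kl = _gaussian_kl(mu_true, var_true, mu_theta, sigma_theta)
        return kl.mean()

    # t = 1: discretized-Gaussian reconstruction of x0
    lo, hi = cfg.data_range
    d = cfg.delta
    std = ag.sqrt(sigma_theta)
    cdf_plus = gaussian_cdf_approx((x0 + d - mu_theta) / std)
    cdf_minus = gaussian_cdf_approx((x0 - d - mu_theta) / std)
    x0d = x0.data if isinstance(x0, Tensor) else np.asarray(x0)
    low_mask = (x0d <= lo + d).astype(np.float64)
    high_mask = (x0d >= hi - d).astype(np.float64)
    mid_mask = 1.0 - np.clip(low_mask + high_mask, 0.0, 1.0)
    tiny = 1e-12
    log_prob = (
        low_mask * ag.log(cdf_plus + tiny)
        + high_mask * ag.log(1.0 - cdf_minus + tiny)
        + mid_mask * ag.log(cdf_plus - cdf_minus + tiny)
    )
    return -(log_prob.mean())


def hybrid_loss(batch: NoisyBatch, out: DenoiserOutput, schedule: NoiseSchedule, cfg: LossConfig):
    """``L = L_mean + gamma * L_var`` with ``L_var`` averaged over the batch."""
    l_mean = noise_mse_loss(batch.eps, out.eps_pred)
    ts = np.atleast_1d(batch.t)
    vlb_sum = None
    for i, t in enumerate(ts):
        v_raw_i = out.v_raw[i] if out.v_raw is not None else None
        sub = DenoiserOutput(out.eps_pred[i], v_raw_i, out.v[i])
        term = vlb_term(batch.x0[i], batch.xt[i], int(t), sub, schedule, cfg)
        vlb_sum = term if vlb_sum is None else vlb_sum + term
    l_var = vlb_sum * (1.0 / len(ts))
    return l_mean + cfg.gamma * l_var, l_mean, l_var


def make_noisy_batch(x0: np.ndarray, schedule: NoiseSchedule, rng: np.random.Generator) -> NoisyBatch:
    """Draw uniform timesteps and fresh noise for a training batch.

    ``x0`` has shape ``(B, ...)``; one timestep per leading index.
    """
    B = x0.shape[0]
    t = rng.integers(1, schedule.T + 1, size=B)
    eps = rng.standard_normal(x0.shape)
    xt = np.empty_like(x0, dtype=np.float64)
    for i in range(B):
        xt[i] = q_sample(x0[i], int(t[i]), eps[i], schedule)
    return NoisyBatch(x0=np.asarray(x0, dtype=np.float64), t=t, eps=eps, xt=xt)
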