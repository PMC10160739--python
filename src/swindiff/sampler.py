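"""Spaced-timestep reverse-diffusion sampling.

A sub-chain ``S`` of the training chain is selected by even spacing; per-step
quantities are recomputed from cumulative-alpha ratios so the sub-chain's
marginals match the parent chain (``effective_beta_j = 1 - ab_{S_j}/ab_{S_{j-1}}``).
With ``n_steps = T`` the construction reduces exactly to the full chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diffusion import (
    DenoiserOutput,
    NoiseSchedule,
    log_var_interp,
    mean_from_noise,
    posterior_coeffs,
)
from .nn.autograd import Tensor, no_grad

__all__ = ["SpacedChain", "make_spaced_chain", "reverse_step", "generate"]

CLIP_RANGES = {"xray": (-1.0, 1.0), "mri": (-1.0, 1.0), "phantom": (-1.0, 1.0), "ct": (0.0, 1.0)}


@dataclass(frozen=True)
class SpacedChain:
    """Sub-chain of parent timesteps with marginal-preserving quantities.

    ``S`` holds parent timesteps (1-indexed, strictly increasing); arrays are
    indexed by sub-step ``j`` = 1..|S| via ``[j-1]``.
    """

    S: np.ndarray
    effective_betas: np.ndarray
    effective_alphas: np.ndarray
    effective_alpha_bars: np.ndarray
    effective_posterior_variances: np.ndarray

    def __len__(self):
        return len(self.S)

    def check_j(self, j: int) -> int:
        j = int(j)
        if not 1 <= j <= len(self.S):
            raise IndexError(f"sub-step {j} outside 1..{len(self.S)}")
        return j


def make_spaced_chain(schedule: NoiseSchedule, n_steps: int) -> SpacedChain:
    """Select ``round(linspace(1, T, n_steps))`` (round half up, deduplicated)
    and recompute per-sub-step quantities from the parent's alpha-bars."""
    n_steps = int(n_steps)
    if not 1 <= n_steps <= schedule.T:
        raise ValueError(f"n_steps {n_steps} outside 1..{schedule.T}")
    raw = np.floor(np.linspace(1.0, schedule.T, n_steps) + 0.5).astype(int)
    S = np.unique(raw)  # already sorted ascending
    ab = schedule.alpha_bars[S - 1]
    ab_prev = np.concatenate([[1.0], ab[:-1]])
    betas = 1.0 - ab / ab_prev
    # a sub-step spanning exactly one parent step reuses the parent beta
    # bit-for-bit, so the identity sub-chain reproduces the parent chain
    single = np.diff(np.concatenate([[0], S])) == 1
    betas[single] = schedule.betas[S[single] - 1]
    alphas = 1.0 - betas
    post = (1.0 - ab_prev) / (1.0 - ab) * betas
    return SpacedChain(S, betas, alphas, ab, post)


def reverse_step(xs, j: int, out: DenoiserOutput, chain: SpacedChain, noise,
                 clip_x0_range=None):
    """One reverse update ``x_{j} -> x_{j-1}`` on the sub-chain.

    ``mu_theta + sqrt(Sigma_theta) * noise``; at the first sub-step (j = 1,
    which produces x0) the noise term is dropped.

    With ``clip_x0_range`` set, the implied clean image is clipped to that
    range before the mean is formed (static thresholding — the standard
    stabilizer for partially converged noise predictors; identical to the
    plain mean whenever the implied image is already in range).
    """
    j = chain.check_j(j)
    beta = chain.effective_betas[j - 1]
    alpha = chain.effective_alphas[j - 1]
    ab = chain.effective_alpha_bars[j - 1]
    ab_prev = 1.0 if j == 1 else chain.effective_alpha_bars[j - 2]
    post = chain.effective_posterior_variances[j - 1]

    eps = out.eps_pred.data if isinstance(out.eps_pred, Tensor) else np.asarray(out.eps_pred)
    v = out.v.data if isinstance(out.v, Tensor) else np.asarray(out.v)
    if clip_x0_range is None:
        mu = mean_from_noise(xs, eps, beta, alpha, ab)
    else:
        x0_hat = (xs - np.sqrt(1.0 - ab) * eps) / np.sqrt(ab)
        x0_hat = np.clip(x0_hat, *clip_x0_range)
        c0, ct, _ = posterior_coeffs(beta, alpha, ab, ab_prev)
        mu = c0 * x0_hat + ct * xs
    if j == 1:
        return mu
    sigma = log_var_interp(v, beta, post)
    return mu + np.sqrt(sigma) * noise


def generate(
    model,
    chain: SpacedChain,
    n_images: int,
    seed: int,
    modality: str = "phantom",
    side: int | None = None,
    batch_size: int = 16,
    clip_x0: bool = True,
) -> np.ndarray:
    """Run the full reverse recursion from seeded Gaussian noise.

    One generator drives the initial noise (drawn first, for all images) and
    then the per-step noise, so the result is a pure function of ``seed``.
    Outputs are clipped to the modality's normalized range and returned as an
    ``(n_images, side, side)`` array.
    """
    if modality not in CLIP_RANGES:
        raise ValueError(f"unknown modality {modality!r}")
    if side is None:
        raise ValueError("side must be given")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_images, side, side))
    lo, hi = CLIP_RANGES[modality]
    with no_grad():
        for j in range(len(chain), 0, -1):
            t_parent = int(chain.S[j - 1])
            noise = rng.standard_normal(x.shape) if j > 1 else np.zeros_like(x)
            new = np.empty_like(x)
            for start in range(0, n_images, batch_size):
                sl = slice(start, min(start + batch_size, n_images))
                out = model(x[sl], np.full(sl.stop - sl.start, t_parent))
                eps_raw = out.eps_pred.data if isinstance(out.eps_pred, Tensor) else np.asarray(out.eps_pred)
                v_raw = out.v.data if isinstance(out.v, Tensor) else np.asarray(out.v)
                eps = eps_raw.reshape(x[sl].shape)
                v = v_raw.reshape(x[sl].shape)
                new[sl] = reverse_step(
                    x[sl], j, DenoiserOutput(eps, None, v), chain, noise[sl],
                    clip_x0_range=(lo, hi) if clip_x0 else None,
                )
            x = new
    return np.clip(x, lo, hi)
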