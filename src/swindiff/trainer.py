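"""Optimization loop: AdamW over the denoiser under the hybrid loss."""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .diffusion import LossConfig, build_linear_schedule, hybrid_loss, make_noisy_batch
from .nn.denoiser import NetworkConfig, SwinDenoiser, save_checkpoint

__all__ = ["TrainConfig", "AdamW", "train"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 2e-5
    weight_decay: float = 1e-4
    epochs: int = 250
    batch_size: int = 8
    T: int = 4000
    slope: float = 5e-6
    gamma: float = 0.01
    seed: int = 0
    checkpoint_interval: int = 0  # epochs between periodic checkpoints; 0 = final only
    ema_decay: float = 0.0  # 0 disables EMA
    max_steps: int = -1  # -1 = no cap; 0 is a valid "initialize only" run
    grad_clip: float = 1.0
    data_range: tuple = (-1.0, 1.0)

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("rates and sizes must be positive")


class AdamW(object):
    """Decoupled-weight-decay Adam (beta1=0.9, beta2=0.999)."""

    def __init__(self, params, lr, weight_decay=0.0, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * self.wd * p.data
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def _clip_global_norm(params, max_norm: float) -> float:
    total = math.sqrt(sum(float((p.grad**2).sum()) for p in params if p.grad is not None))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return total


def train(
    dataset: np.ndarray,
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
    out_dir=None,
    model: SwinDenoiser | None = None,
    progress: bool = False,
):
    """Train the denoiser on ``dataset`` (an ``(N, H, W)`` array of normalized
    images). Returns ``(model, trace)`` where ``trace`` is a list of
    ``(step, l_mean, l_var, l_total)`` rows. Fully seeded: a given seed
    reproduces the same trace on the same hardware.
    """
    dataset = np.asarray(dataset, dtype=np.float64)
    if dataset.ndim != 3 or dataset.shape[0] == 0:
        raise ValueError("dataset must be a non-empty (N, H, W) array")
    rng = np.random.default_rng(train_cfg.seed)
    schedule = build_linear_schedule(train_cfg.T, train_cfg.slope)
    loss_cfg = LossConfig(gamma=train_cfg.gamma, data_range=tuple(train_cfg.data_range))
    if model is None:
        model = SwinDenoiser(net_cfg, np.random.default_rng(rng.integers(2**32)))
    opt = AdamW(model.parameters(), train_cfg.learning_rate, train_cfg.weight_decay)
    ema = None
    if train_cfg.ema_decay > 0:
        ema = {k: v.copy() for k, v in model.state_dict().items()}

    trace = []
    step = 0
    n = dataset.shape[0]
    stop = False
    iterator = range(train_cfg.epochs)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="epochs")
    if train_cfg.max_steps == 0:
        stop = True
    for epoch in iterator:
        if stop:
            break
        order = rng.permutation(n)
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start : start + train_cfg.batch_size]
            if len(idx) == 0:
                continue
            x0 = dataset[idx][:, None, :, :]
            batch = make_noisy_batch(x0, schedule, rng)
            out = model(batch.xt, batch.t)
            total, l_mean, l_var = hybrid_loss(batch, out, schedule, loss_cfg)
            if not np.isfinite(total.item()):
                raise FloatingPointError(
                    f"non-finite loss at step {step}: "
                    f"L_mean={l_mean.item()!r} L_var={l_var.item()!r}"
                )
            model.zero_grad()
            total.backward()
            _clip_global_norm(model.parameters(), train_cfg.grad_clip)
            opt.step()
            if ema is not None:
                d = train_cfg.ema_decay
                for k, p in model.named_parameters():
                    ema[k] = d * ema[k] + (1.0 - d) * p.data
            trace.append((step, l_mean.item(), l_var.item(), total.item()))
            step += 1
            if train_cfg.max_steps >= 0 and step >= train_cfg.max_steps:
                stop = True
                break
        if out_dir is not None and train_cfg.checkpoint_interval:
            if (epoch + 1) % train_cfg.checkpoint_interval == 0:
                _save(out_dir, f"checkpoint_ep{epoch + 1}.npz", model, train_cfg, step)
        if stop:
            break

    if out_dir is not None:
        _save(out_dir, "checkpoint_final.npz", model, train_cfg, step)
        _write_trace(Path(out_dir) / "loss_trace.csv", trace)
    return model, trace


def _save(out_dir, name, model, train_cfg, step):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_checkpoint(
        out_dir / name,
        model,
        extra={"T": train_cfg.T, "slope": train_cfg.slope, "step": step,
               "data_range": list(train_cfg.data_range)},
    )


def _write_trace(path, trace):
    with open(path, "w") as fh:
        fh.write("step,L_mean,L_var,L\n")
        for row in trace:
            fh.write(f"{row[0]},{row[1]:.8g},{row[2]:.8g},{row[3]:.8g}\n")
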