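"""U-shaped denoiser mixing residual convolutional blocks (high resolution)
with shifted-window transformer blocks (low resolution).

The network maps a noisy image and a timestep to two image-shaped outputs:
a noise estimate and a raw variance-interpolation field. Block plan (full
preset): 2 conv-down + 4 swin-down encoder, 3 middle swin, mirrored decoder
with 4 swin-up + 2 conv-up and encoder-to-decoder shortcut connections by
channel concatenation. A reduced preset (2 conv-down + 2 swin-down, 1 middle)
serves small inputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .autograd import Tensor, concat, softmax
from .layers import Module, Linear, Conv2d, GroupNorm, downsample2x, upsample2x
from ..diffusion import DenoiserOutput

__all__ = [
    "NetworkConfig",
    "SwinDenoiser",
    "WindowAttention",
    "sinusoidal_embed",
    "window_partition",
    "window_merge",
    "window_mhsa",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters.

    ``width_multiplier`` scales every stage's channel count (the 25/50/75/100%
    ablation knob). ``depth_preset`` selects the block plan.
    """

    base_channels: int = 32
    width_multiplier: float = 1.0
    window_size: int = 8
    num_heads: int = 4
    time_embed_dim: int = 128
    time_embed_max_period: float = 1e6
    groupnorm_groups: int = 32
    depth_preset: str = "full"
    # small inner-weight init: the pre-norm layout is invariant to hidden
    # weight scale, and shrinking it raises Adam's relative step size, which
    # matters at the very small default learning rate
    init_scale: float = 0.1
    dtype: str = "float64"

    def __post_init__(self):
        if not 0 < self.width_multiplier <= 1:
            raise ValueError("width_multiplier must be in (0, 1]")
        if self.depth_preset not in ("full", "reduced"):
            raise ValueError("depth_preset must be 'full' or 'reduced'")
        if self.init_scale <= 0:
            raise ValueError("init_scale must be > 0")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be 'float32' or 'float64'")

    @property
    def block_plan(self):
        """(n_conv_down, n_swin_down, n_middle); decoder mirrors the encoder."""
        return (2, 4, 3) if self.depth_preset == "full" else (2, 2, 1)

    def stage_channels(self):
        """Per-level output channels: stem plus one entry per down block.

        Doubles at each level, capped at 8x base, scaled by the width
        multiplier and rounded up to a groupnorm/head-compatible multiple.
        """
        n_conv, n_swin, _ = self.block_plan
        n_levels = n_conv + n_swin + 1
        unit = int(np.lcm(self.groupnorm_groups, self.num_heads))
        chans = []
        for lv in range(n_levels):
            raw = self.base_channels * min(2**lv, 8) * self.width_multiplier
            chans.append(max(unit, int(np.ceil(raw / unit)) * unit))
        return chans


def sinusoidal_embed(t, dim: int, max_period: float = 1e6) -> np.ndarray:
    """Sinusoidal timestep embedding: ``[sin(t*w_k), cos(t*w_k)]`` with
    geometric frequencies ``w_k = max_period^(-2k/dim)`` for ``k < dim/2``."""
    if dim % 2 != 0:
        raise ValueError("embedding dim must be even")
    half = dim // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half) * 2.0 / dim)
    scalar = np.ndim(t) == 0
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    args = t[:, None] * freqs[None, :]
    emb = np.concatenate([np.sin(args), np.cos(args)], axis=1)
    return emb[0] if scalar else emb


def window_partition(x: Tensor, l: int) -> Tensor:
    """(B, C, H, W) -> (B * H/l * W/l, l*l, C) window token batches."""
    B, C, H, W = x.shape
    if H % l or W % l:
        raise ValueError(f"feature side ({H}x{W}) not divisible by window size {l}")
    x = x.transpose(0, 2, 3, 1)  # B H W C
    x = x.reshape(B, H // l, l, W // l, l, C)
    x = x.transpose(0, 1, 3, 2, 4, 5)  # B nH nW l l C
    return x.reshape(B * (H // l) * (W // l), l * l, C)


def window_merge(tokens: Tensor, l: int, B: int, H: int, W: int) -> Tensor:
    """Inverse of :func:`window_partition`."""
    C = tokens.shape[-1]
    x = tokens.reshape(B, H // l, W // l, l, l, C)
    x = x.transpose(0, 1, 3, 2, 4, 5)  # B nH l nW l C
    x = x.reshape(B, H, W, C)
    return x.transpose(0, 3, 1, 2)


class WindowAttention(Module):
    """Multi-head self-attention within non-overlapping l x l windows.

    The shifted variant cyclically shifts the feature map by (l/2, l/2)
    before partitioning and un-shifts afterwards (no cross-wrap masking).
    """

    def __init__(self, channels: int, num_heads: int, window_size: int, rng: np.random.Generator):
        if channels % num_heads != 0:
            raise ValueError("heads must divide channels")
        self.num_heads = num_heads
        self.window_size = window_size
        self.head_dim = channels // num_heads
        self.qkv = Linear(channels, 3 * channels, rng)
        self.proj = Linear(channels, channels, rng)

    def forward(self, x: Tensor, shifted: bool = False) -> Tensor:
        B, C, H, W = x.shape
        l = min(self.window_size, H, W)
        s = l // 2
        if shifted and s > 0:
            x = x.roll((-s, -s), axis=(2, 3))
        tokens = window_partition(x, l)  # (nB, T, C)
        nB, T, _ = tokens.shape
        M, d = self.num_heads, self.head_dim
        qkv = self.qkv(tokens).reshape(nB, T, 3, M, d).transpose(2, 0, 3, 1, 4)  # 3 nB M T d
        q, k, v = qkv[0], qkv[1], qkv[2]
        att = softmax((q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d)), axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(nB, T, C)
        out = self.proj(out)
        out = window_merge(out, l, B, H, W)
        if shifted and s > 0:
            out = out.roll((s, s), axis=(2, 3))
        return out


def window_mhsa(f: Tensor, attn: WindowAttention, shifted: bool = False) -> Tensor:
    """Functional wrapper: windowed MHSA followed by nothing else."""
    return attn(f, shifted=shifted)


def _act(x: Tensor) -> Tensor:
    return x.silu()


def _fit_groups(groups: int, channels: int) -> int:
    """Largest divisor of ``channels`` not exceeding ``groups``."""
    g = min(groups, channels)
    while channels % g:
        g -= 1
    return g


class ConvSection(Module):
    """Residual convolutional section with timestep injection.

    timestep linear -> early conv -> add -> two further convs, with a
    residual connection from the early conv output; optional 2x resampling
    before the early conv. GroupNorm + SiLU around every conv.
    """

    def __init__(self, cin, cout, temb_dim, groups, rng, resample=None):
        self.resample = resample
        self.time_proj = Linear(temb_dim, cout, rng)
        self.norm0 = GroupNorm(_fit_groups(groups, cin), cin)
        self.conv0 = Conv2d(cin, cout, rng)
        self.norm1 = GroupNorm(groups, cout)
        self.conv1 = Conv2d(cout, cout, rng)
        self.norm2 = GroupNorm(groups, cout)
        self.conv2 = Conv2d(cout, cout, rng)

    def forward(self, x: Tensor, temb: Tensor) -> Tensor:
        h = _act(self.norm0(x))
        if self.resample == "down":
            h = downsample2x(h)
        elif self.resample == "up":
            h = upsample2x(h)
        h = self.conv0(h)
        B, C = h.shape[0], h.shape[1]
        h = h + self.time_proj(_act(temb)).reshape(B, C, 1, 1)
        r = h
        h = self.conv1(_act(self.norm1(h)))
        h = self.conv2(_act(self.norm2(h)))
        return h + r


class SwinSection(Module):
    """Transformer section: timestep injection + early conv, then a window
    attention pass and a shifted pass, each followed by a fully connected
    refinement layer, all residual."""

    def __init__(self, cin, cout, temb_dim, groups, heads, window, rng, resample=None):
        self.resample = resample
        self.time_proj = Linear(temb_dim, cout, rng)
        self.norm0 = GroupNorm(_fit_groups(groups, cin), cin)
        self.conv0 = Conv2d(cin, cout, rng)
        self.norm_wa = GroupNorm(groups, cout)
        self.wa = WindowAttention(cout, heads, window, rng)
        self.fc_wa = Linear(cout, cout, rng)
        self.norm_swa = GroupNorm(groups, cout)
        self.swa = WindowAttention(cout, heads, window, rng)
        self.fc_swa = Linear(cout, cout, rng)

    def _refine(self, x: Tensor, fc: Linear) -> Tensor:
        B, C, H, W = x.shape
        t = x.transpose(0, 2, 3, 1).reshape(B * H * W, C)
        t = fc(t)
        return t.reshape(B, H, W, C).transpose(0, 3, 1, 2)

    def forward(self, x: Tensor, temb: Tensor) -> Tensor:
        h = _act(self.norm0(x))
        if self.resample == "down":
            h = downsample2x(h)
        elif self.resample == "up":
            h = upsample2x(h)
        h = self.conv0(h)
        B, C = h.shape[0], h.shape[1]
        h = h + self.time_proj(_act(temb)).reshape(B, C, 1, 1)
        h = h + self._refine(self.wa(self.norm_wa(h), shifted=False), self.fc_wa)
        h = h + self._refine(self.swa(self.norm_swa(h), shifted=True), self.fc_swa)
        return h


class ConvBlock(Module):
    """Three sequential conv sections; resampling lives in the last one."""

    def __init__(self, cin, cout, temb_dim, groups, rng, resample):
        self.sections = [
            ConvSection(cin, cout, temb_dim, groups, rng),
            ConvSection(cout, cout, temb_dim, groups, rng),
            ConvSection(cout, cout, temb_dim, groups, rng, resample=resample),
        ]

    def forward(self, x, temb):
        for s in self.sections:
            x = s(x, temb)
        return x


class SwinBlock(Module):
    """Two sequential swin sections; resampling lives in the last one."""

    def __init__(self, cin, cout, temb_dim, groups, heads, window, rng, resample):
        self.sections = [
            SwinSection(cin, cout, temb_dim, groups, heads, window, rng),
            SwinSection(cout, cout, temb_dim, groups, heads, window, rng, resample=resample),
        ]

    def forward(self, x, temb):
        for s in self.sections:
            x = s(x, temb)
        return x


class SwinDenoiser(Module):
    """Full U-shaped denoiser; ``forward`` returns a :class:`DenoiserOutput`."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        self.cfg = cfg
        n_conv, n_swin, n_mid = cfg.block_plan
        chans = cfg.stage_channels()
        g = min(cfg.groupnorm_groups, min(chans))
        td, heads, win = cfg.time_embed_dim, cfg.num_heads, cfg.window_size

        self.time_fc1 = Linear(cfg.time_embed_dim, td, rng)
        self.time_fc2 = Linear(td, td, rng)

        self.stem = Conv2d(1, chans[0], rng)

        self.enc = []
        cur = chans[0]
        for i in range(n_conv):
            self.enc.append(ConvBlock(cur, chans[i + 1], td, g, rng, resample="down"))
            cur = chans[i + 1]
        for i in range(n_swin):
            self.enc.append(SwinBlock(cur, chans[n_conv + i + 1], td, g, heads, win, rng, resample="down"))
            cur = chans[n_conv + i + 1]

        self.middle = [
            SwinBlock(cur, cur, td, g, heads, win, rng, resample=None) for _ in range(n_mid)
        ]

        # decoder mirrors the encoder; each block consumes [up-path, skip]
        self.dec = []
        skip_chans = chans[:-1][::-1]  # encoder outputs, deepest first
        for j in range(n_swin + n_conv):
            cin = cur + skip_chans[j]
            cout = skip_chans[j]
            if j < n_swin:
                self.dec.append(SwinBlock(cin, cout, td, g, heads, win, rng, resample="up"))
            else:
                self.dec.append(ConvBlock(cin, cout, td, g, rng, resample="up"))
            cur = cout

        self.out_norm = GroupNorm(g, cur)
        self.head_eps = Conv2d(cur, 1, rng)
        self.head_v = Conv2d(cur, 1, rng)

        # hidden weights shrunk by init_scale (heads keep their natural scale
        # so the output magnitude is right from the start)
        head_ids = {id(self.head_eps.weight), id(self.head_v.weight)}
        for _, p in self.named_parameters():
            if p.data.ndim >= 2 and id(p) not in head_ids:
                p.data *= cfg.init_scale
        dt = np.dtype(cfg.dtype)
        for _, p in self.named_parameters():
            p.data = p.data.astype(dt)

    def forward(self, xt, t) -> DenoiserOutput:
        dt = np.dtype(self.cfg.dtype)
        if isinstance(xt, Tensor):
            x = xt if xt.data.dtype == dt else Tensor(xt.data.astype(dt))
        else:
            x = Tensor(np.asarray(xt, dtype=dt))
        if x.ndim == 2:
            x = x.reshape(1, 1, *x.shape)
        elif x.ndim == 3:
            x = x.reshape(x.shape[0], 1, x.shape[1], x.shape[2])
        B = x.shape[0]
        n_conv, n_swin, _ = self.cfg.block_plan
        depth = n_conv + n_swin
        H, W = x.shape[2], x.shape[3]
        if H != W or H % (2**depth):
            raise ValueError(
                f"input side {H}x{W} incompatible with depth plan: needs a square "
                f"side divisible by {2**depth}"
            )
        t_arr = np.broadcast_to(np.atleast_1d(np.asarray(t, dtype=np.float64)), (B,))
        emb = sinusoidal_embed(t_arr, self.cfg.time_embed_dim, self.cfg.time_embed_max_period)
        temb = self.time_fc2(_act(self.time_fc1(Tensor(np.atleast_2d(emb).astype(dt)))))

        h = self.stem(x)
        skips = [h]
        for blk in self.enc:
            h = blk(h, temb)
            skips.append(h)
        for blk in self.middle:
            h = blk(h, temb)
        # skips[-1] is the deepest encoder output, consumed first
        for blk, skip in zip(self.dec, reversed(skips[:-1])):
            h = blk(concat([h, _match_res(skip, h)], axis=1), temb)
        h = _act(self.out_norm(h))
        eps_pred = self.head_eps(h)
        v_raw = self.head_v(h)
        v = (v_raw.tanh() + 1.0) * 0.5
        return DenoiserOutput(eps_pred=eps_pred, v_raw=v_raw, v=v)


def _match_res(skip: Tensor, h: Tensor) -> Tensor:
    """Skips are taken before a block's internal resampling; align them."""
    while skip.shape[2] > h.shape[2]:
        skip = downsample2x(skip)
    while skip.shape[2] < h.shape[2]:
        skip = upsample2x(skip)
    return skip


def save_checkpoint(path, model: SwinDenoiser, extra: dict | None = None) -> None:
    """Flat named-parameter archive with the config embedded as JSON."""
    payload = {f"param/{k}": v for k, v in model.state_dict().items()}
    meta = {"config": asdict(model.cfg), "extra": extra or {}}
    payload["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path) -> tuple[SwinDenoiser, dict]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta_json"].tobytes()).decode())
        state = {k[len("param/") :]: z[k] for k in z.files if k.startswith("param/")}
    cfg = NetworkConfig(**meta["config"])
    model = SwinDenoiser(cfg, np.random.default_rng(0))
    model.load_state_dict(state)
    return model, meta["extra"]
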