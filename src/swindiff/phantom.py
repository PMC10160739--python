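"""Seeded generator of anatomy-like toy images (ellipse "organs" on a dark
background) used to exercise the whole pipeline without any dataset."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import ellipse as _ellipse

__all__ = ["PhantomConfig", "generate_phantoms"]


@dataclass(frozen=True)
class PhantomConfig:
    n_images: int = 16
    side: int = 32
    n_ellipses: tuple = (1, 3)  # inclusive range per image
    intensity_levels: tuple = (-0.2, 0.2, 0.6)  # tissue-class intensities
    background: float = -0.9
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        side = self.side
        if side < 16 or side & (side - 1):
            raise ValueError("side must be a power of two >= 16")
        if self.n_ellipses[0] < 1 or self.n_ellipses[1] < self.n_ellipses[0]:
            raise ValueError("bad ellipse-count range")


def generate_phantoms(cfg: PhantomConfig, with_labels: bool = False):
    """Return an ``(n, side, side)`` array in [-1, 1], fully seeded.

    Each image is a dark background plus 1..n random non-border-clipping
    ellipses at tissue-class intensities, plus Gaussian texture noise. With
    ``with_labels`` also returns the integer union mask of the ellipses.
    """
    rng = np.random.default_rng(cfg.seed)
    s = cfg.side
    margin = max(2, s // 8)
    images = np.empty((cfg.n_images, s, s))
    masks = np.zeros((cfg.n_images, s, s), dtype=np.int64)
    counts = rng.integers(cfg.n_ellipses[0], cfg.n_ellipses[1] + 1, size=cfg.n_images)
    for i in range(cfg.n_images):
        img = np.full((s, s), cfg.background)
        for _ in range(counts[i]):
            r0 = rng.uniform(margin + 2, s - margin - 2)
            c0 = rng.uniform(margin + 2, s - margin - 2)
            max_r = min(r0, c0, s - 1 - r0, s - 1 - c0, s / 3)
            a = rng.uniform(2, max(2.01, max_r))
            b = rng.uniform(2, max(2.01, max_r))
            level = cfg.intensity_levels[rng.integers(len(cfg.intensity_levels))]
            rr, cc = _ellipse(r0, c0, a, b, shape=(s, s))
            img[rr, cc] = level
            masks[i, rr, cc] = 1
        if cfg.noise_sigma > 0:
            img = img + rng.normal(0.0, cfg.noise_sigma, (s, s))
        images[i] = np.clip(img, -1.0, 1.0)
    if with_labels:
        return images, masks, counts
    return images
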