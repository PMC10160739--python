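"""Four-metric evaluation suite for real/synthetic image sets.

* **IS** — exponentiated mean KL between per-image class-probability rows and
  their split marginal (mean +/- std over splits).
* **FID** — Fréchet distance between Gaussians fit to feature embeddings.
* **FDS** — KL divergence between 2D Gaussians fit to a pooled
  low-dimensional (t-SNE) embedding of the two sets.
* **DS** — KL divergence between 1D Gaussians fit to each set's
  nearest-neighbour SSIM values.

Feature/probability extraction is pluggable so the suite runs offline: a
seeded random projection, a small classifier trained on labelled phantoms, or
(optionally, if torchvision is installed) the ImageNet Inception network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from skimage.metrics import structural_similarity

__all__ = [
    "GaussianSummary",
    "MetricReport",
    "RandomProjectionExtractor",
    "ToyClassifierExtractor",
    "inception_score",
    "fid",
    "gaussian_kl",
    "fds",
    "nearest_ssim",
    "diversity_score",
    "compute_report",
    "embed_2d",
]


def _as_images(x) -> np.ndarray:
    imgs = getattr(x, "images", x)
    imgs = np.asarray(imgs, dtype=np.float64)
    if imgs.ndim != 3:
        raise ValueError("expected an (N, H, W) stack")
    return imgs


# ---------------------------------------------------------------- extractors
class RandomProjectionExtractor:
    """Seeded Gaussian random projection of flattened pixels.

    Probability rows (for IS) are obtained by a softmax over the projected
    features — artifact plumbing that keeps the suite exercisable offline.
    """

    name = "random-projection"

    def __init__(self, dim: int = 16, seed: int = 0):
        self.dim = dim
        self.seed = seed
        self._proj = None
        self._npix = None

    def _matrix(self, npix: int) -> np.ndarray:
        if self._proj is None or self._npix != npix:
            rng = np.random.default_rng(self.seed)
            self._proj = rng.standard_normal((npix, self.dim)) / np.sqrt(npix)
            self._npix = npix
        return self._proj

    def features(self, images) -> np.ndarray:
        imgs = _as_images(images)
        flat = imgs.reshape(imgs.shape[0], -1)
        return flat @ self._matrix(flat.shape[1])

    def probabilities(self, images) -> np.ndarray:
        f = self.features(images)
        e = np.exp(f - f.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)


class ToyClassifierExtractor:
    """Logistic-regression classifier trained on seeded labelled phantoms.

    Class label is the per-image ellipse count, so probability rows carry
    genuine image structure. Features are the classifier's decision scores.
    """

    name = "toy-classifier"

    def __init__(self, side: int = 32, seed: int = 0, n_train: int = 128):
        from sklearn.linear_model import LogisticRegression

        from .phantom import PhantomConfig, generate_phantoms

        imgs, _, counts = generate_phantoms(
            PhantomConfig(n_images=n_train, side=side, seed=seed), with_labels=True
        )
        self._clf = LogisticRegression(max_iter=500, random_state=seed)
        self._clf.fit(imgs.reshape(n_train, -1), counts)

    def features(self, images) -> np.ndarray:
        imgs = _as_images(images)
        return np.atleast_2d(self._clf.decision_function(imgs.reshape(imgs.shape[0], -1)))

    def probabilities(self, images) -> np.ndarray:
        imgs = _as_images(images)
        return self._clf.predict_proba(imgs.reshape(imgs.shape[0], -1))


def make_extractor(name: str, seed: int = 0, side: int = 32):
    if name in ("random", "random-projection"):
        return RandomProjectionExtractor(seed=seed)
    if name in ("toy", "toy-classifier"):
        return ToyClassifierExtractor(side=side, seed=seed)
    if name in ("inception", "pretrained-inception"):
        raise RuntimeError(
            "the pretrained-inception extractor needs torch/torchvision and a "
            "network download; use 'toy' or 'random' offline"
        )
    raise ValueError(f"unknown extractor {name!r}")


# ------------------------------------------------------------------- metrics
def inception_score(probs: np.ndarray, n_splits: int = 10):
    """Per split ``exp(mean_i KL(p_i || marginal))``; returns (mean, std)."""
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 2:
        raise ValueError("probs must be 2D")
    if np.any(probs < 0) or np.any(probs.sum(axis=1) <= 0):
        raise ValueError("rows must be non-negative with positive mass")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("rows must sum to 1")
    if not 1 <= n_splits <= probs.shape[0]:
        raise ValueError("n_splits must be in 1..n_rows")
    scores = []
    for chunk in np.array_split(probs, n_splits):
        marginal = chunk.mean(axis=0, keepdims=True)
        kl = np.sum(chunk * (np.log(chunk + 1e-12) - np.log(marginal + 1e-12)), axis=1)
        scores.append(np.exp(kl.mean()))
    return float(np.mean(scores)), float(np.std(scores))


@dataclass(frozen=True)
class GaussianSummary:
    mean: np.ndarray
    cov: np.ndarray

    @classmethod
    def fit(cls, rows: np.ndarray, ridge: float = 1e-10) -> "GaussianSummary":
        rows = np.atleast_2d(np.asarray(rows, dtype=np.float64))
        if rows.shape[0] < 2:
            raise ValueError("need >= 2 rows to fit a covariance")
        mean = rows.mean(axis=0)
        cov = np.cov(rows, rowvar=False)
        cov = np.atleast_2d(cov) + ridge * np.eye(rows.shape[1])
        return cls(mean, 0.5 * (cov + cov.T))


def fid(feats_a: np.ndarray, feats_b: np.ndarray) -> float:
    """Fréchet distance ``|mu_a-mu_b|^2 + Tr(Sa + Sb - 2 (Sa Sb)^1/2)``."""
    a = GaussianSummary.fit(feats_a)
    b = GaussianSummary.fit(feats_b)
    if a.mean.shape != b.mean.shape:
        raise ValueError("feature dimensions differ")
    diff = a.mean - b.mean
    covmean = np.real(np.asarray(linalg.sqrtm(a.cov @ b.cov)))
    covmean = 0.5 * (covmean + covmean.T)
    val = diff @ diff + np.trace(a.cov) + np.trace(b.cov) - 2.0 * np.trace(covmean)
    return float(max(val, 0.0))


def gaussian_kl(p: GaussianSummary, q: GaussianSummary) -> float:
    """Closed-form multivariate ``KL(p || q)`` in nats."""
    k = p.mean.shape[0]
    diff = q.mean - p.mean
    q_inv_p = np.linalg.solve(q.cov, p.cov)
    _, logdet_q = np.linalg.slogdet(q.cov)
    _, logdet_p = np.linalg.slogdet(p.cov)
    maha = diff @ np.linalg.solve(q.cov, diff)
    return float(0.5 * (np.trace(q_inv_p) + maha - k + logdet_q - logdet_p))


def embed_2d(pooled: np.ndarray, seed: int) -> np.ndarray:
    """2D t-SNE embedding of flattened images.

    Exact-duplicate images are collapsed to a single point before embedding
    (their pixel distance is zero) and share coordinates afterwards, so
    identical groups yield identical point clouds.
    """
    from sklearn.manifold import TSNE

    flat = pooled.reshape(pooled.shape[0], -1)
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    n_uniq = uniq.shape[0]
    if n_uniq < 3:
        # degenerate: spread duplicates deterministically on a tiny line
        pts = np.zeros((n_uniq, 2))
        pts[:, 0] = np.arange(n_uniq)
        return pts[inverse]
    perplexity = float(min(30.0, max(2.0, pooled.shape[0] / 4.0), n_uniq - 1))
    emb = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca" if n_uniq > 4 else "random",
    ).fit_transform(uniq)
    return emb[inverse]


def fds(real, synth, seed: int = 0, direction: str = "real_to_synth") -> float:
    """Feature-distribution similarity: pooled 2D embedding, per-group
    Gaussian fits, KL between them (direction recorded by the caller)."""
    r = _as_images(real)
    s = _as_images(synth)
    if len(r) < 3 or len(s) < 3:
        raise ValueError("each group needs >= 3 images")
    emb = embed_2d(np.concatenate([r, s]), seed)
    g_real = GaussianSummary.fit(emb[: len(r)], ridge=1e-9)
    g_synth = GaussianSummary.fit(emb[len(r) :], ridge=1e-9)
    if direction == "real_to_synth":
        return gaussian_kl(g_real, g_synth)
    if direction == "synth_to_real":
        return gaussian_kl(g_synth, g_real)
    raise ValueError("direction must be 'real_to_synth' or 'synth_to_real'")


def nearest_ssim(images, normalized_range=(-1.0, 1.0)) -> np.ndarray:
    """For each image, its maximum SSIM against every other image in the set.

    SSIM uses the standard 11x11 Gaussian window on 8-bit-equivalent
    intensities.
    """
    imgs = _as_images(images)
    n = imgs.shape[0]
    if n < 2:
        raise ValueError("need >= 2 images")
    lo, hi = normalized_range
    scaled = (imgs - lo) / (hi - lo) * 255.0
    win = min(11, imgs.shape[1] - (imgs.shape[1] + 1) % 2)
    vals = np.full((n, n), -np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            s = structural_similarity(
                scaled[i],
                scaled[j],
                data_range=255.0,
                win_size=win,
                gaussian_weights=True,
                sigma=1.5,
                use_sample_covariance=False,
            )
            vals[i, j] = vals[j, i] = s
    return vals.max(axis=1)


def _kl_1d(mu_p, var_p, mu_q, var_q) -> float:
    return float(0.5 * (np.log(var_q / var_p) + (var_p + (mu_p - mu_q) ** 2) / var_q - 1.0))


def diversity_score(real, synth, normalized_range=(-1.0, 1.0),
                    direction: str = "real_to_synth", var_floor: float = 1e-8) -> float:
    """KL between 1D Gaussian fits of the two sets' nearest-SSIM values."""
    r = nearest_ssim(real, normalized_range)
    s = nearest_ssim(synth, normalized_range)
    if len(r) < 3 or len(s) < 3:
        raise ValueError("each set needs >= 3 images")
    mu_r, var_r = r.mean(), max(r.var(), var_floor)
    mu_s, var_s = s.mean(), max(s.var(), var_floor)
    if direction == "real_to_synth":
        return _kl_1d(mu_r, var_r, mu_s, var_s)
    if direction == "synth_to_real":
        return _kl_1d(mu_s, var_s, mu_r, var_r)
    raise ValueError("direction must be 'real_to_synth' or 'synth_to_real'")


@dataclass(frozen=True)
class MetricReport:
    is_mean: float
    is_std: float
    fid: float
    fds: float
    ds: float
    n_real: int
    n_synth: int
    extractor: str
    embedding_seed: int
    is_splits: int = 10
    kl_direction: str = "real_to_synth"

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def compute_report(real, synth, extractor, seed: int = 0, n_splits: int = 10,
                   normalized_range=(-1.0, 1.0), kl_direction: str = "real_to_synth") -> MetricReport:
    """Run all four metrics on a real/synthetic pair of image sets."""
    r = _as_images(real)
    s = _as_images(synth)
    n_splits = min(n_splits, s.shape[0])
    is_mean, is_std = inception_score(extractor.probabilities(s), n_splits)
    return MetricReport(
        is_mean=is_mean,
        is_std=is_std,
        fid=fid(extractor.features(r), extractor.features(s)),
        fds=fds(r, s, seed=seed, direction=kl_direction),
        ds=diversity_score(r, s, normalized_range, direction=kl_direction),
        n_real=r.shape[0],
        n_synth=s.shape[0],
        extractor=extractor.name,
        embedding_seed=seed,
        is_splits=n_splits,
        kl_direction=kl_direction,
    )
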