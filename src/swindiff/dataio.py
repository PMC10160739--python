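"""Image I/O, modality normalization and geometry conforming.

Modality conventions:

* ``xray``   — 8-bit source range [0, 255] mapped affinely to [-1, 1]
* ``mri``    — per-scan min/max mapped to [-1, 1]
* ``ct``     — fixed attenuation window [-1024, 3012] mapped to [0, 1]
* ``phantom``— already in [-1, 1]; identity map
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "ImageSet",
    "MODALITY_RANGES",
    "normalize",
    "denormalize",
    "conform_geometry",
    "save_image_set",
    "load_image_set",
]

#: modality -> (raw_range or None for per-scan, normalized_range)
MODALITY_RANGES = {
    "xray": ((0.0, 255.0), (-1.0, 1.0)),
    "mri": (None, (-1.0, 1.0)),
    "ct": ((-1024.0, 3012.0), (0.0, 1.0)),
    "phantom": ((-1.0, 1.0), (-1.0, 1.0)),
}


@dataclass
class ImageSet:
    images: np.ndarray  # (N, H, W), normalized
    modality: str
    normalized_range: tuple
    raw_range: tuple
    pixel_spacing: tuple | None = None

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float64)
        if self.images.ndim != 3:
            raise ValueError("images must be (N, H, W)")
        lo, hi = self.normalized_range
        if self.images.size and (self.images.min() < lo - 1e-9 or self.images.max() > hi + 1e-9):
            raise ValueError("pixels outside the normalized range")

    def __len__(self):
        return self.images.shape[0]


def _check_modality(modality: str):
    if modality not in MODALITY_RANGES:
        raise ValueError(f"unknown modality {modality!r}; expected one of {sorted(MODALITY_RANGES)}")
    return MODALITY_RANGES[modality]


def normalize(image: np.ndarray, modality: str) -> np.ndarray:
    """Affine map of raw intensities onto the modality's normalized range."""
    raw, (lo, hi) = _check_modality(modality)
    image = np.asarray(image, dtype=np.float64)
    if raw is None:  # per-scan min/max (MRI)
        rlo, rhi = float(image.min()), float(image.max())
        if rhi - rlo <= 0:
            raise ValueError("constant scan has zero dynamic range")
    else:
        rlo, rhi = raw
    return (image - rlo) / (rhi - rlo) * (hi - lo) + lo


def denormalize(image: np.ndarray, modality: str, raw_range: tuple | None = None) -> np.ndarray:
    """Clip to the normalized range, then invert the affine map."""
    raw, (lo, hi) = _check_modality(modality)
    if raw is None:
        if raw_range is None:
            raise ValueError("per-scan modality needs an explicit raw_range")
        raw = raw_range
    rlo, rhi = raw
    clipped = np.clip(np.asarray(image, dtype=np.float64), lo, hi)
    return (clipped - lo) / (hi - lo) * (rhi - rlo) + rlo


def conform_geometry(image: np.ndarray, target_side: int, mode: str = "pad") -> np.ndarray:
    """Bring a 2D image to ``target_side`` square.

    ``pad`` centers the image with edge-replicate padding (inputs must not
    exceed the target); ``resample`` rescales bilinearly.
    """
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    if mode == "pad":
        if h > target_side or w > target_side:
            raise ValueError(f"input {h}x{w} exceeds pad target {target_side}")
        if (h, w) == (target_side, target_side):
            return image
        top = (target_side - h) // 2
        left = (target_side - w) // 2
        return np.pad(
            image,
            ((top, target_side - h - top), (left, target_side - w - left)),
            mode="edge",
        )
    if mode == "resample":
        from skimage.transform import resize

        if (h, w) == (target_side, target_side):
            return image
        return resize(image, (target_side, target_side), order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)
    raise ValueError("mode must be 'pad' or 'resample'")


# ------------------------------------------------------------------ directories
def save_image_set(image_set: ImageSet, out_dir, fmt: str = "png") -> None:
    """Write one file per image plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lo, hi = image_set.normalized_range
    names = []
    for i, img in enumerate(image_set.images):
        if fmt == "png":
            arr = np.clip((img - lo) / (hi - lo) * 255.0, 0, 255).round().astype(np.uint8)
            name = f"img_{i:05d}.png"
            Image.fromarray(arr, mode="L").save(out_dir / name)
        elif fmt == "nifti":
            import nibabel as nib

            name = f"img_{i:05d}.nii"
            nib.save(nib.Nifti1Image(img.astype(np.float32), np.eye(4)), out_dir / name)
        else:
            raise ValueError("fmt must be 'png' or 'nifti'")
        names.append(name)
    manifest = {
        "modality": image_set.modality,
        "normalized_range": list(image_set.normalized_range),
        "raw_range": list(image_set.raw_range),
        "pixel_spacing": list(image_set.pixel_spacing) if image_set.pixel_spacing else None,
        "format": fmt,
        "files": names,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def load_image_set(in_dir) -> ImageSet:
    """Load a directory written by :func:`save_image_set` (or raw PNGs)."""
    in_dir = Path(in_dir)
    manifest_path = in_dir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        fmt = manifest.get("format", "png")
        files = [in_dir / f for f in manifest["files"]]
        modality = manifest["modality"]
        norm_range = tuple(manifest["normalized_range"])
        raw_range = tuple(manifest["raw_range"])
        spacing = tuple(manifest["pixel_spacing"]) if manifest.get("pixel_spacing") else None
    else:
        files = sorted(p for p in in_dir.iterdir() if p.suffix.lower() == ".png")
        fmt, modality, norm_range, raw_range, spacing = "png", "phantom", (-1.0, 1.0), (-1.0, 1.0), None
    if not files:
        raise FileNotFoundError(f"no images found in {in_dir}")
    images = []
    lo, hi = norm_range
    for f in files:
        if fmt == "png":
            arr = np.asarray(Image.open(f).convert("L"), dtype=np.float64)
            images.append(arr / 255.0 * (hi - lo) + lo)
        else:
            import nibabel as nib

            images.append(np.asarray(nib.load(str(f)).get_fdata(), dtype=np.float64))
    return ImageSet(np.stack(images), modality, norm_range, raw_range, spacing)
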