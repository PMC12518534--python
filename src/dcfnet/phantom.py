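"""Seeded synthetic segmentation phantoms for three imaging regimes.

The generator emulates the difficulty axes of clinical 2D segmentation —
low contrast between classes, weak (blurred) boundaries, irregular
smoothly-deformed shapes, and acquisition noise — in three regimes:

* ``multi_organ`` — CT-like slice with 8 organ-like structures of varied
  size plus background (9 classes), mimicking abdominal multi-organ data;
* ``cardiac`` — MR-like slice with a ventricle/myocardium/ventricle
  triplet plus background (4 classes): an inner disk (LV blood pool), a
  ring around it (myocardium), and an adjacent crescent (RV);
* ``lesion`` — a single irregular lesion on textured background
  (2 classes), mimicking dermoscopy.

Identical (spec, index) always reproduces the same image bytes. Images
are float in [0, 1]; masks are exact integer label maps (computed before
blurring and noise, so the geometry is ground truth by construction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .config import ConfigError

__all__ = [
    "PhantomSpec",
    "REGIME_CLASSES",
    "generate_phantom",
    "generate_split",
    "load_split",
    "augment",
    "apply_transform",
    "identity_transform",
    "save_nifti_volume",
]

REGIME_CLASSES = {"multi_organ": 9, "cardiac": 4, "lesion": 2}


@dataclass
class PhantomSpec:
    """Generation parameters for one synthetic dataset."""

    regime: str = "multi_organ"
    img_size: int = 224
    contrast: float = 0.6
    noise_sd: float = 0.04
    boundary_softness: float = 1.5
    n_images: int = 100
    seed: int = 0

    @property
    def num_classes(self) -> int:
        return REGIME_CLASSES[self.regime]

    def validate(self):
        if self.regime not in REGIME_CLASSES:
            raise ConfigError(f"unknown regime {self.regime!r}")
        if not (0 < self.contrast <= 1):
            raise ConfigError("contrast must lie in (0, 1]")
        if self.noise_sd < 0 or self.boundary_softness < 0:
            raise ConfigError("noise_sd and boundary_softness must be >= 0")
        if self.img_size < 16 or self.n_images < 1:
            raise ConfigError("img_size and n_images must be positive (img_size >= 16)")


def _blob_mask(size: int, center, radii, angle: float, rng) -> np.ndarray:
    """Rasterize a smoothly deformed ellipse (irregular organ shape)."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dy, dx = yy - center[0], xx - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = (ca * dx + sa * dy) / radii[1]
    v = (-sa * dx + ca * dy) / radii[0]
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    bound = np.ones_like(theta)
    for m in range(2, 6):
        amp = rng.uniform(0.0, 0.25 / m)
        bound += amp * np.cos(m * theta + rng.uniform(0, 2 * np.pi))
    return rho <= bound


def _place(occupied: np.ndarray, size: int, r_range, rng, margin: float = 0.02,
           max_tries: int = 60):
    """Find a non-overlapping blob; returns its mask or None."""
    for _ in range(max_tries):
        r = rng.uniform(*r_range) * size
        aspect = rng.uniform(0.6, 1.0)
        c = rng.uniform(r * 1.1, size - r * 1.1, size=2)
        blob = _blob_mask(size, c, (r, r * aspect), rng.uniform(0, np.pi), rng)
        grown = ndimage.binary_dilation(blob, iterations=max(1, int(margin * size)))
        if not (grown & occupied).any():
            return blob
    return None


def _mask_multi_organ(size: int, rng) -> np.ndarray:
    mask = np.zeros((size, size), dtype=np.int64)
    occupied = np.zeros_like(mask, dtype=bool)
    # organ size ranges as fractions of the image side (large liver-like
    # structure down to small gland-like structures)
    ranges = [(0.13, 0.18), (0.10, 0.14), (0.08, 0.12), (0.08, 0.12),
              (0.06, 0.10), (0.06, 0.10), (0.05, 0.08), (0.04, 0.07)]
    for cls, rr in enumerate(ranges, start=1):
        blob = _place(occupied, size, rr, rng)
        if blob is None:
            continue  # skip an organ rather than fail; census tested on average
        mask[blob] = cls
        occupied |= blob
    if mask.max() == 0:
        raise RuntimeError(f"phantom placement failed for multi_organ at size {size}")
    return mask


def _mask_cardiac(size: int, rng) -> np.ndarray:
    mask = np.zeros((size, size), dtype=np.int64)
    c = rng.uniform(0.35 * size, 0.65 * size, size=2)
    r_lv = rng.uniform(0.08, 0.12) * size
    r_myo = r_lv + rng.uniform(0.04, 0.06) * size
    disk_myo = _blob_mask(size, c, (r_myo, r_myo), 0.0, rng)
    disk_lv = _blob_mask(size, c, (r_lv, r_lv), 0.0, rng)
    # RV: crescent-like blob adjacent to the myocardium
    ang = rng.uniform(0, 2 * np.pi)
    c_rv = c + 1.5 * r_myo * np.array([np.sin(ang), np.cos(ang)])
    c_rv = np.clip(c_rv, 0.15 * size, 0.85 * size)
    rv = _blob_mask(size, c_rv, (r_myo * 0.9, r_myo * 0.55), ang, rng)
    mask[rv] = 1                       # RV
    mask[disk_myo] = 2                 # myocardium ring (under LV for now)
    mask[disk_lv & disk_myo] = 3       # LV blood pool
    return mask


def _mask_lesion(size: int, rng) -> np.ndarray:
    mask = np.zeros((size, size), dtype=np.int64)
    blob = _place(np.zeros_like(mask, dtype=bool), size, (0.15, 0.3), rng)
    if blob is None:
        raise RuntimeError(f"phantom placement failed for lesion at size {size}")
    mask[blob] = 1
    return mask


def class_intensity(cls: int, num_classes: int, contrast: float) -> float:
    """Class gray level: evenly spaced levels spanning ``contrast`` around 0.5."""
    return 0.5 + contrast * (cls / (num_classes - 1) - 0.5)


def generate_phantom(spec: PhantomSpec, index: int):
    """Return (image, mask) for dataset item ``index``: image float64 in
    [0, 1] of shape (S, S), mask int64 of shape (S, S)."""
    spec.validate()
    if index < 0:
        raise ConfigError("index must be >= 0")
    rng = np.random.default_rng([abs(spec.seed) % (2 ** 31), index])
    size = spec.img_size
    if spec.regime == "multi_organ":
        mask = _mask_multi_organ(size, rng)
    elif spec.regime == "cardiac":
        mask = _mask_cardiac(size, rng)
    else:
        mask = _mask_lesion(size, rng)
    levels = np.array([class_intensity(c, spec.num_classes, spec.contrast)
                       for c in range(spec.num_classes)])
    img = levels[mask]
    # smooth within-class texture, scaled to stay well below the contrast step
    texture = ndimage.gaussian_filter(rng.normal(0, 1, mask.shape), 3.0)
    step = spec.contrast / (spec.num_classes - 1)
    img = img + 0.15 * step * texture / max(np.abs(texture).max(), 1e-9)
    if spec.boundary_softness > 0:
        img = ndimage.gaussian_filter(img, spec.boundary_softness)
    if spec.noise_sd > 0:
        img = img + rng.normal(0, spec.noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0), mask


# ---------------------------------------------------------------------------
# splits and on-disk layout
# ---------------------------------------------------------------------------

def generate_split(spec: PhantomSpec, fractions, out_dir) -> dict:
    """Generate the dataset into ``out_dir/{train,val,test}`` as 8-bit PNG
    image/mask pairs with a JSON manifest; returns the manifest."""
    spec.validate()
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError(f"split fractions must sum to 1, got {fractions}")
    out_dir = Path(out_dir)
    n = spec.n_images
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    counts = (n_train, n_val, n - n_train - n_val)
    indices = {
        "train": list(range(counts[0])),
        "val": list(range(counts[0], counts[0] + counts[1])),
        "test": list(range(counts[0] + counts[1], n)),
    }
    for split, idxs in indices.items():
        d = out_dir / split
        d.mkdir(parents=True, exist_ok=True)
        for i in idxs:
            img, mask = generate_phantom(spec, i)
            Image.fromarray(np.round(img * 255).astype(np.uint8)).save(d / f"img_{i:05d}.png")
            Image.fromarray(mask.astype(np.uint8)).save(d / f"mask_{i:05d}.png")
    manifest = {"spec": asdict(spec), "num_classes": spec.num_classes,
                "fractions": list(fractions), "indices": indices}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_split(data_dir, split: str):
    """Load one split back as (images (N,S,S) float, masks (N,S,S) int)."""
    d = Path(data_dir) / split
    imgs, masks = [], []
    for f in sorted(d.glob("img_*.png")):
        imgs.append(np.asarray(Image.open(f), dtype=np.float64) / 255.0)
        masks.append(np.asarray(Image.open(d / f.name.replace("img_", "mask_")),
                                dtype=np.int64))
    if not imgs:
        raise FileNotFoundError(f"no phantom images under {d}")
    return np.stack(imgs), np.stack(masks)


def save_nifti_volume(images: np.ndarray, masks: np.ndarray, out_prefix) -> None:
    """Stack (N, S, S) slices into NIfTI volumes (volumetric metric path)."""
    import nibabel as nib
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.moveaxis(images, 0, -1).astype(np.float32), affine),
             str(out_prefix) + "_img.nii.gz")
    nib.save(nib.Nifti1Image(np.moveaxis(masks, 0, -1).astype(np.int16), affine),
             str(out_prefix) + "_mask.nii.gz")


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def identity_transform() -> dict:
    return {"flip_h": False, "flip_v": False, "rot90": 0, "angle": 0.0}


def apply_transform(image: np.ndarray, mask: np.ndarray, t: dict):
    """Apply one geometric transform jointly to an aligned pair.

    Flips and quarter-turns permute pixels exactly; the small-angle
    rotation interpolates the image bilinearly and the mask by nearest
    neighbor, so label values are preserved.
    """
    if image.shape != mask.shape:
        raise ValueError("image and mask must be aligned")
    img, msk = image.copy(), mask.copy()
    if t["flip_h"]:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if t["flip_v"]:
        img, msk = img[::-1, :], msk[::-1, :]
    k = int(t["rot90"]) % 4
    if k:
        img, msk = np.rot90(img, k), np.rot90(msk, k)
    if abs(t["angle"]) > 1e-12:
        img = ndimage.rotate(img, t["angle"], reshape=False, order=1, mode="nearest")
        msk = ndimage.rotate(msk, t["angle"], reshape=False, order=0, mode="nearest")
    return np.ascontiguousarray(img), np.ascontiguousarray(msk)


def augment(image: np.ndarray, mask: np.ndarray, seed: int):
    """Random joint flip / quarter-turn / small-angle (+-20 deg) rotation."""
    rng = np.random.default_rng(seed)
    t = {
        "flip_h": bool(rng.random() < 0.5),
        "flip_v": bool(rng.random() < 0.5),
        "rot90": int(rng.integers(0, 4)),
        "angle": float(rng.uniform(-20.0, 20.0)) if rng.random() < 0.5 else 0.0,
    }
    return apply_transform(image, mask, t)
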