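"""Seeded synthetic breast-ultrasound phantom generator.

Each phantom is a hypoechoic (dark) lesion with an irregular, star-shaped
boundary on a brighter speckled background, optionally with bright internal
calcification spots and a posterior enhancement/shadow band below the
lesion — the confounds that make B-mode lesion segmentation hard. The
ground-truth mask and a loose RROI (lesion bounding box plus a margin,
mimicking a radiologist's drag box) are returned alongside the image, so
every pipeline stage is testable without any clinical dataset.

The generator is a simplified appearance model, not an acoustic simulator:
speckle is unit-mean multiplicative gamma noise with a short spatial
correlation, and geometry is drawn in the image plane (no beam geometry or
depth-dependent attenuation).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import DomainError
from .image_model import RROI, as_binary_mask

__all__ = [
    "PhantomParams",
    "PhantomSample",
    "PRESETS",
    "lesion_shape",
    "speckle_field",
    "generate_phantom",
    "phantom_params",
    "write_phantom_set",
]


@dataclass(frozen=True)
class PhantomParams:
    shape: tuple[int, int] = (160, 160)
    centre: tuple[int, int] = (80, 80)
    semi_axes: tuple[float, float] = (22.0, 28.0)  # (rows, cols)
    irregularity: float = 0.15
    lesion_mean: float = 55.0
    background_mean: float = 150.0
    speckle_scale: float = 0.25
    calcification_count: int = 0
    posterior_gain: float = 1.0
    rroi_margin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.irregularity < 0.5:
            raise DomainError("irregularity must lie in [0, 0.5)")
        if not (0 <= self.lesion_mean <= 255 and 0 <= self.background_mean <= 255):
            raise DomainError("mean intensities must lie in [0, 255]")
        if self.calcification_count < 0:
            raise DomainError("calcification count must be >= 0")
        if self.rroi_margin < 0:
            raise DomainError("rroi margin must be >= 0")


@dataclass(frozen=True)
class PhantomSample:
    image: np.ndarray
    gt: np.ndarray
    rroi: RROI
    params: PhantomParams


def lesion_shape(params: PhantomParams) -> np.ndarray:
    """Star-shaped lesion mask: an ellipse whose radius is modulated by a
    seeded low-order harmonic series of relative amplitude
    ``params.irregularity`` (harmonics k = 2..6, so the perturbation has
    zero mean and the mask stays a single hole-free component)."""
    b, a = params.semi_axes  # row, col semi-axes
    if b < 2 or a < 2:
        raise DomainError("lesion semi-axes must be >= 2 pixels")
    rng = np.random.default_rng(params.seed)
    ks = np.arange(2, 7)
    amps = rng.normal(size=ks.size) / ks  # damp high orders
    phases = rng.uniform(0, 2 * np.pi, size=ks.size)
    rr = np.arange(params.shape[0], dtype=np.float64)[:, None] - params.centre[0]
    cc = np.arange(params.shape[1], dtype=np.float64)[None, :] - params.centre[1]
    rho = np.sqrt((rr / b) ** 2 + (cc / a) ** 2)
    phi = np.arctan2(rr / b, cc / a)
    if params.irregularity > 0:
        f = np.zeros_like(phi)
        for k, amp, ph in zip(ks, amps, phases):
            f += amp * np.cos(k * phi + ph)
        peak = np.abs(f).max()
        if peak > 0:
            f = f / peak
        boundary = 1.0 + params.irregularity * f
    else:
        boundary = np.ones_like(phi)
    mask = rho <= boundary
    rows, cols = np.nonzero(mask)
    if (
        rows.min() == 0
        or cols.min() == 0
        or rows.max() == params.shape[0] - 1
        or cols.max() == params.shape[1] - 1
    ):
        raise DomainError("lesion shape exits the image")
    return mask


def speckle_field(shape: tuple[int, int], scale: float, seed: int) -> np.ndarray:
    """Unit-mean multiplicative speckle factor field.

    Gamma-distributed (right-skewed) with standard deviation ``scale``,
    lightly smoothed to give speckle its grain; the smoothing keeps the
    mean at 1. ``scale`` <= 0 degenerates to a field of ones.
    """
    if scale <= 0:
        return np.ones(shape)
    rng = np.random.default_rng(seed)
    k = 1.0 / scale**2
    field = rng.gamma(k, 1.0 / k, size=shape)
    return ndimage.gaussian_filter(field, 0.5, mode="nearest")


def generate_phantom(params: PhantomParams | None = None) -> PhantomSample:
    """Compose background, lesion, calcifications and posterior band, then
    apply multiplicative speckle; returns image + ground truth + RROI."""
    params = params or PhantomParams()
    rng = np.random.default_rng(np.random.default_rng(params.seed).integers(2**31))
    gt = lesion_shape(params)
    img = np.full(params.shape, params.background_mean, dtype=np.float64)
    img[gt] = params.lesion_mean

    rows, cols = np.nonzero(gt)
    r1, r2 = rows.min(), rows.max()
    c1, c2 = cols.min(), cols.max()

    if params.posterior_gain != 1.0:
        band = np.zeros(params.shape, dtype=bool)
        depth = r2 - r1 + 1
        band[r2 + 1 : min(params.shape[0], r2 + 1 + depth), c1 : c2 + 1] = True
        band &= ~gt
        gain = np.ones(params.shape)
        gain[band] = params.posterior_gain
        gain = ndimage.gaussian_filter(gain, 2.0, mode="nearest")
        img *= gain

    img = ndimage.gaussian_filter(img, 1.0, mode="nearest")  # soften edges

    if params.calcification_count:
        interior = ndimage.binary_erosion(gt, iterations=4)
        ir, ic = np.nonzero(interior)
        if len(ir) == 0:
            raise DomainError("lesion too small for internal calcifications")
        picks = rng.choice(len(ir), size=params.calcification_count, replace=False)
        rr_g = np.arange(params.shape[0])[:, None]
        cc_g = np.arange(params.shape[1])[None, :]
        for p in picks:
            rad = rng.uniform(1.0, 1.5)  # 2-3 px across
            spot = (rr_g - ir[p]) ** 2 + (cc_g - ic[p]) ** 2 <= rad**2
            img[spot] = 240.0

    speckle_seed = int(np.random.default_rng(params.seed + 1).integers(2**31))
    img *= speckle_field(params.shape, params.speckle_scale, speckle_seed)
    img = np.clip(img, 0.0, 255.0)

    m = params.rroi_margin
    rroi = RROI(
        w1=max(0, int(c1) - m),
        w2=min(params.shape[1], int(c2) + 1 + m),
        h1=max(0, int(r1) - m),
        h2=min(params.shape[0], int(r2) + 1 + m),
    )
    return PhantomSample(image=img, gt=as_binary_mask(gt), rroi=rroi, params=params)


# Parameter presets exercising the four AMS dispatch branches and the
# image confounds discussed for real lesions.
PRESETS: dict[str, dict] = {
    "default": {},
    "tall": {"semi_axes": (34.0, 16.0), "rroi_margin": 6},
    "wide": {"semi_axes": (16.0, 34.0), "rroi_margin": 6},
    "small": {"semi_axes": (6.0, 5.0), "rroi_margin": 3, "irregularity": 0.1},
    "calcified": {"calcification_count": 3},
    "shadowed": {"posterior_gain": 0.6},
    "enhanced": {"posterior_gain": 1.3},
}


def phantom_params(seed: int, preset: str = "default") -> PhantomParams:
    """Deterministic per-seed phantom parameters with mild geometric jitter
    (centre +-4 px, semi-axes +-10%) around the preset's geometry."""
    if preset not in PRESETS:
        raise DomainError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    base = PhantomParams(seed=seed, **PRESETS[preset])
    rng = np.random.default_rng(seed + 10_000)
    jit_c = rng.integers(-4, 5, size=2)
    jit_ax = rng.uniform(0.9, 1.1, size=2)
    return replace(
        base,
        centre=(int(base.centre[0] + jit_c[0]), int(base.centre[1] + jit_c[1])),
        semi_axes=(base.semi_axes[0] * jit_ax[0], base.semi_axes[1] * jit_ax[1]),
    )


def write_phantom_set(
    out_dir: str | Path, n: int, seed: int = 0, preset: str = "default"
) -> Path:
    """Write ``n`` phantoms (img_XXX.png, gt_XXX.png) plus a manifest CSV
    with the RROI bounds; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image", "gt", "w1", "h1", "w2", "h2", "seed", "preset"])
        for i in range(n):
            s = seed + i
            sample = generate_phantom(phantom_params(s, preset))
            img_name = f"img_{i:03d}.png"
            gt_name = f"gt_{i:03d}.png"
            Image.fromarray(np.round(sample.image).astype(np.uint8), mode="L").save(
                out_dir / img_name
            )
            Image.fromarray(sample.gt.astype(np.uint8) * 255, mode="L").save(
                out_dir / gt_name
            )
            r = sample.rroi
            writer.writerow([img_name, gt_name, r.w1, r.h1, r.w2, r.h2, s, preset])
    return manifest
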