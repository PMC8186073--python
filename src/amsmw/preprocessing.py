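"""Image preprocessing: contrast enhancement, side-window filtering, the
constrained Gaussian weighting that highlights the region of interest, and
the grayscale openings feeding the marker and segmentation functions.

The chain (default scheme ``clahe_swf``) is::

    I --CLAHE--> --SWF--> I_enh --Gaussian weighting--> J --opening r=9--> J_M
                                                          --opening r=15-> J_N

``J`` inverts contrast: the hypoechoic (dark) lesion becomes the brightest
structure, weighted by a union of five Gaussians anchored on the
radiologist's RROI, so that everything far from the box is strongly
darkened. ``J_M`` seeds the watershed marker function and ``J_N`` the
segmentation (flood) surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import exposure, morphology

from .errors import DomainError
from .image_model import RROI, as_gray_image, rroi_center

__all__ = [
    "ClaheParams",
    "SwfParams",
    "PreprocessedPair",
    "clahe",
    "side_window_filter",
    "constrained_gaussian_set",
    "gaussian_centres",
    "apply_gaussian_weighting",
    "opening_disk",
    "preprocess",
    "SCHEMES",
]

SCHEMES = ("clahe_swf", "swf_only", "clahe_only", "none")


@dataclass(frozen=True)
class ClaheParams:
    """Contrast-limited adaptive histogram equalization parameters.

    ``clip_limit`` is the histogram clip expressed as a multiple of the
    uniform bin height (the familiar cv2-style scale); 2.0 means each bin
    may hold at most twice the average count before the excess is
    redistributed.
    """

    clip_limit: float = 2.0
    tile_rows: int = 8
    tile_cols: int = 8

    def __post_init__(self) -> None:
        if self.clip_limit <= 0:
            raise DomainError("clip_limit must be positive")
        if self.tile_rows < 1 or self.tile_cols < 1:
            raise DomainError("tile counts must be >= 1")


@dataclass(frozen=True)
class SwfParams:
    radius: int = 3
    kernel: str = "box"
    iterations: int = 5

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise DomainError("SWF radius must be >= 1")
        if self.kernel not in ("box", "gaussian"):
            raise DomainError(f"unknown SWF kernel {self.kernel!r}")
        if self.iterations < 1:
            raise DomainError("SWF iterations must be >= 1")


@dataclass(frozen=True)
class PreprocessedPair:
    """Outputs of the preprocessing stage.

    ``enhanced`` is the contrast-enhanced, edge-preserving-filtered image in
    the original polarity (lesion dark); ``J`` is the Gaussian-weighted
    inverted image rescaled to [0, 255]; ``J_M``/``J_N`` are its openings
    with 9- and 15-pixel-radius disks.
    """

    enhanced: np.ndarray
    J: np.ndarray
    J_M: np.ndarray
    J_N: np.ndarray
    scheme: str = "clahe_swf"
    extras: dict = field(default_factory=dict)


def clahe(image: np.ndarray, params: ClaheParams | None = None) -> np.ndarray:
    """Tile-wise histogram equalization with a clipped histogram.

    A constant image is returned unchanged (there is no contrast to
    redistribute); tiles larger than the image are reduced to a single tile
    with a warning.
    """
    image = as_gray_image(image)
    params = params or ClaheParams()
    if image.max() - image.min() < 1e-9:
        return image.copy()
    kr = image.shape[0] // params.tile_rows
    kc = image.shape[1] // params.tile_cols
    if kr < 1 or kc < 1:
        warnings.warn("CLAHE tile larger than image; using a single tile", stacklevel=2)
        kr, kc = image.shape
    out = exposure.equalize_adapthist(
        image / 255.0,
        kernel_size=(max(kr, 1), max(kc, 1)),
        clip_limit=min(1.0, params.clip_limit / 256.0),
        nbins=256,
    )
    return np.clip(out * 255.0, 0.0, 255.0)


def _side_window_kernels(r: int, kernel: str) -> list[np.ndarray]:
    """The eight normalised side-window kernels, in index order
    L, R, U, D, NW, NE, SW, SE.

    Each is a (2r+1)x(2r+1) kernel zeroed outside its half/quarter window:
    L/R/U/D align the target pixel with a side of the window, the four
    corner windows align it with a corner.
    """
    size = 2 * r + 1
    if kernel == "box":
        base = np.ones((size, size))
    else:  # gaussian weights, sigma = r/2 over the full window
        ax = np.arange(size) - r
        g = np.exp(-(ax**2) / (2 * (r / 2.0) ** 2))
        base = np.outer(g, g)
    full = slice(0, size)
    lo = slice(0, r + 1)  # rows above / cols left of centre, inclusive
    hi = slice(r, size)  # rows below / cols right of centre, inclusive
    windows = {
        "L": (full, lo),
        "R": (full, hi),
        "U": (lo, full),
        "D": (hi, full),
        "NW": (lo, lo),
        "NE": (lo, hi),
        "SW": (hi, lo),
        "SE": (hi, hi),
    }
    kernels = []
    for name in ("L", "R", "U", "D", "NW", "NE", "SW", "SE"):
        k = np.zeros((size, size))
        rs, cs = windows[name]
        k[rs, cs] = base[rs, cs]
        kernels.append(k)
    return kernels


def side_window_filter(image: np.ndarray, params: SwfParams | None = None) -> np.ndarray:
    """Edge-preserving side-window filter.

    For every pixel the eight side-window means are computed (windows whose
    side or corner, rather than centre, aligns with the pixel) and the one
    closest to the pixel's own intensity is kept. A window lying entirely on
    one side of an edge reproduces the pixel exactly, so ideal step edges
    are fixed points. Borders are handled by edge replication. Ties go to
    the first window in the index order L, R, U, D, NW, NE, SW, SE.
    """
    image = as_gray_image(image)
    params = params or SwfParams()
    if params.radius >= min(image.shape):
        raise DomainError("SWF radius must be smaller than the smallest image dimension")
    kernels = _side_window_kernels(params.radius, params.kernel)
    out = image
    for _ in range(params.iterations):
        # weighted sums first, one division by the weight total at the end:
        # box-kernel means of integer-valued images are then exact, so a
        # window lying flat on one side of a step reproduces q_i bitwise.
        means = np.stack(
            [ndimage.correlate(out, k, mode="nearest") / k.sum() for k in kernels],
            axis=0,
        )
        dev = (means - out[None]) ** 2
        pick = np.argmin(dev, axis=0)
        out = np.take_along_axis(means, pick[None], axis=0)[0]
    return np.clip(out, 0.0, 255.0)


def gaussian_centres(rroi: RROI) -> list[tuple[int, int]]:
    """The five Gaussian centres: the RROI centre and its four diagonal
    translations by (round(sigma_h), round(sigma_w)) — i.e. the RROI
    corners, since sigma = half extent. Integer offsets keep the set
    exactly symmetric about the centre."""
    mh, mw = rroi_center(rroi)
    dh = int(round((rroi.h2 - rroi.h1) / 2.0))
    dw = int(round((rroi.w2 - rroi.w1) / 2.0))
    return [
        (mh, mw),
        (mh - dh, mw - dw),
        (mh - dh, mw + dw),
        (mh + dh, mw - dw),
        (mh + dh, mw + dw),
    ]


def constrained_gaussian_set(shape: tuple[int, int], rroi: RROI) -> np.ndarray:
    """Pixelwise maximum of the five constrained Gaussians.

    All five share sigma_w = (w2-w1)/2, sigma_h = (h2-h1)/2 and the peak
    height 1/(2 pi sigma_w sigma_h); only the centres differ.
    """
    rroi.validate_within(shape)
    if rroi.width < 2 or rroi.height < 2:
        raise DomainError("RROI extents must be >= 2 pixels for Gaussian weighting")
    sigma_w = rroi.width / 2.0
    sigma_h = rroi.height / 2.0
    rr = np.arange(shape[0], dtype=np.float64)[:, None]
    cc = np.arange(shape[1], dtype=np.float64)[None, :]
    norm = 1.0 / (2.0 * np.pi * sigma_w * sigma_h)
    field = np.zeros(shape, dtype=np.float64)
    for ch, cw in gaussian_centres(rroi):
        q = ((rr - ch) ** 2) / sigma_h**2 + ((cc - cw) ** 2) / sigma_w**2
        np.maximum(field, norm * np.exp(-0.5 * q), out=field)
    return field


def apply_gaussian_weighting(
    filtered: np.ndarray, weight_field: np.ndarray, rescale: bool = True
) -> np.ndarray:
    """J = G_T * (1 - I/max(I)): weight the *negative* of the filtered image
    so the dark lesion near the RROI becomes the brightest structure.

    With ``rescale`` the result is linearly mapped to [0, 255] so that the
    1-255 threshold sweep downstream is meaningful.
    """
    filtered = as_gray_image(filtered)
    if filtered.shape != weight_field.shape:
        raise DomainError("filtered image and weight field shapes differ")
    peak = filtered.max()
    if peak <= 0:
        raise DomainError("blank image")
    j = weight_field * (1.0 - filtered / peak)
    if not rescale:
        return j
    jmax = j.max()
    if jmax <= 0:
        return np.zeros_like(j)
    return np.clip(j * (255.0 / jmax), 0.0, 255.0)


def opening_disk(image: np.ndarray, radius: int) -> np.ndarray:
    """Grayscale morphological opening with a discrete disk of ``radius``."""
    if radius < 1:
        raise DomainError("opening radius must be >= 1")
    return morphology.opening(as_gray_image(image), morphology.disk(radius))


def preprocess(
    image: np.ndarray,
    rroi: RROI,
    scheme: str = "clahe_swf",
    clahe_params: ClaheParams | None = None,
    swf_params: SwfParams | None = None,
    marker_opening_radius: int = 9,
    segmentation_opening_radius: int = 15,
) -> PreprocessedPair:
    """Full preprocessing chain producing (enhanced, J, J_M, J_N)."""
    image = as_gray_image(image)
    rroi.validate_within(image.shape)
    if scheme not in SCHEMES:
        raise DomainError(f"unknown preprocessing scheme {scheme!r}; choose from {SCHEMES}")
    enhanced = image
    if scheme in ("clahe_swf", "clahe_only"):
        enhanced = clahe(enhanced, clahe_params)
    if scheme in ("clahe_swf", "swf_only"):
        enhanced = side_window_filter(enhanced, swf_params)
    field = constrained_gaussian_set(image.shape, rroi)
    j = apply_gaussian_weighting(enhanced, field)
    j_m = opening_disk(j, marker_opening_radius)
    j_n = opening_disk(j, segmentation_opening_radius)
    return PreprocessedPair(enhanced=enhanced, J=j, J_M=j_m, J_N=j_n, scheme=scheme)
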