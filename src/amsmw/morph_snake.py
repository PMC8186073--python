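"""Morphological geodesic active contour (morphological snake, MS) and its
adaptive variant (AMS).

The snake is a binary embedding ``u`` (1 inside the curve) evolved by three
morphological sub-steps per iteration:

1. balloon: unit dilation (v > 0) or erosion (v < 0) wherever
   ``|v| * g > theta``, with the 3x3 square (unit Chebyshev ball) as
   structuring element;
2. attraction: set ``u`` to 1/0 by the sign of the inner product of the
   gradients of ``u`` and of the edge-stopping function ``g``;
3. curvature smoothing: the SI/IS operators, which keep a white (black)
   pixel only if some (every) 3-pixel straight segment through it is white;
   the composition order alternates between iterations (SI o IS, then
   IS o SI) so neither the extensive nor the anti-extensive operator
   biases the curve.

AMS replaces the fixed circle initialisation of MS by a circle centred on
the RROI's geometric centre whose radius and iteration count are dispatched
from the RROI aspect ratio (tall lesions evolve longer, small boxes start
from a smaller circle).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DomainError
from .image_model import RROI, as_gray_image, rroi_center

__all__ = [
    "MsParams",
    "AmsParams",
    "STRAIGHT_SEGMENTS",
    "stopping_function",
    "circle_levelset",
    "smooth_si_is",
    "ms_evolve",
    "ams_params",
    "ams_segment",
]

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _segment_footprints() -> list[np.ndarray]:
    """3x3 footprints of the four 3-pixel straight segments through the
    origin: horizontal, vertical and the two diagonals."""
    offs = [
        [(0, -1), (0, 0), (0, 1)],
        [(-1, 0), (0, 0), (1, 0)],
        [(-1, -1), (0, 0), (1, 1)],
        [(-1, 1), (0, 0), (1, -1)],
    ]
    fps = []
    for seg in offs:
        fp = np.zeros((3, 3), dtype=bool)
        for dr, dc in seg:
            fp[dr + 1, dc + 1] = True
        fps.append(fp)
    return fps


STRAIGHT_SEGMENTS = _segment_footprints()


_SQUARE = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class MsParams:
    balloon: float = -1.0
    theta: float = 0.3
    iterations: int = 120
    smooth_passes: int = 1
    alpha: float = 20000.0
    sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise DomainError("iterations must be >= 1")
        if self.smooth_passes < 0:
            raise DomainError("smooth_passes must be >= 0")
        if self.theta < 0:
            raise DomainError("theta must be non-negative")


@dataclass(frozen=True)
class AmsParams:
    centre: tuple[int, int]
    radius: int
    iterations: int


def stopping_function(image: np.ndarray, alpha: float = 20000.0, sigma: float = 2.0) -> np.ndarray:
    """Edge-stopping field g = 1/sqrt(1 + alpha |grad(G_sigma * I)|^2).

    The image is normalised to [0, 1] before smoothing so that ``alpha`` is
    intensity-scale free; g is 1 on flat regions and approaches 0 on strong
    edges, which is where the snake is attracted and the balloon stalls.
    """
    if sigma <= 0 or alpha <= 0:
        raise DomainError("alpha and sigma must be positive")
    img = as_gray_image(image) / 255.0
    smoothed = ndimage.gaussian_filter(img, sigma, mode="nearest")
    gr, gc = np.gradient(smoothed)
    return 1.0 / np.sqrt(1.0 + alpha * (gr**2 + gc**2))


def circle_levelset(
    shape: tuple[int, int], centre: tuple[int, int], radius: float
) -> np.ndarray:
    """Binary disk: pixels within Euclidean distance ``radius`` of ``centre``."""
    if radius < 1:
        raise DomainError("circle radius must be >= 1")
    r0, c0 = centre
    if not (0 <= r0 < shape[0] and 0 <= c0 < shape[1]):
        raise DomainError(f"circle centre {centre} outside image of shape {shape}")
    rr = np.arange(shape[0])[:, None] - r0
    cc = np.arange(shape[1])[None, :] - c0
    return rr**2 + cc**2 <= radius**2


def _si(u: np.ndarray) -> np.ndarray:
    """Sup-inf operator: a white pixel survives iff some straight 3-pixel
    segment through it is entirely white; black pixels are unchanged (every
    segment contains the centre pixel)."""
    out = np.zeros_like(u)
    for fp in STRAIGHT_SEGMENTS:
        np.maximum(out, ndimage.minimum_filter(u, footprint=fp, mode="nearest"), out=out)
    return out


def _is(u: np.ndarray) -> np.ndarray:
    """Inf-sup operator, the dual: a black pixel turns white iff every
    straight segment through it contains a white pixel."""
    out = np.ones_like(u)
    for fp in STRAIGHT_SEGMENTS:
        np.minimum(out, ndimage.maximum_filter(u, footprint=fp, mode="nearest"), out=out)
    return out


def smooth_si_is(u: np.ndarray, passes: int = 1) -> np.ndarray:
    """Curvature smoothing SI o IS applied ``passes`` times (IS first).

    Pixels on straight or smooth edges are fixed points; isolated pixels and
    sharp single-pixel corners are removed.
    """
    u = np.ascontiguousarray(u, dtype=np.uint8)
    for _ in range(passes):
        u = _si(_is(u))
    return u


def ms_evolve(g: np.ndarray, init: np.ndarray, params: MsParams) -> np.ndarray:
    """Run the morphological snake for ``params.iterations`` iterations.

    ``g`` is the edge-stopping field and ``init`` the initial binary
    embedding (1 inside the curve). Returns the final binary mask.
    """
    g = np.asarray(g, dtype=np.float64)
    u = np.asarray(init)
    if g.shape != u.shape:
        raise DomainError("edge field and level-set shapes differ")
    if not u.any():
        raise DomainError("initial level set is empty")
    u = u.astype(np.uint8)
    ggr, ggc = np.gradient(g)
    balloon_zone = np.abs(params.balloon) * g > params.theta
    smooth_zone = g > 0
    for n in range(params.iterations):
        if params.balloon > 0:
            grown = ndimage.maximum_filter(u, footprint=_SQUARE, mode="nearest")
            u = np.where(balloon_zone, grown, u)
        elif params.balloon < 0:
            shrunk = ndimage.minimum_filter(u, footprint=_SQUARE, mode="nearest")
            u = np.where(balloon_zone, shrunk, u)
        dur, duc = np.gradient(u.astype(np.float64))
        dot = dur * ggr + duc * ggc
        u = np.where(dot > 0, 1, np.where(dot < 0, 0, u)).astype(np.uint8)
        if params.smooth_passes:
            smoothed = u
            for _ in range(params.smooth_passes):
                # alternate composition order to avoid directional bias
                smoothed = _is(_si(smoothed)) if n % 2 else _si(_is(smoothed))
            u = np.where(smooth_zone, smoothed, u).astype(np.uint8)
    return u.astype(bool)


def ams_params(rroi: RROI) -> AmsParams:
    """Adaptive dispatch of initial circle radius and iteration count.

    With RROI extents (h, w) in pixels:

    ====================  ===========  ==========
    condition             radius       iterations
    ====================  ===========  ==========
    min(h,w) >= 20, tall  w - 20       250
    min(h,w) >= 20, else  w - 20       120
    min(h,w) <  20, tall  w - 10       250
    min(h,w) <  20, else  w - 10       120
    ====================  ===========  ==========

    "tall" means h >= 1.5 w. The radius is clamped below by
    max(round(0.3 min(h,w)), 1) so small boxes (w <= 20) still yield a
    usable circle.
    """
    h, w = rroi.height, rroi.width
    base = w - 20 if min(h, w) >= 20 else w - 10
    iterations = 250 if h >= 1.5 * w else 120
    radius = max(base, int(round(0.3 * min(h, w))), 1)
    return AmsParams(centre=rroi_center(rroi), radius=radius, iterations=iterations)


def ams_segment(
    J: np.ndarray,
    rroi: RROI,
    ms: MsParams | None = None,
    dispatch_override: tuple[int, int] | None = None,
) -> np.ndarray:
    """Adaptive morphological snake on the preprocessed image ``J``.

    Builds the stopping function on J, initialises a circle level set from
    the RROI dispatch (or ``dispatch_override`` = (radius, iterations)), and
    evolves with a shrinking balloon. The largest 4-connected component is
    returned; if evolution collapses to an empty mask the initial circle is
    returned with a warning.
    """
    J = as_gray_image(J)
    rroi.validate_within(J.shape)
    ms = ms or MsParams()
    ap = ams_params(rroi)
    if dispatch_override is not None:
        ap = AmsParams(centre=ap.centre, radius=int(dispatch_override[0]),
                       iterations=int(dispatch_override[1]))
    g = stopping_function(J, alpha=ms.alpha, sigma=ms.sigma)
    init = circle_levelset(J.shape, ap.centre, ap.radius)
    run = MsParams(
        balloon=ms.balloon,
        theta=ms.theta,
        iterations=ap.iterations,
        smooth_passes=ms.smooth_passes,
        alpha=ms.alpha,
        sigma=ms.sigma,
    )
    u = ms_evolve(g, init, run)
    if not u.any():
        warnings.warn("AMS evolution collapsed to an empty mask; "
                      "falling back to the initial circle", stacklevel=2)
        return init
    labels, n = ndimage.label(u, structure=_CROSS)
    if n > 1:
        sizes = ndimage.sum_labels(u, labels, index=np.arange(1, n + 1))
        u = labels == (int(np.argmax(sizes)) + 1)
    return u.astype(bool)
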