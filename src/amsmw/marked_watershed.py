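"""Marker-function construction, AMS-corrected marked area, marker-controlled
watershed candidate generation, and final contour selection by the average
radial derivative (ARD).

Per threshold ``th`` in 1..255 the marker input ``J_M`` is binarised into
``f_p``; the internal marker is its erosion by a 15-pixel-radius disk and
the external marker the morphological gradient (by a 15-pixel-wide square)
of its dilation by the same disk. Intersecting the marker union with the
AMS pre-segmentation and closing with a 25-pixel-radius disk gives the
marked area, which seeds a watershed flood of the gradient surface of
``J_N``. The candidate contour whose mean outward image derivative (ARD) is
largest is the lesion boundary; the fast path skips the sweep and takes the
single candidate at threshold 96.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed as _skimage_watershed

from .errors import DomainError
from .image_model import (
    RROI,
    as_binary_mask,
    as_gray_image,
    mask_to_contour,
    rroi_center,
)
from .morph_snake import MsParams, ams_segment
from .preprocessing import ClaheParams, PreprocessedPair, SwfParams, preprocess

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerMask",
    "MarkedArea",
    "CandidateContour",
    "SegmentationResult",
    "binarize_at",
    "marker_function",
    "marked_area",
    "label_markers",
    "watershed_flood",
    "ard",
    "select_final_contour",
    "amsmw_segment",
]

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

MARKER_DISK_RADIUS = 15  # B1: 15-pixel-radius disk
MARKER_SQUARE_WIDTH = 15  # B2: 15-pixel-wide square
CLOSING_DISK_RADIUS = 25
FAST_THRESHOLD = 96


def _erosion_disk(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary erosion by the discrete Euclidean disk of ``radius`` (pixels
    outside the image count as background), via the distance transform."""
    padded = np.pad(mask, radius + 1, mode="constant", constant_values=False)
    dist = ndimage.distance_transform_edt(padded)
    out = dist > radius
    return out[radius + 1 : -(radius + 1), radius + 1 : -(radius + 1)]


def _dilation_disk(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary dilation by the discrete Euclidean disk of ``radius``."""
    if not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask)
    return dist <= radius


def _closing_disk(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary closing by the disk of ``radius``, padded so that structures
    near the border are treated the same as interior ones."""
    pad = radius + 1
    padded = np.pad(mask, pad, mode="constant", constant_values=False)
    closed = _erosion_disk(_dilation_disk(padded, radius), radius)
    return closed[pad:-pad, pad:-pad]


@dataclass(frozen=True)
class MarkerMask:
    internal: np.ndarray
    external: np.ndarray

    @property
    def union(self) -> np.ndarray:
        return self.internal | self.external


@dataclass(frozen=True)
class MarkedArea:
    mask: np.ndarray
    threshold: int

    @property
    def empty(self) -> bool:
        return not self.mask.any()


@dataclass(frozen=True)
class CandidateContour:
    contour: np.ndarray
    threshold: int
    ard_score: float
    mask: np.ndarray | None = None


@dataclass(frozen=True)
class SegmentationResult:
    mask: np.ndarray
    contour: np.ndarray
    threshold: int
    ams_mask: np.ndarray
    marked: MarkedArea | None
    candidates: tuple[CandidateContour, ...] = ()
    preprocessed: PreprocessedPair | None = None
    fallback: bool = False


def binarize_at(image: np.ndarray, th: int) -> np.ndarray:
    """Foreground = pixels with intensity >= th, th in [1, 255]."""
    if not 1 <= int(th) <= 255:
        raise DomainError(f"threshold {th} outside [1, 255]")
    return as_gray_image(image) >= th


def marker_function(f_p: np.ndarray) -> MarkerMask:
    """Internal marker: erosion of f_p by the 15-px disk. External marker:
    morphological gradient (dilation minus erosion by the 15-px square) of
    the 15-px-disk dilation of f_p."""
    f_p = as_binary_mask(f_p)
    internal = _erosion_disk(f_p, MARKER_DISK_RADIUS)
    grown = _dilation_disk(f_p, MARKER_DISK_RADIUS)
    u8 = grown.astype(np.uint8)
    dil = ndimage.maximum_filter(u8, size=MARKER_SQUARE_WIDTH, mode="constant", cval=0)
    ero = ndimage.minimum_filter(u8, size=MARKER_SQUARE_WIDTH, mode="constant", cval=0)
    external = (dil - ero).astype(bool)
    return MarkerMask(internal=internal, external=external)


def marked_area(ams_mask: np.ndarray, marker: MarkerMask, th: int) -> MarkedArea:
    """Intersection of the AMS segmentation with the marker union, closed
    with a 25-pixel-radius disk. An empty intersection yields an empty
    MarkedArea for the caller to fall back on."""
    ams_mask = as_binary_mask(ams_mask, marker.internal.shape)
    inter = ams_mask & marker.union
    if not inter.any():
        return MarkedArea(mask=inter, threshold=int(th))
    return MarkedArea(mask=_closing_disk(inter, CLOSING_DISK_RADIUS), threshold=int(th))


def label_markers(area: MarkedArea, rroi: RROI, shape: tuple[int, int]) -> np.ndarray:
    """Labelled marker image for the watershed: label 1 = the marked-area
    component nearest the RROI centre (the lesion seed), label 2 = a
    3-pixel border band minus a 5-pixel safety dilation of label 1."""
    if area.empty:
        raise DomainError("no lesion marker")
    mask = as_binary_mask(area.mask, shape)
    labels, n = ndimage.label(mask, structure=_CROSS)
    ch, cw = rroi_center(rroi)
    if labels[ch, cw] > 0:
        lesion = labels == labels[ch, cw]
    else:
        rows, cols = np.nonzero(mask)
        d2 = (rows - ch) ** 2 + (cols - cw) ** 2
        lesion = labels == labels[rows[np.argmin(d2)], cols[np.argmin(d2)]]
    out = np.zeros(shape, dtype=np.int32)
    out[lesion] = 1
    band = np.zeros(shape, dtype=bool)
    band[:3, :] = band[-3:, :] = True
    band[:, :3] = band[:, -3:] = True
    band &= ~_dilation_disk(lesion, 5)
    out[band] = 2
    return out


def watershed_flood(surface: np.ndarray, markers: np.ndarray) -> np.ndarray:
    """Marker-controlled watershed flooding (4-connectivity) of ``surface``;
    returns the region grown from label 1."""
    surface = np.asarray(surface, dtype=np.float64)
    labs = np.unique(markers)
    if (labs > 0).sum() < 2:
        raise DomainError("watershed needs at least two marker labels")
    ws = _skimage_watershed(surface, markers=markers, connectivity=1)
    return ws == 1


def ard(image: np.ndarray, contour: np.ndarray, centre: tuple[int, int]) -> float:
    """Average radial derivative: mean over contour points of the central
    difference image gradient projected on the unit outward radial direction
    from ``centre``. Points coincident with the centre are skipped."""
    image = as_gray_image(image)
    pts = np.asarray(contour, dtype=np.intp)
    if len(pts) == 0:
        raise DomainError("empty contour")
    r0, c0 = centre
    if not (0 <= r0 < image.shape[0] and 0 <= c0 < image.shape[1]):
        raise DomainError("centre outside image")
    gr, gc = np.gradient(image)
    dr = pts[:, 0] - r0
    dc = pts[:, 1] - c0
    norm = np.sqrt(dr.astype(np.float64) ** 2 + dc.astype(np.float64) ** 2)
    keep = norm > 0
    if not keep.any():
        raise DomainError("all contour points coincide with the centre")
    dr, dc, norm = dr[keep], dc[keep], norm[keep]
    p = pts[keep]
    vals = gr[p[:, 0], p[:, 1]] * (dr / norm) + gc[p[:, 0], p[:, 1]] * (dc / norm)
    return float(vals.mean())


def select_final_contour(
    candidates: list[CandidateContour] | tuple[CandidateContour, ...],
    mode: str = "fast",
    fast_threshold: int = FAST_THRESHOLD,
) -> CandidateContour:
    """Fast mode: the candidate at the calibrated threshold (nearest
    available one if absent, ties toward the lower threshold). Full mode:
    the candidate with the largest ARD, ties broken toward the calibrated
    threshold and then the lower threshold."""
    if not candidates:
        raise DomainError("no candidate contours")
    if mode == "fast":
        return min(
            candidates, key=lambda c: (abs(c.threshold - fast_threshold), c.threshold)
        )
    if mode == "full":
        return min(
            candidates,
            key=lambda c: (-c.ard_score, abs(c.threshold - fast_threshold), c.threshold),
        )
    raise DomainError(f"unknown selection mode {mode!r}")


def _gradient_surface(image: np.ndarray) -> np.ndarray:
    """Morphological gradient (radius-1 disk) of the segmentation input;
    the watershed relief whose ridges are the lesion boundary."""
    dil = ndimage.maximum_filter(image, footprint=_CROSS, mode="nearest")
    ero = ndimage.minimum_filter(image, footprint=_CROSS, mode="nearest")
    return dil - ero


def amsmw_segment(
    image: np.ndarray,
    rroi: RROI,
    mode: str = "fast",
    scheme: str = "clahe_swf",
    clahe_params: ClaheParams | None = None,
    swf_params: SwfParams | None = None,
    ms_params: MsParams | None = None,
    dispatch_override: tuple[int, int] | None = None,
    fast_threshold: int = FAST_THRESHOLD,
    keep_candidates: bool = False,
    preprocessed: PreprocessedPair | None = None,
) -> SegmentationResult:
    """End-to-end semi-automatic lesion segmentation.

    Preprocess, run the adaptive morphological snake on J, then per
    threshold build the marker function, intersect, close, label and flood.
    Fast mode evaluates only the calibrated threshold; full mode sweeps
    1..255 and keeps the ARD argmax. Deterministic for fixed inputs.

    ``preprocessed`` lets a caller reuse an existing PreprocessedPair (the
    RROI and scheme must match how it was produced).
    """
    if mode not in ("fast", "full"):
        raise DomainError(f"unknown mode {mode!r}")
    image = as_gray_image(image)
    rroi.validate_within(image.shape)
    if rroi.width < 5 or rroi.height < 5:
        raise DomainError("RROI extents must be at least 5 pixels")

    pp = preprocessed or preprocess(
        image, rroi, scheme=scheme, clahe_params=clahe_params, swf_params=swf_params
    )
    ams_mask = ams_segment(pp.J, rroi, ms=ms_params, dispatch_override=dispatch_override)
    centre = rroi_center(rroi)
    surface = _gradient_surface(pp.J_N)
    # ARD is scored on the enhanced image in the original polarity (lesion
    # dark), so the true boundary maximises the outward derivative.
    score_image = pp.enhanced

    thresholds = [int(fast_threshold)] if mode == "fast" else list(range(1, 256))
    candidates: list[CandidateContour] = []
    for th in thresholds:
        f_p = binarize_at(pp.J_M, th)
        if not f_p.any():
            continue
        marker = marker_function(f_p)
        area = marked_area(ams_mask, marker, th)
        if area.empty:
            continue
        labels = label_markers(area, rroi, image.shape)
        if (np.unique(labels) > 0).sum() < 2:
            continue
        lesion = watershed_flood(surface, labels)
        if not lesion.any():
            continue
        contour = mask_to_contour(lesion)
        score = ard(score_image, contour, centre)
        candidates.append(
            CandidateContour(contour=contour, threshold=th, ard_score=score, mask=lesion)
        )
    if not candidates:
        warnings.warn(
            "empty marked area at all thresholds; falling back to the AMS mask",
            stacklevel=2,
        )
        contour = mask_to_contour(ams_mask)
        score = ard(score_image, contour, centre)
        best = CandidateContour(
            contour=contour, threshold=int(fast_threshold), ard_score=score, mask=ams_mask
        )
        return SegmentationResult(
            mask=ams_mask, contour=contour, threshold=best.threshold,
            ams_mask=ams_mask, marked=None, candidates=(best,) if keep_candidates else (),
            preprocessed=pp, fallback=True,
        )
    best = select_final_contour(candidates, mode=mode, fast_threshold=fast_threshold)
    logger.info(
        "amsmw_segment mode=%s chosen_th=%d ard=%.4f candidates=%d",
        mode, best.threshold, best.ard_score, len(candidates),
    )
    best_marked = marked_area(ams_mask, marker_function(binarize_at(pp.J_M, best.threshold)),
                              best.threshold)
    return SegmentationResult(
        mask=best.mask,
        contour=best.contour,
        threshold=best.threshold,
        ams_mask=ams_mask,
        marked=best_marked,
        candidates=tuple(candidates) if keep_candidates else (),
        preprocessed=pp,
        fallback=False,
    )
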