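"""Core raster and geometry types: grayscale images, binary masks, the
rectangular region of interest (RROI), and mask/contour conversion.

Conventions used throughout the package
---------------------------------------
* Images are 2-D ``float64`` arrays with intensities in ``[0, 255]``; masks
  are 2-D ``bool`` arrays.
* Coordinates are 0-based ``(row, col)`` with row 0 at the top.
* RROI bounds are half-open: columns ``[w1, w2)``, rows ``[h1, h2)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import DomainError, ImageIOError

__all__ = [
    "RROI",
    "as_gray_image",
    "as_binary_mask",
    "read_grayscale",
    "write_mask",
    "rroi_center",
    "mask_to_contour",
    "contour_to_mask",
    "write_contour_csv",
    "read_contour_csv",
]


def as_gray_image(arr: np.ndarray) -> np.ndarray:
    """Validate and coerce ``arr`` to a float64 grayscale image in [0, 255]."""
    a = np.asarray(arr, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] < 1 or a.shape[1] < 1:
        raise DomainError(f"expected a 2-D image, got shape {a.shape}")
    if not np.isfinite(a).all():
        raise DomainError("image contains non-finite intensities")
    if a.min() < 0 or a.max() > 255:
        raise DomainError("intensities must lie in [0, 255]")
    return a


def as_binary_mask(arr: np.ndarray, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Validate and coerce ``arr`` to a boolean mask, optionally checking shape."""
    a = np.asarray(arr)
    if a.dtype != bool:
        vals = np.unique(a)
        if not np.isin(vals, (0, 1)).all():
            raise DomainError("mask values must be exactly 0 or 1")
        a = a.astype(bool)
    if a.ndim != 2:
        raise DomainError(f"expected a 2-D mask, got shape {a.shape}")
    if shape is not None and a.shape != tuple(shape):
        raise DomainError(f"mask shape {a.shape} does not match image shape {tuple(shape)}")
    return a


@dataclass(frozen=True)
class RROI:
    """Rectangular region of interest, half-open bounds [w1, w2) x [h1, h2).

    ``w`` indexes columns (lesion width), ``h`` indexes rows (lesion height),
    mirroring how a radiologist drags a box across the B-mode image.
    """

    w1: int
    w2: int
    h1: int
    h2: int

    def __post_init__(self) -> None:
        if not (0 <= self.w1 < self.w2 and 0 <= self.h1 < self.h2):
            raise DomainError(
                f"invalid RROI bounds w=[{self.w1},{self.w2}) h=[{self.h1},{self.h2})"
            )

    @property
    def width(self) -> int:
        return self.w2 - self.w1

    @property
    def height(self) -> int:
        return self.h2 - self.h1

    def validate_within(self, shape: tuple[int, int]) -> None:
        if self.w2 > shape[1] or self.h2 > shape[0]:
            raise DomainError(
                f"RROI w=[{self.w1},{self.w2}) h=[{self.h1},{self.h2}) "
                f"exceeds image shape {shape}"
            )


def _round_half_down(x: float) -> int:
    """Nearest integer, ties toward the lower index."""
    return int(np.ceil(x - 0.5))


def rroi_center(rroi: RROI) -> tuple[int, int]:
    """Geometric centre of the RROI as an integer (row, col) pixel.

    The exact centre is (h1 + (h2-h1)/2, w1 + (w2-w1)/2); it is rounded to
    the nearest pixel with ties toward the lower index so that discrete
    operators (circle level sets, Gaussian centring) get a grid point.
    """
    r = rroi.h1 + (rroi.h2 - rroi.h1) / 2.0
    c = rroi.w1 + (rroi.w2 - rroi.w1) / 2.0
    return (_round_half_down(r), _round_half_down(c))


def read_grayscale(path: str | Path) -> np.ndarray:
    """Read a raster image (PNG/TIFF/BMP...) as a grayscale float image.

    Multi-channel inputs are reduced by averaging the colour channels
    (alpha, if present, is ignored); 16-bit inputs are rescaled to [0, 255].
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            arr = np.asarray(im)
    except (OSError, SyntaxError, ValueError) as exc:
        raise ImageIOError(f"cannot read image file {path}: {exc}") from exc
    arr = arr.astype(np.float64)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        arr = arr.mean(axis=2)
    if arr.ndim != 2:
        raise ImageIOError(f"unsupported image layout in {path}: shape {arr.shape}")
    if arr.max() > 255:  # 16-bit input
        arr = arr * (255.0 / arr.max())
    return as_gray_image(arr)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit single-channel file (foreground 255)."""
    mask = as_binary_mask(mask)
    path = Path(path)
    try:
        Image.fromarray((mask.astype(np.uint8)) * 255, mode="L").save(path)
    except OSError as exc:
        raise ImageIOError(f"cannot write mask file {path}: {exc}") from exc


# Clockwise Moore neighbourhood starting north.
_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n == 0:
        raise DomainError("empty mask")
    if n == 1:
        return labels == 1
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def mask_to_contour(mask: np.ndarray) -> np.ndarray:
    """Closed outer boundary of the largest 4-connected component.

    Returns an (N, 2) int array of (row, col) pixels, ordered clockwise by
    Moore-neighbour tracing; consecutive points (and last-to-first) are
    8-connected. Interior holes are ignored (outer boundary only).
    """
    mask = as_binary_mask(mask)
    comp = ndimage.binary_fill_holes(_largest_component(mask))
    rows, cols = np.nonzero(comp)
    r0 = rows.min()
    c0 = cols[rows == r0].min()
    start = (int(r0), int(c0))

    padded = np.zeros((comp.shape[0] + 2, comp.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = comp

    def fg(p: tuple[int, int]) -> bool:
        return padded[p[0] + 1, p[1] + 1]

    # Moore tracing with Jacob's stopping criterion: stop when the start
    # pixel is re-entered from the same backtrack (background) pixel as the
    # initial one. The topmost-leftmost pixel has background to its west.
    # On 1-pixel-thick shapes the walk can re-enter the start with a
    # different backtrack than the artificial initial one, so Jacob's test
    # never fires; the (pixel, backtrack) state is deterministic, hence a
    # repeated state closes the boundary cycle and terminates too.
    b0 = (start[0], start[1] - 1)
    contour = [start]
    cur, back = start, b0
    seen: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    while True:
        i = _MOORE.index((back[0] - cur[0], back[1] - cur[1]))
        nxt = None
        for k in range(1, 9):
            d = _MOORE[(i + k) % 8]
            cand = (cur[0] + d[0], cur[1] + d[1])
            if fg(cand):
                nxt = cand
                break
            back = cand  # last background pixel scanned is the new backtrack
        if nxt is None:  # isolated single pixel
            return np.asarray([start], dtype=np.intp)
        if nxt == start and back == b0:
            break
        state = (cur, back)
        if state in seen:
            if contour[-1] == contour[0]:
                contour.pop()
            break
        seen.add(state)
        contour.append(nxt)
        cur = nxt
    return np.asarray(contour, dtype=np.intp)


def contour_to_mask(contour: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Fill a closed 8-connected contour into a binary mask of ``shape``."""
    pts = np.asarray(contour, dtype=np.intp)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise DomainError("contour must be a non-empty (N, 2) array of (row, col)")
    if pts.min() < 0 or pts[:, 0].max() >= shape[0] or pts[:, 1].max() >= shape[1]:
        raise DomainError("contour extends outside the target shape")
    if len(pts) > 1:
        closed = np.vstack([pts, pts[:1]])
        steps = np.abs(np.diff(closed, axis=0)).max(axis=1)
        if (steps > 1).any():
            raise DomainError("contour is open: consecutive points must be 8-connected")
    mask = np.zeros(shape, dtype=bool)
    mask[pts[:, 0], pts[:, 1]] = True
    return ndimage.binary_fill_holes(mask)


def write_contour_csv(path: str | Path, contour: np.ndarray) -> None:
    """Export a contour as CSV with header ``row,col``."""
    pts = np.asarray(contour, dtype=np.intp)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row", "col"])
        writer.writerows(pts.tolist())


def read_contour_csv(path: str | Path) -> np.ndarray:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != ["row", "col"]:
            raise DomainError(f"unexpected contour CSV header {header!r}")
        return np.asarray([[int(r), int(c)] for r, c in reader], dtype=np.intp)
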