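"""Corner-border detection and removal.

Round dermatoscope lenses leave dark borders in the image corners; naive
segmenters confuse them with lesion tissue.  This stage locates the extreme
outer contour of the dark corner components (their endpoint positions, which
for edge-touching borders are the image corners themselves) and the extreme
inner contour found by walking each corner diagonal inward until three
consecutive sub-threshold pixels are seen.  The ring between the two
rectangles is then detached by cropping to the interior of the inner
rectangle; the crop offset is recorded so downstream masks can be re-embedded
into the original frame.

The inner-corner test at a diagonal position (i, j) is

    I(i, j) < T  and  I(i-1, j-1) < T  and  I(i-2, j-2) < T

with the walk starting at (estimated_extent, estimated_extent) and moving
toward the corner one diagonal step at a time.  If the top-left search fails
the image is declared border-free and no further corner is searched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_core import BorderRemovalError, InvalidInputError, validate_gray, validate_rgb

__all__ = [
    "BorderSearchConfig",
    "CornerPoint",
    "CornerRects",
    "detect_outer_contour",
    "find_inner_corner",
    "detect_inner_rectangle",
    "remove_borders",
]

#: Orientations of the four corner searches. The sign pair mirrors the
#: coordinate reflection applied before the diagonal walk: TL (+,+),
#: BL (-,+), TR (+,-), BR (-,-).
ORIENTATIONS = ("TL", "TR", "BL", "BR")


@dataclass
class BorderSearchConfig:
    """Parameters of the corner-border search.

    gray_threshold
        Gray level T below which a pixel counts as border (default 4).
    estimated_extent
        Largest expected border length/width in pixels (default 20); the
        diagonal walk starts here.
    """

    gray_threshold: int = 4
    estimated_extent: int = 20

    def __post_init__(self) -> None:
        if not (0 < self.gray_threshold < 255):
            raise InvalidInputError("gray_threshold must lie in (0, 255)")
        if self.estimated_extent < 3:
            raise InvalidInputError("estimated_extent must be >= 3 (the corner test needs two diagonal predecessors)")


@dataclass
class CornerPoint:
    row: int = 0
    col: int = 0
    found: bool = False


@dataclass
class CornerRects:
    """Outer endpoint vector plus the four inner-rectangle corners."""

    outer_endpoints: list = field(default_factory=list)
    inner_tl: CornerPoint = field(default_factory=CornerPoint)
    inner_tr: CornerPoint = field(default_factory=CornerPoint)
    inner_bl: CornerPoint = field(default_factory=CornerPoint)
    inner_br: CornerPoint = field(default_factory=CornerPoint)
    borders_present: bool = False
    searches_run: int = 0


def detect_outer_contour(gray: np.ndarray, cfg: BorderSearchConfig | None = None) -> list[list[int]]:
    """Endpoint positions of the extreme outer contour of the corner borders.

    Binarizes at the gray threshold, keeps the connected components that touch
    an image corner, and returns for each touched corner the component pixel
    at that corner — for edge-touching borders these are the image corners,
    e.g. ``[[0, 0], [0, W-1], [H-1, W-1], [H-1, 0]]``.  Returns an empty list
    when no corner-touching dark component exists.
    """
    cfg = cfg or BorderSearchConfig()
    gray = validate_gray(gray)
    h, w = gray.shape
    dark = gray < cfg.gray_threshold
    if not dark.any():
        return []
    labels, _ = ndimage.label(dark, structure=np.ones((3, 3), dtype=int))
    corners = [(0, 0), (0, w - 1), (h - 1, w - 1), (h - 1, 0)]  # TL, TR, BR, BL
    corner_labels = {labels[r, c] for r, c in corners if labels[r, c] != 0}
    if not corner_labels:
        return []
    keep = np.isin(labels, sorted(corner_labels))
    rows, cols = np.nonzero(keep)
    endpoints: list[list[int]] = []
    for r0, c0 in corners:
        # component pixel closest (Chebyshev) to this corner; the corner
        # itself when the border touches the edge
        d = np.maximum(np.abs(rows - r0), np.abs(cols - c0))
        i = int(np.argmin(d))
        endpoints.append([int(rows[i]), int(cols[i])])
    return endpoints


def _reflect(gray: np.ndarray, orientation: str) -> np.ndarray:
    """Mirror the image so *orientation*'s corner becomes the top-left."""
    if orientation == "TL":
        return gray
    if orientation == "TR":
        return gray[:, ::-1]
    if orientation == "BL":
        return gray[::-1, :]
    if orientation == "BR":
        return gray[::-1, ::-1]
    raise InvalidInputError(f"unknown orientation {orientation!r}")


def find_inner_corner(gray: np.ndarray, cfg: BorderSearchConfig | None = None, orientation: str = "TL") -> CornerPoint:
    """Walk a corner diagonal inward-to-corner to find the inner endpoint.

    After reflecting coordinates so the requested corner is top-left, the
    walk starts at ``(e, e)`` with ``e = estimated_extent`` and decrements
    both indices; the first position whose value and two diagonal
    predecessors all fall below the threshold is the inner corner, mapped
    back to original coordinates.  Positions with fewer than two predecessors
    (index < 2) cannot satisfy the test, so reaching them means "not found".
    """
    cfg = cfg or BorderSearchConfig()
    gray = validate_gray(gray)
    h, w = gray.shape
    e, t = cfg.estimated_extent, cfg.gray_threshold
    if h < e + 1 or w < e + 1:
        raise InvalidInputError(f"image {gray.shape} smaller than the {e + 1}-pixel corner search window")
    view = _reflect(gray, orientation)
    for i in range(e, 1, -1):
        if view[i, i] < t and view[i - 1, i - 1] < t and view[i - 2, i - 2] < t:
            row = i if orientation in ("TL", "TR") else h - 1 - i
            col = i if orientation in ("TL", "BL") else w - 1 - i
            return CornerPoint(row=row, col=col, found=True)
    return CornerPoint(found=False)


def detect_inner_rectangle(gray: np.ndarray, cfg: BorderSearchConfig | None = None) -> CornerRects:
    """Locate the extreme inner rectangle of the corner borders.

    The top-left corner is searched first; if it is absent the image is
    declared border-free and the other three searches are skipped (the
    ``searches_run`` counter makes the early exit observable).  A corner that
    is individually not found defaults to the image corner, so that side of
    the inner rectangle sits on the image edge and is not cropped.
    """
    cfg = cfg or BorderSearchConfig()
    gray = validate_gray(gray)
    h, w = gray.shape
    rects = CornerRects(outer_endpoints=detect_outer_contour(gray, cfg))
    tl = find_inner_corner(gray, cfg, "TL")
    rects.searches_run = 1
    rects.inner_tl = tl
    if not tl.found:
        rects.borders_present = False
        return rects
    rects.inner_bl = find_inner_corner(gray, cfg, "BL")
    rects.inner_tr = find_inner_corner(gray, cfg, "TR")
    rects.inner_br = find_inner_corner(gray, cfg, "BR")
    rects.searches_run = 4
    # unfound corners collapse to the image corner (no crop on that side)
    if not rects.inner_tr.found:
        rects.inner_tr = CornerPoint(row=-1, col=w, found=False)
    if not rects.inner_bl.found:
        rects.inner_bl = CornerPoint(row=h, col=-1, found=False)
    if not rects.inner_br.found:
        rects.inner_br = CornerPoint(row=h, col=w, found=False)
    rects.borders_present = True
    return rects


def inner_bounds(rects: CornerRects) -> tuple[int, int, int, int]:
    """(top, left, bottom, right) of the inner rectangle, inclusive."""
    top = max(rects.inner_tl.row, rects.inner_tr.row)
    left = max(rects.inner_tl.col, rects.inner_bl.col)
    bottom = min(rects.inner_bl.row, rects.inner_br.row)
    right = min(rects.inner_tr.col, rects.inner_br.col)
    return top, left, bottom, right


def remove_borders(img: np.ndarray, rects: CornerRects) -> tuple[np.ndarray, tuple[int, int]]:
    """Detach the border ring by cropping strictly inside the inner rectangle.

    Returns the crop (bit-identical pixels, no resampling) and the
    ``(row, col)`` offset of its top-left pixel in the original frame, so a
    downstream mask can be padded back to original size.  A border-free
    detection returns the input unchanged with offset ``(0, 0)``.
    """
    img = validate_rgb(img)
    if not rects.borders_present:
        return img, (0, 0)
    h, w = img.shape[:2]
    top, left, bottom, right = inner_bounds(rects)
    r0, c0 = top + 1, left + 1
    r1, c1 = min(bottom, h), min(right, w)  # crop rows r0..r1-1 (exclusive of inner edge)
    if r1 - r0 <= 2 or c1 - c0 <= 2:
        raise BorderRemovalError(f"degenerate inner rectangle: interior {r1 - r0}x{c1 - c0} pixels")
    return img[r0:r1, c0:c1], (r0, c0)


def embed_mask(mask: np.ndarray, offset: tuple[int, int], shape: tuple[int, int]) -> np.ndarray:
    """Re-embed a cropped-frame mask into the original frame (ring = 0)."""
    out = np.zeros(shape, dtype=np.uint8)
    r0, c0 = offset
    out[r0 : r0 + mask.shape[0], c0 : c0 + mask.shape[1]] = mask
    return out
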