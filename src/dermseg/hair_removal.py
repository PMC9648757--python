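"""Hair detection and removal by fast-marching inpainting.

Hairs are thin dark strokes.  Three steps:

1. **Contour** — morphological closing of the grayscale image by a
   structuring element K minus the image itself (a blackhat),
   ``T(I) = (I ● K) − I``; thin dark structures that fit inside K light up.
2. **Mask** — gray-level slicing of the contour image: values below the
   slice threshold go to 0, everything else to 255.  An all-zero mask means
   no hairs and the stage stops there.
3. **Inpainting** — masked pixels are filled in order of arrival time from
   the mask boundary (fast marching on the unit-speed eikonal equation).
   Each pixel p is the normalized weighted sum of first-order extrapolations
   from the already-known pixels q in its radius-ε neighborhood:

       I(p) = Σ w(p,q) [I(q) + ∇I(q)·(p−q)] / Σ w(p,q)
       w    = dir · dst · lev

   with ``dir`` the projection of the unit p−q vector on the boundary normal
   N = ∇T (clamped at 0 so weights stay non-negative), ``dst = d0²/|p−q|²``
   and ``lev = T0/(1 + |T(p)−T(q)|)``, d0 = T0 = 1.

Pixels outside the mask are never touched.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_core import InvalidInputError, rgb_to_gray, validate_gray, validate_rgb

__all__ = [
    "HairConfig",
    "InpaintState",
    "cross_element",
    "hair_contour",
    "make_hair_mask",
    "inpaint_weight",
    "inpaint_pixel",
    "inpaint",
    "remove_hairs",
]

_KNOWN, _BAND, _INSIDE = 0, 1, 2
_INF = np.float64(1e12)


@dataclass
class HairConfig:
    """Hair-removal parameters.

    struct_size
        Diameter/side of the structuring element K (odd, default 17); hairs
        must be strictly thinner than K.
    struct_shape
        ``disk`` (default), ``cross`` or ``square``.  The disk is isotropic:
        it stays quiet on smooth lesion outlines while lighting up on thin
        strokes; a cross or square of the same size also fires on the
        diagonal arcs of any rounded blob.
    slice_threshold
        Gray-level slicing cut (default 10): contour < threshold → 0,
        otherwise 255.
    inpaint_radius
        Neighborhood radius ε used when filling a pixel (default 2).
    dilate_mask
        Grow the mask by 1 px before inpainting so anti-aliased hair fringes
        are covered (default on).
    clean_speckles
        Drop mask components smaller than ``min_speckle`` pixels before
        inpainting (default off).
    """

    struct_size: int = 17
    struct_shape: str = "disk"
    slice_threshold: int = 10
    inpaint_radius: int = 2
    dilate_mask: bool = True
    clean_speckles: bool = False
    min_speckle: int = 4

    def __post_init__(self) -> None:
        if self.struct_size % 2 == 0 or self.struct_size < 3:
            raise InvalidInputError("struct_size must be odd and >= 3")
        if not (0 < self.slice_threshold < 255):
            raise InvalidInputError("slice_threshold must lie in (0, 255)")
        if self.inpaint_radius < 1:
            raise InvalidInputError("inpaint_radius must be >= 1")


@dataclass
class InpaintState:
    """Fast-marching bookkeeping: arrival times and the known/band/inside flags."""

    distance_map: np.ndarray  # T, travel time from the initial boundary
    flags: np.ndarray  # _KNOWN / _BAND / _INSIDE per pixel
    d0: float = 1.0
    t0: float = 1.0


def cross_element(size: int) -> np.ndarray:
    """Cross-shaped (plus) structuring element of odd side *size*."""
    k = np.zeros((size, size), dtype=bool)
    k[size // 2, :] = True
    k[:, size // 2] = True
    return k


def _footprint(cfg: HairConfig) -> np.ndarray:
    if cfg.struct_shape == "disk":
        # isotropic: silent on smooth blob boundaries (curvature radius above
        # its own), responsive to strokes thinner than its diameter
        from skimage.morphology import disk

        return disk(cfg.struct_size // 2).astype(bool)
    if cfg.struct_shape == "cross":
        return cross_element(cfg.struct_size)
    if cfg.struct_shape == "square":
        return np.ones((cfg.struct_size, cfg.struct_size), dtype=bool)
    raise InvalidInputError(f"unknown struct_shape {cfg.struct_shape!r}")


def hair_contour(gray: np.ndarray, cfg: HairConfig | None = None) -> np.ndarray:
    """Blackhat response ``closing(gray, K) − gray`` clamped to [0, 255]."""
    cfg = cfg or HairConfig()
    gray = validate_gray(gray)
    if cfg.struct_size > min(gray.shape):
        raise InvalidInputError("structuring element larger than the image")
    # nearest-edge padding: reflection would mirror intensity dips that touch
    # the frame into closable pits and produce spurious border responses
    closed = ndimage.grey_closing(gray.astype(np.int16), footprint=_footprint(cfg), mode="nearest")
    return np.clip(closed - gray.astype(np.int16), 0, 255).astype(np.uint8)


def make_hair_mask(contour: np.ndarray, cfg: HairConfig | None = None) -> tuple[np.ndarray, bool]:
    """Gray-level slicing of the contour image into an in-paint mask.

    Contour values below the slice threshold map to 0, all others to 255;
    ``hairs_present`` is True iff any pixel sliced to 255.
    """
    cfg = cfg or HairConfig()
    contour = validate_gray(contour)
    mask = np.where(contour < cfg.slice_threshold, 0, 255).astype(np.uint8)
    return mask, bool((mask == 255).any())


def _prepare_mask(mask: np.ndarray, cfg: HairConfig) -> np.ndarray:
    m = mask == 255
    if cfg.clean_speckles:
        labels, n = ndimage.label(m)
        if n:
            sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
            drop = np.flatnonzero(sizes < cfg.min_speckle) + 1
            m[np.isin(labels, drop)] = False
    if cfg.dilate_mask:
        m = ndimage.binary_dilation(m, structure=np.ones((3, 3), dtype=bool))
    return m


def _solve_eikonal(T: np.ndarray, flags: np.ndarray, i: int, j: int) -> float:
    """Upwind quadratic update of the unit-speed arrival time at (i, j)."""
    h, w = T.shape
    tx = _INF
    if i > 0 and flags[i - 1, j] != _INSIDE:
        tx = T[i - 1, j]
    if i < h - 1 and flags[i + 1, j] != _INSIDE:
        tx = min(tx, T[i + 1, j])
    ty = _INF
    if j > 0 and flags[i, j - 1] != _INSIDE:
        ty = T[i, j - 1]
    if j < w - 1 and flags[i, j + 1] != _INSIDE:
        ty = min(ty, T[i, j + 1])
    if tx >= _INF and ty >= _INF:
        return float(_INF)
    if abs(tx - ty) >= 1.0:
        return float(min(tx, ty) + 1.0)
    s = tx + ty
    disc = s * s - 2.0 * (tx * tx + ty * ty - 1.0)
    return float(0.5 * (s + np.sqrt(max(disc, 0.0))))


def _normal(T: np.ndarray, flags: np.ndarray, i: int, j: int) -> tuple[float, float]:
    """N = ∇T by central differences on available arrival times, normalized."""
    h, w = T.shape

    def grad(axis: int) -> float:
        if axis == 0:
            lo = T[i - 1, j] if i > 0 and flags[i - 1, j] != _INSIDE else None
            hi = T[i + 1, j] if i < h - 1 and flags[i + 1, j] != _INSIDE else None
        else:
            lo = T[i, j - 1] if j > 0 and flags[i, j - 1] != _INSIDE else None
            hi = T[i, j + 1] if j < w - 1 and flags[i, j + 1] != _INSIDE else None
        if lo is not None and hi is not None:
            return 0.5 * (hi - lo)
        if hi is not None:
            return hi - T[i, j]
        if lo is not None:
            return T[i, j] - lo
        return 0.0

    gr, gc = grad(0), grad(1)
    norm = np.hypot(gr, gc)
    if norm == 0.0:
        return 0.0, 0.0
    return gr / norm, gc / norm


def inpaint_weight(p: tuple[int, int], q: tuple[int, int], state: InpaintState) -> float:
    """w(p,q) = dir · dst · lev for a known neighbor q of p.

    ``dir`` is the projection of the unit p−q vector on the boundary normal
    at p, clamped at 0; ``dst`` decays with squared distance; ``lev`` decays
    with the arrival-time difference.  A zero normal falls back to dst·lev.
    """
    if p == q:
        raise InvalidInputError("inpaint weight undefined for p == q")
    T = state.distance_map
    dr, dc = p[0] - q[0], p[1] - q[1]
    dist2 = dr * dr + dc * dc
    dist = np.sqrt(dist2)
    nr, nc = _normal(T, state.flags, p[0], p[1])
    if nr == 0.0 and nc == 0.0:
        direc = 1.0
    else:
        direc = max((dr * nr + dc * nc) / dist, 0.0)
    dst = state.d0 * state.d0 / dist2
    lev = state.t0 / (1.0 + abs(float(T[p]) - float(T[q])))
    return float(direc * dst * lev)


def _image_gradient(img: np.ndarray, flags: np.ndarray, i: int, j: int) -> tuple[np.ndarray, np.ndarray]:
    """∇I at a known pixel using known pixels only (central, else one-sided)."""
    h, w = img.shape[:2]
    zero = np.zeros(img.shape[2:], dtype=np.float64)

    def grad(axis: int) -> np.ndarray:
        if axis == 0:
            lo = img[i - 1, j] if i > 0 and flags[i - 1, j] == _KNOWN else None
            hi = img[i + 1, j] if i < h - 1 and flags[i + 1, j] == _KNOWN else None
        else:
            lo = img[i, j - 1] if j > 0 and flags[i, j - 1] == _KNOWN else None
            hi = img[i, j + 1] if j < w - 1 and flags[i, j + 1] == _KNOWN else None
        if lo is not None and hi is not None:
            return 0.5 * (hi.astype(np.float64) - lo.astype(np.float64))
        if hi is not None:
            return hi.astype(np.float64) - img[i, j].astype(np.float64)
        if lo is not None:
            return img[i, j].astype(np.float64) - lo.astype(np.float64)
        return zero

    return grad(0), grad(1)


def inpaint_pixel(
    p: tuple[int, int], img: np.ndarray, state: InpaintState, cfg: HairConfig | None = None
) -> np.ndarray:
    """First-order weighted extrapolation of the image at p from known neighbors.

    Per channel: ``Σ w(p,q) [I(q) + ∇I(q)·(p−q)] / Σ w(p,q)`` over known q in
    the radius-ε neighborhood, clamped to [0, 255].
    """
    cfg = cfg or HairConfig()
    h, w = img.shape[:2]
    i, j = p
    eps = cfg.inpaint_radius
    num = np.zeros(img.shape[2:], dtype=np.float64)
    den = 0.0
    num_flat = np.zeros_like(num)  # dst·lev fallback if all dir clamp to zero
    den_flat = 0.0
    for qi in range(max(i - eps, 0), min(i + eps + 1, h)):
        for qj in range(max(j - eps, 0), min(j + eps + 1, w)):
            if (qi == i and qj == j) or state.flags[qi, qj] != _KNOWN:
                continue
            dr, dc = i - qi, j - qj
            gr, gc = _image_gradient(img, state.flags, qi, qj)
            est = img[qi, qj].astype(np.float64) + gr * dr + gc * dc
            w_full = inpaint_weight((i, j), (qi, qj), state)
            dist2 = dr * dr + dc * dc
            w_flat = (state.d0**2 / dist2) * (
                state.t0 / (1.0 + abs(float(state.distance_map[i, j]) - float(state.distance_map[qi, qj])))
            )
            num += w_full * est
            den += w_full
            num_flat += w_flat * est
            den_flat += w_flat
    if den > 0.0:
        val = num / den
    elif den_flat > 0.0:
        val = num_flat / den_flat
    else:
        raise RuntimeError("no known neighbor in the inpainting neighborhood")
    return np.clip(np.rint(val), 0, 255).astype(np.uint8)


def inpaint(img: np.ndarray, mask: np.ndarray, cfg: HairConfig | None = None) -> np.ndarray:
    """Fill the masked region of *img* in fast-marching order.

    The arrival-time map T is 0 on known pixels; masked pixels are popped in
    non-decreasing T from a priority queue (ties broken by insertion order),
    filled with :func:`inpaint_pixel`, and promoted to known.
    """
    cfg = cfg or HairConfig()
    img = validate_rgb(img)
    m = _prepare_mask(validate_gray(mask), cfg)
    if not m.any():
        return img.copy()
    out = img.copy()
    h, w = m.shape
    flags = np.where(m, _INSIDE, _KNOWN).astype(np.uint8)
    T = np.where(m, _INF, 0.0)
    state = InpaintState(distance_map=T, flags=flags)
    heap: list[tuple[float, int, tuple[int, int]]] = []
    counter = 0
    rows, cols = np.nonzero(m)
    for i, j in zip(rows.tolist(), cols.tolist()):
        if any(
            0 <= i + di < h and 0 <= j + dj < w and flags[i + di, j + dj] == _KNOWN
            for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1))
        ):
            T[i, j] = _solve_eikonal(T, flags, i, j)
            flags[i, j] = _BAND
            heapq.heappush(heap, (T[i, j], counter, (i, j)))
            counter += 1
    while heap:
        t, _, (i, j) = heapq.heappop(heap)
        if flags[i, j] != _BAND or t > T[i, j]:
            continue  # stale entry
        out[i, j] = inpaint_pixel((i, j), out, state, cfg)
        flags[i, j] = _KNOWN
        for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            ni, nj = i + di, j + dj
            if 0 <= ni < h and 0 <= nj < w and flags[ni, nj] != _KNOWN:
                t_new = _solve_eikonal(T, flags, ni, nj)
                if t_new < T[ni, nj]:
                    T[ni, nj] = t_new
                if flags[ni, nj] == _INSIDE:
                    flags[ni, nj] = _BAND
                heapq.heappush(heap, (T[ni, nj], counter, (ni, nj)))
                counter += 1
    return out


def remove_hairs(img: np.ndarray, cfg: HairConfig | None = None) -> tuple[np.ndarray, bool]:
    """Full hair-removal stage: contour → slicing mask → inpainting.

    Returns the hair-free image and the ``hairs_present`` flag.  When the
    sliced mask is empty the input is returned bit-identical and inpainting
    is skipped entirely.
    """
    cfg = cfg or HairConfig()
    img = validate_rgb(img)
    contour = hair_contour(rgb_to_gray(img), cfg)
    mask, present = make_hair_mask(contour, cfg)
    if not present:
        return img.copy(), False
    return inpaint(img, mask, cfg), True
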