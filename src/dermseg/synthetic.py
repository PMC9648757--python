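"""Seeded synthetic dermoscopy fixtures with paired ground truth.

Real dermoscopic frames combine a pinkish skin background, one irregular
darker lesion, and two acquisition artifacts: dark corner borders left by the
round lens, and thin dark hairs.  The generator composites exactly these
layers — skin (Gaussian noise plus a low-frequency illumination gradient),
lesion (ellipse with low-frequency radial perturbation and a smoothed edge),
hairs (smooth random curves 1–3 px wide), and corner borders (near-black
wedges touching the four corners) — and returns the image together with
faithful per-layer masks.  Everything is driven by one RNG stream per
fixture, so a spec reproduces its fixture bit-identically.

The defaults keep the invariants the pipeline relies on: border intensity is
below the border-detection threshold (4), hair intensity is well above it so
hairs never masquerade as borders, hair width is far below the hair kernel
size, and the lesion stays inside the automatic GrabCut rectangle of the
post-crop frame.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage

from .image_core import InvalidInputError, write_image, write_mask

__all__ = ["FixtureSpec", "Fixture", "generate_fixture", "generate_suite", "load_manifest"]


@dataclass
class FixtureSpec:
    """Knobs of one synthetic dermoscopy frame; all randomness comes from ``seed``."""

    seed: int = 0
    size: tuple[int, int] = (512, 512)
    skin_rgb: tuple[int, int, int] = (205, 160, 145)
    skin_noise_sd: float = 3.0
    noise_corr_sigma: float = 5.0
    illumination_amp: float = 10.0
    lesion_rgb: tuple[int, int, int] = (120, 70, 60)
    lesion_radius_frac: float = 0.21
    lesion_aspect: float = 0.8
    lesion_boundary_amp: float = 0.08
    lesion_edge_sigma: float = 2.5
    lesion_center_jitter: float = 0.04
    borders: bool = False
    border_thickness: int = 12
    border_intensity: int = 1
    hairs: bool = False
    hair_count: int = 12
    hair_width: int = 2
    hair_intensity: int = 60
    hair_curvature: float = 0.25

    def __post_init__(self) -> None:
        h, w = self.size
        if h < 64 or w < 64:
            raise InvalidInputError("fixture must be at least 64x64")
        if self.borders and not (4 <= self.border_thickness <= 20):
            raise InvalidInputError("border_thickness must lie in [4, 20]")
        if self.borders and not (0 <= self.border_intensity < 4):
            raise InvalidInputError("border intensity must stay below the detection threshold 4")
        if self.hairs and not (1 <= self.hair_width <= 3):
            raise InvalidInputError("hair_width must lie in [1, 3]")
        if self.lesion_radius_frac * min(h, w) * (1 + self.lesion_boundary_amp) > 0.38 * min(h, w):
            raise InvalidInputError("lesion too large to stay inside the initialization rectangle")


@dataclass
class Fixture:
    image: np.ndarray
    lesion_truth: np.ndarray
    border_truth: np.ndarray
    hair_truth: np.ndarray
    spec: FixtureSpec = field(repr=False, default=None)


def _skin(rng: np.random.Generator, spec: FixtureSpec) -> np.ndarray:
    h, w = spec.size
    rows = np.linspace(0, 1, h)[:, None]
    cols = np.linspace(0, 1, w)[None, :]
    phase = rng.uniform(0, 2 * np.pi)
    illum = spec.illumination_amp * (
        0.6 * np.sin(2 * np.pi * 0.7 * rows + phase) + 0.4 * np.cos(2 * np.pi * 0.5 * cols + phase / 2)
    )
    base = np.asarray(spec.skin_rgb, dtype=np.float64)
    # spatially correlated texture: white noise low-passed then rescaled, so
    # skin mottling is visible but its dips are wider and shallower than the
    # structures the hair detector responds to
    noise = rng.normal(0.0, 1.0, size=(h, w, 3))
    noise = ndimage.gaussian_filter(noise, sigma=(spec.noise_corr_sigma, spec.noise_corr_sigma, 0))
    sd = noise.std()
    if sd > 0:
        noise *= spec.skin_noise_sd / sd
    return base[None, None, :] + illum[..., None] + noise


def _lesion_mask(rng: np.random.Generator, spec: FixtureSpec) -> np.ndarray:
    h, w = spec.size
    jitter = spec.lesion_center_jitter
    cy = h / 2 + rng.uniform(-jitter, jitter) * h
    cx = w / 2 + rng.uniform(-jitter, jitter) * w
    r0 = spec.lesion_radius_frac * min(h, w)
    aspect = spec.lesion_aspect + rng.uniform(-0.05, 0.05)
    angle = rng.uniform(0, np.pi)
    # low-frequency wobble: high harmonics would put hair-scale curvature on
    # the outline and excite the blackhat hair detector on a hair-free image
    k = rng.integers(2, 4)
    phase = rng.uniform(0, 2 * np.pi)
    amp2 = rng.uniform(0.3, 0.6) * spec.lesion_boundary_amp
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    # rotate into the ellipse frame
    ry = dy * np.cos(angle) - dx * np.sin(angle)
    rx = dy * np.sin(angle) + dx * np.cos(angle)
    theta = np.arctan2(ry, rx)
    rho = np.hypot(ry / aspect, rx)
    wobble = 1.0 + spec.lesion_boundary_amp * np.sin(k * theta + phase) + amp2 * np.sin((k + 1) * theta - phase)
    return rho < r0 * wobble


def _draw_hairs(rng: np.random.Generator, spec: FixtureSpec) -> np.ndarray:
    h, w = spec.size
    mask = np.zeros((h, w), dtype=bool)
    margin = 24  # keep strokes off the corner diagonals' very tips
    for _ in range(spec.hair_count):
        x0 = rng.uniform(margin, w - margin)
        y0 = rng.uniform(margin, h - margin)
        angle = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(0.25, 0.6) * min(h, w)
        bend = spec.hair_curvature * length * rng.uniform(-1, 1)
        t = np.linspace(0.0, 1.0, int(2 * length))
        dx, dy = np.cos(angle), np.sin(angle)
        xs = x0 + t * length * dx - bend * np.sin(np.pi * t) * dy
        ys = y0 + t * length * dy + bend * np.sin(np.pi * t) * dx
        xi = np.rint(xs).astype(int)
        yi = np.rint(ys).astype(int)
        keep = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
        mask[yi[keep], xi[keep]] = True
    if spec.hair_width > 1:
        r = spec.hair_width - 1
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        disk = (yy**2 + xx**2) <= r * r + (1 if spec.hair_width == 2 else 0)
        # width-2 strokes use a 2-px cross-ish footprint, width-3 a disk
        if spec.hair_width == 2:
            disk = np.array([[False, True, False], [True, True, True], [False, True, False]])
        mask = ndimage.binary_dilation(mask, structure=disk)
    return mask


def _border_mask(spec: FixtureSpec) -> np.ndarray:
    h, w = spec.size
    t = spec.border_thickness
    yy, xx = np.mgrid[0:h, 0:w]
    depth = 2 * (t - 1)  # wedge reaches exactly t - 1 pixels along each corner diagonal
    tl = yy + xx <= depth
    tr = yy + (w - 1 - xx) <= depth
    bl = (h - 1 - yy) + xx <= depth
    br = (h - 1 - yy) + (w - 1 - xx) <= depth
    return tl | tr | bl | br


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Composite skin → lesion → hairs → borders, deterministically from the seed."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    img = _skin(rng, spec)

    lesion = _lesion_mask(rng, spec)
    # gradated lesion border; sharp edges would read as hair-scale structure
    alpha = ndimage.gaussian_filter(lesion.astype(np.float64), sigma=spec.lesion_edge_sigma)
    lesion_noise = ndimage.gaussian_filter(
        rng.normal(0, 1.0, size=(h, w, 3)), sigma=(spec.noise_corr_sigma, spec.noise_corr_sigma, 0)
    )
    lesion_sd = lesion_noise.std()
    if lesion_sd > 0:
        lesion_noise *= 0.8 * spec.skin_noise_sd / lesion_sd
    lesion_color = np.asarray(spec.lesion_rgb, dtype=np.float64) + lesion_noise
    img = img * (1 - alpha[..., None]) + lesion_color * alpha[..., None]

    hair_mask = np.zeros((h, w), dtype=bool)
    if spec.hairs:
        hair_mask = _draw_hairs(rng, spec)
        hair_val = spec.hair_intensity + rng.normal(0, 3.0, size=(h, w, 3))
        img = np.where(hair_mask[..., None], np.minimum(img, hair_val), img)

    border_mask = np.zeros((h, w), dtype=bool)
    if spec.borders:
        border_mask = _border_mask(spec)
        img = np.where(border_mask[..., None], float(spec.border_intensity), img)

    image = np.clip(np.rint(img), 4, 255).astype(np.uint8)  # content floor stays above the border threshold
    if spec.borders:
        image[border_mask] = spec.border_intensity

    lesion_truth = np.where(lesion & ~border_mask, 255, 0).astype(np.uint8)
    return Fixture(
        image=image,
        lesion_truth=lesion_truth,
        border_truth=np.where(border_mask, 255, 0).astype(np.uint8),
        hair_truth=np.where(hair_mask, 255, 0).astype(np.uint8),
        spec=spec,
    )


def _spec_to_plain(spec: FixtureSpec) -> dict:
    d = asdict(spec)
    for key in ("size", "skin_rgb", "lesion_rgb"):
        d[key] = list(d[key])
    return d


def _spec_from_plain(d: dict) -> FixtureSpec:
    d = dict(d)
    for key in ("size", "skin_rgb", "lesion_rgb"):
        if key in d:
            d[key] = tuple(d[key])
    return FixtureSpec(**d)


def generate_suite(n: int, base_spec: FixtureSpec, out_dir: str | os.PathLike) -> str:
    """Write *n* fixtures (seeds base..base+n−1) plus a YAML manifest.

    Each fixture produces ``<seed>_image.png`` and the three truth masks;
    the manifest path is returned and :func:`load_manifest` round-trips it.
    """
    import yaml

    if n < 1:
        raise InvalidInputError("n must be >= 1")
    os.makedirs(out_dir, exist_ok=True)
    entries = []
    for i in range(n):
        spec = _spec_from_plain({**_spec_to_plain(base_spec), "seed": base_spec.seed + i})
        fx = generate_fixture(spec)
        stem = f"{spec.seed:04d}"
        write_image(os.path.join(out_dir, f"{stem}_image.png"), fx.image)
        write_mask(os.path.join(out_dir, f"{stem}_lesion.png"), fx.lesion_truth)
        write_mask(os.path.join(out_dir, f"{stem}_border.png"), fx.border_truth)
        write_mask(os.path.join(out_dir, f"{stem}_hair.png"), fx.hair_truth)
        entries.append(_spec_to_plain(spec))
    manifest = os.path.join(out_dir, "manifest.yaml")
    with open(manifest, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=True)
    return manifest


def load_manifest(path: str | os.PathLike) -> list[FixtureSpec]:
    import yaml

    with open(path) as fh:
        entries = yaml.safe_load(fh)
    return [_spec_from_plain(e) for e in entries]
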