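"""Synthetic NIR vein phantoms and stereo pairs.

Veins absorb near-infrared light, so in a reflectance image they appear
as dark curvilinear tubes on a brighter, unevenly illuminated and noisy
tissue background.  This module generates such images deterministically
from a seed, together with the ground truth every downstream stage
needs: the binary vessel mask, the generating centerline, and (for
stereo pairs) the disparity field and a visibility mask.

All intensities are synthesized as float64 in [0, 1] and quantized to
8-bit only when written to disk, so arithmetic on the arrays is exact.
Stereo pairs are built by forward-warping the left image with an
integer-valued disparity field; occlusions are resolved by the standard
rightmost-wins visibility rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import distance_transform_edt, gaussian_filter

__all__ = [
    "PhantomSpec",
    "StereoPhantomSpec",
    "make_vein_phantom",
    "make_stereo_pair",
    "make_repetitive_stereo_pair",
    "make_unlabeled_set",
    "rasterize_vessel",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a single synthetic vein image.

    ``vessel_contrast`` is the fractional intensity drop inside a vessel
    relative to the locally-lit background; ``illumination_gradient`` is
    the total fractional intensity ramp across the field (left edge
    darker, right edge brighter); ``noise_sigma`` is the std of additive
    Gaussian noise in intensity units.
    """

    height: int = 128
    width: int = 128
    n_vessels: int = 3
    vessel_width_range: tuple[int, int] = (3, 7)
    vessel_contrast: float = 0.5
    background_level: float = 0.75
    illumination_gradient: float = 0.3
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError(f"dimensions must be positive, got {self.height}x{self.width}")
        if self.n_vessels < 0:
            raise ValueError("n_vessels must be nonnegative")
        lo, hi = self.vessel_width_range
        if lo < 1 or hi < lo:
            raise ValueError("vessel_width_range must satisfy 1 <= min <= max")
        if not (0.0 < self.vessel_contrast <= 1.0):
            raise ValueError("vessel_contrast must lie in (0, 1]")
        if not (0.0 <= self.background_level <= 1.0):
            raise ValueError("background_level must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


@dataclass(frozen=True)
class StereoPhantomSpec:
    """A vein phantom plus the geometry of a rectified stereo pair.

    ``disparity`` is either a nonnegative integer constant or an
    integer-valued (height, width) field on the left-image grid; the
    right image satisfies ``left(r, c) == right(r, c - d(r, c))`` at
    non-occluded pixels.  ``texture_amplitude`` adds band-limited
    texture to the background so homogeneous regions stay matchable.
    """

    base: PhantomSpec = field(default_factory=PhantomSpec)
    disparity: float | np.ndarray = 6
    texture_amplitude: float = 0.08
    model_occlusions: bool = True

    def disparity_field(self) -> np.ndarray:
        d = np.asarray(self.disparity)
        if d.ndim == 0:
            d = np.full((self.base.height, self.base.width), float(d))
        if d.shape != (self.base.height, self.base.width):
            raise ValueError("disparity field shape must match the image")
        if np.any(d < 0):
            raise ValueError("disparity must be nonnegative")
        if np.any(d >= self.base.width):
            raise ValueError("disparity must be smaller than the image width")
        if not np.allclose(d, np.rint(d)):
            raise ValueError("disparity field must be integer-valued")
        return d.astype(np.float64)


def _spline_centerline(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Dense (row, col) samples of a cubic spline through jittered waypoints."""
    h, w = spec.height, spec.width
    horizontal = rng.random() < 0.5
    n_way = 5
    t = np.linspace(0.0, 1.0, n_way)
    if horizontal:
        main = t * (w - 1)
        cross = rng.uniform(0.15, 0.85) * (h - 1) + rng.normal(0.0, 0.08 * h, n_way)
        cross = np.clip(cross, 1, h - 2)
        rows, cols = CubicSpline(t, cross), CubicSpline(t, main)
    else:
        main = t * (h - 1)
        cross = rng.uniform(0.15, 0.85) * (w - 1) + rng.normal(0.0, 0.08 * w, n_way)
        cross = np.clip(cross, 1, w - 2)
        rows, cols = CubicSpline(t, main), CubicSpline(t, cross)
    ts = np.linspace(0.0, 1.0, 4 * max(h, w))
    pts = np.stack([rows(ts), cols(ts)], axis=1)
    keep = (pts[:, 0] >= 0) & (pts[:, 0] <= h - 1) & (pts[:, 1] >= 0) & (pts[:, 1] <= w - 1)
    return pts[keep]


def rasterize_vessel(shape: tuple[int, int], centerline: np.ndarray, width: float) -> np.ndarray:
    """Binary tube mask: pixels within ``width / 2`` of the rasterized curve."""
    canvas = np.zeros(shape, dtype=bool)
    pts = np.rint(np.asarray(centerline, dtype=np.float64)).astype(int)
    pts = pts[(pts[:, 0] >= 0) & (pts[:, 0] < shape[0]) & (pts[:, 1] >= 0) & (pts[:, 1] < shape[1])]
    if len(pts) == 0:
        return canvas
    canvas[pts[:, 0], pts[:, 1]] = True
    dist = distance_transform_edt(~canvas)
    return dist <= width / 2.0


def _background(spec: PhantomSpec) -> np.ndarray:
    ramp = np.linspace(-0.5, 0.5, spec.width) * spec.illumination_gradient
    return np.clip(spec.background_level * (1.0 + ramp), 0.0, 1.0)[None, :] * np.ones(
        (spec.height, 1)
    )


def make_vein_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate one phantom.

    Returns ``(image, mask, centerline)`` where ``image`` is float64 in
    [0, 1], ``mask`` is the boolean tube mask and ``centerline`` is an
    (N, 2) integer array of (row, col) points of the generating curves.
    """
    rng = np.random.default_rng(spec.seed)
    img = _background(spec)
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    center_pts: list[np.ndarray] = []
    for _ in range(spec.n_vessels):
        curve = _spline_centerline(spec, rng)
        width = rng.uniform(*spec.vessel_width_range)
        mask |= rasterize_vessel((spec.height, spec.width), curve, width)
        pts = np.unique(np.rint(curve).astype(int), axis=0)
        center_pts.append(pts)
    img = img * (1.0 - spec.vessel_contrast * mask)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)
    centerline = (
        np.unique(np.concatenate(center_pts), axis=0) if center_pts else np.empty((0, 2), int)
    )
    return img, mask, centerline


def make_stereo_pair(
    spec: StereoPhantomSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Generate a rectified stereo pair with ground truth.

    Returns ``(left, right, gt_disparity, valid)``.  ``gt_disparity`` is
    defined on the left-image grid; ``valid`` excludes occluded pixels,
    pixels whose correspondence falls outside the right frame, and a
    1-pixel image border.
    """
    base = spec.base
    d = spec.disparity_field()
    left, _, _ = make_vein_phantom(base)
    if spec.texture_amplitude > 0:
        rng = np.random.default_rng(base.seed + 1)
        texture = gaussian_filter(rng.standard_normal(left.shape), 1.2)
        texture *= spec.texture_amplitude / max(texture.std(), 1e-12)
        left = np.clip(left + texture, 0.0, 1.0)

    h, w = left.shape
    di = np.rint(d).astype(int)
    right = np.zeros_like(left)
    writer = np.full((h, w), -1, dtype=int)  # which left column wrote each right pixel
    rows = np.arange(h)
    for c in range(w):  # left-to-right so rightmost (nearest) surface wins
        target = c - di[:, c]
        ok = (target >= 0) & (target < w)
        right[rows[ok], target[ok]] = left[rows[ok], c]
        writer[rows[ok], target[ok]] = c

    # fill never-written right pixels with the nearest written neighbor in-row
    for r in range(h):
        hole = writer[r] < 0
        if hole.any():
            idx = np.where(~hole)[0]
            if len(idx) == 0:
                continue
            src = idx[np.searchsorted(idx, np.where(hole)[0]).clip(max=len(idx) - 1)]
            right[r, hole] = right[r, src]

    target = np.arange(w)[None, :] - di
    in_frame = (target >= 0) & (target < w)
    visible = np.zeros((h, w), dtype=bool)
    tr = target.clip(0, w - 1)
    if spec.model_occlusions:
        visible = writer[rows[:, None], tr] == np.arange(w)[None, :]
    else:
        visible[:] = True
    valid = in_frame & visible
    valid[0, :] = valid[-1, :] = False
    valid[:, 0] = valid[:, -1] = False
    gt = d.copy()
    gt[~valid] = np.inf  # Middlebury invalid sentinel
    return left, right, gt, valid


def make_repetitive_stereo_pair(
    seed: int = 1,
    height: int = 48,
    width: int = 160,
    band: tuple[int, int] = (30, 100),
    period: int = 8,
    texture_amplitude: float = 0.015,
    disparity: int = 9,
    sensor_noise: float = 0.008,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stereo pair dominated by repetitive texture, the hard case for
    local matching.

    A central vertical band carries a pure sinusoidal stripe pattern of
    the given period, flanked by aperiodic low-amplitude texture; the
    true disparity is constant and larger than the stripe period, so
    every local window inside the band is ambiguous between d and
    d - period.  Each eye receives independent Gaussian sensor noise
    and is quantized to 8 bits, as a real camera pair would.  Only a
    matcher whose support region reaches the aperiodic flanks resolves
    the band interior.

    Returns ``(left, right, gt_disparity, valid)`` with 8-bit images.
    """
    from .io import to_uint8

    rng = np.random.default_rng(seed)
    col = np.arange(width)
    aperiodic = gaussian_filter(rng.normal(0.0, 1.0, width), 1.2)
    aperiodic *= texture_amplitude / np.abs(aperiodic).max()
    stripes = texture_amplitude * np.sin(2.0 * np.pi * col / period)
    texture = np.where((col >= band[0]) & (col < band[1]), stripes, aperiodic)
    img = 0.6 + texture[None, :] * np.ones((height, 1))
    d = disparity
    left = img.copy()
    right = np.empty_like(left)
    right[:, : width - d] = left[:, d:]
    right[:, width - d :] = left[:, -1:]
    left = to_uint8(np.clip(left + rng.normal(0.0, sensor_noise, left.shape), 0, 1))
    right = to_uint8(np.clip(right + rng.normal(0.0, sensor_noise, right.shape), 0, 1))
    gt = np.full((height, width), float(d))
    valid = np.ones((height, width), dtype=bool)
    valid[:, :d] = False
    valid[0, :] = valid[-1, :] = False
    valid[:, 0] = valid[:, -1] = False
    gt[~valid] = np.inf
    return left, right, gt, valid


def make_unlabeled_set(
    n: int, spec: PhantomSpec, seed: int | None = None
) -> list[np.ndarray]:
    """Generate ``n`` phantoms with per-image derived seeds (no masks)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    return [make_vein_phantom(replace(spec, seed=int(s)))[0] for s in seeds]
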