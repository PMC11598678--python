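"""Hessian-eigenvalue vein centerline extraction and refinement.

Veins are locally linear, dark structures; at the scale of a vessel the
Hessian of the smoothed intensity has one large positive eigenvalue
(curvature across the dark tube) and one near-zero eigenvalue (along
it).  The line filter used here is the two-eigenvalue vesselness

    V = exp(-R_b^2 / (2 beta^2)) * (1 - exp(-S^2 / (2 c^2))),

with R_b = lambda1 / lambda2 (blobness) and S = sqrt(lambda1^2 +
lambda2^2) (second-order structure), gated to dark-on-bright polarity
(lambda2 > 0) and maximized over a list of Gaussian scales with
sigma^2-normalized derivatives.  Thresholding the response and thinning
the surviving region yields a 1-px-wide skeleton, which is refined by
removing small components, pruning short spur branches, and joining
nearby endpoints across gaps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.morphology import skeletonize

__all__ = [
    "HessianConfig",
    "RefineConfig",
    "hessian_eigenvalues",
    "vein_response",
    "extract_centerline",
    "refine_centerline",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HessianConfig:
    """Scales and threshold of the vesselness filter (dark-vessel polarity)."""

    sigmas: tuple[float, ...] = (2.0, 3.0, 4.0)
    response_threshold: float = 0.2
    beta: float = 0.5
    gamma: float = 15.0  # structureness scale c, in sigma^2-normalized units

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sigmas):
            raise ValueError("all sigmas must be positive")
        if self.response_threshold < 0:
            raise ValueError("response threshold must be nonnegative")


@dataclass(frozen=True)
class RefineConfig:
    min_region_area: int = 50
    max_gap_distance: float = 15.0
    spur_length: int = 10

    def __post_init__(self) -> None:
        if self.min_region_area < 0 or self.max_gap_distance < 0 or self.spur_length < 0:
            raise ValueError("refinement parameters must be nonnegative")


def hessian_eigenvalues(img: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Ordered eigenvalue maps (|lam1| <= |lam2|) of the image Hessian at one scale.

    Second-order partials are Gaussian derivatives at scale ``sigma``
    (in intensity units, no sigma^2 normalization here).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    img = np.asarray(img, dtype=np.float64)
    # generous kernel truncation keeps the discrete second derivatives of
    # smooth test functions (constants, quadratics) near their analytic values
    irr = ndimage.gaussian_filter(img, sigma, order=(2, 0), truncate=6.0)
    icc = ndimage.gaussian_filter(img, sigma, order=(0, 2), truncate=6.0)
    irc = ndimage.gaussian_filter(img, sigma, order=(1, 1), truncate=6.0)
    # closed-form eigenvalues of the symmetric 2x2 Hessian
    half_trace = (irr + icc) / 2.0
    root = np.sqrt(((irr - icc) / 2.0) ** 2 + irc**2)
    ea, eb = half_trace - root, half_trace + root
    swap = np.abs(ea) > np.abs(eb)
    lam1 = np.where(swap, eb, ea)
    lam2 = np.where(swap, ea, eb)
    return lam1, lam2


def _vesselness(lam1: np.ndarray, lam2: np.ndarray, beta: float, gamma: float) -> np.ndarray:
    rb2 = np.divide(lam1, lam2, out=np.zeros_like(lam1), where=lam2 != 0) ** 2
    s2 = lam1**2 + lam2**2
    v = np.exp(-rb2 / (2.0 * beta**2)) * (1.0 - np.exp(-s2 / (2.0 * gamma**2)))
    return np.where(lam2 > 0, v, 0.0)  # dark tube: positive curvature across it


def vein_response(
    lam1: np.ndarray, lam2: np.ndarray, cfg: HessianConfig | None = None
) -> np.ndarray:
    """Single-scale vesselness response from precomputed eigenvalue maps."""
    cfg = cfg or HessianConfig()
    lam1 = np.asarray(lam1, dtype=np.float64)
    lam2 = np.asarray(lam2, dtype=np.float64)
    if lam1.shape != lam2.shape:
        raise ValueError(f"shape mismatch: {lam1.shape} vs {lam2.shape}")
    return _vesselness(lam1, lam2, cfg.beta, cfg.gamma)


def multiscale_response(img: np.ndarray, cfg: HessianConfig | None = None) -> np.ndarray:
    """Per-pixel max of the vesselness over cfg.sigmas, sigma^2-normalized.

    The sigma^2 factor compensates the amplitude decay of Gaussian
    second derivatives so responses at different scales are comparable.
    ``gamma`` is interpreted on this normalized scale, with intensities
    in [0, 255].
    """
    cfg = cfg or HessianConfig()
    img = np.asarray(img, dtype=np.float64)
    if img.max() <= 1.0:
        img = img * 255.0  # keep gamma meaningful for float [0,1] inputs
    out = np.zeros_like(img)
    for s in cfg.sigmas:
        lam1, lam2 = hessian_eigenvalues(img, s)
        out = np.maximum(out, _vesselness(lam1 * s**2, lam2 * s**2, cfg.beta, cfg.gamma))
    return out


def extract_centerline(response: np.ndarray, cfg: HessianConfig | None = None) -> np.ndarray:
    """Threshold the response and thin to a 1-px-wide skeleton."""
    cfg = cfg or HessianConfig()
    region = np.asarray(response, dtype=np.float64) >= cfg.response_threshold
    if cfg.response_threshold == 0:
        region &= np.asarray(response) > 0
    if not region.any():
        warnings.warn("no pixels survive the response threshold; empty centerline")
        return np.zeros_like(region)
    return skeletonize(region)


def _neighbor_count(skel: np.ndarray) -> np.ndarray:
    k = np.ones((3, 3), dtype=int)
    k[1, 1] = 0
    return ndimage.convolve(skel.astype(int), k, mode="constant")


def _prune_spurs(skel: np.ndarray, spur_length: int) -> np.ndarray:
    """Remove spur branches shorter than ``spur_length`` pixels.

    Each endpoint is traced along the skeleton until a branch point
    (>= 3 neighbors) is met; if the traced path is shorter than
    ``spur_length`` it is deleted.  Components without branch points
    (bare paths) are left intact.
    """
    skel = skel.copy()
    h, w = skel.shape
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

    def neighbors(r: int, c: int) -> list[tuple[int, int]]:
        return [
            (r + dr, c + dc)
            for dr, dc in offsets
            if 0 <= r + dr < h and 0 <= c + dc < w and skel[r + dr, c + dc]
        ]

    def mutually_connected(pts: list[tuple[int, int]]) -> bool:
        if len(pts) <= 1:
            return True
        seen = {pts[0]}
        frontier = [pts[0]]
        rest = set(pts[1:])
        while frontier:
            r, c = frontier.pop()
            for q in list(rest):
                if abs(q[0] - r) <= 1 and abs(q[1] - c) <= 1:
                    rest.discard(q)
                    seen.add(q)
                    frontier.append(q)
        return not rest

    changed = True
    while changed:
        changed = False
        nc = _neighbor_count(skel)
        for r0, c0 in np.argwhere(skel & (nc == 1)):
            path = [(int(r0), int(c0))]
            while len(path) < spur_length:
                r, c = path[-1]
                nxt = [q for q in neighbors(r, c) if q not in path]
                if len(nxt) == 0:  # isolated bare path: keep it
                    path = []
                    break
                if len(nxt) == 1:
                    path.append(nxt[0])
                    continue
                # reached a pixel attached to a thicker structure: it belongs
                # to the spur too if its removal cannot disconnect anything
                if mutually_connected(nxt):
                    break
                path.pop()  # the previous pixel was the last safe deletion
                break
            else:
                path = []  # walked spur_length pixels: long enough to keep
            if path:
                for pr, pc in path:
                    skel[pr, pc] = False
                changed = True
                break  # recompute neighbor counts after each removal
    return skel


def _endpoints(skel: np.ndarray) -> np.ndarray:
    return np.argwhere(skel & (_neighbor_count(skel) <= 1))


def refine_centerline(skel: np.ndarray, cfg: RefineConfig | None = None) -> np.ndarray:
    """Clean a raw skeleton: drop small components, prune spurs, join gaps.

    Gap joining draws a straight rasterized segment between the nearest
    endpoint pairs of distinct components that lie within
    ``max_gap_distance`` (greedy, nearest pairs first); joining never
    splits a component, so the component count never increases.
    """
    cfg = cfg or RefineConfig()
    skel = np.asarray(skel, dtype=bool).copy()

    if cfg.min_region_area > 0:
        labels, n = ndimage.label(skel, structure=np.ones((3, 3)))
        areas = ndimage.sum_labels(skel, labels, index=np.arange(1, n + 1))
        for lbl in np.where(areas < cfg.min_region_area)[0] + 1:
            skel[labels == lbl] = False

    if cfg.spur_length > 0:
        skel = _prune_spurs(skel, cfg.spur_length)

    if cfg.max_gap_distance > 0:
        labels, n = ndimage.label(skel, structure=np.ones((3, 3)))
        if n > 1:
            eps = _endpoints(skel)
            if len(eps) == 0:  # e.g. closed loops: fall back to all pixels
                eps = np.argwhere(skel)
            ep_lbl = labels[eps[:, 0], eps[:, 1]]
            pairs = []
            for i in range(len(eps)):
                for j in range(i + 1, len(eps)):
                    if ep_lbl[i] == ep_lbl[j]:
                        continue
                    d = float(np.hypot(*(eps[i] - eps[j])))
                    if d <= cfg.max_gap_distance:
                        pairs.append((d, i, j))
            parent = list(range(n + 1))

            def find(x: int) -> int:
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for d, i, j in sorted(pairs):
                a, b = find(ep_lbl[i]), find(ep_lbl[j])
                if a == b:
                    continue
                rr, cc = draw_line(*eps[i], *eps[j])
                skel[rr, cc] = True
                parent[a] = b
    return skel


def centerline_pipeline(
    img: np.ndarray,
    hessian_cfg: HessianConfig | None = None,
    refine_cfg: RefineConfig | None = None,
) -> np.ndarray:
    """Response -> threshold -> thin -> refine, end to end."""
    resp = multiscale_response(img, hessian_cfg)
    skel = extract_centerline(resp, hessian_cfg)
    return refine_centerline(skel, refine_cfg)
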