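"""Variable-weight AD-Census stereo matching with cross-based aggregation.

The matching cost between a left pixel p and its disparity-d candidate
q combines the absolute intensity difference (AD) and the Hamming
distance of census bit strings, each squashed by the robust
normalization rho(c, lambda) = 1 - exp(-c / lambda):

    C(p, q) = alpha * rho(C_AD, lambda_AD) + (1 - alpha) * rho(C_C, lambda_C).

In the variable-weight mode the blend follows the local image
structure: alpha = 1 - exp(-1 / h_min), where h_min is the minimum of
the four cross-arm extensions of p.  Near object edges arms are short,
h_min is small and the AD term dominates; inside homogeneous regions
arms are long and the census term dominates.

Cross arms extend from each pixel in the four axial directions until
an intensity-similarity rule fails.  The classic rule accepts an arm
pixel p' while |I(p) - I(p')| < tau and the extension stays below L.
The optimized two-tier rule uses a strict threshold tau1 (on both the
center difference and the consecutive-pixel difference) up to length
L2, and a tighter tau2 from L2 to L1, which stops arms at object edges
while still allowing long arms in weak texture.  Costs are aggregated
over the cross-defined support region (union over one arm of the
orthogonal arms of its pixels), averaged with exact pixel counts, with
alternating horizontal-first / vertical-first passes.  Winner-takes-all
over the aggregated volume gives the disparity, optionally refined by
a left-right consistency check, hole filling and a median pass.

Intensities are handled on the 8-bit scale (float inputs in [0, 1] are
scaled by 255), matching the conventional lambda values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "StereoParams",
    "CrossArms",
    "census_transform",
    "hamming_cost",
    "ad_cost",
    "rho",
    "build_cross",
    "alpha_weight",
    "combined_cost_volume",
    "aggregate_cbca",
    "wta_disparity",
    "lr_refine",
    "match_pair",
]

log = logging.getLogger(__name__)

INVALID = np.inf  # disparity sentinel, PFM-compatible
OUT_OF_RANGE_COST = 1.0  # supremum of the normalized combined cost


@dataclass(frozen=True)
class StereoParams:
    d_min: int = 0
    d_max: int = 16
    census_window: tuple[int, int] = (9, 7)
    lambda_ad: float = 10.0
    lambda_c: float = 30.0
    # classic single-tier cross rule
    L: int = 17
    tau: float = 20.0
    # optimized two-tier rule
    L1: int = 34
    L2: int = 17
    tau1: float = 20.0
    tau2: float = 6.0
    aggregation_iterations: int = 2
    first_pass: str = "horizontal"
    lr_threshold: float = 1.0
    mode: str = "optimized"
    weight_mode: str = "variable"

    def __post_init__(self) -> None:
        if self.d_min < 0 or self.d_max <= self.d_min:
            raise ValueError("need d_max > d_min >= 0")
        wh, ww = self.census_window
        if wh % 2 == 0 or ww % 2 == 0 or wh < 1 or ww < 1:
            raise ValueError("census window must be odd in both dimensions")
        if wh * ww - 1 > 64:
            raise ValueError("census window larger than 64 bits is not supported")
        if self.mode not in ("original", "optimized"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.weight_mode not in ("fixed", "variable"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")
        if self.mode == "optimized":
            if not (self.L1 > self.L2 >= 1):
                raise ValueError("optimized mode requires L1 > L2 >= 1")
            if not (self.tau1 > self.tau2 > 0):
                raise ValueError("optimized mode requires tau1 > tau2 > 0")
        if self.first_pass not in ("horizontal", "vertical"):
            raise ValueError("first_pass must be horizontal or vertical")

    @property
    def num_disparities(self) -> int:
        return self.d_max - self.d_min + 1


@dataclass
class CrossArms:
    """Per-pixel arm extension lengths in the four axial directions.

    An extension of k means k pixels beyond the center satisfy the arm
    rule; the center itself always belongs to its own cross.
    """

    left: np.ndarray
    right: np.ndarray
    up: np.ndarray
    down: np.ndarray

    def h_min(self) -> np.ndarray:
        """Minimum arm length, clamped to >= 1 for the weight formula."""
        return np.maximum(
            np.minimum(np.minimum(self.left, self.right), np.minimum(self.up, self.down)),
            1,
        )


def _gray255(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    img = img.astype(np.float64)
    if img.max() <= 1.0:
        img = img * 255.0
    return img


# ------------------------------------------------------------- costs


def census_transform(img: np.ndarray, window: tuple[int, int] = (9, 7)) -> np.ndarray:
    """Per-pixel census bit string packed into a uint64 map.

    Bit b = 1 iff the neighbor is darker than the center; neighbors are
    visited in row-major order (center skipped), first neighbor in the
    most significant position.  Borders use reflected neighborhoods.
    """
    wh, ww = window
    if wh % 2 == 0 or ww % 2 == 0:
        raise ValueError("census window must be odd in both dimensions")
    img = _gray255(img)
    ph, pw = wh // 2, ww // 2
    padded = np.pad(img, ((ph, ph), (pw, pw)), mode="symmetric")  # edge-inclusive reflection
    h, w = img.shape
    code = np.zeros((h, w), dtype=np.uint64)
    for dr in range(-ph, ph + 1):
        for dc in range(-pw, pw + 1):
            if dr == 0 and dc == 0:
                continue
            neighbor = padded[ph + dr : ph + dr + h, pw + dc : pw + dc + w]
            code = (code << np.uint64(1)) | (neighbor < img).astype(np.uint64)
    return code


def hamming_cost(code_a: np.ndarray, code_b: np.ndarray) -> np.ndarray:
    """Census matching cost: Hamming distance between bit strings."""
    return np.bitwise_count(code_a ^ code_b).astype(np.float64)


def ad_cost(left: np.ndarray, right: np.ndarray, p: tuple[int, int], d: int) -> float:
    """AD matching cost |I_left(p) - I_right(p - d)| on the 8-bit scale.

    A correspondence outside the right frame costs the out-of-range
    sentinel (the maximum normalized cost), so WTA never prefers it.
    """
    left = _gray255(left)
    right = _gray255(right)
    r, c = p
    if not (0 <= c - d < right.shape[1]):
        return OUT_OF_RANGE_COST
    return float(abs(left[r, c] - right[r, c - d]))


def rho(c: np.ndarray | float, lam: float) -> np.ndarray | float:
    """Robust cost normalization rho(c, lambda) = 1 - exp(-c / lambda)."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    return 1.0 - np.exp(-np.asarray(c, dtype=np.float64) / lam)


def alpha_weight(h_min: np.ndarray | float) -> np.ndarray | float:
    """Variable AD weight alpha = 1 - exp(-1 / h_min), decreasing in h_min."""
    h = np.maximum(np.asarray(h_min, dtype=np.float64), 1.0)
    out = 1.0 - np.exp(-1.0 / h)
    return float(out) if np.isscalar(h_min) else out


# ------------------------------------------------------------- crosses


def build_cross(img: np.ndarray, params: StereoParams) -> CrossArms:
    """Maximal arm extensions under the active similarity rule.

    Traversal stops at the first failing pixel.  In ``original`` mode
    an extension k needs |I(p) - I(p_k)| < tau and k < L.  In
    ``optimized`` mode extensions up to L2 need both |I(p) - I(p_k)| and
    the consecutive difference along the arm, |I(p_k) - I(p_{k-1})|
    (the arm pixel against its inward neighbor), below tau1; extensions
    in (L2, L1] need both below tau2.  The consecutive condition is
    applied uniformly in both tiers and is what stops an arm exactly at
    an intensity edge instead of letting it cross.
    """
    img = _gray255(img)
    h, w = img.shape
    arms = {}
    for name, (dr, dc) in (("left", (0, -1)), ("right", (0, 1)), ("up", (-1, 0)), ("down", (1, 0))):
        max_ext = params.L - 1 if params.mode == "original" else params.L1
        alive = np.ones((h, w), dtype=bool)
        ext = np.zeros((h, w), dtype=np.int32)
        for k in range(1, max_ext + 1):
            pk = _shift(img, dr * k, dc * k)
            in_bounds = _in_bounds_mask((h, w), dr * k, dc * k)
            center_diff = np.abs(img - pk)
            if params.mode == "original":
                ok = center_diff < params.tau
            else:
                pk_prev = _shift(img, dr * (k - 1), dc * (k - 1))
                consec = np.abs(pk - pk_prev)
                tau = params.tau1 if k <= params.L2 else params.tau2
                ok = (center_diff < tau) & (consec < tau)
            alive &= ok & in_bounds
            if not alive.any():
                break
            ext += alive
        arms[name] = ext
    return CrossArms(**arms)


def _shift(img: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Image sampled at (r + dr, c + dc) with edge replication."""
    h, w = img.shape
    r_idx = np.clip(np.arange(h) + dr, 0, h - 1)
    c_idx = np.clip(np.arange(w) + dc, 0, w - 1)
    return img[r_idx][:, c_idx]


def _in_bounds_mask(shape: tuple[int, int], dr: int, dc: int) -> np.ndarray:
    h, w = shape
    rows = (np.arange(h) + dr >= 0) & (np.arange(h) + dr < h)
    cols = (np.arange(w) + dc >= 0) & (np.arange(w) + dc < w)
    return rows[:, None] & cols[None, :]


# ----------------------------------------------------------- volume


def combined_cost_volume(
    left: np.ndarray,
    right: np.ndarray,
    arms_left: CrossArms | None,
    params: StereoParams,
    alpha: np.ndarray | float | None = None,
) -> np.ndarray:
    """H x W x D volume of normalized AD-Census costs.

    ``weight_mode='variable'`` takes alpha per pixel from the left
    image's cross arms; ``'fixed'`` uses the classic equal blend
    alpha = 0.5.  An explicit ``alpha`` overrides either (e.g. 1.0
    degenerates to the pure normalized AD volume).  Out-of-frame
    correspondences get the sentinel cost.
    """
    lg = _gray255(left)
    rg = _gray255(right)
    if lg.shape != rg.shape:
        raise ValueError("left/right shape mismatch")
    h, w = lg.shape
    if alpha is not None:
        if np.any((np.asarray(alpha) < 0) | (np.asarray(alpha) > 1)):
            raise ValueError("alpha must lie in [0, 1]")
        alpha = np.broadcast_to(np.asarray(alpha, dtype=np.float64), (h, w))
    elif params.weight_mode == "variable":
        if arms_left is None:
            raise ValueError("variable weights need the left image's cross arms")
        alpha = alpha_weight(arms_left.h_min())
    else:
        alpha = np.full((h, w), 0.5)

    code_l = census_transform(left, params.census_window)
    code_r = census_transform(right, params.census_window)
    volume = np.full((h, w, params.num_disparities), OUT_OF_RANGE_COST, dtype=np.float64)
    for i, d in enumerate(range(params.d_min, params.d_max + 1)):
        if d >= w:
            continue
        valid = slice(d, w)
        c_ad = np.abs(lg[:, valid] - rg[:, : w - d])
        c_c = hamming_cost(code_l[:, valid], code_r[:, : w - d])
        a = alpha[:, valid]
        volume[:, valid, i] = a * rho(c_ad, params.lambda_ad) + (1.0 - a) * rho(
            c_c, params.lambda_c
        )
    return volume


# ------------------------------------------------------- aggregation


def _directional_sum(values: np.ndarray, lo_arm: np.ndarray, hi_arm: np.ndarray, axis: int) -> np.ndarray:
    """Per-pixel sum of ``values`` over [i - lo_arm, i + hi_arm] along axis."""
    values = np.moveaxis(values, axis, -1)
    lo = np.moveaxis(lo_arm, axis, -1)
    hi = np.moveaxis(hi_arm, axis, -1)
    n = values.shape[-1]
    cs = np.concatenate([np.zeros(values.shape[:-1] + (1,)), np.cumsum(values, axis=-1)], axis=-1)
    idx = np.arange(n)
    hi_idx = np.minimum(idx + hi, n - 1) + 1
    lo_idx = np.maximum(idx - lo, 0)
    out = np.take_along_axis(cs, hi_idx, axis=-1) - np.take_along_axis(cs, lo_idx, axis=-1)
    return np.moveaxis(out, -1, axis)


def _one_pass(
    cost: np.ndarray, count: np.ndarray, arms: CrossArms, horizontal_first: bool
) -> tuple[np.ndarray, np.ndarray]:
    if horizontal_first:
        c = _directional_sum(cost, arms.left, arms.right, axis=1)
        n = _directional_sum(count, arms.left, arms.right, axis=1)
        c = _directional_sum(c, arms.up, arms.down, axis=0)
        n = _directional_sum(n, arms.up, arms.down, axis=0)
    else:
        c = _directional_sum(cost, arms.up, arms.down, axis=0)
        n = _directional_sum(count, arms.up, arms.down, axis=0)
        c = _directional_sum(c, arms.left, arms.right, axis=1)
        n = _directional_sum(n, arms.left, arms.right, axis=1)
    return c, n


def _combined_arms(arms_l: CrossArms, arms_r: CrossArms | None, d: int) -> CrossArms:
    """Intersection of p's arms with its match q = (r, c - d)'s arms."""
    if arms_r is None:
        return arms_l
    out = {}
    for name in ("left", "right", "up", "down"):
        a_l = getattr(arms_l, name)
        a_r = getattr(arms_r, name)
        shifted = np.empty_like(a_r)
        if d > 0:
            shifted[:, d:] = a_r[:, :-d]
            shifted[:, :d] = a_l[:, :d]  # no correspondence: keep left arms
        else:
            shifted = a_r
        out[name] = np.minimum(a_l, shifted)
    return CrossArms(**out)


def aggregate_cbca(
    volume: np.ndarray,
    arms: CrossArms,
    params: StereoParams,
    arms_right: CrossArms | None = None,
) -> np.ndarray:
    """Cross-based cost aggregation with exact per-region pixel counts.

    Each pass sums costs over the support region (union over the
    vertical arm of each member pixel's horizontal arms, or the
    transpose) and divides by the aggregated pixel count, i.e. the
    region mean.  Successive iterations alternate the pass order,
    starting with ``params.first_pass``.  When ``arms_right`` is given
    the support region at disparity d uses the per-direction minimum of
    p's arms and its correspondence q's arms.
    """
    h, w, nd = volume.shape
    out = np.empty_like(volume)
    for i in range(nd):
        d = params.d_min + i
        eff = _combined_arms(arms, arms_right, d)
        cost = volume[:, :, i]
        count = np.ones((h, w))
        for it in range(params.aggregation_iterations):
            horizontal = (params.first_pass == "horizontal") == (it % 2 == 0)
            agg_c, agg_n = _one_pass(cost, count, eff, horizontal)
            cost = agg_c / agg_n
            count = np.ones((h, w))
        out[:, :, i] = cost
    return out


# ----------------------------------------------------------- readout


def wta_disparity(volume: np.ndarray, d_min: int = 0) -> np.ndarray:
    """Winner-takes-all: per-pixel argmin cost; ties go to the smaller d."""
    return volume.argmin(axis=2).astype(np.float64) + d_min


def lr_refine(d_left: np.ndarray, d_right: np.ndarray, params: StereoParams) -> np.ndarray:
    """Left-right consistency check, hole filling and median cleanup.

    A pixel is invalidated when |d_L(p) - d_R(p - d_L(p))| exceeds
    ``lr_threshold`` (or its match is out of frame), then filled with
    the smaller of the nearest valid horizontal neighbors (background
    disparity), then smoothed with a 3x3 median.  Unfillable pixels
    keep the invalid sentinel.
    """
    d_left = np.asarray(d_left, dtype=np.float64)
    h, w = d_left.shape
    cols = np.arange(w)[None, :]
    match = np.rint(cols - d_left).astype(int)
    in_frame = (match >= 0) & (match < w)
    dr = np.full((h, w), np.inf)
    rows = np.arange(h)[:, None].repeat(w, axis=1)
    dr[in_frame] = np.asarray(d_right)[rows[in_frame], match[in_frame]]
    consistent = in_frame & (np.abs(d_left - dr) <= params.lr_threshold)
    if not consistent.any():
        warnings.warn("left-right check invalidated every pixel")
        return np.full((h, w), INVALID)

    filled = np.where(consistent, d_left, np.nan)
    out = filled.copy()
    for r in range(h):
        row = filled[r]
        good = np.where(np.isfinite(row))[0]
        if len(good) == 0:
            out[r] = INVALID
            continue
        bad = np.where(~np.isfinite(row))[0]
        pos = np.searchsorted(good, bad)
        left_idx = good[np.clip(pos - 1, 0, len(good) - 1)]
        right_idx = good[np.clip(pos, 0, len(good) - 1)]
        left_val = np.where(pos > 0, row[left_idx], np.inf)
        right_val = np.where(pos < len(good), row[right_idx], np.inf)
        out[r, bad] = np.minimum(left_val, right_val)
    med = ndimage.median_filter(out, size=3, mode="nearest")
    out = np.where(np.isfinite(out), med, INVALID)
    return out


def match_pair(left: np.ndarray, right: np.ndarray, params: StereoParams) -> np.ndarray:
    """Full matcher: crosses, variable-weight costs, CBCA, WTA, LR refine."""
    arms_l = build_cross(left, params)
    arms_r = build_cross(right, params)
    vol = combined_cost_volume(left, right, arms_l, params)
    vol = aggregate_cbca(vol, arms_l, params, arms_right=arms_r)
    d_l = wta_disparity(vol, params.d_min)
    if params.lr_threshold < 0:
        return d_l
    # right-referenced disparity via the mirrored problem
    lf, rf = left[:, ::-1], right[:, ::-1]
    arms_lf = build_cross(rf, params)
    arms_rf = build_cross(lf, params)
    vol_r = combined_cost_volume(rf, lf, arms_lf, params)
    vol_r = aggregate_cbca(vol_r, arms_lf, params, arms_right=arms_rf)
    d_r = wta_disparity(vol_r, params.d_min)[:, ::-1]
    return lr_refine(d_l, d_r, params)
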