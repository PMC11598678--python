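"""Independent brute-force reference implementations for oracle tests.

Everything here is written as directly as possible from the matching
rules — explicit per-pixel loops, no shared code with the package — so
the vectorized implementations can be checked against it on small
random instances.
"""

from __future__ import annotations

import numpy as np


def gray255(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    return img * 255.0 if img.max() <= 1.0 else img


def census_bits_brute(img: np.ndarray, window: tuple[int, int], r: int, c: int) -> int:
    """Census bit string at one pixel with reflected borders."""
    img = gray255(img)
    h, w = img.shape
    ph, pw = window[0] // 2, window[1] // 2

    def reflect(i: int, n: int) -> int:
        while i < 0 or i >= n:
            i = -i - 1 if i < 0 else 2 * n - 1 - i
        return i

    code = 0
    for dr in range(-ph, ph + 1):
        for dc in range(-pw, pw + 1):
            if dr == 0 and dc == 0:
                continue
            v = img[reflect(r + dr, h), reflect(c + dc, w)]
            code = (code << 1) | int(v < img[r, c])
    return code


def cross_arms_brute(img: np.ndarray, params) -> dict[str, np.ndarray]:
    """Arm extensions by literal traversal of the similarity rules."""
    img = gray255(img)
    h, w = img.shape
    out = {}
    for name, (dr, dc) in (
        ("left", (0, -1)),
        ("right", (0, 1)),
        ("up", (-1, 0)),
        ("down", (1, 0)),
    ):
        ext = np.zeros((h, w), dtype=int)
        for r in range(h):
            for c in range(w):
                k = 0
                while True:
                    kk = k + 1
                    rr, cc = r + dr * kk, c + dc * kk
                    if not (0 <= rr < h and 0 <= cc < w):
                        break
                    if params.mode == "original":
                        if kk >= params.L or abs(img[r, c] - img[rr, cc]) >= params.tau:
                            break
                    else:
                        if kk > params.L1:
                            break
                        tau = params.tau1 if kk <= params.L2 else params.tau2
                        # consecutive condition: arm pixel vs its inward neighbor
                        consec = abs(img[rr, cc] - img[rr - dr, cc - dc])
                        if abs(img[r, c] - img[rr, cc]) >= tau or consec >= tau:
                            break
                    k = kk
                ext[r, c] = k
        out[name] = ext
    return out


def combined_cost_brute(left, right, alpha, params) -> np.ndarray:
    """Per-pixel AD-Census cost volume evaluated pointwise."""
    lg, rg = gray255(left), gray255(right)
    h, w = lg.shape
    nd = params.d_max - params.d_min + 1
    vol = np.full((h, w, nd), 1.0)
    for r in range(h):
        for c in range(w):
            for i, d in enumerate(range(params.d_min, params.d_max + 1)):
                if c - d < 0:
                    continue
                ad = abs(lg[r, c] - rg[r, c - d])
                cc = bin(
                    census_bits_brute(left, params.census_window, r, c)
                    ^ census_bits_brute(right, params.census_window, r, c - d)
                ).count("1")
                a = alpha[r, c] if np.ndim(alpha) == 2 else alpha
                vol[r, c, i] = a * (1 - np.exp(-ad / params.lambda_ad)) + (1 - a) * (
                    1 - np.exp(-cc / params.lambda_c)
                )
    return vol


def cbca_one_pass_brute(
    cost: np.ndarray, arms: dict[str, np.ndarray], horizontal_first: bool
) -> np.ndarray:
    """Mean cost over the explicitly enumerated cross support region.

    Horizontal-first: the region is the union, over every pixel q on
    p's vertical arm, of q's own horizontal arm segment (and the
    transpose for vertical-first).
    """
    h, w = cost.shape
    out = np.zeros_like(cost, dtype=np.float64)
    for r in range(h):
        for c in range(w):
            total, count = 0.0, 0
            if horizontal_first:
                for rr in range(r - arms["up"][r, c], r + arms["down"][r, c] + 1):
                    for cc in range(c - arms["left"][rr, c], c + arms["right"][rr, c] + 1):
                        total += cost[rr, cc]
                        count += 1
            else:
                for cc in range(c - arms["left"][r, c], c + arms["right"][r, c] + 1):
                    for rr in range(r - arms["up"][r, cc], r + arms["down"][r, cc] + 1):
                        total += cost[rr, cc]
                        count += 1
            out[r, c] = total / count
    return out


def occlusion_brute(disparity: np.ndarray) -> np.ndarray:
    """Visibility by exhaustive rightmost-wins check per target column."""
    d = np.rint(np.asarray(disparity)).astype(int)
    h, w = d.shape
    visible = np.zeros((h, w), dtype=bool)
    for r in range(h):
        winner: dict[int, int] = {}
        for c in range(w):
            t = c - d[r, c]
            if 0 <= t < w:
                winner[t] = c  # later (rightmost) writer wins
        for t, c in winner.items():
            visible[r, c] = True
    return visible


def hausdorff_brute(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    fwd = max(min(np.hypot(*(p - q)) for q in b) for p in a)
    bwd = max(min(np.hypot(*(p - q)) for q in a) for p in b)
    return max(fwd, bwd)
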