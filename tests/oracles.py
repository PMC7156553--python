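"""Independent brute-force reference implementations of the metrics.

These are deliberately written as explicit loops over index pairs, sharing no
code with the package, so agreement is a meaningful cross-check.
"""

import math

import numpy as np


def pearson_pairs(xs, ys) -> float:
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    if sxx == 0 or syy == 0:
        return float("nan")
    return sxy / math.sqrt(sxx * syy)


def pearson_by_distance_brute(a: np.ndarray, b: np.ndarray, dmax: int) -> list[float]:
    out = []
    n = a.shape[0]
    for d in range(dmax + 1):
        xs = [a[i, i + d] for i in range(n - d)]
        ys = [b[i, i + d] for i in range(n - d)]
        out.append(pearson_pairs(xs, ys))
    return out


def smooth_brute(a: np.ndarray, h: int) -> np.ndarray:
    n = a.shape[0]
    out = np.zeros_like(a, dtype=float)
    for i in range(n):
        for j in range(n):
            vals = [
                a[u, v]
                for u in range(max(0, i - h), min(n, i + h + 1))
                for v in range(max(0, j - h), min(n, j + h + 1))
            ]
            out[i, j] = sum(vals) / len(vals)
    return out


def scc_brute(a: np.ndarray, b: np.ndarray, h: int, dmax: int) -> float:
    sa = smooth_brute(a, h)
    sb = smooth_brute(b, h)
    n = a.shape[0]
    num = den = 0.0
    for d in range(1, dmax + 1):
        xs = [sa[i, i + d] for i in range(n - d)]
        ys = [sb[i, i + d] for i in range(n - d)]
        mx = sum(xs) / len(xs)
        my = sum(ys) / len(ys)
        vx = sum((x - mx) ** 2 for x in xs) / len(xs)
        vy = sum((y - my) ** 2 for y in ys) / len(ys)
        if vx == 0 or vy == 0:
            continue
        rho = pearson_pairs(xs, ys)
        w = len(xs) * math.sqrt(vx) * math.sqrt(vy)
        num += w * rho
        den += w
    return num / den if den else float("nan")


def ssim_brute(a: np.ndarray, b: np.ndarray, window: int, L: float) -> float:
    c1 = (0.01 * L) ** 2
    c2 = (0.03 * L) ** 2
    n = a.shape[0]
    npix = window * window
    scores = []
    for i in range(n - window + 1):
        for j in range(n - window + 1):
            wa = [a[u, v] for u in range(i, i + window) for v in range(j, j + window)]
            wb = [b[u, v] for u in range(i, i + window) for v in range(j, j + window)]
            mu_a = sum(wa) / npix
            mu_b = sum(wb) / npix
            va = sum((x - mu_a) ** 2 for x in wa) / (npix - 1)
            vb = sum((x - mu_b) ** 2 for x in wb) / (npix - 1)
            cov = sum((x - mu_a) * (y - mu_b) for x, y in zip(wa, wb)) / (npix - 1)
            scores.append(
                ((2 * mu_a * mu_b + c1) * (2 * cov + c2))
                / ((mu_a**2 + mu_b**2 + c1) * (va + vb + c2))
            )
    return sum(scores) / len(scores)


def p2ll_brute(grid: np.ndarray, loops, r: int, corner: int) -> float:
    kept = []
    n = grid.shape[0]
    for i, j in loops:
        i, j = (i, j) if i <= j else (j, i)
        if i - r < 0 or j - r < 0 or i + r >= n or j + r >= n or j - i <= 2 * r:
            continue
        kept.append((i, j))
    side = 2 * r + 1
    agg = np.zeros((side, side))
    for i, j in kept:
        for u in range(side):
            for v in range(side):
                agg[u, v] += grid[i - r + u, j - r + v]
    agg /= len(kept)
    ll = [agg[u, v] for u in range(side - corner, side) for v in range(corner)]
    return agg[r, r] / (sum(ll) / len(ll))
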