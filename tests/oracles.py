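"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity by direct enumeration or a closed
form, sharing no code with the implementation under test.
"""

from __future__ import annotations

import numpy as np


def brute_force_otsu(img: np.ndarray) -> int:
    """Exhaustive argmax of between-class variance over all 255 splits."""
    hist = np.bincount(img.ravel(), minlength=256).astype(float)
    n = hist.sum()
    best_t, best_v = None, -1.0
    for t in range(255):
        n0 = hist[: t + 1].sum()
        n1 = n - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = (hist[: t + 1] * np.arange(t + 1)).sum() / n0
        mu1 = (hist[t + 1 :] * np.arange(t + 1, 256)).sum() / n1
        v = (n0 / n) * (n1 / n) * (mu0 - mu1) ** 2
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return best_t


def brute_force_yen(img: np.ndarray) -> int:
    """Exhaustive argmax of Yen's maximum-correlation criterion."""
    hist = np.bincount(img.ravel(), minlength=256).astype(float)
    p = hist / hist.sum()
    best_t, best_c = None, -np.inf
    for t in range(255):
        p0 = p[: t + 1].sum()
        p1 = 1.0 - p0
        g0 = (p[: t + 1] ** 2).sum()
        g1 = (p[t + 1 :] ** 2).sum()
        if p0 <= 0 or p1 <= 0 or g0 <= 0 or g1 <= 0:
            continue
        c = -np.log(g0 * g1) + 2.0 * np.log(p0 * p1)
        if c > best_c + 1e-12:
            best_c, best_t = c, t
    return best_t


def flood_fill_labels(mask: np.ndarray) -> np.ndarray:
    """8-connected component labelling by explicit breadth-first flood
    fill in raster-scan order."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    nxt = 0
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if mask[i, j] and labels[i, j] == 0:
                nxt += 1
                stack = [(i, j)]
                labels[i, j] = nxt
                while stack:
                    y, x = stack.pop()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if (
                                0 <= yy < h and 0 <= xx < w
                                and mask[yy, xx] and labels[yy, xx] == 0
                            ):
                                labels[yy, xx] = nxt
                                stack.append((yy, xx))
    return labels


def labelings_equivalent(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two labelings induce the same partition of foreground."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape or np.any((a > 0) != (b > 0)):
        return False
    fg = a > 0
    pairs = set(zip(a[fg].tolist(), b[fg].tolist()))
    return len(pairs) == len({x for x, _ in pairs}) == len({y for _, y in pairs})


def neighborhood_filter(img: np.ndarray, radius: int, fn) -> np.ndarray:
    """Per-pixel neighbourhood statistic, by loops; edges reflect about
    the border including the edge sample (numpy's "symmetric")."""
    img = np.asarray(img, dtype=float)
    pad = np.pad(img, radius, mode="symmetric")
    out = np.empty_like(img)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = fn(pad[i : i + 2 * radius + 1, j : j + 2 * radius + 1])
    return out


def ols_slope(x, y) -> float:
    """Closed-form ordinary least-squares slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    return float((xc * (y - y.mean())).sum() / (xc * xc).sum())


def max_pairwise_distance(points: np.ndarray) -> float:
    """Max distance over all point pairs, by full enumeration."""
    pts = np.asarray(points, dtype=float)
    best = 0.0
    for i in range(len(pts)):
        d = np.hypot(*(pts[i + 1 :] - pts[i]).T)
        if len(d) and d.max() > best:
            best = float(d.max())
    return best
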