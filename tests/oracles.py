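"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's algorithms: intervals are checked by
exhaustive enumeration, Otsu by scanning all 256 candidate thresholds, and
Mann-Whitney p-values by enumerating group assignments.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

SQRT2 = math.sqrt(2.0)


def brute_path_nm(pixels, i0, i1, pitch=40.0):
    """Sum step lengths one step at a time."""
    total = 0.0
    lo, hi = sorted((i0, i1))
    for k in range(lo, hi):
        dr = abs(pixels[k + 1][0] - pixels[k][0])
        dc = abs(pixels[k + 1][1] - pixels[k][1])
        total += pitch * SQRT2 if (dr and dc) else pitch
    return total


def brute_main_stretch(both, max_gap):
    """Try every candidate interval; keep the longest valid one (head-most tie)."""
    n = len(both)
    best, best_len = None, -1
    for i in range(n):
        if not both[i]:
            continue
        for j in range(i, n):
            if not both[j]:
                continue
            run, ok = 0, True
            for k in range(i, j + 1):
                if both[k]:
                    run = 0
                else:
                    run += 1
                    if run > max_gap:
                        ok = False
                        break
            if ok and j - i + 1 > best_len:
                best, best_len = (i, j), j - i + 1
    return best


def brute_protrusion(pos_red, pos_green, interval, end, pixels, max_gap,
                     pitch=40.0):
    """Literal restatement of the per-end rule, computed step by step."""
    both = [r and g for r, g in zip(pos_red, pos_green)]
    n = len(both)
    i0, i1 = interval
    step = -1 if end == "head" else 1
    while True:
        boundary = i0 if end == "head" else i1
        border = boundary + step
        if not 0 <= border < n:
            return "none", 0.0, (i0, i1)
        if both[border]:
            while 0 <= border < n and both[border]:
                if end == "head":
                    i0 = border
                else:
                    i1 = border
                border += step
            continue
        if not pos_red[border] and not pos_green[border]:
            return "none", 0.0, (i0, i1)
        channel = "red" if pos_red[border] else "green"
        pos = pos_red if channel == "red" else pos_green
        last, gap, j = border, 0, border + step
        while 0 <= j < n:
            if pos[j]:
                last, gap = j, 0
            else:
                gap += 1
                if gap > max_gap:
                    break
            j += step
        return channel, brute_path_nm(pixels, boundary, last, pitch), (i0, i1)


def brute_otsu_threshold(image, nbins=256):
    """Scan all candidate thresholds, maximising between-class variance."""
    image = np.asarray(image, dtype=float).ravel()
    counts, edges = np.histogram(image, bins=nbins,
                                 range=(image.min(), image.max()))
    centres = 0.5 * (edges[:-1] + edges[1:])
    best_t, best_var = centres[0], -1.0
    total = counts.sum()
    for k in range(1, nbins):
        w0, w1 = counts[:k].sum(), counts[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:k] * centres[:k]).sum() / w0
        mu1 = (counts[k:] * centres[k:]).sum() / w1
        var = w0 / total * w1 / total * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, centres[k - 1]
    return best_t


def brute_mannwhitney(x, y):
    """Exact two-sided p by enumerating all group assignments of the pool."""
    x, y = list(map(float, x)), list(map(float, y))
    nx = len(x)
    pool = x + y

    def u_of(subset):
        u = 0.0
        rest = [pool[i] for i in range(len(pool)) if i not in subset]
        for a in (pool[i] for i in subset):
            for b in rest:
                u += 1.0 if a > b else (0.5 if a == b else 0.0)
        return u

    u_obs = u_of(tuple(range(nx)))
    mu = nx * len(y) / 2.0
    extreme = total = 0
    for subset in itertools.combinations(range(len(pool)), nx):
        total += 1
        if abs(u_of(subset) - mu) >= abs(u_obs - mu) - 1e-9:
            extreme += 1
    return u_obs, extreme / total


def brute_median_filter(values, window):
    out = []
    h = window // 2
    n = len(values)
    for i in range(n):
        out.append(float(np.median(values[max(0, i - h):min(n, i + h + 1)])))
    return np.array(out)
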