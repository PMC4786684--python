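"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle recomputes a quantity with the most literal method available —
per-pixel enumeration, graph components, explicit point-to-line geometry —
deliberately sharing no code path with the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from gliaquant.morphology import circle_pixels


def classify_counts_bruteforce(m1: np.ndarray, m2: np.ndarray) -> dict[str, int]:
    """Pixel-pair classification counts by explicit per-pixel enumeration."""
    counts = {"stable": 0, "extended": 0, "retracted": 0, "background": 0}
    for r in range(m1.shape[0]):
        for c in range(m1.shape[1]):
            a, b = bool(m1[r, c]), bool(m2[r, c])
            if a and b:
                counts["stable"] += 1
            elif b:
                counts["extended"] += 1
            elif a:
                counts["retracted"] += 1
            else:
                counts["background"] += 1
    return counts


def sholl_crossings_bruteforce(mask: np.ndarray, center: tuple[int, int], radius_px: int) -> int:
    """Crossing count as 8-connected components of foreground circle pixels.

    Walks the discretized sampling circle pixel-by-pixel, keeps the
    foreground ones, and counts connected groups with a flood fill — an
    independent counting method from the ordered-run transition count.
    """
    rr, cc = circle_pixels(center, radius_px)
    pts = [
        (int(r), int(c))
        for r, c in zip(rr, cc)
        if 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c]
    ]
    remaining = set(pts)
    components = 0
    while remaining:
        components += 1
        stack = [remaining.pop()]
        while stack:
            r, c = stack.pop()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    p = (r + dr, c + dc)
                    if p in remaining:
                        remaining.remove(p)
                        stack.append(p)
    return components


def triangle_threshold_bruteforce(hist: np.ndarray) -> int:
    """Triangle threshold by explicit point-to-line distance at every bin.

    The line joins the histogram peak to the farthest non-empty tail bin;
    each candidate bin's perpendicular distance is computed from the
    normalized line equation; ties go to the bin nearest the peak.
    """
    hist = np.asarray(hist, dtype=float)
    nz = np.nonzero(hist)[0]
    peak = int(np.argmax(hist))
    left, right = int(nz[0]), int(nz[-1])
    tail = right if (right - peak) >= (peak - left) else left
    x1, y1 = float(peak), float(hist[peak])
    x2, y2 = float(tail), float(hist[tail])
    norm = math.hypot(x2 - x1, y2 - y1)
    best_d, best_x = -1.0, peak
    lo, hi = sorted((peak, tail))
    for x in range(lo, hi + 1):
        # distance from (x, h(x)) to the line through (x1,y1)-(x2,y2)
        d = abs((y2 - y1) * (x - x1) - (x2 - x1) * (hist[x] - y1)) / norm
        if d > best_d + 1e-12 or (abs(d - best_d) <= 1e-12 and abs(x - peak) < abs(best_x - peak)):
            best_d, best_x = d, x
    return best_x


def grubbs_decision_bruteforce(values: np.ndarray, alpha: float) -> int | None:
    """Index of the value a single two-sided Grubbs pass removes, or None."""
    x = np.asarray(values, dtype=float)
    n = x.size
    sd = x.std(ddof=1)
    if sd == 0:
        return None
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = dev[idx] / sd
    t = stats.t.ppf(1 - alpha / (2 * n), df=n - 2)
    g_crit = ((n - 1) / math.sqrt(n)) * math.sqrt(t**2 / (n - 2 + t**2))
    return idx if g > g_crit else None
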