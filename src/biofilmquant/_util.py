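"""Shared numeric helpers: seeded RNG streams, parabolic morphology, geometry."""

from __future__ import annotations

import numpy as np
from numba import njit


def stream_rng(seed: int, *keys: int) -> np.random.Generator:
    """Named child stream of a master seed (stable across runs)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


# ---------------------------------------------------------------------------
# 1-D parabolic (quadratic structuring function) morphology, used by the
# sliding-paraboloid background estimator.  The erosion is the lower envelope
# min_q f(q) + a (p - q)^2, computed per line in O(n) with the standard
# lower-envelope-of-parabolas sweep.


@njit(cache=False)
def _parabolic_erosion_lines(f: np.ndarray, a: float) -> np.ndarray:
    n_lines, n = f.shape
    out = np.empty_like(f)
    v = np.empty(n, dtype=np.int64)
    z = np.empty(n + 1, dtype=np.float64)
    for li in range(n_lines):
        line = f[li]
        k = 0
        v[0] = 0
        z[0] = -1e30
        z[1] = 1e30
        for q in range(1, n):
            s = ((line[q] + a * q * q) - (line[v[k]] + a * v[k] * v[k])) / (2.0 * a * (q - v[k]))
            while s <= z[k]:
                k -= 1
                s = ((line[q] + a * q * q) - (line[v[k]] + a * v[k] * v[k])) / (2.0 * a * (q - v[k]))
            k += 1
            v[k] = q
            z[k] = s
            z[k + 1] = 1e30
        k = 0
        for p in range(n):
            while z[k + 1] < p:
                k += 1
            d = p - v[k]
            out[li, p] = a * d * d + line[v[k]]
    return out


def _erode_axis(f: np.ndarray, a: float, axis: int) -> np.ndarray:
    arr = np.ascontiguousarray(np.moveaxis(f, axis, -1), dtype=np.float64)
    shp = arr.shape
    res = _parabolic_erosion_lines(arr.reshape(-1, shp[-1]), a).reshape(shp)
    return np.moveaxis(res, -1, axis)


def paraboloid_opening(f: np.ndarray, curvature: float) -> np.ndarray:
    """Grayscale opening with the rotationally symmetric paraboloid
    s(x, y) = -curvature * (x^2 + y^2).

    The paraboloid is the separable choice of structuring function, so the
    exact 2-D result is obtained from 1-D passes along rows and columns.
    Returns the lower envelope traced by sliding the paraboloid under the
    intensity surface ``f`` (same shape, <= f everywhere).
    """
    a = float(curvature)
    ero = _erode_axis(_erode_axis(f, a, 0), a, 1)
    dil = -_erode_axis(_erode_axis(-ero, a, 0), a, 1)
    return dil


def largest_true_rectangle(valid: np.ndarray) -> tuple[int, int, int, int]:
    """Maximal-area axis-aligned all-True rectangle of a boolean matrix.

    Returns ``(r0, c0, r1, c1)`` with half-open row/col ranges.  Classic
    histogram-of-heights + monotonic stack sweep, O(rows * cols).
    """
    valid = np.asarray(valid, dtype=bool)
    h, w = valid.shape
    heights = np.zeros(w, dtype=np.int64)
    best = (0, 0, 0, 0)
    best_area = 0
    for r in range(h):
        heights = np.where(valid[r], heights + 1, 0)
        stack: list[int] = []
        for c in range(w + 1):
            cur = int(heights[c]) if c < w else 0
            while stack and int(heights[stack[-1]]) > cur:
                idx = stack.pop()
                hgt = int(heights[idx])
                left = stack[-1] + 1 if stack else 0
                area = hgt * (c - left)
                if area > best_area:
                    best_area = area
                    best = (r + 1 - hgt, left, r + 1, c)
            stack.append(c)
    return best
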