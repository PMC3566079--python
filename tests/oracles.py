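"""Independent brute-force oracles for the texture and rank statistics.

Everything here is coded directly from the parameter definitions with
explicit loops and sums, deliberately avoiding the vectorized paths used
by the package, so the two can be compared as independent routes.
"""

from __future__ import annotations

import math

import numpy as np


def plane_coefficients(z: np.ndarray, dx: float, dy: float):
    """Least-squares mean plane via explicitly assembled normal equations."""
    nr, nc = z.shape
    xs = [(j - (nc - 1) / 2.0) * dx for j in range(nc)]
    ys = [(i - (nr - 1) / 2.0) * dy for i in range(nr)]
    s = {"1": 0.0, "x": 0.0, "y": 0.0, "xx": 0.0, "yy": 0.0, "xy": 0.0,
         "z": 0.0, "zx": 0.0, "zy": 0.0}
    for i in range(nr):
        for j in range(nc):
            x, y, v = xs[j], ys[i], z[i, j]
            s["1"] += 1; s["x"] += x; s["y"] += y
            s["xx"] += x * x; s["yy"] += y * y; s["xy"] += x * y
            s["z"] += v; s["zx"] += v * x; s["zy"] += v * y
    A = np.array([[s["1"], s["x"], s["y"]],
                  [s["x"], s["xx"], s["xy"]],
                  [s["y"], s["xy"], s["yy"]]])
    b = np.array([s["z"], s["zx"], s["zy"]])
    return np.linalg.solve(A, b), xs, ys


def detrended(z: np.ndarray, dx: float, dy: float) -> np.ndarray:
    (a, bx, by), xs, ys = plane_coefficients(z, dx, dy)
    out = np.empty_like(z, dtype=float)
    for i in range(z.shape[0]):
        for j in range(z.shape[1]):
            out[i, j] = z[i, j] - (a + bx * xs[j] + by * ys[i])
    return out


def height_params(z: np.ndarray, dx: float, dy: float) -> dict:
    r = detrended(z, dx, dy)
    vals = [v for row in r for v in row]
    n = len(vals)
    sa = sum(abs(v) for v in vals) / n
    sq = math.sqrt(sum(v * v for v in vals) / n)
    m3 = sum(v**3 for v in vals) / n
    m4 = sum(v**4 for v in vals) / n
    sp = max(vals)
    sv = -min(vals)
    return {"Sa": sa, "Sq": sq, "Ssk": m3 / sq**3, "Sku": m4 / sq**4,
            "Sp": sp, "Sv": sv, "Sz": sp + sv}


def hybrid_params(z: np.ndarray, dx: float, dy: float) -> dict:
    nr, nc = z.shape
    g2sum = 0.0
    devsum = 0.0
    for i in range(nr):
        for j in range(nc):
            if 0 < j < nc - 1:
                gx = (z[i, j + 1] - z[i, j - 1]) / (2 * dx)
            elif j == 0:
                gx = (z[i, 1] - z[i, 0]) / dx
            else:
                gx = (z[i, nc - 1] - z[i, nc - 2]) / dx
            if 0 < i < nr - 1:
                gy = (z[i + 1, j] - z[i - 1, j]) / (2 * dy)
            elif i == 0:
                gy = (z[1, j] - z[0, j]) / dy
            else:
                gy = (z[nr - 1, j] - z[nr - 2, j]) / dy
            g2 = gx * gx + gy * gy
            g2sum += g2
            devsum += math.sqrt(1.0 + g2) - 1.0
    n = nr * nc
    return {"Sdq": math.sqrt(g2sum / n), "Sdr": devsum / n * 100.0}


def height_at_material_ratio(values, p: float) -> float:
    """Type-7 quantile at (1 - p/100), coded from the order statistics."""
    a = sorted(values)
    n = len(a)
    q = (1.0 - p / 100.0) * (n - 1)
    lo = int(math.floor(q))
    hi = min(lo + 1, n - 1)
    return a[lo] + (q - lo) * (a[hi] - a[lo])


def functional_params(z: np.ndarray, dx: float, dy: float,
                      c_um: float = 1.0) -> dict:
    r = detrended(z, dx, dy)
    vals = [v for row in r for v in row]
    n = len(vals)

    def vm(p):
        h = height_at_material_ratio(vals, p)
        return sum(v - h for v in vals if v > h) / n

    def vv(p):
        h = height_at_material_ratio(vals, p)
        return sum(h - v for v in vals if v < h) / n

    level = max(vals) - c_um
    smr = sum(1 for v in vals if v >= level) / n * 100.0
    return {
        "Smr": smr,
        "Smc": height_at_material_ratio(vals, 10.0),
        "Sxp": (height_at_material_ratio(vals, 50.0)
                - height_at_material_ratio(vals, 97.5)),
        "Vm": vm(10.0), "Vv": vv(10.0), "Vmp": vm(10.0),
        "Vmc": vm(80.0) - vm(10.0), "Vvc": vv(10.0) - vv(80.0),
        "Vvv": vv(80.0),
    }


def cliff_delta(x, y) -> float:
    """Cliff's dominance by exhaustive pair enumeration."""
    more = less = 0
    for xi in x:
        for yj in y:
            if xi > yj:
                more += 1
            elif xi < yj:
                less += 1
    return (more - less) / (len(x) * len(y))


def trimmed_mean(x, trim: float) -> float:
    a = sorted(x)
    g = math.floor(trim * len(a))
    kept = a[g:len(a) - g]
    return sum(kept) / len(kept)
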