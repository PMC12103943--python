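"""Independent brute-force oracles for cross-checking the package.

Everything here is deliberately naive (cell-by-cell loops, explicit double
sums) and shares no code with the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np


def flood_fill_patches(data: np.ndarray, nodata: int, connectivity: int):
    """Cell-by-cell BFS patch delineation. Returns a list of dicts with
    class, area and perimeter (cell-edge units)."""
    rows, cols = data.shape
    seen = np.zeros(data.shape, dtype=bool)
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1)]
    patches = []
    for r0 in range(rows):
        for c0 in range(cols):
            if seen[r0, c0] or data[r0, c0] == nodata:
                continue
            code = data[r0, c0]
            stack = [(r0, c0)]
            seen[r0, c0] = True
            cells = []
            while stack:
                r, c = stack.pop()
                cells.append((r, c))
                for dr, dc in steps:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols and not seen[rr, cc] and data[rr, cc] == code:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            perim = 0
            for r, c in cells:
                for dr, dc in [(-1, 0), (1, 0), (0, -1), (0, 1)]:
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < rows and 0 <= cc < cols) or data[rr, cc] != code:
                        perim += 1
            patches.append({"class": int(code), "area": len(cells), "perimeter": perim})
    return patches


def naive_cohesion(data: np.ndarray, nodata: int, connectivity: int) -> float:
    patches = flood_fill_patches(data, nodata, connectivity)
    n = sum(p["area"] for p in patches)
    num = sum(p["perimeter"] for p in patches)
    den = sum(p["perimeter"] * math.sqrt(p["area"]) for p in patches)
    return 100.0 * (1.0 - num / den) / (1.0 - 1.0 / math.sqrt(n))


def naive_contag(data: np.ndarray, nodata: int) -> float:
    """Contagion from explicit cell-pair counting (double-count adjacency)."""
    rows, cols = data.shape
    valid = data != nodata
    codes = sorted({int(v) for v in data[valid].ravel()})
    m = len(codes)
    assert m >= 2
    idx = {c: k for k, c in enumerate(codes)}
    g = np.zeros((m, m))
    for r in range(rows):
        for c in range(cols):
            if not valid[r, c]:
                continue
            for dr, dc in [(-1, 0), (1, 0), (0, -1), (0, 1)]:
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols and valid[rr, cc]:
                    g[idx[data[r, c]], idx[data[rr, cc]]] += 1
    counts = np.array([(data[valid] == c).sum() for c in codes], dtype=float)
    p = counts / counts.sum()
    acc = 0.0
    for i in range(m):
        gi = g[i].sum()
        for k in range(m):
            if gi > 0 and g[i, k] > 0:
                q = p[i] * g[i, k] / gi
                acc += q * math.log(q)
    return 100.0 * (1.0 + acc / (2.0 * math.log(m)))


def naive_moran(x: np.ndarray, W: np.ndarray) -> float:
    """Global Moran's I as an explicit double loop."""
    n = len(x)
    xbar = x.mean()
    s0 = 0.0
    num = 0.0
    for i in range(n):
        for j in range(n):
            s0 += W[i, j]
            num += W[i, j] * (x[i] - xbar) * (x[j] - xbar)
    den = sum((xi - xbar) ** 2 for xi in x)
    return n / s0 * num / den


def points_in_polygon_mean(values, xs, ys, poly) -> float:
    """Zonal mean by testing every cell centre with shapely's predicate
    one point at a time."""
    from shapely.geometry import Point

    picked = [
        values[r, c]
        for r in range(values.shape[0])
        for c in range(values.shape[1])
        if poly.intersects(Point(xs[c], ys[r])) and np.isfinite(values[r, c])
    ]
    return float(np.mean(picked))


def naive_vif(X: np.ndarray) -> np.ndarray:
    """VIF via statsmodels (independent of the package's lstsq route)."""
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    Xc = sm.add_constant(np.asarray(X, dtype=float))
    return np.array([variance_inflation_factor(Xc, j) for j in range(1, Xc.shape[1])])
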