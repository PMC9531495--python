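"""Independent brute-force oracles for the scan statistic.

Everything here is written directly against the definitions (closed-form
log-likelihood ratio, rotation-matrix ellipse membership, exhaustive window
enumeration, polygonal ellipse intersection) in plain Python, deliberately
sharing no code path with the package's vectorized implementation.
"""

from __future__ import annotations

import math

import numpy as np


def llr_oracle(c: int, n: int, C: int, N: int) -> float:
    """Closed-form Bernoulli scan LLR with the 0 ln 0 = 0 convention."""

    def xl(x: float, ratio: float) -> float:
        return 0.0 if x == 0 else x * math.log(ratio)

    inside = xl(c, c / n) + xl(n - c, (n - c) / n)
    outside = xl(C - c, (C - c) / (N - n)) + xl(
        N - n - C + c, (N - n - C + c) / (N - n)
    )
    null = xl(C, C / N) + xl(N - C, (N - C) / N)
    return inside + outside - null


def rr_oracle(c: int, n: int, C: int, N: int) -> float:
    """Risk inside / risk outside, from the raw proportions."""
    if c == 0:
        return 0.0
    if c == C:
        return math.inf
    return (c / n) / ((C - c) / (N - n))


def in_ellipse_oracle(
    px: float, py: float, cx: float, cy: float,
    a: float, shape: float, theta: float,
) -> bool:
    """Closed-ellipse membership via an explicit rotation matrix."""
    rot = np.array(
        [[math.cos(-theta), -math.sin(-theta)],
         [math.sin(-theta), math.cos(-theta)]]
    )
    u, v = rot @ np.array([px - cx, py - cy])
    b = a / shape
    if a == 0:
        return u == 0 and v == 0
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0 + 1e-9


def elliptic_distance(
    px: float, py: float, cx: float, cy: float, shape: float, theta: float
) -> float:
    """Semi-major axis of the smallest (shape, theta) ellipse at (cx, cy)
    whose closed boundary reaches (px, py)."""
    rot = np.array(
        [[math.cos(-theta), -math.sin(-theta)],
         [math.sin(-theta), math.cos(-theta)]]
    )
    u, v = rot @ np.array([px - cx, py - cy])
    return math.hypot(u, shape * v)


def brute_force_best(
    x, y, year, is_case,
    shapes=(1.0,),
    angles_per_shape=(1,),
    max_spatial_fraction=0.5,
    max_temporal_fraction=0.5,
):
    """Exhaustive maximizer of the LLR over every candidate cylinder.

    Enumerates every distinct location as a center, every (shape, angle),
    every inter-point elliptic distance as a semi-major axis (up to the
    spatial fraction cap), and every year interval with endpoints on observed
    years (up to the temporal fraction cap). Returns (max_llr, argmax member
    frozensets).
    """
    x = list(map(float, x))
    y = list(map(float, y))
    year = list(map(int, year))
    is_case = list(map(bool, is_case))
    N = len(x)
    C = sum(is_case)
    kmax = max(1, math.floor(max_spatial_fraction * N))
    years = sorted(set(year))
    span = years[-1] - years[0] + 1
    lmax = max(1, math.floor(max_temporal_fraction * span))
    centers = sorted(set(zip(x, y)))
    orientations = [
        (s, math.pi * j / k)
        for s, k in zip(shapes, angles_per_shape)
        for j in range(k)
    ]
    intervals = [
        (y1, y2)
        for y1 in years
        for y2 in years
        if y1 <= y2 and y2 - y1 + 1 <= lmax
    ]
    best = -1.0
    argmax: list[frozenset] = []
    for cx, cy in centers:
        for s, theta in orientations:
            dists = [
                elliptic_distance(x[i], y[i], cx, cy, s, theta) for i in range(N)
            ]
            for a in sorted(set(dists)):
                spatial = [i for i in range(N) if dists[i] <= a * (1 + 1e-12)]
                if len(spatial) > kmax:
                    break
                for y1, y2 in intervals:
                    members = [i for i in spatial if y1 <= year[i] <= y2]
                    n = len(members)
                    if n < 1 or n > N - 1:
                        continue
                    c = sum(1 for i in members if is_case[i])
                    llr = llr_oracle(c, n, C, N)
                    key = frozenset(members)
                    if llr > best + 1e-9:
                        best = llr
                        argmax = [key]
                    elif abs(llr - best) <= 1e-9 and key not in argmax:
                        argmax.append(key)
    return best, argmax


def enumerate_member_sets_oracle(
    x, y, year,
    max_spatial_fraction=1.0,
    max_temporal_fraction=1.0,
):
    """All (spatial member frozenset, year interval) pairs for circular
    windows, by exhaustive center/radius/interval enumeration."""
    N = len(x)
    kmax = max(1, math.floor(max_spatial_fraction * N))
    years = sorted(set(year))
    span = years[-1] - years[0] + 1
    lmax = max(1, math.floor(max_temporal_fraction * span))
    out = set()
    for cx, cy in sorted(set(zip(x, y))):
        dists = [math.hypot(x[i] - cx, y[i] - cy) for i in range(N)]
        for a in sorted(set(dists)):
            spatial = frozenset(i for i in range(N) if dists[i] <= a)
            if len(spatial) > kmax:
                break
            for y1 in years:
                for y2 in years:
                    if y1 <= y2 and y2 - y1 + 1 <= lmax:
                        out.add((spatial, (y1, y2)))
    return out


def ellipse_polygon_oracle(cx, cy, a, shape, theta, n_vertices=256):
    """Polygonal ellipse via explicit parametric rotation (for intersection
    checks)."""
    from shapely.geometry import Polygon

    b = a / shape
    pts = []
    for k in range(n_vertices):
        t = 2 * math.pi * k / n_vertices
        u, v = a * math.cos(t), b * math.sin(t)
        pts.append(
            (
                cx + u * math.cos(theta) - v * math.sin(theta),
                cy + u * math.sin(theta) + v * math.cos(theta),
            )
        )
    return Polygon(pts)


def greedy_selection_oracle(candidates, max_reported=None):
    """Brute-force greedy non-overlap selection with 256-vertex polygons.

    ``candidates``: (cylinder, llr, n) triples as in the implementation.
    """
    order = sorted(
        range(len(candidates)),
        key=lambda i: (
            -candidates[i][1],
            candidates[i][2],
            candidates[i][0].center,
            candidates[i][0].semi_major,
        ),
    )
    polys = {}
    reported = []
    for i in order:
        cyl, llr, _ = candidates[i]
        if llr <= 0:
            break
        if max_reported is not None and len(reported) >= max_reported:
            break
        polys[i] = ellipse_polygon_oracle(
            cyl.center[0], cyl.center[1], cyl.semi_major, cyl.shape, cyl.angle
        )
        if any(polys[i].intersects(polys[j]) for j in reported):
            continue
        reported.append(i)
    return reported


def morans_i_oracle(grid_values: dict[tuple[int, int], float]) -> float:
    """Direct double-sum Moran's I with rook contiguity on a value grid."""
    keys = sorted(grid_values)
    vals = [grid_values[k] for k in keys]
    n = len(vals)
    mean = sum(vals) / n
    z = {k: grid_values[k] - mean for k in keys}
    num = 0.0
    W = 0
    for (i, j) in keys:
        for nb in ((i + 1, j), (i - 1, j), (i, j + 1), (i, j - 1)):
            if nb in z:
                num += z[(i, j)] * z[nb]
                W += 1
    denom = sum(v * v for v in z.values())
    return (n / W) * num / denom
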