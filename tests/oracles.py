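"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's accelerated code paths: closest-point
uses a direct barycentric/edge-clamping formulation, ray casting is a plain
per-triangle Moller-Trumbore loop, and the statistics oracles enumerate or
simulate.
"""
from __future__ import annotations

import numpy as np


def closest_point_on_triangle(p, a, b, c):
    """Closest point on one triangle by solving the plane projection and
    clamping against each edge segment explicitly."""
    p, a, b, c = (np.asarray(x, dtype=float) for x in (p, a, b, c))
    e0 = b - a
    e1 = c - a
    n = np.cross(e0, e1)
    nn = n @ n
    candidates = []
    if nn > 0:
        # project into the plane and solve for barycentric coordinates
        w = p - a
        d00, d01, d11 = e0 @ e0, e0 @ e1, e1 @ e1
        dw0, dw1 = w @ e0, w @ e1
        denom = d00 * d11 - d01 * d01
        if denom > 0:
            v = (d11 * dw0 - d01 * dw1) / denom
            u = (d00 * dw1 - d01 * dw0) / denom
            if v >= 0 and u >= 0 and v + u <= 1:
                candidates.append(a + v * e0 + u * e1)
    for s, t in ((a, b), (b, c), (c, a)):
        seg = t - s
        denom = seg @ seg
        lam = 0.0 if denom == 0 else np.clip(((p - s) @ seg) / denom, 0.0, 1.0)
        candidates.append(s + lam * seg)
    dists = [np.linalg.norm(p - q) for q in candidates]
    return candidates[int(np.argmin(dists))]


def brute_force_closest(scan, query):
    """(point, squared distance, face id) over every triangle; ties -> lowest id."""
    best_d2 = np.inf
    best = (None, np.inf, -1)
    for fi, (ia, ib, ic) in enumerate(scan.faces):
        q = closest_point_on_triangle(query, scan.vertices[ia], scan.vertices[ib], scan.vertices[ic])
        d2 = float(np.sum((np.asarray(query) - q) ** 2))
        if d2 < best_d2 - 1e-15:
            best_d2 = d2
            best = (q, d2, fi)
    return best


def brute_force_ray(scan, origin, direction, eps=1e-12):
    """All (t, face) line-triangle intersections by per-triangle MT."""
    origin = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    hits = []
    for fi, (ia, ib, ic) in enumerate(scan.faces):
        a = scan.vertices[ia]
        e1 = scan.vertices[ib] - a
        e2 = scan.vertices[ic] - a
        pvec = np.cross(d, e2)
        det = e1 @ pvec
        if abs(det) < eps:
            continue
        inv = 1.0 / det
        tvec = origin - a
        u = (tvec @ pvec) * inv
        qvec = np.cross(tvec, e1)
        v = (d @ qvec) * inv
        if u < -1e-9 or v < -1e-9 or u + v > 1 + 1e-9:
            continue
        hits.append((float((e2 @ qvec) * inv), fi))
    return hits


def wilcoxon_exact_enumeration(diffs):
    """Two-sided exact p for W = min(W+, W-) by enumerating all 2^n signs."""
    from itertools import product
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    w_obs = min(w_plus, w_minus)
    n = len(d)
    count = 0
    for signs in product((1, -1), repeat=n):
        wp = sum(r for r, s in zip(ranks, signs) if s > 0)
        wm = ranks.sum() - wp
        if min(wp, wm) <= w_obs + 1e-12:
            count += 1
    return count / 2**n


def icc_a1_by_hand(x, y):
    """ICC(A,1) for k=2 raters from explicitly written ANOVA sums of squares."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    data = np.column_stack([x, y])
    grand = data.mean()
    msr = 2 * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((data.mean(axis=0) - grand) ** 2).sum() / 1
    sse = ((data - data.mean(axis=1, keepdims=True)
            - data.mean(axis=0, keepdims=True) + grand) ** 2).sum()
    mse = sse / (n - 1)
    return (msr - mse) / (msr + mse + 2.0 * (msc - mse) / n)
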