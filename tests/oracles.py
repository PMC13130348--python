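"""Independent brute-force oracles used to cross-check the package.

Deliberately naive (nested loops, no shared code with the package) so they
constitute an independent second route to the same quantities.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def naive_shdi(grid) -> float:
    counts: dict = {}
    for row in np.asarray(grid):
        for v in row:
            counts[v] = counts.get(v, 0) + 1
    n = sum(counts.values())
    h = 0.0
    for c in counts.values():
        p = c / n
        h -= p * math.log(p)
    return h


def naive_patches(grid, connectivity: int = 8) -> list[set]:
    """Flood-fill connected components of equal class; returns cell sets."""
    grid = np.asarray(grid)
    nr, nc = grid.shape
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = set()
    patches = []
    for i in range(nr):
        for j in range(nc):
            if (i, j) in seen:
                continue
            cls = grid[i, j]
            stack, comp = [(i, j)], set()
            seen.add((i, j))
            while stack:
                a, b = stack.pop()
                comp.add((a, b))
                for da, db in nbrs:
                    na, nb = a + da, b + db
                    if (0 <= na < nr and 0 <= nb < nc and (na, nb) not in seen
                            and grid[na, nb] == cls):
                        seen.add((na, nb))
                        stack.append((na, nb))
            patches.append(comp)
    return patches


def naive_patch_perimeter(grid, patch: set, res: float) -> float:
    grid = np.asarray(grid)
    nr, nc = grid.shape
    sides = 0
    for (i, j) in patch:
        for di, dj in [(-1, 0), (1, 0), (0, -1), (0, 1)]:
            ni, nj = i + di, j + dj
            if not (0 <= ni < nr and 0 <= nj < nc):
                sides += 1
            elif (ni, nj) not in patch:
                sides += 1
    return sides * res


def naive_par(grid, res: float, connectivity: int = 8) -> float:
    patches = naive_patches(grid, connectivity)
    ratios = []
    for patch in patches:
        area = len(patch) * res * res
        perim = naive_patch_perimeter(grid, patch, res)
        ratios.append(perim / area)
    return sum(ratios) / len(ratios)


def naive_are(grid) -> float:
    grid = np.asarray(grid, dtype=float)
    total, n = 0.0, 0
    for row in grid:
        for v in row:
            total += v
            n += 1
    mean = total / n
    acc = 0.0
    for row in grid:
        for v in row:
            acc += abs(v - mean)
    return acc / n


def lmg_bruteforce(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """All-orderings sequential R^2 averaging, by explicit enumeration."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, t = X.shape
    ones = np.ones((n, 1))
    tss = ((y - y.mean()) ** 2).sum()

    def r2(cols):
        M = np.hstack([ones] + [X[:, [c]] for c in cols]) if cols else ones
        beta, *_ = np.linalg.lstsq(M, y, rcond=None)
        resid = y - M @ beta
        return 1.0 - (resid**2).sum() / tss

    shares = np.zeros(t)
    perms = list(itertools.permutations(range(t)))
    for perm in perms:
        done: list[int] = []
        prev = 0.0
        for c in perm:
            done.append(c)
            cur = r2(done)
            shares[c] += cur - prev
            prev = cur
    return shares / len(perms)


def dense_boundary_distance(point, vertices, n_samples: int = 10_000) -> float:
    """Min distance from a point to a closed polyline via dense sampling."""
    verts = np.asarray(vertices, float)
    closed = np.vstack([verts, verts[:1]])
    seg = np.diff(closed, axis=0)
    lengths = np.hypot(seg[:, 0], seg[:, 1])
    total = lengths.sum()
    pts = []
    for i in range(len(seg)):
        k = max(int(round(n_samples * lengths[i] / total)), 2)
        ts = np.linspace(0.0, 1.0, k)
        pts.append(closed[i] + ts[:, None] * seg[i])
    pts = np.vstack(pts)
    d = np.hypot(pts[:, 0] - point[0], pts[:, 1] - point[1])
    return float(d.min())


def dense_ns_edge_distance(point, vertices, n_samples: int = 10_000) -> float:
    """Brute-force distance to the nearer of the N/S boundary parts."""
    verts = np.asarray(vertices, float)
    closed = np.vstack([verts, verts[:1]])
    seg = np.diff(closed, axis=0)
    lengths = np.hypot(seg[:, 0], seg[:, 1])
    total = lengths.sum()
    pts = []
    for i in range(len(seg)):
        k = max(int(round(n_samples * lengths[i] / total)), 2)
        ts = np.linspace(0.0, 1.0, k)
        pts.append(closed[i] + ts[:, None] * seg[i])
    pts = np.vstack(pts)
    d = np.hypot(pts[:, 0] - point[0], pts[:, 1] - point[1])
    north = pts[:, 1] >= point[1]
    dists = []
    if north.any():
        dists.append(d[north].min())
    if (~north).any():
        dists.append(d[~north].min())
    return float(min(dists))
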