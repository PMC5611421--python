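"""Independent brute-force oracles used by the tests.

Deliberately written with explicit Python loops and no calls into the
package, so they cannot share a bug with the implementation they check.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def flood_largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest 8-connected component by iterative flood fill."""
    mask = np.asarray(mask, bool)
    visited = np.zeros_like(mask)
    best: list[tuple[int, int]] = []
    h, w = mask.shape
    for sr in range(h):
        for sc in range(w):
            if mask[sr, sc] and not visited[sr, sc]:
                stack, comp = [(sr, sc)], []
                visited[sr, sc] = True
                while stack:
                    r, c = stack.pop()
                    comp.append((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < h and 0 <= cc < w
                                    and mask[rr, cc] and not visited[rr, cc]):
                                visited[rr, cc] = True
                                stack.append((rr, cc))
                if len(comp) > len(best):
                    best = comp
    out = np.zeros_like(mask)
    for r, c in best:
        out[r, c] = True
    return out


def boundary_pixels(mask: np.ndarray) -> list[tuple[int, int]]:
    """Foreground pixels of the largest component with any background pixel
    (or the frame edge) among their 8 neighbours."""
    comp = flood_largest_component(mask)
    h, w = comp.shape
    out = []
    for r in range(h):
        for c in range(w):
            if not comp[r, c]:
                continue
            edge = False
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < h and 0 <= cc < w) or not comp[rr, cc]:
                        edge = True
            if edge:
                out.append((r, c))
    return out


def circularity_bruteforce(mask: np.ndarray) -> float:
    """mean(boundary distance to full-mask centroid) / population SD."""
    mask = np.asarray(mask, bool)
    rows, cols = np.nonzero(mask)
    cy = sum(rows) / len(rows)
    cx = sum(cols) / len(cols)
    dists = [math.hypot(r - cy, c - cx) for r, c in boundary_pixels(mask)]
    mean = sum(dists) / len(dists)
    var = sum((d - mean) ** 2 for d in dists) / len(dists)
    sd = math.sqrt(var)
    if sd < 1e-9:
        return 100.0
    return mean / sd


def midranks(values: list[float]) -> list[float]:
    """Mid-ranks computed by hand (ties share the average rank)."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j + 2) / 2.0  # ranks are 1-based
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def wilcoxon_exact_bruteforce(x, y) -> float:
    """Two-tailed exact rank-sum p by enumerating every assignment."""
    x, y = list(x), list(y)
    pooled = x + y
    ranks = midranks(pooled)
    nx, n = len(x), len(pooled)
    w_obs = sum(ranks[:nx])
    total = le = ge = 0
    for idx in combinations(range(n), nx):
        w = sum(ranks[i] for i in idx)
        total += 1
        if w <= w_obs + 1e-12:
            le += 1
        if w >= w_obs - 1e-12:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def gate_membership_bruteforce(row: dict, gates: list) -> list[str]:
    """Re-evaluate one object against a gate tree, one gate at a time."""
    passed: list[str] = []
    byname = {g.name: g for g in gates}

    def inside(g) -> bool:
        for ax, (lo, hi) in zip(g.axes, g.region):
            v = row[ax]
            if v != v:  # NaN
                return False
            if lo is not None and v < lo:
                return False
            if hi is not None and v >= hi:
                return False
        return True

    def in_gate(g) -> bool:
        if g.parent is not None and not in_gate(byname[g.parent]):
            return False
        return inside(g)

    for g in gates:
        if in_gate(g):
            passed.append(g.name)
    return passed
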