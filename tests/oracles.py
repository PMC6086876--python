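"""Independent brute-force oracle for the greedy cutoff clustering.

Plain O(n^2) loops, no k-d trees, no shared code with the implementation
under test.
"""

from __future__ import annotations

import math


def brute_pairs(points, cutoff):
    """All (i, j, d) with i<j and d < cutoff, sorted by (d, i, j). O(n^2)."""
    pts = [tuple(map(float, p)) for p in points]
    out = []
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d = math.dist(pts[i], pts[j])
            if d < cutoff:
                out.append((i, j, d))
    out.sort(key=lambda t: (t[2], t[0], t[1]))
    return out


def brute_iteration(points, weights, cutoff, unmatched="carry"):
    """One greedy round: drop isolated, merge ascending pairs, carry the rest."""
    pairs = brute_pairs(points, cutoff)
    neighboured = set()
    for i, j, _ in pairs:
        neighboured.add(i)
        neighboured.add(j)
    used = set()
    merges = []
    for i, j, d in pairs:
        if i not in used and j not in used:
            used.add(i)
            used.add(j)
            merges.append((i, j))
    carried = sorted(neighboured - used) if unmatched == "carry" else []
    new_points, new_weights = [], []
    for i, j in merges:
        new_points.append([(a + b) / 2.0 for a, b in zip(points[i], points[j])])
        new_weights.append(weights[i] + weights[j])
    for k in carried:
        new_points.append(list(points[k]))
        new_weights.append(weights[k])
    return new_points, new_weights, len(merges)


def brute_converge(points, cutoff, max_iterations=64):
    """Full iterative reduction; returns the per-iteration point lists."""
    pts = [list(map(float, p)) for p in points]
    wts = [1] * len(pts)
    out = [(pts, wts)]
    for _ in range(max_iterations):
        if len(pts) <= 1 or not brute_pairs(pts, cutoff):
            break
        pts, wts, n_merges = brute_iteration(pts, wts, cutoff)
        out.append((pts, wts))
        if n_merges == 0:
            break
    return out
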