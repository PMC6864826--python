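"""Independent brute-force reference implementations used only by tests.

These are deliberately written as plain per-element loops, separate from the
package's vectorized / compiled code paths, so that agreement between the two
routes is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def mean_shift_oracle(values, valid, hs, hr, kernel="epanechnikov", max_iter=100, tol=0.1):
    """Direct per-pixel summation of the mode-seeking iteration.

    ``values``: (B, H, W); returns (spatial (2,H,W) as (x, y), spectral (B,H,W)).
    Neighborhood membership requires spatial distance <= hs and spectral
    distance <= hr of the current estimate; the kernel weight acts on the
    range-normalized joint difference.
    """
    B, H, W = values.shape
    sp = np.full((2, H, W), np.nan)
    sr = np.full((B, H, W), np.nan)
    for r in range(H):
        for c in range(W):
            if not valid[r, c]:
                continue
            ys = np.array([float(c), float(r)])
            yr = values[:, r, c].astype(float).copy()
            for _ in range(max_iter):
                wsum = 0.0
                acc_s = np.zeros(2)
                acc_r = np.zeros(B)
                for rr in range(H):
                    for cc in range(W):
                        if not valid[rr, cc]:
                            continue
                        ds = math.hypot(cc - ys[0], rr - ys[1])
                        if ds > hs:
                            continue
                        dr = math.sqrt(float(((values[:, rr, cc] - yr) ** 2).sum()))
                        if dr > hr:
                            continue
                        u2 = (ds / hs) ** 2 + (dr / hr) ** 2
                        if kernel == "gaussian":
                            w = math.exp(-0.5 * u2)
                        else:
                            w = 1.0 - u2
                            if w <= 0.0:
                                continue
                        wsum += w
                        acc_s += w * np.array([cc, rr], dtype=float)
                        acc_r += w * values[:, rr, cc]
                if wsum <= 0.0:
                    break
                new_s = acc_s / wsum
                new_r = acc_r / wsum
                disp = math.sqrt(float(((new_s - ys) ** 2).sum() + ((new_r - yr) ** 2).sum()))
                ys, yr = new_s, new_r
                if disp < tol:
                    break
            sp[:, r, c] = ys
            sr[:, r, c] = yr
    return sp, sr


def flood_fill_mode_labels(spectral_modes, valid, tol):
    """Flood-fill labeling of the 4-adjacency graph thresholded at ``tol``.

    Two 4-neighbors join when the Euclidean distance of their spectral modes
    is <= tol.  Labels are dense, ordered by first occurrence in scan order.
    """
    B, H, W = spectral_modes.shape
    labels = np.full((H, W), -1, dtype=int)
    nxt = 0
    for r in range(H):
        for c in range(W):
            if not valid[r, c] or labels[r, c] >= 0:
                continue
            q = deque([(r, c)])
            labels[r, c] = nxt
            while q:
                rr, cc = q.popleft()
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    r2, c2 = rr + dr, cc + dc
                    if not (0 <= r2 < H and 0 <= c2 < W):
                        continue
                    if not valid[r2, c2] or labels[r2, c2] >= 0:
                        continue
                    d = math.sqrt(float(((spectral_modes[:, rr, cc] - spectral_modes[:, r2, c2]) ** 2).sum()))
                    if d <= tol:
                        labels[r2, c2] = nxt
                        q.append((r2, c2))
            nxt += 1
    return labels


def flood_fill_mask_components(mask):
    """4-connected components of a boolean mask by BFS; returns a label grid (-1 outside)."""
    H, W = mask.shape
    labels = np.full((H, W), -1, dtype=int)
    nxt = 0
    for r in range(H):
        for c in range(W):
            if not mask[r, c] or labels[r, c] >= 0:
                continue
            q = deque([(r, c)])
            labels[r, c] = nxt
            while q:
                rr, cc = q.popleft()
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    r2, c2 = rr + dr, cc + dc
                    if 0 <= r2 < H and 0 <= c2 < W and mask[r2, c2] and labels[r2, c2] < 0:
                        labels[r2, c2] = nxt
                        q.append((r2, c2))
            nxt += 1
    return labels


def partitions_of(items, k):
    """All ways to split ``items`` into k non-empty unordered groups."""
    items = list(items)
    if k == 1:
        yield [items]
        return
    if len(items) == k:
        yield [[x] for x in items]
        return
    first, rest = items[0], items[1:]
    for part in partitions_of(rest, k - 1):
        yield [[first]] + part
    for part in partitions_of(rest, k):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1:]


def best_kmeans_objective(points, k):
    """Global optimum of the within-cluster sum of squares by exhaustion."""
    points = np.asarray(points, dtype=float)
    best = math.inf
    for part in partitions_of(range(len(points)), k):
        obj = 0.0
        for group in part:
            sub = points[list(group)]
            obj += float(((sub - sub.mean(axis=0)) ** 2).sum())
        best = min(best, obj)
    return best
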