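"""Independent brute-force oracles used by the test suite.

Each function here re-computes a quantity with a deliberately different,
simpler algorithm than the package uses, so agreement is meaningful.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np


def flood_fill_enclosed_areas(mask: np.ndarray) -> list[int]:
    """Pixel areas of background regions NOT reachable from the border.

    4-connected BFS flood fill from every border background pixel; the
    remaining background pixels are grouped into 4-connected components
    and their sizes returned (sorted).  This is the "completely enclosed
    by hyphae" rule computed directly on pixels.
    """
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    reach = np.zeros((H, W), dtype=bool)
    q: deque[tuple[int, int]] = deque()
    for r in range(H):
        for c in (0, W - 1):
            if not mask[r, c] and not reach[r, c]:
                reach[r, c] = True
                q.append((r, c))
    for c in range(W):
        for r in (0, H - 1):
            if not mask[r, c] and not reach[r, c]:
                reach[r, c] = True
                q.append((r, c))
    while q:
        r, c = q.popleft()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < H and 0 <= cc < W and not mask[rr, cc] \
                    and not reach[rr, cc]:
                reach[rr, cc] = True
                q.append((rr, cc))
    enclosed = ~mask & ~reach
    areas = []
    seen = np.zeros((H, W), dtype=bool)
    for r0 in range(H):
        for c0 in range(W):
            if enclosed[r0, c0] and not seen[r0, c0]:
                size = 0
                seen[r0, c0] = True
                q.append((r0, c0))
                while q:
                    r, c = q.popleft()
                    size += 1
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < H and 0 <= cc < W \
                                and enclosed[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            q.append((rr, cc))
                areas.append(size)
    return sorted(areas)


def segment_circle_length(p0, p1, center, radius) -> float:
    """Length of the part of segment p0-p1 inside the circle (brute force).

    Dense sampling (adaptive, 1e5 samples) -- intentionally different from
    the package's analytic quadratic solution.
    """
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    n = 100_000
    t = (np.arange(n) + 0.5) / n
    pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    inside = ((pts - np.asarray(center, float)) ** 2).sum(axis=1) \
        <= radius ** 2
    return float(inside.mean() * np.linalg.norm(p1 - p0))


def segment_circle_length_exact(p0, p1, center, radius) -> float:
    """Exact chord clip via shapely (second independent route)."""
    from shapely.geometry import LineString, Point
    seg = LineString([tuple(p0), tuple(p1)])
    circle = Point(tuple(center)).buffer(radius, quad_segs=4096)
    return float(seg.intersection(circle).length)


def jenks_best_cost(values, k: int) -> float:
    """Minimum within-class SSD over all k-partitions of the sorted data."""
    xs = np.sort(np.asarray(values, dtype=float))
    m = len(xs)
    best = math.inf
    for cuts in itertools.combinations(range(1, m), k - 1):
        bounds = (0, *cuts, m)
        tot = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg = xs[a:b]
            tot += float(((seg - seg.mean()) ** 2).sum())
        best = min(best, tot)
    return best


def partition_cost(values, labels) -> float:
    """Within-class SSD of a given label assignment."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    tot = 0.0
    for lab in np.unique(labels):
        seg = values[labels == lab]
        tot += float(((seg - seg.mean()) ** 2).sum())
    return tot


def stroke_pixel_count(segments, shape, width) -> int:
    """Pixels whose center lies within width/2 of any segment (brute force)."""
    H, W = shape
    rr, cc = np.mgrid[0:H, 0:W]
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    close = np.zeros(len(pts), dtype=bool)
    for r0, c0, r1, c1 in segments:
        a = np.array([r0, c0])
        d = np.array([r1 - r0, c1 - c0])
        L2 = float(d @ d)
        if L2 == 0:
            dist = np.linalg.norm(pts - a, axis=1)
        else:
            t = np.clip((pts - a) @ d / L2, 0.0, 1.0)
            dist = np.linalg.norm(pts - a - t[:, None] * d, axis=1)
        close |= dist <= width / 2.0
    return int(close.sum())


def count_components(mask: np.ndarray, connectivity: int = 2) -> int:
    """Connected components by BFS (8-connectivity default)."""
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    seen = np.zeros((H, W), dtype=bool)
    if connectivity == 2:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    else:
        nbrs = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    n = 0
    q: deque[tuple[int, int]] = deque()
    for r0 in range(H):
        for c0 in range(W):
            if mask[r0, c0] and not seen[r0, c0]:
                n += 1
                seen[r0, c0] = True
                q.append((r0, c0))
                while q:
                    r, c = q.popleft()
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < H and 0 <= cc < W and mask[rr, cc] \
                                and not seen[rr, cc]:
                            seen[rr, cc] = True
                            q.append((rr, cc))
    return n


def euler_holes(mask: np.ndarray) -> int:
    """Number of holes: background components not touching the border (4-conn)."""
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1, constant_values=False)
    bg_comps = count_components(~padded, connectivity=1)
    return bg_comps - 1   # minus the unbounded background


def random_stroke_mask(rng: np.random.Generator, size: int = 96,
                       n_strokes: int | None = None,
                       width: float = 3.0) -> np.ndarray:
    """A hypha-like mask: a few random thick line strokes (some loops)."""
    if n_strokes is None:
        n_strokes = int(rng.integers(3, 9))
    segs = []
    for _ in range(n_strokes):
        r0, c0 = rng.uniform(5, size - 5, size=2)
        ang = rng.uniform(0, 2 * np.pi)
        ln = rng.uniform(15, size * 0.8)
        r1 = np.clip(r0 + ln * np.sin(ang), 2, size - 3)
        c1 = np.clip(c0 + ln * np.cos(ang), 2, size - 3)
        segs.append((r0, c0, r1, c1))
    rr, cc = np.mgrid[0:size, 0:size]
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    mask = np.zeros(size * size, dtype=bool)
    for r0, c0, r1, c1 in segs:
        a = np.array([r0, c0])
        d = np.array([r1 - r0, c1 - c0])
        L2 = float(d @ d)
        t = np.clip((pts - a) @ d / max(L2, 1e-12), 0.0, 1.0)
        dist = np.linalg.norm(pts - a - t[:, None] * d, axis=1)
        mask |= dist <= width / 2.0
    return mask.reshape(size, size)
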