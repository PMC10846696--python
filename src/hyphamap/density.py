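"""Hyphal density maps, density distributions and natural-breaks classes.

The skeleton is treated as a set of line segments.  A regular grid of
square cells is laid over the image (50 px cells by default) and the
density at each cell center is the total skeleton length inside a search
disc (200 px radius by default) divided by the disc area -- a smoothed
line density in px/px^2, i.e. a dimensionless length per unit area.
Segment-disc intersections are computed analytically (exact chord
clipping), so the map is an exact line-integral kernel estimate rather
than a pixel count.

The distribution of cell densities is histogrammed with a fixed bin width
(0.0024 by default) and normalized to a probability density over the
cells of the thallus envelope.  For choropleth-style rendering, densities
are classified with exact Fisher-Jenks natural breaks (5 classes by
default), computed by dynamic programming, which minimizes the total
within-class sum of squared deviations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DensityMap",
    "JenksClasses",
    "line_density",
    "density_distribution",
    "jenks_classify",
    "save_density_map",
    "render_density_png",
]

DEFAULT_CELL_SIZE_PX = 50
DEFAULT_SEARCH_RADIUS_PX = 200
DEFAULT_BIN_SIZE = 0.0024
DEFAULT_N_CLASSES = 5


@dataclass
class DensityMap:
    """Gridded line density of one frame.

    ``values[i, j]`` is the density at the cell center
    ``(row, col) = (cell_rows[i], cell_cols[j])`` in pixel coordinates of
    the source image.
    """

    values: np.ndarray
    cell_rows: np.ndarray
    cell_cols: np.ndarray
    cell_size: float
    search_radius: float
    source_shape: tuple[int, int]


def line_density(segments: np.ndarray, shape: tuple[int, int],
                 cell_size: float = DEFAULT_CELL_SIZE_PX,
                 search_radius: float = DEFAULT_SEARCH_RADIUS_PX,
                 ) -> DensityMap:
    """Exact line density of a segment set on a regular cell grid.

    ``segments`` is an (n, 4) array of (r0, c0, r1, c1) pixel coordinates
    (e.g. from :func:`hyphamap.skeleton.adjacency_segments`).  For each
    cell center the chord of every segment inside the search disc is
    accumulated analytically and divided by the disc area pi*R^2.
    """
    segments = np.asarray(segments, dtype=float).reshape(-1, 4)
    H, W = int(shape[0]), int(shape[1])
    if cell_size <= 0 or search_radius <= 0:
        raise ValueError("cell_size and search_radius must be positive")
    rows = np.arange(cell_size / 2.0, H, cell_size)
    cols = np.arange(cell_size / 2.0, W, cell_size)
    values = np.zeros((len(rows), len(cols)))
    if len(segments) == 0:
        return DensityMap(values=values, cell_rows=rows, cell_cols=cols,
                          cell_size=cell_size, search_radius=search_radius,
                          source_shape=(H, W))

    p0 = segments[:, :2]
    d = segments[:, 2:] - p0
    a = (d * d).sum(axis=1)               # squared segment lengths
    seg_len = np.sqrt(a)
    ok = a > 0
    p0, d, a, seg_len = p0[ok], d[ok], a[ok], seg_len[ok]
    mid = p0 + 0.5 * d
    reach = search_radius + 0.5 * seg_len.max() if len(seg_len) else 0.0

    # bin segment midpoints so each cell only tests nearby segments
    bin_size = max(search_radius, cell_size)
    bins_r = np.floor(mid[:, 0] / bin_size).astype(int)
    bins_c = np.floor(mid[:, 1] / bin_size).astype(int)
    order = np.lexsort((bins_c, bins_r))
    buckets: dict[tuple[int, int], np.ndarray] = {}
    keys = np.column_stack([bins_r[order], bins_c[order]])
    if len(keys):
        change = np.nonzero(np.any(np.diff(keys, axis=0) != 0, axis=1))[0] + 1
        for chunk in np.split(order, change):
            buckets[(int(bins_r[chunk[0]]), int(bins_c[chunk[0]]))] = chunk

    disc_area = np.pi * search_radius ** 2
    for i, cr in enumerate(rows):
        br_lo = int(np.floor((cr - reach) / bin_size))
        br_hi = int(np.floor((cr + reach) / bin_size))
        for j, cc in enumerate(cols):
            bc_lo = int(np.floor((cc - reach) / bin_size))
            bc_hi = int(np.floor((cc + reach) / bin_size))
            cand = [buckets[(br, bc)]
                    for br in range(br_lo, br_hi + 1)
                    for bc in range(bc_lo, bc_hi + 1)
                    if (br, bc) in buckets]
            if not cand:
                continue
            idx = np.concatenate(cand)
            f = p0[idx] - (cr, cc)
            b = 2.0 * (f * d[idx]).sum(axis=1)
            c0 = (f * f).sum(axis=1) - search_radius ** 2
            disc = b * b - 4.0 * a[idx] * c0
            hit = disc > 0
            if not hit.any():
                continue
            sq = np.sqrt(disc[hit])
            aa = a[idx][hit]
            t_lo = np.maximum((-b[hit] - sq) / (2.0 * aa), 0.0)
            t_hi = np.minimum((-b[hit] + sq) / (2.0 * aa), 1.0)
            inside = np.clip(t_hi - t_lo, 0.0, None) * seg_len[idx][hit]
            values[i, j] = inside.sum() / disc_area
    return DensityMap(values=values, cell_rows=rows, cell_cols=cols,
                      cell_size=cell_size, search_radius=search_radius,
                      source_shape=(H, W))


def density_distribution(dmap: DensityMap,
                         bin_size: float = DEFAULT_BIN_SIZE) -> pd.DataFrame:
    """Histogram of cell densities, normalized to a probability density.

    The envelope is the set of cells with nonzero density (a proxy for the
    area the network occupies); frequencies are counts divided by
    (envelope cell count x bin width), so ``sum(frequency) * bin_size``
    is 1.  The returned frame carries ``envelope_cells``, ``max_density``
    and ``bin_size`` in ``DataFrame.attrs``; an all-zero map yields an
    empty distribution with ``envelope_cells == 0``.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    vals = dmap.values
    sel = vals[vals > 0]
    if sel.size == 0:
        df = pd.DataFrame(columns=["bin_left", "bin_right", "count",
                                   "frequency"])
        df.attrs.update(envelope_cells=0, max_density=0.0, bin_size=bin_size)
        return df
    n_bins = int(np.ceil((sel.max() + 1e-12) / bin_size)) or 1
    edges = np.arange(n_bins + 1) * bin_size
    counts, _ = np.histogram(sel, bins=edges)
    freq = counts / (sel.size * bin_size)
    df = pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "count": counts,
        "frequency": freq,
    })
    df.attrs.update(envelope_cells=int(sel.size),
                    max_density=float(sel.max()), bin_size=bin_size)
    return df


@dataclass
class JenksClasses:
    """Exact natural-breaks partition of a 1-D value set.

    ``breaks`` has ``n_classes + 1`` entries: the data minimum followed by
    the upper value of each class.  ``labels[i]`` in ``0..n_classes-1``
    assigns each input value to its class.  ``gvf`` is the goodness of
    variance fit, 1 - (within-class SSD / total SSD).
    """

    breaks: np.ndarray
    labels: np.ndarray
    n_classes: int
    gvf: float


def jenks_classify(values, n_classes: int = DEFAULT_N_CLASSES,
                   ) -> JenksClasses:
    """Exact Fisher-Jenks natural-breaks classification.

    The partition minimizes the within-class sum of squared deviations,
    computed by exact dynamic programming (not a heuristic), so it is
    deterministic and permutation-invariant.  If the data have fewer
    distinct values than classes, the class count is reduced with a
    warning.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("no values to classify")
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    uniq = np.unique(x)
    if len(uniq) < n_classes:
        warnings.warn(f"only {len(uniq)} distinct values; reducing classes "
                      f"from {n_classes}", stacklevel=2)
        n_classes = len(uniq)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    m = len(xs)
    s1 = np.concatenate([[0.0], np.cumsum(xs)])
    s2 = np.concatenate([[0.0], np.cumsum(xs * xs)])

    def ssd_to(j: int) -> np.ndarray:
        """ssd(i, j) for all starts i = 0..j (inclusive bounds)."""
        i = np.arange(j + 1)
        n = j - i + 1
        tot = s1[j + 1] - s1[i]
        sq = s2[j + 1] - s2[i]
        return sq - tot * tot / n

    # cost[k][j]: best total ssd of splitting xs[0..j] into k+1 classes
    cost = np.full((n_classes, m), np.inf)
    back = np.zeros((n_classes, m), dtype=int)
    for j in range(m):
        cost[0, j] = ssd_to(j)[0]
    for k in range(1, n_classes):
        for j in range(k, m):
            tails = ssd_to(j)               # tails[i] = ssd(i, j)
            i = np.arange(k, j + 1)
            tot = cost[k - 1, i - 1] + tails[i]
            best = int(np.argmin(tot))
            cost[k, j] = tot[best]
            back[k, j] = k + best           # class k starts at this index

    # recover class start indices
    starts = np.zeros(n_classes, dtype=int)
    j = m - 1
    for k in range(n_classes - 1, 0, -1):
        starts[k] = back[k, j]
        j = starts[k] - 1
    breaks = np.empty(n_classes + 1)
    breaks[0] = xs[0]
    for k in range(n_classes):
        hi = (starts[k + 1] - 1) if k + 1 < n_classes else m - 1
        breaks[k + 1] = xs[hi]
    labels_sorted = np.zeros(m, dtype=int)
    for k in range(1, n_classes):
        labels_sorted[starts[k]:] = k
    labels = np.empty(m, dtype=int)
    labels[order] = labels_sorted
    ss_tot = float(((xs - xs.mean()) ** 2).sum())
    ss_within = float(cost[n_classes - 1, m - 1])
    gvf = 1.0 - ss_within / ss_tot if ss_tot > 0 else 1.0
    return JenksClasses(breaks=breaks, labels=labels, n_classes=n_classes,
                        gvf=gvf)


# ---------------------------------------------------------------------------
# export helpers


def save_density_map(dmap: DensityMap, tiff_path: str | Path,
                     meta_path: str | Path) -> None:
    """Write the density grid as a float32 TIFF plus a JSON sidecar.

    The sidecar records the cell size, search radius, source image shape
    and the pixel coordinate of the first cell center, so the grid can be
    georeferenced back onto the panorama.
    """
    import tifffile
    tifffile.imwrite(str(tiff_path), dmap.values.astype(np.float32))
    meta = {
        "cell_size_px": dmap.cell_size,
        "search_radius_px": dmap.search_radius,
        "source_shape": list(dmap.source_shape),
        "origin_row": float(dmap.cell_rows[0]) if len(dmap.cell_rows) else None,
        "origin_col": float(dmap.cell_cols[0]) if len(dmap.cell_cols) else None,
    }
    Path(meta_path).write_text(json.dumps(meta, indent=2))


def render_density_png(dmap: DensityMap, path: str | Path,
                       n_classes: int = DEFAULT_N_CLASSES) -> np.ndarray:
    """Render a natural-breaks classed density map to a PNG; returns breaks."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm

    jc = jenks_classify(dmap.values, n_classes=n_classes)
    breaks = jc.breaks
    edges = np.unique(breaks)
    if len(edges) < 2:
        edges = np.array([edges[0], edges[0] + 1e-9])
    cmap = plt.get_cmap("viridis", len(edges) - 1)
    norm = BoundaryNorm(edges, cmap.N)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(dmap.values, cmap=cmap, norm=norm,
                   extent=(0, dmap.source_shape[1], dmap.source_shape[0], 0))
    fig.colorbar(im, ax=ax, label="line density (px/px$^2$)")
    ax.set_xlabel("col (px)")
    ax.set_ylabel("row (px)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return breaks
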