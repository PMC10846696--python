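"""Skeletonization of the thallus and hyphal graph measurements.

The clean binary thallus mask is thinned to a one-pixel-wide skeleton
(homotopic thinning, Zhang-Suen family), and the skeleton is vectorized
into a graph whose vertices are classified by connectivity: an *apex* is a
degree-1 endpoint (a hyphal tip), a *node* is a junction of degree >= 3 (a
true branch point, an anastomosis, or a mere overlap of two hyphae -- the
image cannot distinguish them), and degree-2 pixels form the hyphal paths.
Adjacent junction pixels are merged into a single node, since thinning can
smear one biological junction over several pixels.

Lengths use the chamfer metric: 1 per orthogonal step, sqrt(2) per
diagonal step, times the pixel size.  Counts carry Poisson uncertainties
(sigma_A = sqrt(A), sigma_N = sqrt(N)); the total length uncertainty
treats L as about A + N segments of mean length <l> = L / (A + N), giving
sigma_L = sqrt(A + N) * <l>.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

from .frames import TIME_UNCERTAINTY_H

__all__ = ["Skeleton", "HyphalGraph", "thin", "skeleton_to_graph",
           "adjacency_segments", "measure_series"]

SQRT2 = math.sqrt(2.0)


@dataclass
class Skeleton:
    """A 1-px-wide thinned mask."""

    mask: np.ndarray
    source_shape: tuple[int, int] | None = None


@dataclass
class HyphalGraph:
    """Skeleton-derived network measurements for one frame.

    A     apex count (degree-1 endpoints)
    N     node count (8-connected clusters of degree >= 3 pixels)
    L_px  total skeleton length in px (chamfer metric)
    edges list of pixel polylines between terminal vertices
    """

    A: int
    N: int
    L_px: float
    pixel_size: float
    vertices: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)
    edges: list[np.ndarray] = field(default_factory=list, repr=False)

    @property
    def L_um(self) -> float:
        return self.L_px * self.pixel_size

    @property
    def mean_segment_length_um(self) -> float:
        """<l> = L / (A + N); 0 when the graph is empty."""
        return self.L_um / (self.A + self.N) if (self.A + self.N) else 0.0

    @property
    def sigma_A(self) -> float:
        return math.sqrt(self.A)

    @property
    def sigma_N(self) -> float:
        return math.sqrt(self.N)

    @property
    def sigma_L_um(self) -> float:
        n_seg = self.A + self.N
        return math.sqrt(n_seg) * self.mean_segment_length_um if n_seg else 0.0


def thin(mask: np.ndarray, max_thickness: float = 5.0) -> Skeleton:
    """Thin a binary mask to 1-px-wide strokes, preserving topology.

    ``max_thickness`` documents the expected maximum stroke width (px);
    wider strokes are thinned all the same but trigger a warning, since
    the skeleton of a blob much wider than a hypha is not a centreline.
    An empty mask yields an empty skeleton.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return Skeleton(mask=np.zeros_like(mask), source_shape=mask.shape)
    width = 2.0 * ndimage.distance_transform_edt(mask).max()
    if width > max_thickness + 1.0:
        warnings.warn(
            f"mask strokes up to ~{width:.0f} px wide exceed max_thickness="
            f"{max_thickness}; skeleton may cut corners", stacklevel=2)
    sk = _sk_skeletonize(mask)
    sk = _remove_2x2_blocks(sk)
    return Skeleton(mask=sk, source_shape=mask.shape)


_N8_OFFSETS = ((-1, -1), (-1, 0), (-1, 1), (0, 1),
               (1, 1), (1, 0), (1, -1), (0, -1))


def _build_simple_lut() -> np.ndarray:
    """256-entry table: is the center of a 3x3 patch an (8,4) simple point?

    A foreground pixel is simple (removable without changing topology) iff
    its foreground 8-neighbors form exactly one 8-connected component and
    its background neighbors form exactly one 4-connected component that
    touches a 4-neighbor.
    """
    lut = np.zeros(256, dtype=bool)
    for cfg in range(256):
        patch = np.zeros((3, 3), dtype=bool)
        for bit, (dr, dc) in enumerate(_N8_OFFSETS):
            if cfg >> bit & 1:
                patch[1 + dr, 1 + dc] = True
        nb_fg, n_fg = ndimage.label(patch, structure=np.ones((3, 3)))
        bg = ~patch
        bg[1, 1] = False   # center counts as foreground
        nb_bg, _ = ndimage.label(bg, structure=np.array(
            [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
        touching = {nb_bg[1 + dr, 1 + dc]
                    for dr, dc in ((-1, 0), (0, 1), (1, 0), (0, -1))
                    if nb_bg[1 + dr, 1 + dc] > 0}
        lut[cfg] = (n_fg == 1) and (len(touching) == 1)
    return lut


_SIMPLE_LUT = _build_simple_lut()


def _neighborhood_code(pad: np.ndarray, r: int, c: int) -> int:
    """Bit code of the 8-neighborhood of (r, c) in a 1-px padded mask."""
    code = 0
    for bit, (dr, dc) in enumerate(_N8_OFFSETS):
        if pad[r + 1 + dr, c + 1 + dc]:
            code |= 1 << bit
    return code


def _remove_2x2_blocks(sk: np.ndarray) -> np.ndarray:
    """Delete simple points until no 2x2 all-foreground block remains.

    Thinning algorithms occasionally leave 2x2 blocks in dense tangles;
    deleting only simple points keeps components and holes intact.
    """
    sk = sk.astype(bool).copy()
    for _ in range(16):
        blocks = sk[:-1, :-1] & sk[1:, :-1] & sk[:-1, 1:] & sk[1:, 1:]
        if not blocks.any():
            break
        pad = np.zeros((sk.shape[0] + 2, sk.shape[1] + 2), dtype=bool)
        pad[1:-1, 1:-1] = sk
        progress = False
        for r, c in np.argwhere(blocks):
            for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1)):
                rr, cc = r + dr, c + dc
                if not sk[rr, cc]:
                    continue
                # still part of a full 2x2 block?
                if not _in_full_block(sk, rr, cc):
                    continue
                if _SIMPLE_LUT[_neighborhood_code(pad, rr, cc)]:
                    sk[rr, cc] = False
                    pad[rr + 1, cc + 1] = False
                    progress = True
        if not progress:
            warnings.warn("residual 2x2 skeleton block could not be thinned "
                          "without changing topology", stacklevel=3)
            break
    return sk


def _in_full_block(sk: np.ndarray, r: int, c: int) -> bool:
    H, W = sk.shape
    for r0 in (r - 1, r):
        for c0 in (c - 1, c):
            if 0 <= r0 < H - 1 and 0 <= c0 < W - 1:
                if sk[r0:r0 + 2, c0:c0 + 2].all():
                    return True
    return False


def adjacency_segments(sk: Skeleton) -> np.ndarray:
    """Skeleton pixel adjacencies as line segments (r0, c0, r1, c1).

    Uses the same redundant-diagonal pruning as :func:`skeleton_to_graph`,
    so summing the segment lengths reproduces the chamfer length L_px
    exactly.  Coordinates are pixel centers in (row, col) order.
    """
    mask = np.asarray(sk.mask, dtype=bool)
    H, W = mask.shape
    pad = np.zeros((H + 2, W + 2), dtype=bool)
    pad[1:-1, 1:-1] = mask

    def nb(dr: int, dc: int) -> np.ndarray:
        return pad[1 + dr:H + 1 + dr, 1 + dc:W + 1 + dc]

    segs: list[np.ndarray] = []
    for dr, dc, diag in ((0, 1, False), (1, 0, False),
                         (1, 1, True), (1, -1, True)):
        both = mask & nb(dr, dc)
        if diag:
            both &= ~(nb(dr, 0) | nb(0, dc))
        rr, cc = np.nonzero(both)
        if len(rr):
            segs.append(np.column_stack([rr, cc, rr + dr, cc + dc]))
    if not segs:
        return np.empty((0, 4), dtype=float)
    return np.concatenate(segs).astype(float)


def skeleton_to_graph(sk: Skeleton, pixel_size: float = 1.0) -> HyphalGraph:
    """Classify skeleton pixels and measure A, N and L.

    Pixel adjacency is 8-connected with the redundant-diagonal rule: a
    diagonal step is dropped when an orthogonal 2-step path through a
    skeleton pixel exists, so lengths are not double counted around
    corners.  Degree-1 pixels are apexes; 8-connected clusters of
    degree >= 3 pixels collapse to one node at their centroid.
    """
    mask = np.asarray(sk.mask, dtype=bool)
    coords = np.argwhere(mask)
    if len(coords) == 0:
        return HyphalGraph(A=0, N=0, L_px=0.0, pixel_size=pixel_size,
                           vertices=pd.DataFrame(
                               columns=["row", "col", "degree", "class"]))
    index = -np.ones(mask.shape, dtype=np.int64)
    index[mask] = np.arange(len(coords))

    # adjacency as index pairs (i < j), orthogonal then pruned diagonal
    pairs: list[tuple[np.ndarray, np.ndarray, float]] = []
    H, W = mask.shape
    pad = np.zeros((H + 2, W + 2), dtype=bool)
    pad[1:-1, 1:-1] = mask

    def nb(dr: int, dc: int) -> np.ndarray:
        return pad[1 + dr:H + 1 + dr, 1 + dc:W + 1 + dc]

    for dr, dc, w in ((0, 1, 1.0), (1, 0, 1.0), (1, 1, SQRT2), (1, -1, SQRT2)):
        both = mask & nb(dr, dc)
        if w > 1.0:
            # redundant diagonal: orthogonal shortcut through a skeleton px
            both &= ~(nb(dr, 0) | nb(0, dc))
        rr, cc = np.nonzero(both)
        if len(rr):
            pairs.append((index[rr, cc], index[rr + dr, cc + dc], w))

    degree = np.zeros(len(coords), dtype=np.int64)
    L_px = 0.0
    adj: list[list[int]] = [[] for _ in range(len(coords))]
    for a, b, w in pairs:
        np.add.at(degree, a, 1)
        np.add.at(degree, b, 1)
        L_px += w * len(a)
        for i, j in zip(a.tolist(), b.tolist()):
            adj[i].append(j)
            adj[j].append(i)

    apex = degree <= 1          # includes isolated dots
    junction = degree >= 3
    # merge adjacent junction pixels into single nodes
    jmask = np.zeros(mask.shape, dtype=bool)
    jmask[coords[junction, 0], coords[junction, 1]] = True
    jlabels, n_nodes = ndimage.label(jmask, structure=np.ones((3, 3)))
    A = int(apex.sum())

    classes = np.where(apex, "apex", np.where(junction, "node", "path"))
    vertices = pd.DataFrame({
        "row": coords[:, 0], "col": coords[:, 1],
        "degree": degree, "class": classes,
    })

    edges = _trace_edges(coords, adj, degree)
    return HyphalGraph(A=A, N=int(n_nodes), L_px=float(L_px),
                       pixel_size=pixel_size, vertices=vertices, edges=edges)


def _trace_edges(coords: np.ndarray, adj: list[list[int]],
                 degree: np.ndarray) -> list[np.ndarray]:
    """Contract degree-2 chains into polylines between terminal pixels."""
    terminal = degree != 2
    used: set[tuple[int, int]] = set()
    edges: list[np.ndarray] = []

    def walk(start: int, nxt: int) -> None:
        path = [start, nxt]
        used.add((min(start, nxt), max(start, nxt)))
        prev, cur = start, nxt
        while not terminal[cur]:
            a, b = adj[cur]
            nxt2 = b if a == prev else a
            key = (min(cur, nxt2), max(cur, nxt2))
            if key in used:
                break
            used.add(key)
            path.append(nxt2)
            prev, cur = cur, nxt2
        edges.append(coords[path])

    for i in np.nonzero(terminal)[0]:
        for j in adj[i]:
            key = (min(int(i), j), max(int(i), j))
            if key not in used:
                walk(int(i), j)
    # pure cycles (no terminal pixel): trace from any unused pixel
    for i in np.nonzero(~terminal)[0]:
        for j in adj[i]:
            key = (min(int(i), j), max(int(i), j))
            if key not in used:
                walk(int(i), j)
    return edges


def measure_series(graphs: list[HyphalGraph], times: list[float],
                   ) -> pd.DataFrame:
    """Tabulate A, N, L over time with Poisson/derived uncertainties.

    The returned frame carries ``delta_t_h`` (acquisition-time
    uncertainty, 1 min) in ``DataFrame.attrs``.
    """
    if not graphs:
        raise ValueError("no graphs")
    if len(graphs) != len(times):
        raise ValueError("graphs and times differ in length")
    rows = []
    for g, t in sorted(zip(graphs, times), key=lambda p: p[1]):
        rows.append({
            "time_h": t,
            "A": g.A, "sigma_A": g.sigma_A,
            "N": g.N, "sigma_N": g.sigma_N,
            "L_um": g.L_um, "sigma_L_um": g.sigma_L_um,
            "mean_segment_um": g.mean_segment_length_um,
        })
    df = pd.DataFrame(rows)
    df.attrs["delta_t_h"] = TIME_UNCERTAINTY_H
    return df
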