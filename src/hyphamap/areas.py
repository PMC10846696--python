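"""Intra-thallus empty areas: the surfaces enclosed between hyphae.

The intra-thallus areas ``S_i`` are the background polygons that lie
completely inside the thallus; their sum ``S`` measures the surface the
network has closed off, and their count tracks the densification of the
network over time.  Background regions that touch the image border, or that
are not fully enclosed (the outermost open ring of the thallus), are
excluded by construction.

Counts carry Poisson uncertainties (sigma = sqrt(count)); the total area
``S`` carries a bootstrap uncertainty obtained by resampling the ``S_i``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Polygon
from shapely.prepared import prep

from .vectorize import Region, RegionSet

__all__ = [
    "AreaRecord",
    "extract_intra_areas",
    "area_time_series",
    "bootstrap_S_uncertainty",
]


@dataclass
class AreaRecord:
    """Intra-thallus areas of one frame.

    ``S_i_px2`` are the individual enclosed areas in px^2; ``S`` is their
    exact sum.  ``pixel_size`` (um/px) converts to physical units:
    mm^2 = px^2 * (pixel_size / 1000)^2.
    """

    time: float
    S_i_px2: np.ndarray
    pixel_size: float
    regions: list[Region] = field(default_factory=list, repr=False)

    @property
    def S_px2(self) -> int:
        return int(self.S_i_px2.sum())

    @property
    def count(self) -> int:
        return len(self.S_i_px2)

    @property
    def count_uncertainty(self) -> float:
        """Poisson sigma on the number of enclosed areas."""
        return float(np.sqrt(self.count))

    @property
    def S_i_mm2(self) -> np.ndarray:
        return self.S_i_px2 * (self.pixel_size / 1000.0) ** 2

    @property
    def S_mm2(self) -> float:
        return float(self.S_i_mm2.sum())

    @property
    def mean_Si_mm2(self) -> float:
        return float(self.S_i_mm2.mean()) if self.count else 0.0

    def S_uncertainty_mm2(self, n_boot: int = 1000, seed: int = 0) -> float:
        if self.count == 0:
            return 0.0
        return bootstrap_S_uncertainty(self.S_i_mm2, n_boot=n_boot, seed=seed)


def extract_intra_areas(rs: RegionSet, thallus: Region, time: float = 0.0,
                        pixel_size: float = 1.0) -> AreaRecord:
    """Collect the background regions completely enclosed by the thallus.

    A background region qualifies when it does not touch the image border
    (it cannot be reached from the unbounded background) and the thallus
    encloses it: either it lies within the outer shell of the thallus
    polygon, or -- for holes pinched between diagonally-touching parts of
    the thallus, which fall outside every exterior ring -- every foreground
    pixel it touches belongs to the thallus.  A tree-like thallus with no
    closed loops yields an empty record, not an error.
    """
    shell = _outer_shell(thallus.geometry)
    shell_prep = prep(shell)
    adjacency = _bg_fg_adjacency(rs)
    keep: list[Region] = []
    for reg in rs.background():
        if reg.touches_border:
            continue
        neighbors = adjacency.get(reg.label, set())
        if neighbors == {thallus.label} \
                or shell_prep.contains(reg.geometry.representative_point()):
            keep.append(reg)
    keep.sort(key=lambda r: r.label)
    areas = np.asarray([r.pixel_area for r in keep], dtype=np.int64)
    return AreaRecord(time=time, S_i_px2=areas, pixel_size=pixel_size,
                      regions=keep)


def _bg_fg_adjacency(rs: RegionSet) -> dict[int, set[int]]:
    """Map each background label to the set of 4-adjacent foreground labels."""
    bg, fg = rs.bg_labels, rs.fg_labels
    adj: dict[int, set[int]] = {}
    pairs = set()
    for src, dst in (((slice(1, None), slice(None)),
                      (slice(None, -1), slice(None))),
                     ((slice(None), slice(1, None)),
                      (slice(None), slice(None, -1)))):
        for a, b in ((src, dst), (dst, src)):
            hit = (bg[a] > 0) & (fg[b] > 0)
            pairs.update(zip(bg[a][hit].tolist(), fg[b][hit].tolist()))
    for b_lab, f_lab in pairs:
        adj.setdefault(b_lab, set()).add(f_lab)
    return adj


def _outer_shell(geom: Polygon | MultiPolygon) -> Polygon | MultiPolygon:
    """The polygon(s) with holes filled: everything inside the outer ring."""
    if isinstance(geom, MultiPolygon):
        return MultiPolygon([Polygon(p.exterior) for p in geom.geoms])
    return Polygon(geom.exterior)


def area_time_series(records: list[AreaRecord], n_boot: int = 1000,
                     seed: int = 0) -> pd.DataFrame:
    """Tabulate S, count and mean S_i over time with their uncertainties.

    Rows are ordered by time; duplicate timestamps are rejected.  The S
    uncertainty is a bootstrap sd of the resampled sum; count uncertainty
    is the Poisson sqrt(count).
    """
    if not records:
        raise ValueError("no frames")
    records = sorted(records, key=lambda r: r.time)
    times = [r.time for r in records]
    if len(set(times)) != len(times):
        raise ValueError("duplicate timestamps in area records")
    rows = []
    for i, r in enumerate(records):
        rows.append({
            "time_h": r.time,
            "S_px2": r.S_px2,
            "S_mm2": r.S_mm2,
            "S_sd_mm2": r.S_uncertainty_mm2(n_boot=n_boot, seed=seed + i),
            "count_Si": r.count,
            "count_sd": r.count_uncertainty,
            "mean_Si_mm2": r.mean_Si_mm2,
        })
    return pd.DataFrame(rows)


def bootstrap_S_uncertainty(S_i: np.ndarray, n_boot: int = 1000,
                            seed: int = 0) -> float:
    """Bootstrap standard deviation of the total area S = sum(S_i).

    Resamples the individual areas with replacement ``n_boot`` times and
    returns the sd of the resampled sums.  For n areas this converges to
    sqrt(n) times the population sd of the S_i.
    """
    S_i = np.asarray(S_i, dtype=float)
    if S_i.size == 0:
        raise ValueError("S_i is empty")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, S_i.size, size=(n_boot, S_i.size))
    sums = S_i[idx].sum(axis=1)
    return float(sums.std())


def record_to_csv_rows(rec: AreaRecord, frame_index: int) -> pd.DataFrame:
    """Per-area table (frame, time_h, area_px2, area_mm2) for export."""
    return pd.DataFrame({
        "frame": frame_index,
        "time_h": rec.time,
        "area_px2": rec.S_i_px2,
        "area_mm2": rec.S_i_mm2,
    })


def holes_to_geojson(rec: AreaRecord, path) -> None:
    """Export the enclosed areas as GeoJSON for map rendering."""
    from shapely.geometry import mapping
    feats = [{
        "type": "Feature",
        "geometry": mapping(reg.geometry),
        "properties": {"area_px2": reg.pixel_area,
                       "area_mm2": float(reg.pixel_area
                                         * (rec.pixel_size / 1000.0) ** 2)},
    } for reg in rec.regions]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
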