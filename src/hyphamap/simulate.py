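"""Synthetic growing mycelium: ground-truthed networks and rasterized panoramas.

The generator emulates a two-dimensional thallus growing radially from a
germination point: a fixed number of initial hyphae elongate at constant tip
speed with small angular diffusion, branch laterally as a Poisson process per
active tip, and (optionally) fuse with pre-existing hyphae when a tip comes
within an anastomosis radius.  With a per-tip branching rate ``b`` the apex
count follows a Yule (pure-birth) process, so apexes, nodes and total length
all double with characteristic time ``tau = ln 2 / b`` after the lag phase --
the exponential growth-law regime the analysis pipeline is designed to
measure.  Condition presets target the doubling-time ordering observed for
a filamentous fungus grown under abiotic stresses (standard ~ high
temperature < low nutrient ~ osmotic < intense light < low temperature).

Lengths are micrometres, times are hours.  Simulation is event-driven in
continuous space with a fixed internal time step; identical seeds give
bit-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .frames import PanoramaFrame, DEFAULT_PIXEL_SIZE_UM

__all__ = [
    "GrowthParams",
    "GroundTruthNetwork",
    "RasterizationParams",
    "simulate",
    "rasterize",
    "condition_preset",
    "realized_doubling_time",
    "count_crossings",
    "PRESET_NAMES",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the synthetic growth model.

    tip_speed          um/h apex elongation speed
    branch_rate        lateral branching events per hour per active tip
                       (sets the doubling time, tau = ln2 / branch_rate)
    branch_angle_mean  mean absolute branching angle, degrees
    branch_angle_sd    sd of the branching angle, degrees
    heading_sd         angular diffusion of tip headings, degrees per step
    anastomosis_radius um; a tip within this distance of an older hypha
                       fuses and stops (0 disables fusion)
    initial_tips       number of hyphae germinating at the origin
    lag_time           hours of dormancy before growth starts (temporal
                       offset of the exponential phase)
    duration           simulated hours
    frame_interval     hours between recorded frames
    seed               RNG seed
    """

    tip_speed: float = 250.0
    branch_rate: float = LN2 / 2.09
    branch_angle_mean: float = 40.0
    branch_angle_sd: float = 10.0
    heading_sd: float = 3.0
    anastomosis_radius: float = 0.0
    initial_tips: int = 3
    lag_time: float = 0.31
    duration: float = 20.0
    frame_interval: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tip_speed", "branch_rate", "branch_angle_sd", "heading_sd",
                     "anastomosis_radius", "lag_time"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if not np.isfinite(self.branch_angle_mean):
            raise ValueError("branch_angle_mean must be finite")
        if not (np.isfinite(self.duration) and self.duration > 0):
            raise ValueError("duration must be positive")
        if not (np.isfinite(self.frame_interval) and self.frame_interval > 0):
            raise ValueError("frame_interval must be positive")
        if self.initial_tips < 1:
            raise ValueError("initial_tips must be >= 1")


@dataclass
class GroundTruthNetwork:
    """Exact record of a simulated network.

    ``segments`` are the elementary growth steps: rows of
    ``(x0, y0, x1, y1)`` um with ``seg_birth`` the time each segment appeared
    and ``seg_tip`` the index of the tip that laid it.  ``events`` is the
    list of ``(time, kind)`` with kind in {"branch", "anastomosis"}.
    ``per_frame`` tabulates the exact apex count ``A_true``, branch-point
    count ``N_true`` and total length ``L_true`` (um) at each frame time.
    """

    params: GrowthParams
    segments: np.ndarray          # (n, 4) float
    seg_birth: np.ndarray         # (n,) float hours
    seg_tip: np.ndarray           # (n,) int
    tip_birth: np.ndarray         # (m,) float hours
    tip_death: np.ndarray         # (m,) float hours (inf if never fused)
    events: list[tuple[float, str]] = field(default_factory=list)
    frame_times: np.ndarray = field(default_factory=lambda: np.array([]))
    per_frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    def segments_at(self, t: float) -> np.ndarray:
        """Segments already laid down at time ``t`` (rows of x0,y0,x1,y1)."""
        return self.segments[self.seg_birth <= t + 1e-9]

    def radius_at(self, t: float) -> float:
        """Largest distance (um) from the origin reached by time ``t``."""
        seg = self.segments_at(t)
        if len(seg) == 0:
            return 0.0
        pts = seg.reshape(-1, 2)
        return float(np.sqrt((pts ** 2).sum(axis=1)).max())


def simulate(params: GrowthParams) -> GroundTruthNetwork:
    """Grow a network from ``initial_tips`` hyphae at the origin.

    Off-lattice simulation with fixed step ``dt = min(frame_interval, 0.05)``
    h; per step each active tip elongates by ``tip_speed * dt`` along its
    heading (perturbed by ``heading_sd``), then branches with probability
    ``branch_rate * dt``.  Branches inherit the parent position and deviate
    by a signed angle drawn from N(branch_angle_mean, branch_angle_sd).
    """
    p = params
    rng = np.random.default_rng(p.seed)
    dt = min(p.frame_interval, 0.05)
    n_steps = int(math.ceil(p.duration / dt - 1e-9))

    pos = np.zeros((p.initial_tips, 2))
    headings = list(rng.uniform(0.0, 2.0 * math.pi, size=p.initial_tips))
    positions = [pos[i].copy() for i in range(p.initial_tips)]
    active = [True] * p.initial_tips
    tip_birth = [0.0] * p.initial_tips
    tip_death = [math.inf] * p.initial_tips

    seg_rows: list[tuple[float, float, float, float]] = []
    seg_birth: list[float] = []
    seg_tip: list[int] = []
    events: list[tuple[float, str]] = []

    step_len = p.tip_speed * dt
    heading_sd_rad = math.radians(p.heading_sd)
    branch_p = p.branch_rate * dt

    # coarse spatial hash for anastomosis queries
    use_fusion = p.anastomosis_radius > 0
    cell = max(p.anastomosis_radius, step_len, 1e-9)
    grid: dict[tuple[int, int], list[int]] = {}

    def _register(idx: int) -> None:
        x0, y0, x1, y1 = seg_rows[idx]
        key = (int(((x0 + x1) / 2) // cell), int(((y0 + y1) / 2) // cell))
        grid.setdefault(key, []).append(idx)

    def _fuses(pt: np.ndarray, tip: int, now: float) -> bool:
        kx, ky = int(pt[0] // cell), int(pt[1] // cell)
        r = p.anastomosis_radius
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for idx in grid.get((kx + dx, ky + dy), ()):
                    # ignore the trail this tip laid very recently
                    if seg_tip[idx] == tip and seg_birth[idx] > now - 5 * dt:
                        continue
                    if _point_segment_dist(pt, seg_rows[idx]) <= r:
                        return True
        return False

    for step in range(n_steps):
        t1 = (step + 1) * dt
        if t1 <= p.lag_time + 1e-12:
            continue
        n_now = len(positions)
        for i in range(n_now):
            if not active[i]:
                continue
            headings[i] += rng.normal(0.0, heading_sd_rad)
            d = np.array([math.cos(headings[i]), math.sin(headings[i])])
            new_pos = positions[i] + step_len * d
            seg_rows.append((positions[i][0], positions[i][1],
                             new_pos[0], new_pos[1]))
            seg_birth.append(t1)
            seg_tip.append(i)
            if use_fusion:
                _register(len(seg_rows) - 1)
                if _fuses(new_pos, i, t1):
                    active[i] = False
                    tip_death[i] = t1
                    events.append((t1, "anastomosis"))
                    positions[i] = new_pos
                    continue
            positions[i] = new_pos
            if rng.random() < branch_p:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                delta = math.radians(
                    rng.normal(p.branch_angle_mean, p.branch_angle_sd))
                positions.append(new_pos.copy())
                headings.append(headings[i] + sign * delta)
                active.append(True)
                tip_birth.append(t1)
                tip_death.append(math.inf)
                events.append((t1, "branch"))

    segments = np.asarray(seg_rows, dtype=float).reshape(-1, 4)
    sb = np.asarray(seg_birth, dtype=float)
    st = np.asarray(seg_tip, dtype=int)
    tb = np.asarray(tip_birth, dtype=float)
    td = np.asarray(tip_death, dtype=float)

    n_frames = int(math.floor(p.duration / p.frame_interval + 1e-9)) + 1
    frame_times = np.arange(n_frames) * p.frame_interval
    seg_len = np.hypot(segments[:, 2] - segments[:, 0],
                       segments[:, 3] - segments[:, 1]) if len(segments) else np.array([])
    ev_times = np.asarray([t for t, k in events if k == "branch"], dtype=float)
    rows = []
    for t in frame_times:
        alive = (tb <= t + 1e-9) & (td > t + 1e-9)
        mask = sb <= t + 1e-9 if len(segments) else np.array([], dtype=bool)
        rows.append({
            "time_h": t,
            "A_true": int(alive.sum()),
            "N_true": int((ev_times <= t + 1e-9).sum()),
            "L_true": float(seg_len[mask].sum()) if len(segments) else 0.0,
        })
    per_frame = pd.DataFrame(rows)

    return GroundTruthNetwork(
        params=p, segments=segments, seg_birth=sb, seg_tip=st,
        tip_birth=tb, tip_death=td, events=events,
        frame_times=frame_times, per_frame=per_frame,
    )


def _point_segment_dist(pt: np.ndarray, seg: tuple[float, float, float, float]) -> float:
    x0, y0, x1, y1 = seg
    dx, dy = x1 - x0, y1 - y0
    denom = dx * dx + dy * dy
    if denom == 0:
        return math.hypot(pt[0] - x0, pt[1] - y0)
    t = ((pt[0] - x0) * dx + (pt[1] - y0) * dy) / denom
    t = min(1.0, max(0.0, t))
    return math.hypot(pt[0] - (x0 + t * dx), pt[1] - (y0 + t * dy))


def count_crossings(network: GroundTruthNetwork, t: float) -> int:
    """Number of transversal segment-segment crossings present at time ``t``.

    Crossings are emergent overlaps of hyphae in the plane (segments that
    intersect away from shared endpoints).  In the rasterized image they
    appear as extra junctions, which is why the measured node count grows
    faster than the branch-point count.
    """
    from shapely import STRtree
    from shapely.geometry import LineString

    seg = network.segments_at(t)
    if len(seg) < 2:
        return 0
    lines = [LineString([(s[0], s[1]), (s[2], s[3])]) for s in seg]
    tree = STRtree(lines)
    pairs = tree.query(lines, predicate="crosses")
    # query returns directed pairs (i, j); count each unordered pair once
    return int((pairs[0] < pairs[1]).sum())


@dataclass(frozen=True)
class RasterizationParams:
    """How a ground-truth network is drawn into a panorama image.

    pixel_size     um/px (1.63 by default, the imaging rig's calibration)
    hypha_width    stroke width in px (5 px, matching the thinning thickness)
    blur_sigma     Gaussian blur in px (0 disables)
    noise_sd       additive Gaussian noise sd on the unit intensity scale
    image_extent   (rows, cols) of the output image
    polarity       "dark_hyphae" (dark strokes on light background) or
                   "light_hyphae"
    """

    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    hypha_width: float = 5.0
    blur_sigma: float = 0.0
    noise_sd: float = 0.0
    image_extent: tuple[int, int] = (2048, 2048)
    polarity: str = "dark_hyphae"

    def __post_init__(self) -> None:
        if self.hypha_width < 1:
            raise ValueError("hypha_width must be >= 1 px")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.polarity not in ("dark_hyphae", "light_hyphae"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


def rasterize(network: GroundTruthNetwork, frame_time: float,
              rp: RasterizationParams, noise_seed: int = 0) -> PanoramaFrame:
    """Draw the network state at ``frame_time`` as a grayscale panorama.

    Strokes cover every pixel whose center lies within ``hypha_width / 2``
    of a segment.  The germination point maps to the image center.
    """
    if frame_time > network.params.duration + 1e-9:
        raise ValueError("frame_time beyond simulation duration")
    rows, cols = rp.image_extent
    cr, cc = rows // 2, cols // 2

    seg = network.segments_at(frame_time)
    mask = np.zeros((rows, cols), dtype=bool)
    if len(seg):
        # physical (x, y) to pixel (row, col): y down the rows
        px = np.empty_like(seg)
        px[:, 0] = cr + seg[:, 1] / rp.pixel_size   # r0
        px[:, 1] = cc + seg[:, 0] / rp.pixel_size   # c0
        px[:, 2] = cr + seg[:, 3] / rp.pixel_size   # r1
        px[:, 3] = cc + seg[:, 2] / rp.pixel_size   # c1
        half = rp.hypha_width / 2.0
        margin = half + 1
        lo_r = min(px[:, 0].min(), px[:, 2].min()) - margin
        hi_r = max(px[:, 0].max(), px[:, 2].max()) + margin
        lo_c = min(px[:, 1].min(), px[:, 3].min()) - margin
        hi_c = max(px[:, 1].max(), px[:, 3].max()) + margin
        if lo_r < 0 or lo_c < 0 or hi_r > rows - 1 or hi_c > cols - 1:
            need_r = 2 * int(math.ceil(max(hi_r - cr, cr - lo_r))) + 2
            need_c = 2 * int(math.ceil(max(hi_c - cc, cc - lo_c))) + 2
            raise ValueError(
                f"image_extent {rp.image_extent} too small for the network at "
                f"t={frame_time} h; need at least ({need_r}, {need_c})")
        for r0, c0, r1, c1 in px:
            _paint_stroke(mask, r0, c0, r1, c1, half)

    fg, bg = (0.15, 0.85) if rp.polarity == "dark_hyphae" else (0.85, 0.15)
    img = np.full((rows, cols), bg, dtype=float)
    img[mask] = fg
    if rp.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, rp.blur_sigma)
    if rp.noise_sd > 0:
        rng = np.random.default_rng(noise_seed)
        img = img + rng.normal(0.0, rp.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return PanoramaFrame(image=(img * 255).round().astype(np.uint8),
                         time=frame_time, pixel_size=rp.pixel_size,
                         center=(cr, cc))


def _paint_stroke(mask: np.ndarray, r0: float, c0: float, r1: float, c1: float,
                  half_width: float) -> None:
    """Set pixels whose center is within ``half_width`` of the segment."""
    rows, cols = mask.shape
    rlo = max(0, int(math.floor(min(r0, r1) - half_width)))
    rhi = min(rows - 1, int(math.ceil(max(r0, r1) + half_width)))
    clo = max(0, int(math.floor(min(c0, c1) - half_width)))
    chi = min(cols - 1, int(math.ceil(max(c0, c1) + half_width)))
    if rhi < rlo or chi < clo:
        return
    rr, cc = np.meshgrid(np.arange(rlo, rhi + 1), np.arange(clo, chi + 1),
                         indexing="ij")
    dr, dc = r1 - r0, c1 - c0
    denom = dr * dr + dc * dc
    if denom == 0:
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
    else:
        t = ((rr - r0) * dr + (cc - c0) * dc) / denom
        t = np.clip(t, 0.0, 1.0)
        d2 = (rr - (r0 + t * dr)) ** 2 + (cc - (c0 + t * dc)) ** 2
    mask[rlo:rhi + 1, clo:chi + 1] |= d2 <= half_width ** 2


# ---------------------------------------------------------------------------
# condition presets

PRESET_NAMES = ("standard", "low_nutrient", "osmotic", "intense_light",
                "low_temp", "high_temp")

# (target apex doubling time [h], lag [h], tip speed [um/h])
_PRESETS: dict[str, tuple[float, float, float]] = {
    "standard":      (2.09, 0.31, 250.0),
    "low_nutrient":  (2.91, 0.51, 180.0),
    "osmotic":       (3.01, 0.58, 170.0),
    "intense_light": (3.33, 2.67, 60.0),
    "low_temp":      (3.66, 0.39, 100.0),
    "high_temp":     (2.00, 1.76, 200.0),
}


def condition_preset(name: str, **overrides) -> GrowthParams:
    """Growth parameters emulating one of the six culture conditions.

    The branching rate is set to ``ln 2 / tau`` so the realized apex
    doubling time targets the observed per-condition value; lag times follow
    the observed temporal offsets (intense light and high temperature
    delayed).  Tip speeds encode the qualitative envelope sizes (stressed
    thalli smaller; intense light dense and compact).  Keyword overrides are
    forwarded to :class:`GrowthParams`.
    """
    try:
        tau, lag, speed = _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    base = dict(tip_speed=speed, branch_rate=LN2 / tau, lag_time=lag)
    base.update(overrides)
    return GrowthParams(**base)


def realized_doubling_time(times: np.ndarray, counts: np.ndarray,
                           base: float | None = None,
                           window: tuple[float, float] | None = None,
                           weighted: bool = True,
                           include_partial: bool = True) -> float:
    """Doubling time measured from successive-doubling crossing times.

    Finds the times at which ``counts`` first reaches ``base * 2**k`` for
    k = 0, 1, 2, ... (log2-interpolated between samples) and returns the
    least-squares slope of crossing time versus k -- the mean interval
    between successive doublings.  ``window`` restricts the measurement to
    a time interval (e.g. the same window a growth-law fit uses);
    ``base`` defaults to the first in-window count.

    By default each doubling level is weighted by its count, because the
    realized interval between levels c and 2c has relative sd of order
    1/sqrt(c) for a branching process: early, low-count doublings are far
    noisier than late ones.  ``include_partial`` appends the final
    fractional level (t_end, log2(count_end / base)) so the measurement
    uses the full window rather than discarding up to one trailing
    doubling.  Set ``weighted=False, include_partial=False`` for the plain
    equal-weight integer-level variant.
    """
    times = np.asarray(times, dtype=float)
    counts = np.asarray(counts, dtype=float)
    keep = counts > 0
    if window is not None:
        keep &= (times >= window[0] - 1e-12) & (times <= window[1] + 1e-12)
    times, counts = times[keep], counts[keep]
    if len(times) < 2:
        raise ValueError("fewer than two usable samples")
    if base is None:
        base = counts[0]
    log2c = np.log2(counts / base)
    ks: list[float] = []
    crossing: list[float] = []
    k = 0
    while k <= log2c.max():
        idx = int(np.argmax(log2c >= k))
        if log2c[idx] >= k:
            if idx == 0:
                t_cross = times[0]
            else:
                y0, y1 = log2c[idx - 1], log2c[idx]
                t0, t1 = times[idx - 1], times[idx]
                t_cross = t0 + (k - y0) / (y1 - y0) * (t1 - t0) \
                    if y1 > y0 else t1
            ks.append(float(k))
            crossing.append(t_cross)
        k += 1
    if include_partial and log2c[-1] > ks[-1] + 1e-9:
        ks.append(float(log2c[-1]))
        crossing.append(times[-1])
    if len(ks) < 3:
        raise ValueError("series spans fewer than two doublings")
    ka = np.asarray(ks)
    ta = np.asarray(crossing)
    w = base * 2.0 ** ka if weighted else np.ones_like(ka)
    W = w.sum()
    kb = (w * ka).sum() / W
    tb = (w * ta).sum() / W
    slope = (w * (ka - kb) * (ta - tb)).sum() / (w * (ka - kb) ** 2).sum()
    return float(slope)


# ---------------------------------------------------------------------------
# ground-truth export


def save_ground_truth(network: GroundTruthNetwork, out_dir: str | Path) -> None:
    """Write the network as JSON (segments, events) + per-frame truth CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "params": asdict(network.params),
        "segments": network.segments.round(4).tolist(),
        "seg_birth": network.seg_birth.round(6).tolist(),
        "events": [[round(t, 6), k] for t, k in network.events],
    }
    (out / "ground_truth.json").write_text(json.dumps(payload))
    network.per_frame.to_csv(out / "ground_truth_frames.csv", index=False)


def _scaled_preset(name: str, seed: int, duration: float,
                   frame_interval: float, extent: int) -> GrowthParams:
    """Preset with run-length fields replaced (helper for demos/CLI)."""
    p = condition_preset(name, seed=seed)
    return replace(p, duration=duration, frame_interval=frame_interval)
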