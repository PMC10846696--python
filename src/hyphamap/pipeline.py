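"""End-to-end orchestration: simulate/load -> vectorize -> measure -> fit.

A run is described by a :class:`RunConfig` (loadable from YAML), executed
stage by stage with every intermediate artifact written to the output
directory, and summarized in a machine-readable ``manifest.json``.  Reruns
with the same config and seed reproduce all numeric outputs bit-identically.

Stages:

1. ``frames``    -- simulate a synthetic network and rasterize panoramas,
                    or load an existing frame directory with its manifest;
2. ``vectorize`` -- threshold each frame, polygonize, select the thallus;
3. ``areas``     -- intra-thallus enclosed areas per frame, S/count series;
4. ``skeleton``  -- thin, build the hyphal graph, A/N/L series;
5. ``density``   -- line-density map, distribution and Jenks classes for
                    the final frame;
6. ``fits``      -- doubling-law fits of A, N, L; linear fit of S;
                    exponential fit of the enclosed-area count.

A note on thresholding a time series: the automatic (Otsu) threshold is
computed once, on the frame designated by ``threshold_frame`` (the last
frame by default), and applied to every frame.  Early frames contain
almost no foreground, and a per-frame automatic threshold would split the
background noise distribution instead of separating hyphae from
background; since illumination is common to the whole series, a single
threshold from the most-contrasted frame is both robust and physically
sensible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .frames import PanoramaFrame, load_frames, save_frames
from .simulate import (GrowthParams, RasterizationParams, condition_preset,
                       rasterize, realized_doubling_time, save_ground_truth,
                       simulate)
from .vectorize import (NoThallusAtCenterError, binarize, polygonize,
                        regions_to_geojson, select_thallus)
from .areas import (area_time_series, extract_intra_areas, holes_to_geojson,
                    record_to_csv_rows)
from .skeleton import adjacency_segments, measure_series, skeleton_to_graph, thin
from .density import (density_distribution, jenks_classify, line_density,
                      render_density_png, save_density_map)
from .fits import (FitError, fit_doubling, fit_exponential_counts,
                   fit_linear_area)

__all__ = ["RunConfig", "run_pipeline", "report", "PipelineError"]

log = logging.getLogger("hyphamap")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Measurement defaults follow the reference acquisition and processing
    parameters: pixel size 1.63 um/px, thinning thickness limit 5 px,
    density cells 50 px with a 200 px search radius, distribution bin
    0.0024, 5 natural-breaks classes, count fit window 5..336.

    Simulation defaults are the validated demonstration configuration: a
    12 h standard-condition series at 0.8 h intervals on a 2048^2 px
    canvas, with the tip speed slowed to 110 um/h so the thallus fits the
    canvas for the whole series (tip speed does not influence doubling
    times -- branching is a pure birth process on tips) and a 2 px stroke
    width matching real hyphal diameters at this pixel size (wider
    strokes merge neighboring parallel tips and undercount apexes; see
    the package documentation).
    """

    # input: either a simulation preset or a directory of frames
    source: str = "simulate"            # "simulate" | "images"
    preset: str = "standard"
    seed: int = 7
    duration_h: float = 12.0
    frame_interval_h: float = 0.8
    tip_speed_um_h: float | None = 110.0   # None -> the preset's own speed
    extent_px: tuple[int, int] = (2048, 2048)
    hypha_width_px: float = 2.0
    blur_sigma_px: float = 0.5
    noise_sd: float = 0.03
    frames_dir: str | None = None       # when source == "images"

    # vectorization
    threshold: float | None = None      # None -> Otsu on threshold_frame
    threshold_frame: str = "last"       # "last" | "per_frame" | frame index
    polarity: str = "dark_hyphae"
    min_speckle_px: int = 25

    # skeleton / density
    max_thickness_px: float = 5.0
    cell_size_px: float = 50.0
    search_radius_px: float = 200.0
    bin_size: float = 0.0024
    n_classes: int = 5

    # areas / fits
    n_boot: int = 1000
    boot_seed: int = 0
    t0_h: float | None = None           # None -> -lag_time (simulated) or 0
    fit_window_h: tuple[float, float | None] = (1.0, None)
    linear_window_h: tuple[float, float] | None = None
    count_window: tuple[float, float] = (5.0, 336.0)

    out_dir: str = "hyphamap_run"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def validate(self) -> None:
        if self.source not in ("simulate", "images"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.source == "images":
            if not self.frames_dir:
                raise ValueError("source 'images' requires frames_dir")
            if not Path(self.frames_dir).is_dir():
                raise ValueError(f"frames_dir {self.frames_dir!r} "
                                 "does not exist")
        for name in ("duration_h", "frame_interval_h", "cell_size_px",
                     "search_radius_px", "bin_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; return (and write) the run manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    cfg.to_yaml(out / "config.yaml")
    manifest: dict = {"version": __version__, "config": str(out / "config.yaml"),
                      "stages": {}}
    try:
        try:
            frames, truth = _stage_frames(cfg, out, manifest)
        except Exception as exc:
            raise PipelineError(f"stage 'frames' failed: {exc}") from exc
        try:
            masks, thalli, region_sets = _stage_vectorize(cfg, out, manifest,
                                                          frames)
        except Exception as exc:
            raise PipelineError(f"stage 'vectorize' failed: {exc}") from exc
        try:
            area_df = _stage_areas(cfg, out, manifest, frames, region_sets,
                                   thalli)
        except Exception as exc:
            raise PipelineError(f"stage 'areas' failed: {exc}") from exc
        try:
            graph_df, last_sk = _stage_skeleton(cfg, out, manifest, frames,
                                                masks)
        except Exception as exc:
            raise PipelineError(f"stage 'skeleton' failed: {exc}") from exc
        try:
            _stage_density(cfg, out, manifest, last_sk)
        except Exception as exc:
            raise PipelineError(f"stage 'density' failed: {exc}") from exc
        try:
            _stage_fits(cfg, out, manifest, graph_df, area_df, truth)
        except Exception as exc:
            raise PipelineError(f"stage 'fits' failed: {exc}") from exc
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        log.removeHandler(fh)
        fh.close()
    return manifest


# ---------------------------------------------------------------------------
# stages


def _artifacts(manifest: dict, stage: str, started: float,
               **paths) -> None:
    manifest["stages"][stage] = {
        "artifacts": {k: str(v) for k, v in paths.items()},
        "seconds": round(time.time() - started, 3),
    }


def _stage_frames(cfg: RunConfig, out: Path, manifest: dict):
    started = time.time()
    if cfg.source == "images":
        frames = load_frames(cfg.frames_dir)
        _artifacts(manifest, "frames", started, frames_dir=cfg.frames_dir)
        return frames, None
    overrides = {"seed": cfg.seed, "duration": cfg.duration_h,
                 "frame_interval": cfg.frame_interval_h}
    if cfg.tip_speed_um_h is not None:
        overrides["tip_speed"] = cfg.tip_speed_um_h
    params = condition_preset(cfg.preset, **overrides)
    log.info("simulating preset %s seed %d", cfg.preset, cfg.seed)
    net = simulate(params)
    rp = RasterizationParams(hypha_width=cfg.hypha_width_px,
                             blur_sigma=cfg.blur_sigma_px,
                             noise_sd=cfg.noise_sd,
                             image_extent=tuple(cfg.extent_px),
                             polarity=cfg.polarity)
    frames = [rasterize(net, t, rp, noise_seed=cfg.seed * 100003 + i)
              for i, t in enumerate(net.frame_times)]
    frames_dir = out / "frames"
    save_frames(frames, frames_dir)
    truth_dir = out / "ground_truth"
    save_ground_truth(net, truth_dir)
    _artifacts(manifest, "frames", started, frames_dir=frames_dir,
               ground_truth=truth_dir)
    truth = {"network": net, "params": params}
    return frames, truth


def _resolve_threshold(cfg: RunConfig, frames: list[PanoramaFrame]):
    if cfg.threshold is not None:
        return float(cfg.threshold)
    if cfg.threshold_frame == "per_frame":
        return None                      # binarize falls back to Otsu per frame
    from skimage.filters import threshold_otsu
    if cfg.threshold_frame == "last":
        ref = frames[-1]
    else:
        ref = frames[int(cfg.threshold_frame)]
    return float(threshold_otsu(np.asarray(ref.image)))


def _stage_vectorize(cfg: RunConfig, out: Path, manifest: dict,
                     frames: list[PanoramaFrame]):
    started = time.time()
    thr = _resolve_threshold(cfg, frames)
    log.info("threshold: %s", "per-frame Otsu" if thr is None else f"{thr:.1f}")
    vdir = out / "vectorize"
    vdir.mkdir(exist_ok=True)
    masks, thalli, region_sets = [], [], []
    rows = []
    from PIL import Image
    for i, fr in enumerate(frames):
        mask = binarize(fr, threshold=thr, polarity=cfg.polarity,
                        min_speckle_px=cfg.min_speckle_px)
        Image.fromarray((mask * np.uint8(255))).save(vdir / f"mask_{i:03d}.png")
        rs = polygonize(mask)
        try:
            th = select_thallus(rs, fr.center)
        except NoThallusAtCenterError:
            log.warning("frame %d (t=%.2f h): no thallus at center; "
                        "recorded as empty", i, fr.time)
            th = None
        masks.append(mask)
        region_sets.append(rs)
        thalli.append(th)
        rows.append({"frame": i, "time_h": fr.time,
                     "n_foreground": len(rs.foreground()),
                     "n_background": len(rs.background()),
                     "thallus_px2": th.pixel_area if th else 0})
    summary = vdir / "regions_summary.csv"
    pd.DataFrame(rows).to_csv(summary, index=False)
    last_geojson = vdir / "regions_last.geojson"
    regions_to_geojson(region_sets[-1], last_geojson)
    _artifacts(manifest, "vectorize", started, masks_dir=vdir,
               summary=summary, regions_last=last_geojson)
    manifest["stages"]["vectorize"]["threshold"] = thr
    return masks, thalli, region_sets


def _stage_areas(cfg: RunConfig, out: Path, manifest: dict, frames,
                 region_sets, thalli) -> pd.DataFrame:
    started = time.time()
    adir = out / "areas"
    adir.mkdir(exist_ok=True)
    records, tables = [], []
    for i, (fr, rs, th) in enumerate(zip(frames, region_sets, thalli)):
        if th is None:
            from .areas import AreaRecord
            rec = AreaRecord(time=fr.time, S_i_px2=np.empty(0, dtype=np.int64),
                             pixel_size=fr.pixel_size)
        else:
            rec = extract_intra_areas(rs, th, time=fr.time,
                                      pixel_size=fr.pixel_size)
        records.append(rec)
        tables.append(record_to_csv_rows(rec, i))
    per_area = adir / "areas_per_frame.csv"
    pd.concat(tables, ignore_index=True).to_csv(per_area, index=False)
    df = area_time_series(records, n_boot=cfg.n_boot, seed=cfg.boot_seed)
    series = adir / "area_series.csv"
    df.to_csv(series, index=False)
    holes = adir / "holes_last.geojson"
    holes_to_geojson(records[-1], holes)
    _artifacts(manifest, "areas", started, per_area=per_area, series=series,
               holes_last=holes)
    return df


def _stage_skeleton(cfg: RunConfig, out: Path, manifest: dict, frames, masks):
    started = time.time()
    sdir = out / "skeleton"
    sdir.mkdir(exist_ok=True)
    from PIL import Image
    graphs, sks = [], []
    for i, (fr, mask) in enumerate(zip(frames, masks)):
        sk = thin(mask, max_thickness=cfg.max_thickness_px)
        Image.fromarray((sk.mask * np.uint8(255))).save(
            sdir / f"skeleton_{i:03d}.png")
        g = skeleton_to_graph(sk, pixel_size=fr.pixel_size)
        graphs.append(g)
        sks.append(sk)
        log.info("frame %d (t=%.2f h): A=%d N=%d L=%.0f um",
                 i, fr.time, g.A, g.N, g.L_um)
    df = measure_series(graphs, [fr.time for fr in frames])
    series = sdir / "graph_series.csv"
    df.to_csv(series, index=False)
    verts = sdir / "vertices_last.csv"
    graphs[-1].vertices.to_csv(verts, index=False)
    _artifacts(manifest, "skeleton", started, series=series,
               vertices_last=verts, skeletons_dir=sdir)
    return df, sks[-1]


def _stage_density(cfg: RunConfig, out: Path, manifest: dict, last_sk):
    started = time.time()
    ddir = out / "density"
    ddir.mkdir(exist_ok=True)
    segs = adjacency_segments(last_sk)
    dmap = line_density(segs, last_sk.mask.shape,
                        cell_size=cfg.cell_size_px,
                        search_radius=cfg.search_radius_px)
    tiff, meta = ddir / "density_last.tiff", ddir / "density_last.json"
    save_density_map(dmap, tiff, meta)
    dist = density_distribution(dmap, bin_size=cfg.bin_size)
    dist_csv = ddir / "distribution_last.csv"
    dist.rename(columns={"bin_left": "bin_low", "bin_right": "bin_high",
                         "frequency": "pdf"}).to_csv(dist_csv, index=False)
    jc = jenks_classify(dmap.values, n_classes=cfg.n_classes)
    breaks_json = ddir / "breaks_last.json"
    breaks_json.write_text(json.dumps(
        {"breaks": jc.breaks.tolist(), "n_classes": jc.n_classes,
         "gvf": jc.gvf}, indent=2))
    png = ddir / "density_last.png"
    render_density_png(dmap, png, n_classes=cfg.n_classes)
    _artifacts(manifest, "density", started, raster=tiff, raster_meta=meta,
               distribution=dist_csv, breaks=breaks_json, map_png=png)
    manifest["stages"]["density"].update(
        envelope_cells=dist.attrs.get("envelope_cells", 0),
        max_density=dist.attrs.get("max_density", 0.0))


def _stage_fits(cfg: RunConfig, out: Path, manifest: dict,
                graph_df: pd.DataFrame, area_df: pd.DataFrame, truth):
    started = time.time()
    fdir = out / "fits"
    fdir.mkdir(exist_ok=True)
    if cfg.t0_h is not None:
        t0 = cfg.t0_h
    elif truth is not None:
        t0 = -truth["params"].lag_time
    else:
        t0 = 0.0
    t = graph_df["time_h"].to_numpy()
    lo = cfg.fit_window_h[0]
    hi = cfg.fit_window_h[1] if cfg.fit_window_h[1] is not None \
        else float(t.max())
    results: dict = {"t0_h": t0, "window_h": [lo, hi]}
    for name, col, sig in (("A", "A", "sigma_A"), ("N", "N", "sigma_N"),
                           ("L", "L_um", "sigma_L_um")):
        x = graph_df[col].to_numpy(dtype=float)
        s = graph_df[sig].to_numpy(dtype=float)
        ok = (x > 0) & (s > 0)
        try:
            f = fit_doubling(t[ok], x[ok], s[ok], t0=t0, window=(lo, hi))
            results[f"doubling_{name}"] = {
                "X0": f.X0, "X0_sd": f.X0_sd, "tau_h": f.tau,
                "tau_sd_h": f.tau_sd, "chi2_reduced": f.chi2_reduced,
                "n_points": f.n_points}
        except FitError as exc:
            log.warning("doubling fit of %s failed: %s", name, exc)
            results[f"doubling_{name}"] = {"error": str(exc)}

    ta = area_df["time_h"].to_numpy()
    S = area_df["S_mm2"].to_numpy()
    if cfg.linear_window_h is not None:
        lw = tuple(cfg.linear_window_h)
    else:
        nz = ta[S > 0]
        lw = (float(nz[0]), float(ta.max())) if len(nz) >= 2 else None
    if lw is None:
        results["linear_S"] = {"error": "fewer than 2 frames with S > 0"}
    else:
        try:
            lf = fit_linear_area(ta, S, lw[0], lw[1])
            results["linear_S"] = {
                "slope_mm2_h": lf.slope, "slope_sd_mm2_h": lf.slope_sd,
                "intercept_mm2": lf.intercept, "r_squared": lf.r_squared,
                "t_min_h": lf.t_min, "t_max_h": lf.t_max,
                "n_points": lf.n_points}
        except FitError as exc:
            log.warning("linear fit of S failed: %s", exc)
            results["linear_S"] = {"error": str(exc)}

    counts = area_df["count_Si"].to_numpy(dtype=float)
    try:
        ef = fit_exponential_counts(ta, counts,
                                    count_window=tuple(cfg.count_window))
        results["exp_count"] = {
            "alpha_per_h": ef.alpha, "alpha_sd_per_h": ef.alpha_sd,
            "beta": ef.beta, "r_squared": ef.r_squared,
            "count_window": list(ef.count_window), "n_points": ef.n_points}
    except FitError as exc:
        log.warning("exponential count fit failed: %s", exc)
        results["exp_count"] = {"error": str(exc)}

    if truth is not None:
        results["truth"] = _truth_summary(truth, (lo, hi))

    fits_json = fdir / "fits.json"
    fits_json.write_text(json.dumps(results, indent=2))
    summary = fdir / "summary.csv"
    _summary_csv(results).to_csv(summary, index=False)
    _artifacts(manifest, "fits", started, fits=fits_json, summary=summary)
    manifest["stages"]["fits"]["results"] = results


def _truth_summary(truth, window) -> dict:
    """Realized ground-truth doubling time over the fit window."""
    net = truth["network"]
    params = truth["params"]
    ev = np.sort([tt for tt, kind in net.events if kind == "branch"])
    an = np.sort([tt for tt, kind in net.events if kind == "anastomosis"])
    tg = np.linspace(0.0, params.duration, 8000)
    A = (params.initial_tips + np.searchsorted(ev, tg)
         - np.searchsorted(an, tg))
    target = math.log(2.0) / params.branch_rate \
        if params.branch_rate > 0 else float("inf")
    out = {"target_tau_A_h": target,
           "n_branch_events": int(len(ev))}
    try:
        out["realized_tau_A_h"] = realized_doubling_time(tg, A, window=window)
    except ValueError as exc:
        out["realized_tau_A_h"] = None
        out["realized_error"] = str(exc)
    return out


def _summary_csv(results: dict) -> pd.DataFrame:
    rows = []
    for name in ("A", "N", "L"):
        r = results.get(f"doubling_{name}", {})
        rows.append({"quantity": f"tau_{name}", "value": r.get("tau_h"),
                     "sd": r.get("tau_sd_h"),
                     "gof": r.get("chi2_reduced"), "gof_kind": "chi2_reduced"})
    lr = results.get("linear_S", {})
    rows.append({"quantity": "a_S", "value": lr.get("slope_mm2_h"),
                 "sd": lr.get("slope_sd_mm2_h"),
                 "gof": lr.get("r_squared"), "gof_kind": "r_squared"})
    er = results.get("exp_count", {})
    rows.append({"quantity": "alpha_count", "value": er.get("alpha_per_h"),
                 "sd": er.get("alpha_sd_per_h"),
                 "gof": er.get("r_squared"), "gof_kind": "r_squared"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report


def report(manifest_path: str | Path) -> str:
    """Human-readable summary of a completed (or partial) run."""
    manifest = json.loads(Path(manifest_path).read_text())
    lines = [f"hyphamap run report (version {manifest.get('version', '?')})",
             ""]
    stages = manifest.get("stages", {})
    fits = stages.get("fits", {}).get("results")
    if fits:
        lines.append("Growth-law fits")
        lines.append(f"  t0 = {fits['t0_h']:+.2f} h, "
                     f"window {fits['window_h']} h")
        for name in ("A", "N", "L"):
            r = fits.get(f"doubling_{name}", {})
            if "tau_h" in r:
                lines.append(f"  tau_{name} = {r['tau_h']:.2f} "
                             f"+/- {r['tau_sd_h']:.2f} h   "
                             f"(chi2_red {r['chi2_reduced']:.2f}, "
                             f"n={r['n_points']})")
            else:
                lines.append(f"  tau_{name}: MISSING "
                             f"({r.get('error', 'not computed')})")
        r = fits.get("linear_S", {})
        if "slope_mm2_h" in r:
            sd = r["slope_sd_mm2_h"]
            sd_txt = f"{sd:.3f}" if sd == sd else "undefined (2 points)"
            lines.append(f"  S slope a = {r['slope_mm2_h']:.3f} "
                         f"+/- {sd_txt} mm^2/h   (R^2 {r['r_squared']:.3f})")
        else:
            lines.append(f"  S slope: MISSING ({r.get('error', '?')})")
        r = fits.get("exp_count", {})
        if "alpha_per_h" in r:
            lines.append(f"  count alpha = {r['alpha_per_h']:.3f} "
                         f"+/- {r['alpha_sd_per_h']:.3f} /h   "
                         f"(R^2 {r['r_squared']:.3f})")
        else:
            lines.append(f"  count alpha: MISSING ({r.get('error', '?')})")
        tr = fits.get("truth")
        if tr:
            lines.append(f"  ground truth: realized tau_A = "
                         f"{_fmt(tr.get('realized_tau_A_h'))} h "
                         f"(target {tr['target_tau_A_h']:.2f} h, "
                         f"{tr['n_branch_events']} branch events)")
    else:
        lines.append("Growth-law fits: MISSING")
    lines.append("")
    dens = stages.get("density")
    if dens:
        lines.append(f"Density (final frame): {dens.get('envelope_cells', 0)} "
                     f"envelope cells, max density "
                     f"{dens.get('max_density', 0.0):.4f}")
    else:
        lines.append("Density distribution: MISSING")
    lines.append("")
    lines.append("Artifacts")
    for stage, info in stages.items():
        for kind, path in info.get("artifacts", {}).items():
            lines.append(f"  {stage}/{kind}: {path}")
    return "\n".join(lines)


def _fmt(x) -> str:
    return f"{x:.2f}" if isinstance(x, (int, float)) else "n/a"
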