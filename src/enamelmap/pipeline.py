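"""End-to-end experiment drivers.

``run_static`` reproduces the static carious-sample workflow: phantom ->
projections -> reconstruction -> calibration -> WAXS map -> scalar maps
-> registration/overlay -> gauge volumes -> report. ``run_dynamic`` runs
the interlaced in-situ demineralization schedule against the evolving
phantom and emits time-lapse curves, per-time maps and the cross-modal
correlation. Every run writes a manifest (config, seeds, output hashes)
sufficient to reproduce it byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import correlate as corr
from . import io as emio
from . import recon, simulate, waxs
from .config import PipelineConfig
from .geometry import Image2D, ScalarMap
from .phantom import Phantom, build_enamel_phantom, evolve_demineralization

log = logging.getLogger("enamelmap")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def _sub_seed(seed: int, *tags: int) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence([int(seed) % (2**31), *[int(t) % (2**31) for t in tags]])
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, cfg: PipelineConfig, kind: str, t0: float) -> Path:
    outputs = sorted(p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "experiment": kind,
        "config": json.loads(json.dumps(cfg.to_dict())),
        "seed": cfg.seed,
        "elapsed_s": round(time.time() - t0, 3),
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def _build_phantom(cfg: PipelineConfig, immersed: bool) -> Phantom:
    return build_enamel_phantom(
        size=cfg.phantom_size(),
        voxel_size=cfg.pixel_size,
        rod_pitch=cfg.rod_pitch,
        window=cfg.window,
        seed=_sub_seed(cfg.seed, 1),
        rod_density=cfg.rod_density,
        inter_rod_density=cfg.inter_rod_density,
        mu_mineral=cfg.mu_mineral,
        immersed=immersed,
    )


def _acquire_waxs_grid(
    cfg: PipelineConfig, phantom: Phantom, timestamp: float, tag: int
) -> Dict[Tuple[int, int], Image2D]:
    grid = cfg.raster_grid()
    geometry = cfg.detector_geometry()
    reflections = cfg.reflections()
    patterns = {}
    for iy in range(grid.counts[1]):
        for ix in range(grid.counts[0]):
            patterns[(iy, ix)] = simulate.simulate_waxs_pattern(
                phantom, grid, (ix, iy), geometry, cfg.waxs_shape, reflections,
                texture=cfg.texture(), background=cfg.background(), gaps=cfg.gaps(),
                ring_gain=cfg.ring_gain, sigma_r=cfg.ring_sigma_px,
                dark_level=cfg.waxs_dark_level,
                noise_seed=_sub_seed(cfg.seed, 7, tag, iy * grid.counts[0] + ix)
                if cfg.noise else None,
                timestamp=timestamp,
            )
    return patterns


def _acquire_projection(
    cfg: PipelineConfig, phantom: Phantom, angle: float, timestamp: float, tag: int
) -> Image2D:
    imaging = cfg.imaging_geometry()
    beam = simulate.vignette_profile(imaging, cfg.i0, cfg.vignette_strength)
    return simulate.simulate_radiograph(
        phantom, angle, imaging, i0=cfg.i0,
        noise_seed=_sub_seed(cfg.seed, 3, tag) if cfg.noise else None,
        flat_field=beam, dark_level=cfg.dark_level, timestamp=timestamp,
    )


def _calibrated_geometry(cfg: PipelineConfig) -> waxs.CalibrationResult:
    """Calibrant simulation + ring fit at the instrument-scale geometry."""
    truth = cfg.calibration_geometry()
    pattern = simulate.simulate_calibrant_pattern(
        truth, cfg.calibrant(), seed=_sub_seed(cfg.seed, 5),
        detector_shape=cfg.calib_shape, amplitude=cfg.calib_amplitude,
    )
    start = truth.replace(
        distance=truth.distance + 2.0,
        beam_center=(truth.beam_center[0] + 5.0, truth.beam_center[1] - 5.0),
    )
    return waxs.calibrate_geometry(pattern, list(cfg.calibrant().d_spacings), start)


def _analysis_maps(cfg: PipelineConfig, patterns) -> Dict[str, ScalarMap]:
    mask = waxs.build_detector_mask(cfg.waxs_shape, cfg.gaps())
    maps = waxs.build_maps(
        patterns, cfg.raster_grid(), cfg.detector_geometry(), mask,
        q002_window=cfg.q002_window, phi_range=cfg.phi_range, n_bins=cfg.n_q_bins,
    )
    return {m.quantity: m for m in maps}


def run_static_experiment(cfg: PipelineConfig, outdir) -> dict:
    """Static carious-sample analysis; returns a result bundle."""
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    try:
        phantom = _build_phantom(cfg, immersed=False)
        if cfg.static_lesion_time > 0:
            phantom = evolve_demineralization(phantom, cfg.static_lesion_time,
                                              cfg.demin_params())
        bundle["phantom"] = phantom
    except Exception as exc:
        raise StageError("phantom", exc)

    try:
        imaging = cfg.imaging_geometry()
        flats, darks = simulate.simulate_flats_darks(
            imaging, n=cfg.n_flats, i0=cfg.i0, dark_level=cfg.dark_level,
            seed=_sub_seed(cfg.seed, 2), vignette_strength=cfg.vignette_strength,
            noise=cfg.noise,
        )
        raw = [
            _acquire_projection(cfg, phantom, a, timestamp=float(i), tag=i)
            for i, a in enumerate(imaging.angle_list)
        ]
        corrected = recon.correct_projections(raw, flats, darks)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("projections", exc)

    try:
        volume = recon.reconstruct_fbp(corrected, imaging.angle_list)
        emio.write_volume(outdir / "volume.tif", volume)
        bundle["volume"] = volume
    except Exception as exc:
        raise StageError("reconstruction", exc)

    try:
        calib = _calibrated_geometry(cfg)
        bundle["calibration"] = calib
        (outdir / "calibration.json").write_text(json.dumps({
            "distance_cm": calib.geometry.distance,
            "beam_center_px": list(calib.geometry.beam_center),
            "residual_rms_px": calib.residual_rms_px,
            "n_rings": calib.n_rings,
        }, indent=2))
    except Exception as exc:
        raise StageError("calibration", exc)

    try:
        patterns = _acquire_waxs_grid(cfg, phantom, timestamp=0.0, tag=0)
        maps = _analysis_maps(cfg, patterns)
        bundle["maps"] = maps
        for name, m in maps.items():
            emio.write_map(outdir / f"map_{name}.csv", m)
        # one sample diffractogram for the report
        mask = waxs.build_detector_mask(cfg.waxs_shape, cfg.gaps())
        mid = (cfg.grid_counts[0] // 2, cfg.grid_counts[1] // 2)
        dg = waxs.azimuthal_integrate(
            patterns[(mid[1], mid[0])], cfg.detector_geometry(), mask, cfg.n_q_bins
        )
        emio.write_diffractogram(outdir / "diffractogram_center.csv", dg)
    except Exception as exc:
        raise StageError("waxs_map", exc)

    try:
        tf = corr.GridTransform.from_metadata(cfg.raster_grid(), imaging)
        projection0 = corrected[0]
        overlay = corr.overlay_map_on_projection(maps["total_intensity"], projection0,
                                                 tf, alpha=0.5)
        _save_png(outdir / "overlay_total_intensity.png", overlay.values)
        tot = maps["total_intensity"].values
        overlap = corr.silhouette_overlap(
            maps["total_intensity"], projection0, tf,
            map_threshold=0.5 * (tot.min() + tot.max()),
            projection_threshold=_silhouette_threshold(projection0.values),
        )
        bundle["transform"] = tf
        bundle["silhouette_overlap"] = overlap
    except Exception as exc:
        raise StageError("registration", exc)

    try:
        grid = cfg.raster_grid()
        points = _lesion_and_sound_points(cfg)
        stats_rows = []
        for name, pt in points.items():
            gmask, sub = corr.extract_gauge_volume(volume, grid, pt, cross_section="beam")
            if sub.size:
                st = corr.gauge_statistics(sub)
                stats_rows.append({"region": name, "ix": pt[0], "iy": pt[1],
                                   "mean": st.mean, "sd": st.sd, "n_voxels": st.n_voxels})
                bundle.setdefault("gauge", {})[name] = st
        emio.write_curves(outdir / "gauge_statistics.csv", pd.DataFrame(stats_rows))
    except Exception as exc:
        raise StageError("gauge", exc)

    bundle["manifest"] = _write_manifest(outdir, cfg, "static", t0)
    return bundle


def _silhouette_threshold(values: np.ndarray) -> float:
    """Transmission threshold separating sample from bright background."""
    lo, hi = np.percentile(values, [1, 99])
    return float(0.5 * (lo + hi))


def _lesion_and_sound_points(cfg: PipelineConfig) -> Dict[str, Tuple[int, int]]:
    """Raster points probing the lesion window and sound enamel."""
    grid = cfg.raster_grid()
    (wx0, wx1), (wy0, wy1), _ = cfg.window
    lesion = sound = None
    best_l = best_s = np.inf
    ext_x = cfg.n_u * cfg.pixel_size
    slab_x = (0.20 * ext_x, 0.80 * ext_x)
    for iy in range(grid.counts[1]):
        for ix in range(grid.counts[0]):
            x, y = grid.point_xy(ix, iy)
            if not slab_x[0] < x < slab_x[1]:
                continue
            if wx0 <= x <= wx1 and wy0 <= y <= wy1:
                # lesion points sit right at the exposed face
                d = abs(x - 0.5 * (wx0 + wx1)) + abs(y - 0.5 * (wy0 + wy1))
                if d < best_l:
                    lesion, best_l = (ix, iy), d
            elif slab_x[0] + 5 < x < slab_x[1] - 5 and not (wy0 <= y <= wy1):
                d = abs(x - 0.5 * sum(slab_x))
                if d < best_s:
                    sound, best_s = (ix, iy), d
    out = {}
    if lesion:
        out["lesion"] = lesion
    if sound:
        out["sound"] = sound
    return out


def run_dynamic_experiment(cfg: PipelineConfig, outdir) -> dict:
    """In-situ demineralization: interlaced schedule, curves, correlation."""
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    try:
        schedule = simulate.plan_interlaced_acquisition(
            cfg.total_s, cfg.tomo_duration_s, cfg.map_duration_s(), cfg.n_tomo
        )
        bundle["schedule"] = schedule
    except Exception as exc:
        raise StageError("schedule", exc)

    try:
        phantom0 = _build_phantom(cfg, immersed=True)
        params = cfg.demin_params()
    except Exception as exc:
        raise StageError("phantom", exc)

    try:
        frames: List[Image2D] = []
        map_series: List[Tuple[float, Dict[str, ScalarMap]]] = []
        raw_series: List[Tuple[float, dict]] = []
        for event in schedule.events:
            ph = evolve_demineralization(phantom0, event.t_mid, params)
            if event.kind == "tomography":
                frames.append(_acquire_projection(
                    cfg, ph, cfg.dynamic_projection_angle, timestamp=event.t_mid,
                    tag=1000 + event.index,
                ))
            else:
                patterns = _acquire_waxs_grid(cfg, ph, timestamp=event.t_mid,
                                              tag=2000 + event.index)
                raw_series.append((event.t_mid, patterns))
        imaging = cfg.imaging_geometry()
        flats, darks = simulate.simulate_flats_darks(
            imaging, n=cfg.n_flats, i0=cfg.i0, dark_level=cfg.dark_level,
            seed=_sub_seed(cfg.seed, 2), vignette_strength=cfg.vignette_strength,
            noise=cfg.noise,
        )
        corrected = recon.correct_projections(frames, flats, darks)
        for c, f in zip(corrected, frames):
            c.timestamp = f.timestamp
    except StageError:
        raise
    except Exception as exc:
        raise StageError("acquisition", exc)

    try:
        for t, patterns in raw_series:
            map_series.append((t, _analysis_maps(cfg, patterns)))
        for i, (t, maps) in enumerate(map_series):
            emio.write_map(outdir / f"map_amp002_t{i:03d}.csv", maps["peak002_intensity"])
    except Exception as exc:
        raise StageError("waxs_map", exc)

    try:
        roi = (cfg.window[0], cfg.window[1])
        curves = corr.track_timeseries(schedule, corrected, map_series, roi)
        emio.write_curves(outdir / "curve_imaging.csv", curves["imaging"])
        emio.write_curves(outdir / "curve_diffraction.csv", curves["diffraction"])
        bundle["curves"] = curves
    except Exception as exc:
        raise StageError("timeseries", exc)

    try:
        delta = _per_point_deltas(cfg, corrected, map_series)
        emio.write_curves(outdir / "per_point_deltas.csv", delta)
        result = corr.cross_modal_correlation(
            delta["delta_attenuation"].to_numpy(),
            delta["delta_amp002"].to_numpy(),
            valid=delta["valid"].to_numpy(),
        )
        bundle["correlation"] = result
        result.table.to_csv(outdir / "correlation_table.csv", index=False)
        (outdir / "correlation.json").write_text(json.dumps(
            {"pearson_r": result.coefficient, "n_points": result.n}, indent=2))
    except ValueError as exc:
        # degenerate input (e.g. zero demineralization rates) is reported, not fatal
        bundle["correlation"] = None
        bundle["correlation_note"] = str(exc)
        (outdir / "correlation.json").write_text(json.dumps({"degenerate": str(exc)}, indent=2))
    except Exception as exc:
        raise StageError("correlation", exc)

    bundle["maps"] = map_series
    bundle["projections"] = corrected
    bundle["manifest"] = _write_manifest(outdir, cfg, "dynamic", t0)
    return bundle


def point_attenuation(projection: Image2D, cfg: PipelineConfig, ix: int, iy: int) -> float:
    """Mean -log transmission over the beam footprint of a raster point."""
    grid = cfg.raster_grid()
    x, y = grid.point_xy(ix, iy)
    px = projection.pixel_size
    hw, hh = grid.beam_size[0] / 2, grid.beam_size[1] / 2
    u0, u1 = int(np.floor((x - hw) / px)), int(np.ceil((x + hw) / px))
    v0, v1 = int(np.floor((y - hh) / px)), int(np.ceil((y + hh) / px))
    patch = projection.values[max(v0, 0): v1, max(u0, 0): u1]
    if patch.size == 0:
        return np.nan
    return float(np.mean(-np.log(np.clip(patch, 1e-9, None))))


def _per_point_deltas(cfg, corrected, map_series) -> pd.DataFrame:
    first_p, last_p = corrected[0], corrected[-1]
    first_m, last_m = map_series[0][1], map_series[-1][1]
    grid = cfg.raster_grid()
    rows = []
    for iy in range(grid.counts[1]):
        for ix in range(grid.counts[0]):
            da = point_attenuation(last_p, cfg, ix, iy) - point_attenuation(first_p, cfg, ix, iy)
            damp = (last_m["peak002_intensity"].values[iy, ix]
                    - first_m["peak002_intensity"].values[iy, ix])
            ok = bool(first_m["peak002_intensity"].valid[iy, ix]
                      and last_m["peak002_intensity"].valid[iy, ix])
            rows.append({"ix": ix, "iy": iy, "delta_attenuation": da,
                         "delta_amp002": damp, "valid": ok})
    return pd.DataFrame(rows)


def _save_png(path: Path, values: np.ndarray) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(values, cmap="gray", origin="lower")
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_xlabel("u (px)")
    ax.set_ylabel("v (px)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
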