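"""Pipeline configuration: plain-text (INI-style) config file, defaults,
and validation.

The default configuration is a desk-scale scene: the same physics and
scan plan as a full experiment (0-180 degree scan, interlaced
tomography/diffraction schedule, 18 keV WAXS on 172 um pixels) on a
phantom small enough to simulate and reconstruct in seconds. All
lengths in micrometres except the sample-to-detector distance (cm).
"""

from __future__ import annotations

import configparser
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Tuple

from .geometry import DetectorGeometry, GapSpec, ImagingGeometry, RasterGrid, make_angle_list
from .phantom import Box, DeminParams
from .simulate import LiquidBackground, ReflectionList, TextureModel

log = logging.getLogger("enamelmap")


@dataclass
class PipelineConfig:
    """Everything both experiment drivers need, with desk-scale defaults."""

    # imaging branch
    pixel_size: float = 2.0
    n_u: int = 128
    n_v: int = 96
    angle_start: float = 0.0
    angle_stop: float = 180.0
    angle_step: float = 1.0
    imaging_energy: float = 22.0
    i0: float = 5000.0
    dark_level: float = 10.0
    vignette_strength: float = 0.05
    n_flats: int = 20

    # diffraction detector (mapping)
    waxs_energy: float = 18.0
    waxs_distance_cm: float = 9.6
    waxs_pixel_pitch: float = 172.0
    waxs_shape: Tuple[int, int] = (256, 256)
    waxs_beam_center: Optional[Tuple[float, float]] = None
    gap_row_start: int = 120
    gap_row_width: int = 6
    gap_col_start: int = 60
    gap_col_width: int = 4

    # raster grid
    grid_origin: Tuple[float, float] = (40.0, 16.0)
    grid_step: Tuple[float, float] = (24.0, 20.0)
    grid_counts: Tuple[int, int] = (8, 8)
    beam_size: Tuple[float, float] = (10.0, 10.0)
    dwell_s: float = 5.0

    # phantom
    rod_pitch: float = 5.0
    rod_density: float = 0.95
    inter_rod_density: float = 0.80
    mu_mineral: float = 1.1e-3
    window: Box = ((184.0, 205.0), (60.0, 140.0), (100.0, 160.0))
    static_lesion_time: float = 30000.0

    # demineralization kinetics
    rate_rod: float = 8.0e-4
    rate_inter: float = 4.0e-4
    softening: float = 0.12

    # WAXS simulation / analysis
    hap_a: float = 9.4218
    hap_c: float = 6.8813
    ring_gain: float = 2.0
    ring_sigma_px: float = 2.0
    waxs_dark_level: float = 2.0
    texture_kappa: float = 2.0
    texture_phi0: float = 0.0
    liquid_gain: float = 0.6
    container_level: float = 0.0
    q002_window: Tuple[float, float] = (1.70, 1.95)
    phi_range: float = 67.0
    n_q_bins: int = 200
    noise: bool = True

    # calibration branch (instrument-scale geometry)
    calib_distance_cm: float = 38.4
    calib_shape: Tuple[int, int] = (1679, 1475)
    calib_lattice_a: float = 4.1569
    calib_amplitude: float = 2000.0

    # schedule (dynamic experiment)
    total_s: float = 52000.0
    tomo_duration_s: float = 600.0
    n_tomo: int = 20
    dynamic_projection_angle: float = 0.0

    # bookkeeping
    seed: int = 0

    def __post_init__(self) -> None:
        if self.waxs_beam_center is None:
            self.waxs_beam_center = (
                (self.waxs_shape[1] - 1) / 2.0,
                (self.waxs_shape[0] - 1) / 2.0,
            )
            log.warning(
                "beam_center not configured; defaulting to detector geometric centre %s",
                self.waxs_beam_center,
            )
        grid = self.raster_grid()
        if not grid.non_overlapping:
            log.warning(
                "beam footprint %s exceeds raster step %s: adjacent points overlap",
                grid.beam_size, grid.step,
            )

    # --- derived objects -------------------------------------------------

    def imaging_geometry(self) -> ImagingGeometry:
        return ImagingGeometry(
            pixel_size=self.pixel_size,
            n_u=self.n_u,
            n_v=self.n_v,
            angle_list=make_angle_list(self.angle_start, self.angle_stop, self.angle_step),
            energy=self.imaging_energy,
        )

    def detector_geometry(self) -> DetectorGeometry:
        return DetectorGeometry(
            energy=self.waxs_energy,
            distance=self.waxs_distance_cm,
            beam_center=self.waxs_beam_center,  # type: ignore[arg-type]
            pixel_pitch=(self.waxs_pixel_pitch, self.waxs_pixel_pitch),
        )

    def calibration_geometry(self) -> DetectorGeometry:
        return DetectorGeometry(
            energy=self.waxs_energy,
            distance=self.calib_distance_cm,
            beam_center=((self.calib_shape[1] - 1) / 2.0, (self.calib_shape[0] - 1) / 2.0),
            pixel_pitch=(self.waxs_pixel_pitch, self.waxs_pixel_pitch),
        )

    def raster_grid(self) -> RasterGrid:
        return RasterGrid(
            origin=self.grid_origin, step=self.grid_step, counts=self.grid_counts,
            beam_size=self.beam_size,
        )

    def gaps(self) -> GapSpec:
        return GapSpec(
            row_gaps=((self.gap_row_start, self.gap_row_width),),
            col_gaps=((self.gap_col_start, self.gap_col_width),),
        )

    def reflections(self) -> ReflectionList:
        return ReflectionList.hydroxyapatite(a=self.hap_a, c=self.hap_c)

    def calibrant(self) -> ReflectionList:
        return ReflectionList.lab6(a=self.calib_lattice_a)

    def texture(self) -> TextureModel:
        return TextureModel(kappa=self.texture_kappa, phi0_deg=self.texture_phi0)

    def background(self) -> LiquidBackground:
        return LiquidBackground(gain=self.liquid_gain, container_level=self.container_level)

    def demin_params(self) -> DeminParams:
        return DeminParams(rate_rod=self.rate_rod, rate_inter=self.rate_inter,
                           softening=self.softening)

    def phantom_size(self) -> Tuple[int, int, int]:
        return (self.n_u, self.n_v, self.n_u)

    def map_duration_s(self) -> float:
        return self.raster_grid().n_points * self.dwell_s

    def to_dict(self) -> dict:
        return asdict(self)


_TUPLE_KEYS = {
    "waxs_shape": int, "waxs_beam_center": float, "grid_origin": float,
    "grid_step": float, "grid_counts": int, "beam_size": float,
    "q002_window": float, "calib_shape": int,
}
_SECTIONS = ("imaging", "detector", "grid", "phantom", "demineralization",
             "analysis", "calibration", "schedule", "run")


def load_config(path) -> PipelineConfig:
    """Load a plain-text config file into a validated :class:`PipelineConfig`.

    The file is INI-style; keys in any recognised section map one-to-one
    to :class:`PipelineConfig` field names (section headers organise the
    file, they do not namespace keys). Unknown keys and violated
    invariants raise a validation error naming the key; omitted keys
    fall back to the documented defaults (logged).
    """
    parser = configparser.ConfigParser(inline_comment_prefixes=("#", ";"))
    text = Path(path).read_text()
    parser.read_string(text)
    kwargs = {}
    defaults = PipelineConfig.__dataclass_fields__
    for section in parser.sections():
        if section not in _SECTIONS:
            raise ValueError(f"unknown config section [{section}]")
        for key, raw in parser.items(section):
            if key == "window":
                parts = [float(v) for v in raw.replace(",", " ").split()]
                if len(parts) != 6:
                    raise ValueError("config key 'window' needs 6 numbers: x0 x1 y0 y1 z0 z1")
                kwargs["window"] = ((parts[0], parts[1]), (parts[2], parts[3]),
                                    (parts[4], parts[5]))
                continue
            if key not in defaults:
                raise ValueError(f"unknown config key {key!r} in section [{section}]")
            target = defaults[key].type
            if key in _TUPLE_KEYS:
                conv = _TUPLE_KEYS[key]
                kwargs[key] = tuple(conv(v) for v in raw.replace(",", " ").split())
            elif key == "noise":
                kwargs[key] = raw.strip().lower() in ("1", "true", "yes", "on")
            elif "int" in str(target):
                kwargs[key] = int(raw)
            else:
                kwargs[key] = float(raw)
    missing = [k for k in defaults if k not in kwargs]
    if missing:
        log.info("config: %d keys defaulted (%s...)", len(missing), ", ".join(missing[:5]))
    try:
        cfg = PipelineConfig(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"config validation failed: {exc}") from exc
    # eager validation of derived objects so errors name their keys
    try:
        cfg.imaging_geometry()
    except ValueError as exc:
        raise ValueError(f"config validation failed (imaging keys): {exc}") from exc
    try:
        cfg.detector_geometry()
        cfg.calibration_geometry()
    except ValueError as exc:
        raise ValueError(f"config validation failed (detector keys): {exc}") from exc
    try:
        cfg.raster_grid()
    except ValueError as exc:
        raise ValueError(f"config validation failed (grid keys): {exc}") from exc
    return cfg


def write_default_config(path) -> None:
    """Write a template config file with every key at its default."""
    cfg = PipelineConfig()
    lines = ["# enamelmap pipeline configuration (all keys optional)", "[run]",
             f"seed = {cfg.seed}", "", "[imaging]"]
    imaging_keys = ["pixel_size", "n_u", "n_v", "angle_start", "angle_stop", "angle_step",
                    "imaging_energy", "i0", "dark_level", "vignette_strength", "n_flats"]
    det_keys = ["waxs_energy", "waxs_distance_cm", "waxs_pixel_pitch", "waxs_shape",
                "waxs_beam_center", "gap_row_start", "gap_row_width", "gap_col_start",
                "gap_col_width"]
    grid_keys = ["grid_origin", "grid_step", "grid_counts", "beam_size", "dwell_s"]
    phantom_keys = ["rod_pitch", "rod_density", "inter_rod_density", "mu_mineral",
                    "static_lesion_time"]
    demin_keys = ["rate_rod", "rate_inter", "softening"]
    ana_keys = ["hap_a", "hap_c", "ring_gain", "ring_sigma_px", "waxs_dark_level",
                "texture_kappa", "texture_phi0", "liquid_gain", "container_level",
                "q002_window", "phi_range", "n_q_bins", "noise"]
    cal_keys = ["calib_distance_cm", "calib_shape", "calib_lattice_a", "calib_amplitude"]
    sched_keys = ["total_s", "tomo_duration_s", "n_tomo", "dynamic_projection_angle"]

    def fmt(key):
        v = getattr(cfg, key)
        if isinstance(v, tuple):
            return " ".join(str(x) for x in v)
        return str(v)

    for section, keys in (("imaging", imaging_keys), ("detector", det_keys),
                          ("grid", grid_keys), ("phantom", phantom_keys),
                          ("demineralization", demin_keys), ("analysis", ana_keys),
                          ("calibration", cal_keys), ("schedule", sched_keys)):
        if section != "imaging":
            lines.append(f"[{section}]")
        for k in keys:
            lines.append(f"{k} = {fmt(k)}")
        lines.append("")
    w = cfg.window
    lines.insert(lines.index("[demineralization]"),
                 f"window = {w[0][0]} {w[0][1]} {w[1][0]} {w[1][1]} {w[2][0]} {w[2][1]}\n")
    Path(path).write_text("\n".join(lines))
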