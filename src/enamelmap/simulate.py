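"""Virtual beamline: forward simulation of both acquisition modalities.

Radiographs follow Beer-Lambert attenuation through the phantom along
parallel rays (mass-conserving linear splatting, so the projection of a
field conserves its integral exactly). WAXS frames are built analytically
from Debye-Scherrer ring geometry: each reachable reflection contributes
a Gaussian-radial ring at r = D tan(2 theta), with amplitude proportional
to the mineral thickness inside the beam prism, an azimuthal texture
factor on the basal (002) reflection, a broad liquid background scaled by
the liquid path length, and dead module-gap strips carrying a sentinel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .geometry import (
    GAP_SENTINEL,
    DetectorGeometry,
    GapSpec,
    Image2D,
    ImagingGeometry,
    RasterGrid,
)
from .phantom import Phantom

log = logging.getLogger("enamelmap")


# ---------------------------------------------------------------------------
# Reflection lists
# ---------------------------------------------------------------------------

def hexagonal_d(h: int, k: int, l: int, a: float, c: float) -> float:
    """d-spacing (Angstrom) of (hkl) in a hexagonal lattice."""
    inv_d2 = 4.0 / 3.0 * (h * h + h * k + k * k) / a**2 + l * l / c**2
    return 1.0 / np.sqrt(inv_d2)


@dataclass(frozen=True)
class ReflectionList:
    """Powder reflections: (h, k, l, d-spacing Angstrom, relative intensity)."""

    entries: Tuple[Tuple[int, int, int, float, float], ...]
    lattice: Tuple[float, float]
    textured_hkl: Tuple[Tuple[int, int, int], ...] = ()

    def __post_init__(self) -> None:
        ds = [e[3] for e in self.entries]
        if any(d <= 0 for d in ds):
            raise ValueError("d-spacings must be positive")
        if any(ds[i] < ds[i + 1] for i in range(len(ds) - 1)):
            raise ValueError("reflections must be sorted by descending d-spacing")

    @property
    def d_spacings(self) -> np.ndarray:
        return np.array([e[3] for e in self.entries])

    def d_of(self, hkl: Tuple[int, int, int]) -> float:
        for h, k, l, d, _ in self.entries:
            if (h, k, l) == hkl:
                return d
        raise KeyError(f"reflection {hkl} not in list")

    @classmethod
    def hydroxyapatite(cls, a: float = 9.4218, c: float = 6.8813) -> "ReflectionList":
        """Hydroxyapatite lines within reach of a transmission WAXS setup.

        The hexagonal lattice constants default to the accepted apatite
        structure values (configurable); relative intensities are
        approximate powder values. The basal (002) reflection, at
        d = c/2, is the texture-sensitive line: in enamel the crystallite
        c axes co-align with the rod axis.
        """
        hkls = [
            ((1, 0, 0), 12.0),
            ((0, 0, 2), 40.0),
            ((2, 1, 0), 18.0),
            ((2, 1, 1), 100.0),
            ((1, 1, 2), 60.0),
            ((3, 0, 0), 60.0),
            ((2, 0, 2), 25.0),
            ((3, 1, 0), 20.0),
        ]
        entries = sorted(
            ((h, k, l, hexagonal_d(h, k, l, a, c), rel) for (h, k, l), rel in hkls),
            key=lambda e: -e[3],
        )
        return cls(entries=tuple(entries), lattice=(a, c), textured_hkl=((0, 0, 2),))

    @classmethod
    def lab6(cls, a: float = 4.1569) -> "ReflectionList":
        """LaB6-like cubic calibrant (NIST-style lattice constant)."""
        lines = [
            ((1, 0, 0), 58.0),
            ((1, 1, 0), 100.0),
            ((1, 1, 1), 48.0),
            ((2, 0, 0), 22.0),
            ((2, 1, 0), 40.0),
            ((2, 1, 1), 28.0),
        ]
        entries = tuple(
            (h, k, l, a / np.sqrt(h * h + k * k + l * l), rel) for (h, k, l), rel in lines
        )
        return cls(entries=entries, lattice=(a, a))


@dataclass(frozen=True)
class TextureModel:
    """Axial texture of the (002) arc: I(phi) ~ exp(kappa cos^2(phi - phi0)).

    ``kappa`` = 0 is isotropic; ``phi0_deg`` is the azimuth of the rod
    (crystallite c-axis) direction on the detector, degrees CCW from +x.
    """

    kappa: float = 2.0
    phi0_deg: float = 0.0

    def factor(self, phi_deg: np.ndarray) -> np.ndarray:
        d = np.radians(phi_deg - self.phi0_deg)
        return np.exp(self.kappa * (np.cos(d) ** 2 - 1.0))


@dataclass(frozen=True)
class LiquidBackground:
    """Broad diffuse scattering from liquid (and container) around the sample.

    ``gain`` scales counts per micrometre of liquid path; the profile is a
    wide Gaussian bump in q plus a flat term; ``container_level`` is a
    liquid-independent baseline from the sample holder.
    """

    gain: float = 0.6
    q_center: float = 2.0
    q_sigma: float = 0.8
    flat_frac: float = 0.25
    container_level: float = 0.0

    def profile(self, q: np.ndarray, liquid_path_um: float) -> np.ndarray:
        bump = np.exp(-0.5 * ((q - self.q_center) / self.q_sigma) ** 2)
        return self.gain * liquid_path_um * (bump + self.flat_frac) + self.container_level


# ---------------------------------------------------------------------------
# Imaging branch
# ---------------------------------------------------------------------------

def project_density(
    values: np.ndarray, angle_deg: float, n_u: int, n_v: int
) -> np.ndarray:
    """Parallel projection of a voxel field onto the detector, (n_v, n_u).

    The volume rotates about the vertical (y) axis; rays run along z at
    angle 0. Each voxel's contribution is splat onto the detector row
    with linear weights that sum to one, so the projection integral
    equals the field integral exactly whenever the rotated footprint
    stays inside the detector.
    """
    nx, ny, nz = values.shape
    if n_v < ny:
        raise ValueError("projection height smaller than phantom height")
    th = np.radians(angle_deg)
    ct, st = np.cos(th), np.sin(th)
    u = (
        (np.arange(nx) - (nx - 1) / 2.0)[:, None] * ct
        + (np.arange(nz) - (nz - 1) / 2.0)[None, :] * st
        + (n_u - 1) / 2.0
    )
    i0 = np.floor(u).astype(np.int64)
    w1 = (u - i0).ravel()
    w0 = 1.0 - w1
    i0 = i0.ravel()
    i1 = i0 + 1
    ok0 = (i0 >= 0) & (i0 < n_u)
    ok1 = (i1 >= 0) & (i1 < n_u)
    v0 = (n_v - ny) // 2
    out = np.zeros((n_v, n_u))
    vals = np.moveaxis(values, 1, 0).reshape(ny, -1)  # (ny, nx*nz)
    for iy in range(ny):
        row = vals[iy].astype(np.float64)
        acc = np.bincount(i0[ok0], weights=row[ok0] * w0[ok0], minlength=n_u)
        acc += np.bincount(i1[ok1], weights=row[ok1] * w1[ok1], minlength=n_u)
        out[v0 + iy] += acc
    return out


def simulate_radiograph(
    phantom: Phantom,
    angle: float,
    imaging: ImagingGeometry,
    i0: float = 5000.0,
    noise_seed: Optional[int] = None,
    flat_field: Optional[np.ndarray] = None,
    dark_level: float = 0.0,
    timestamp: float = 0.0,
) -> Image2D:
    """Beer-Lambert radiograph of the phantom at one rotation angle.

    Expected counts are ``flat_field * exp(-integral mu dl) + dark_level``
    with ``flat_field`` defaulting to a uniform ``i0``; optional Poisson
    noise is seeded by ``noise_seed``.
    """
    if abs(imaging.pixel_size - phantom.voxel_size) > 1e-9 * imaging.pixel_size:
        raise ValueError("imaging pixel size must equal phantom voxel size (no resampling)")
    path = project_density(phantom.mu.astype(np.float64), angle, imaging.n_u, imaging.n_v)
    transmission = np.exp(-path * phantom.voxel_size)
    beam = np.full((imaging.n_v, imaging.n_u), float(i0)) if flat_field is None else flat_field
    counts = beam * transmission + dark_level
    if noise_seed is not None:
        counts = np.random.default_rng(noise_seed).poisson(counts).astype(np.float64)
    return Image2D(values=counts, pixel_size=imaging.pixel_size, frame_tag="projection",
                   timestamp=timestamp)


def vignette_profile(imaging: ImagingGeometry, i0: float, strength: float = 0.05) -> np.ndarray:
    """Smooth radially-falling beam profile (structured flat field)."""
    v, u = np.meshgrid(np.arange(imaging.n_v), np.arange(imaging.n_u), indexing="ij")
    ru = (u - (imaging.n_u - 1) / 2) / imaging.n_u
    rv = (v - (imaging.n_v - 1) / 2) / imaging.n_v
    return i0 * (1.0 - strength * 4.0 * (ru**2 + rv**2))


def simulate_flats_darks(
    imaging: ImagingGeometry,
    n: int = 20,
    i0: float = 5000.0,
    dark_level: float = 10.0,
    seed: int = 0,
    vignette_strength: float = 0.05,
    dark_sigma: float = 1.0,
    noise: bool = True,
) -> Tuple[List[Image2D], List[Image2D]]:
    """Flat-field and dark-field frame stacks (n of each)."""
    if n < 1:
        raise ValueError("need at least one flat/dark frame")
    rng = np.random.default_rng(seed)
    beam = vignette_profile(imaging, i0, vignette_strength)
    flats, darks = [], []
    for i in range(n):
        f = rng.poisson(beam + dark_level).astype(np.float64) if noise else beam + dark_level
        d = (
            np.clip(rng.normal(dark_level, dark_sigma, beam.shape), 0, None)
            if noise
            else np.full(beam.shape, float(dark_level))
        )
        flats.append(Image2D(f, imaging.pixel_size, "flat", timestamp=float(i)))
        darks.append(Image2D(d, imaging.pixel_size, "dark", timestamp=float(i)))
    return flats, darks


# ---------------------------------------------------------------------------
# Diffraction branch
# ---------------------------------------------------------------------------

_POLAR_CACHE: Dict[tuple, Tuple[np.ndarray, np.ndarray]] = {}


def detector_polar(shape: Tuple[int, int], beam_center: Tuple[float, float]):
    """Per-pixel radius (pixels) and azimuth (degrees CCW from +x).

    Rows index detector y, columns detector x; results are cached.
    """
    key = (shape, round(beam_center[0], 6), round(beam_center[1], 6))
    hit = _POLAR_CACHE.get(key)
    if hit is not None:
        return hit
    yy, xx = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    dx = xx - beam_center[0]
    dy = yy - beam_center[1]
    r = np.hypot(dx, dy)
    phi = np.degrees(np.arctan2(dy, dx)) % 360.0
    if len(_POLAR_CACHE) > 8:
        _POLAR_CACHE.clear()
    _POLAR_CACHE[key] = (r, phi)
    return r, phi


def beam_prism_stats(phantom: Phantom, grid: RasterGrid, point: Tuple[int, int]) -> dict:
    """Mineral and liquid content of the beam prism at one raster point.

    The prism is an axis-aligned box of the beam's cross-section through
    the full phantom depth along z (mapping at rotation 0). Returns mean
    mineral thickness and liquid path length (um) plus voxel masks.
    """
    ix, iy = point
    px, py = grid.point_xy(ix, iy)
    wx, wy = grid.beam_size
    xc = phantom.voxel_centers(0)
    yc = phantom.voxel_centers(1)
    sel_x = np.abs(xc - px) <= wx / 2.0
    sel_y = np.abs(yc - py) <= wy / 2.0
    n_cols = int(sel_x.sum()) * int(sel_y.sum())
    if n_cols == 0:
        return {"mineral_thickness": 0.0, "liquid_path": 0.0, "n_columns": 0,
                "sel_x": sel_x, "sel_y": sel_y}
    sub = phantom.density[np.ix_(np.flatnonzero(sel_x), np.flatnonzero(sel_y))]
    mineral = float(sub.sum(dtype=np.float64)) * phantom.voxel_size / n_cols
    liq = phantom.liquid_fraction()[np.ix_(np.flatnonzero(sel_x), np.flatnonzero(sel_y))]
    liquid = float(liq.sum(dtype=np.float64)) * phantom.voxel_size / n_cols
    return {"mineral_thickness": mineral, "liquid_path": liquid, "n_columns": n_cols,
            "sel_x": sel_x, "sel_y": sel_y}


def simulate_waxs_pattern(
    phantom: Phantom,
    grid: RasterGrid,
    point: Tuple[int, int],
    geometry: DetectorGeometry,
    detector_shape: Tuple[int, int],
    reflections: ReflectionList,
    texture: TextureModel = TextureModel(),
    background: LiquidBackground = LiquidBackground(),
    gaps: Optional[GapSpec] = None,
    ring_gain: float = 2.0,
    sigma_r: float = 2.0,
    dark_level: float = 2.0,
    noise_seed: Optional[int] = None,
    timestamp: float = 0.0,
) -> Image2D:
    """One 2-D WAXS frame for the beam parked at a raster point.

    Ring amplitudes scale linearly with the mineral thickness in the beam
    prism (``ring_gain`` counts per um per unit relative intensity); the
    liquid background scales with the liquid path length. Reflections
    with d < lambda/2 are unreachable and skipped with a warning.
    """
    stats = beam_prism_stats(phantom, grid, point)
    r, phi = detector_polar(detector_shape, geometry.beam_center)
    q = geometry.q_of_radius(r)

    img = np.full(detector_shape, float(dark_level))
    img += background.profile(q, stats["liquid_path"])
    s_min = geometry.wavelength / 2.0
    for h, k, l, d, rel in reflections.entries:
        if d < s_min:
            log.warning("reflection (%d%d%d) d=%.3f A unreachable at %.3f A; skipped",
                        h, k, l, d, geometry.wavelength)
            continue
        r0 = geometry.ring_radius_pixels(d)
        amp = ring_gain * (rel / 100.0) * stats["mineral_thickness"]
        if amp == 0.0:
            continue
        band = np.abs(r - r0) < 8.0 * sigma_r
        ring = amp * np.exp(-0.5 * ((r[band] - r0) / sigma_r) ** 2)
        if (h, k, l) in reflections.textured_hkl and texture.kappa != 0.0:
            ring = ring * texture.factor(phi[band])
        img[band] += ring
    if noise_seed is not None:
        img = np.random.default_rng(noise_seed).poisson(np.clip(img, 0, None)).astype(np.float64)
    if gaps is not None:
        img[gaps.gap_mask(detector_shape)] = GAP_SENTINEL
    return Image2D(values=img, pixel_size=geometry.pixel_pitch[0], frame_tag="waxs",
                   timestamp=timestamp)


def simulate_calibrant_pattern(
    geometry: DetectorGeometry,
    calibrant: ReflectionList,
    seed: Optional[int] = None,
    detector_shape: Tuple[int, int] = (1679, 1475),
    amplitude: float = 2000.0,
    sigma_r: float = 2.0,
    baseline: float = 20.0,
    gaps: Optional[GapSpec] = None,
) -> Image2D:
    """Isotropic calibrant pattern: complete rings with Gaussian radial profile."""
    r, _ = detector_polar(detector_shape, geometry.beam_center)
    img = np.full(detector_shape, float(baseline))
    s_min = geometry.wavelength / 2.0
    for h, k, l, d, rel in calibrant.entries:
        if d < s_min:
            continue
        r0 = geometry.ring_radius_pixels(d)
        band = np.abs(r - r0) < 8.0 * sigma_r
        img[band] += amplitude * (rel / 100.0) * np.exp(-0.5 * ((r[band] - r0) / sigma_r) ** 2)
    if seed is not None:
        img = np.random.default_rng(seed).poisson(img).astype(np.float64)
    if gaps is not None:
        img[gaps.gap_mask(detector_shape)] = GAP_SENTINEL
    return Image2D(values=img, pixel_size=geometry.pixel_pitch[0], frame_tag="calibrant")


# ---------------------------------------------------------------------------
# Acquisition schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionEvent:
    kind: str  # "tomography" | "diffraction_map"
    t_start: float
    t_stop: float
    index: int

    @property
    def t_mid(self) -> float:
        return 0.5 * (self.t_start + self.t_stop)


@dataclass(frozen=True)
class Schedule:
    events: Tuple[AcquisitionEvent, ...]

    def of_kind(self, kind: str) -> List[AcquisitionEvent]:
        return [e for e in self.events if e.kind == kind]

    @property
    def total(self) -> float:
        return self.events[-1].t_stop if self.events else 0.0


def plan_interlaced_acquisition(
    total: float, tomo_duration: float, map_duration: float, n_tomo: int
) -> Schedule:
    """Alternating tomography / diffraction-map schedule spanning ``total``.

    Each of the ``n_tomo`` acquisition cycles starts with a tomography
    scan immediately followed by a diffraction map; cycles are spread
    evenly over the total time (the acid keeps acting during the idle
    remainder of each cycle, as in a real in-situ run).
    """
    if tomo_duration <= 0 or map_duration <= 0:
        raise ValueError("event durations must be > 0")
    if n_tomo < 1:
        raise ValueError("need at least one tomography event")
    cycle = tomo_duration + map_duration
    minimum = n_tomo * cycle
    if total < minimum:
        raise ValueError(
            f"schedule infeasible: {n_tomo} tomography scans interlaced with maps "
            f"require at least {minimum:.0f} s, got {total:.0f} s"
        )
    period = max(cycle, (total - cycle) / max(n_tomo - 1, 1))
    events: List[AcquisitionEvent] = []
    for i in range(n_tomo):
        t = i * period
        events.append(AcquisitionEvent("tomography", t, t + tomo_duration, i))
        events.append(
            AcquisitionEvent("diffraction_map", t + tomo_duration, t + cycle, i)
        )
    return Schedule(events=tuple(events))
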