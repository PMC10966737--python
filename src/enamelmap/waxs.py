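"""Diffraction-side analysis: geometry calibration, azimuthal integration,
texture profiling, peak fitting, and per-raster-point scalar maps.

Conventions: the azimuth phi is measured counterclockwise from the
detector +x axis, in degrees. Integrated intensities are the *mean*
counts per bin (coverage is stored separately) so that module-gap
coverage differences do not masquerade as intensity changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage, optimize

from .geometry import (
    GAP_SENTINEL,
    AzimuthalProfile,
    DetectorGeometry,
    Diffractogram1D,
    GapSpec,
    Image2D,
    PeakFit,
    RasterGrid,
    ScalarMap,
)
from .simulate import detector_polar

log = logging.getLogger("enamelmap")


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------

def build_detector_mask(
    shape: Tuple[int, int],
    gaps: Optional[GapSpec] = None,
    user_mask: Optional[Image2D] = None,
) -> Image2D:
    """Boolean usable-pixel mask (True = usable); gap strips and any
    user-supplied mask are ANDed in."""
    mask = np.ones(shape, dtype=bool)
    if gaps is not None:
        mask &= ~gaps.gap_mask(shape)
    if user_mask is not None:
        if user_mask.values.shape != shape:
            raise ValueError("user mask shape does not match detector shape")
        mask &= user_mask.values.astype(bool)
    return Image2D(values=mask, pixel_size=1.0, frame_tag="mask")


def _usable(pattern: Image2D, mask: Optional[Image2D]) -> np.ndarray:
    m = np.ones(pattern.values.shape, dtype=bool) if mask is None else mask.values.astype(bool)
    return m & (pattern.values != GAP_SENTINEL)


# ---------------------------------------------------------------------------
# Geometry calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    geometry: DetectorGeometry
    residual_rms_px: float
    n_points: int
    n_rings: int


def _detect_ring_points(
    img: np.ndarray,
    geometry: DetectorGeometry,
    d_spacings: Sequence[float],
    n_rays: int,
    half_window: float,
    window_frac: float = 0.0,
) -> List[np.ndarray]:
    """Sub-pixel ring points per reflection by radial centre-of-mass along rays.

    ``window_frac`` widens the search window to that fraction of the
    expected radius (used on the first pass, when the initial geometry
    may be off by a few per cent).
    """
    cx, cy = geometry.beam_center
    rad_step = 0.25
    phis = np.radians(np.linspace(0.0, 360.0, n_rays, endpoint=False))
    points: List[np.ndarray] = []
    for d in d_spacings:
        try:
            r0 = geometry.ring_radius_pixels(d)
        except ValueError:
            points.append(np.empty((0, 2)))
            continue
        hw = max(half_window, window_frac * r0)
        offsets = np.arange(-hw, hw + rad_step / 2, rad_step)
        radii = r0 + offsets
        xs = cx + radii[None, :] * np.cos(phis)[:, None]
        ys = cy + radii[None, :] * np.sin(phis)[:, None]
        samples = ndimage.map_coordinates(
            img, [ys.ravel(), xs.ravel()], order=1, mode="constant", cval=-1.0
        ).reshape(len(phis), len(radii))
        ring_pts = []
        for j in range(len(phis)):
            prof = samples[j]
            if prof.min() < 0:  # crossed a gap sentinel or left the detector
                continue
            base = prof.min()
            net = prof - base
            k = int(np.argmax(net))
            peak = net[k]
            if peak <= 5.0 * (np.median(net) + 1.0):
                continue
            # contiguous region around the maximum, so a neighbouring ring
            # entering a wide search window cannot skew the centre of mass
            lo = k
            while lo > 0 and net[lo - 1] >= 0.2 * peak:
                lo -= 1
            hi = k
            while hi < len(net) - 1 and net[hi + 1] >= 0.2 * peak:
                hi += 1
            seg = slice(lo, hi + 1)
            rho = float(np.sum(net[seg] * radii[seg]) / np.sum(net[seg]))
            ring_pts.append((cx + rho * np.cos(phis[j]), cy + rho * np.sin(phis[j])))
        points.append(np.asarray(ring_pts).reshape(-1, 2))
    return points


def calibrate_geometry(
    pattern: Image2D,
    calibrant_d: Sequence[float],
    initial: DetectorGeometry,
    n_rays: int = 180,
    half_window: float = 12.0,
    n_iter: int = 3,
    min_points_per_ring: int = 12,
) -> CalibrationResult:
    """Fit sample-to-detector distance and beam centre from calibrant rings.

    Ring points are detected by radial centre-of-mass along azimuthal
    rays, then (distance, beam_center) are least-squares fitted so that
    point radii match r(d) = D tan(2 asin(lambda / 2d)); detection is
    repeated with the refined geometry. Requires >= 2 resolvable rings.
    """
    img = np.where(pattern.values == GAP_SENTINEL, -1.0, pattern.values.astype(float))
    geometry = initial
    result: Optional[optimize.OptimizeResult] = None
    used_d: List[float] = []
    pts_all: np.ndarray = np.empty((0, 2))
    for it in range(n_iter):
        ring_points = _detect_ring_points(
            img, geometry, calibrant_d, n_rays, half_window,
            window_frac=0.08 if it == 0 else 0.0,
        )
        used_d, groups = [], []
        for d, pts in zip(calibrant_d, ring_points):
            if len(pts) >= min_points_per_ring:
                used_d.append(d)
                groups.append(pts)
        if len(used_d) < 2:
            raise RuntimeError(
                f"calibration needs >= 2 resolvable rings, found {len(used_d)}"
            )
        pts_all = np.vstack(groups)
        ring_idx = np.concatenate(
            [np.full(len(g), i) for i, g in enumerate(groups)]
        ).astype(int)
        wavelength = initial.wavelength
        tth = 2.0 * np.arcsin(wavelength / (2.0 * np.asarray(used_d)))
        tan_tth = np.tan(tth)
        pitch = initial.pixel_pitch[0]

        def residuals(p):
            cx, cy, dist_cm = p
            rho = np.hypot(pts_all[:, 0] - cx, pts_all[:, 1] - cy)
            model = dist_cm * 1.0e4 * tan_tth[ring_idx] / pitch
            return rho - model

        result = optimize.least_squares(
            residuals,
            x0=[geometry.beam_center[0], geometry.beam_center[1], geometry.distance],
            method="lm",
        )
        if not result.success:
            raise RuntimeError(
                f"calibration fit did not converge: {result.message}; "
                f"residual trace: {result.fun[:10]}"
            )
        cx, cy, dist = result.x
        geometry = initial.replace(beam_center=(float(cx), float(cy)), distance=float(dist))
    rms = float(np.sqrt(np.mean(result.fun**2)))
    return CalibrationResult(
        geometry=geometry, residual_rms_px=rms, n_points=len(pts_all), n_rings=len(used_d)
    )


# ---------------------------------------------------------------------------
# Azimuthal integration and profiles
# ---------------------------------------------------------------------------

def azimuthal_integrate(
    pattern: Image2D,
    geometry: DetectorGeometry,
    mask: Optional[Image2D] = None,
    n_bins: int = 200,
    q_range: Optional[Tuple[float, float]] = None,
    min_coverage_frac: float = 0.10,
) -> Diffractogram1D:
    """Azimuthally integrate a 2-D pattern into I(q).

    Per-pixel q = (4 pi / lambda) sin(atan(r / D) / 2); pixels are binned
    by q and averaged. Bins whose pixel coverage falls below
    ``min_coverage_frac`` of the median coverage are flagged invalid.
    """
    if n_bins < 8:
        raise ValueError("n_bins must be >= 8")
    usable = _usable(pattern, mask)
    if not usable.any():
        raise ValueError("empty mask: no usable pixels to integrate")
    r, _ = detector_polar(pattern.values.shape, geometry.beam_center)
    q = np.asarray(geometry.q_of_radius(r))
    qm = q[usable]
    vm = pattern.values[usable].astype(np.float64)
    lo, hi = q_range if q_range is not None else (float(qm.min()), float(qm.max()))
    if hi <= lo:
        raise ValueError("degenerate q range")
    width = (hi - lo) / n_bins
    inside = (qm >= lo) & (qm <= hi)
    idx = np.minimum(((qm[inside] - lo) / width).astype(np.int64), n_bins - 1)
    coverage = np.bincount(idx, minlength=n_bins).astype(np.float64)
    sums = np.bincount(idx, weights=vm[inside], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        intensity = np.where(coverage > 0, sums / np.maximum(coverage, 1), 0.0)
    med = np.median(coverage)
    valid = coverage >= min_coverage_frac * med
    centers = lo + width * (np.arange(n_bins) + 0.5)
    return Diffractogram1D(q=centers, intensity=intensity, coverage=coverage, valid=valid)


def azimuthal_profile(
    pattern: Image2D,
    geometry: DetectorGeometry,
    mask: Optional[Image2D],
    q_window: Tuple[float, float],
    phi_range: float = 360.0,
    n_phi: int = 67,
    phi_center: Optional[float] = None,
    min_coverage_frac: float = 0.10,
) -> AzimuthalProfile:
    """Mean intensity versus azimuth phi over a q annulus (texture profile).

    With ``phi_center`` set, only the span ``phi_center +- phi_range / 2``
    is profiled (e.g. a 67-degree window across the basal arc); otherwise
    the span starts at phi = 0. Bins starved by gaps/mask are flagged.
    """
    usable = _usable(pattern, mask)
    r, phi = detector_polar(pattern.values.shape, geometry.beam_center)
    q = np.asarray(geometry.q_of_radius(r))
    annulus = usable & (q >= q_window[0]) & (q <= q_window[1])
    if not annulus.any():
        raise ValueError("q annulus is fully masked or outside detector coverage")
    start = (phi_center - phi_range / 2.0) if phi_center is not None else 0.0
    rel = np.mod(phi[annulus] - start, 360.0)
    inside = rel <= phi_range
    width = phi_range / n_phi
    idx = np.minimum((rel[inside] / width).astype(np.int64), n_phi - 1)
    coverage = np.bincount(idx, minlength=n_phi).astype(np.float64)
    sums = np.bincount(idx, weights=pattern.values[annulus][inside].astype(np.float64),
                       minlength=n_phi)
    intensity = np.where(coverage > 0, sums / np.maximum(coverage, 1), 0.0)
    med = np.median(coverage)
    valid = coverage >= min_coverage_frac * med
    centers = np.mod(start + width * (np.arange(n_phi) + 0.5), 360.0)
    return AzimuthalProfile(
        phi=centers, intensity=intensity, q_window=tuple(q_window),
        phi_range=float(phi_range), coverage=coverage, valid=valid,
    )


# ---------------------------------------------------------------------------
# Peak fitting
# ---------------------------------------------------------------------------

def _pseudo_voigt(q, center, amplitude, fwhm, eta, slope, intercept):
    x = q - center
    g = np.exp(-4.0 * np.log(2.0) * (x / fwhm) ** 2)
    lz = 1.0 / (1.0 + 4.0 * (x / fwhm) ** 2)
    return amplitude * (eta * lz + (1.0 - eta) * g) + slope * q + intercept


def _gaussian(q, center, amplitude, fwhm, slope, intercept):
    return _pseudo_voigt(q, center, amplitude, fwhm, 0.0, slope, intercept)


def fit_peak(
    diffractogram: Diffractogram1D,
    q_window: Tuple[float, float],
    model: str = "pseudo_voigt",
) -> PeakFit:
    """Least-squares single-peak fit (peak + linear background) in a q window.

    Initialisation: centre at the argmax after removing the end-point
    baseline, FWHM at a fifth of the window. Bounded: amplitude >= 0,
    centre inside the window, 0 <= eta <= 1, and FWHM at least two bin
    widths (narrower peaks are unresolvable and would let the fit chase
    single-bin noise spikes). A non-convergent fit returns
    a flagged, map-safe result (amplitude 0, rss = inf).
    """
    sel = (diffractogram.q >= q_window[0]) & (diffractogram.q <= q_window[1]) & diffractogram.valid
    q = diffractogram.q[sel]
    y = diffractogram.intensity[sel]
    if q.size < 8:
        raise ValueError(f"peak fitting needs >= 8 valid bins in the window, got {q.size}")
    span = q_window[1] - q_window[0]
    slope0 = (y[-1] - y[0]) / (q[-1] - q[0])
    icpt0 = y[0] - slope0 * q[0]
    net = y - (slope0 * q + icpt0)
    c0 = float(q[np.argmax(net)])
    a0 = max(float(net.max()), 1.0e-12)
    w0 = max(span / 5.0, 2.5 * float(np.median(np.diff(q))))
    bin_w = float(np.median(np.diff(q)))
    try:
        if model == "pseudo_voigt":
            p0 = [c0, a0, w0, 0.5, slope0, icpt0]
            lb = [q_window[0], 0.0, 2.0 * bin_w, 0.0, -np.inf, -np.inf]
            ub = [q_window[1], np.inf, 2.0 * span, 1.0, np.inf, np.inf]
            popt, _ = optimize.curve_fit(_pseudo_voigt, q, y, p0=p0, bounds=(lb, ub),
                                         maxfev=20000)
            center, amplitude, fwhm, eta, slope, intercept = popt
            resid = y - _pseudo_voigt(q, *popt)
        elif model == "gaussian":
            p0 = [c0, a0, w0, slope0, icpt0]
            lb = [q_window[0], 0.0, 2.0 * bin_w, -np.inf, -np.inf]
            ub = [q_window[1], np.inf, 2.0 * span, np.inf, np.inf]
            popt, _ = optimize.curve_fit(_gaussian, q, y, p0=p0, bounds=(lb, ub),
                                         maxfev=20000)
            center, amplitude, fwhm, slope, intercept = popt
            eta = 0.0
            resid = y - _gaussian(q, *popt)
        else:
            raise ValueError(f"unknown peak model {model!r}")
    except RuntimeError:
        return PeakFit(center=0.5 * (q_window[0] + q_window[1]), amplitude=0.0, fwhm=0.0,
                       eta=0.0, background=(0.0, 0.0), rss=np.inf, converged=False)
    return PeakFit(center=float(center), amplitude=float(amplitude), fwhm=float(fwhm),
                   eta=float(eta), background=(float(slope), float(intercept)),
                   rss=float(np.sum(resid**2)), converged=True)


def summed_intensity(pattern: Image2D, mask: Optional[Image2D] = None) -> float:
    """Sum of usable (masked-in, non-gap) pixel values."""
    usable = _usable(pattern, mask)
    return float(pattern.values[usable].sum(dtype=np.float64))


def texture_width(profile: AzimuthalProfile) -> float:
    """Angular spread (degrees) of an azimuthal arc: intensity-weighted
    circular standard deviation about the profile maximum, baseline
    removed."""
    y = profile.intensity[profile.valid]
    phi = profile.phi[profile.valid]
    if y.size < 3 or y.max() <= 0:
        return 0.0
    net = y - y.min()
    if net.sum() <= 0:
        return 0.0
    phi0 = phi[np.argmax(net)]
    d = (phi - phi0 + 180.0) % 360.0 - 180.0
    var = float(np.sum(net * d**2) / np.sum(net))
    return float(np.sqrt(var))


# ---------------------------------------------------------------------------
# Raster lookup correction
# ---------------------------------------------------------------------------

@dataclass
class LookupTable:
    """Per-raster-point geometry offsets relative to a reference geometry.

    Arrays are (ny, nx): beam-centre offsets in pixels, distance offset
    in cm. Applied before integrating each point's pattern.
    """

    d_center_x: np.ndarray
    d_center_y: np.ndarray
    d_distance: np.ndarray
    reference: DetectorGeometry

    def geometry_at(self, ix: int, iy: int) -> DetectorGeometry:
        ref = self.reference
        return ref.replace(
            beam_center=(
                ref.beam_center[0] + float(self.d_center_x[iy, ix]),
                ref.beam_center[1] + float(self.d_center_y[iy, ix]),
            ),
            distance=ref.distance + float(self.d_distance[iy, ix]),
        )


def raster_lookup_correction(
    per_point_calibrations: Dict[Tuple[int, int], DetectorGeometry],
    reference: DetectorGeometry,
    grid: RasterGrid,
) -> LookupTable:
    """Geometry-offset lookup table from per-point calibrant fits.

    Rastering the beam (not the stage) perturbs the diffraction geometry
    point-to-point; per-point calibrations yield (dx, dy, dD) offsets.
    Missing points are nearest-neighbour filled with a warning.
    """
    nx, ny = grid.counts
    dcx = np.full((ny, nx), np.nan)
    dcy = np.full((ny, nx), np.nan)
    dd = np.full((ny, nx), np.nan)
    for (iy, ix), geo in per_point_calibrations.items():
        dcx[iy, ix] = geo.beam_center[0] - reference.beam_center[0]
        dcy[iy, ix] = geo.beam_center[1] - reference.beam_center[1]
        dd[iy, ix] = geo.distance - reference.distance
    missing = np.isnan(dcx)
    if missing.any():
        if missing.all():
            raise ValueError("no per-point calibrations supplied")
        log.warning("lookup table: %d missing points nearest-neighbour filled",
                    int(missing.sum()))
        idx = ndimage.distance_transform_edt(missing, return_distances=False,
                                             return_indices=True)
        for arr in (dcx, dcy, dd):
            arr[...] = arr[tuple(idx)]
    return LookupTable(d_center_x=dcx, d_center_y=dcy, d_distance=dd, reference=reference)


# ---------------------------------------------------------------------------
# Maps
# ---------------------------------------------------------------------------

def build_maps(
    patterns: Dict[Tuple[int, int], Image2D],
    grid: RasterGrid,
    geometry: Union[DetectorGeometry, LookupTable],
    mask: Optional[Image2D] = None,
    q002_window: Tuple[float, float] = (1.70, 1.95),
    phi_range: float = 67.0,
    n_bins: int = 200,
    q_range: Optional[Tuple[float, float]] = None,
    model: str = "pseudo_voigt",
) -> List[ScalarMap]:
    """Scalar maps over the raster grid.

    Produces total summed intensity, fitted (002) peak amplitude, (002)
    peak centre, and texture width maps. Missing patterns and failed fits
    are map-safe: value 0 with the companion validity flag cleared. A
    converged fit is flagged valid only when it is a genuine peak
    detection: amplitude above five times the residual noise level and a
    physically plausible width (the bounded-positive amplitude makes the
    no-peak null one-sided and heavy-tailed, so a plain 3-sigma rule
    under-rejects; off-sample points, where the fit can latch onto the
    broad liquid/container background, stay map-safe but invalid).
    ``geometry`` may be a single reference or a per-point lookup table.
    """
    nx, ny = grid.counts
    total = np.zeros((ny, nx))
    amp = np.zeros((ny, nx))
    center = np.zeros((ny, nx))
    width = np.zeros((ny, nx))
    valid = np.zeros((ny, nx), dtype=bool)
    for iy in range(ny):
        for ix in range(nx):
            frame = patterns.get((iy, ix))
            if frame is None:
                log.warning("missing pattern at raster point (ix=%d, iy=%d)", ix, iy)
                continue
            geo = geometry.geometry_at(ix, iy) if isinstance(geometry, LookupTable) else geometry
            total[iy, ix] = summed_intensity(frame, mask)
            dg = azimuthal_integrate(frame, geo, mask, n_bins=n_bins, q_range=q_range)
            try:
                fit = fit_peak(dg, q002_window, model=model)
            except ValueError:
                continue
            if fit.converged:
                amp[iy, ix] = fit.amplitude
                center[iy, ix] = fit.center
                in_win = (dg.q >= q002_window[0]) & (dg.q <= q002_window[1]) & dg.valid
                noise = np.sqrt(fit.rss / max(int(in_win.sum()) - 6, 1))
                span = q002_window[1] - q002_window[0]
                bin_w = float(np.median(np.diff(dg.q)))
                valid[iy, ix] = (
                    fit.amplitude > 5.0 * noise and 2.0 * bin_w < fit.fwhm < span / 2.0
                )
            try:
                prof = azimuthal_profile(
                    frame, geo, mask, q002_window, phi_range=360.0, n_phi=72
                )
                phi_max = prof.phi[np.argmax(prof.intensity)]
                arc = azimuthal_profile(
                    frame, geo, mask, q002_window, phi_range=phi_range,
                    n_phi=max(16, int(phi_range)), phi_center=float(phi_max),
                )
                width[iy, ix] = texture_width(arc)
            except ValueError:
                pass
    return [
        ScalarMap(values=total, grid=grid, quantity="total_intensity", valid=None),
        ScalarMap(values=amp, grid=grid, quantity="peak002_intensity", valid=valid.copy()),
        ScalarMap(values=center, grid=grid, quantity="peak002_center", valid=valid.copy()),
        ScalarMap(values=width, grid=grid, quantity="texture_width", valid=valid.copy()),
    ]
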