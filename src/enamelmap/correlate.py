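"""Cross-modal registration and correlation.

Maps live on the raster grid; projections and volumes live on the
imaging pixel grid. A :class:`GridTransform` maps raster indices
(ix, iy) to projection pixels (u, v); because both modalities share the
unified lab frame, the exact-metadata path gives scale = step /
pixel_size directly. Gauge volumes are the beam footprint extruded
through the sample depth, cut from the reconstructed volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import Image2D, ImagingGeometry, RasterGrid, ScalarMap, Volume3D
from .simulate import AcquisitionEvent, Schedule

log = logging.getLogger("enamelmap")


@dataclass
class GridTransform:
    """Affine map from raster indices (ix, iy) to projection pixels (u, v).

    u = sx * (R ix') + tu with optional in-plane rotation; scale is in
    pixels per raster step, offset in pixels.
    """

    scale: Tuple[float, float]
    offset: Tuple[float, float]
    rotation: float = 0.0
    residual_rms_px: float = 0.0

    def __post_init__(self) -> None:
        if any(abs(s) < 1.0e-12 for s in self.scale):
            raise ValueError("transform scale must be non-zero (invertible)")

    def _rot(self) -> np.ndarray:
        th = np.radians(self.rotation)
        return np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])

    def raster_to_pixel(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        scaled = pts * np.asarray(self.scale)
        return scaled @ self._rot().T + np.asarray(self.offset)

    def pixel_to_raster(self, pixels: np.ndarray) -> np.ndarray:
        px = np.atleast_2d(np.asarray(pixels, dtype=float))
        unrot = (px - np.asarray(self.offset)) @ np.linalg.inv(self._rot()).T
        return unrot / np.asarray(self.scale)

    @classmethod
    def from_metadata(
        cls, grid: RasterGrid, imaging: ImagingGeometry, frame_origin: Tuple[float, float] = (0.0, 0.0)
    ) -> "GridTransform":
        """Exact transform from shared metadata (no fiducials).

        ``frame_origin`` is the lab (x, y) of projection pixel (0, 0),
        micrometres. Scale is step / pixel_size in px per raster step.
        """
        sx = grid.step[0] / imaging.pixel_size
        sy = grid.step[1] / imaging.pixel_size
        tu = (grid.origin[0] - frame_origin[0]) / imaging.pixel_size
        tv = (grid.origin[1] - frame_origin[1]) / imaging.pixel_size
        return cls(scale=(sx, sy), offset=(tu, tv))


def fit_grid_transform(
    points_raster: Sequence[Tuple[float, float]],
    points_pixel: Sequence[Tuple[float, float]],
    allow_rotation: bool = False,
) -> GridTransform:
    """Least-squares scale+offset (optionally rotation) transform fit.

    Needs >= 3 non-collinear correspondences between raster indices and
    projection pixels (fiducials).
    """
    P = np.asarray(points_raster, dtype=float)
    Q = np.asarray(points_pixel, dtype=float)
    if P.shape[0] < 3 or P.shape != Q.shape:
        raise ValueError("need >= 3 matching raster/pixel correspondences")
    spread = P - P.mean(axis=0)
    if np.linalg.matrix_rank(np.column_stack([spread, np.ones(len(P))])) < 3:
        raise ValueError("fiducials are collinear; transform is under-determined")
    if not allow_rotation:
        # decoupled 1-D least squares per axis
        params = []
        for k in range(2):
            A = np.column_stack([P[:, k], np.ones(len(P))])
            (s, t), *_ = np.linalg.lstsq(A, Q[:, k], rcond=None)
            params.append((s, t))
        tf = GridTransform(scale=(params[0][0], params[1][0]),
                           offset=(params[0][1], params[1][1]))
    else:
        from scipy.optimize import least_squares

        def resid(p):
            tf = GridTransform(scale=(p[0], p[1]), offset=(p[2], p[3]), rotation=p[4])
            return (tf.raster_to_pixel(P) - Q).ravel()

        sx0 = (np.ptp(Q[:, 0]) / max(np.ptp(P[:, 0]), 1e-9)) or 1.0
        sy0 = (np.ptp(Q[:, 1]) / max(np.ptp(P[:, 1]), 1e-9)) or 1.0
        sol = least_squares(resid, x0=[sx0, sy0, Q[:, 0].mean(), Q[:, 1].mean(), 0.0])
        tf = GridTransform(scale=(sol.x[0], sol.x[1]), offset=(sol.x[2], sol.x[3]),
                           rotation=sol.x[4])
    res = tf.raster_to_pixel(P) - Q
    tf.residual_rms_px = float(np.sqrt(np.mean(res**2)))
    return tf


# ---------------------------------------------------------------------------
# Overlay
# ---------------------------------------------------------------------------

def resample_map_to_pixels(
    smap: ScalarMap, shape: Tuple[int, int], transform: GridTransform
) -> np.ndarray:
    """Nearest-neighbour resampling of a raster map into the pixel frame.

    Each raster cell becomes a constant block (the measurement's support
    is genuinely blocky); pixels outside the grid footprint are NaN.
    """
    v, u = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    ridx = transform.pixel_to_raster(np.column_stack([u.ravel(), v.ravel()]))
    ix = np.rint(ridx[:, 0]).astype(int)
    iy = np.rint(ridx[:, 1]).astype(int)
    nx, ny = smap.grid.counts
    inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    out = np.full(shape[0] * shape[1], np.nan)
    out[inside] = smap.values[iy[inside], ix[inside]]
    return out.reshape(shape)


def overlay_map_on_projection(
    smap: ScalarMap, projection: Image2D, transform: GridTransform, alpha: float
) -> Image2D:
    """Alpha-blend a raster map over a projection.

    The map is resampled nearest-neighbour and min-max rescaled to the
    projection's intensity range over its support before blending;
    alpha = 0 returns the projection unchanged, alpha = 1 the rescaled
    map over its support.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    res = resample_map_to_pixels(smap, projection.values.shape, transform)
    support = np.isfinite(res)
    if not support.any():
        log.warning("map extent lies outside the projection; overlay clipped to nothing")
        return Image2D(projection.values.copy(), projection.pixel_size, "overlay",
                       projection.timestamp)
    composite = projection.values.astype(float).copy()
    lo, hi = np.nanmin(res), np.nanmax(res)
    p_lo, p_hi = float(projection.values.min()), float(projection.values.max())
    scaled = (
        (res - lo) / (hi - lo) * (p_hi - p_lo) + p_lo if hi > lo else np.full_like(res, p_lo)
    )
    composite[support] = (1.0 - alpha) * composite[support] + alpha * scaled[support]
    return Image2D(composite, projection.pixel_size, "overlay", projection.timestamp)


def silhouette_overlap(
    smap: ScalarMap,
    projection: Image2D,
    transform: GridTransform,
    map_threshold: float,
    projection_threshold: float,
) -> Dict[str, float]:
    """Overlap between the high-signal map region and the sample silhouette.

    The silhouette is where transmission drops below
    ``projection_threshold``; comparison is restricted to the raster
    footprint. Returns the Jaccard index and the fraction of
    above-threshold map pixels falling inside the silhouette.
    """
    res = resample_map_to_pixels(smap, projection.values.shape, transform)
    footprint = np.isfinite(res)
    map_on = footprint & (res > map_threshold)
    sil = footprint & (projection.values < projection_threshold)
    union = np.count_nonzero(map_on | sil)
    inter = np.count_nonzero(map_on & sil)
    jacc = inter / union if union else 0.0
    frac = inter / np.count_nonzero(map_on) if map_on.any() else 0.0
    return {"jaccard": float(jacc), "fraction_inside": float(frac)}


# ---------------------------------------------------------------------------
# Gauge volumes
# ---------------------------------------------------------------------------

@dataclass
class GaugeMask:
    """Labelled gauge prisms: 0 = unprobed, k = raster point index + 1."""

    labels: np.ndarray
    voxel_size: float


def _prism_selectors(
    volume: Volume3D, grid: RasterGrid, point: Tuple[int, int], cross_section: str
) -> Tuple[np.ndarray, np.ndarray]:
    ix, iy = point
    px, py = grid.point_xy(ix, iy)
    if cross_section == "beam":
        w, h = grid.beam_size
    elif cross_section == "step":
        w, h = grid.step
    else:
        raise ValueError("cross_section must be 'beam' or 'step'")
    nx, ny, _ = volume.shape
    xc = volume.origin[0] + (np.arange(nx) + 0.5) * volume.voxel_size
    yc = volume.origin[1] + (np.arange(ny) + 0.5) * volume.voxel_size
    return (np.abs(xc - px) <= w / 2.0), (np.abs(yc - py) <= h / 2.0)


def extract_gauge_volume(
    volume: Volume3D,
    grid: RasterGrid,
    point: Tuple[int, int],
    cross_section: str = "beam",
) -> Tuple[GaugeMask, np.ndarray]:
    """Gauge prism of one raster point: mask plus the extracted subvolume.

    The prism is the beam (or step) cross-section extruded along z
    through the full volume depth at the mapping rotation (0 degrees). A
    point beyond the volume footprint yields an empty mask, not an
    error.
    """
    sel_x, sel_y = _prism_selectors(volume, grid, point, cross_section)
    labels = np.zeros(volume.shape, dtype=np.uint16)
    if sel_x.any() and sel_y.any():
        ix, iy = point
        labels[np.ix_(np.flatnonzero(sel_x), np.flatnonzero(sel_y))] = (
            iy * grid.counts[0] + ix + 1
        )
        sub = volume.values[np.ix_(np.flatnonzero(sel_x), np.flatnonzero(sel_y))]
    else:
        log.info("raster point %s outside volume footprint; empty gauge", point)
        sub = np.empty((0, 0, 0))
    return GaugeMask(labels=labels, voxel_size=volume.voxel_size), sub


def build_gauge_mask(
    volume: Volume3D, grid: RasterGrid, cross_section: str = "beam"
) -> GaugeMask:
    """Labelled mask of every raster point's prism (disjoint when beam <= step)."""
    labels = np.zeros(volume.shape, dtype=np.uint16)
    for iy in range(grid.counts[1]):
        for ix in range(grid.counts[0]):
            sel_x, sel_y = _prism_selectors(volume, grid, (ix, iy), cross_section)
            if sel_x.any() and sel_y.any():
                labels[np.ix_(np.flatnonzero(sel_x), np.flatnonzero(sel_y))] = (
                    iy * grid.counts[0] + ix + 1
                )
    return GaugeMask(labels=labels, voxel_size=volume.voxel_size)


@dataclass
class GaugeStats:
    mean: float
    sd: float
    n_voxels: int
    hist_counts: np.ndarray
    hist_edges: np.ndarray


def gauge_statistics(subvolume: np.ndarray, n_bins: int = 64) -> GaugeStats:
    """Summary statistics and gray-level histogram of a gauge subvolume."""
    values = np.asarray(subvolume, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty gauge subvolume")
    counts, edges = np.histogram(values, bins=n_bins)
    return GaugeStats(mean=float(values.mean()), sd=float(values.std()),
                      n_voxels=int(values.size), hist_counts=counts, hist_edges=edges)


# ---------------------------------------------------------------------------
# Time series and cross-modal correlation
# ---------------------------------------------------------------------------

def track_timeseries(
    schedule: Schedule,
    frames: Sequence[Image2D],
    maps: Sequence[Tuple[float, Dict[str, ScalarMap]]],
    roi: Tuple[Tuple[float, float], Tuple[float, float]],
) -> Dict[str, pd.DataFrame]:
    """Per-time curves of both modalities.

    ``frames`` are time-stamped projections; ``maps`` is a sequence of
    (timestamp, {quantity: ScalarMap}); ``roi`` is the window box
    ((x0, x1), (y0, y1)) in lab micrometres. Returns an imaging table
    (ROI mean transmission) and a diffraction table (per-point (002)
    amplitude and total intensity versus time).
    """
    if len(frames) < 2 or len(maps) < 2:
        raise ValueError("need >= 2 time points per modality")
    t_img = [f.timestamp for f in frames]
    if np.any(np.diff(t_img) < 0) or np.any(np.diff([t for t, _ in maps]) < 0):
        raise ValueError("timestamps must be ordered")
    (x0, x1), (y0, y1) = roi
    rows = []
    for f in frames:
        px = f.pixel_size
        u0, u1 = int(np.floor(x0 / px)), int(np.ceil(x1 / px))
        v0, v1 = int(np.floor(y0 / px)), int(np.ceil(y1 / px))
        patch = f.values[max(v0, 0): v1, max(u0, 0): u1]
        rows.append({"t_s": f.timestamp, "roi_mean": float(patch.mean()),
                     "roi_attenuation": float(-np.log(np.clip(patch.mean(), 1e-9, None)))})
    imaging = pd.DataFrame(rows)
    drows = []
    for t, bundle in maps:
        amp = bundle["peak002_intensity"]
        tot = bundle["total_intensity"]
        ny_, nx_ = amp.values.shape
        for iy in range(ny_):
            for ix in range(nx_):
                drows.append({
                    "t_s": t, "ix": ix, "iy": iy,
                    "amp002": amp.values[iy, ix],
                    "total_intensity": tot.values[iy, ix],
                    "valid": bool(amp.valid[iy, ix]),
                })
    return {"imaging": imaging, "diffraction": pd.DataFrame(drows)}


@dataclass
class CorrelationResult:
    coefficient: float
    n: int
    table: pd.DataFrame


def cross_modal_correlation(
    delta_attenuation: np.ndarray,
    delta_waxs: np.ndarray,
    valid: Optional[np.ndarray] = None,
) -> CorrelationResult:
    """Pearson correlation between per-point attenuation and WAXS changes."""
    a = np.asarray(delta_attenuation, dtype=float).ravel()
    w = np.asarray(delta_waxs, dtype=float).ravel()
    if a.shape != w.shape:
        raise ValueError("per-point vectors must match in length")
    keep = np.isfinite(a) & np.isfinite(w)
    if valid is not None:
        keep &= np.asarray(valid, dtype=bool).ravel()
    a, w = a[keep], w[keep]
    if a.size < 3:
        raise ValueError("correlation needs >= 3 valid points")
    if np.allclose(a, a[0]) or np.allclose(w, w[0]):
        raise ValueError("degenerate input: a modality shows no variance across points")
    r, _ = stats.pearsonr(a, w)
    table = pd.DataFrame({"delta_attenuation": a, "delta_waxs": w})
    return CorrelationResult(coefficient=float(r), n=int(a.size), table=table)
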