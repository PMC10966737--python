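"""Shared domain types for the correlative imaging/diffraction pipeline.

Conventions used throughout the package:

* Lab frame is right-handed: ``x`` horizontal (transverse to the beam),
  ``y`` vertical, ``z`` along the beam at rotation angle 0.
* All physical lengths are micrometres unless a field says otherwise
  (sample-to-detector distance is in centimetres, matching how the
  instrument geometry is normally quoted).
* Angles are degrees in every public interface; radians appear only
  inside numerical kernels.
* Pixel and voxel indices are 0-based and refer to element centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

#: hc in keV * Angstrom; converts photon energy to wavelength.
HC_KEV_ANGSTROM = 12.398419843320026

#: Frame roles understood by :class:`Image2D`.
FRAME_ROLES = ("projection", "flat", "dark", "waxs", "calibrant", "mask", "overlay")

#: Sentinel written into detector-gap pixels of simulated patterns.
GAP_SENTINEL = -1.0


def energy_to_wavelength(energy_kev: float) -> float:
    """Photon wavelength in Angstrom for an energy in keV."""
    if energy_kev <= 0:
        raise ValueError(f"photon energy must be positive, got {energy_kev}")
    return HC_KEV_ANGSTROM / energy_kev


@dataclass(frozen=True)
class DetectorGeometry:
    """Geometry of the diffraction (WAXS) detector.

    Parameters
    ----------
    energy : float
        Photon energy, keV.
    distance : float
        Sample-to-detector distance, cm.
    beam_center : (float, float)
        Direct-beam position on the detector as (x, y) in pixels;
        fractional values allowed.
    pixel_pitch : (float, float)
        Detector pixel size (x, y), micrometres.
    """

    energy: float
    distance: float
    beam_center: Tuple[float, float]
    pixel_pitch: Tuple[float, float] = (172.0, 172.0)

    def __post_init__(self) -> None:
        if self.energy <= 0:
            raise ValueError("energy must be > 0 keV")
        if self.distance <= 0:
            raise ValueError("sample-to-detector distance must be > 0 cm")
        if any(p <= 0 for p in self.pixel_pitch):
            raise ValueError("pixel_pitch must be > 0")
        object.__setattr__(self, "beam_center", tuple(float(c) for c in self.beam_center))
        object.__setattr__(self, "pixel_pitch", tuple(float(p) for p in self.pixel_pitch))

    @property
    def wavelength(self) -> float:
        """Wavelength in Angstrom, derived from the photon energy."""
        return energy_to_wavelength(self.energy)

    @property
    def distance_um(self) -> float:
        return self.distance * 1.0e4

    def two_theta(self, d_spacing: float) -> float:
        """Scattering angle 2-theta (degrees) for a lattice spacing d (Angstrom).

        Bragg's law: lambda = 2 d sin(theta).
        """
        s = self.wavelength / (2.0 * d_spacing)
        if not 0 < s <= 1:
            raise ValueError(
                f"d = {d_spacing} Angstrom unreachable at lambda = {self.wavelength:.4f}"
            )
        return float(np.degrees(2.0 * np.arcsin(s)))

    def ring_radius_pixels(self, d_spacing: float) -> float:
        """Debye-Scherrer ring radius in pixels: r = D tan(2 theta)."""
        tth = np.radians(self.two_theta(d_spacing))
        return float(self.distance_um * np.tan(tth) / self.pixel_pitch[0])

    def q_of_radius(self, r_pixels: np.ndarray | float) -> np.ndarray | float:
        """Scattering vector q (1/Angstrom) at radius r (pixels) from the beam centre."""
        r_um = np.asarray(r_pixels, dtype=float) * self.pixel_pitch[0]
        tth = np.arctan2(r_um, self.distance_um)
        q = (4.0 * np.pi / self.wavelength) * np.sin(tth / 2.0)
        return q if np.ndim(r_pixels) else float(q)

    def replace(self, **kw) -> "DetectorGeometry":
        from dataclasses import replace as _replace

        return _replace(self, **kw)


@dataclass(frozen=True)
class GapSpec:
    """Insensitive inter-module strips of a tiled pixel detector.

    ``row_gaps`` / ``col_gaps`` list (start, width) pixel bands of dead
    rows / columns. Simulated patterns carry :data:`GAP_SENTINEL` there;
    masks exclude them.
    """

    row_gaps: Tuple[Tuple[int, int], ...] = ()
    col_gaps: Tuple[Tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "row_gaps", tuple((int(s), int(w)) for s, w in self.row_gaps)
        )
        object.__setattr__(
            self, "col_gaps", tuple((int(s), int(w)) for s, w in self.col_gaps)
        )
        for s, w in self.row_gaps + self.col_gaps:
            if s < 0 or w < 1:
                raise ValueError("gap bands need start >= 0 and width >= 1")

    @classmethod
    def periodic(cls, shape: Tuple[int, int], module_shape: Tuple[int, int],
                 gap_width: Tuple[int, int]) -> "GapSpec":
        """Regular module tiling: modules of ``module_shape`` separated by gaps."""
        rows = []
        r = module_shape[0]
        while r < shape[0]:
            rows.append((r, gap_width[0]))
            r += module_shape[0] + gap_width[0]
        cols = []
        c = module_shape[1]
        while c < shape[1]:
            cols.append((c, gap_width[1]))
            c += module_shape[1] + gap_width[1]
        return cls(row_gaps=tuple(rows), col_gaps=tuple(cols))

    def gap_mask(self, shape: Tuple[int, int]) -> np.ndarray:
        """Boolean array, True on gap pixels."""
        gap = np.zeros(shape, dtype=bool)
        for s, w in self.row_gaps:
            gap[s : s + w, :] = True
        for s, w in self.col_gaps:
            gap[:, s : s + w] = True
        return gap


def make_angle_list(start: float = 0.0, stop: float = 180.0, step: float = 0.1) -> np.ndarray:
    """Inclusive list of projection angles in degrees.

    A 0-180 degree scan at 0.1 degree steps yields 1801 projections.
    """
    if step <= 0:
        raise ValueError("angle step must be > 0")
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


@dataclass(frozen=True)
class ImagingGeometry:
    """Geometry of the full-field imaging branch.

    ``pixel_size`` is the effective pixel size at the sample, micrometres.
    """

    pixel_size: float
    n_u: int
    n_v: int
    angle_list: np.ndarray = field(default_factory=make_angle_list)
    energy: float = 22.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_u < 1 or self.n_v < 1:
            raise ValueError("projection dimensions must be >= 1")
        angles = np.asarray(self.angle_list, dtype=float)
        if angles.ndim != 1 or angles.size < 1:
            raise ValueError("angle_list must be a 1-D sequence")
        if np.any(np.diff(angles) <= 0):
            raise ValueError("angle_list must be strictly increasing")
        if angles[0] < 0 or angles[-1] > 180:
            raise ValueError("projection angles must lie within [0, 180] degrees")
        object.__setattr__(self, "angle_list", angles)

    @property
    def n_angles(self) -> int:
        return int(self.angle_list.size)

    @property
    def fov_mm(self) -> Tuple[float, float]:
        """Field of view (horizontal, vertical) in millimetres."""
        return (self.n_u * self.pixel_size / 1000.0, self.n_v * self.pixel_size / 1000.0)


@dataclass
class Image2D:
    """A single detector frame with physical pixel size and role metadata."""

    values: np.ndarray
    pixel_size: float
    frame_tag: str = "projection"
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("Image2D requires a 2-D array")
        if self.frame_tag not in FRAME_ROLES:
            raise ValueError(f"unknown frame role {self.frame_tag!r}; expected one of {FRAME_ROLES}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class Volume3D:
    """Reconstructed voxel grid, indexed ``values[x, y, z]`` in the lab frame.

    ``origin`` is the lab-frame coordinate of the centre of voxel (0, 0, 0),
    micrometres.
    """

    values: np.ndarray
    voxel_size: float
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("Volume3D requires a 3-D array")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        self.origin = tuple(float(c) for c in self.origin)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


def volume_shape_for(n_u: int, n_v: int) -> Tuple[int, int, int]:
    """Reconstructed-volume shape implied by projection dimensions.

    Parallel-beam FBP of n_u-wide, n_v-tall projections yields an
    (n_u, n_v, n_u) voxel grid — e.g. 2560 x 2160 projections give a
    2560 x 2160 x 2560 volume.
    """
    return (int(n_u), int(n_v), int(n_u))


@dataclass(frozen=True)
class RasterGrid:
    """Diffraction mapping grid in the unified lab frame.

    ``origin`` is the lab (x, y) of the first raster point, micrometres;
    ``step`` is (horizontal, vertical) spacing; ``counts`` is (nx, ny);
    ``beam_size`` the beam footprint (width, height).
    """

    origin: Tuple[float, float]
    step: Tuple[float, float]
    counts: Tuple[int, int]
    beam_size: Tuple[float, float] = (25.0, 25.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.step):
            raise ValueError("raster steps must be > 0")
        if any(c < 1 for c in self.counts):
            raise ValueError("raster counts must be >= 1")
        if any(b <= 0 for b in self.beam_size):
            raise ValueError("beam_size must be > 0")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "step", tuple(float(v) for v in self.step))
        object.__setattr__(self, "counts", tuple(int(v) for v in self.counts))
        object.__setattr__(self, "beam_size", tuple(float(v) for v in self.beam_size))

    @property
    def n_points(self) -> int:
        return self.counts[0] * self.counts[1]

    @property
    def non_overlapping(self) -> bool:
        """True when adjacent beam footprints cannot overlap (beam <= step)."""
        return self.beam_size[0] <= self.step[0] and self.beam_size[1] <= self.step[1]

    def point_xy(self, ix: int, iy: int) -> Tuple[float, float]:
        """Lab-frame (x, y) of raster point (ix, iy), micrometres."""
        if not (0 <= ix < self.counts[0] and 0 <= iy < self.counts[1]):
            raise IndexError(f"raster index ({ix}, {iy}) outside grid {self.counts}")
        return (self.origin[0] + ix * self.step[0], self.origin[1] + iy * self.step[1])

    def all_points(self) -> np.ndarray:
        """(n_points, 2) array of lab (x, y), raster-major order (iy outer, ix inner)."""
        xs = self.origin[0] + self.step[0] * np.arange(self.counts[0])
        ys = self.origin[1] + self.step[1] * np.arange(self.counts[1])
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass
class Diffractogram1D:
    """Azimuthally integrated 1-D pattern I(q).

    ``intensity`` is the *mean* counts per q bin (not the sum) so that
    detector-gap coverage differences do not masquerade as intensity
    changes; ``coverage`` records the number of contributing pixels and
    ``valid`` flags bins whose coverage passes the configured minimum.
    """

    q: np.ndarray
    intensity: np.ndarray
    coverage: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q bin centres must be strictly increasing")
        for name in ("intensity", "coverage", "valid"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != self.q.shape:
                raise ValueError(f"{name} must match q in shape")
            setattr(self, name, arr)

    @property
    def d_spacing(self) -> np.ndarray:
        """Lattice-spacing axis, d = 2 pi / q (Angstrom)."""
        return 2.0 * np.pi / self.q


@dataclass
class AzimuthalProfile:
    """Intensity versus azimuth phi within a q annulus (texture profile).

    phi is measured counterclockwise from the detector +x axis, degrees,
    wrapped to [0, 360).
    """

    phi: np.ndarray
    intensity: np.ndarray
    q_window: Tuple[float, float]
    phi_range: float
    coverage: Optional[np.ndarray] = None
    valid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.phi = np.mod(np.asarray(self.phi, dtype=float), 360.0)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.phi.shape != self.intensity.shape:
            raise ValueError("phi and intensity must match in shape")
        if self.coverage is None:
            self.coverage = np.ones_like(self.intensity)
        if self.valid is None:
            self.valid = np.ones(self.intensity.shape, dtype=bool)


@dataclass
class PeakFit:
    """Fitted single-peak model over a q window (peak + linear background)."""

    center: float
    amplitude: float
    fwhm: float
    eta: float
    background: Tuple[float, float]
    rss: float
    converged: bool = True

    def __post_init__(self) -> None:
        if self.converged:
            if self.amplitude < 0:
                raise ValueError("amplitude must be >= 0")
            if self.fwhm <= 0:
                raise ValueError("fwhm must be > 0")
            if not 0.0 <= self.eta <= 1.0:
                raise ValueError("eta must lie in [0, 1]")


@dataclass
class ScalarMap:
    """Per-raster-point scalar quantity laid out as a (ny, nx) image."""

    values: np.ndarray
    grid: RasterGrid
    quantity: str
    valid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        nx, ny = self.grid.counts
        if self.values.shape != (ny, nx):
            raise ValueError(
                f"map shape {self.values.shape} does not match grid counts (ny={ny}, nx={nx})"
            )
        if self.valid is None:
            self.valid = np.ones_like(self.values, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values.shape:
                raise ValueError("validity mask must match map shape")
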