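"""Digital enamel phantom with acid-demineralization kinetics.

The phantom is a slab of enamel-like material: quasi-hexagonally packed
rods (~5 um across, bundles of co-aligned hydroxyapatite crystallites)
running along the lab x axis, embedded in inter-rod substance with a
slightly lower mineral volume fraction and weaker texture. A window on
the +x face of the slab is exposed to acid; demineralization advances as
a geometric front from that face, faster along the rods than through the
inter-rod substance (preferential rod dissolution). Kinetics are a
front-advance model with per-label rates — a morphological emulation,
not reaction-diffusion chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

Box = Tuple[Tuple[float, float], Tuple[float, float], Tuple[float, float]]

#: voxel label values
LBL_BACKGROUND = 0
LBL_ROD = 1
LBL_INTER_ROD = 2
LBL_LIQUID = 3


@dataclass
class DeminParams:
    """Front-advance demineralization rates.

    rate_rod and rate_inter are front speeds (um/s) along the rod axis in
    rod and inter-rod voxels; ``softening`` is the residual density
    multiplier left behind the front (0 = complete dissolution).
    """

    rate_rod: float = 8.0e-4
    rate_inter: float = 4.0e-4
    softening: float = 0.12

    def __post_init__(self) -> None:
        # preferential rod dissolution; both rates may be zero (no acid attack)
        if self.rate_inter < 0 or self.rate_rod < self.rate_inter:
            raise ValueError("preferential rod dissolution requires rate_rod >= rate_inter >= 0")
        if self.rate_rod == self.rate_inter != 0:
            raise ValueError("preferential rod dissolution requires rate_rod > rate_inter")
        if not 0.0 <= self.softening < 1.0:
            raise ValueError("softening must lie in [0, 1)")


@dataclass
class Phantom:
    """Mineral-density field with rod/inter-rod labels and a lesion window.

    ``density`` is mineral volume fraction in [0, 1]; ``density0`` the
    pristine field before any acid exposure; ``t`` the exposure time (s)
    already applied. ``window`` is an axis-aligned box in lab um; acid
    enters through the +x face of the slab over the window's (y, z)
    extent. ``mu_mineral`` is the linear attenuation coefficient of fully
    mineralized tissue at the imaging energy (1/um).
    """

    density: np.ndarray
    labels: np.ndarray
    voxel_size: float
    window: Optional[Box] = None
    mu_mineral: float = 1.1e-3
    immersed: bool = False
    t: float = 0.0
    density0: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    face_x: float = 0.0  # lab x (um) of the exposed slab face

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.density.shape != self.labels.shape:
            raise ValueError("density and labels must share a shape")
        if self.density.min() < 0 or self.density.max() > 1:
            raise ValueError("density must lie in [0, 1]")
        if self.density0 is None:
            self.density0 = self.density.copy()

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.density.shape  # type: ignore[return-value]

    @property
    def support(self) -> np.ndarray:
        """Voxels belonging to the sample (rod or inter-rod)."""
        return (self.labels == LBL_ROD) | (self.labels == LBL_INTER_ROD)

    @property
    def mu(self) -> np.ndarray:
        """Linear attenuation field (1/um), float64."""
        return self.mu_mineral * self.density.astype(np.float64)

    def liquid_fraction(self) -> np.ndarray:
        """Per-voxel liquid volume fraction (drives the WAXS background).

        When immersed, liquid fills everything outside the sample support
        and the pore space opened by demineralization inside it.
        """
        frac = np.zeros(self.shape, dtype=np.float32)
        if self.immersed:
            frac[~self.support] = 1.0
            sup = self.support
            frac[sup] = np.clip(self.density0[sup] - self.density[sup], 0.0, 1.0)
        return frac

    def total_mineral_mass(self) -> float:
        """Integral of density over the volume (um^3 of mineral)."""
        return float(self.density.sum(dtype=np.float64) * self.voxel_size**3)

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Lab coordinates (um) of voxel centres along one axis."""
        return (np.arange(self.shape[axis]) + 0.5) * self.voxel_size


def _hex_rod_centers(
    extent_y: float, extent_z: float, pitch: float, rng: np.random.Generator, jitter: float
) -> np.ndarray:
    """Quasi-hexagonal lattice of rod centres in the (y, z) plane, um."""
    dy = pitch
    dz = pitch * np.sqrt(3.0) / 2.0
    n_rows = int(np.ceil(extent_z / dz)) + 2
    n_cols = int(np.ceil(extent_y / dy)) + 2
    centers = []
    for r in range(n_rows):
        off = 0.5 * dy if r % 2 else 0.0
        for c in range(n_cols):
            centers.append(((c - 0.5) * dy + off, (r - 0.5) * dz))
    centers = np.asarray(centers)
    centers += rng.normal(scale=jitter * pitch, size=centers.shape)
    return centers


def build_enamel_phantom(
    size: Tuple[int, int, int],
    voxel_size: float,
    rod_pitch: float = 5.0,
    window: Optional[Box] = None,
    seed: int = 0,
    slab: Optional[Box] = None,
    rod_density: float = 0.95,
    inter_rod_density: float = 0.80,
    rod_radius_frac: float = 0.44,
    center_jitter: float = 0.04,
    density_noise: float = 0.01,
    mu_mineral: float = 1.1e-3,
    immersed: bool = False,
) -> Phantom:
    """Build the pristine enamel slab phantom.

    Parameters
    ----------
    size : (nx, ny, nz)
        Voxel counts along lab x, y, z.
    voxel_size : float
        Isotropic voxel size, um. Must satisfy ``rod_pitch >= 2 * voxel_size``.
    rod_pitch : float
        Spacing of the quasi-hexagonal rod lattice, um. Rod cross-sections
        have diameter ~ ``2 * rod_radius_frac * rod_pitch``.
    window : box or None
        Lesion-exposure box in lab um; only its (y, z) extent selects the
        exposed area on the slab's +x face. Must intersect the slab.
    slab : box or None
        Sample support box in lab um. Default: central 60% in x, full y,
        central 40% in z.
    """
    nx, ny, nz = size
    if rod_pitch < 2 * voxel_size:
        raise ValueError("rod_pitch must be at least 2 voxels for a resolvable rod lattice")
    rng = np.random.default_rng(seed)
    ext = np.array(size) * voxel_size

    if slab is None:
        slab = (
            (0.20 * ext[0], 0.80 * ext[0]),
            (0.0, ext[1]),
            (0.30 * ext[2], 0.70 * ext[2]),
        )
    (sx0, sx1), (sy0, sy1), (sz0, sz1) = slab

    x = (np.arange(nx) + 0.5) * voxel_size
    y = (np.arange(ny) + 0.5) * voxel_size
    z = (np.arange(nz) + 0.5) * voxel_size
    in_x = (x >= sx0) & (x < sx1)
    in_y = (y >= sy0) & (y < sy1)
    in_z = (z >= sz0) & (z < sz1)
    support = in_x[:, None, None] & in_y[None, :, None] & in_z[None, None, :]

    # rods run along x; classify (y, z) by distance to the nearest rod centre
    centers = _hex_rod_centers(sy1 - sy0, sz1 - sz0, rod_pitch, rng, center_jitter)
    yy, zz = np.meshgrid(y - sy0, z - sz0, indexing="ij")
    pts = np.column_stack([yy.ravel(), zz.ravel()])
    from scipy.spatial import cKDTree

    dist, _ = cKDTree(centers).query(pts, k=1)
    rod_yz = (dist.reshape(ny, nz) <= rod_radius_frac * rod_pitch)

    labels = np.zeros(size, dtype=np.uint8)
    labels[support] = LBL_INTER_ROD
    rod3 = support & rod_yz[None, :, :]
    labels[rod3] = LBL_ROD
    if immersed:
        labels[~support] = LBL_LIQUID

    density = np.zeros(size, dtype=np.float32)
    density[labels == LBL_ROD] = rod_density
    density[labels == LBL_INTER_ROD] = inter_rod_density
    if density_noise > 0:
        noise = rng.normal(scale=density_noise, size=size).astype(np.float32)
        density[support] = np.clip(density[support] + noise[support], 0.0, 1.0)

    if window is not None:
        (wy0, wy1) = window[1]
        (wz0, wz1) = window[2]
        if wy1 <= sy0 or wy0 >= sy1 or wz1 <= sz0 or wz0 >= sz1:
            raise ValueError("lesion window lies outside the slab support")

    return Phantom(
        density=density,
        labels=labels,
        voxel_size=voxel_size,
        window=window,
        mu_mineral=mu_mineral,
        immersed=immersed,
        face_x=sx1,
    )


def evolve_demineralization(phantom: Phantom, t: float, params: DeminParams) -> Phantom:
    """Phantom state after ``t`` seconds of acid exposure (from t = 0).

    The front advances from the exposed +x face into the slab, by
    ``rate_rod * t`` in rod voxels and ``rate_inter * t`` in inter-rod
    voxels, within the window's (y, z) extent. Behind the front the
    density is multiplied by ``softening``; the voxel straddling the
    front is attenuated proportionally to its submerged fraction, so the
    front position is resolved below the voxel size on average.
    """
    if t < 0:
        raise ValueError("exposure time must be >= 0")
    if t == 0:
        return replace(phantom, density=phantom.density0.copy(), t=0.0, density0=phantom.density0)
    if phantom.window is None:
        return replace(phantom, t=float(t))

    (wy0, wy1) = phantom.window[1]
    (wz0, wz1) = phantom.window[2]
    y = phantom.voxel_centers(1)
    z = phantom.voxel_centers(2)
    in_window = ((y >= wy0) & (y < wy1))[None, :, None] & ((z >= wz0) & (z < wz1))[None, None, :]

    x = phantom.voxel_centers(0)
    depth = phantom.face_x - x  # um behind the exposed face
    dx = phantom.voxel_size

    density = phantom.density0.astype(np.float64).copy()
    for lbl, rate in ((LBL_ROD, params.rate_rod), (LBL_INTER_ROD, params.rate_inter)):
        front = rate * t
        # fraction of each voxel behind the front, in [0, 1]
        frac = np.clip((front - (depth - 0.5 * dx)) / dx, 0.0, 1.0)
        factor = 1.0 - frac * (1.0 - params.softening)
        sel = (phantom.labels == lbl) & in_window
        density[sel] *= np.broadcast_to(factor[:, None, None], density.shape)[sel]

    return replace(
        phantom,
        density=density.astype(np.float32),
        t=float(t),
        density0=phantom.density0,
    )


def measured_rod_diameters(phantom: Phantom) -> np.ndarray:
    """Equivalent-circle diameters (um) of rod cross-sections.

    Labels a mid-slab (y, z) cross-section and returns one diameter per
    connected rod region not touching the slab boundary.
    """
    from scipy import ndimage

    ix = int(np.argmax((phantom.labels == LBL_ROD).sum(axis=(1, 2))))
    section = phantom.labels[ix] == LBL_ROD
    lab, n = ndimage.label(section)
    if n == 0:
        return np.array([])
    support2d = (phantom.labels[ix] != LBL_BACKGROUND) & (phantom.labels[ix] != LBL_LIQUID)
    edge_labels = set(np.unique(lab[~support2d])) | set(np.unique(lab[[0, -1], :])) | set(
        np.unique(lab[:, [0, -1]])
    )
    areas = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
    diam = []
    for i, a in enumerate(areas, start=1):
        if i in edge_labels:
            continue
        diam.append(2.0 * np.sqrt(a * phantom.voxel_size**2 / np.pi))
    return np.asarray(diam)
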