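"""Flat/dark correction and parallel-beam filtered back-projection.

The reconstruction is a classical FBP: -log of the corrected
transmission, frequency-domain ramp (optionally Hann-apodized) filtering
with zero-padding to the next power of two, then linear-interpolation
back-projection about a vertical axis through column (n_u - 1) / 2.
Geometry matches the forward projector in :mod:`enamelmap.simulate`, so
projector -> FBP round trips are self-consistent. Output voxel values
are linear attenuation per micrometre.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy import ndimage

from .geometry import Image2D, Volume3D

log = logging.getLogger("enamelmap")


@dataclass
class Sinogram:
    """Per-slice-row sinogram: values[(angle, u)] with its angle list (degrees)."""

    values: np.ndarray
    angles: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.values.shape[0] != self.angles.size:
            raise ValueError("sinogram row count must equal the number of angles")


def correct_projections(
    raw: Sequence[Image2D],
    flats: Sequence[Image2D],
    darks: Sequence[Image2D],
    floor: float = 1.0e-6,
) -> List[Image2D]:
    """Flat/dark-correct raw projections to transmission images.

    corrected = (raw - mean(darks)) / (mean(flats) - mean(darks)), clipped
    to a positive floor. Pixels where the flat does not exceed the dark
    are inpainted with a local median of the denominator and counted in
    the log.
    """
    if not flats or not darks:
        raise ValueError("need at least one flat and one dark frame")
    shapes = {f.values.shape for f in list(raw) + list(flats) + list(darks)}
    if len(shapes) != 1:
        raise ValueError(f"frame dimensions differ across stacks: {sorted(shapes)}")
    dark_m = np.mean([d.values for d in darks], axis=0)
    flat_m = np.mean([f.values for f in flats], axis=0)
    denom = flat_m - dark_m
    bad = denom <= 0
    if bad.any():
        filled = ndimage.median_filter(denom, size=5)
        denom = np.where(bad, filled, denom)
        denom = np.where(denom <= 0, np.median(denom[denom > 0]), denom)
        log.warning("flat-dark correction: %d non-positive pixels inpainted", int(bad.sum()))
    out = []
    for frame in raw:
        corrected = np.clip((frame.values - dark_m) / denom, floor, None)
        out.append(Image2D(corrected, frame.pixel_size, "projection", frame.timestamp))
    return out


def _ramp_filter(n: int) -> np.ndarray:
    """Frequency response of the discrete ramp filter (Kak & Slaney)."""
    k = np.concatenate([np.arange(1, n // 2 + 1, 2), np.arange(n // 2 - 1, 0, -2)])
    f = np.zeros(n)
    f[0] = 0.25
    f[1::2] = -1.0 / (np.pi * k) ** 2
    return 2.0 * np.real(np.fft.fft(f))


def filter_sinogram(sino: np.ndarray, filter_name: str = "ramp") -> np.ndarray:
    """Apply the FBP filter along the detector axis (last axis)."""
    n_u = sino.shape[-1]
    size = max(64, int(2 ** np.ceil(np.log2(2 * n_u))))
    resp = _ramp_filter(size)
    if filter_name == "hann":
        freq = np.fft.fftfreq(size)
        resp = resp * (0.5 + 0.5 * np.cos(2.0 * np.pi * freq))  # Hann taper, 1 at DC
    elif filter_name != "ramp":
        raise ValueError(f"unknown filter {filter_name!r}; use 'ramp' or 'hann'")
    pad = [(0, 0)] * (sino.ndim - 1) + [(0, size - n_u)]
    padded = np.pad(sino, pad)
    filtered = np.real(np.fft.ifft(np.fft.fft(padded, axis=-1) * resp, axis=-1))
    return filtered[..., :n_u]


def fbp_slice(
    sinogram: Sinogram, filter_name: str = "ramp", cor_offset: float = 0.0
) -> np.ndarray:
    """Reconstruct a single (n_u, n_u) slice from its sinogram."""
    vol = _backproject(
        filter_sinogram(sinogram.values, filter_name)[:, None, :],
        sinogram.angles,
        cor_offset,
    )
    return vol[:, 0, :]


def _backproject(filtered: np.ndarray, angles: np.ndarray, cor_offset: float) -> np.ndarray:
    """Back-project filtered projections (n_angles, n_v, n_u) to (n_u, n_v, n_u)."""
    n_angles, n_v, n_u = filtered.shape
    c = (n_u - 1) / 2.0 + cor_offset
    xg = np.arange(n_u) - c
    vol = np.zeros((n_u, n_v, n_u))
    for a, th in enumerate(np.radians(angles)):
        t = xg[:, None] * np.cos(th) + xg[None, :] * np.sin(th) + c  # (x, z)
        i0 = np.floor(t).astype(np.int64)
        w1 = t - i0
        i0c = np.clip(i0, 0, n_u - 1)
        i1c = np.clip(i0 + 1, 0, n_u - 1)
        inside = (t >= 0) & (t <= n_u - 1)
        p = filtered[a]  # (n_v, n_u)
        contrib = p[:, i0c] * (1.0 - w1)[None, :, :] + p[:, i1c] * w1[None, :, :]
        contrib *= inside[None, :, :]
        vol += np.moveaxis(contrib, 0, 1)
    return vol * np.pi / (2.0 * n_angles)


def reconstruct_fbp(
    projections: Sequence[Image2D],
    angles: Sequence[float],
    filter_name: str = "ramp",
    cor_offset: float = 0.0,
    transmission_floor: float = 1.0e-6,
) -> Volume3D:
    """Filtered back-projection of corrected transmission projections.

    Projections are -log transformed internally (transmission clipped at
    ``transmission_floor``). The output volume has shape
    (n_u, n_v, n_u) — in-plane dimensions equal the projection width —
    and voxel size equal to the projection pixel size, with values in
    attenuation per micrometre.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size < 2:
        raise ValueError("reconstruction requires at least 2 projection angles")
    if angles.size != len(projections):
        raise ValueError("angle count must match the number of projections")
    px = projections[0].pixel_size
    sino = np.stack([
        -np.log(np.clip(p.values, transmission_floor, None)) for p in projections
    ])  # (n_angles, n_v, n_u)
    filtered = filter_sinogram(sino, filter_name)
    vol = _backproject(filtered, angles, cor_offset)
    return Volume3D(values=vol / px, voxel_size=px)
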