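"""File readers and writers.

Two interchange dialects are supported for frame stacks:

* a directory of numbered single-page TIFFs (or one multi-page TIFF),
* an HDF5 container with groups ``/projections``, ``/flats``, ``/darks``,
  ``/waxs/<iy>_<ix>`` and ``/meta`` (our own layout; documented in
  ``docs/methods.md``).

1-D curves and raster maps travel as headered CSV ('.' decimal, comma
separated). Volumes are written as multi-page 32-bit TIFF.
"""

from __future__ import annotations

import logging
import os
import re
from pathlib import Path
from typing import List, Optional, Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile

from .geometry import (
    AzimuthalProfile,
    Diffractogram1D,
    Image2D,
    RasterGrid,
    ScalarMap,
    Volume3D,
)

log = logging.getLogger("enamelmap")


class FormatError(RuntimeError):
    """Raised when on-disk data violate the declared layout."""


_TIFF_RE = re.compile(r"(\d+)\D*\.tiff?$", re.IGNORECASE)


def _frame_index(name: str) -> int:
    m = _TIFF_RE.search(name)
    return int(m.group(1)) if m else -1


def write_image_stack(path: os.PathLike, frames: Sequence[Image2D], prefix: str = "frame") -> None:
    """Write frames as numbered single-page TIFFs under a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(len(frames))))
    for i, frame in enumerate(frames):
        tifffile.imwrite(path / f"{prefix}_{i:0{width}d}.tif", frame.values)


def read_image_stack(
    path: os.PathLike,
    role: str = "projection",
    pixel_size: Optional[float] = None,
    expected_count: Optional[int] = None,
) -> List[Image2D]:
    """Read an ordered TIFF stack (directory of TIFFs or one multi-page file).

    TIFF carries no pixel-size metadata in our dialect, so ``pixel_size``
    must be supplied (micrometres).

    Raises
    ------
    FormatError
        If frames have mixed dimensions, or ``expected_count`` frames were
        declared and one is missing (the error names the missing index).
    ValueError
        If ``pixel_size`` is not given.
    """
    if pixel_size is None:
        raise ValueError("pixel_size metadata is required to read a TIFF stack")
    path = Path(path)
    if path.is_dir():
        names = sorted(
            (p for p in path.iterdir() if _TIFF_RE.search(p.name)),
            key=lambda p: _frame_index(p.name),
        )
        if not names:
            raise FormatError(f"no TIFF frames found under {path}")
        if expected_count is not None:
            indices = [_frame_index(p.name) for p in names]
            expected = set(range(min(indices), min(indices) + expected_count))
            missing = sorted(expected - set(indices))
            if missing:
                raise FormatError(
                    f"{expected_count} frames declared but frame index {missing[0]} is missing"
                )
        arrays = [tifffile.imread(p) for p in names]
    else:
        arrays = list(tifffile.imread(path))
        if expected_count is not None and len(arrays) != expected_count:
            raise FormatError(
                f"{expected_count} frames declared but frame index {len(arrays)} is missing"
            )
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise FormatError(f"mixed frame dimensions in stack: {sorted(shapes)}")
    return [
        Image2D(values=a, pixel_size=pixel_size, frame_tag=role, timestamp=float(i))
        for i, a in enumerate(arrays)
    ]


def write_volume(path: os.PathLike, volume: Volume3D) -> None:
    """Write a volume as a multi-page 32-bit TIFF (pages along x)."""
    tifffile.imwrite(Path(path), volume.values.astype(np.float32))


def read_volume(path: os.PathLike, voxel_size: float) -> Volume3D:
    values = tifffile.imread(Path(path))
    return Volume3D(values=np.asarray(values), voxel_size=voxel_size)


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def write_container(
    path: os.PathLike,
    projections: Optional[Sequence[Image2D]] = None,
    flats: Optional[Sequence[Image2D]] = None,
    darks: Optional[Sequence[Image2D]] = None,
    waxs: Optional[dict] = None,
    meta: Optional[dict] = None,
) -> None:
    """Write the experiment container.

    ``waxs`` maps ``(iy, ix)`` raster indices to :class:`Image2D`;
    ``meta`` is a flat dict of scalars/strings stored as attributes.
    """
    with h5py.File(Path(path), "w") as f:
        for name, frames in (("projections", projections), ("flats", flats), ("darks", darks)):
            if frames:
                g = f.create_group(name)
                g.create_dataset("data", data=np.stack([fr.values for fr in frames]))
                g.create_dataset("timestamps", data=np.array([fr.timestamp for fr in frames]))
                g.attrs["pixel_size_um"] = frames[0].pixel_size
        if waxs:
            g = f.create_group("waxs")
            for (iy, ix), frame in waxs.items():
                d = g.create_dataset(f"{iy}_{ix}", data=frame.values)
                d.attrs["timestamp_s"] = frame.timestamp
                d.attrs["pixel_size_um"] = frame.pixel_size
        if meta:
            g = f.require_group("meta")
            for k, v in meta.items():
                g.attrs[k] = v


def read_container_frames(path: os.PathLike, group: str, role: str) -> List[Image2D]:
    with h5py.File(Path(path), "r") as f:
        if group not in f:
            raise FormatError(f"group /{group} not present in {path}")
        g = f[group]
        data = np.asarray(g["data"])
        times = np.asarray(g["timestamps"]) if "timestamps" in g else np.arange(len(data))
        px = float(g.attrs.get("pixel_size_um", 1.0))
    return [
        Image2D(values=a, pixel_size=px, frame_tag=role, timestamp=float(t))
        for a, t in zip(data, times)
    ]


def read_container_waxs(path: os.PathLike, role: str = "waxs") -> dict:
    out = {}
    with h5py.File(Path(path), "r") as f:
        if "waxs" not in f:
            raise FormatError(f"group /waxs not present in {path}")
        for name, dset in f["waxs"].items():
            iy, ix = (int(v) for v in name.split("_"))
            out[(iy, ix)] = Image2D(
                values=np.asarray(dset),
                pixel_size=float(dset.attrs.get("pixel_size_um", 172.0)),
                frame_tag=role,
                timestamp=float(dset.attrs.get("timestamp_s", 0.0)),
            )
    return out


# ---------------------------------------------------------------------------
# CSV curves and maps
# ---------------------------------------------------------------------------

def write_diffractogram(path: os.PathLike, dg: Diffractogram1D) -> None:
    pd.DataFrame(
        {
            "q_invA": dg.q,
            "intensity": dg.intensity,
            "coverage": dg.coverage,
            "valid": dg.valid.astype(int),
        }
    ).to_csv(Path(path), index=False, float_format="%.10g")


def read_diffractogram(path: os.PathLike) -> Diffractogram1D:
    df = pd.read_csv(Path(path))
    return Diffractogram1D(
        q=df["q_invA"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        coverage=df["coverage"].to_numpy(),
        valid=df["valid"].to_numpy().astype(bool),
    )


def write_azimuthal_profile(path: os.PathLike, prof: AzimuthalProfile) -> None:
    pd.DataFrame(
        {
            "phi_deg": prof.phi,
            "intensity": prof.intensity,
            "coverage": prof.coverage,
            "valid": np.asarray(prof.valid).astype(int),
        }
    ).to_csv(Path(path), index=False, float_format="%.10g")


def write_map(path: os.PathLike, smap: ScalarMap) -> None:
    """Write a scalar map as CSV (rows = iy). A .tif sibling is also written."""
    path = Path(path)
    pd.DataFrame(smap.values).to_csv(path, index=False, float_format="%.10g")
    tifffile.imwrite(path.with_suffix(".tif"), smap.values.astype(np.float32))


def read_map(path: os.PathLike, grid: RasterGrid, quantity: str) -> ScalarMap:
    values = pd.read_csv(Path(path)).to_numpy(dtype=float)
    return ScalarMap(values=values, grid=grid, quantity=quantity)


def write_curves(path: os.PathLike, table: pd.DataFrame) -> None:
    table.to_csv(Path(path), index=False, float_format="%.10g")
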