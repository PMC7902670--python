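"""Density-volume containers and MRC2014 I/O.

A cryo-EM map is a 3D scalar field sampled on a cubic grid with an isotropic
voxel size in Angstrom.  All frequency-domain machinery in this package
(radial band-pass shells, the spiral-phase multiplier) assumes an isotropic
cubic grid, so the loader rejects anisotropic voxel sizes and non-cubic
volumes are zero-padded to the smallest enclosing cube before processing.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field

import gemmi
import numpy as np

logger = logging.getLogger("spiralmap")

__all__ = [
    "VolumeGrid",
    "SolventMask",
    "ResolutionRange",
    "read_volume",
    "write_volume",
    "read_mask",
    "validate_pair",
    "pad_to_cube",
    "crop_to_shape",
]

#: relative tolerance on voxel-size isotropy accepted by the loader
ANISOTROPY_TOL = 1e-3


@dataclass
class VolumeGrid:
    """A 3D density map V(r) with its sampling metadata.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar densities in arbitrary units, floating dtype.
    voxel_size : float
        Isotropic sampling step in Angstrom per voxel.
    origin : tuple of float
        Physical origin in Angstrom, carried through to output headers but
        never interpreted.
    """

    data: np.ndarray
    voxel_size: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    #: permit NaN voxels (used for fit outputs whose invalid voxels are NaN
    #: by design); the loader never sets this, so inputs must be finite
    allow_non_finite: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float32)
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if not self.allow_non_finite and not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite (NaN/Inf) voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def is_cubic(self) -> bool:
        nx, ny, nz = self.data.shape
        return nx == ny == nz

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        """Same grid metadata, new densities."""
        return VolumeGrid(data, self.voxel_size, self.origin)


@dataclass
class SolventMask:
    """Binary macromolecule/solvent mask on the same grid as its map.

    Voxels equal to 1 belong to the macromolecule, 0 to solvent/background.
    """

    data: np.ndarray
    voxel_size: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {arr.shape}")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            logger.warning(
                "soft mask detected (values outside {0,1}); binarising at 0.5"
            )
            arr = (arr > 0.5).astype(np.uint8)
        else:
            arr = arr.astype(np.uint8)
        self.data = arr
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def coverage_fraction(self) -> float:
        return float(self.data.mean())

    def inside(self) -> np.ndarray:
        """Boolean index of macromolecule voxels."""
        return self.data.astype(bool)

    def outside(self) -> np.ndarray:
        """Boolean index of solvent/background voxels."""
        return ~self.data.astype(bool)


@dataclass
class ResolutionRange:
    """Analysis band [r_min, r_max] in Angstrom, r_min the coarse edge.

    ``n_bands`` may be left as None, in which case the filter bank chooses a
    spacing of two Fourier voxels (capped at 40 bands) when built against a
    concrete grid.
    """

    r_min: float
    r_max: float
    n_bands: int | None = None

    def __post_init__(self) -> None:
        if not (self.r_min > self.r_max > 0):
            raise ValueError(
                f"require r_min > r_max > 0 A, got [{self.r_min}, {self.r_max}]"
            )
        if self.n_bands is not None and self.n_bands < 2:
            raise ValueError("n_bands must be >= 2")

    def check_nyquist(self, voxel_size: float) -> None:
        if self.r_max < 2.0 * voxel_size:
            raise ValueError(
                f"r_max={self.r_max} A is finer than the Nyquist spacing "
                f"{2.0 * voxel_size} A at voxel size {voxel_size} A"
            )


def _grid_metadata(ccp4: gemmi.Ccp4Map) -> tuple[float, tuple[float, float, float]]:
    sx, sy, sz = ccp4.grid.spacing
    mean = (sx + sy + sz) / 3.0
    if mean <= 0 or (max(sx, sy, sz) - min(sx, sy, sz)) > ANISOTROPY_TOL * mean:
        raise ValueError(
            f"anisotropic voxel size ({sx:.4g}, {sy:.4g}, {sz:.4g}) A; "
            "an isotropic grid is required"
        )
    origin = tuple(float(ccp4.header_float(w)) for w in (50, 51, 52))
    return float(mean), origin  # type: ignore[return-value]


def read_volume(path: str | os.PathLike) -> VolumeGrid:
    """Read a single-volume MRC2014/CCP4 density map.

    Voxel size is taken from the header cell; densities are cast to float32.
    Rejects anisotropic voxel sizes (beyond 0.1% relative) and non-finite
    densities.
    """
    if not os.path.isfile(path):
        raise FileNotFoundError(f"no such volume file: {path}")
    ccp4 = gemmi.read_ccp4_map(os.fspath(path))
    voxel, origin = _grid_metadata(ccp4)
    data = np.array(ccp4.grid, copy=True).astype(np.float32)
    return VolumeGrid(data, voxel, origin)


def read_mask(path: str | os.PathLike) -> SolventMask:
    """Read a solvent mask; soft masks are binarised at 0.5 with a warning."""
    if not os.path.isfile(path):
        raise FileNotFoundError(f"no such mask file: {path}")
    ccp4 = gemmi.read_ccp4_map(os.fspath(path))
    voxel, origin = _grid_metadata(ccp4)
    data = np.array(ccp4.grid, copy=True)
    return SolventMask(data, voxel, origin)


def write_volume(v: VolumeGrid | SolventMask, path: str | os.PathLike) -> None:
    """Write a volume (or mask) as MRC2014 mode-2 (32-bit float)."""
    if os.path.isdir(path):
        raise IsADirectoryError(f"refusing to write volume to a directory: {path}")
    nx, ny, nz = v.data.shape
    grid = gemmi.FloatGrid(np.ascontiguousarray(v.data, dtype=np.float32))
    grid.set_unit_cell(
        gemmi.UnitCell(nx * v.voxel_size, ny * v.voxel_size, nz * v.voxel_size,
                       90.0, 90.0, 90.0)
    )
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for word, val in zip((50, 51, 52), v.origin):
        ccp4.set_header_float(word, float(val))
    ccp4.write_ccp4_map(os.fspath(path))


def validate_pair(v: VolumeGrid, m: SolventMask) -> None:
    """Raise unless map and mask share grid shape and voxel size."""
    if v.shape != m.shape:
        raise ValueError(
            f"map/mask shape mismatch: {v.shape} vs {m.shape}"
        )
    if not math.isclose(v.voxel_size, m.voxel_size, rel_tol=ANISOTROPY_TOL):
        raise ValueError(
            f"map/mask voxel-size mismatch: {v.voxel_size} vs {m.voxel_size} A"
        )


def pad_to_cube(arr: np.ndarray) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Zero-pad to the smallest enclosing cube; returns (cube, original_shape).

    Radial frequency shells and the spiral multiplier assume one cube edge;
    outputs are cropped back with :func:`crop_to_shape` before writing.
    """
    shape = arr.shape
    n = max(shape)
    if shape == (n, n, n):
        return arr, shape
    logger.warning("non-cubic input %s zero-padded to %d^3", shape, n)
    out = np.zeros((n, n, n), dtype=arr.dtype)
    out[: shape[0], : shape[1], : shape[2]] = arr
    return out, shape


def crop_to_shape(arr: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    return arr[: shape[0], : shape[1], : shape[2]]
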