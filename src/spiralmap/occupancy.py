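"""Local electron-density occupancy maps and the maturity-level index.

The occupancy of a voxel over a resolution range is the fraction of bands
at which its local amplitude exceeds the 25% quantile of the in-mask
(macromolecule) amplitude distribution, relative to the bands at which it
at least reaches the in-mask minimum:

    O(r) = sum_w [ m_w(r) >  m_w^M(q=25%) ]
           -----------------------------------
           sum_w [ m_w(r) >= m_w^M(q=0%)  ]

with O(r) = 0 where the denominator vanishes (no band reaches even the
weakest in-mask signal).  O lies in [0, 1], responds monotonically to
amplitude scaling of a motif, and is invariant under global rescaling of
the map because the quantile thresholds rescale identically.

The maturity-level index of an assembly intermediate compares the highly
occupied regions of its occupancy map (O > 0.75 by default) against the
solvent mask of the mature reference: the percentage of mature-mask voxels
that the intermediate already occupies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .filterbank import BandDecomposition, build_filterbank, decompose_map
from .grid import (
    ResolutionRange,
    SolventMask,
    VolumeGrid,
    crop_to_shape,
    pad_to_cube,
    validate_pair,
)
from .quantiles import nearest_rank_quantile

logger = logging.getLogger("spiralmap")

__all__ = [
    "MacroThresholds",
    "OccupancyMap",
    "MaturityReport",
    "macro_thresholds",
    "occupancy_from_amplitudes",
    "lococcupancy",
    "occupancy_mask",
    "maturity_index",
    "segment_missing",
]

MIN_POPULATION = 1000


@dataclass
class MacroThresholds:
    """Per-band macromolecule amplitude quantiles from in-mask voxels."""

    q25: np.ndarray
    q0: np.ndarray


@dataclass
class OccupancyMap:
    """Per-voxel occupancy O(r) in [0, 1] over a stated resolution range."""

    data: np.ndarray
    range_used: tuple[float, float]
    voxel_size: float
    origin: tuple = (0.0, 0.0, 0.0)


@dataclass
class MaturityReport:
    occupancy_mask_voxels: int
    reference_mask_voxels: int
    maturity_percent: float


def macro_thresholds(
    bands: list[BandDecomposition], mask: SolventMask
) -> MacroThresholds:
    """25% and 0% (minimum) amplitude quantiles over in-mask voxels, per band."""
    inside = mask.inside()
    n_inside = int(inside.sum())
    if n_inside == 0:
        raise ValueError("empty mask: no macromolecule voxels to threshold")
    if n_inside < MIN_POPULATION:
        raise ValueError(
            f"only {n_inside} in-mask voxels; need at least {MIN_POPULATION} "
            "for stable macromolecule quantiles"
        )
    q25 = np.array([nearest_rank_quantile(b.amplitude[inside], 0.25) for b in bands])
    q0 = np.array([nearest_rank_quantile(b.amplitude[inside], 0.0) for b in bands])
    return MacroThresholds(q25, q0)


def occupancy_from_amplitudes(
    amp: np.ndarray, thr: MacroThresholds, denominator: str = "quantile"
) -> np.ndarray:
    """Occupancy from a (n_bands, ...) amplitude stack and its thresholds.

    Numerator counts bands strictly above the 25% quantile; denominator
    counts bands at or above the in-mask minimum (or all bands with
    ``denominator="bands"``); zero denominator gives occupancy 0.
    """
    nb = amp.shape[0]
    bshape = (nb,) + (1,) * (amp.ndim - 1)
    numer = (amp > np.reshape(thr.q25, bshape)).sum(axis=0)
    if denominator == "quantile":
        denom = (amp >= np.reshape(thr.q0, bshape)).sum(axis=0)
    else:
        denom = np.full(numer.shape, nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, numer / np.maximum(denom, 1), 0.0)


def lococcupancy(
    v: VolumeGrid,
    mask: SolventMask,
    rr: ResolutionRange,
    denominator: str = "quantile",
    highpass: float = 30.0,
    apodize: bool = True,
) -> OccupancyMap:
    """Per-voxel occupancy over the resolution range.

    ``denominator="quantile"`` (default) counts bands whose amplitude is at
    least the in-mask minimum; ``denominator="bands"`` averages over all
    bands in the range instead.
    """
    if denominator not in ("quantile", "bands"):
        raise ValueError("denominator must be 'quantile' or 'bands'")
    validate_pair(v, mask)
    rr.check_nyquist(v.voxel_size)
    data, orig_shape = pad_to_cube(v.data)
    mdata, _ = pad_to_cube(mask.data)
    vol = VolumeGrid(data, v.voxel_size, v.origin)
    msk = SolventMask(mdata, mask.voxel_size, mask.origin)
    fb = build_filterbank(rr, v.voxel_size, data.shape[0], highpass=highpass)
    bands = decompose_map(vol, fb, apodize=apodize)
    thr = macro_thresholds(bands, msk)

    amp = np.stack([b.amplitude for b in bands])
    occ = occupancy_from_amplitudes(amp, thr, denominator)
    return OccupancyMap(
        crop_to_shape(occ, orig_shape), (rr.r_min, rr.r_max), v.voxel_size, v.origin
    )


def occupancy_mask(o: OccupancyMap, cut: float = 0.75) -> SolventMask:
    """Binary mask of highly occupied voxels (O strictly above ``cut``)."""
    return SolventMask((o.data > cut).astype(np.uint8), o.voxel_size, o.origin)


def maturity_index(
    immature_occ_mask: SolventMask, mature_mask: SolventMask
) -> MaturityReport:
    """Percentage of mature-mask voxels occupied in the intermediate.

    The occupancy mask is intersected with the mature mask before counting,
    so spurious occupancy outside the reference cannot push the index past
    100%.
    """
    if immature_occ_mask.shape != mature_mask.shape:
        raise ValueError(
            f"grid mismatch: {immature_occ_mask.shape} vs {mature_mask.shape}"
        )
    ref = mature_mask.inside()
    n_ref = int(ref.sum())
    if n_ref == 0:
        raise ValueError("empty mature reference mask")
    n_occ = int((immature_occ_mask.inside() & ref).sum())
    return MaturityReport(n_occ, n_ref, 100.0 * n_occ / n_ref)


def segment_missing(
    mature_map: VolumeGrid,
    mature_mask: SolventMask,
    immature_occ_mask: SolventMask,
) -> VolumeGrid:
    """Mature-map densities present in the mature mask but absent from the
    intermediate's occupancy mask; zero elsewhere."""
    validate_pair(mature_map, mature_mask)
    if mature_mask.shape != immature_occ_mask.shape:
        raise ValueError(
            f"grid mismatch: {mature_mask.shape} vs {immature_occ_mask.shape}"
        )
    keep = mature_mask.inside() & ~immature_occ_mask.inside()
    return mature_map.with_data(np.where(keep, mature_map.data, 0.0))
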