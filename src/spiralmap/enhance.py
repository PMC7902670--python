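"""Local map enhancement: LocSpiral and LocBSharpen.

LocSpiral rebuilds the map band by band, keeping only local amplitudes that
exceed a per-band noise threshold estimated from voxels outside the solvent
mask, and re-expressing the surviving signal with a normalised amplitude:

    V'(r) = sum_w  C_ref,w(r) * [m_w(r) > m_w^N(q)] * cos(phi_w(r))

with C_ref,w(r) = m_w(r) / (m_w(r) + m_w^N(q)) the SNR weight (optional) and
m_w^N(q) the q-quantile (default 0.95) of the empirical amplitude
distribution outside the mask at band w.

LocBSharpen instead clamps the local amplitude of every band at or beyond a
reference frequency w0 (typically 1/15 - 1/10 1/A) to the band-w0 amplitude
map, flattening the local amplitude fall-off:

    V'(r) = sum_{w<w0} C m_w cos(phi_w)  +  sum_{w>=w0} C m_w0 cos(phi_w)
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

__all__ = ["NoiseModel", "estimate_noise", "snr_weight", "locspiral", "locbsharpen"]

#: minimum number of voxels for a stable empirical quantile
MIN_POPULATION = 1000


@dataclass
class NoiseModel:
    """Per-band noise amplitude thresholds m_w^N(q) from outside-mask voxels."""

    quantile_q: float
    thresholds: np.ndarray
    n_outside: int


def estimate_noise(
    bands: list[BandDecomposition], mask: SolventMask, q: float = 0.95
) -> NoiseModel:
    """Empirical q-quantile of each band's amplitude outside the solvent mask."""
    if not 0.90 <= q <= 0.99:
        raise ValueError(f"noise quantile must be in [0.90, 0.99], got {q}")
    outside = mask.outside()
    n_outside = int(outside.sum())
    if n_outside == 0:
        raise ValueError("empty noise population: the mask covers every voxel")
    if n_outside < MIN_POPULATION:
        raise ValueError(
            f"only {n_outside} voxels outside the mask; need at least "
            f"{MIN_POPULATION} for a stable empirical quantile"
        )
    thresholds = np.array(
        [nearest_rank_quantile(b.amplitude[outside], q) for b in bands]
    )
    return NoiseModel(q, thresholds, n_outside)


def snr_weight(amplitude: np.ndarray, threshold: float) -> np.ndarray:
    """C_ref = m / (m + m^N): 0 at zero amplitude, 0.5 at the threshold, -> 1."""
    denom = amplitude + threshold
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, amplitude / np.where(denom > 0, denom, 1.0), 0.0)


def _prepare(v, mask, rr, highpass, apodize):
    validate_pair(v, mask)
    rr.check_nyquist(v.voxel_size)
    data, orig_shape = pad_to_cube(v.data)
    mdata, _ = pad_to_cube(mask.data)
    vol = VolumeGrid(data, v.voxel_size, v.origin)
    msk = SolventMask(mdata, mask.voxel_size, mask.origin)
    fb = build_filterbank(rr, v.voxel_size, data.shape[0], highpass=highpass)
    bands = decompose_map(vol, fb, apodize=apodize)
    return bands, fb, msk, orig_shape


def locspiral(
    v: VolumeGrid,
    mask: SolventMask,
    rr: ResolutionRange,
    q: float = 0.95,
    weighted: bool = True,
    soft: bool = False,
    highpass: float = 30.0,
    apodize: bool = True,
) -> VolumeGrid:
    """Noise-quantile-normalised locally enhanced map.

    Parameters
    ----------
    weighted : bool
        Multiply each surviving band contribution by the SNR weight C_ref
        (default).  With ``weighted=False`` surviving signal contributes
        with unit local amplitude.
    soft : bool
        Replace the unit amplitude by min(m/threshold, 1) so amplitudes
        near the threshold are not boosted all the way to 1.
    """
    bands, fb, msk, orig_shape = _prepare(v, mask, rr, highpass, apodize)
    noise = estimate_noise(bands, msk, q)
    out = np.zeros(bands[0].v_band.shape)
    for b, thr in zip(bands, noise.thresholds):
        keep = b.amplitude > thr
        contrib = keep * b.cosine
        if soft:
            contrib = contrib * np.minimum(b.amplitude / thr if thr > 0 else 1.0, 1.0)
        if weighted:
            contrib = contrib * snr_weight(b.amplitude, thr)
        out += contrib
    return v.with_data(crop_to_shape(out, orig_shape))


def locbsharpen(
    v: VolumeGrid,
    mask: SolventMask,
    rr: ResolutionRange,
    omega0_resolution: float = 10.0,
    q: float = 0.95,
    use_a_map: bool = False,
    highpass: float = 30.0,
    apodize: bool = True,
) -> VolumeGrid:
    """Local-B-factor sharpened map with amplitudes clamped beyond 1/w0.

    ``omega0_resolution`` (A) selects the reference band w0: the first band
    at or beyond 1/omega0_resolution.  ``use_a_map=True`` replaces the
    clamped linear amplitude m_w0(r) by exp(A(r)) from the local Guinier
    fit, for comparison.
    """
    if not (rr.r_max <= omega0_resolution <= rr.r_min):
        raise ValueError(
            f"omega0 resolution {omega0_resolution} A outside the analysis "
            f"range [{rr.r_min}, {rr.r_max}] A"
        )
    bands, fb, msk, orig_shape = _prepare(v, mask, rr, highpass, apodize)
    noise = estimate_noise(bands, msk, q)
    w0 = 1.0 / omega0_resolution
    i0 = int(np.searchsorted(fb.band_centers, w0))
    i0 = min(i0, fb.n_bands - 1)

    if use_a_map:
        from .bfactor import locbfactor

        res = locbfactor(v, mask, rr, q=q, highpass=highpass, apodize=apodize)
        a_pad, _ = pad_to_cube(np.nan_to_num(res.a_map, nan=-np.inf))
        amp0 = np.where(np.isfinite(a_pad), np.exp(a_pad), 0.0)
    else:
        amp0 = bands[i0].amplitude

    out = np.zeros(bands[0].v_band.shape)
    for i, (b, thr) in enumerate(zip(bands, noise.thresholds)):
        c = snr_weight(b.amplitude, thr)
        amp = b.amplitude if i < i0 else amp0
        out += c * amp * b.cosine
    return v.with_data(crop_to_shape(out, orig_shape))
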