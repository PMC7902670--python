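"""Per-voxel Guinier analysis: local B-factor and amplitude maps.

At every voxel the SNR-weighted log-amplitudes of the band decomposition,

    log F_w(r) = log( C_ref,w(r) * m_w(r) ),

are fitted by ordinary least squares against squared spatial frequency over
the analysis range, anchored at the lowest in-range band frequency w0:

    log F_w(r) ~ B(r) * (w^2 - w0^2) + A(r)

Bands whose amplitude does not strictly exceed the noise threshold are
excluded from the fit; voxels with fewer than two above-noise samples are
flagged invalid (such fits would describe the noise fall-off, not the
structure).  The slope map B(r) is the local Guinier slope in A^2 and the
sharpening map is 4*B(r), the B-factor to use for sharpening under the
standard amplitude-decay convention exp(-B w^2 / 4).

By default each band's amplitude is divided (inside the logarithm) by the
band filter's RMS gain on a flat spectrum before fitting.  A band-pass shell
integrates a number of Fourier modes proportional to its area, so raw local
amplitudes grow with frequency even for a flat underlying spectrum; the
normalisation removes that geometric trend and makes the fitted slope track
the Fourier-amplitude decay.  It does not affect thresholds, C_ref or the
above-noise rule, which compare amplitudes within one band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .enhance import NoiseModel, estimate_noise, snr_weight
from .filterbank import BandDecomposition, build_filterbank, decompose_map
from .grid import (
    ResolutionRange,
    SolventMask,
    VolumeGrid,
    crop_to_shape,
    pad_to_cube,
    validate_pair,
)

logger = logging.getLogger("spiralmap")

__all__ = [
    "GuinierSample",
    "BFactorResult",
    "sharpening_bfactor",
    "guinier_samples",
    "fit_guinier",
    "locbfactor",
]


def sharpening_bfactor(slope: float) -> float:
    """Sharpening B-factor from a Guinier slope: 4 x slope.

    The Guinier line fits log-amplitude against squared frequency; under the
    exp(-B w^2/4) amplitude-decay convention the B-factor to apply for
    sharpening is four times the fitted slope (e.g. a slope of -21.14 A^2
    gives a sharpening B-factor of -84.56 A^2).
    """
    return 4.0 * slope


@dataclass
class GuinierSample:
    """One band's contribution to a voxel's local Guinier plot."""

    omega2: float
    logF: float
    above_noise: bool


@dataclass
class BFactorResult:
    """Per-voxel local Guinier fit over the analysis range.

    ``b_map`` is the slope B(r) in A^2 (typically negative), ``a_map`` the
    log-amplitude intercept at the low-resolution anchor w0, ``sharpen_map``
    exactly 4*b_map.  Voxels with fewer than two above-noise samples are
    NaN in all three and 0 in ``valid_mask``.
    """

    b_map: np.ndarray
    a_map: np.ndarray
    sharpen_map: np.ndarray
    valid_mask: np.ndarray
    n_points_map: np.ndarray
    omega0: float
    voxel_size: float
    origin: tuple = (0.0, 0.0, 0.0)

    def summary(self, mask: SolventMask | None = None) -> dict:
        """Mean/SD of B and sharpening B over valid (optionally in-mask) voxels."""
        sel = self.valid_mask.astype(bool)
        if mask is not None:
            sel &= mask.inside()
        b = self.b_map[sel]
        out = {
            "n_valid": int(sel.sum()),
            "b_mean": float(np.mean(b)) if b.size else float("nan"),
            "b_sd": float(np.std(b)) if b.size else float("nan"),
        }
        out["sharpen_mean"] = sharpening_bfactor(out["b_mean"])
        out["sharpen_sd"] = 4.0 * out["b_sd"]
        return out


def guinier_samples(
    bands: list[BandDecomposition],
    noise: NoiseModel,
    voxel: tuple[int, int, int],
    shell_normalize: bool = True,
) -> list[GuinierSample]:
    """The local Guinier plot of one voxel: one sample per band.

    Samples whose amplitude does not strictly exceed the band's noise
    threshold (including zero amplitudes) are marked below-noise.
    """
    samples = []
    for b, thr in zip(bands, noise.thresholds):
        m = float(b.amplitude[voxel])
        above = bool(m > thr)
        gain = b.rms_gain if shell_normalize else 1.0
        if m > 0:
            logf = float(np.log(snr_weight(np.array(m), thr) * m / gain))
        else:
            logf = float("-inf")
            above = False
        samples.append(GuinierSample(b.omega**2, logf, above))
    return samples


def fit_guinier(
    samples: list[GuinierSample], omega0: float
) -> tuple[float, float] | None:
    """OLS line through (w^2 - w0^2, logF) over above-noise samples.

    Returns (B, A), or None when fewer than two samples lie above noise.
    """
    pts = [(s.omega2 - omega0**2, s.logF) for s in samples if s.above_noise]
    if len(pts) < 2:
        return None
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    design = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(coef[0]), float(coef[1])


def locbfactor(
    v: VolumeGrid,
    mask: SolventMask,
    rr: ResolutionRange,
    q: float = 0.95,
    shell_normalize: bool = True,
    wls: bool = False,
    highpass: float = 30.0,
    apodize: bool = True,
) -> BFactorResult:
    """Local B-factor, amplitude and sharpening maps by vectorised OLS.

    ``rr.r_min`` is conventionally in the 15-10 A regime (a warning is
    logged outside it).  ``wls=True`` weights each band by the number of
    Fourier voxels in its shell (the squared RMS gain, up to the constant
    grid size) instead of the default unweighted fit.
    """
    validate_pair(v, mask)
    if not 10.0 <= rr.r_min <= 15.0:
        logger.warning(
            "r_min=%.3g A is outside the conventional 15-10 A regime for "
            "local Guinier fits", rr.r_min,
        )
    data, orig_shape = pad_to_cube(v.data)
    mdata, _ = pad_to_cube(mask.data)
    vol = VolumeGrid(data, v.voxel_size, v.origin)
    msk = SolventMask(mdata, mask.voxel_size, mask.origin)
    fb = build_filterbank(rr, v.voxel_size, data.shape[0], highpass=highpass)
    bands = decompose_map(vol, fb, apodize=apodize)
    noise = estimate_noise(bands, msk, q)

    omega0 = float(fb.band_centers[0])
    shape = data.shape
    nb = len(bands)
    x = np.array([b.omega**2 - omega0**2 for b in bands])

    # stack amplitudes once; everything below is per-band algebra
    amp = np.stack([b.amplitude for b in bands])
    thr = noise.thresholds.reshape(nb, 1, 1, 1)
    above = amp > thr
    gains = np.array(
        [b.rms_gain if shell_normalize else 1.0 for b in bands]
    ).reshape(nb, 1, 1, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        logf = np.where(amp > 0, np.log(amp / (amp + thr) * amp / gains), 0.0)

    w = above.astype(float)
    if wls:
        w = w * (np.array([b.rms_gain for b in bands]) ** 2).reshape(nb, 1, 1, 1)
    xs = x.reshape(nb, 1, 1, 1)
    sw = w.sum(axis=0)
    sx = (w * xs).sum(axis=0)
    sy = (w * logf).sum(axis=0)
    sxx = (w * xs * xs).sum(axis=0)
    sxy = (w * xs * logf).sum(axis=0)
    det = sw * sxx - sx * sx
    n_points = above.sum(axis=0)
    valid = (n_points >= 2) & (det > 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        b_map = np.where(valid, (sw * sxy - sx * sy) / np.where(det > 0, det, 1.0), np.nan)
        a_map = np.where(valid, (sy - b_map * sx) / np.where(sw > 0, sw, 1.0), np.nan)
    sharpen = 4.0 * b_map

    crop = lambda a: crop_to_shape(a, orig_shape)  # noqa: E731
    result = BFactorResult(
        b_map=crop(b_map),
        a_map=crop(a_map),
        sharpen_map=crop(sharpen),
        valid_mask=crop(valid.astype(np.uint8)),
        n_points_map=crop(n_points.astype(np.int32)),
        omega0=omega0,
        voxel_size=v.voxel_size,
        origin=v.origin,
    )
    s = result.summary(mask)
    logger.info(
        "local B-factor: %d valid in-mask voxels, slope %.4g +/- %.4g A^2 "
        "(sharpening B %.4g A^2)",
        s["n_valid"], s["b_mean"], s["b_sd"], s["sharpen_mean"],
    )
    return result
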