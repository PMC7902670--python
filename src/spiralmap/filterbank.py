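"""Band-pass filter bank and the 3D spiral-phase (Riesz) transform.

A high-pass-filtered map is decomposed into overlapping radial frequency
bands V_w(r); each band is factorised in real space into a local amplitude
m_w(r) and a cosine phase term cos(phi_w(r)) using the isotropic Riesz
transform, whose Fourier multiplier is -i q/|q| applied per component.  The
local amplitude is the monogenic amplitude

    m_w(r) = sqrt( V_w(r)^2 + |Q{V_w}(r)|^2 )

with Q the Euclidean magnitude of the three Riesz component volumes.  Only
the magnitude of the Riesz vector is used: the amplitude and the cosine
ratio V_w/m_w never need the quadrature sign, which is not determined by the
transform alone.

Band profiles are raised-cosine annular shells with half-overlap whose
squared transfer functions form a partition of unity on the analysis band,
so summing all band-passed volumes reconstructs the band-limited high-passed
map.  The bank composes a smooth high-pass (default 30 A) into every profile
and has no DC response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.fft
from scipy.special import erf

from .grid import ResolutionRange, VolumeGrid

logger = logging.getLogger("spiralmap")

__all__ = [
    "FilterBank",
    "BandDecomposition",
    "build_filterbank",
    "bandpass",
    "spiral_quadrature",
    "decompose",
    "decompose_map",
    "apodize_volume",
]

#: hard cap on the number of bands chosen automatically
MAX_BANDS = 40
#: default high-pass resolution (A) composed into every band profile
DEFAULT_HIGHPASS = 30.0
#: fraction of the box width tapered by the real-space apodisation edge
APOD_EDGE_FRACTION = 0.05


@dataclass
class FilterBank:
    """Radial band-pass profiles H_i(|q|) sharing one analysis band.

    ``band_centers`` are spatial frequencies in 1/A, ascending, uniformly
    spaced between 1/r_min and 1/r_max.  ``highpass_resolution`` is the
    resolution (A) of the smooth high-pass composed into every profile;
    ``highpass_width`` its transition width in 1/A (one Fourier voxel).
    """

    band_centers: np.ndarray
    highpass_resolution: float
    highpass_width: float

    @property
    def n_bands(self) -> int:
        return len(self.band_centers)

    @property
    def spacing(self) -> float:
        return float(self.band_centers[1] - self.band_centers[0])

    def _highpass(self, q: np.ndarray) -> np.ndarray:
        q_hp = 1.0 / self.highpass_resolution
        h = 0.5 * (1.0 + erf((q - q_hp) / self.highpass_width))
        return np.where(q == 0.0, 0.0, h)

    def profile(self, i: int, q: np.ndarray) -> np.ndarray:
        """Evaluate H_i on radial frequencies ``q`` (1/A)."""
        c = self.band_centers
        d = self.spacing
        ci = c[i]
        q = np.asarray(q, dtype=float)
        h2 = np.zeros_like(q)

        # rising edge (from the previous centre, or a taper below the first)
        w_left = d if i > 0 else min(d, ci)
        t = np.clip((ci - q) / w_left, 0.0, 1.0)
        left = np.cos(0.5 * np.pi * t) ** 2
        # falling edge towards the next centre (taper above the last)
        t = np.clip((q - ci) / d, 0.0, 1.0)
        right = np.cos(0.5 * np.pi * t) ** 2
        h2 = np.where(q < ci, left, right)

        h = np.sqrt(h2) * self._highpass(q)
        return np.where(q == 0.0, 0.0, h)

    def rms_gain(self, i: int, shape: tuple[int, int, int], voxel_size: float) -> float:
        """RMS gain of band i on a flat (white) spectrum over the grid.

        sqrt(mean over all Fourier voxels of H_i^2); grows with the shell
        area, so it measures how many Fourier modes the band integrates.
        Used to make band amplitudes comparable across bands in the local
        Guinier fit.
        """
        q = radial_frequency_grid(shape, voxel_size)
        h = self.profile(i, q)
        return float(np.sqrt(np.mean(h * h)))

    def partition_error(self, q: np.ndarray) -> np.ndarray:
        """|sum_i H_i(q)^2 - 1| on radial frequencies ``q``."""
        total = np.zeros_like(np.asarray(q, dtype=float))
        for i in range(self.n_bands):
            h = self.profile(i, q)
            total += h * h
        return np.abs(total - 1.0)


def build_filterbank(
    rr: ResolutionRange,
    voxel_size: float,
    n_voxels: int,
    highpass: float = DEFAULT_HIGHPASS,
) -> FilterBank:
    """Construct the raised-cosine annular bank over [1/r_min, 1/r_max].

    Band centres are uniformly spaced in spatial frequency.  If
    ``rr.n_bands`` is None the spacing defaults to two Fourier voxels
    (2/(N*voxel_size)), capped at 40 bands.  Rejects a band count whose
    spacing falls below one Fourier voxel: adjacent shells would then be
    indistinguishable on the discrete frequency grid.
    """
    rr.check_nyquist(voxel_size)
    if highpass < rr.r_min:
        raise ValueError(
            f"high-pass resolution {highpass} A must be at or coarser than "
            f"r_min={rr.r_min} A"
        )
    w_min, w_max = 1.0 / rr.r_min, 1.0 / rr.r_max
    fourier_voxel = 1.0 / (n_voxels * voxel_size)

    n_bands = rr.n_bands
    if n_bands is None:
        n_bands = int(np.floor((w_max - w_min) / (2.0 * fourier_voxel))) + 1
        n_bands = int(np.clip(n_bands, 2, MAX_BANDS))
    spacing = (w_max - w_min) / (n_bands - 1)
    if spacing < fourier_voxel:
        raise ValueError(
            f"{n_bands} bands over [{rr.r_min}, {rr.r_max}] A give a spacing "
            f"of {spacing:.3g} 1/A, below one Fourier voxel "
            f"({fourier_voxel:.3g} 1/A); reduce n_bands to at most "
            f"{int((w_max - w_min) / fourier_voxel) + 1}"
        )
    centers = np.linspace(w_min, w_max, n_bands)
    # erf scale of half a Fourier voxel: the full 10-90% transition spans
    # about one Fourier voxel and the edge has decayed to ~1 at the first
    # band centre, preserving the partition of unity there
    return FilterBank(centers, float(highpass), 0.5 * fourier_voxel)


@dataclass
class BandDecomposition:
    """One band's factorisation into amplitude and cosine-phase terms.

    Satisfies amplitude^2 = v_band^2 + quadrature^2 and
    cosine * amplitude = v_band wherever amplitude > 0.  ``rms_gain`` is the
    band filter's RMS gain on a flat spectrum (see FilterBank.rms_gain),
    carried along for cross-band amplitude comparisons.
    """

    omega: float
    v_band: np.ndarray
    quadrature: np.ndarray
    amplitude: np.ndarray
    cosine: np.ndarray
    rms_gain: float = 1.0


def radial_frequency_grid(shape: tuple[int, int, int], voxel_size: float) -> np.ndarray:
    """|q| (1/A) on the unshifted FFT grid."""
    axes = [scipy.fft.fftfreq(n, d=voxel_size) for n in shape]
    qx, qy, qz = np.meshgrid(*axes, indexing="ij", sparse=True)
    return np.sqrt(qx * qx + qy * qy + qz * qz)


def _frequency_components(shape, voxel_size):
    axes = [scipy.fft.fftfreq(n, d=voxel_size) for n in shape]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def apodize_volume(data: np.ndarray, edge_fraction: float = APOD_EDGE_FRACTION) -> np.ndarray:
    """Soft cosine (Tukey) edge to suppress wrap-around before transforms."""
    out = np.asarray(data, dtype=float)
    for ax, n in enumerate(out.shape):
        edge = max(int(round(edge_fraction * n)), 1)
        w = np.ones(n)
        ramp = 0.5 * (1.0 - np.cos(np.pi * (np.arange(edge) + 0.5) / edge))
        w[:edge] = ramp
        w[-edge:] = ramp[::-1]
        shape = [1, 1, 1]
        shape[ax] = n
        out = out * w.reshape(shape)
    return out


def bandpass(v: VolumeGrid, fb: FilterBank, i: int, apodize: bool = False) -> np.ndarray:
    """Band-pass V through H_i: FT^-1{ H_i(|q|) FT{V} }.  DC-free output."""
    data = apodize_volume(v.data) if apodize else np.asarray(v.data, dtype=float)
    q = radial_frequency_grid(data.shape, v.voxel_size)
    f = scipy.fft.fftn(data)
    return scipy.fft.ifftn(f * fb.profile(i, q)).real


def spiral_quadrature(v_band: np.ndarray, voxel_size: float = 1.0) -> np.ndarray:
    """Unsigned quadrature magnitude of a zero-mean band-passed volume.

    Applies the Riesz multiplier -i q_a/|q| per frequency component a,
    inverse-transforms each, and returns the Euclidean norm of the three
    real component volumes.  The multiplier at q=0 is defined as 0 (the
    directional limit does not exist and DC is already removed).
    """
    data = np.asarray(v_band, dtype=float)
    f = scipy.fft.fftn(data)
    comps = _frequency_components(data.shape, voxel_size)
    qmag = np.sqrt(sum(c * c for c in comps))
    out = np.zeros_like(data)
    with np.errstate(invalid="ignore", divide="ignore"):
        for qa in comps:
            mult = np.where(qmag > 0, -1j * qa / qmag, 0.0)
            comp = scipy.fft.ifftn(f * mult).real
            out += comp * comp
    return np.sqrt(out)


#: relative floor below which the cosine term is defined as 0
_AMP_EPS = 1e-12


def _factorise(v_band: np.ndarray, quad: np.ndarray):
    amplitude = np.sqrt(v_band * v_band + quad * quad)
    eps = _AMP_EPS * amplitude.max() if amplitude.size else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        cosine = np.where(amplitude > eps, v_band / np.maximum(amplitude, eps), 0.0)
    return amplitude, cosine


def decompose(
    v: VolumeGrid, fb: FilterBank, i: int, apodize: bool = False
) -> BandDecomposition:
    """Band-pass V at band i and factorise into amplitude and cosine terms."""
    vb = bandpass(v, fb, i, apodize=apodize)
    quad = spiral_quadrature(vb, v.voxel_size)
    amplitude, cosine = _factorise(vb, quad)
    gain = fb.rms_gain(i, v.data.shape, v.voxel_size)
    return BandDecomposition(float(fb.band_centers[i]), vb, quad, amplitude, cosine, gain)


def decompose_map(
    v: VolumeGrid, fb: FilterBank, apodize: bool = True
) -> list[BandDecomposition]:
    """Decompose all bands, sharing one forward FFT of the (apodised) map."""
    data = apodize_volume(v.data) if apodize else np.asarray(v.data, dtype=float)
    shape = data.shape
    f = scipy.fft.fftn(data)
    comps = _frequency_components(shape, v.voxel_size)
    qmag = np.sqrt(sum(c * c for c in comps))
    with np.errstate(invalid="ignore", divide="ignore"):
        riesz = [np.where(qmag > 0, -1j * qa / qmag, 0.0) for qa in comps]

    bands = []
    for i in range(fb.n_bands):
        h = fb.profile(i, qmag)
        fh = f * h
        vb = scipy.fft.ifftn(fh).real
        quad2 = np.zeros(shape)
        for mult in riesz:
            comp = scipy.fft.ifftn(fh * mult).real
            quad2 += comp * comp
        quad = np.sqrt(quad2)
        amplitude, cosine = _factorise(vb, quad)
        gain = float(np.sqrt(np.mean(h * h)))
        bands.append(
            BandDecomposition(float(fb.band_centers[i]), vb, quad, amplitude, cosine, gain)
        )

    # zero the cosine of bands whose amplitude is pure roundoff relative to
    # the decomposition as a whole: a numerically empty band must not turn
    # FFT noise into a +-1 phase pattern
    gmax = max(b.amplitude.max() for b in bands)
    eps = _AMP_EPS * gmax
    for b in bands:
        b.cosine = np.where(b.amplitude > eps, b.cosine, 0.0)
    return bands
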