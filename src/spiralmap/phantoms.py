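"""Seeded synthetic density volumes with known ground truth.

Every algorithm in this package has a parameter-recovery test built on
these phantoms instead of external deposited maps: plane waves and
envelope-modulated waves probe the spiral-phase factorisation; Gaussian-atom
models with an imposed exp(-B w^2/4) Fourier-amplitude decay probe the
local Guinier fit; duplicated motifs at reduced density probe occupancy
estimation; pure-noise boxes probe the noise-quantile thresholds.

Atoms are rendered as unit impulses scattered inside a spherical region and
blurred by a Gaussian of width ``atom_sigma`` in Fourier space, so the
imposed B-factor is exact on the discrete grid.  Noise is white Gaussian in
real space; its sigma is set from the requested in-support signal-to-noise
ratio (RMS signal over the support, divided by snr).  A colored-noise kind
band-shapes the same white noise to test quantile thresholds under non-flat
noise spectra.  Masks are built from the noiseless signal support (dilated
by two voxels) so mask quality is never a confounder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft
from scipy.ndimage import binary_dilation

from .grid import SolventMask, VolumeGrid

__all__ = ["PhantomSpec", "make_phantom", "impose_bfactor"]

PHANTOM_KINDS = (
    "plane_wave",
    "modulated_wave",
    "gaussian_atoms",
    "two_region_b",
    "partial_occupancy",
    "noise_only",
)

_DEFAULTS: dict[str, dict] = {
    "plane_wave": {"freq": 0.125, "axis": 0},
    "modulated_wave": {"freq": 0.125, "sigma": 12.0, "axis": 0},
    "gaussian_atoms": {
        "n_atoms": 600, "atom_sigma": 0.25, "radius": None,
        "b_factor": 0.0, "snr": None, "signed": True,
    },
    "two_region_b": {
        "n_atoms": 400, "atom_sigma": 0.25, "radius": None,
        "b_factors": (50.0, 300.0), "snr": None, "signed": True,
    },
    "partial_occupancy": {
        "n_atoms": 1000, "atom_sigma": 0.25, "radius": None,
        "occupancy": 0.5, "snr": None,
    },
    "noise_only": {"sigma": 1.0, "mask_radius": None, "colored": False},
}

#: fraction of the signal maximum defining the noiseless support
SUPPORT_LEVEL = 0.1
#: voxels of binary dilation applied to the support to form the mask
MASK_DILATION = 2


@dataclass
class PhantomSpec:
    """Recipe for one synthetic volume; identical spec + seed is bit-identical."""

    kind: str
    box: int = 64
    voxel_size: float = 1.0
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; one of {PHANTOM_KINDS}")
        merged = dict(_DEFAULTS[self.kind])
        merged.update(self.params)
        self.params = merged


def _q2_grid(box: int, voxel_size: float) -> np.ndarray:
    f = scipy.fft.fftfreq(box, d=voxel_size)
    qx, qy, qz = np.meshgrid(f, f, f, indexing="ij", sparse=True)
    return qx * qx + qy * qy + qz * qz


def impose_bfactor(v: VolumeGrid, b: float) -> VolumeGrid:
    """Damp Fourier amplitudes by exp(-B |q|^2 / 4); B = 0 is the identity.

    Negative B (sharpening) is rejected: boosting amplitudes is a different
    code path with different noise behaviour.
    """
    if b < 0:
        raise ValueError(f"impose_bfactor requires B >= 0, got {b}")
    if b == 0:
        return v.with_data(v.data.copy())
    q2 = _q2_grid(v.data.shape[0], v.voxel_size)
    f = scipy.fft.fftn(np.asarray(v.data, dtype=float))
    out = scipy.fft.ifftn(f * np.exp(-b * q2 / 4.0)).real
    return v.with_data(out)


def _gaussian_blur_fourier(data: np.ndarray, sigma: float, voxel_size: float) -> np.ndarray:
    """Blur by a Gaussian of real-space width sigma (A) via its exact FT."""
    if sigma <= 0:
        return data
    q2 = _q2_grid(data.shape[0], voxel_size)
    f = scipy.fft.fftn(data)
    return scipy.fft.ifftn(f * np.exp(-2.0 * np.pi**2 * sigma**2 * q2)).real


def _scatter_atoms(rng, box, center, radius_vox, n_atoms, signed=False):
    """Impulses at random integer voxels inside a sphere.

    ``signed=True`` alternates atom amplitudes in sign (zero-mean field):
    a nonzero mean density carries the region's form factor into the
    lowest analysis bands, which would contaminate B-factor recovery with
    the region shape rather than the imposed Fourier decay.
    """
    out = np.zeros((box, box, box))
    count = 0
    while count < n_atoms:
        pts = rng.integers(0, box, size=(4 * n_atoms, 3))
        d2 = ((pts - np.asarray(center)) ** 2).sum(axis=1)
        pts = pts[d2 <= radius_vox**2]
        for pt in pts[: n_atoms - count]:
            amp = rng.choice((-1.0, 1.0)) if signed else 1.0
            out[tuple(pt)] += amp
        count += min(len(pts), n_atoms - count)
    return out


def _sphere(box, center, radius_vox):
    idx = np.indices((box, box, box))
    d2 = sum((idx[a] - center[a]) ** 2 for a in range(3))
    return d2 <= radius_vox**2


def _support_mask(signal: np.ndarray) -> np.ndarray:
    peak = np.abs(signal).max()
    support = np.abs(signal) > SUPPORT_LEVEL * peak if peak > 0 else np.zeros_like(signal, bool)
    return binary_dilation(support, iterations=MASK_DILATION)


def make_phantom(spec: PhantomSpec) -> tuple[VolumeGrid, SolventMask, dict]:
    """Build (map, tight mask, ground-truth record) for the given recipe."""
    n = spec.box
    vx = spec.voxel_size
    p = spec.params
    rng = np.random.default_rng(spec.seed)
    coords = np.arange(n) * vx
    truth: dict = {"kind": spec.kind}

    if spec.kind == "plane_wave":
        freq = p["freq"]
        if freq > 0.5 / vx:
            raise ValueError(f"frequency {freq} 1/A above Nyquist {0.5 / vx} 1/A")
        x = coords.reshape([-1 if a == p["axis"] else 1 for a in range(3)])
        signal = np.broadcast_to(np.cos(2 * np.pi * freq * x), (n, n, n)).copy()
        mask = np.ones((n, n, n), dtype=np.uint8)
        truth.update(freq=freq)
        return (VolumeGrid(signal, vx), SolventMask(mask, vx), truth)

    if spec.kind == "modulated_wave":
        freq, sig = p["freq"], p["sigma"]
        if freq > 0.5 / vx:
            raise ValueError(f"frequency {freq} 1/A above Nyquist {0.5 / vx} 1/A")
        c = (n // 2) * vx
        idx = np.indices((n, n, n)).astype(float) * vx
        r2 = sum((idx[a] - c) ** 2 for a in range(3))
        envelope = np.exp(-r2 / (2 * sig**2))
        x = coords.reshape([-1 if a == p["axis"] else 1 for a in range(3)])
        signal = envelope * np.cos(2 * np.pi * freq * x)
        mask = _support_mask(envelope - 0.0).astype(np.uint8)
        truth.update(freq=freq, envelope=envelope)
        return (VolumeGrid(signal, vx), SolventMask(mask, vx), truth)

    if spec.kind == "gaussian_atoms":
        radius = p["radius"] if p["radius"] is not None else n * vx / 4
        center = (n // 2,) * 3
        impulses = _scatter_atoms(rng, n, center, radius / vx, p["n_atoms"],
                                  signed=p["signed"])
        signal = _gaussian_blur_fourier(impulses, p["atom_sigma"], vx)
        vol = VolumeGrid(signal, vx)
        if p["b_factor"]:
            vol = impose_bfactor(vol, p["b_factor"])
        # atoms fill the sphere, so the sphere is the signal support
        mask = binary_dilation(_sphere(n, center, radius / vx),
                               iterations=MASK_DILATION)
        core = _sphere(n, center, radius / vx - MASK_DILATION)
        data, noise_sigma = _maybe_add_noise(vol.data, mask, p["snr"], rng)
        truth.update(
            b_true=p["b_factor"], atom_sigma=p["atom_sigma"],
            core_mask=core, noise_sigma=noise_sigma,
        )
        return (VolumeGrid(data, vx), SolventMask(mask.astype(np.uint8), vx), truth)

    if spec.kind == "two_region_b":
        radius = p["radius"] if p["radius"] is not None else n * vx / 6
        off = n // 4
        centers = [(n // 2 - off, n // 2, n // 2), (n // 2 + off, n // 2, n // 2)]
        total = np.zeros((n, n, n))
        cores = []
        for center, b in zip(centers, p["b_factors"]):
            imp = _scatter_atoms(rng, n, center, radius / vx, p["n_atoms"],
                                 signed=p["signed"])
            sig = _gaussian_blur_fourier(imp, p["atom_sigma"], vx)
            sig = impose_bfactor(VolumeGrid(sig, vx), b).data
            # equalise in-region power: a scalar rescale leaves the local
            # Guinier slope (the imposed B) unchanged but gives both
            # regions the same SNR against the common noise floor
            sphere = _sphere(n, center, radius / vx)
            sig /= np.sqrt(np.mean(sig[sphere] ** 2))
            total += sig
            cores.append(_sphere(n, center, radius / vx - MASK_DILATION))
        mask = binary_dilation(_sphere(n, centers[0], radius / vx)
                               | _sphere(n, centers[1], radius / vx),
                               iterations=MASK_DILATION)
        data, noise_sigma = _maybe_add_noise(total, mask, p["snr"], rng)
        truth.update(
            b_factors=tuple(p["b_factors"]), region_cores=cores,
            noise_sigma=noise_sigma,
        )
        return (VolumeGrid(data, vx), SolventMask(mask.astype(np.uint8), vx), truth)

    if spec.kind == "partial_occupancy":
        radius = p["radius"] if p["radius"] is not None else n * vx / 6
        off = n // 4
        centers = [(n // 2 - off, n // 2, n // 2), (n // 2 + off, n // 2, n // 2)]
        scales = (1.0, float(p["occupancy"]))
        # one motif realisation, copied to both sites so shapes are identical
        rel = _scatter_atoms(rng, n, (n // 2, n // 2, n // 2), radius / vx, p["n_atoms"])
        total = np.zeros((n, n, n))
        cores = []
        for center, s in zip(centers, scales):
            shifted = np.roll(rel, center[0] - n // 2, axis=0)
            total += s * shifted
            cores.append(_sphere(n, center, radius / vx - MASK_DILATION))
        total = _gaussian_blur_fourier(total, p["atom_sigma"], vx)
        # the tight mask covers only sites that actually hold density;
        # a fully absent motif (scale 0) is solvent, not macromolecule
        spheres = [
            _sphere(n, c, radius / vx)
            for c, s in zip(centers, scales) if s > 0
        ]
        mask = binary_dilation(np.logical_or.reduce(spheres),
                               iterations=MASK_DILATION)
        data, noise_sigma = _maybe_add_noise(total, mask, p["snr"], rng)
        truth.update(
            occupancies=scales, region_cores=cores, noise_sigma=noise_sigma,
        )
        return (VolumeGrid(data, vx), SolventMask(mask.astype(np.uint8), vx), truth)

    # noise_only
    sigma = p["sigma"]
    noise = rng.normal(0.0, sigma, size=(n, n, n))
    if p["colored"]:
        # band-shape the spectrum so the per-band quantile thresholds are
        # tested under non-flat noise
        q2 = _q2_grid(n, vx)
        shape_f = 1.0 / (1.0 + q2 / (0.05**2))
        noise = scipy.fft.ifftn(scipy.fft.fftn(noise) * np.sqrt(shape_f)).real
        noise *= sigma / noise.std()
    mradius = p["mask_radius"] if p["mask_radius"] is not None else n / 4
    mask = _sphere(n, (n // 2,) * 3, mradius)
    truth.update(noise_sigma=sigma)
    return (VolumeGrid(noise, vx), SolventMask(mask.astype(np.uint8), vx), truth)


def _maybe_add_noise(signal, support, snr, rng):
    """White Gaussian noise at the requested in-support SNR (None = noiseless)."""
    if snr is None:
        return signal, 0.0
    rms = float(np.sqrt(np.mean(signal[support] ** 2)))
    sigma = rms / snr
    return signal + rng.normal(0.0, sigma, size=signal.shape), sigma
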