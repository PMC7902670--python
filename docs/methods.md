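# Methods

## The model

A cryo-EM density map V(r) is treated, after removal of its low-frequency
background by a smooth high-pass filter (default 30 Å), as a superposition
of band-passed components, each an amplitude-modulated oscillation:

    V_HP(r) = Σ_ω m_ω(r) · cos(φ_ω(r))

where ω indexes a discrete set of spatial-frequency bands, m_ω(r) ≥ 0 is the
local amplitude ("strength" of the map signal at resolution 1/ω around r)
and cos(φ_ω) the local phase term carrying the shape. The factorisation is
computed per band with the isotropic Riesz (spiral phase) transform: the
Fourier multiplier −i q_a/|q| is applied per frequency component a, the
three inverse transforms are combined as a Euclidean norm into an unsigned
quadrature magnitude Q, and

    m_ω = sqrt(V_ω² + Q²),   cos(φ_ω) = V_ω / m_ω  (0 where m_ω ≈ 0).

Only the Riesz magnitude is used; the quadrature sign is never needed
because both the amplitude and the cosine ratio are sign-free. The
multiplier at q = 0 is defined as 0 (DC is already removed). The
factorisation is exact for a pure plane wave and accurate to a few percent
for envelopes that vary slowly compared to the carrier — the
envelope-recovery test quantifies this assumption (≤ 5 % relative error for
a Gaussian envelope with σ = 12 Å modulating a 8 Å carrier, away from the
envelope tails).

### Filter bank

Band profiles H_i(|q|) are raised-cosine annuli with half overlap whose
squares form a partition of unity over the analysis band [1/r_min, 1/r_max]:
Σ_i H_i² = 1 to ≲10⁻⁹ on that interval. Centres are uniformly spaced in
spatial frequency; the default spacing is two Fourier voxels
(2/(N·voxel_size)), capped at 40 bands, and a spacing below one Fourier
voxel is rejected. A smooth error-function high-pass (default 30 Å, edge
scale of half a Fourier voxel) is composed into every profile, and H_i(0)=0
always. Because the squares, not the profiles, sum to one, the plain sum of
band outputs carries a composite response Σ_i H_i ∈ [1, √2] inside the
band; the methods below never rely on additive reconstruction of the raw
bands (they resynthesise with replaced amplitudes), so the H² normalisation
is the appropriate one for amplitude estimation.

A soft cosine edge covering 5 % of the box width is applied in real space
before the transforms (wrap-around suppression); it can be disabled.
Non-cubic maps are zero-padded to the smallest enclosing cube and cropped
back on output. Anisotropic voxel sizes are rejected.

## LocSpiral — local enhancement

For each band, the empirical amplitude distribution of voxels *outside* the
solvent mask defines a noise threshold m_ω^N(q), the nearest-rank q-quantile
(default q = 0.95; accepted range 0.90–0.99; at least 1000 outside voxels
are required). The enhanced map is

    V'(r) = Σ_ω C_ref,ω(r) · [m_ω(r) > m_ω^N(q)] · cos(φ_ω(r)),

i.e. surviving signal is re-expressed with unit (noise-normalised) local
amplitude, optionally weighted by the SNR factor
C_ref = m/(m + m^N) ∈ [0, 1), which equals 0.5 exactly at the threshold.
By the nearest-rank definition at most a fraction (1−q) of outside voxels
can pass each band's indicator — the noise-suppression contract is exact,
not statistical. A soft variant replaces the unit amplitude by
min(m/m^N, 1).

## LocBSharpen — local amplitude clamping

The local amplitude of every band at or beyond a user-chosen reference
frequency ω₀ (1/ω₀ typically 15–10 Å) is replaced by the band-ω₀ amplitude
map m_ω0(r), flattening the local amplitude fall-off:

    V'(r) = Σ_{ω<ω0} C·m_ω·cos(φ_ω) + Σ_{ω≥ω0} C·m_ω0·cos(φ_ω).

The clamped amplitude is the linear band amplitude m_ω0(r); an option
substitutes exp(A(r)) from the local Guinier fit instead. No indicator
thresholding is applied here; C_ref provides the soft noise damping.
Re-decomposing a sharpened phantom shows per-band mean amplitudes flat to
≤ 10 % CoV (after removing the C_ref trend; the band straddling ω₀ mixes
clamped and unclamped content through the filter overlap and is excluded
from that measurement).

## LocBFactor — per-voxel Guinier analysis

At every voxel the SNR-weighted log-amplitudes log F_ω = log(C_ref,ω·m_ω)
are fitted by unweighted OLS against squared frequency over the analysis
range (conventionally [15 Å, global resolution]), anchored at the lowest
band frequency ω₀:

    log F_ω(r) ≈ B(r)·(ω² − ω₀²) + A(r).

B(r) is the local Guinier slope (Å²) and 4·B(r) the sharpening B-factor
under the exp(−B ω²/4) amplitude-decay convention (a slope of −21.14 Å²
gives a sharpening B of −84.56 Å²). Bands whose amplitude does not
*strictly* exceed the noise threshold are excluded; voxels with fewer than
two surviving samples are invalid (NaN in the output maps, 0 in the
validity mask) — such fits would track the noise fall-off, not the
structure. A(r) is the log-amplitude at the low-resolution anchor ω₀.

**Shell-gain normalisation.** A band-pass shell integrates a number of
Fourier modes proportional to its surface area, so the raw local amplitude
of a flat-spectrum field grows with ω. Left in place, this geometric trend
biases the fitted slope by the effective slope of log ω against ω² — tens
of Å² over a [15, 3.5] Å range, dominated by the low-frequency end. Each
band's amplitude is therefore divided, inside the logarithm only, by the
filter's RMS gain on a flat spectrum, sqrt(mean_q H_i²). Thresholds, C_ref
and the above-noise rule compare amplitudes within one band and are
unaffected. The normalisation is what makes the recovery experiments below
track the imposed decay; it can be disabled.

## LocOccupancy — density occupancy

Per band, the in-mask (macromolecule) amplitude distribution defines two
thresholds: the nearest-rank 25 % quantile m_ω^M(25 %) and the minimum
m_ω^M(0 %). The occupancy of a voxel over the range is

    O(r) = Σ_ω [m_ω(r) > m_ω^M(25%)] / Σ_ω [m_ω(r) ≥ m_ω^M(0%)],

defined as 0 where the denominator vanishes. O ∈ [0, 1], is monotone in
local amplitude, and is exactly invariant under global rescaling of the map
(quantiles rescale identically). C_ref plays no role here. An option
replaces the denominator by the plain band count. Typical ranges: 30 to
10–8 Å for secondary-structure-scale occupancies, 5 to ~1.5 Å for
high-resolution maps.

## Maturity-level index

Given a mature reference reconstruction and an intermediate, the
intermediate's occupancy map is thresholded at O > 0.75 to give an
occupancy mask; the index is the percentage of mature-reference-mask voxels
present in that occupancy mask (the occupancy mask is intersected with the
reference first, so the index cannot exceed 100 %). Missing densities are
segmented as the mature map restricted to reference-mask voxels absent
from the intermediate's occupancy mask.

## Numerical choices

- **Quantiles**: one rule everywhere — nearest rank, the ceil(q·n)-th
  smallest of n values; q = 0 is the minimum exactly. This makes the
  ≤ (1−q) pass-fraction bound exact.
- **Strict inequalities**: above-noise and occupancy-numerator comparisons
  use strict >; a sample exactly at a threshold does not pass.
- **Cosine floor**: cos(φ) is set to 0 where the amplitude is below 10⁻¹²
  of the decomposition's global maximum amplitude, so numerically empty
  bands cannot turn FFT round-off into ±1 phase patterns.
- **Ties/degenerate fits**: a voxel fit is invalid when fewer than two
  samples survive or the design matrix is singular (all surviving samples
  at one frequency).
- **Output conventions**: B-maps and 4×B sharpening maps are both written;
  invalid voxels are NaN plus a companion binary validity mask.

## The phantom generator

Phantoms emulate the method's inputs with known ground truth on a 64³ grid
at 1 Å/voxel by default:

- **plane_wave / modulated_wave** — exact cosine carriers, optionally under
  a Gaussian envelope; probe the factorisation itself.
- **gaussian_atoms** — impulses at random voxels inside a sphere, blurred
  by a σ = 0.25 Å Gaussian (intrinsic B ≈ 5 Å², small against the imposed
  values), optionally damped by exp(−B ω²/4) and noised. Atom amplitudes
  alternate in sign by default: a net-positive region carries its shape's
  form factor into the lowest analysis bands, which would contaminate the
  recovered slope with region geometry rather than the imposed decay.
- **two_region_b** — two such clusters with different imposed B; each
  region is rescaled to unit in-sphere RMS (a scalar, slope-preserving)
  so both face the common noise floor at the same SNR.
- **partial_occupancy** — one motif realisation copied to two sites, the
  second scaled by an occupancy factor; the motif is dense (1000 atoms,
  ~20 % voxel fill) emulating a filled protein envelope. The mask covers
  only sites with non-zero scale.
- **noise_only** — white (optionally band-shaped) Gaussian noise with a
  central spherical mask; probes the quantile contracts.

Noise is white Gaussian in real space; its σ is set from the requested
in-support signal RMS over SNR. Masks derive from the generating geometry
(spheres dilated by 2 voxels), so mask quality is not a confounder.

What the phantoms do *not* emulate: CTF effects, reconstruction
artefacts, soft molecular envelopes, correlated (reconstruction-weighted)
noise, or conformational blurring. Passing the recovery experiments shows
the estimators track imposed amplitude decay and occupancy under white
noise at moderate SNR; it does not certify behaviour on maps with strongly
anisotropic resolution or model-correlated noise.

## Experiment scales

The recovery experiments run on 64³ boxes: B-factor recovery uses imposed
B ∈ {50, 100, 300} Å² at SNR 3 over [15, 3.5] Å (the phantom's content
extends to near-Nyquist, so the analysis edge sits at its resolution
limit), three seeds each, recovering −B within 20 % in region cores;
occupancy separates full from half-density motifs by ≥ 0.2 mean occupancy
at SNR 3; the maturity index is exactly 100 % for identical inputs and
≈ 50 % after deleting one of two identical motifs. The two-region spectral
oracle uses a 128³ box so the Gaussian analysis windows resolve the
imposed decay.

## Known limitations

- Local amplitudes at band ω are blurred over ≈ the band kernel width
  (one over the band spacing), so B- and occupancy maps have an intrinsic
  spatial resolution far coarser than the voxel size.
- Near region boundaries the Guinier fit mixes populations; region-core
  statistics are the meaningful summaries.
- For maps whose local resolution is coarser than the chosen range, the
  surviving points describe noise; the two-point rule removes most such
  voxels but a conservative r_max is the real safeguard.
- The occupancy denominator's 0 %-quantile indicator is near-saturated by
  construction; the alternative plain band count changes O only at voxels
  weaker than the weakest in-mask signal.
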