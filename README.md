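# combinesr

Super-resolution MRI with the low-flip-angle unbalanced-SSFP off-resonance
comb: a simulator and reconstruction/analysis toolkit.

## The idea

A balanced SSFP sequence run at a very low flip angle (α ≤ 1°) has a
steady-state off-resonance profile that approximates a damped comb: sharp
magnitude peaks wherever the per-TR precession angle θ is a multiple of 2π,
repeating every 1/TR in frequency. Adding an unbalanced spoiler gradient of
area 4π·k_max/γ per excitation turns that spectral comb into a *spatial*
modulation with exactly one period per acquired voxel, so each
low-resolution voxel's signal comes predominantly from a narrow region
inside it. Incrementing the RF phase by Δφ between excitations slides the
comb across the voxel by Δφ/2π of a voxel. A series of N phase-cycled
low-resolution images therefore samples every sub-voxel position — the MRI
analogue of non-linear structured illumination microscopy — and can be
merged into a super-resolution image at a tiny fraction of the usual RF
power (SAR).

Two reconstructions are provided:

* **Interleaving** — take the magnitude of each low-resolution image and
  slot the voxels into the fine grid in pattern-shift order.
* **k-space band least squares** — writing the periodic pattern as a
  Fourier series with configuration-state amplitudes F₀, F₁, … (one-sided
  for tissues with T₂ ≪ T₁), frame n measures

      sₙ(k) = Σₘ e^(−i m Δφₙ) · F₍ₘ₋₁₎ · S(k + 2(m−1)k_max),  m = 1..M,

  a Ψ·x = s system with Ψ[n,m] = e^(−i m Δφₙ) solved per k-sample by one
  pseudoinverse. The M recovered bands are equalized by 1/F₍ₘ₋₁₎, mirrored
  by conjugate symmetry (partial Fourier), and inverse-transformed into an
  image (2M−1)× finer than the acquisition. A local off-resonance ω
  (radians per TR) multiplies band m by e^(i m ω); because the central
  band's voxel phase equals ω, the data navigate their own B0 correction:
  the multi-frequency reconstruction tries n_freqs offsets, picks per voxel
  the one minimizing |phase|, and returns the image plus the ω map.

The analysis module quantifies the technique: PSF width vs number of bands
M (the harmonic decay, set mostly by exp(−TR/T₂), imposes a tissue-dependent
limiting FWHM), closed-form noise propagation of the equalized
reconstruction (σ²_comb = N⁻¹·tr(Σ_comb⁻²)·σ_s²) against an M-segment
spoiled-GRE comparator at the Ernst angle, geometric distortion under B0
gradients, and phase-encode gradient-area savings.

It is written for MRI physicists prototyping comb super-resolution
protocols: everything runs on synthetic phantoms, no scanner required.

## Worked example

```python
import numpy as np
from combinesr import (AcquisitionScheme, ReconSpec, SequenceParams,
                       make_brain_phantom, simulate_combine_series,
                       multifrequency_recon, GRAY_MATTER,
                       psf_fwhm, relative_snr, gradient_area_savings)

maps = make_brain_phantom(128)                       # 3-compartment head
seq = SequenceParams(tr=8, te=4, flip=0.5)
scheme = AcquisitionScheme(n_images=36, n_pe=16, n_fe=128)
series = simulate_combine_series(maps, None, seq, scheme, fidelity="profile")
spec = ReconSpec(m_bands=3, n_freqs=100, equalize=True, tissue_ref=GRAY_MATTER)
result = multifrequency_recon(series, spec)
print(result.image.shape)                            # (80, 128): (2M-1) x 16 rows
print(float(np.median(result.omega_map)))            # 0.0628 = one trial step

print(psf_fwhm(GRAY_MATTER, SequenceParams(tr=8, te=4, flip=1), 8).fwhm_fraction)
# 9.29   -> with 8 bands the PSF is 9.3% of the acquired voxel width
print(relative_snr(GRAY_MATTER, SequenceParams(tr=8, te=4, flip=1), 3, 3).snr_ratio)
# 0.4119 -> 41% of the SNR of a 3-segment Ernst-angle spoiled GRE at 3T values
print(gradient_area_savings(3)["total_factor"])
# 2.5    -> total phase-encode gradient area reduced 2.5-fold
```

The 16-line frames reconstruct to an 80-row image: three k-space bands give
a 5× finer grid along the pattern axis. With no B0 applied the selected ω
sits within one trial step of zero (the residual is the configuration-state
phase of the non-reference tissues). The PSF and SNR numbers trade against
each other through the harmonic decay of the tissue's comb.

A CLI covers the same pipeline: `combine phantom`, `combine simulate`,
`combine recon`, `combine analyze` (see `combine --help`); series are
stored as self-describing HDF5, images and ω maps as NIfTI.

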