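"""Super-resolution reconstruction from phase-cycled unbalanced-SSFP series.

Two routes are provided:

* :func:`interleave_recon` — the image-domain route: take the magnitude of
  each low-resolution image and interleave the voxels in pattern-shift
  order (no deconvolution).
* :func:`multifrequency_recon` / :func:`solve_bands` — the k-space route:
  at every low-resolution k-space coordinate solve the least-squares system
  ``Psi @ [S(k), S(k + 2 k_max), ..., S(k + 2(M-1) k_max)] = [s_1 ... s_N]``
  with ``Psi[n, m] = exp(-i*m*dphi_n)``, assemble the M one-sided bands into
  a wide k-space, optionally equalize each band by the inverse of its
  configuration-state amplitude, and complete the missing half by conjugate
  symmetry.  A B0 offset ``omega = 2*pi*b0*TR`` multiplies band m by
  ``exp(+i*m*omega)``, which the multi-frequency reconstruction exploits:
  the phase of the zero-filled central band is itself an omega navigator.

Band m = 1..M covers wide-grid frequencies ``[(2m-3)h, (2m-1)h)`` rows
(h = n_pe/2), band 1 being the central band; the output size along the
super-resolution axis is exactly ``(2M-1) * n_pe``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .acquisition import AcquisitionSeries
from .kspace import band_slice, conjugate_fill, ifft2c
from .physics import (
    HarmonicSpectrum,
    SequenceParams,
    Tissue,
    harmonic_spectrum,
    steady_state_profile,
)

__all__ = [
    "ReconSpec",
    "SRResult",
    "build_psi",
    "interleave_recon",
    "solve_bands",
    "equalize_harmonics",
    "partial_fourier_complete",
    "multifrequency_recon",
    "tissue_band_spectrum",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReconSpec:
    """Reconstruction parameters.

    m_bands : number of one-sided k-space bands M (1 <= M <= N).
    n_freqs : trial frequency offsets for the multi-frequency route.
    equalize : divide band m by its configuration-state amplitude.
    tissue_ref : tissue whose harmonic spectrum supplies the band weights
        when ``equalize`` is on (also de-biases the navigator phase).
    include_negative_orders : keep this False for the one-sided route; the
        flag exists for tissues with very long T1 and T2 whose negative
        configuration states are not negligible.
    """

    m_bands: int
    n_freqs: int = 1
    equalize: bool = False
    tissue_ref: Tissue | None = None
    include_negative_orders: bool = False

    def __post_init__(self) -> None:
        if self.m_bands < 1:
            raise ValueError("m_bands must be >= 1")
        if self.n_freqs < 1:
            raise ValueError("n_freqs must be >= 1")
        if self.equalize and self.tissue_ref is None:
            raise ValueError("equalize=True requires tissue_ref")


@dataclass(frozen=True)
class SRResult:
    """Super-resolution image plus reconstruction provenance.

    ``image`` is complex with the super-resolution axis restored to the
    series' ``sr_axis``; ``omega_map`` (radians per TR, same shape) is
    present only when the multi-frequency route ran.
    """

    image: np.ndarray
    spec: ReconSpec
    omega_map: np.ndarray | None = None


def build_psi(phase_increments, m_bands: int) -> np.ndarray:
    """Pattern-shift encoding matrix, entry (n, m) = exp(-i*m*dphi_n), m=1..M."""
    dphi = np.asarray(phase_increments, dtype=float)
    if dphi.ndim != 1 or dphi.size < 1:
        raise ValueError("phase_increments must be a non-empty 1-D sequence")
    if m_bands < 1:
        raise ValueError("m_bands must be >= 1")
    m = np.arange(1, m_bands + 1)
    return np.exp(-1j * np.outer(dphi, m))


def _check_equidistant(dphi: np.ndarray) -> None:
    n = dphi.size
    if not np.allclose(np.mod(dphi - dphi[0], 2 * np.pi), 2 * np.pi * np.arange(n) / n):
        raise ValueError(
            "interleaving requires equidistant phase increments covering 2*pi"
        )


def interleave_recon(series: AcquisitionSeries) -> np.ndarray:
    """Magnitude interleaving of the low-resolution images (no deconvolution).

    Frame n samples the object at the intravoxel position of its modulation
    peak, offset by ``dphi_n / (2*pi)`` nominal voxels from the dphi=0 peak
    at the voxel's first super-resolution sample; each magnitude image is
    slotted into the super-resolution grid at that offset.  Requires N
    equidistant phase increments (the patterns then tile each voxel
    uniformly) and returns a real image of shape (N * n_pe, n_fe) along the
    pattern axis.
    """
    scheme = series.scheme
    dphi = scheme.phase_increments
    n = scheme.n_images
    if n == 1:
        out = np.abs(series.lowres_images()[0])
        return out if scheme.sr_axis == 0 else out.T
    _check_equidistant(dphi)
    mags = np.abs(series.lowres_images())
    out = np.zeros((n * scheme.n_pe, scheme.n_fe))
    for i, d in enumerate(dphi):
        slot = int(np.round(-n * d / (2 * np.pi))) % n
        out[slot::n, :] = mags[i]
    return out if scheme.sr_axis == 0 else out.T


def solve_bands(
    series: AcquisitionSeries,
    spec: ReconSpec,
    freq_offset: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares recovery of M one-sided k-space bands.

    Solves the N x M system with one precomputed pseudoinverse of Psi
    (identical at every k-space coordinate), removes the trial B0 phase
    ``exp(+i*m*freq_offset)`` from band m, and assembles the bands on the
    wide fftshifted grid of ``(2M-1)*n_pe`` rows.  Returns ``(kspace,
    filled)`` where ``filled`` marks the measured (one-sided) half.

    Raises if M > N or Psi is rank deficient.
    """
    scheme = series.scheme
    m_bands = spec.m_bands
    if m_bands > scheme.n_images:
        raise ValueError(
            f"m_bands={m_bands} exceeds the number of images N={scheme.n_images}"
        )
    psi = build_psi(scheme.phase_increments, m_bands)
    if np.linalg.matrix_rank(psi) < m_bands:
        raise np.linalg.LinAlgError(
            "Psi is rank deficient for the given phase increments"
        )
    logger.debug("Psi condition number: %.3g", np.linalg.cond(psi))
    pinv = np.linalg.pinv(psi)

    n_pe, n_fe = scheme.n_pe, scheme.n_fe
    data = series.frames.reshape(scheme.n_images, -1)
    bands = pinv @ data  # (M, n_pe*n_fe)
    m = np.arange(1, m_bands + 1)
    bands = bands * np.exp(-1j * m * freq_offset)[:, None]
    bands = bands.reshape(m_bands, n_pe, n_fe)

    wide_rows = (2 * m_bands - 1) * n_pe
    k = np.zeros((wide_rows, n_fe), dtype=complex)
    filled = np.zeros((wide_rows, n_fe), dtype=bool)
    for mm in range(1, m_bands + 1):
        sl = band_slice(mm, n_pe, wide_rows)
        k[sl, :] = bands[mm - 1]
        filled[sl, :] = True
    return k, filled


def tissue_band_spectrum(
    tissue: Tissue, seq: SequenceParams, m_bands: int, n_theta: int = 512
) -> HarmonicSpectrum:
    """Configuration-state amplitudes of a tissue's modulation pattern.

    Band m of the acquisition carries harmonic order m-1 of the steady-state
    profile (the central band is the zeroth configuration state), so the
    returned spectrum is evaluated up to order ``m_bands - 1``.  The weights
    are computed at unit proton density — pd scales the object, not the
    modulation pattern — so equalizing with them recovers the pd-weighted
    object in absolute units.  Results are cached: the underlying Bloch
    iteration depends only on (T1, T2, TR, TE, flip) and the grid size.
    """
    ref = Tissue(t1=tissue.t1, t2=tissue.t2, pd=1.0)
    return _cached_band_spectrum(
        ref, seq.tr, seq.te, seq.flip, max(m_bands - 1, 1), n_theta
    )


@lru_cache(maxsize=64)
def _cached_band_spectrum(tissue, tr, te, flip, m_max, n_theta):
    profile = steady_state_profile(
        tissue, SequenceParams(tr=tr, te=te, flip=flip), n_theta
    )
    return harmonic_spectrum(profile, m_max)


def equalize_harmonics(
    sr_kspace: np.ndarray,
    spectrum: HarmonicSpectrum,
    n_pe: int | None = None,
    normalize_band1: bool = False,
    drop_tol: float = 1e-12,
) -> np.ndarray:
    """Divide each one-sided band by its configuration-state amplitude.

    Reverses the implicit low-pass filtering of the comb acquisition: band m
    is scaled by ``1 / amplitude(m-1)`` (or ``amplitude(0)/amplitude(m-1)``
    with ``normalize_band1``, leaving the central band untouched).  Bands
    whose amplitude magnitude is below ``drop_tol`` times the maximum are
    dropped (zeroed) with a warning rather than amplified to infinity.
    """
    amps = spectrum.amplitude(np.arange(0, spectrum.m_max + 1))
    if np.all(np.abs(amps) == 0):
        raise ValueError("all-zero harmonic spectrum")
    rows = sr_kspace.shape[0]
    if n_pe is None:
        # assume the spectrum was computed for exactly the bands present
        if rows % (2 * spectrum.m_max + 1):
            raise ValueError("cannot infer n_pe from the spectrum; pass it")
        n_pe = rows // (2 * spectrum.m_max + 1)
    m_bands = (rows // n_pe + 1) // 2
    if (2 * m_bands - 1) * n_pe != rows:
        raise ValueError(f"{rows} rows is not (2M-1)*n_pe for n_pe={n_pe}")
    if m_bands - 1 > spectrum.m_max:
        raise ValueError(
            f"spectrum provides orders up to {spectrum.m_max}; need {m_bands - 1}"
        )
    out = sr_kspace.copy()
    ref = np.max(np.abs(amps))
    scale0 = amps[0] if normalize_band1 else 1.0
    for mm in range(1, m_bands + 1):
        amp = amps[mm - 1]
        sl = band_slice(mm, n_pe, rows)
        if np.abs(amp) < drop_tol * ref:
            logger.warning("band %d amplitude ~0; band dropped", mm)
            out[sl, :] = 0.0
        else:
            out[sl, :] *= scale0 / amp
    return out


def partial_fourier_complete(
    sr_kspace: np.ndarray, filled: np.ndarray | None = None
) -> np.ndarray:
    """Fill the unmeasured mirror bands by conjugate symmetry S(-k) = S(k)*.

    With the modulation phase ~0 in every voxel the super-resolution image
    is (approximately) real, so the one-sided band solution determines the
    other half of k-space exactly.  ``filled`` defaults to marking every
    nonzero sample as measured.
    """
    if filled is None:
        filled = sr_kspace != 0
    return conjugate_fill(sr_kspace, filled)


def _single_frequency_image(series, spec, spectrum, freq_offset):
    k, filled = solve_bands(series, spec, freq_offset)
    if spec.equalize:
        k = equalize_harmonics(k, spectrum, n_pe=series.scheme.n_pe)
        filled = filled & (k != 0)
    k = partial_fourier_complete(k, filled)
    return ifft2c(k)


def reconstruct(
    series: AcquisitionSeries, spec: ReconSpec, freq_offset: float = 0.0
) -> SRResult:
    """Single-frequency band reconstruction (the n_freqs=1 path)."""
    spectrum = (
        tissue_band_spectrum(spec.tissue_ref, series.seq, spec.m_bands)
        if spec.tissue_ref is not None
        else None
    )
    img = _single_frequency_image(series, spec, spectrum, freq_offset)
    if series.scheme.sr_axis == 1:
        img = img.T
    return SRResult(image=img, spec=spec, omega_map=None)


def multifrequency_recon(series: AcquisitionSeries, spec: ReconSpec) -> SRResult:
    """Self-navigated multi-frequency B0-corrected reconstruction.

    For each of ``n_freqs`` equidistant trial offsets omega in [0, 2*pi):
    the low-pass image from the zero-filled central band acquires phase
    ``(omega_true - omega)`` per voxel, so the trial minimizing the absolute
    voxel phase estimates the local per-TR off-resonance angle.  The final
    image is assembled voxel-by-voxel from full reconstructions at each
    selected omega.  Ties in |phase| break toward the smaller omega.

    When ``tissue_ref`` is given the constant configuration-state phase of
    the central band is removed before the phase is read off; without it the
    navigator carries that tissue-dependent bias.
    """
    scheme = series.scheme
    if spec.n_freqs == 1:
        res = reconstruct(series, spec, 0.0)
        omega = np.zeros(res.image.shape)
        return SRResult(image=res.image, spec=spec, omega_map=omega)

    spectrum = (
        tissue_band_spectrum(spec.tissue_ref, series.seq, max(spec.m_bands, 2))
        if spec.tissue_ref is not None
        else None
    )
    bias = np.angle(spectrum.amplitude(0)) if spectrum is not None else 0.0

    # navigator: central band of the band solve, zero-filled to the SR grid
    k1, _ = solve_bands(series, ReconSpec(m_bands=spec.m_bands), 0.0)
    n_pe = scheme.n_pe
    rows = k1.shape[0]
    lp = np.zeros_like(k1)
    sl = band_slice(1, n_pe, rows)
    lp[sl, :] = k1[sl, :]
    lp_img = ifft2c(lp)
    omega_grid = 2.0 * np.pi * np.arange(spec.n_freqs) / spec.n_freqs
    voxel_phase = np.angle(lp_img * np.exp(-1j * bias))
    # residual phase after demodulating by trial omega; minimize |wrapped|
    resid = np.angle(
        np.exp(1j * (voxel_phase[None, :, :] - omega_grid[:, None, None]))
    )
    best = np.argmin(np.abs(np.round(resid, 12)), axis=0)  # ties -> smaller omega
    omega_map = omega_grid[best]

    image = np.zeros(lp_img.shape, dtype=complex)
    for idx in np.unique(best):
        img = _single_frequency_image(series, spec, spectrum, omega_grid[idx])
        sel = best == idx
        image[sel] = img[sel]
    if spec.n_freqs < 8:
        logger.info(
            "only %d trial offsets; phase wraps may be unresolved", spec.n_freqs
        )
    if scheme.sr_axis == 1:
        image = image.T
        omega_map = omega_map.T
    return SRResult(image=image, spec=spec, omega_map=omega_map)
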