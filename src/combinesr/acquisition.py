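"""Forward simulation of comb super-resolution (COMBINE) acquisitions.

An acquisition is a series of N low-resolution 2-D images of the same
object, each taken with a different RF phase increment of the unbalanced
SSFP sequence.  The unbalanced spoiler gradient winds ``spoiler_cycles_per_
voxel`` cycles of precession across each nominal (low-resolution) voxel
along the super-resolution axis — the paper-standard gradient area of
4*pi*k_max/gamma corresponds to exactly one cycle — so the steady-state
off-resonance profile becomes a spatial modulation pattern with one period
per nominal voxel, and the phase increment sweeps that pattern across the
voxel.

Demodulation convention (fixed here; the reconstruction depends on it):
the stored frame for phase increment dphi is

    frame(y, x) = pd * m_ss(theta_sp(y) + omega(y,x) - dphi)
                  * exp(i*omega) * exp(-i*dphi) * exp(-TE/T2)

with ``theta_sp`` the spoiler winding (zero at each nominal voxel's first
super-resolution sample),
``omega = 2*pi*b0*TR`` the per-TR off-resonance angle, and ``m_ss`` the
post-pulse steady state.  The per-frame receiver increment ``exp(-i*dphi)``
models the receiver-phase adjustment that keeps the modulation pattern
bookkeeping aligned with the imaging grid, and the off-resonance factor
``exp(i*omega)`` is the full-TR B0 phase referenced at the echo.  Under
this convention k-space band m (band 1 central) of frame n carries exactly
``exp(-i*m*dphi_n) * exp(+i*m*omega)``, which is the model inverted by the
band least-squares reconstruction and its multi-frequency B0 navigator.

Frames are stored as fftshifted k-space arrays of shape (n_pe, n_fe); the
frequency-encode axis is ideal Fourier encoding at full resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kspace import band_slice, conjugate_fill, fft2c, ifft2c
from .phantom import FieldMaps, Grid, TissueMaps
from .physics import SequenceParams, steady_state_signal_arrays

__all__ = [
    "AcquisitionScheme",
    "AcquisitionSeries",
    "simulate_combine_series",
    "simulate_gre_reference",
    "add_complex_noise",
    "equidistant_increments",
]


def equidistant_increments(n: int) -> np.ndarray:
    """The default phase-increment schedule: dphi_n = 2*pi*(n-1)/N."""
    return 2.0 * np.pi * np.arange(n) / n


@dataclass(frozen=True)
class AcquisitionScheme:
    """Protocol of a phase-cycled unbalanced-SSFP series.

    ``n_pe`` is the low-resolution phase-encode matrix along the
    super-resolution axis, ``n_fe`` the frequency-encode matrix.
    ``phase_increments`` defaults to N equidistant steps over 2*pi.
    ``noise_sigma`` is the standard deviation of the complex receiver noise
    per k-space sample (E|n|^2 = sigma^2), in the same arbitrary units as
    the simulated signal.
    """

    n_images: int
    n_pe: int
    n_fe: int
    phase_increments: np.ndarray | None = None
    spoiler_cycles_per_voxel: float = 1.0
    sr_axis: int = 0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.spoiler_cycles_per_voxel <= 0:
            raise ValueError("spoiler_cycles_per_voxel must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.sr_axis not in (0, 1):
            raise ValueError("sr_axis must be 0 or 1")
        inc = (
            equidistant_increments(self.n_images)
            if self.phase_increments is None
            else np.asarray(self.phase_increments, dtype=float)
        )
        if inc.shape != (self.n_images,):
            raise ValueError(
                f"phase_increments must have length n_images={self.n_images}"
            )
        object.__setattr__(self, "phase_increments", inc)


@dataclass(frozen=True)
class AcquisitionSeries:
    """N low-resolution k-space frames plus everything needed to reconstruct.

    ``frames`` has shape (N, n_pe, n_fe) in the fftshifted k-space layout;
    ``grid`` is the super-resolution object grid the frames were encoded
    from, so the nominal voxel ``dy_nom = enhancement * dy``.
    """

    frames: np.ndarray
    scheme: AcquisitionScheme
    seq: SequenceParams
    grid: Grid

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=complex)
        expect = (self.scheme.n_images, self.scheme.n_pe, self.scheme.n_fe)
        if frames.shape != expect:
            raise ValueError(f"frames shape {frames.shape} != {expect}")
        n_sr = self.grid.shape[self.scheme.sr_axis]
        if n_sr % self.scheme.n_pe:
            raise ValueError(
                f"SR grid size {n_sr} not a multiple of n_pe={self.scheme.n_pe}"
            )
        object.__setattr__(self, "frames", frames)

    @property
    def enhancement(self) -> int:
        """Super-resolution factor along the pattern axis."""
        return self.grid.shape[self.scheme.sr_axis] // self.scheme.n_pe

    @property
    def dy(self) -> float:
        """Super-resolution voxel size (mm) along the pattern axis."""
        ax = self.scheme.sr_axis
        return self.grid.fov[ax] / self.grid.shape[ax]

    @property
    def dy_nom(self) -> float:
        """Nominal (acquired) voxel size (mm) along the pattern axis."""
        ax = self.scheme.sr_axis
        return self.grid.fov[ax] / self.scheme.n_pe

    def lowres_images(self) -> np.ndarray:
        """Complex low-resolution images, shape (N, n_pe, n_fe)."""
        return np.stack([ifft2c(f) for f in self.frames])


def _oriented(maps: TissueMaps, fields: FieldMaps, sr_axis: int):
    """Return (t1, t2, pd, b0, b1) with the SR axis first."""
    arrs = (maps.t1, maps.t2, maps.pd, fields.b0, fields.b1)
    if sr_axis == 1:
        arrs = tuple(a.T for a in arrs)
    return arrs


def _spoiler_angle(n_sr: int, enhancement: int, cycles: float) -> np.ndarray:
    """Per-TR spoiler precession angle at each SR sample.

    Winds ``cycles`` turns per nominal voxel, zero (mod 2*pi for integer
    cycle counts) at the first SR sample of every acquired voxel — the
    voxel's DFT reference point — so the dphi=0 modulation peak is aligned
    with the low-resolution sampling grid and the k-space band amplitudes
    are exactly the profile's harmonic coefficients.
    """
    pos = np.arange(n_sr) / enhancement  # in nominal voxels
    # negative winding: harmonic order q of the profile then multiplies the
    # object copy shifted UP by 2*q*k_max, so the measured one-sided bands
    # sit on the positive-frequency side of the wide k-space grid
    return -2.0 * np.pi * cycles * pos


def _checked_geometry(maps: TissueMaps, fields: FieldMaps, scheme: AcquisitionScheme):
    if maps.shape != fields.b0.shape:
        raise ValueError("tissue and field maps must share a grid")
    n_sr = maps.shape[scheme.sr_axis]
    n_fe = maps.shape[1 - scheme.sr_axis]
    if n_sr % scheme.n_pe:
        raise ValueError(
            f"SR grid ({n_sr}) must be an integer multiple of n_pe ({scheme.n_pe})"
        )
    if n_fe != scheme.n_fe:
        raise ValueError(
            f"frequency-encode size {n_fe} != scheme.n_fe ({scheme.n_fe})"
        )
    return n_sr, n_fe, n_sr // scheme.n_pe


def simulate_combine_series(
    maps: TissueMaps,
    fields: FieldMaps | None,
    seq: SequenceParams,
    scheme: AcquisitionScheme,
    fidelity: str = "profile",
) -> AcquisitionSeries:
    """Forward-simulate a phase-cycled unbalanced-SSFP series.

    fidelity="bloch" runs the per-isochromat recursion over every
    excitation, including ``seq.n_dummy`` dummy excitations re-establishing
    the steady state for each frame, and encodes one phase-encode line per
    excitation (bottom-to-top line order) so transient magnetization leaks
    into the data exactly as in a real scan.  fidelity="profile" is the
    steady-state shortcut: the object is multiplied by the converged,
    shifted modulation pattern and its k-space truncated to the low-
    resolution band — valid after full steady-state preparation, and the
    model the band reconstruction inverts exactly.
    """
    if fields is None:
        fields = FieldMaps.identity(maps.shape)
    n_sr, n_fe, enh = _checked_geometry(maps, fields, scheme)
    t1, t2, pd, b0, b1 = _oriented(maps, fields, scheme.sr_axis)

    fg = pd > 0
    t1s = np.where(fg, t1, 1.0)
    t2s = np.where(fg, t2, 1.0)
    theta_sp = _spoiler_angle(n_sr, enh, scheme.spoiler_cycles_per_voxel)[:, None]
    omega = 2.0 * np.pi * b0 * (seq.tr * 1e-3)
    flip_rad = seq.flip_rad * b1

    if fidelity == "profile":
        sim = _profile_frames
    elif fidelity == "bloch":
        sim = _bloch_frames
    else:
        raise ValueError(f"unknown fidelity {fidelity!r}")
    frames = sim(
        t1s, t2s, pd, flip_rad, theta_sp, omega, seq, scheme, n_sr, n_fe, enh
    )

    if scheme.noise_sigma > 0:
        frames = add_complex_noise(frames, scheme.noise_sigma, scheme.seed)
    grid = maps.grid
    return AcquisitionSeries(frames=frames, scheme=scheme, seq=seq, grid=grid)


def _band_truncate(k_full: np.ndarray, n_pe: int) -> np.ndarray:
    return k_full[band_slice(1, n_pe, k_full.shape[0]), :]


def _profile_frames(t1, t2, pd, flip_rad, theta_sp, omega, seq, scheme, n_sr, n_fe, enh):
    frames = np.empty((scheme.n_images, scheme.n_pe, n_fe), dtype=complex)
    for n, dphi in enumerate(scheme.phase_increments):
        pattern = steady_state_signal_arrays(
            t1=t1,
            t2=t2,
            pd=pd,
            flip_rad=flip_rad,
            theta=theta_sp + omega - dphi,
            tr=seq.tr,
            te=seq.te,
        )
        img = pattern * np.exp(1j * omega) * np.exp(-1j * dphi)
        frames[n] = _band_truncate(fft2c(img), scheme.n_pe)
    return frames


def _bloch_frames(t1, t2, pd, flip_rad, theta_sp, omega, seq, scheme, n_sr, n_fe, enh):
    e1 = np.exp(-seq.tr / t1)
    e2 = np.exp(-seq.tr / t2)
    e2_te = np.exp(-seq.te / t2)
    cosa = np.cos(flip_rad) * np.ones_like(e1)
    sina = np.sin(flip_rad) * np.ones_like(e1)
    n_pe = scheme.n_pe
    # DFT row vectors for each phase-encode line (fftshifted row f = l - n_pe//2
    # on the SR grid), encoding SR positions into low-resolution k-space rows
    ys = np.arange(n_sr)
    freqs = np.arange(n_pe) - n_pe // 2  # line frequency, cycles per FOV
    encode = np.exp(-2j * np.pi * np.outer(freqs, ys) / n_sr)

    frames = np.empty((scheme.n_images, n_pe, n_fe), dtype=complex)
    for n, dphi in enumerate(scheme.phase_increments):
        theta_eff = theta_sp + omega - dphi
        cost, sint = np.cos(theta_eff), np.sin(theta_eff)
        mx = np.zeros_like(e1)
        my = np.zeros_like(e1)
        mz = pd.copy()
        # pd enters through the equilibrium magnetization; not repeated here
        demod = np.exp(1j * omega) * np.exp(-1j * dphi) * e2_te

        def pulse():
            nonlocal my, mz
            my, mz = cosa * my + sina * mz, -sina * my + cosa * mz

        def evolve():
            nonlocal mx, my, mz
            mx, my = e2 * (mx * cost - my * sint), e2 * (mx * sint + my * cost)
            mz = e1 * mz + (1.0 - e1) * pd

        for _ in range(seq.n_dummy):
            pulse()
            evolve()
        for line in range(n_pe):
            pulse()
            img = (mx + 1j * my) * demod
            # one phase-encode line: project onto the line's DFT row, then
            # Fourier-encode the readout axis
            row = encode[line] @ img
            frames[n, line] = np.fft.fftshift(np.fft.fft(row))
            evolve()
    return frames


def simulate_gre_reference(
    maps: TissueMaps,
    seq: SequenceParams,
    m_segments: int,
    noise_sigma: float = 0.0,
    seed: int = 0,
    sr_axis: int = 0,
) -> np.ndarray:
    """Ideally spoiled GRE comparator with matched asymmetric k-space coverage.

    The voxel signal is the spoiled steady-state amplitude at TE = 0,
    ``pd * (1 - E1) * sin(a) / (1 - E1 cos(a))``.  The image is Fourier
    encoded on the full grid of ``maps``, but only the asymmetric band
    coverage of an ``m_segments``-segment acquisition is retained (the
    central band plus m-1 positive bands, ``n_sr / (2M-1)`` rows each);
    complex noise of ``noise_sigma`` is added to the measured samples and
    the rest completed by conjugate symmetry.  Returns the complex image.
    """
    if m_segments < 1:
        raise ValueError("m_segments must be >= 1")
    n_sr = maps.shape[sr_axis]
    if n_sr % (2 * m_segments - 1):
        raise ValueError(
            f"grid size {n_sr} must be a multiple of 2*m_segments-1"
        )
    n_pe = n_sr // (2 * m_segments - 1)
    t1 = maps.t1 if sr_axis == 0 else maps.t1.T
    pd = maps.pd if sr_axis == 0 else maps.pd.T
    fg = pd > 0
    e1 = np.exp(-seq.tr / np.where(fg, t1, 1.0))
    a = seq.flip_rad
    img = pd * (1.0 - e1) * math.sin(a) / (1.0 - e1 * math.cos(a))

    k = fft2c(img.astype(complex))
    mask = np.zeros(k.shape, dtype=bool)
    for m in range(1, m_segments + 1):
        mask[band_slice(m, n_pe, n_sr), :] = True
    k = np.where(mask, k, 0.0)
    if noise_sigma > 0:
        noise = add_complex_noise(np.zeros_like(k), noise_sigma, seed)
        k = k + np.where(mask, noise, 0.0)
    k = conjugate_fill(k, mask)
    out = ifft2c(k)
    return out if sr_axis == 0 else out.T


def add_complex_noise(kspace: np.ndarray, sigma: float, seed) -> np.ndarray:
    """Add i.i.d. circular complex Gaussian noise, E|n|^2 = sigma^2.

    ``seed`` may be an int or a ``numpy.random.Generator``; the same seed
    reproduces the same noise.  sigma=0 returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return kspace
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = sigma / math.sqrt(2.0)
    noise = rng.normal(scale=s, size=kspace.shape) + 1j * rng.normal(
        scale=s, size=kspace.shape
    )
    return kspace + noise
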