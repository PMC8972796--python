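"""Steady-state and transient SSFP signal physics.

This module computes the complex transverse magnetization of a (balanced or
unbalanced) SSFP experiment as a function of the precession angle ``theta``
accrued per TR, and decomposes the resulting periodic off-resonance profile
into its Fourier harmonics (the SSFP configuration states).  At low flip
angle the magnitude of the profile approximates a damped comb with peaks
wherever the per-TR phase accumulation is an integer multiple of 2*pi; the
complex profile is markedly one-sided in its harmonic content, which is what
the comb super-resolution reconstruction exploits.

Conventions (fixed here, honored everywhere in the package):

* ``theta`` is the total per-TR precession angle in radians,
  ``theta = 2*pi*f*TR`` with positive ``f`` meaning higher frequency.
  A positive angle rotates the complex transverse magnetization as
  ``Mxy -> Mxy * exp(+i*theta)``; with this choice the dominant
  configuration states sit on non-negative harmonic orders.
* An RF phase increment ``dphi`` per excitation, demodulated at the
  receiver, is equivalent to replacing ``theta`` by ``theta - dphi``.
* Excitation is an instantaneous rotation by the flip angle about the x
  axis of the (demodulated) rotating frame; the complex transverse signal
  is ``Mx + i*My``.
* The canonical profile value is the post-pulse steady state relaxed to the
  echo time (multiplied by exp(-TE/T2)).  This profile is exactly
  2*pi-periodic in ``theta``, which the harmonic decomposition requires.
  The additional free-precession phase ramp exp(i*theta*TE/TR) accrued at
  the echo can be applied with ``echo_phase=True`` when the at-echo phase
  profile itself is of interest; it does not change the magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Tissue",
    "SequenceParams",
    "OffResonanceProfile",
    "HarmonicSpectrum",
    "closed_form_steady_state",
    "steady_state_profile",
    "transient_signal",
    "harmonic_spectrum",
    "SteadyStateConvergenceError",
]


class SteadyStateConvergenceError(RuntimeError):
    """Raised when the fixed-point iteration does not reach tolerance."""


@dataclass(frozen=True)
class Tissue:
    """Voxel relaxation parameters.

    Parameters
    ----------
    t1, t2 : float
        Longitudinal / transverse relaxation times in ms.  ``t2 <= t1``.
    pd : float
        Proton density as a fraction of water, in [0, 1].
    """

    t1: float
    t2: float
    pd: float = 1.0

    def __post_init__(self) -> None:
        if not self.t1 > 0:
            raise ValueError(f"t1 must be positive, got {self.t1}")
        if not self.t2 > 0:
            raise ValueError(f"t2 must be positive, got {self.t2}")
        if self.t2 > self.t1:
            raise ValueError(f"t2 ({self.t2}) must not exceed t1 ({self.t1})")
        if not 0.0 <= self.pd <= 1.0:
            raise ValueError(f"pd must lie in [0, 1], got {self.pd}")


# Brain-phantom compartments (3T literature values used by the numeric phantom).
CSF = Tissue(t1=2569.0, t2=329.0, pd=1.00)
GRAY_MATTER = Tissue(t1=1331.0, t2=80.0, pd=0.86)
WHITE_MATTER = Tissue(t1=832.0, t2=110.0, pd=0.77)


@dataclass(frozen=True)
class SequenceParams:
    """SSFP sequence timing and excitation parameters.

    tr, te in ms (0 < te <= tr), flip in degrees, phase_increment in
    radians per excitation, n_dummy = discarded excitations before readout.
    """

    tr: float
    te: float
    flip: float
    phase_increment: float = 0.0
    n_dummy: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.te <= self.tr:
            raise ValueError(f"need 0 < te <= tr, got te={self.te}, tr={self.tr}")
        if self.flip < 0:
            raise ValueError(f"flip must be >= 0, got {self.flip}")
        if self.n_dummy < 0:
            raise ValueError(f"n_dummy must be >= 0, got {self.n_dummy}")

    @property
    def flip_rad(self) -> float:
        return math.radians(self.flip)


@dataclass(frozen=True)
class OffResonanceProfile:
    """Complex steady-state signal at the echo versus per-TR precession angle.

    ``theta`` is a uniform grid covering one period [0, 2*pi); ``signal`` is
    the complex transverse magnetization for each grid point.  When ``theta``
    is mapped to intravoxel position this is the spatial modulation pattern
    of the unbalanced acquisition.  ``periodic`` records whether the complex
    values are 2*pi-periodic (False when the at-echo phase ramp was applied).
    """

    theta: np.ndarray
    signal: np.ndarray
    periodic: bool = True

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        signal = np.asarray(self.signal, dtype=complex)
        if theta.ndim != 1 or theta.size < 2:
            raise ValueError("theta must be a 1-D grid with at least 2 points")
        steps = np.diff(theta)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
            raise ValueError("theta must be strictly increasing and uniform")
        if signal.shape != theta.shape:
            raise ValueError("signal and theta must have the same shape")
        if not np.all(np.isfinite(signal)):
            raise ValueError("signal must be finite everywhere")
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "signal", signal)


@dataclass(frozen=True)
class HarmonicSpectrum:
    """Fourier-series coefficients of a 2*pi-periodic off-resonance profile.

    ``amplitudes[i]`` is the coefficient of exp(i*m*theta) for
    ``m = orders[i]``; orders run from -m_max to +m_max.  Order m maps to the
    k-space band offset by ``2*m*k_max`` when the profile is laid out
    spatially with one period per nominal voxel.
    """

    orders: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        orders = np.asarray(self.orders, dtype=int)
        amplitudes = np.asarray(self.amplitudes, dtype=complex)
        if orders.shape != amplitudes.shape or orders.ndim != 1:
            raise ValueError("orders and amplitudes must be matching 1-D arrays")
        if not np.all(np.isfinite(amplitudes)):
            raise ValueError("amplitudes must be finite")
        object.__setattr__(self, "orders", orders)
        object.__setattr__(self, "amplitudes", amplitudes)

    def amplitude(self, m: int | np.ndarray) -> np.ndarray:
        """Coefficient(s) at harmonic order(s) ``m``."""
        m = np.asarray(m, dtype=int)
        m_max = int(self.orders.max())
        if np.any(np.abs(m) > m_max):
            raise ValueError(f"order out of range (|m| <= {m_max})")
        return self.amplitudes[m + m_max]

    @property
    def m_max(self) -> int:
        return int(self.orders.max())


def _relaxation_factors(tissue: Tissue, dt: float) -> tuple[float, float]:
    return math.exp(-dt / tissue.t1), math.exp(-dt / tissue.t2)


def closed_form_steady_state(
    tissue: Tissue,
    seq: SequenceParams,
    theta,
    *,
    echo_phase: bool = False,
):
    """Analytic (Freeman–Hill) steady-state signal at the echo.

    Solves the per-TR fixed point of rotation–precession–relaxation in
    closed form and returns the complex transverse magnetization at TE for
    precession angle ``theta`` (scalar or array, radians).  The sequence's
    ``phase_increment`` shifts the effective precession angle by its
    negative, matching receiver demodulation of the phase-cycled RF.

    All inputs broadcast, so tissue/flip maps can be evaluated voxelwise by
    calling the underlying arithmetic with arrays (see
    :func:`steady_state_signal_arrays`).
    """
    theta = np.asarray(theta, dtype=float)
    sig = steady_state_signal_arrays(
        t1=tissue.t1,
        t2=tissue.t2,
        pd=tissue.pd,
        flip_rad=seq.flip_rad,
        theta=theta - seq.phase_increment,
        tr=seq.tr,
        te=seq.te,
    )
    if echo_phase:
        sig = sig * np.exp(1j * (theta - seq.phase_increment) * (seq.te / seq.tr))
    return sig if sig.shape else complex(sig)


def steady_state_signal_arrays(t1, t2, pd, flip_rad, theta, tr, te):
    """Vectorized Freeman–Hill steady state; all arguments broadcast.

    Returns the post-pulse complex transverse magnetization relaxed to TE
    (no echo phase ramp).  Units: t1/t2/tr/te in ms, theta/flip in radians.
    """
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    e1 = np.exp(-tr / t1)
    e2 = np.exp(-tr / t2)
    cosa = np.cos(flip_rad)
    sina = np.sin(flip_rad)
    cost = np.cos(theta)
    sint = np.sin(theta)
    denom = (1.0 - e1 * cosa) * (1.0 - e2 * cost) - e2 * (e1 - cosa) * (e2 - cost)
    mx = -pd * (1.0 - e1) * sina * e2 * sint / denom
    my = pd * (1.0 - e1) * sina * (1.0 - e2 * cost) / denom
    return (mx + 1j * my) * np.exp(-te / np.asarray(t2, dtype=float))


def _bloch_step(mx, my, mz, theta_eff, e1, e2, cosa, sina, pd):
    """One TR of free evolution followed by an x-rotation (in place on copies)."""
    # precession about z by theta_eff with transverse decay, then T1 recovery
    cost = np.cos(theta_eff)
    sint = np.sin(theta_eff)
    mx, my = e2 * (mx * cost - my * sint), e2 * (mx * sint + my * cost)
    mz = e1 * mz + (1.0 - e1) * pd
    # excitation: rotation by flip about x, sending +z toward +y
    my, mz = cosa * my + sina * mz, -sina * my + cosa * mz
    return mx, my, mz


def steady_state_profile(
    tissue: Tissue,
    seq: SequenceParams,
    n_theta: int,
    *,
    echo_phase: bool = False,
    tol: float = 1e-12,
    max_steps: int | None = None,
) -> OffResonanceProfile:
    """Bloch-iterated steady-state off-resonance profile on a uniform grid.

    Iterates the rotation–precession–relaxation recursion from thermal
    equilibrium until the per-step signal change falls below ``tol``
    (relative; the default 1e-12 keeps the accumulated error of the fixed
    point itself below ~1e-9 even for CSF-like T1/TR), capped at
    ``100 * T1 / TR`` steps by default.  The result
    agrees with :func:`closed_form_steady_state` to ~1e-12; the iteration is
    kept as the reference route because it generalizes to the transient
    regime.

    Raises
    ------
    SteadyStateConvergenceError
        If the tolerance is not reached within the step cap.
    """
    if n_theta < 2:
        raise ValueError("n_theta must be >= 2")
    theta = np.arange(n_theta) * (2.0 * np.pi / n_theta)
    theta_eff = theta - seq.phase_increment
    e1, e2 = _relaxation_factors(tissue, seq.tr)
    cosa, sina = math.cos(seq.flip_rad), math.sin(seq.flip_rad)
    if max_steps is None:
        max_steps = max(1000, int(math.ceil(100.0 * tissue.t1 / seq.tr)))

    mx = np.zeros(n_theta)
    my = np.zeros(n_theta)
    mz = np.full(n_theta, tissue.pd)
    # start with one excitation so the reference scale is the post-pulse signal
    my, mz = cosa * my + sina * mz, -sina * my + cosa * mz
    prev = mx + 1j * my
    scale = max(float(np.max(np.abs(prev))), np.finfo(float).tiny)
    for _ in range(max_steps):
        mx, my, mz = _bloch_step(mx, my, mz, theta_eff, e1, e2, cosa, sina, tissue.pd)
        cur = mx + 1j * my
        if float(np.max(np.abs(cur - prev))) < tol * scale:
            prev = cur
            break
        prev = cur
    else:
        raise SteadyStateConvergenceError(
            f"steady state not reached: per-step change above {tol:g} (relative) "
            f"after {max_steps} iterations"
        )
    sig = prev * math.exp(-seq.te / tissue.t2)
    if echo_phase:
        sig = sig * np.exp(1j * theta_eff * (seq.te / seq.tr))
    return OffResonanceProfile(theta=theta, signal=sig, periodic=not echo_phase)


def transient_signal(
    tissue: Tissue,
    seq: SequenceParams,
    n_reps: int,
    theta: float,
    *,
    echo_phase: bool = False,
) -> np.ndarray:
    """Echo signal for each of ``n_reps`` excitations from thermal equilibrium.

    Models the approach to steady state of a continuously running sequence
    at a single precession angle; at very low flip angle the approach is a
    smooth exponential, without the oscillations seen at conventional bSSFP
    flip angles.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    theta_eff = float(theta) - seq.phase_increment
    e1, e2 = _relaxation_factors(tissue, seq.tr)
    cosa, sina = math.cos(seq.flip_rad), math.sin(seq.flip_rad)
    decay = math.exp(-seq.te / tissue.t2)
    ramp = np.exp(1j * theta_eff * seq.te / seq.tr) if echo_phase else 1.0

    mx, my, mz = 0.0, 0.0, tissue.pd
    cost, sint = math.cos(theta_eff), math.sin(theta_eff)
    out = np.empty(n_reps, dtype=complex)
    for j in range(n_reps):
        # excitation
        my, mz = cosa * my + sina * mz, -sina * my + cosa * mz
        out[j] = (mx + 1j * my) * decay * ramp
        # free evolution over one TR
        mx, my = e2 * (mx * cost - my * sint), e2 * (mx * sint + my * cost)
        mz = e1 * mz + (1.0 - e1) * tissue.pd
    return out


def harmonic_spectrum(
    profile: OffResonanceProfile,
    m_max: int,
    *,
    use_modulus: bool = False,
) -> HarmonicSpectrum:
    """Fourier-series coefficients of the off-resonance profile.

    Computes ``c_m = (1/n) * sum_j s(theta_j) * exp(-i*m*theta_j)`` for
    ``m = -m_max..m_max``, i.e. the coefficient of exp(i*m*theta).  By
    default the complex profile is decomposed (the one-sided configuration
    state route); ``use_modulus=True`` decomposes |s| instead, which yields
    the symmetric comb of the magnitude pattern.

    For tissues with t2 << t1 at low flip angle the complex-profile spectrum
    is strongly asymmetric: negative orders carry a negligible fraction of
    the energy of the positive orders.
    """
    if m_max < 0:
        raise ValueError("m_max must be >= 0")
    n = profile.theta.size
    if n < 2 * m_max + 1:
        raise ValueError(
            f"profile has {n} samples; need >= {2 * m_max + 1} for m_max={m_max}"
        )
    if not use_modulus and not profile.periodic:
        raise ValueError(
            "harmonic decomposition of the complex profile requires the "
            "2*pi-periodic form (echo_phase=False)"
        )
    s = np.abs(profile.signal) if use_modulus else profile.signal
    coeffs = np.fft.fft(s) / n  # coeffs[m] multiplies exp(+i*m*theta), m mod n
    orders = np.arange(-m_max, m_max + 1)
    amplitudes = coeffs[np.mod(orders, n)]
    return HarmonicSpectrum(orders=orders, amplitudes=amplitudes)
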