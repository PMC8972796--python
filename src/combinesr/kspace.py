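"""Shared k-space grid bookkeeping.

All k-space arrays in the package use the fftshifted layout: for an axis of
length ``n`` the row index ``i`` holds spatial frequency ``f = i - n//2``
(in cycles per FOV), so the DC sample sits at index ``n//2``.

Band indexing along the super-resolution axis: with low-resolution matrix
``n_pe`` (half-band ``h = n_pe/2``) band ``m`` (m = 1..M, band 1 central)
covers frequencies ``f`` in ``[(2m-3)h, (2m-1)h)``, i.e. the band centered
at ``2(m-1)*h``; on a wide grid of ``(2M-1)*n_pe`` rows the negative-
frequency mirror bands are filled by conjugate symmetry.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fft2c", "ifft2c", "band_slice", "conjugate_fill"]


def fft2c(img: np.ndarray) -> np.ndarray:
    """2-D DFT with the DC sample moved to the array center."""
    return np.fft.fftshift(np.fft.fft2(img))


def ifft2c(k: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c`."""
    return np.fft.ifft2(np.fft.ifftshift(k))


def band_slice(m: int, n_pe: int, n_rows: int) -> slice:
    """Row slice of band ``m`` on an fftshifted grid with ``n_rows`` rows.

    Band m spans the ``n_pe`` frequencies centered (DC-sample-aligned) on
    ``(m-1)*n_pe``; for even ``n_pe`` this is ``[(2m-3)h, (2m-1)h)`` with
    ``h = n_pe/2``.
    """
    lo = n_rows // 2 - n_pe // 2 + (m - 1) * n_pe
    hi = lo + n_pe
    if lo < 0 or hi > n_rows:
        raise ValueError(f"band {m} does not fit on a grid of {n_rows} rows")
    return slice(lo, hi)


def conjugate_fill(k: np.ndarray, filled: np.ndarray) -> np.ndarray:
    """Complete unmeasured samples of a 2-D fftshifted k-space by symmetry.

    For every unfilled coordinate with an available mirror the value
    ``S(-ky, -kx) = S(ky, kx)*`` is inserted (the Hermitian symmetry of a
    real image).  Mirrors are taken modulo the grid, so the Nyquist row and
    column (which are their own mirrors) map onto themselves; samples whose
    mirror is also unmeasured stay zero.  Returns a copy; ``filled`` is the
    boolean mask of measured samples.
    """
    ny, nx = k.shape
    iy = np.arange(ny)
    ix = np.arange(nx)
    # mirror of frequency f = i - n//2 is -f at index n//2 - f (mod n)
    my = np.mod(ny // 2 - (iy - ny // 2), ny)
    mx = np.mod(nx // 2 - (ix - nx // 2), nx)
    mirror = np.conj(k[np.ix_(my, mx)])
    mirror_filled = filled[np.ix_(my, mx)]
    out = k.copy()
    take = ~filled & mirror_filled
    out[take] = mirror[take]
    return out
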