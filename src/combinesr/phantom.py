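"""Synthetic tissue-parameter maps and field maps.

Phantoms are 2-D maps of (T1, T2, proton density) on a square imaging grid,
plus optional B0 (Hz) and relative-B1 field maps.  All generators are
deterministic functions of their parameters.

Coordinate convention (honored by the simulator and reconstruction):
0-based voxel indices, voxel centers at ``(i + 0.5) / n`` of the FOV along
each axis; axis 0 is the default super-resolution (pattern) axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .physics import CSF, GRAY_MATTER, WHITE_MATTER, Tissue

__all__ = [
    "Grid",
    "TissueMaps",
    "FieldMaps",
    "make_brain_phantom",
    "make_resolution_target",
    "make_field_maps",
]

#: Water-like background compartment for resolution targets.
WATER = Tissue(t1=3000.0, t2=1500.0, pd=1.0)


@dataclass(frozen=True)
class Grid:
    """Imaging geometry: matrix size and field of view in mm."""

    shape: tuple[int, int]
    fov: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 2 or any(n < 1 for n in self.shape):
            raise ValueError(f"shape must be two positive ints, got {self.shape}")
        if len(self.fov) != 2 or any(f <= 0 for f in self.fov):
            raise ValueError(f"fov must be two positive lengths, got {self.fov}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "fov", tuple(float(f) for f in self.fov))

    @property
    def voxel_size(self) -> tuple[float, float]:
        return (self.fov[0] / self.shape[0], self.fov[1] / self.shape[1])

    def coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along ``axis`` in mm, origin at FOV edge."""
        n = self.shape[axis]
        return (np.arange(n) + 0.5) * (self.fov[axis] / n)

    def centered_coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates with the origin at the FOV center."""
        return self.coords(axis) - self.fov[axis] / 2.0


@dataclass(frozen=True)
class TissueMaps:
    """Voxelwise T1/T2/PD maps over an imaging grid; pd == 0 is background."""

    t1: np.ndarray
    t2: np.ndarray
    pd: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        t1 = np.asarray(self.t1, dtype=float)
        t2 = np.asarray(self.t2, dtype=float)
        pd = np.asarray(self.pd, dtype=float)
        if not (t1.shape == t2.shape == pd.shape == self.grid.shape):
            raise ValueError("t1/t2/pd maps and grid shape must all agree")
        fg = pd > 0
        if np.any(pd < 0) or np.any(pd > 1):
            raise ValueError("pd must lie in [0, 1]")
        if np.any(t1[fg] <= 0) or np.any(t2[fg] <= 0) or np.any(t2[fg] > t1[fg]):
            raise ValueError("foreground voxels must satisfy 0 < t2 <= t1")
        object.__setattr__(self, "t1", t1)
        object.__setattr__(self, "t2", t2)
        object.__setattr__(self, "pd", pd)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass(frozen=True)
class FieldMaps:
    """B0 off-resonance (Hz) and relative transmit-field maps."""

    b0: np.ndarray
    b1: np.ndarray

    def __post_init__(self) -> None:
        b0 = np.asarray(self.b0, dtype=float)
        b1 = np.asarray(self.b1, dtype=float)
        if b0.shape != b1.shape:
            raise ValueError("b0 and b1 maps must have the same shape")
        if np.any(b1 < 0):
            raise ValueError("b1 must be non-negative")
        object.__setattr__(self, "b0", b0)
        object.__setattr__(self, "b1", b1)

    @classmethod
    def identity(cls, shape: tuple[int, int]) -> "FieldMaps":
        return cls(b0=np.zeros(shape), b1=np.ones(shape))


def _fill(masks_and_tissues, shape) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t1 = np.zeros(shape)
    t2 = np.zeros(shape)
    pd = np.zeros(shape)
    for mask, tissue in masks_and_tissues:
        t1[mask] = tissue.t1
        t2[mask] = tissue.t2
        pd[mask] = tissue.pd
    return t1, t2, pd


def _ellipse(grid: Grid, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    """Boolean mask of an axis-aligned ellipse; centers/radii as FOV fractions."""
    y = (np.arange(grid.shape[0]) + 0.5) / grid.shape[0]
    x = (np.arange(grid.shape[1]) + 0.5) / grid.shape[1]
    yy, xx = np.meshgrid(y, x, indexing="ij")
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def make_brain_phantom(n: int, fov: float | None = None) -> TissueMaps:
    """Three-compartment head-like numeric phantom.

    Nested ellipses of CSF, gray matter and white matter, with two
    CSF-filled ventricles, on an ``n x n`` grid (``n >= 32``).  Compartment
    values are fixed 3T literature constants: CSF (T1=2569, T2=329,
    PD=1.00), GM (T1=1331, T2=80, PD=0.86), WM (T1=832, T2=110, PD=0.77).
    The geometry scales with ``n``; at n=289 with the default 1 mm voxels
    the phantom spans a 289 mm FOV.
    """
    if n < 32:
        raise ValueError("n must be >= 32")
    if fov is None:
        fov = float(n)
    grid = Grid(shape=(n, n), fov=(fov, fov))
    csf_outer = _ellipse(grid, 0.5, 0.5, 0.45, 0.38)
    gm_outer = _ellipse(grid, 0.5, 0.5, 0.40, 0.33)
    wm_outer = _ellipse(grid, 0.5, 0.5, 0.31, 0.24)
    vent_l = _ellipse(grid, 0.44, 0.42, 0.10, 0.045)
    vent_r = _ellipse(grid, 0.44, 0.58, 0.10, 0.045)
    t1, t2, pd = _fill(
        [
            (csf_outer, CSF),
            (gm_outer, GRAY_MATTER),
            (wm_outer, WHITE_MATTER),
            (vent_l | vent_r, CSF),
        ],
        grid.shape,
    )
    return TissueMaps(t1=t1, t2=t2, pd=pd, grid=grid)


def make_resolution_target(
    n: int,
    bar_widths: Sequence[int],
    tissue: Tissue = GRAY_MATTER,
    background: Tissue = WATER,
    fov: float | None = None,
    axis: int = 0,
) -> TissueMaps:
    """Bar-pattern resolution phantom for PSF / achieved-resolution checks.

    For each requested width ``w`` (in voxels of this grid, >= 1) an
    alternating on/off bar pattern of period ``2w`` is laid out along
    ``axis``; each width occupies an equal strip along the other axis.  Bars
    are ``tissue`` on a water-like ``background``.
    """
    bar_widths = [int(w) for w in bar_widths]
    if any(w < 1 for w in bar_widths):
        raise ValueError("bar widths must be >= 1 voxel")
    if any(w > n for w in bar_widths):
        raise ValueError(f"bar width exceeds the grid/FOV ({n} voxels)")
    if fov is None:
        fov = float(n)
    grid = Grid(shape=(n, n), fov=(fov, fov))
    idx = np.arange(n)
    mask = np.zeros((n, n), dtype=bool)
    strips = np.array_split(np.arange(n), len(bar_widths))
    for strip, w in zip(strips, bar_widths):
        bars = (idx // w) % 2 == 0
        if axis == 0:
            mask[np.ix_(idx[bars], strip)] = True
        else:
            mask[np.ix_(strip, idx[bars])] = True
    t1, t2, pd = _fill([(~mask, background), (mask, tissue)], grid.shape)
    return TissueMaps(t1=t1, t2=t2, pd=pd, grid=grid)


def make_field_maps(
    maps: TissueMaps,
    b0_model: tuple[str, ...] = ("uniform", 0.0),
    b1_model: tuple[str, ...] = ("uniform", 1.0),
) -> FieldMaps:
    """Deterministic analytic field maps on the grid of ``maps``.

    b0 models (values in Hz):
      ("uniform", f0) | ("linear-gradient", slope_hz_per_mm[, axis]) |
      ("smooth-polynomial", peak_hz) — a centered concave quadratic dome
      peaking at ``peak_hz`` and falling to 0 at the FOV corners.
    b1 models (dimensionless, 1 = nominal):
      ("uniform", s) | ("linear", slope_per_mm[, axis]) |
      ("radial", edge_scale) — 1 at the center dropping quadratically to
      ``edge_scale`` at the FOV edge.
    """
    grid = maps.grid
    yy = grid.centered_coords(0)[:, None] * np.ones((1, grid.shape[1]))
    xx = np.ones((grid.shape[0], 1)) * grid.centered_coords(1)[None, :]

    kind, *params = b0_model
    if kind == "uniform":
        b0 = np.full(grid.shape, float(params[0]))
    elif kind == "linear-gradient":
        axis = int(params[1]) if len(params) > 1 else 0
        b0 = float(params[0]) * (yy if axis == 0 else xx)
    elif kind == "smooth-polynomial":
        ry, rx = grid.fov[0] / 2.0, grid.fov[1] / 2.0
        r2 = (yy / ry) ** 2 + (xx / rx) ** 2
        b0 = float(params[0]) * (1.0 - r2 / 2.0)
    else:
        raise ValueError(f"unknown b0 model {kind!r}")

    kind, *params = b1_model
    if kind == "uniform":
        b1 = np.full(grid.shape, float(params[0]))
    elif kind == "linear":
        axis = int(params[1]) if len(params) > 1 else 0
        b1 = 1.0 + float(params[0]) * (yy if axis == 0 else xx)
    elif kind == "radial":
        edge = float(params[0])
        ry, rx = grid.fov[0] / 2.0, grid.fov[1] / 2.0
        r2 = np.minimum((yy / ry) ** 2 + (xx / rx) ** 2, 1.0)
        b1 = 1.0 + (edge - 1.0) * r2
    else:
        raise ValueError(f"unknown b1 model {kind!r}")

    if not (np.all(np.isfinite(b0)) and np.all(np.isfinite(b1))):
        raise ValueError("field model parameters must be finite")
    return FieldMaps(b0=b0, b1=np.clip(b1, 0.0, None))
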