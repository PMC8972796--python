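"""Persistence: HDF5 series container, NIfTI image export, YAML run configs.

An acquisition series is stored as a single HDF5 file holding the complex
frames plus every protocol attribute needed to reconstruct without side
channels; images and maps go to NIfTI with voxel sizes derived from the
FOV.  Run configurations round-trip losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .acquisition import AcquisitionScheme, AcquisitionSeries
from .phantom import Grid
from .physics import SequenceParams

__all__ = [
    "save_series",
    "load_series",
    "export_nifti",
    "load_nifti",
    "RunConfig",
    "SeriesFormatError",
]

FORMAT_VERSION = 1

_SCHEME_KEYS = (
    "n_images",
    "n_pe",
    "n_fe",
    "phase_increments",
    "spoiler_cycles_per_voxel",
    "sr_axis",
    "noise_sigma",
    "seed",
)
_SEQ_KEYS = ("tr", "te", "flip", "phase_increment", "n_dummy")


class SeriesFormatError(ValueError):
    """A series file is missing a required key or has the wrong version."""


def save_series(series: AcquisitionSeries, path) -> None:
    """Write an acquisition series (frames + full protocol) to one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.create_dataset("frames", data=series.frames)
        g = f.create_group("scheme")
        sch = series.scheme
        for key in _SCHEME_KEYS:
            g.attrs[key] = getattr(sch, key)
        g = f.create_group("seq")
        for key in _SEQ_KEYS:
            g.attrs[key] = getattr(series.seq, key)
        g = f.create_group("grid")
        g.attrs["shape"] = series.grid.shape
        g.attrs["fov"] = series.grid.fov


def _require(attrs, key, where):
    if key not in attrs:
        raise SeriesFormatError(f"series file is missing key {where}/{key!r}")
    return attrs[key]


def load_series(path) -> AcquisitionSeries:
    """Read a series written by :func:`save_series`; lossless round-trip."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version")
        if version != FORMAT_VERSION:
            raise SeriesFormatError(
                f"unsupported series format version {version!r} "
                f"(expected {FORMAT_VERSION})"
            )
        if "frames" not in f:
            raise SeriesFormatError("series file is missing key 'frames'")
        frames = f["frames"][...]
        sa = f["scheme"].attrs if "scheme" in f else {}
        scheme = AcquisitionScheme(
            n_images=int(_require(sa, "n_images", "scheme")),
            n_pe=int(_require(sa, "n_pe", "scheme")),
            n_fe=int(_require(sa, "n_fe", "scheme")),
            phase_increments=np.asarray(
                _require(sa, "phase_increments", "scheme"), dtype=float
            ),
            spoiler_cycles_per_voxel=float(
                _require(sa, "spoiler_cycles_per_voxel", "scheme")
            ),
            sr_axis=int(_require(sa, "sr_axis", "scheme")),
            noise_sigma=float(_require(sa, "noise_sigma", "scheme")),
            seed=int(_require(sa, "seed", "scheme")),
        )
        qa = f["seq"].attrs if "seq" in f else {}
        seq = SequenceParams(
            tr=float(_require(qa, "tr", "seq")),
            te=float(_require(qa, "te", "seq")),
            flip=float(_require(qa, "flip", "seq")),
            phase_increment=float(_require(qa, "phase_increment", "seq")),
            n_dummy=int(_require(qa, "n_dummy", "seq")),
        )
        ga = f["grid"].attrs if "grid" in f else {}
        grid = Grid(
            shape=tuple(int(v) for v in _require(ga, "shape", "grid")),
            fov=tuple(float(v) for v in _require(ga, "fov", "grid")),
        )
    return AcquisitionSeries(frames=frames, scheme=scheme, seq=seq, grid=grid)


def export_nifti(image: np.ndarray, grid: Grid, path, description: str = "") -> list:
    """Write a 2-D image or map as NIfTI with voxel sizes from the grid FOV.

    Real arrays produce one file; complex images are written as separate
    magnitude and phase volumes (suffixes ``_mag`` / ``_phase``).  The
    ``description`` string (e.g. units such as 'radians per TR') is stored
    in the header.  Returns the list of written paths.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    if image.shape != tuple(grid.shape):
        raise ValueError(f"image shape {image.shape} != grid shape {grid.shape}")
    vy = grid.fov[0] / grid.shape[0]
    vx = grid.fov[1] / grid.shape[1]
    affine = np.diag([vy, vx, 1.0, 1.0])

    def write_one(arr, p):
        img = nib.Nifti1Image(arr[..., None].astype(np.float64), affine)
        img.header["pixdim"][1:4] = (vy, vx, 1.0)
        img.header["descrip"] = description.encode()[:79]
        nib.save(img, str(p))
        return Path(p)

    path = Path(path)
    if np.iscomplexobj(image):
        stem = path.name
        for suffix in (".nii.gz", ".nii"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
                break
        else:
            suffix = ".nii.gz"
        base = path.parent / stem
        return [
            write_one(np.abs(image), f"{base}_mag{suffix}"),
            write_one(np.angle(image), f"{base}_phase{suffix}"),
        ]
    return [write_one(image, path)]


def load_nifti(path) -> tuple[np.ndarray, Grid]:
    """Read a NIfTI written by :func:`export_nifti` back to (array, grid)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)[..., 0]
    vy, vx = float(img.header["pixdim"][1]), float(img.header["pixdim"][2])
    grid = Grid(shape=data.shape, fov=(vy * data.shape[0], vx * data.shape[1]))
    return data, grid


@dataclass
class RunConfig:
    """Structured run configuration; round-trips losslessly through YAML.

    Mirrors the sequence, acquisition-scheme and reconstruction parameters
    plus the phantom / field-model choices of a full pipeline run.  Every
    pipeline command writes its resolved config next to its outputs.
    """

    tr: float = 8.0
    te: float = 4.0
    flip: float = 0.5
    n_dummy: int = 0
    n_images: int = 9
    n_pe: int = 16
    n_fe: int = 64
    spoiler_cycles_per_voxel: float = 1.0
    sr_axis: int = 0
    noise_sigma: float = 0.0
    seed: int = 0
    fidelity: str = "profile"
    phantom: str = "brain"
    phantom_n: int = 144
    bar_widths: list = field(default_factory=lambda: [1, 2, 3, 4])
    b0_model: list = field(default_factory=lambda: ["uniform", 0.0])
    b1_model: list = field(default_factory=lambda: ["uniform", 1.0])
    m_bands: int = 1
    n_freqs: int = 1
    equalize: bool = False
    tissue_ref: list | None = None  # [t1, t2, pd]

    def seq(self) -> SequenceParams:
        return SequenceParams(
            tr=self.tr, te=self.te, flip=self.flip, n_dummy=self.n_dummy
        )

    def scheme(self) -> AcquisitionScheme:
        return AcquisitionScheme(
            n_images=self.n_images,
            n_pe=self.n_pe,
            n_fe=self.n_fe,
            spoiler_cycles_per_voxel=self.spoiler_cycles_per_voxel,
            sr_axis=self.sr_axis,
            noise_sigma=self.noise_sigma,
            seed=self.seed,
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)
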