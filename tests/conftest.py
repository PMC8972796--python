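import numpy as np
import pytest

from combinesr import (
    AcquisitionScheme,
    Grid,
    SequenceParams,
    Tissue,
    TissueMaps,
    simulate_combine_series,
)
from combinesr.kspace import fft2c, ifft2c


@pytest.fixture(scope="session")
def gm():
    return Tissue(t1=1331.0, t2=80.0, pd=0.86)


@pytest.fixture(scope="session")
def seq8():
    """TR/TE = 8/4 ms, 1 degree: the reference low-flip protocol."""
    return SequenceParams(tr=8.0, te=4.0, flip=1.0)


def uniform_maps(tissue, n_sr, n_fe, dy_nom, pd=None):
    """Single-tissue rectangular maps with the SR axis first."""
    shape = (n_sr, n_fe)
    pd_map = np.full(shape, tissue.pd if pd is None else 0.0)
    if pd is not None:
        pd_map = np.asarray(pd, dtype=float)
    return TissueMaps(
        t1=np.full(shape, tissue.t1),
        t2=np.full(shape, tissue.t2),
        pd=pd_map,
        grid=Grid(shape=shape, fov=(dy_nom * n_sr / 1.0, float(n_fe))),
    )


def bandlimited_object(n_sr, band_rows, n_fe=6, seed=3):
    """Smooth positive 2-D object whose SR-axis spectrum fits in band_rows rows."""
    rng = np.random.default_rng(seed)
    k_max = band_rows // 2 - 1
    u = np.arange(n_sr) / n_sr
    prof = np.full(n_sr, 0.55)
    for f in range(1, k_max + 1):
        amp = 0.3 * np.exp(-((f / 6.0) ** 2)) / (1 + f)
        prof = prof + amp * np.cos(2 * np.pi * f * u + rng.uniform(0, 2 * np.pi))
    prof = np.clip(prof, 0.05, 1.0)
    return np.tile(prof[:, None], (1, n_fe)) * np.linspace(0.5, 1.0, n_fe)[None, :]


def bandlimit_truth(obj, band_rows):
    """Band-limited projection of ``obj`` onto a band_rows-tall output grid."""
    k = fft2c(obj.astype(complex))
    ctr = obj.shape[0] // 2
    return ifft2c(k[ctr - band_rows // 2 : ctr + (band_rows + 1) // 2, :])


def forward_series(obj, tissue, seq, n_pe, n_images, fields=None, fidelity="profile"):
    """Profile- or Bloch-fidelity series of a pd-modulated single-tissue object."""
    n_sr, n_fe = obj.shape
    maps = TissueMaps(
        t1=np.full(obj.shape, tissue.t1),
        t2=np.full(obj.shape, tissue.t2),
        pd=obj,
        grid=Grid(shape=obj.shape, fov=(float(n_pe), float(n_fe))),
    )
    scheme = AcquisitionScheme(n_images=n_images, n_pe=n_pe, n_fe=n_fe)
    return simulate_combine_series(maps, fields, seq, scheme, fidelity=fidelity)
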