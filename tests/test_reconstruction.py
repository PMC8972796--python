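"""Interleaving, band least squares, equalization, partial Fourier, multi-frequency."""

import numpy as np
import pytest

from combinesr import (
    AcquisitionScheme,
    AcquisitionSeries,
    FieldMaps,
    ReconSpec,
    SequenceParams,
    Tissue,
    build_psi,
    equalize_harmonics,
    interleave_recon,
    make_brain_phantom,
    multifrequency_recon,
    partial_fourier_complete,
    simulate_combine_series,
    solve_bands,
    tissue_band_spectrum,
)
from combinesr.kspace import ifft2c
from combinesr.physics import HarmonicSpectrum
from combinesr.reconstruction import reconstruct

from conftest import bandlimit_truth, bandlimited_object, forward_series


class TestPsi:
    def test_zero_increments_give_all_ones(self):
        assert np.allclose(build_psi([0.0, 0.0, 0.0], 2), np.ones((3, 2)))

    def test_two_point_cycling(self):
        psi = build_psi([0.0, np.pi], 2)
        assert np.allclose(psi, [[1, 1], [-1, 1]])

    @pytest.mark.parametrize("n,m", [(5, 2), (9, 4), (36, 3)])
    def test_equidistant_columns_are_orthogonal(self, n, m):
        psi = build_psi(2 * np.pi * np.arange(n) / n, m)
        assert np.allclose(psi.conj().T @ psi, n * np.eye(m))


class TestInterleave:
    def test_single_frame_returned_unchanged(self, gm, seq8):
        obj = bandlimited_object(24, 8, n_fe=4)
        series = forward_series(obj, gm, seq8, n_pe=8, n_images=1)
        img = interleave_recon(series)
        assert np.allclose(img, np.abs(series.lowres_images()[0]))

    def test_output_shape_matches_reference_protocol(self, seq8):
        """17 frames of 17x289 interleave to a 289x289 image."""
        maps = make_brain_phantom(289)
        scheme = AcquisitionScheme(n_images=17, n_pe=17, n_fe=289)
        series = simulate_combine_series(maps, None, seq8, scheme, "profile")
        assert interleave_recon(series).shape == (289, 289)

    def test_boundaries_land_within_one_sr_voxel(self, seq8):
        """Compartment edges of the fully-prepared interleave sit within one
        super-resolution voxel of the phantom's own edges."""
        maps = make_brain_phantom(81)
        scheme = AcquisitionScheme(n_images=9, n_pe=9, n_fe=81)
        seq = SequenceParams(tr=8, te=4, flip=0.2)
        img = interleave_recon(simulate_combine_series(maps, None, seq, scheme, "profile"))
        col = img[:, 40]
        ref = maps.pd[:, 40]
        edge_img = np.nonzero(col > 0.4 * col.max())[0]
        edge_ref = np.nonzero(ref > 0)[0]
        assert abs(edge_img[0] - edge_ref[0]) <= 1
        assert abs(edge_img[-1] - edge_ref[-1]) <= 1

    def test_non_equidistant_increments_rejected(self, gm, seq8):
        obj = bandlimited_object(24, 8, n_fe=4)
        series = forward_series(obj, gm, seq8, n_pe=8, n_images=3)
        bad = AcquisitionScheme(
            n_images=3, n_pe=8, n_fe=4, phase_increments=np.array([0.0, 0.5, 1.0])
        )
        series = AcquisitionSeries(frames=series.frames, scheme=bad,
                                   seq=series.seq, grid=series.grid)
        with pytest.raises(ValueError, match="equidistant"):
            interleave_recon(series)


class TestBandSolve:
    def test_single_band_single_image_is_identity(self, gm, seq8):
        obj = bandlimited_object(24, 8, n_fe=4)
        series = forward_series(obj, gm, seq8, n_pe=8, n_images=1)
        k, filled = solve_bands(series, ReconSpec(m_bands=1), 0.0)
        assert np.allclose(k, series.frames[0])
        assert filled.all()

    @pytest.mark.parametrize("m_bands", [1, 2, 3])
    @pytest.mark.parametrize("n_kind", ["minimal", "redundant"])
    def test_noiseless_roundtrip_recovers_object(self, gm, seq8, m_bands, n_kind):
        """Forward simulation + band solve + equalization + partial Fourier
        reproduces the band-limited object to high accuracy."""
        n_images = 2 * m_bands - 1 if n_kind == "minimal" else 36
        n_pe, enh = 10, 105
        obj = bandlimited_object(n_pe * enh, (2 * m_bands - 1) * n_pe)
        series = forward_series(obj, gm, seq8, n_pe=n_pe, n_images=n_images)
        res = reconstruct(
            series, ReconSpec(m_bands=m_bands, equalize=True, tissue_ref=gm)
        )
        truth = bandlimit_truth(obj, (2 * m_bands - 1) * n_pe)
        nrmse = np.linalg.norm(res.image - truth) / np.linalg.norm(truth)
        assert nrmse < 1e-5

    def test_output_rows_are_2m_minus_1_times_n_pe(self, gm, seq8):
        obj = bandlimited_object(300, 30)
        series = forward_series(obj, gm, seq8, n_pe=10, n_images=5)
        for m in (1, 2):
            k, _ = solve_bands(series, ReconSpec(m_bands=m), 0.0)
            assert k.shape[0] == (2 * m - 1) * 10

    def test_m_exceeding_n_rejected(self, gm, seq8):
        obj = bandlimited_object(24, 8, n_fe=4)
        series = forward_series(obj, gm, seq8, n_pe=8, n_images=2)
        with pytest.raises(ValueError, match="exceeds"):
            solve_bands(series, ReconSpec(m_bands=3), 0.0)

    def test_degenerate_increments_rejected(self, gm, seq8):
        obj = bandlimited_object(24, 8, n_fe=4)
        series = forward_series(obj, gm, seq8, n_pe=8, n_images=3)
        bad = AcquisitionScheme(n_images=3, n_pe=8, n_fe=4,
                                phase_increments=np.zeros(3))
        series = AcquisitionSeries(frames=series.frames, scheme=bad,
                                   seq=series.seq, grid=series.grid)
        with pytest.raises(np.linalg.LinAlgError):
            solve_bands(series, ReconSpec(m_bands=2), 0.0)

    def test_reconstruction_is_linear_in_the_frames(self, gm, seq8):
        obj1 = bandlimited_object(150, 30, seed=1)
        obj2 = bandlimited_object(150, 30, seed=2)
        s1 = forward_series(obj1, gm, seq8, n_pe=10, n_images=5)
        s2 = forward_series(obj2, gm, seq8, n_pe=10, n_images=5)
        spec = ReconSpec(m_bands=2, equalize=True, tissue_ref=gm)

        def recon_frames(frames):
            s = AcquisitionSeries(frames=frames, scheme=s1.scheme,
                                  seq=s1.seq, grid=s1.grid)
            return reconstruct(s, spec).image

        # real coefficients: the conjugate-symmetry completion is antilinear
        # in the mirrored samples, so complex scalars do not distribute
        combo = recon_frames(2.0 * s1.frames - 0.7 * s2.frames)
        parts = 2.0 * recon_frames(s1.frames) - 0.7 * recon_frames(s2.frames)
        assert np.allclose(combo, parts)


class TestEqualizeAndComplete:
    def test_flat_spectrum_equalization_is_identity(self):
        spec = HarmonicSpectrum(orders=np.arange(-2, 3),
                                amplitudes=np.ones(5, dtype=complex))
        k = np.arange(30, dtype=complex).reshape(30, 1)
        out = equalize_harmonics(k, spec, n_pe=10)
        assert np.allclose(out, k)

    def test_all_zero_spectrum_raises(self):
        spec = HarmonicSpectrum(orders=np.arange(-1, 2),
                                amplitudes=np.zeros(3, dtype=complex))
        with pytest.raises(ValueError, match="all-zero"):
            equalize_harmonics(np.ones((10, 1), dtype=complex), spec, n_pe=10)

    def test_vanishing_band_is_dropped_with_warning(self, caplog):
        # order 0 (central band) strong, order 1 vanishing
        amps = np.array([0.0, 0.0, 1.0, 1e-15, 0.0], dtype=complex)
        spec = HarmonicSpectrum(orders=np.arange(-2, 3), amplitudes=amps)
        k = np.ones((30, 2), dtype=complex)
        with caplog.at_level("WARNING"):
            out = equalize_harmonics(k, spec, n_pe=10)
        assert "dropped" in caplog.text
        assert np.all(out[20:, :] == 0)  # outer band zeroed, not amplified

    def test_completion_gives_real_image_for_real_object(self, gm, seq8):
        obj = bandlimited_object(1050, 30)
        series = forward_series(obj, gm, seq8, n_pe=10, n_images=5)
        k, filled = solve_bands(series, ReconSpec(m_bands=2), 0.0)
        spectrum = tissue_band_spectrum(gm, seq8, 2)
        k = equalize_harmonics(k, spectrum, n_pe=10)
        img = ifft2c(partial_fourier_complete(k, filled))
        assert np.max(np.abs(img.imag)) < 1e-6 * np.max(np.abs(img.real))

    def test_m1_completion_is_noop(self, gm, seq8):
        obj = bandlimited_object(24, 8, n_fe=4)
        series = forward_series(obj, gm, seq8, n_pe=8, n_images=1)
        k, filled = solve_bands(series, ReconSpec(m_bands=1), 0.0)
        assert np.array_equal(partial_fourier_complete(k, filled), k)


class TestMultiFrequency:
    def _disc_series(self, b0_field, n_images=36, n_pe=16, enh=8):
        """Uniform gray-matter disc: the navigator's clean regime."""
        n_sr = n_pe * enh
        yy, xx = np.meshgrid(np.arange(n_sr), np.arange(n_sr), indexing="ij")
        disc = (yy - n_sr / 2) ** 2 + (xx - n_sr / 2) ** 2 < (0.4 * n_sr) ** 2
        from combinesr import Grid, TissueMaps

        maps = TissueMaps(
            t1=np.where(disc, 1331.0, 0.0), t2=np.where(disc, 80.0, 0.0),
            pd=np.where(disc, 0.86, 0.0),
            grid=Grid(shape=(n_sr, n_sr), fov=(float(n_pe), float(n_pe))),
        )
        fields = FieldMaps(b0=b0_field * np.ones(maps.shape),
                           b1=np.ones(maps.shape))
        seq = SequenceParams(tr=8, te=4, flip=0.5)
        scheme = AcquisitionScheme(n_images=n_images, n_pe=n_pe, n_fe=n_sr)
        series = simulate_combine_series(maps, fields, seq, scheme, "profile")
        return series, disc

    def _interior(self, disc, rows):
        from scipy.ndimage import binary_erosion, zoom

        fg = zoom(disc.astype(float), (rows / disc.shape[0], 1.0), order=0) > 0.5
        return binary_erosion(fg, iterations=3)

    def test_zero_field_gives_zero_omega_and_single_freq_image(self):
        series, disc = self._disc_series(0.0)
        spec = ReconSpec(m_bands=2, n_freqs=100, equalize=True,
                         tissue_ref=Tissue(1331.0, 80.0, 1.0))
        multi = multifrequency_recon(series, spec)
        single = reconstruct(series, spec)
        interior = self._interior(disc, multi.omega_map.shape[0])
        wrapped = np.minimum(multi.omega_map, 2 * np.pi - multi.omega_map)
        assert np.quantile(wrapped[interior], 0.9) <= 2 * np.pi / 100 * (1 + 1e-9)
        # voxels whose selected omega is 0 reproduce the single-frequency recon
        sel = multi.omega_map == 0
        assert np.allclose(multi.image[sel], single.image[sel])

    @pytest.mark.parametrize("b0", [10.0, 25.0, 90.0])
    def test_constant_field_recovered_within_one_step(self, b0):
        series, disc = self._disc_series(b0)
        spec = ReconSpec(m_bands=2, n_freqs=100, equalize=True,
                         tissue_ref=Tissue(1331.0, 80.0, 1.0))
        multi = multifrequency_recon(series, spec)
        omega_true = (2 * np.pi * b0 * 8e-3) % (2 * np.pi)
        err = np.abs(np.angle(np.exp(1j * (multi.omega_map - omega_true))))
        interior = self._interior(disc, err.shape[0])
        assert np.quantile(err[interior], 0.9) <= 2 * np.pi / 100 * (1 + 1e-9)

    def test_omega_map_units_are_radians_per_tr(self):
        series, _ = self._disc_series(10.0)
        spec = ReconSpec(m_bands=1, n_freqs=50, equalize=True,
                         tissue_ref=Tissue(1331.0, 80.0, 1.0))
        multi = multifrequency_recon(series, spec)
        assert multi.omega_map.min() >= 0
        assert multi.omega_map.max() < 2 * np.pi
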