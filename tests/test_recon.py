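"""Gridding reconstruction, sliding windows, zero-filling."""

import numpy as np
import pytest

from o17mri import (
    GridSpec,
    SequenceParams,
    grid_reconstruct,
    sliding_window_series,
    zero_fill,
)
from o17mri.acquisition import KSpaceSeries, make_da_radial_trajectory
from o17mri.recon import ImageFrame, grid_reconstruct_complex

from conftest import direct_dft_volume


@pytest.fixture(scope="module")
def small_setup():
    seq = SequenceParams(tr_ms=200.0, n_projections=700, samples_per_spoke=33)
    traj = make_da_radial_trajectory(seq)
    grid = GridSpec((16, 16, 16), 7.5)
    return seq, traj, grid


def _sphere_samples(traj, radius_mm=22.0):
    """Analytic Fourier transform of a centred uniform sphere."""
    pts = traj.points_per_mm()
    kr = np.linalg.norm(pts, axis=1)
    u = 2.0 * np.pi * kr * radius_mm
    vol = 4.0 / 3.0 * np.pi * radius_mm**3
    with np.errstate(invalid="ignore", divide="ignore"):
        f = vol * 3.0 * (np.sin(u) - u * np.cos(u)) / u**3
    f[u < 1e-9] = vol
    return f.reshape(traj.n_spokes, traj.samples_per_spoke)


class TestGridReconstruct:
    def test_all_zero_samples_give_all_zero_image(self, small_setup):
        _, traj, grid = small_setup
        frame = grid_reconstruct(np.zeros((700, 33), complex), traj, grid)
        assert np.all(frame.data == 0)

    def test_uniform_sphere_contrast_and_oracle_agreement(self, small_setup):
        """In-sphere/out-sphere contrast > 20 and agreement with a direct
        inverse-DFT oracle applied to the identical weighted samples."""
        _, traj, grid = small_setup
        samples = _sphere_samples(traj)
        frame = grid_reconstruct(samples, traj, grid, apodization="hamming")
        xs = grid.coords_mm(0)
        x, y, z = np.meshgrid(xs, xs, xs, indexing="ij")
        r2 = x**2 + y**2 + z**2
        inside = r2 <= (22.0 - 7.5) ** 2
        outside = r2 >= (22.0 + 7.5) ** 2
        assert frame.data[inside].mean() / frame.data[outside].mean() > 20

        # oracle on the same density-compensated, apodized samples
        from o17mri.recon import _hamming_radial

        fov = grid.fov_mm[0]
        n = grid.shape[0]
        nu = traj.points_per_mm() * fov
        w = traj.density_weights() * fov**3 * 4 * np.pi / traj.n_spokes / n**3
        w = w * _hamming_radial(traj.radii_per_mm * fov, traj.kmax_per_mm * fov)
        oracle = np.abs(direct_dft_volume(nu, samples * w[None, :], grid.shape))
        rms = np.sqrt(np.mean((frame.data - oracle) ** 2))
        assert rms / oracle.max() < 0.01

    def test_linearity_before_magnitude(self, small_setup):
        _, traj, grid = small_setup
        rng = np.random.default_rng(3)
        s1 = rng.normal(size=(700, 33)) + 1j * rng.normal(size=(700, 33))
        s2 = rng.normal(size=(700, 33)) + 1j * rng.normal(size=(700, 33))
        a, b = 1.7, -0.4 + 0.2j
        lhs = grid_reconstruct_complex(a * s1 + b * s2, traj, grid)
        rhs = a * grid_reconstruct_complex(s1, traj, grid) + b * grid_reconstruct_complex(
            s2, traj, grid
        )
        assert np.allclose(lhs, rhs, rtol=1e-10, atol=1e-12)

    def test_spoke_permutation_within_window_is_irrelevant(self, small_setup):
        _, traj, grid = small_setup
        samples = _sphere_samples(traj)
        perm = np.random.default_rng(0).permutation(700)
        direct = grid_reconstruct(samples, traj, grid, spoke_indices=np.arange(700))
        shuffled = grid_reconstruct(samples[perm], traj, grid, spoke_indices=perm)
        assert np.allclose(direct.data, shuffled.data, rtol=1e-12, atol=1e-12)

    def test_image_energy_grows_with_sample_energy(self, small_setup):
        _, traj, grid = small_setup
        rng = np.random.default_rng(5)
        noise = rng.normal(size=(700, 33)) + 1j * rng.normal(size=(700, 33))
        energies = [
            (grid_reconstruct(scale * noise, traj, grid).data ** 2).sum()
            for scale in (0.5, 1.0, 2.0, 4.0)
        ]
        assert np.all(np.diff(energies) > 0)

    def test_samples_beyond_kmax_rejected(self, small_setup):
        _, traj, _ = small_setup
        tight = GridSpec((8, 8, 8), 7.5)  # FOV too small for k_max
        tight = GridSpec((8, 8, 8), 15.0)  # nu_max = k_max * 120 mm = 8 > N/2
        with pytest.raises(ValueError, match="k_max|Nyquist"):
            grid_reconstruct(np.zeros((700, 33), complex), traj, tight)

    def test_empty_window_rejected(self, small_setup):
        _, traj, grid = small_setup
        with pytest.raises(ValueError, match="empty"):
            grid_reconstruct(np.zeros((0, 33), complex), traj, grid)


class TestSlidingWindow:
    def _kspace(self, n_projections: int) -> KSpaceSeries:
        seq = SequenceParams(n_projections=n_projections, samples_per_spoke=4)
        traj = make_da_radial_trajectory(seq)
        return KSpaceSeries(
            samples=np.zeros((n_projections, 4), complex),
            timestamps_s=np.arange(n_projections) * seq.tr_ms / 1000.0,
            trajectory=traj,
            sequence=seq,
        )

    @pytest.mark.parametrize(
        "n_projections,expected_frames", [(90000, 30), (120000, 40)]
    )
    def test_reference_frame_counts(self, n_projections, expected_frames):
        """3000-projection windows at TR 20 ms are one-minute frames; the
        patient and volunteer protocols give 30 and 40 images."""
        grid = GridSpec((8, 8, 8), 7.5)
        series = sliding_window_series(self._kspace(n_projections), 3000, grid)
        assert len(series) == expected_frames
        assert series.frame_duration_s == pytest.approx(60.0)
        assert series.frames[-1].t_end_s == pytest.approx(expected_frames * 60.0)

    def test_single_window_equals_direct_reconstruction(self):
        seq = SequenceParams(tr_ms=200.0, n_projections=150, samples_per_spoke=20)
        traj = make_da_radial_trajectory(seq)
        rng = np.random.default_rng(11)
        samples = rng.normal(size=(150, 20)) + 1j * rng.normal(size=(150, 20))
        ks = KSpaceSeries(
            samples=samples,
            timestamps_s=np.arange(150) * 0.2,
            trajectory=traj,
            sequence=seq,
        )
        grid = GridSpec((16, 16, 16), 7.5)
        series = sliding_window_series(ks, 150, grid)
        single = grid_reconstruct(samples, traj, grid, spoke_indices=slice(0, 150))
        assert len(series) == 1
        assert np.array_equal(series.frames[0].data, single.data)

    def test_leftover_spokes_are_dropped_with_warning(self, caplog):
        grid = GridSpec((8, 8, 8), 7.5)
        with caplog.at_level("WARNING"):
            series = sliding_window_series(self._kspace(3500), 3000, grid)
        assert len(series) == 1
        assert any("leftover" in r.message for r in caplog.records)

    def test_bad_window_rejected(self):
        grid = GridSpec((8, 8, 8), 7.5)
        with pytest.raises(ValueError):
            sliding_window_series(self._kspace(3000), 0, grid)
        with pytest.raises(ValueError):
            sliding_window_series(self._kspace(3000), 4000, grid)


class TestZeroFill:
    def _frame(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        grid = GridSpec((n, n, n), 7.5)
        return ImageFrame(
            data=np.abs(rng.normal(size=(n, n, n))) + 0.5,
            grid=grid,
            t_start_s=0.0,
            t_end_s=60.0,
            n_projections=100,
        )

    def test_factor_one_is_identity(self):
        frame = self._frame()
        assert zero_fill(frame, 1) is frame

    def test_factor_eight_geometry(self):
        fine = zero_fill(self._frame(12), 8)
        assert fine.data.shape == (96, 96, 96)
        assert fine.grid.voxel_size_mm == pytest.approx(7.5 / 8)

    @pytest.mark.parametrize("n", [12, 9])
    def test_interpolation_reproduces_original_voxel_centres(self, n):
        frame = self._frame(n)
        fine = zero_fill(frame, 4)
        sub = fine.data[::4, ::4, ::4]
        assert np.allclose(sub, frame.data, rtol=1e-9, atol=1e-12)

    def test_dc_value_preserved(self):
        frame = self._frame()
        fine = zero_fill(frame, 2)
        assert fine.data.mean() == pytest.approx(frame.data.mean(), rel=1e-3)

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            zero_fill(self._frame(), 2.5)
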