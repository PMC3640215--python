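"""Temporal preprocessing: discarding, motion GLM, scaling, filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hftica import preprocess as pp
from tests.conftest import TR, make_matrix, on_grid_sinusoid


class TestDiscard:
    def test_paper_scale_counts(self):
        m = make_matrix(np.random.default_rng(0).normal(size=(1024, 3)))
        out = pp.discard_initial_volumes(m, 24)
        assert out.n_volumes == 1000

    def test_zero_is_identity_and_order_preserved(self):
        data = np.arange(30.0).reshape(10, 3)
        m = make_matrix(data)
        np.testing.assert_array_equal(pp.discard_initial_volumes(m, 0).data, data)
        np.testing.assert_array_equal(
            pp.discard_initial_volumes(m, 4).data, data[4:]
        )

    def test_discarding_everything_is_an_error(self):
        m = make_matrix(np.zeros((10, 2)))
        with pytest.raises(ValueError, match="empty"):
            pp.discard_initial_volumes(m, 10)


class TestMotionRegression:
    def test_voxel_equal_to_motion_column_vanishes(self, rng):
        motion = rng.normal(size=(50, 6))
        m = make_matrix(np.column_stack([motion[:, 2], rng.normal(size=50)]))
        out = pp.regress_motion(m, motion)
        assert np.max(np.abs(out.data[:, 0])) < 1e-10

    def test_zero_motion_reduces_to_demeaning(self, rng):
        data = rng.normal(size=(40, 5)) + 3.0
        m = make_matrix(data)
        out = pp.regress_motion(m, np.zeros((40, 6)))
        np.testing.assert_allclose(out.data, data - data.mean(axis=0), atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        data = rng.normal(size=(50, 20))
        motion = rng.normal(size=(50, 6))
        out = pp.regress_motion(make_matrix(data), motion)
        design = np.column_stack([np.ones(50), motion])
        beta = np.linalg.solve(design.T @ design, design.T @ data)
        np.testing.assert_allclose(out.data, data - design @ beta, atol=1e-8)

    def test_residuals_orthogonal_to_regressors(self, rng):
        data = rng.normal(size=(60, 8))
        motion = rng.normal(size=(60, 6))
        out = pp.regress_motion(make_matrix(data), motion)
        design = np.column_stack([np.ones(60), motion])
        inner = np.abs(design.T @ out.data)
        norms = np.linalg.norm(design, axis=0)[:, None] * np.linalg.norm(
            out.data, axis=0
        )
        assert np.all(inner < 1e-8 * np.maximum(norms, 1.0))


class TestStandardize:
    def test_columns_become_zero_mean_unit_sd(self):
        m = make_matrix(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))
        out = pp.standardize_voxels(m)
        assert abs(out.data[:, 0].mean()) < 1e-10
        assert out.data[:, 0].std() == pytest.approx(1.0)
        # constant column zeroed
        np.testing.assert_array_equal(out.data[:, 1], 0.0)

    def test_idempotent_on_standardized_input(self, rng):
        data = rng.normal(size=(64, 4))
        once = pp.standardize_voxels(make_matrix(data))
        twice = pp.standardize_voxels(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_scale_is_retained_for_map_units(self, rng):
        data = rng.normal(size=(64, 4)) * np.array([1.0, 2.0, 3.0, 4.0])
        out = pp.standardize_voxels(make_matrix(data))
        np.testing.assert_allclose(out.voxel_scale, data.std(axis=0), rtol=1e-12)


class TestHighpass:
    def test_subcutoff_sinusoid_removed(self):
        x, _ = on_grid_sinusoid(0.1, 512)
        out = pp.highpass_fourier(make_matrix(x[:, None]))
        assert np.max(np.abs(out.data)) < 1e-10

    def test_supracutoff_sinusoid_unchanged(self):
        x, _ = on_grid_sinusoid(0.5, 512)
        out = pp.highpass_fourier(make_matrix(x[:, None]))
        np.testing.assert_allclose(out.data[:, 0], x, atol=1e-10)

    def test_mixture_keeps_only_high_band_oracle(self):
        lo, _ = on_grid_sinusoid(0.1, 500)
        hi, _ = on_grid_sinusoid(0.5, 500)
        out = pp.highpass_fourier(make_matrix((lo + hi)[:, None]))
        # independent oracle: direct DFT zeroing
        coeffs = np.fft.rfft(lo + hi)
        freqs = np.fft.rfftfreq(500, d=TR)
        coeffs[freqs < 0.25 * (1 - 1e-12)] = 0
        oracle = np.fft.irfft(coeffs, n=500)
        np.testing.assert_allclose(out.data[:, 0], oracle, atol=1e-10)
        np.testing.assert_allclose(out.data[:, 0], hi, atol=1e-10)

    def test_bin_at_cutoff_is_retained(self):
        n = 512
        grid = np.fft.rfftfreq(n, d=TR)
        f_on = grid[np.searchsorted(grid, 0.25)]
        x = np.sin(2 * np.pi * f_on * np.arange(n) * TR)
        out = pp.highpass_fourier(
            make_matrix(x[:, None]), pp.FilterSpec(cutoff_hz=f_on)
        )
        np.testing.assert_allclose(out.data[:, 0], x, atol=1e-10)

    def test_cutoff_at_or_above_nyquist_rejected(self):
        m = make_matrix(np.zeros((64, 1)))
        with pytest.raises(ValueError, match="Nyquist"):
            pp.highpass_fourier(m, pp.FilterSpec(cutoff_hz=1.5))

    @settings(max_examples=25, deadline=None)
    @given(
        n=st.integers(min_value=65, max_value=513),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_idempotence_parseval_and_real_output(self, n, seed):
        x = np.random.default_rng(seed).normal(size=(n, 2))
        m = make_matrix(x)
        hp = pp.highpass_fourier(m)
        lp = pp.lowpass_complement(m)
        # idempotence
        np.testing.assert_allclose(
            pp.highpass_fourier(hp).data, hp.data, atol=1e-10
        )
        # Parseval energy split
        assert np.sum(hp.data**2) + np.sum(lp.data**2) == pytest.approx(
            np.sum(x**2), rel=1e-8
        )
        # exact additivity in the time domain (both outputs real)
        np.testing.assert_allclose(hp.data + lp.data, x, atol=1e-10)


class TestSmoothing:
    @staticmethod
    def _volume_matrix(rng, shape=(7, 6, 5)):
        mask = np.ones(shape, dtype=bool)
        idx = np.argwhere(mask)
        order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))  # any fixed order
        idx = idx[order]
        data = rng.normal(size=(3, idx.shape[0]))
        return pp.VoxelTimeSeriesMatrix(
            data=data,
            tr_seconds=TR,
            voxel_index=idx,
            subject_id="sub-01",
            grid_shape=shape,
        )

    def test_fwhm_zero_is_identity(self, rng):
        m = self._volume_matrix(rng)
        out = pp.smooth_gaussian(m, 0.0)
        np.testing.assert_array_equal(out.data, m.data)

    def test_impulse_response_is_gaussian_and_sum_preserved(self):
        shape = (15, 15, 15)
        mask_idx = np.argwhere(np.ones(shape, dtype=bool))
        data = np.zeros((1, mask_idx.shape[0]))
        center = np.ravel_multi_index((7, 7, 7), shape)
        data[0, center] = 1.0
        m = pp.VoxelTimeSeriesMatrix(
            data=data, tr_seconds=TR, voxel_index=mask_idx,
            subject_id="s", grid_shape=shape,
        )
        out = pp.smooth_gaussian(m, 2.0)
        assert out.data.sum() == pytest.approx(1.0, abs=1e-8)
        vol = np.zeros(shape)
        vol[tuple(mask_idx.T)] = out.data[0]
        assert vol[7, 7, 7] == vol.max()
        assert vol[7, 7, 8] == pytest.approx(vol[7, 8, 7], rel=1e-10)

    def test_matches_dense_convolution_oracle(self, rng):
        m = self._volume_matrix(rng, shape=(6, 6, 6))
        fwhm = 1.5
        out = pp.smooth_gaussian(m, fwhm)
        # brute-force renormalized Gaussian convolution oracle
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        shape = m.grid_shape
        vol = np.zeros(shape)
        vol[tuple(m.voxel_index.T)] = m.data[0]
        coords = np.argwhere(np.ones(shape, dtype=bool)).astype(float)
        expected = np.empty(m.n_voxels)
        radius = int(np.ceil(4 * sigma))
        for i, c in enumerate(m.voxel_index):
            acc, wsum = 0.0, 0.0
            for dx in range(-radius, radius + 1):
                for dy in range(-radius, radius + 1):
                    for dz in range(-radius, radius + 1):
                        p = c + np.array([dx, dy, dz])
                        if np.any(p < 0) or np.any(p >= shape):
                            continue
                        w = np.exp(-(dx**2 + dy**2 + dz**2) / (2 * sigma**2))
                        acc += w * vol[tuple(p)]
                        wsum += w
            expected[i] = acc / wsum
        np.testing.assert_allclose(out.data[0], expected, atol=1e-8)


class TestPipelineOrder:
    def test_steps_run_in_fixed_order(self, rng):
        data = rng.normal(size=(100, 5)) + 10.0
        motion = rng.normal(size=(100, 6))
        out, record = pp.preprocess_subject(
            make_matrix(data), motion=motion, n_discard=10
        )
        assert record.steps == ["discard:10", "motion_glm", "standardize", "highpass:0.25"]
        assert out.n_volumes == 90
        # high-pass output has exactly zero sub-cutoff content
        freqs = np.fft.rfftfreq(90, d=TR)
        spec = np.abs(np.fft.rfft(out.data, axis=0))
        assert np.max(spec[freqs < 0.25 * (1 - 1e-12)]) < 1e-8

    def test_filter_off_keeps_low_frequencies(self, rng):
        data = rng.normal(size=(100, 3))
        out, record = pp.preprocess_subject(
            make_matrix(data), n_discard=0, filter_spec=None
        )
        assert "standardize" in record.steps
        assert not any(s.startswith("highpass") for s in record.steps)
        assert out.data[:, 0].std() == pytest.approx(1.0)


def test_nyquist_frequency_matches_definition():
    assert pp.nyquist_frequency(2.0) == 0.25
    assert pp.nyquist_frequency(0.354) == pytest.approx(1.4124, abs=1e-4)
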