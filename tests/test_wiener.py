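"""Wiener estimation: autocorrelation prior, W matrix, reconstruction, GFC."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from skinspectra import (
    SpectralGrid,
    Spectrum,
    WienerModel,
    compute_autocorrelation,
    compute_wiener_matrix,
    gfc,
    reconstruct_image,
    reconstruct_spectrum,
)
from skinspectra.wiener import load_ensemble_csv, save_ensemble_csv

GRID = SpectralGrid.reconstruction()


class TestAutocorrelation:
    def test_single_basis_spectrum_outer_product(self):
        r = np.zeros(25)
        r[0] = 1.0
        R = compute_autocorrelation([Spectrum(GRID, r)])
        expected = np.zeros((25, 25))
        expected[0, 0] = 1.0
        assert np.array_equal(R, expected)

    def test_sign_cancels_in_outer_product(self, rng):
        r = rng.random(25)
        both = compute_autocorrelation(np.stack([r, -r]))
        single = compute_autocorrelation(r[None, :])
        assert np.allclose(both, single, rtol=1e-14)

    def test_matches_double_loop_oracle_on_341_spectra(self, rng):
        X = rng.random((341, 25))
        R = compute_autocorrelation(X)
        oracle = np.zeros((25, 25))
        for row in X:
            oracle += np.outer(row, row)
        oracle /= X.shape[0]
        assert np.allclose(R, oracle, rtol=0, atol=1e-12)
        assert R.shape == (25, 25)
        assert np.allclose(R, R.T)
        assert np.all(np.linalg.eigvalsh(R) > -1e-10)  # PSD

    def test_empty_and_mixed_grid_ensembles_rejected(self):
        with pytest.raises(ValueError):
            compute_autocorrelation([])
        mixed = [
            Spectrum(GRID, np.ones(25)),
            Spectrum(SpectralGrid.estimation(), np.ones(6)),
        ]
        with pytest.raises(ValueError):
            compute_autocorrelation(mixed)


class TestWienerMatrix:
    def test_square_invertible_case_gives_identity(self):
        W = compute_wiener_matrix(np.eye(3), np.eye(3))
        assert np.allclose(W, np.eye(3), atol=1e-12)

    def test_closed_form_oracle(self, rng):
        """W equals R F^T (F R F^T)^-1 computed by an independent dense solve."""
        X = rng.random((50, 25))
        R = X.T @ X / 50
        F = rng.random((3, 25))
        W = compute_wiener_matrix(R, F)
        oracle = R @ F.T @ np.linalg.inv(F @ R @ F.T)
        assert np.allclose(W, oracle, rtol=0, atol=1e-10)

    def test_rank3_subspace_round_trip(self, rng):
        """Training confined to a 3-dim subspace with injective F: exact recovery."""
        basis = rng.random((3, 25))
        coeffs = rng.random((40, 3))
        X = coeffs @ basis  # ensemble inside span(basis)
        F = rng.random((3, 25))
        R = compute_autocorrelation(X)
        W = compute_wiener_matrix(R, F)
        for r in X:
            assert np.allclose(W @ (F @ r), r, atol=1e-10)

    def test_minimizes_ensemble_mse_locally(self, skin_ensemble, camera):
        model = WienerModel.train(skin_ensemble, camera)
        X = np.stack([s.values for s in skin_ensemble])
        V = X @ model.system_matrix.T

        def mse(W):
            return np.mean((V @ W.T - X) ** 2)

        base = mse(model.W)
        rng = np.random.default_rng(0)
        for _ in range(20):
            i, j = rng.integers(25), rng.integers(3)
            for delta in (1e-3, -1e-3):
                W = model.W.copy()
                W[i, j] += delta
                assert mse(W) >= base

    def test_beats_random_matrices(self, skin_ensemble, camera):
        model = WienerModel.train(skin_ensemble, camera)
        X = np.stack([s.values for s in skin_ensemble])
        V = X @ model.system_matrix.T
        base = np.mean((V @ model.W.T - X) ** 2)
        rng = np.random.default_rng(1)
        for _ in range(100):
            W = rng.standard_normal((25, 3))
            assert np.mean((V @ W.T - X) ** 2) >= base

    def test_singular_gram_falls_back_to_pinv_with_warning(self):
        R = np.eye(25)
        F = np.zeros((3, 25))
        F[0, 0] = 1.0
        F[1, 0] = 1.0  # rows identical -> singular 3x3 Gram
        with pytest.warns(RuntimeWarning):
            W = compute_wiener_matrix(R, F)
        assert np.all(np.isfinite(W))

    def test_nan_inputs_rejected(self):
        R = np.eye(25)
        R[0, 0] = np.nan
        with pytest.raises(ValueError):
            compute_wiener_matrix(R, np.ones((3, 25)))


class TestReconstruction:
    def test_zero_response_gives_zero_spectrum(self, wiener_model):
        r = reconstruct_spectrum(wiener_model, np.zeros(3))
        assert np.array_equal(r.values, np.zeros(25))

    def test_linearity_in_response(self, wiener_model, rng):
        v = rng.random(3)
        r1 = reconstruct_spectrum(wiener_model, v).values
        r2 = reconstruct_spectrum(wiener_model, 2 * v).values
        assert np.allclose(r2, 2 * r1, rtol=1e-12)

    def test_image_single_pixel_matches_spectrum_path(self, wiener_model, rng):
        v = rng.random(3)
        stack = reconstruct_image(wiener_model, v.reshape(1, 1, 3))
        assert stack.shape == (25, 1, 1)
        assert np.allclose(stack[:, 0, 0], reconstruct_spectrum(wiener_model, v).values)

    def test_constant_image_gives_constant_planes(self, wiener_model):
        rgb = np.tile(np.array([0.3, 0.5, 0.2]), (4, 5, 1))
        stack = reconstruct_image(wiener_model, rgb)
        assert np.allclose(stack, stack[:, :1, :1])

    def test_image_matches_per_pixel_loop_oracle(self, wiener_model, rng):
        rgb = rng.random((64, 64, 3))
        stack = reconstruct_image(wiener_model, rgb)
        for i in range(0, 64, 7):
            for j in range(0, 64, 11):
                assert np.allclose(
                    stack[:, i, j],
                    reconstruct_spectrum(wiener_model, rgb[i, j]).values,
                    rtol=1e-12,
                )

    def test_non_rgb_input_rejected(self, wiener_model):
        with pytest.raises(ValueError):
            reconstruct_image(wiener_model, np.ones((4, 4)))
        with pytest.raises(ValueError):
            reconstruct_image(wiener_model, np.ones((4, 4, 4)))


class TestGFC:
    def test_self_similarity_is_one(self, rng):
        r = rng.random(25) + 0.01
        assert gfc(r, r) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_spectra_give_zero(self):
        a = np.zeros(25)
        b = np.zeros(25)
        a[0] = 1.0
        b[1] = 1.0
        assert gfc(a, b) == 0.0

    def test_all_zero_spectrum_rejected(self):
        with pytest.raises(ValueError):
            gfc(np.zeros(25), np.ones(25))

    @given(seed=st.integers(0, 2**16), c=st.floats(1e-3, 1e3))
    def test_bounded_and_scale_invariant(self, seed, c):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(25)
        b = rng.standard_normal(25)
        g = gfc(a, b)
        assert 0.0 <= g <= 1.0
        assert gfc(a, c * b) == pytest.approx(g, rel=1e-9)
        assert gfc(c * a, b) == pytest.approx(g, rel=1e-9)


class TestSerialization:
    def test_model_round_trip(self, tmp_path, wiener_model):
        path = tmp_path / "wiener.csv"
        wiener_model.save(path)
        loaded = WienerModel.load(path)
        assert loaded.grid == wiener_model.grid
        assert np.allclose(loaded.W, wiener_model.W)
        assert np.allclose(loaded.system_matrix, wiener_model.system_matrix)
        assert np.allclose(loaded.autocorrelation, wiener_model.autocorrelation)

    def test_ensemble_csv_round_trip(self, tmp_path, skin_ensemble):
        path = tmp_path / "ensemble.csv"
        save_ensemble_csv(path, skin_ensemble)
        X = load_ensemble_csv(path)
        assert X.shape == (341, 25)
        assert np.allclose(X, np.stack([s.values for s in skin_ensemble]))
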