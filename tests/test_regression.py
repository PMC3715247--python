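"""Absorbance, MRA1, StO2 and the MRA2 conversion-vector machinery."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from skinspectra import (
    ChromophoreState,
    ConversionModel,
    MRA1Coefficients,
    SpectralGrid,
    Spectrum,
    absorbance,
    basis_expand,
    compute_sto2,
    default_basis,
    fit_conversion_vectors,
    mra1,
    predict_concentrations,
)

GRID = SpectralGrid.estimation()


class TestAbsorbance:
    @pytest.mark.parametrize("r,expected", [(0.1, 1.0), (1.0, 0.0), (0.01, 2.0)])
    def test_log10_values(self, r, expected):
        A = absorbance(Spectrum(GRID, np.full(6, r)))
        assert np.allclose(A.values, expected)
        assert not A.flagged

    def test_nonpositive_reflectance_floored_and_flagged(self):
        vals = np.array([0.5, 0.0, -0.1, 0.5, 0.5, 0.5])
        A = absorbance(Spectrum(GRID, vals), floor=1e-4)
        assert A.flagged
        assert np.array_equal(A.floored, vals <= 0)
        assert np.allclose(A.values[1:3], 4.0)  # -log10(1e-4)

    def test_bad_floor_rejected(self):
        with pytest.raises(ValueError):
            absorbance(Spectrum(GRID, np.ones(6)), floor=0.0)


class TestMRA1:
    def test_noiseless_exact_recovery(self, table):
        t = table.on_grid(GRID)
        A_vals = 2.0 * t.eps_melanin + 1.0 * t.eps_oxy + 0.5 * t.eps_deoxy + 0.1
        from skinspectra.regression import AbsorbanceSpectrum

        A = AbsorbanceSpectrum(GRID, A_vals, np.zeros(6, dtype=bool))
        c = mra1(A, table)
        assert c.a_m == pytest.approx(2.0, abs=1e-10)
        assert c.a_ob == pytest.approx(1.0, abs=1e-10)
        assert c.a_db == pytest.approx(0.5, abs=1e-10)
        assert c.a_0 == pytest.approx(0.1, abs=1e-10)
        assert c.a_tb == c.a_ob + c.a_db

    def test_zero_absorbance_gives_zero_coefficients(self, table):
        from skinspectra.regression import AbsorbanceSpectrum

        A = AbsorbanceSpectrum(GRID, np.zeros(6), np.zeros(6, dtype=bool))
        c = mra1(A, table)
        for v in (c.a_m, c.a_ob, c.a_db, c.a_0):
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle_on_noisy_input(self, table, rng):
        from skinspectra.regression import AbsorbanceSpectrum

        t = table.on_grid(GRID)
        X = np.column_stack([t.eps_melanin, t.eps_oxy, t.eps_deoxy, np.ones(6)])
        for _ in range(25):
            y = rng.standard_normal(6)
            c = mra1(AbsorbanceSpectrum(GRID, y, np.zeros(6, dtype=bool)), table)
            oracle = np.linalg.solve(X.T @ X, X.T @ y)
            assert np.allclose([c.a_m, c.a_ob, c.a_db, c.a_0], oracle, atol=1e-10)
            # residual orthogonal to every regressor
            resid = y - X @ oracle
            assert np.allclose(X.T @ resid, 0.0, atol=1e-9)

    def test_collinear_extinction_spectra_named_in_error(self, table):
        from skinspectra.montecarlo import ExtinctionTable

        bad = ExtinctionTable(
            grid=GRID,
            eps_melanin=np.ones(6),
            eps_oxy=2 * np.ones(6),  # collinear with melanin and intercept
            eps_deoxy=np.arange(1.0, 7.0),
        )
        from skinspectra.regression import AbsorbanceSpectrum

        A = AbsorbanceSpectrum(GRID, np.ones(6), np.zeros(6, dtype=bool))
        with pytest.raises(ValueError, match="collinear"):
            mra1(A, bad)

    def test_too_few_wavelengths_rejected(self, table):
        grid3 = SpectralGrid(np.array([500.0, 520.0, 540.0]))
        from skinspectra.regression import AbsorbanceSpectrum

        A = AbsorbanceSpectrum(grid3, np.ones(3), np.zeros(3, dtype=bool))
        with pytest.raises(ValueError):
            mra1(A, table)


class TestStO2:
    @pytest.mark.parametrize(
        "a_ob,a_db,expected", [(0.3, 0.1, 75.0), (0.4, 0.0, 100.0), (0.0, 0.2, 0.0)]
    )
    def test_ratio_arithmetic(self, a_ob, a_db, expected):
        clipped, raw = compute_sto2(MRA1Coefficients(0.1, a_ob, a_db, 0.0))
        assert clipped == pytest.approx(expected)
        assert raw == pytest.approx(expected)

    def test_zero_blood_total_is_undefined(self):
        clipped, raw = compute_sto2(MRA1Coefficients(0.1, 0.0, 0.0, 0.0))
        assert np.isnan(clipped) and np.isnan(raw)

    def test_out_of_range_ratio_clipped_but_raw_kept(self):
        clipped, raw = compute_sto2(MRA1Coefficients(0.0, 0.3, -0.1, 0.0))
        assert clipped == 100.0
        assert raw == pytest.approx(150.0)

    @given(
        a_ob=st.floats(1e-3, 10),
        a_db=st.floats(1e-3, 10),
        c=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, a_ob, a_db, c):
        s1, _ = compute_sto2(MRA1Coefficients(0, a_ob, a_db, 0))
        s2, _ = compute_sto2(MRA1Coefficients(0, c * a_ob, c * a_db, 0))
        assert s1 == pytest.approx(s2, rel=1e-9)


class TestBasisExpansion:
    def test_default_basis_has_14_terms_with_documented_prefix(self):
        spec = default_basis()
        assert len(spec) == 14
        assert spec[:6] == (
            (0, 0, 0),  # 1
            (1, 0, 0),  # a_m
            (0, 1, 0),  # a_tb
            (0, 0, 1),  # a_0
            (1, 1, 0),  # a_m * a_tb
            (1, 0, 1),  # a_m * a_0
        )
        assert len(set(spec)) == 14

    def test_zero_coefficients_leave_only_constant(self):
        a = basis_expand(MRA1Coefficients(0, 0, 0, 0))
        assert a[0] == 1.0
        assert np.array_equal(a[1:], np.zeros(13))

    def test_unit_coefficients_give_all_ones(self):
        a = basis_expand(MRA1Coefficients(1, 0.5, 0.5, 1))  # a_tb = 1
        assert np.array_equal(a, np.ones(14))

    @given(
        am=st.floats(-2, 2),
        atb=st.floats(-2, 2),
        a0=st.floats(-2, 2),
    )
    def test_multiplicative_in_each_exponent(self, am, atb, a0):
        c = MRA1Coefficients(am, atb / 2, atb / 2, a0)
        a = basis_expand(c)
        for j, (p, q, s) in enumerate(default_basis()):
            assert a[j] == pytest.approx(am**p * atb**q * a0**s, rel=1e-9, abs=1e-12)

    def test_malformed_basis_rejected(self):
        c = MRA1Coefficients(1, 1, 1, 1)
        with pytest.raises(ValueError):
            basis_expand(c, [(1, 0, 0), (0, 1, 0)])  # missing constant first
        with pytest.raises(ValueError):
            basis_expand(c, [(0, 0, 0), (1, 0, 0), (1, 0, 0)])  # duplicate


def _planted_training(rng, n=60):
    """Training set where C_m = 3 a_m + 0.5 and C_tb = 2 a_tb - 1 exactly."""
    out = []
    for _ in range(n):
        am, aob, adb, a0 = rng.uniform(0.1, 1.0, size=4)
        c = MRA1Coefficients(am, aob, adb, a0)
        cm = 3.0 * am + 0.5
        ctb = 2.0 * c.a_tb - 1.0 + 2.0  # keep within [0, 100]
        out.append((ChromophoreState(cm, min(ctb, 100.0), 50.0), c))
    return out


class TestConversionVectors:
    def test_planted_linear_model_recovered(self, rng):
        training = _planted_training(rng)
        model = fit_conversion_vectors(training)
        expected = np.zeros(14)
        expected[0] = 0.5
        expected[1] = 3.0
        assert np.allclose(model.b_m, expected, atol=1e-8)
        # C_tb plant: constant 1.0 (= -1 + 2), slope 2 on a_tb
        expected_tb = np.zeros(14)
        expected_tb[0] = 1.0
        expected_tb[2] = 2.0
        assert np.allclose(model.b_tb, expected_tb, atol=1e-8)

    def test_record_order_invariance(self, rng):
        training = _planted_training(rng)
        m1 = fit_conversion_vectors(training)
        m2 = fit_conversion_vectors(training[::-1])
        assert np.allclose(m1.b_m, m2.b_m, atol=1e-10)
        assert np.allclose(m1.b_tb, m2.b_tb, atol=1e-10)

    def test_too_few_records_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_conversion_vectors(_planted_training(rng, n=10))

    def test_rank_deficient_design_rejected(self):
        c = MRA1Coefficients(1.0, 0.5, 0.5, 1.0)  # identical records
        training = [(ChromophoreState(5, 0.5, 50), c)] * 40
        with pytest.raises(ValueError, match="rank deficient"):
            fit_conversion_vectors(training)

    def test_prediction_constant_only_vector(self):
        model = ConversionModel(
            basis=default_basis(),
            b_m=np.r_[4.2, np.zeros(13)],
            b_tb=np.r_[0.7, np.zeros(13)],
        )
        cm, ctb, cm_raw, ctb_raw = predict_concentrations(
            MRA1Coefficients(0, 0, 0, 0), model
        )
        assert (cm, ctb) == (4.2, 0.7)
        assert (cm_raw, ctb_raw) == (4.2, 0.7)

    def test_negative_prediction_clipped_with_raw_preserved(self):
        model = ConversionModel(
            basis=default_basis(),
            b_m=np.r_[-1.0, np.zeros(13)],
            b_tb=np.r_[0.7, np.zeros(13)],
        )
        cm, ctb, cm_raw, _ = predict_concentrations(MRA1Coefficients(0, 0, 0, 0), model)
        assert cm == 0.0 and cm_raw == -1.0

    def test_planted_model_round_trip_prediction(self, rng):
        training = _planted_training(rng)
        model = fit_conversion_vectors(training)
        state, coeffs = training[7]
        cm, *_ = predict_concentrations(coeffs, model)
        assert cm == pytest.approx(state.C_m, abs=1e-7)

    def test_json_round_trip(self, tmp_path, rng):
        model = fit_conversion_vectors(_planted_training(rng))
        path = tmp_path / "conv.json"
        model.to_json(path)
        back = ConversionModel.from_json(path)
        assert back.basis == model.basis
        assert np.allclose(back.b_m, model.b_m)
        assert np.allclose(back.b_tb, model.b_tb)


class TestSurrogateGridRecovery:
    def test_in_sample_r2_on_surrogate_grid(self, table, surrogate_conversion):
        """Training on the fast closed-form forward grid and predicting the
        same grid recovers concentrations with high in-sample R^2."""
        from skinspectra.fixtures import surrogate_training_records
        from skinspectra.regression import absorbance as absf

        records = surrogate_training_records(table)
        cm_t, cm_p, ctb_t, ctb_p = [], [], [], []
        for rec in records:
            c = mra1(absf(rec.spectrum), table)
            cm, ctb, *_ = predict_concentrations(c, surrogate_conversion)
            cm_t.append(rec.state.C_m)
            ctb_t.append(rec.state.C_tb)
            cm_p.append(cm)
            ctb_p.append(ctb)

        def r2(y, p):
            y, p = np.asarray(y), np.asarray(p)
            return 1 - np.sum((y - p) ** 2) / np.sum((y - y.mean()) ** 2)

        assert r2(cm_t, cm_p) > 0.99
        assert r2(ctb_t, ctb_p) > 0.99
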