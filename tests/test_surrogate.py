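"""gPC basis combinatorics, pseudoinverse fitting, Sobol and derivative
sensitivities, and the NRMSD error measure."""

from itertools import product

import numpy as np
import pytest

from tmscouple.surrogate import (
    BasisSpec,
    ParamBounds,
    PolynomialChaosSurrogate,
    default_time_grid,
    enumerate_basis,
    nrmsd,
    sample_params,
)


def small_bounds(d=2):
    return ParamBounds(
        names=tuple(f"p{i}" for i in range(d)),
        lower=tuple([-1.0] * d),
        upper=tuple([1.0] * d),
    )


def brute_force_enumerate(spec: BasisSpec, n_params: int) -> set:
    """Independent oracle: filter the full tensor grid of orders."""
    caps = [spec.cap(j) for j in range(n_params)]
    out = set()
    for alpha in product(*(range(c + 1) for c in caps)):
        nz = [a for a in alpha if a > 0]
        if len(nz) > spec.max_interaction_order:
            continue
        if len(nz) >= 2 and sum(nz) > spec.max_interaction_sum:
            continue
        out.add(alpha)
    return out


class TestEnumerateBasis:
    def test_published_truncation_yields_1642(self):
        assert len(enumerate_basis(BasisSpec(), n_params=6)) == 1642

    def test_single_parameter_cap(self):
        spec = BasisSpec(max_univariate_order=3, gradient_param_order=3,
                         gradient_param_index=0)
        assert len(enumerate_basis(spec, n_params=1)) == 4

    def test_two_parameter_hand_count(self):
        # caps 2, interaction order 2, interaction sum 2:
        # const, (1,0), (2,0), (0,1), (0,2), (1,1) -> 6
        spec = BasisSpec(max_univariate_order=2, gradient_param_order=2,
                         max_interaction_order=2, max_interaction_sum=2,
                         gradient_param_index=0)
        assert len(enumerate_basis(spec, n_params=2)) == 6

    @pytest.mark.parametrize("n_params", [2, 3])
    def test_matches_brute_force_filter(self, n_params):
        spec = BasisSpec(max_univariate_order=6, gradient_param_order=4,
                         max_interaction_order=3, max_interaction_sum=5,
                         gradient_param_index=1)
        got = {tuple(a) for a in enumerate_basis(spec, n_params)}
        assert got == brute_force_enumerate(spec, n_params)

    def test_indices_unique_and_include_constant(self):
        mi = enumerate_basis(BasisSpec(), n_params=6)
        assert len(np.unique(mi, axis=0)) == len(mi)
        assert (mi == 0).all(axis=1).any()


class TestSampleParams:
    def test_within_bounds(self):
        b = ParamBounds()
        x = sample_params(b, 500, seed=0)
        assert np.all(x >= np.asarray(b.lower)) and np.all(x <= np.asarray(b.upper))

    def test_seed_reproducibility(self):
        b = ParamBounds()
        assert np.array_equal(sample_params(b, 100, 7), sample_params(b, 100, 7))

    def test_mean_matches_uniform_moments(self):
        b = ParamBounds()
        x = sample_params(b, 4000, seed=3)
        lo, hi = np.asarray(b.lower), np.asarray(b.upper)
        se = (hi - lo) / np.sqrt(12.0) / np.sqrt(4000)
        assert np.all(np.abs(x.mean(axis=0) - (lo + hi) / 2) < 3 * se)


def legendre_p(n, x):
    from numpy.polynomial import legendre as L

    c = np.zeros(n + 1)
    c[n] = 1.0
    return L.legval(x, c)


class TestFitPredict:
    spec = BasisSpec(max_univariate_order=4, gradient_param_order=4,
                     max_interaction_order=2, max_interaction_sum=4,
                     gradient_param_index=0)

    def test_exact_recovery_of_representable_polynomial(self):
        b = small_bounds(2)
        rng = np.random.default_rng(0)
        x = sample_params(b, 300, 1)

        def f(x):
            return (1.0 + 2.0 * x[:, 0] - x[:, 1] ** 2
                    + 0.5 * x[:, 0] * x[:, 1])[:, None]

        m = PolynomialChaosSurrogate(bounds=b, basis_spec=self.spec).fit(x, f(x))
        x_new = sample_params(b, 200, 2)
        assert nrmsd(f(x_new), m.predict(x_new)) < 1e-8

    def test_constant_response_only_constant_coefficient(self):
        b = small_bounds(2)
        x = sample_params(b, 200, 3)
        y = np.full((200, 4), 3.7)
        m = PolynomialChaosSurrogate(bounds=b, basis_spec=self.spec).fit(x, y)
        const_row = (m.multi_indices_ == 0).all(axis=1)
        assert np.allclose(m.coefficients_[const_row], 3.7)
        assert np.all(np.abs(m.coefficients_[~const_row]) < 1e-10)

    def test_first_degree_legendre_coefficient_recovered(self):
        """Response = orthonormal P1 of parameter 0 -> a single unit
        coefficient; orthonormality checked by Gauss-Legendre quadrature."""
        b = small_bounds(2)
        x = sample_params(b, 400, 4)
        y = (np.sqrt(3.0) * x[:, 0])[:, None]
        m = PolynomialChaosSurrogate(bounds=b, basis_spec=self.spec).fit(x, y)
        target = np.array([1, 0])
        row = (m.multi_indices_ == target).all(axis=1)
        assert np.isclose(m.coefficients_[row, 0], 1.0, atol=1e-8)
        assert np.all(np.abs(m.coefficients_[~row, 0]) < 1e-8)
        # quadrature oracle: the scaled P1 is unit-norm under uniform measure
        nodes, weights = np.polynomial.legendre.leggauss(16)
        norm = np.sum(weights / 2.0 * (np.sqrt(3.0) * legendre_p(1, nodes)) ** 2)
        assert np.isclose(norm, 1.0, atol=1e-12)

    def test_training_point_match_for_representable_model(self):
        b = small_bounds(2)
        x = sample_params(b, 150, 5)
        y = (x[:, 0] ** 2 - x[:, 1])[:, None]
        m = PolynomialChaosSurrogate(bounds=b, basis_spec=self.spec).fit(x, y)
        assert np.allclose(m.predict(x), y, atol=1e-8)

    def test_prediction_linear_in_coefficients(self):
        b = small_bounds(2)
        x = sample_params(b, 100, 6)
        y = np.column_stack([x[:, 0], x[:, 1] ** 2])
        m = PolynomialChaosSurrogate(bounds=b, basis_spec=self.spec).fit(x, y)
        x_new = sample_params(b, 20, 7)
        base = m.predict(x_new)
        m.coefficients_ = 2.0 * m.coefficients_
        assert np.allclose(m.predict(x_new), 2.0 * base)

    def test_vectorized_equals_scalar_predictions(self):
        b = small_bounds(3)
        x = sample_params(b, 100, 8)
        y = np.sin(x).sum(axis=1)[:, None]
        m = PolynomialChaosSurrogate(bounds=b, basis_spec=self.spec).fit(x, y)
        x_new = sample_params(b, 10, 9)
        batch = m.predict(x_new)
        singles = np.vstack([m.predict(xi[None, :]) for xi in x_new])
        assert np.allclose(batch, singles)

    def test_underdetermined_fit_warns(self):
        b = small_bounds(2)
        x = sample_params(b, 5, 10)
        y = x[:, :1]
        with pytest.warns(UserWarning, match="underdetermined"):
            PolynomialChaosSurrogate(bounds=b, basis_spec=self.spec).fit(x, y)

    def test_nrmsd_decreases_with_training_size(self):
        b = small_bounds(2)

        def f(x):
            return np.exp(0.8 * x[:, 0]) * np.cos(1.5 * x[:, 1])

        x_test = sample_params(b, 400, 11)
        y_test = f(x_test)[:, None]
        errs = []
        for n in (40, 160, 640):
            x = sample_params(b, n, 12)
            m = PolynomialChaosSurrogate(bounds=b, basis_spec=self.spec).fit(
                x, f(x)[:, None]
            )
            errs.append(nrmsd(y_test, m.predict(x_test)))
        assert errs[-1] < errs[0]

    def test_hdf5_round_trip(self, tmp_path):
        b = small_bounds(2)
        x = sample_params(b, 100, 13)
        y = np.column_stack([x[:, 0] ** 2, x[:, 1]])
        m = PolynomialChaosSurrogate(bounds=b, basis_spec=self.spec).fit(x, y)
        p = tmp_path / "model.h5"
        m.to_hdf5(p)
        m2 = PolynomialChaosSurrogate.from_hdf5(p)
        x_new = sample_params(b, 25, 14)
        assert np.allclose(m.predict(x_new), m2.predict(x_new))


class TestNrmsd:
    def test_identical_arrays_zero(self):
        a = np.random.default_rng(0).normal(size=(30, 5))
        assert nrmsd(a, a) == 0.0

    def test_hand_computed_example(self):
        """ref {0, 2}, approx {1, 1}: RMS error 1 over range 2 -> 50%."""
        ref = np.array([[0.0], [2.0]])
        approx = np.array([[1.0], [1.0]])
        assert np.isclose(nrmsd(ref, approx), 50.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(50, 6))
        approx = ref + rng.normal(scale=0.1, size=ref.shape)
        a, bshift = 3.7, -11.0
        assert np.isclose(
            nrmsd(ref, approx), nrmsd(a * ref + bshift, a * approx + bshift)
        )

    def test_zero_range_time_points_excluded(self):
        ref = np.zeros((10, 2))
        ref[:, 1] = np.arange(10.0)
        approx = ref + 0.5
        out = nrmsd(ref, approx)  # column 0 has zero range -> excluded
        assert np.isfinite(out)


class TestSobolIndices:
    def test_additive_model_closed_form(self):
        """I = a*xi1 + b*xi2 (orthonormalized): S1 = a^2/(a^2+b^2)."""
        b = small_bounds(2)
        a_coef, b_coef = 2.0, 1.0
        x = sample_params(b, 500, 15)
        y = (a_coef * np.sqrt(3.0) * x[:, 0]
             + b_coef * np.sqrt(3.0) * x[:, 1])[:, None]
        spec = BasisSpec(max_univariate_order=3, gradient_param_order=3,
                         max_interaction_order=2, max_interaction_sum=3,
                         gradient_param_index=0)
        m = PolynomialChaosSurrogate(bounds=b, basis_spec=spec).fit(x, y)
        sens = m.sobol_indices()
        denom = a_coef**2 + b_coef**2
        assert np.isclose(sens.sobol[(0,)][0], a_coef**2 / denom, atol=1e-8)
        assert np.isclose(sens.sobol[(1,)][0], b_coef**2 / denom, atol=1e-8)
        assert sens.sobol.get((0, 1), np.zeros(1))[0] < 1e-10

    def test_indices_sum_to_one(self):
        b = small_bounds(3)
        x = sample_params(b, 600, 16)
        y = np.column_stack([
            np.sin(x[:, 0]) + x[:, 1] * x[:, 2],
            np.cos(x[:, 1]) * (1 + 0.5 * x[:, 0]),
        ])
        spec = BasisSpec(max_univariate_order=5, gradient_param_order=5,
                         max_interaction_order=3, max_interaction_sum=6,
                         gradient_param_index=0)
        m = PolynomialChaosSurrogate(bounds=b, basis_spec=spec).fit(x, y)
        sens = m.sobol_indices()
        total = sum(s for s in sens.sobol.values())
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_single_parameter_dependence(self):
        b = small_bounds(2)
        x = sample_params(b, 300, 17)
        y = (x[:, 0] ** 3)[:, None]
        spec = BasisSpec(max_univariate_order=4, gradient_param_order=4,
                         max_interaction_order=2, max_interaction_sum=4,
                         gradient_param_index=0)
        m = PolynomialChaosSurrogate(bounds=b, basis_spec=spec).fit(x, y)
        sens = m.sobol_indices()
        assert np.isclose(sens.sobol[(0,)][0], 1.0, atol=1e-8)
        for u, s in sens.sobol.items():
            if u != (0,):
                assert s[0] < 1e-10

    def test_agrees_with_saltelli_monte_carlo(self):
        """First-order indices of a 3-parameter toy model vs a Saltelli
        pick-freeze estimator (independent oracle), within 0.02."""
        b = small_bounds(3)

        def f(x):
            return (x[:, 0] + 0.5 * x[:, 1] ** 2
                    + 0.25 * x[:, 0] * x[:, 2] + 0.2 * np.sin(2 * x[:, 2])
                    )

        spec = BasisSpec(max_univariate_order=8, gradient_param_order=8,
                         max_interaction_order=3, max_interaction_sum=10,
                         gradient_param_index=0)
        x = sample_params(b, 2000, 18)
        m = PolynomialChaosSurrogate(bounds=b, basis_spec=spec).fit(
            x, f(x)[:, None]
        )
        sens = m.sobol_indices()
        # Saltelli pick-freeze with matrices A, B
        rng = np.random.default_rng(19)
        n = 1 << 14
        A = rng.uniform(-1, 1, size=(n, 3))
        B = rng.uniform(-1, 1, size=(n, 3))
        fa, fb = f(A), f(B)
        var = np.var(np.concatenate([fa, fb]), ddof=1)
        for j in range(3):
            ABj = A.copy()
            ABj[:, j] = B[:, j]
            s_mc = np.mean(fb * (f(ABj) - fa)) / var
            s_gpc = sens.sobol.get((j,), np.zeros(1))[0]
            assert abs(s_gpc - s_mc) < 0.02


class TestDerivativeSensitivity:
    spec = BasisSpec(max_univariate_order=5, gradient_param_order=5,
                     max_interaction_order=2, max_interaction_sum=5,
                     gradient_param_index=0)

    def test_linear_model_constant_derivative(self):
        bounds = ParamBounds(names=("a", "b"), lower=(0.0, 10.0),
                             upper=(4.0, 30.0))
        x = sample_params(bounds, 400, 20)
        slope = 2.5
        y = (slope * x[:, 0] + 0.1 * x[:, 1])[:, None]
        m = PolynomialChaosSurrogate(bounds=bounds, basis_spec=self.spec).fit(x, y)
        d = m.derivative_sensitivity(n_mc=2000, seed=0)
        assert np.isclose(d[0, 0], slope, rtol=1e-6)
        assert np.isclose(d[1, 0], 0.1, rtol=1e-6)

    def test_even_function_zero_average_derivative(self):
        b = small_bounds(1)
        x = sample_params(b, 300, 21)
        y = (x[:, 0] ** 2)[:, None]  # even about the midpoint
        m = PolynomialChaosSurrogate(bounds=b, basis_spec=self.spec).fit(x, y)
        n_mc = 4000
        d = m.derivative_sensitivity(n_mc=n_mc, seed=1)
        # E[2x] = 0; MC SE of 2x over U(-1,1) is 2/sqrt(3)/sqrt(n)
        se = 2.0 / np.sqrt(3.0) / np.sqrt(n_mc)
        assert abs(d[0, 0]) < 3 * se

    def test_seed_reproducibility_bit_identical(self):
        b = small_bounds(2)
        x = sample_params(b, 200, 22)
        y = np.column_stack([np.sin(x[:, 0]), x[:, 1] ** 3])
        m = PolynomialChaosSurrogate(bounds=b, basis_spec=self.spec).fit(x, y)
        d1 = m.derivative_sensitivity(n_mc=500, seed=42)
        d2 = m.derivative_sensitivity(n_mc=500, seed=42)
        assert np.array_equal(d1, d2)


class TestTimeGrid:
    def test_half_open_grid_has_500_points(self):
        t = default_time_grid(100.0, 0.2)
        assert len(t) == 500
        assert t[0] == 0.0 and np.isclose(t[-1], 99.8)
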