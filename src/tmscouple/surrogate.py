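"""Generalized polynomial chaos surrogate of the dendritic current.

The mean dendritic current I(t, xi) over six uniformly distributed inputs
xi = (theta, d|E|, |E|, f_NMDA, f_GABAa, f_ex) is expanded in a tensor basis
of orthonormal Legendre polynomials,

    I(t, xi) = sum_i c_i(t) Psi_i(xi),

with an anisotropic truncation: univariate order up to 20 (6 for the field-
gradient parameter), at most 3 interacting parameters per basis function,
and interacting orders summing to at most 8.  A separate expansion is fitted
for each time point by the Moore-Penrose pseudoinverse of the regression
matrix; Sobol indices and global derivative-based sensitivities follow
directly from the coefficients.

:class:`PolynomialChaosSurrogate` is a scikit-learn compatible estimator
(``fit(X, Y)`` / ``predict(X)``) so it composes with sklearn model
selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from pathlib import Path

import h5py
import numpy as np
from numpy.polynomial import legendre as npleg
from sklearn.base import BaseEstimator, RegressorMixin

from . import defaults

__all__ = [
    "ParamBounds",
    "BasisSpec",
    "SensitivityResult",
    "PolynomialChaosSurrogate",
    "enumerate_basis",
    "sample_params",
    "nrmsd",
    "default_time_grid",
]


def default_time_grid(t_stop: float = 100.0, dt: float = 0.2) -> np.ndarray:
    """Surrogate time grid over [0, t_stop) ms; half-open so 100 ms at 0.2 ms
    gives exactly 500 points."""
    n = int(round(t_stop / dt))
    return np.arange(n) * dt


@dataclass(frozen=True)
class ParamBounds:
    """Uniform bounds per parameter, in the natural (physical) scale."""

    names: tuple[str, ...] = defaults.PARAM_NAMES
    lower: tuple[float, ...] = tuple(b[0] for b in defaults.PARAM_BOUNDS.values())
    upper: tuple[float, ...] = tuple(b[1] for b in defaults.PARAM_BOUNDS.values())

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.lower) == len(self.upper)):
            raise ValueError("bounds arrays must have equal length")
        for lo, hi in zip(self.lower, self.upper):
            if not lo < hi:
                raise ValueError("require lower < upper per parameter")

    def __len__(self) -> int:
        return len(self.names)

    def to_unit(self, x: np.ndarray) -> np.ndarray:
        """Affine map from the physical box to [-1, 1]^d."""
        lo = np.asarray(self.lower)
        hi = np.asarray(self.upper)
        return 2.0 * (np.asarray(x, float) - lo) / (hi - lo) - 1.0

    def sample(self, n: int, seed) -> np.ndarray:
        rng = np.random.default_rng(seed)
        lo = np.asarray(self.lower)
        hi = np.asarray(self.upper)
        return rng.uniform(lo, hi, size=(n, len(self)))


def sample_params(bounds: ParamBounds, n: int, seed) -> np.ndarray:
    """Uniform i.i.d. parameter draws within bounds; seed-reproducible."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return bounds.sample(n, seed)


@dataclass(frozen=True)
class BasisSpec:
    """Anisotropic truncation of the tensor Legendre basis."""

    max_univariate_order: int = 20
    gradient_param_order: int = 6
    max_interaction_order: int = 3
    max_interaction_sum: int = 8
    gradient_param_index: int = defaults.GRADIENT_PARAM_INDEX

    def __post_init__(self) -> None:
        if min(
            self.max_univariate_order,
            self.gradient_param_order,
            self.max_interaction_order,
            self.max_interaction_sum,
        ) < 1:
            raise ValueError("all truncation orders must be >= 1")
        if self.gradient_param_order > self.max_univariate_order:
            raise ValueError("gradient cap must not exceed the univariate cap")

    def cap(self, param_index: int) -> int:
        if param_index == self.gradient_param_index:
            return self.gradient_param_order
        return self.max_univariate_order


def enumerate_basis(spec: BasisSpec, n_params: int = 6) -> np.ndarray:
    """All exponent multi-indices admitted by the truncation scheme.

    Rules: at most ``max_interaction_order`` nonzero entries; a lone nonzero
    entry may reach its per-parameter cap; with two or more nonzero entries
    the nonzero orders sum to at most ``max_interaction_sum`` (each entry
    still bounded by its own cap).  The constant (all-zero) index is always
    included.  With the shipped defaults over six parameters this yields
    1642 basis functions.
    """
    caps = [spec.cap(j) for j in range(n_params)]
    indices: list[tuple[int, ...]] = [(0,) * n_params]
    # single-parameter polynomials up to the per-parameter cap
    for j in range(n_params):
        for order in range(1, caps[j] + 1):
            alpha = [0] * n_params
            alpha[j] = order
            indices.append(tuple(alpha))
    # interactions of 2 .. max_interaction_order parameters
    for k in range(2, spec.max_interaction_order + 1):
        for subset in combinations(range(n_params), k):
            local_caps = [
                min(caps[j], spec.max_interaction_sum - (k - 1)) for j in subset
            ]
            for orders in product(*(range(1, c + 1) for c in local_caps)):
                if sum(orders) <= spec.max_interaction_sum:
                    alpha = [0] * n_params
                    for j, o in zip(subset, orders):
                        alpha[j] = o
                    indices.append(tuple(alpha))
    return np.array(sorted(set(indices)), dtype=int)


def _legendre_design(x_unit: np.ndarray, multi_indices: np.ndarray) -> np.ndarray:
    """Design matrix of orthonormal Legendre products, samples x basis."""
    n, d = x_unit.shape
    max_order = int(multi_indices.max())
    # vander[j][:, k] = sqrt(2k+1) P_k(x_j): orthonormal under uniform on [-1,1]
    scale = np.sqrt(2.0 * np.arange(max_order + 1) + 1.0)
    vander = [npleg.legvander(x_unit[:, j], max_order) * scale for j in range(d)]
    psi = np.ones((n, len(multi_indices)))
    for j in range(d):
        orders = multi_indices[:, j]
        nz = orders > 0
        if nz.any():
            psi[:, nz] *= vander[j][:, orders[nz]]
    return psi


def _legendre_derivative_design(
    x_unit: np.ndarray, multi_indices: np.ndarray, j_deriv: int
) -> np.ndarray:
    """d Psi / d x_j (unit scale) for every basis function."""
    n, d = x_unit.shape
    max_order = int(multi_indices.max())
    scale = np.sqrt(2.0 * np.arange(max_order + 1) + 1.0)
    vander = [npleg.legvander(x_unit[:, j], max_order) * scale for j in range(d)]
    # derivative Vandermonde for parameter j_deriv
    dv = np.zeros((n, max_order + 1))
    for k in range(1, max_order + 1):
        coef = np.zeros(k + 1)
        coef[k] = 1.0
        dv[:, k] = npleg.legval(x_unit[:, j_deriv], npleg.legder(coef)) * scale[k]
    psi = np.ones((n, len(multi_indices)))
    for j in range(d):
        orders = multi_indices[:, j]
        mat = dv if j == j_deriv else vander[j]
        psi[:, orders > 0] *= mat[:, orders[orders > 0]]
        if j == j_deriv:
            psi[:, orders == 0] *= 0.0
    return psi


@dataclass
class SensitivityResult:
    """Variance-based and derivative-based sensitivities over time.

    ``sobol`` maps a parameter support set (tuple of parameter indices) to
    its normalized Sobol index per time point; indices at a time point sum
    to 1 where the variance is nonzero (masked elsewhere, NaN).
    """

    sobol: dict[tuple[int, ...], np.ndarray]
    sobol_time_averaged: dict[tuple[int, ...], float]
    derivative: np.ndarray | None = None       # (n_params, n_t)
    t_grid: np.ndarray | None = None
    param_names: tuple[str, ...] = ()

    def top_supports(self, n: int = 10) -> list[tuple[tuple[int, ...], float]]:
        ranked = sorted(
            self.sobol_time_averaged.items(), key=lambda kv: kv[1], reverse=True
        )
        return ranked[:n]


class PolynomialChaosSurrogate(BaseEstimator, RegressorMixin):
    """Time-resolved gPC surrogate fitted by Moore-Penrose pseudoinverse.

    Parameters
    ----------
    bounds
        Uniform parameter bounds (defaults to the shipped six-parameter box).
    basis_spec
        Anisotropic truncation (defaults to the 1642-term scheme).
    rcond
        Relative singular-value cutoff of the pseudoinverse.

    Attributes (after ``fit``)
    --------------------------
    multi_indices_ : (N_c, d) exponent tuples of the basis.
    coefficients_ : (N_c, N_t) coefficient matrix [C].
    rank_ : effective rank of the design matrix.
    """

    def __init__(
        self,
        bounds: ParamBounds | None = None,
        basis_spec: BasisSpec | None = None,
        rcond: float = 1e-12,
        t_grid: np.ndarray | None = None,
    ) -> None:
        self.bounds = bounds
        self.basis_spec = basis_spec
        self.rcond = rcond
        self.t_grid = t_grid

    def _resolved(self) -> tuple[ParamBounds, BasisSpec]:
        return (
            self.bounds if self.bounds is not None else ParamBounds(),
            self.basis_spec if self.basis_spec is not None else BasisSpec(),
        )

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "PolynomialChaosSurrogate":
        """Fit coefficients for all time points at once: [C] = pinv(Psi) [I]."""
        bounds, spec = self._resolved()
        X = np.asarray(X, float)
        Y = np.asarray(Y, float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if X.ndim != 2 or X.shape[1] != len(bounds):
            raise ValueError(f"X must be (n, {len(bounds)})")
        if not np.all(np.isfinite(Y)):
            raise ValueError("responses must be finite")
        self.multi_indices_ = enumerate_basis(spec, n_params=len(bounds))
        psi = _legendre_design(bounds.to_unit(X), self.multi_indices_)
        if X.shape[0] < psi.shape[1]:
            import warnings

            warnings.warn(
                f"underdetermined gPC fit: {X.shape[0]} samples for "
                f"{psi.shape[1]} coefficients (minimum-norm solution)",
                stacklevel=2,
            )
        coef, _, rank, _ = np.linalg.lstsq(psi, Y, rcond=self.rcond)
        self.coefficients_ = coef
        self.rank_ = int(rank)
        self.n_features_in_ = X.shape[1]
        self.t_grid_ = (
            np.asarray(self.t_grid, float)
            if self.t_grid is not None
            else np.arange(Y.shape[1], dtype=float)
        )
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Evaluate the expansion at parameter points X (linear in [C])."""
        self._check_fitted()
        bounds, _ = self._resolved()
        X = np.atleast_2d(np.asarray(X, float))
        x_unit = bounds.to_unit(X)
        if np.any(np.abs(x_unit) > 1.0 + 1e-9):
            import warnings

            warnings.warn("evaluating gPC outside its bounds (extrapolation)",
                          stacklevel=2)
        psi = _legendre_design(np.clip(x_unit, -1.5, 1.5), self.multi_indices_)
        return psi @ self.coefficients_

    def _check_fitted(self) -> None:
        if not hasattr(self, "coefficients_"):
            raise RuntimeError("surrogate is not fitted")

    # -- sensitivity analysis ------------------------------------------------

    def sobol_indices(self) -> SensitivityResult:
        """Normalized Sobol indices per support set from the coefficients.

        With an orthonormal basis the variance at a time point is
        sum_{alpha != 0} c_alpha^2 and the index of support u is the share
        contributed by basis functions whose nonzero pattern equals u.
        """
        self._check_fitted()
        bounds, _ = self._resolved()
        c2 = self.coefficients_ ** 2
        nonconst = self.multi_indices_.any(axis=1)
        variance = c2[nonconst].sum(axis=0)
        mask = variance > 0
        supports: dict[tuple[int, ...], np.ndarray] = {}
        for row, alpha in enumerate(self.multi_indices_):
            if not nonconst[row]:
                continue
            u = tuple(np.nonzero(alpha)[0])
            supports.setdefault(u, np.zeros(c2.shape[1]))
            supports[u] += c2[row]
        sobol = {}
        for u, num in supports.items():
            s = np.full(c2.shape[1], np.nan)
            s[mask] = num[mask] / variance[mask]
            sobol[u] = s
        averaged = {u: float(np.nanmean(s)) for u, s in sobol.items()}
        return SensitivityResult(
            sobol=sobol,
            sobol_time_averaged=averaged,
            t_grid=self.t_grid_,
            param_names=bounds.names,
        )

    def derivative_sensitivity(
        self, n_mc: int = 10_000, seed: int | None = 0
    ) -> np.ndarray:
        """Global derivative-based sensitivities E[dI/dxi_j] (n_params, n_t).

        Monte-Carlo average over uniform xi of the analytic basis
        derivatives, mapped to the physical scale by the chain-rule factor
        2 / (upper - lower).  Signed averages are reported.
        """
        self._check_fitted()
        if n_mc < 1:
            raise ValueError("n_mc must be >= 1")
        bounds, _ = self._resolved()
        rng = np.random.default_rng(seed)
        x_unit = rng.uniform(-1.0, 1.0, size=(n_mc, len(bounds)))
        out = np.empty((len(bounds), self.coefficients_.shape[1]))
        span = np.asarray(bounds.upper) - np.asarray(bounds.lower)
        for j in range(len(bounds)):
            dpsi = _legendre_derivative_design(x_unit, self.multi_indices_, j)
            out[j] = (2.0 / span[j]) * (dpsi @ self.coefficients_).mean(axis=0)
        return out

    # -- persistence ---------------------------------------------------------

    def to_hdf5(self, path: str | Path, **attrs) -> None:
        self._check_fitted()
        bounds, spec = self._resolved()
        with h5py.File(path, "w") as f:
            f.create_dataset("multi_indices", data=self.multi_indices_)
            f.create_dataset("coefficients", data=self.coefficients_)
            f.create_dataset("t_grid", data=self.t_grid_)
            f.create_dataset("lower", data=np.asarray(bounds.lower))
            f.create_dataset("upper", data=np.asarray(bounds.upper))
            f.attrs["param_names"] = list(bounds.names)
            f.attrs["rank"] = self.rank_
            for k, v in spec.__dict__.items():
                f.attrs[f"basis_{k}"] = v
            for k, v in attrs.items():
                f.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "PolynomialChaosSurrogate":
        with h5py.File(path, "r") as f:
            lower = tuple(f["lower"][()])
            upper = tuple(f["upper"][()])
            names = tuple(str(n) for n in f.attrs["param_names"])
            spec = BasisSpec(
                max_univariate_order=int(f.attrs["basis_max_univariate_order"]),
                gradient_param_order=int(f.attrs["basis_gradient_param_order"]),
                max_interaction_order=int(f.attrs["basis_max_interaction_order"]),
                max_interaction_sum=int(f.attrs["basis_max_interaction_sum"]),
                gradient_param_index=int(f.attrs["basis_gradient_param_index"]),
            )
            model = cls(bounds=ParamBounds(names, lower, upper), basis_spec=spec)
            model.multi_indices_ = f["multi_indices"][()]
            model.coefficients_ = f["coefficients"][()]
            model.t_grid_ = f["t_grid"][()]
            model.rank_ = int(f.attrs["rank"])
            model.n_features_in_ = len(lower)
        return model


def nrmsd(reference: np.ndarray, approximation: np.ndarray) -> float:
    """Average normalized RMS deviation over time points, in percent.

    Per time point: RMS error over the test set divided by the reference
    range (max - min over the set); averaged over time points.  Time points
    with zero reference range are excluded.
    """
    ref = np.atleast_2d(np.asarray(reference, float))
    app = np.atleast_2d(np.asarray(approximation, float))
    if ref.shape != app.shape:
        raise ValueError("shape mismatch between reference and approximation")
    rms = np.sqrt(np.mean((ref - app) ** 2, axis=0))
    rng = ref.max(axis=0) - ref.min(axis=0)
    valid = rng > 0
    if not valid.any():
        raise ValueError("reference range is zero at every time point")
    return float(np.mean(rms[valid] / rng[valid]) * 100.0)
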