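"""Axonal delay kernels: spike arrivals at axon terminals, binned in depth
and time, averaged over azimuth / morphologies / subtypes, and lifted to
population kernels by cross-correlation with a cell-density profile.

The central object is the :class:`DelayKernel`, a 2D spike density (per ms
per um) over either soma-relative depth z' (single-cell kernels, r(z', t))
or cortical depth z (population kernels, k(z, t)).  The population kernel is

    k(z, t) = sum_s d(z_s) r(z - z_s, t) * count_ratio

i.e. the superposition of the average cell kernel over the normalized soma-
depth density d(z), evaluated as a 'same'-mode correlation along the depth
axis only (time is untouched), cropped centered with start (N_r - 1) // 2 so
the z-index-to-depth mapping is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy.interpolate import PchipInterpolator

from . import defaults
from .cable import CableState, _first_crossing
from .morphology import CompartmentModel

__all__ = [
    "SpikeArrival",
    "DelayKernel",
    "CellDensity",
    "SubtypeWeighting",
    "detect_arrivals",
    "build_histogram",
    "average_kernels",
    "resample_pchip",
    "population_kernel",
    "collapse_depth",
    "truncated_gaussian_density",
]

SOMA_RELATIVE = "soma_relative_zprime"
CORTICAL = "cortical_z"


@dataclass(frozen=True)
class SpikeArrival:
    """First upward 0 mV crossing at an axon terminal after stimulus onset."""

    terminal_id: int
    z_prime: float  # um
    t: float        # ms


@dataclass
class DelayKernel:
    """2D spike density over (depth, time) with a depth-domain tag.

    ``values[i, j]`` is the density (ms^-1 um^-1) in depth bin i, time bin j;
    bins are left-closed, right-open, with the final bin right-closed (the
    numpy histogram convention).
    """

    values: np.ndarray   # (n_z, n_t)
    z_edges: np.ndarray  # (n_z + 1,)
    t_edges: np.ndarray  # (n_t + 1,)
    domain: str = SOMA_RELATIVE
    n_cells_averaged: int = 1
    scaling_ratio: float = 1.0
    overflow: int = 0    # arrivals that fell outside the grid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.z_edges = np.asarray(self.z_edges, dtype=float)
        self.t_edges = np.asarray(self.t_edges, dtype=float)
        if self.values.shape != (len(self.z_edges) - 1, len(self.t_edges) - 1):
            raise ValueError("values shape must match bin edges")
        if self.domain not in (SOMA_RELATIVE, CORTICAL):
            raise ValueError(f"unknown domain tag {self.domain!r}")

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    @property
    def t_centers(self) -> np.ndarray:
        return 0.5 * (self.t_edges[:-1] + self.t_edges[1:])

    @property
    def dz(self) -> float:
        return float(np.mean(np.diff(self.z_edges)))

    @property
    def dt(self) -> float:
        return float(np.mean(np.diff(self.t_edges)))

    def total_count(self) -> float:
        """Total spike mass: integral of density over depth and time."""
        dz = np.diff(self.z_edges)[:, None]
        dt = np.diff(self.t_edges)[None, :]
        return float((self.values * dz * dt).sum())

    def to_hdf5(self, path: str | Path, **attrs) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            f.create_dataset("z_edges", data=self.z_edges)
            f.create_dataset("t_edges", data=self.t_edges)
            f.attrs["domain"] = self.domain
            f.attrs["units"] = "ms^-1 um^-1"
            f.attrs["n_cells_averaged"] = self.n_cells_averaged
            f.attrs["scaling_ratio"] = self.scaling_ratio
            f.attrs["overflow"] = self.overflow
            for k, v in attrs.items():
                f.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "DelayKernel":
        with h5py.File(path, "r") as f:
            return cls(
                values=f["values"][()],
                z_edges=f["z_edges"][()],
                t_edges=f["t_edges"][()],
                domain=str(f.attrs["domain"]),
                n_cells_averaged=int(f.attrs.get("n_cells_averaged", 1)),
                scaling_ratio=float(f.attrs.get("scaling_ratio", 1.0)),
                overflow=int(f.attrs.get("overflow", 0)),
            )


@dataclass
class CellDensity:
    """Soma-depth density d(z) over cortical depth bins (z in [-2700, 0] um)."""

    d: np.ndarray
    z_edges: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.z_edges = np.asarray(self.z_edges, dtype=float)
        if np.any(self.d < 0):
            raise ValueError("density must be nonnegative")
        if len(self.d) != len(self.z_edges) - 1:
            raise ValueError("density length must match bin edges")

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    def normalize(self) -> "CellDensity":
        """Return a copy with sum(d_i) = 1 (the Eq-preserving convention)."""
        total = self.d.sum()
        if total <= 0:
            raise ValueError("cannot normalize a zero density")
        return CellDensity(self.d / total, self.z_edges.copy(), normalized=True)

    def at(self, z: np.ndarray) -> np.ndarray:
        """Linear interpolation of the density at depths z (um)."""
        return np.interp(np.asarray(z, float), self.z_centers, self.d,
                         left=0.0, right=0.0)

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, np.column_stack([self.z_centers, self.d]),
                   delimiter=",", header="z_center_um,density", comments="")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CellDensity":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        centers, d = data[:, 0], data[:, 1]
        step = float(np.mean(np.diff(centers)))
        edges = np.concatenate([centers - step / 2, [centers[-1] + step / 2]])
        return cls(d=d, z_edges=edges)


@dataclass
class SubtypeWeighting:
    """Relative subtype frequencies; normalized to sum 1 before averaging."""

    weights: dict[str, float] = field(
        default_factory=lambda: dict(defaults.BASKET_SUBTYPE_WEIGHTS)
    )

    def normalized(self) -> dict[str, float]:
        total = sum(self.weights.values())
        if total <= 0:
            raise ValueError("weights must not all be zero")
        return {k: v / total for k, v in self.weights.items()}


def detect_arrivals(state: CableState, model: CompartmentModel) -> list[SpikeArrival]:
    """First upward 0 mV crossing per axon terminal, linearly interpolated.

    Terminals whose potential never crosses are omitted; repeated crossings
    (bursting) are ignored after the first.
    """
    arrivals = []
    for tid in model.terminal_ids:
        t = _first_crossing(state.v[tid], state.t_grid)
        if t is not None:
            arrivals.append(
                SpikeArrival(terminal_id=int(tid), z_prime=float(model.z_prime[tid]), t=t)
            )
    return arrivals


def build_histogram(
    arrivals: list[SpikeArrival],
    z_edges: np.ndarray,
    t_edges: np.ndarray,
    domain: str = SOMA_RELATIVE,
) -> DelayKernel:
    """Bin arrivals into a spike-density kernel (count / (dz * dt)).

    Arrivals falling outside the grid are tallied in ``overflow`` rather than
    silently dropped, so histogram mass + overflow always equals the arrival
    count exactly.
    """
    z_edges = np.asarray(z_edges, float)
    t_edges = np.asarray(t_edges, float)
    if np.any(np.diff(z_edges) <= 0) or np.any(np.diff(t_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    z = np.array([a.z_prime for a in arrivals])
    t = np.array([a.t for a in arrivals])
    if len(arrivals):
        counts, _, _ = np.histogram2d(z, t, bins=[z_edges, t_edges])
    else:
        counts = np.zeros((len(z_edges) - 1, len(t_edges) - 1))
    overflow = len(arrivals) - int(round(counts.sum()))
    dz = np.diff(z_edges)[:, None]
    dt = np.diff(t_edges)[None, :]
    return DelayKernel(
        values=counts / (dz * dt),
        z_edges=z_edges,
        t_edges=t_edges,
        domain=domain,
        overflow=overflow,
    )


def average_kernels(kernels: list[DelayKernel], weights=None) -> DelayKernel:
    """Weighted mean of kernels on identical grids (weights normalized)."""
    if not kernels:
        raise ValueError("no kernels to average")
    ref = kernels[0]
    for k in kernels[1:]:
        if (
            k.values.shape != ref.values.shape
            or not np.allclose(k.z_edges, ref.z_edges)
            or not np.allclose(k.t_edges, ref.t_edges)
            or k.domain != ref.domain
        ):
            raise ValueError("kernel grids/domains do not match")
    if weights is None:
        weights = np.ones(len(kernels))
    weights = np.asarray(weights, float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be nonnegative and not all zero")
    weights = weights / weights.sum()
    values = sum(w * k.values for w, k in zip(weights, kernels))
    return DelayKernel(
        values=values,
        z_edges=ref.z_edges.copy(),
        t_edges=ref.t_edges.copy(),
        domain=ref.domain,
        n_cells_averaged=sum(k.n_cells_averaged for k in kernels),
        overflow=sum(k.overflow for k in kernels),
    )


def resample_pchip(kernel: DelayKernel, dz_out: float, dt_out: float) -> DelayKernel:
    """Monotone cubic (pchip) resampling on bin centers, z then t.

    Pchip preserves monotonicity between data points so a nonnegative kernel
    never acquires negative interpolated values.  Intended for refinement
    (output steps <= input steps), e.g. dz = 1 um / dt = 0.005 ms for display
    and dz = 50 um for the dendritic stage.
    """
    if dz_out > kernel.dz + 1e-12 or dt_out > kernel.dt + 1e-12:
        raise ValueError("output steps must be <= input steps")
    zc, tc = kernel.z_centers, kernel.t_centers
    n_z = max(1, int(round((zc[-1] - zc[0]) / dz_out)) + 1)
    n_t = max(1, int(round((tc[-1] - tc[0]) / dt_out)) + 1)
    z_new = zc[0] + np.arange(n_z) * dz_out
    t_new = tc[0] + np.arange(n_t) * dt_out

    if len(zc) > 1:
        vals = PchipInterpolator(zc, kernel.values, axis=0)(z_new)
    else:
        vals = np.repeat(kernel.values, n_z, axis=0)
    if len(tc) > 1:
        vals = PchipInterpolator(tc, vals, axis=1)(t_new)
    else:
        vals = np.repeat(vals, n_t, axis=1)

    z_edges = np.concatenate([z_new - dz_out / 2, [z_new[-1] + dz_out / 2]])
    t_edges = np.concatenate([t_new - dt_out / 2, [t_new[-1] + dt_out / 2]])
    return DelayKernel(
        values=np.maximum(vals, 0.0),
        z_edges=z_edges,
        t_edges=t_edges,
        domain=kernel.domain,
        n_cells_averaged=kernel.n_cells_averaged,
        scaling_ratio=kernel.scaling_ratio,
        overflow=kernel.overflow,
    )


def population_kernel(
    cell_kernel: DelayKernel,
    density: CellDensity,
    count_ratio: float = 1.0,
) -> DelayKernel:
    """Lift a soma-relative cell kernel to a cortical population kernel.

    Per time column, the output is the superposition of the cell kernel over
    soma depths weighted by the normalized density, cropped 'same'-mode
    (centered, crop start (N_r - 1) // 2 in the full array) to the density's
    length, then scaled by the presynaptic/postsynaptic count ratio.  Spike
    mass is preserved by the operation whenever the crop loses no mass; for
    z' grids symmetric about 0 the cell soma maps exactly onto its density
    depth.
    """
    if cell_kernel.domain != SOMA_RELATIVE:
        raise ValueError("cell kernel must be in the soma-relative domain")
    if not density.normalized:
        raise ValueError("density must be normalized (sum d_i = 1)")
    if abs(cell_kernel.dz - float(np.mean(np.diff(density.z_edges)))) > 1e-9:
        raise ValueError("kernel and density depth steps must match")
    d = density.d
    n_r = cell_kernel.values.shape[0]
    start = (n_r - 1) // 2
    out = np.empty((len(d), cell_kernel.values.shape[1]))
    for j in range(cell_kernel.values.shape[1]):
        full = np.convolve(d, cell_kernel.values[:, j])
        out[:, j] = full[start : start + len(d)]
    return DelayKernel(
        values=out * count_ratio,
        z_edges=density.z_edges.copy(),
        t_edges=cell_kernel.t_edges.copy(),
        domain=CORTICAL,
        n_cells_averaged=cell_kernel.n_cells_averaged,
        scaling_ratio=count_ratio,
        overflow=cell_kernel.overflow,
    )


def collapse_depth(kernel: DelayKernel) -> np.ndarray:
    """Arithmetic mean over depth bins per time column (1D time profile)."""
    if kernel.domain != CORTICAL:
        raise ValueError("collapse_depth expects a cortical-domain kernel")
    return kernel.values.mean(axis=0)


def truncated_gaussian_density(
    mean: float,
    sd: float,
    band: tuple[float, float],
    z_edges: np.ndarray | None = None,
) -> CellDensity:
    """Unimodal layer-bounded density: Gaussian truncated to a depth band.

    Default grid covers the cortical column [-2700, 0] um in 100 um bins.
    """
    if z_edges is None:
        z_edges = np.arange(-defaults.COLUMN_DEPTH_UM, 0.0 + 1, defaults.AXONAL_DZ_UM)
    z_edges = np.asarray(z_edges, float)
    centers = 0.5 * (z_edges[:-1] + z_edges[1:])
    lo, hi = band
    d = np.exp(-0.5 * ((centers - mean) / sd) ** 2)
    d[(centers < lo) | (centers > hi)] = 0.0
    return CellDensity(d=d, z_edges=z_edges).normalize()
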