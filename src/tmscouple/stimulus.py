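"""Parameterized TMS electric fields and extracellular quasipotentials.

The induced field is described in spherical coordinates relative to the
somatodendritic axis: polar angle theta (deg), azimuth phi (deg), magnitude
|E| (V/m) and a relative gradient d|E| (%/mm) of the magnitude along the
soma-relative depth axis z'.  The field couples to cable models through the
extracellular quasipotential psi = -int E . dl accumulated along the neurite
tree; only spatial differences of psi are physical, so psi is defined up to
a global constant.  In time, the spatial profile is scaled by a normalized
coil-current waveform w(t) with peak |w| = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .morphology import CompartmentModel

logger = logging.getLogger(__name__)

__all__ = [
    "FieldParams",
    "Waveform",
    "QuasiPotentialProfile",
    "make_biphasic_waveform",
    "field_vector",
    "quasipotential",
    "stimulus_timeseries",
]


@dataclass(frozen=True)
class FieldParams:
    """TMS field parameter set (theta deg, phi deg, |E| V/m, d|E| %/mm)."""

    theta: float = 0.0
    phi: float = 0.0
    intensity: float = 200.0
    rel_gradient: float = 0.0
    waveform_id: str = "biphasic"

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 180.0:
            raise ValueError("theta must be within [0, 180] deg")
        if self.intensity < 0.0:
            raise ValueError("intensity must be >= 0")


@dataclass
class Waveform:
    """Normalized coil-current time factor w(t) with max |w| = 1, w(0) = 0."""

    samples: np.ndarray
    dt: float           # ms
    family: str = "biphasic"
    frequency: float = 2.5   # kHz
    damping_tau: float = 0.4  # ms

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration(self) -> float:
        return self.dt * (len(self.samples) - 1)

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dt

    def __call__(self, t: np.ndarray) -> np.ndarray:
        """Evaluate w at arbitrary times (zero outside the sampled support)."""
        t = np.asarray(t, dtype=float)
        return np.interp(t, self.t, self.samples, left=0.0, right=0.0)

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.t, self.samples]),
                   delimiter=",", header="t_ms,w", comments="")

    @classmethod
    def from_csv(cls, path) -> "Waveform":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        dt = float(np.mean(np.diff(data[:, 0])))
        return cls(samples=data[:, 1], dt=dt, family="imported")


def make_biphasic_waveform(
    frequency: float = 2.5,
    damping_tau: float = 0.4,
    dt: float = 0.005,
    duration: float = 1.2,
) -> Waveform:
    """Damped-sinusoid biphasic pulse w(t) ~ exp(-t/tau) sin(2 pi f t).

    Peak-normalized so max |w| = 1 and w(0) = 0.  A duration shorter than one
    period is allowed but logged, since the pulse is then truncated
    mid-cycle.
    """
    if frequency <= 0 or dt <= 0:
        raise ValueError("frequency and dt must be > 0")
    if duration < 1.0 / frequency:
        logger.warning(
            "waveform duration %.3f ms shorter than one period %.3f ms",
            duration, 1.0 / frequency,
        )
    t = np.arange(0.0, duration + dt / 2, dt)
    w = np.exp(-t / damping_tau) * np.sin(2.0 * np.pi * frequency * t)
    peak = np.max(np.abs(w))
    if peak > 0:
        w = w / peak
    return Waveform(samples=w, dt=dt, frequency=frequency, damping_tau=damping_tau)


def _azimuthal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal pair (e1, e2) perpendicular to the axis."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - np.dot(ref, axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def field_direction(fp: FieldParams, axis: np.ndarray) -> np.ndarray:
    """Unit field direction from (theta, phi) in the soma-relative frame."""
    e1, e2 = _azimuthal_frame(axis)
    th = np.deg2rad(fp.theta)
    ph = np.deg2rad(fp.phi)
    return (
        np.sin(th) * (np.cos(ph) * e1 + np.sin(ph) * e2) + np.cos(th) * axis
    )


def field_magnitude(fp: FieldParams, z_prime_um: np.ndarray) -> np.ndarray:
    """|E| at soma-relative depth z' (um): linear gradient anchored at z'=0.

    Magnitudes that would go negative for extreme depths are clamped at zero
    (and the clamping is logged).
    """
    z_mm = np.asarray(z_prime_um, dtype=float) / 1000.0
    mag = fp.intensity * (1.0 + fp.rel_gradient / 100.0 * z_mm)
    if np.any(mag < 0):
        logger.warning("field magnitude clamped at 0 for %d locations",
                       int(np.sum(mag < 0)))
        mag = np.maximum(mag, 0.0)
    return mag


def field_vector(fp: FieldParams, z_prime_um: float, axis=None) -> np.ndarray:
    """Field vector (V/m) at soma-relative depth z'.

    The direction is global (set by theta, phi); only the magnitude varies
    with depth through the relative gradient.
    """
    if axis is None:
        axis = np.array([0.0, 0.0, 1.0])
    axis = np.asarray(axis, float)
    u = field_direction(fp, axis)
    return u * field_magnitude(fp, np.atleast_1d(z_prime_um))[..., None].squeeze()


@dataclass
class QuasiPotentialProfile:
    """Per-compartment extracellular potential (mV) at unit time factor."""

    psi_spatial: np.ndarray
    field_params: FieldParams = field(default=FieldParams())


def quasipotential(model: CompartmentModel, fp: FieldParams) -> QuasiPotentialProfile:
    """Line-integrate -E.dl along the tree to each compartment midpoint.

    The integral is accumulated from the root (psi = 0 at the soma center)
    with the midpoint rule per tree step, so psi is continuous across branch
    points.  Units: (V/m) * um * 1e-3 = mV.
    """
    if len(model) == 0:
        raise ValueError("empty compartment model")
    axis = model.morphology.somatodendritic_axis
    center = model.morphology.soma_center
    u = field_direction(fp, axis)
    mids = model.midpoints
    psi = np.zeros(len(model))

    order = _topological_order(model.parent)
    for i in order:
        p = model.parent[i]
        start = center if p < 0 else mids[p]
        end = mids[i]
        mid = 0.5 * (start + end)
        z_mid = float((mid - center) @ axis)
        e_vec = u * field_magnitude(fp, np.array([z_mid]))[0]
        base = 0.0 if p < 0 else psi[p]
        psi[i] = base - float(e_vec @ (end - start)) * 1e-3
    return QuasiPotentialProfile(psi_spatial=psi, field_params=fp)


def _topological_order(parent: np.ndarray) -> np.ndarray:
    """Indices ordered so parents precede children."""
    n = len(parent)
    order = np.empty(n, dtype=int)
    seen = np.zeros(n, dtype=bool)
    stack = [i for i in range(n) if parent[i] < 0]
    k = 0
    children: list[list[int]] = [[] for _ in range(n)]
    for i, p in enumerate(parent):
        if p >= 0:
            children[p].append(i)
    while stack:
        i = stack.pop()
        if seen[i]:
            continue
        seen[i] = True
        order[k] = i
        k += 1
        stack.extend(children[i])
    if k != n:
        raise ValueError("compartment tree is not connected")
    return order


def stimulus_timeseries(
    profile: QuasiPotentialProfile, waveform: Waveform, t_grid: np.ndarray
) -> np.ndarray:
    """Per-compartment v_ext(t) = psi_spatial * w(t); zero after the pulse.

    Returns an array of shape (n_compartments, n_t) in mV.
    """
    w = waveform(np.asarray(t_grid, dtype=float))
    return np.outer(profile.psi_spatial, w)
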