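"""Synapto-dendritic delay stage: population delay kernels -> synaptic
conductances on postsynaptic dendrites -> somatic input current.

Excitatory (AMPA/NMDA) and inhibitory (GABAa/GABAb) conductances on each
dendritic compartment are built by convolving double-exponential receptor
kernels with the partial depth-integral of the upstream population delay
kernels over the compartment's 50 um cortical-depth bin, weighted by the
compartment's share of membrane area in the bin.  The postsynaptic cell is
quenched (gNa = 0 on soma and axon) so only synaptically driven dendritic
current reaches the soma; the output measure is the axial current entering
the soma, with the zero-input background current subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import defaults
from .axonal import CORTICAL, DelayKernel, CellDensity
from .cable import (
    CableConfig,
    CableState,
    ChannelSet,
    SynapticInput,
    quench_sodium,
    settle_steady_state,
    simulate,
)
from .morphology import CompartmentModel, SectionKind

__all__ = [
    "SynapseParams",
    "SynapseFractions",
    "BinAssignment",
    "DendriticCurrent",
    "double_exp_kernel",
    "nmda_gate",
    "partial_integral",
    "assign_bins",
    "compartment_conductances",
    "soma_axial_current",
    "run_single",
    "average_current",
    "sample_depths",
    "KernelDrive",
]

RECEPTORS = ("AMPA", "NMDA", "GABAa", "GABAb")
EXCITATORY = ("AMPA", "NMDA")


@dataclass(frozen=True)
class ReceptorParams:
    tau_rise: float   # ms
    tau_fall: float   # ms
    e_reversal: float  # mV
    g_peak: float     # uS

    def __post_init__(self) -> None:
        if not self.tau_fall > self.tau_rise > 0:
            raise ValueError("require tau_fall > tau_rise > 0")
        if self.g_peak <= 0:
            raise ValueError("g_peak must be > 0")


def _default_receptors() -> dict[str, ReceptorParams]:
    return {
        name: ReceptorParams(*defaults.SYNAPSE_TABLE[name]) for name in RECEPTORS
    }


@dataclass
class SynapseParams:
    """Double-exponential constants per receptor (shipped defaults)."""

    receptors: dict[str, ReceptorParams] = field(default_factory=_default_receptors)

    def __getitem__(self, name: str) -> ReceptorParams:
        return self.receptors[name]


@dataclass(frozen=True)
class SynapseFractions:
    """Synapse-balance free parameters and magnesium concentration.

    f_nmda: NMDA fraction among excitatory synapses; f_gabaa: GABAa fraction
    among inhibitory synapses; f_ex: excitatory fraction of all synapses.
    """

    f_nmda: float = 0.5
    f_gabaa: float = 0.95
    f_ex: float = 0.5
    mg: float = defaults.MG_MMOL

    def __post_init__(self) -> None:
        for name in ("f_nmda", "f_gabaa", "f_ex"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be within [0, 1]")
        if self.mg < 0:
            raise ValueError("Mg must be >= 0")


def double_exp_kernel(
    receptor: str, params: SynapseParams, t_grid: np.ndarray
) -> np.ndarray:
    """Normalized double-exponential conductance kernel K_SYN(t) in uS.

    K = (g_peak / N) (exp(-t/tau_fall) - exp(-t/tau_rise)) with N chosen so
    the peak at tmax = tau_r tau_f / (tau_f - tau_r) * ln(tau_f / tau_r)
    equals g_peak exactly.
    """
    p = params[receptor]
    t = np.asarray(t_grid, dtype=float)
    tr, tf = p.tau_rise, p.tau_fall
    tmax = tr * tf / (tf - tr) * np.log(tf / tr)
    norm = np.exp(-tmax / tf) - np.exp(-tmax / tr)
    return p.g_peak / norm * (np.exp(-t / tf) - np.exp(-t / tr))


def nmda_gate(v: np.ndarray, mg: float = defaults.MG_MMOL) -> np.ndarray:
    """Magnesium block of NMDA conductance: 1 / (1 + 0.28 Mg exp(-0.062 v))."""
    return 1.0 / (1.0 + 0.28 * mg * np.exp(-0.062 * np.asarray(v, dtype=float)))


def partial_integral(
    kernel: DelayKernel, z_center: float, dz: float = defaults.DENDRITIC_DZ_UM
) -> np.ndarray:
    """Depth integral of the kernel density over [z - dz/2, z + dz/2] per t.

    The kernel is a binned (piecewise-constant) density, so the integral is
    evaluated exactly as the overlap-weighted sum of bin densities; this
    conserves spike counts when bins tile the column.  A bin outside the
    kernel's depth range yields zeros.  Units: ms^-1 (spike rate into the
    depth slab).
    """
    lo, hi = z_center - dz / 2.0, z_center + dz / 2.0
    edges = kernel.z_edges
    overlap = np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo)
    overlap = np.maximum(overlap, 0.0)
    return overlap @ kernel.values


@dataclass
class BinAssignment:
    """Dendritic compartments mapped to cortical-depth bins.

    ``weight[i] = A_i / A_bin`` for dendritic compartment i (zero for soma
    and axon); within each nonempty bin the weights of its members sum to 1.
    """

    bin_index: np.ndarray    # per compartment; -1 for non-dendritic/outside
    weight: np.ndarray       # per compartment, A / A_bin
    bin_centers: np.ndarray
    bin_area: np.ndarray     # total dendritic membrane area per bin (um^2)


def assign_bins(
    model: CompartmentModel,
    soma_depth: float,
    dz: float = defaults.DENDRITIC_DZ_UM,
    column_depth: float = defaults.COLUMN_DEPTH_UM,
) -> BinAssignment:
    """Place the cell soma at cortical depth ``soma_depth`` (um, negative)
    and bin its dendritic compartments by midpoint depth z = soma_depth + z'.
    """
    n_bins = int(round(column_depth / dz))
    edges = -column_depth + dz * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    z = soma_depth + model.z_prime
    dend = model.dendrite_mask()
    idx = np.floor((z - edges[0]) / dz).astype(int)
    inside = (idx >= 0) & (idx < n_bins) & dend
    bin_index = np.where(inside, idx, -1)
    areas = model.membrane_areas
    bin_area = np.zeros(n_bins)
    np.add.at(bin_area, bin_index[inside], areas[inside])
    weight = np.zeros(len(model))
    nz = inside & (bin_area[np.clip(bin_index, 0, n_bins - 1)] > 0)
    weight[nz] = areas[nz] / bin_area[bin_index[nz]]
    return BinAssignment(bin_index=bin_index, weight=weight,
                         bin_centers=centers, bin_area=bin_area)


def compartment_conductances(
    k_ex: np.ndarray,
    k_inh: np.ndarray,
    fractions: SynapseFractions,
    assignment_weight: float,
    params: SynapseParams,
    t_grid: np.ndarray,
) -> dict[str, np.ndarray]:
    """Per-receptor conductance g(t) in uS for one compartment.

    ``k_ex``/``k_inh`` are the partial-integral spike rates K_z(t) (ms^-1)
    of the compartment's bin on ``t_grid``; the discrete convolution with
    the receptor kernel carries the dt factor so the result is in uS:

        g_AMPA  = (A/A_bin) (1 - f_NMDA) f_ex      K_AMPA  (*) K_z,ex
        g_NMDA  = (A/A_bin) f_NMDA f_ex            K_NMDA  (*) K_z,ex
        g_GABAa = (A/A_bin) f_GABAa (1 - f_ex)     K_GABAa (*) K_z,inh
        g_GABAb = (A/A_bin) (1 - f_GABAa)(1 - f_ex) K_GABAb (*) K_z,inh
    """
    k_ex = np.asarray(k_ex, float)
    k_inh = np.asarray(k_inh, float)
    if np.any(k_ex < 0) or np.any(k_inh < 0):
        raise ValueError("delay-kernel inputs must be nonnegative")
    dt = float(t_grid[1] - t_grid[0])
    n_t = len(t_grid)
    pre = {
        "AMPA": (1.0 - fractions.f_nmda) * fractions.f_ex,
        "NMDA": fractions.f_nmda * fractions.f_ex,
        "GABAa": fractions.f_gabaa * (1.0 - fractions.f_ex),
        "GABAb": (1.0 - fractions.f_gabaa) * (1.0 - fractions.f_ex),
    }
    out = {}
    for rec in RECEPTORS:
        drive = k_ex if rec in EXCITATORY else k_inh
        kern = double_exp_kernel(rec, params, t_grid)
        conv = np.convolve(kern, drive)[:n_t] * dt
        out[rec] = assignment_weight * pre[rec] * conv
    return out


class KernelDrive(SynapticInput):
    """Synaptic input built from population kernels for a placed cell.

    Conductance time courses are computed once per depth bin and scaled to
    compartments by their area share; the NMDA component is multiplied by
    the instantaneous magnesium-block gate each step.
    """

    def __init__(
        self,
        model: CompartmentModel,
        kernel_ex: DelayKernel,
        kernel_inh: DelayKernel,
        fractions: SynapseFractions,
        soma_depth: float,
        t_grid: np.ndarray,
        params: SynapseParams | None = None,
        dz: float = defaults.DENDRITIC_DZ_UM,
    ) -> None:
        for k in (kernel_ex, kernel_inh):
            if k.domain != CORTICAL:
                raise ValueError("dendritic stage requires cortical-domain kernels")
        params = params or SynapseParams()
        self.fractions = fractions
        self.assignment = assign_bins(model, soma_depth, dz=dz)
        n = len(model)
        n_t = len(t_grid)
        self.g = {rec: np.zeros((n, n_t)) for rec in RECEPTORS}
        self.e_rev = {rec: params[rec].e_reversal for rec in RECEPTORS}
        self.received_count = 0.0
        self.unreceived_count = 0.0
        dt = float(t_grid[1] - t_grid[0])

        used_bins = {}
        for i in range(n):
            b = self.assignment.bin_index[i]
            if b < 0 or self.assignment.weight[i] == 0:
                continue
            if b not in used_bins:
                zc = self.assignment.bin_centers[b]
                k_ex = _rate_on_grid(kernel_ex, zc, dz, t_grid)
                k_inh = _rate_on_grid(kernel_inh, zc, dz, t_grid)
                used_bins[b] = compartment_conductances(
                    k_ex, k_inh, fractions, 1.0, params, t_grid
                )
                self.received_count += (k_ex.sum() + k_inh.sum()) * dt
            for rec in RECEPTORS:
                self.g[rec][i] = self.assignment.weight[i] * used_bins[b][rec]

        total = kernel_ex.total_count() + kernel_inh.total_count()
        self.unreceived_count = max(total - self.received_count, 0.0)

    def conductances(self, step: int, v: np.ndarray):
        g_a = self.g["AMPA"][:, step]
        g_n = self.g["NMDA"][:, step] * nmda_gate(v, self.fractions.mg)
        g_ga = self.g["GABAa"][:, step]
        g_gb = self.g["GABAb"][:, step]
        g = g_a + g_n + g_ga + g_gb
        ge = (
            g_a * self.e_rev["AMPA"]
            + g_n * self.e_rev["NMDA"]
            + g_ga * self.e_rev["GABAa"]
            + g_gb * self.e_rev["GABAb"]
        )
        return g, ge


def _rate_on_grid(
    kernel: DelayKernel, z_center: float, dz: float, t_grid: np.ndarray
) -> np.ndarray:
    """Partial-integral rate K_z interpolated onto the simulation grid."""
    rate = partial_integral(kernel, z_center, dz)
    return np.interp(t_grid, kernel.t_centers, rate, left=0.0, right=0.0)


@dataclass
class DendriticCurrent:
    """Baseline-subtracted somatic input current (nA); the model output."""

    i: np.ndarray
    t_grid: np.ndarray
    baseline_subtracted: bool = True
    provenance: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, np.column_stack([self.t_grid, self.i]),
                   delimiter=",", header="t_ms,I_nA", comments="")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DendriticCurrent":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(i=data[:, 1], t_grid=data[:, 0])


#: nA per (um^2 / (Ohm cm)) * (mV / um); see soma_axial_current.
_AXIAL_UNIT = 1e2


def soma_axial_current(state: CableState, model: CompartmentModel) -> np.ndarray:
    """Axial current entering the soma from adjacent dendrites (nA, inward +).

        I = - sum_i (A_i / R_i) (V_soma - V_i) / L_i

    with A_i the dendritic cross-section (um^2), R_i the axial resistivity
    (Ohm cm) and L_i the center-to-center path length (um).  Unit factor:
    um^2 / (Ohm cm) * mV / um = 1e2 nA.
    """
    soma_ids = [
        i for i, c in enumerate(model.compartments) if c.kind is SectionKind.SOMA
    ]
    if not soma_ids:
        raise ValueError("model has no soma compartment")
    s = soma_ids[0]
    soma = model.compartments[s]
    neighbors = [
        i
        for i in model.children[s]
        if model.compartments[i].kind.is_dendrite
    ]
    if model.parent[s] >= 0 and model.compartments[model.parent[s]].kind.is_dendrite:
        neighbors.append(int(model.parent[s]))
    v = state.v if state.v.ndim == 2 else state.v[:, None]
    i_total = np.zeros(v.shape[1])
    for i in neighbors:
        c = model.compartments[i]
        length = 0.5 * soma.length + 0.5 * c.length
        coeff = _AXIAL_UNIT * c.cross_section_area / c.axial_resistivity / length
        i_total += coeff * (v[i] - v[s])
    return i_total if state.v.ndim == 2 else i_total


def run_single(
    model: CompartmentModel,
    kernel_ex: DelayKernel,
    kernel_inh: DelayKernel,
    fractions: SynapseFractions,
    soma_depth: float,
    config: CableConfig,
    channels: ChannelSet | None = None,
    params: SynapseParams | None = None,
    settled: CableState | None = None,
    baseline: np.ndarray | None = None,
) -> DendriticCurrent:
    """One synapto-dendritic delay simulation at a given soma depth.

    The cell is quenched (gNa = 0 on soma and axon), placed at ``soma_depth``
    in the cortical column, driven by conductances derived from the two
    population kernels, and the baseline-subtracted somatic axial current is
    returned.  ``settled``/``baseline`` allow reusing the steady state and
    the zero-input background current across depth samples of the same
    morphology.
    """
    channels = quench_sodium(channels or ChannelSet())
    t_grid = config.t_grid
    drive = KernelDrive(
        model, kernel_ex, kernel_inh, fractions, soma_depth, t_grid, params=params
    )
    if settled is None:
        settled = settle_steady_state(model, channels, config)
    state = simulate(model, channels, config, synaptic=drive, initial=settled)
    i_raw = soma_axial_current(state, model)
    if baseline is None:
        zero_state = simulate(model, channels, config, initial=settled)
        baseline = soma_axial_current(zero_state, model)
    return DendriticCurrent(
        i=i_raw - baseline,
        t_grid=t_grid,
        baseline_subtracted=True,
        provenance={
            "soma_depth_um": soma_depth,
            "fractions": {
                "f_nmda": fractions.f_nmda,
                "f_gabaa": fractions.f_gabaa,
                "f_ex": fractions.f_ex,
            },
            "baseline_nA": float(np.mean(baseline)),
            "unreceived_input": drive.unreceived_count,
        },
    )


def sample_depths(density: CellDensity, n_k: int = defaults.N_DEPTH_SAMPLES):
    """Equidistant soma-depth samples spanning the density's support."""
    support = density.z_centers[density.d > 0]
    return np.linspace(support.min(), support.max(), n_k)


def average_current(
    runs: list[tuple[int, float, DendriticCurrent]],
    density: CellDensity,
) -> DendriticCurrent:
    """Density-weighted depth average, then mean over morphologies.

        <I> = (1/N_morph) sum_j [ sum_k w_k I_jk(t) / sum_m w_m ]

    ``runs`` holds (morphology_id, soma_depth, current); weights w_k are the
    cell density at each sampled depth, normalized per morphology so the
    result is invariant to the density's overall scale.
    """
    if not runs:
        raise ValueError("no runs to average")
    t_grid = runs[0][2].t_grid
    for _, _, cur in runs:
        if len(cur.t_grid) != len(t_grid) or not np.allclose(cur.t_grid, t_grid):
            raise ValueError("all runs must share the same time grid")
    by_morph: dict[int, list[tuple[float, DendriticCurrent]]] = {}
    for morph_id, depth, cur in runs:
        by_morph.setdefault(morph_id, []).append((depth, cur))
    acc = np.zeros(len(t_grid))
    for entries in by_morph.values():
        w = np.array([density.at(np.array([d]))[0] for d, _ in entries])
        if w.sum() <= 0:
            raise ValueError("density weights sum to zero for a morphology")
        w = w / w.sum()
        acc += sum(wk * cur.i for wk, (_, cur) in zip(w, entries))
    return DendriticCurrent(
        i=acc / len(by_morph),
        t_grid=t_grid,
        provenance={"n_morph": len(by_morph), "n_runs": len(runs)},
    )
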