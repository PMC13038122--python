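"""Membrane dynamics of compartment models under extracellular stimulation.

Solves the branched cable equation

    C dv/dt + I_ion(v) + I_syn(v, t) = sum_j g_ij [(v_j + e_j) - (v_i + e_i)]

on the compartment tree, where e is the extracellular quasipotential so that
only spatial differences of e couple into the membrane.  Channels are
classic Hodgkin-Huxley Na/K/leak with Q10 temperature scaling of the gating
rates; per-kind (soma/axon/dendrite) densities are configurable and sodium
can be quenched selectively to suppress postsynaptic spiking.

Integration is implicit: backward Euler with giant steps for steady-state
settling, Crank-Nicolson for transients, with an unconditionally stable
sparse direct solve over the tree at every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .morphology import CompartmentModel, SectionKind

__all__ = [
    "ChannelParams",
    "ChannelSet",
    "CableConfig",
    "CableState",
    "NumericalFailure",
    "settle_steady_state",
    "simulate",
    "quench_sodium",
    "conduction_velocity_check",
]


class NumericalFailure(RuntimeError):
    """Integration failure; carries the first failing time and a snapshot."""

    def __init__(self, message: str, t: float, v_snapshot: np.ndarray):
        super().__init__(f"{message} at t={t:.4f} ms")
        self.t = t
        self.v_snapshot = v_snapshot


@dataclass(frozen=True)
class ChannelParams:
    """Maximal conductance densities (S/cm^2) and reversal potentials (mV)."""

    gna: float = 0.12
    gk: float = 0.036
    gleak: float = 0.0003
    ena: float = 50.0
    ek: float = -77.0
    eleak: float = -70.0


@dataclass(frozen=True)
class ChannelSet:
    """Per-kind channel densities with temperature scaling of kinetics."""

    soma: ChannelParams = field(default_factory=ChannelParams)
    axon: ChannelParams = field(default_factory=lambda: ChannelParams(gna=0.3, gk=0.06))
    dendrite: ChannelParams = field(
        default_factory=lambda: ChannelParams(gna=0.012, gk=0.01)
    )
    q10: float = 3.0
    base_temperature: float = 6.3  # deg C at which the rate constants hold
    cm: float = 1.0  # uF/cm^2

    def for_kind(self, kind: SectionKind) -> ChannelParams:
        if kind is SectionKind.SOMA:
            return self.soma
        if kind is SectionKind.AXON:
            return self.axon
        return self.dendrite

    def rate_scale(self, temperature: float) -> float:
        return self.q10 ** ((temperature - self.base_temperature) / 10.0)


def quench_sodium(
    channels: ChannelSet, kinds: set[SectionKind] | None = None
) -> ChannelSet:
    """Return a copy with gNa = 0 on the listed kinds (default soma + axon)."""
    if kinds is None:
        kinds = {SectionKind.SOMA, SectionKind.AXON}
    out = channels
    if SectionKind.SOMA in kinds:
        out = replace(out, soma=replace(out.soma, gna=0.0))
    if SectionKind.AXON in kinds:
        out = replace(out, axon=replace(out.axon, gna=0.0))
    if kinds & {SectionKind.BASAL_DENDRITE, SectionKind.APICAL_DENDRITE}:
        out = replace(out, dendrite=replace(out.dendrite, gna=0.0))
    return out


@dataclass
class CableConfig:
    dt: float = 0.025           # ms
    duration: float = 3.0       # ms
    temperature: float = 37.0   # deg C
    v_init: float = -70.0       # mV
    settle_step: float = 1e9    # ms
    settle_count: int = 100
    v_band: tuple[float, float] = (-600.0, 300.0)  # numerical sanity band, mV

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    @property
    def t_grid(self) -> np.ndarray:
        n = int(round(self.duration / self.dt)) + 1
        return np.arange(n) * self.dt


@dataclass
class CableState:
    """Membrane potential (mV) per compartment per sample, plus gating."""

    v: np.ndarray          # (n_comp, n_t) or (n_comp,) for a settled state
    t_grid: np.ndarray
    gates: dict[str, np.ndarray]  # final m, h, n per compartment

    @property
    def v_final(self) -> np.ndarray:
        return self.v if self.v.ndim == 1 else self.v[:, -1]


# ---------------------------------------------------------------------------
# Hodgkin-Huxley gating kinetics (rates in 1/ms, v in mV)
# ---------------------------------------------------------------------------

def _exprel(x: np.ndarray) -> np.ndarray:
    """x / (exp(x) - 1), stable near 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-7
    safe = np.where(small, 1.0, x)
    out = np.where(small, 1.0 - x / 2.0, safe / np.expm1(safe))
    return out


def hh_rates(v: np.ndarray) -> dict[str, np.ndarray]:
    v = np.asarray(v, dtype=float)
    am = 1.0 * _exprel(-(v + 40.0) / 10.0)
    bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    an = 0.1 * _exprel(-(v + 55.0) / 10.0)
    bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return {"am": am, "bm": bm, "ah": ah, "bh": bh, "an": an, "bn": bn}


def gate_steady_state(v: np.ndarray) -> dict[str, np.ndarray]:
    r = hh_rates(v)
    return {
        "m": r["am"] / (r["am"] + r["bm"]),
        "h": r["ah"] / (r["ah"] + r["bh"]),
        "n": r["an"] / (r["an"] + r["bn"]),
    }


class SynapticInput:
    """Interface for time-varying synaptic conductance input.

    ``conductances(step, v)`` returns (g_tot, g_times_e) per compartment in
    uS and uS*mV for time sample ``step``; the instantaneous membrane
    potential allows voltage-dependent gating (NMDA magnesium block).
    """

    def conductances(self, step: int, v: np.ndarray):  # pragma: no cover
        raise NotImplementedError


class _Assembly:
    """Precomputed per-model arrays shared by settle and simulate."""

    def __init__(self, model: CompartmentModel, channels: ChannelSet):
        self.model = model
        self.channels = channels
        areas = model.membrane_areas                      # um^2
        self.c_nf = channels.cm * areas * 1e-5            # nF
        # per-compartment maximal conductances in uS
        self.gna = np.empty(len(model))
        self.gk = np.empty(len(model))
        self.gl = np.empty(len(model))
        self.ena = np.empty(len(model))
        self.ek = np.empty(len(model))
        self.el = np.empty(len(model))
        for i, c in enumerate(model.compartments):
            p = channels.for_kind(c.kind)
            scale = c.membrane_area * 1e-2                # S/cm^2*um^2 -> uS
            self.gna[i] = p.gna * scale
            self.gk[i] = p.gk * scale
            self.gl[i] = p.gleak * scale
            self.ena[i] = p.ena
            self.ek[i] = p.ek
            self.el[i] = p.eleak
        child, par, g = model.axial_conductances()
        n = len(model)
        rows = np.concatenate([child, par, child, par])
        cols = np.concatenate([par, child, child, par])
        vals = np.concatenate([-g, -g, g, g])
        self.laplacian = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    def membrane_conductances(self, gates: dict[str, np.ndarray]):
        g_na = self.gna * gates["m"] ** 3 * gates["h"]
        g_k = self.gk * gates["n"] ** 4
        g = g_na + g_k + self.gl
        ge = g_na * self.ena + g_k * self.ek + self.gl * self.el
        return g, ge


def settle_steady_state(
    model: CompartmentModel, channels: ChannelSet, config: CableConfig
) -> CableState:
    """Relax to steady state with implicit giant steps (no stimulus attached).

    Gating variables are pinned to their voltage-clamped steady-state curves
    at each iterate; convergence requires max |dv/dt| < 1e-9 mV/ms.
    """
    asm = _Assembly(model, channels)
    n = len(model)
    v = np.full(n, config.v_init, dtype=float)
    inv_dt = 1.0 / config.settle_step
    for _ in range(config.settle_count):
        gates = gate_steady_state(v)
        g, ge = asm.membrane_conductances(gates)
        mat = asm.laplacian + sp.diags(asm.c_nf * inv_dt + g)
        rhs = asm.c_nf * inv_dt * v + ge
        v = spla.spsolve(mat.tocsc(), rhs)
    gates = gate_steady_state(v)
    g, ge = asm.membrane_conductances(gates)
    dvdt = (ge - g * v - asm.laplacian @ v) / asm.c_nf
    resid = float(np.max(np.abs(dvdt)))
    if resid >= 1e-9:
        raise NumericalFailure(
            f"steady-state settling did not converge (residual {resid:.3e} mV/ms)",
            t=0.0,
            v_snapshot=v,
        )
    return CableState(v=v, t_grid=np.array([0.0]), gates=gates)


def simulate(
    model: CompartmentModel,
    channels: ChannelSet,
    config: CableConfig,
    v_ext: np.ndarray | None = None,
    synaptic: SynapticInput | None = None,
    i_inj: np.ndarray | None = None,
    initial: CableState | None = None,
) -> CableState:
    """Crank-Nicolson integration from a settled initial state.

    ``v_ext`` is the per-compartment extracellular potential (n_comp, n_t) in
    mV; ``i_inj`` an optional injected current (n_comp, n_t) in nA.  Gating
    advances by exponential (Rush-Larsen) updates with Q10-scaled rates; the
    axial tree solve is a sparse direct factorization each step.
    """
    asm = _Assembly(model, channels)
    t_grid = config.t_grid
    n, n_t = len(model), len(t_grid)
    dt = config.dt
    if initial is None:
        initial = settle_steady_state(model, channels, config)
    v = initial.v_final.astype(float).copy()
    gates = {k: a.copy() for k, a in initial.gates.items()}
    phi = asm.channels.rate_scale(config.temperature)

    if v_ext is None:
        v_ext = np.zeros((n, n_t))
    if v_ext.shape != (n, n_t):
        raise ValueError(f"v_ext must have shape {(n, n_t)}")
    if i_inj is not None and i_inj.shape != (n, n_t):
        raise ValueError(f"i_inj must have shape {(n, n_t)}")

    out = np.empty((n, n_t))
    out[:, 0] = v
    half_lap = (0.5 * asm.laplacian).tocsr()
    c_over_dt = asm.c_nf / dt
    lo, hi = config.v_band

    for k in range(n_t - 1):
        # gating: exponential update over dt at the current potential
        r = hh_rates(v)
        for gate, (a_key, b_key) in (
            ("m", ("am", "bm")),
            ("h", ("ah", "bh")),
            ("n", ("an", "bn")),
        ):
            a, b = phi * r[a_key], phi * r[b_key]
            tau = 1.0 / (a + b)
            inf = a * tau
            gates[gate] = inf + (gates[gate] - inf) * np.exp(-dt / tau)

        g_mem, ge_mem = asm.membrane_conductances(gates)
        if synaptic is not None:
            g0, ge0 = synaptic.conductances(k, v)
            g1, ge1 = synaptic.conductances(k + 1, v)
            g_syn, ge_syn = 0.5 * (g0 + g1), 0.5 * (ge0 + ge1)
        else:
            g_syn = ge_syn = 0.0
        g_tot = g_mem + g_syn
        b_tot = ge_mem + ge_syn

        rhs = (
            (c_over_dt - 0.5 * g_tot) * v
            - half_lap @ v
            - half_lap @ (v_ext[:, k] + v_ext[:, k + 1])
            + b_tot
        )
        if i_inj is not None:
            rhs = rhs + 0.5 * (i_inj[:, k] + i_inj[:, k + 1])
        mat = half_lap + sp.diags(c_over_dt + 0.5 * g_tot)
        v = spla.spsolve(mat.tocsc(), rhs)
        if not np.all(np.isfinite(v)):
            raise NumericalFailure("non-finite membrane potential", t_grid[k + 1], v)
        if np.any(v < lo) or np.any(v > hi):
            raise NumericalFailure(
                f"membrane potential outside sanity band [{lo}, {hi}] mV",
                t_grid[k + 1],
                v,
            )
        out[:, k + 1] = v

    return CableState(v=out, t_grid=t_grid, gates=gates)


class _ConductanceClamp(SynapticInput):
    """Fixed excitatory conductance pulse on chosen compartments (test probe)."""

    def __init__(self, n_comp, comp_ids, g_us, n_on, e_rev=0.0):
        self.g = np.zeros(n_comp)
        self.g[list(comp_ids)] = g_us
        self.n_on = n_on
        self.e_rev = e_rev

    def conductances(self, step, v):
        if step < self.n_on:
            return self.g, self.g * self.e_rev
        z = np.zeros_like(self.g)
        return z, z


def conduction_velocity_check(
    model: CompartmentModel,
    channels: ChannelSet,
    config: CableConfig | None = None,
    stim_g_us: float = 0.05,
) -> float:
    """Propagation speed (um/ms) along a straight unbranched axon.

    A brief conductance clamp at the proximal axon end launches a spike;
    velocity is measured from 0 mV upward-crossing times at probes placed at
    1/4 and 3/4 of the axon path length.  Returns 0 if nothing propagates.
    """
    if config is None:
        config = CableConfig(dt=0.0125, duration=6.0)
    axon = [i for i, c in enumerate(model.compartments) if c.kind is SectionKind.AXON]
    if len(axon) < 4:
        raise ValueError("need a straight axon with >= 4 compartments")
    n_on = max(2, int(round(0.5 / config.dt)))
    drive = _ConductanceClamp(len(model), [axon[0]], stim_g_us, n_on)
    state = simulate(model, channels, config, synaptic=drive)
    i1, i2 = axon[len(axon) // 4], axon[3 * len(axon) // 4]
    t1 = _first_crossing(state.v[i1], state.t_grid)
    t2 = _first_crossing(state.v[i2], state.t_grid)
    if t1 is None or t2 is None or t2 <= t1:
        return 0.0
    dist = sum(model.compartments[j].length for j in axon[axon.index(i1): axon.index(i2)])
    return float(dist / (t2 - t1))


def _first_crossing(trace: np.ndarray, t_grid: np.ndarray, level: float = 0.0):
    below = trace[:-1] < level
    above = trace[1:] >= level
    idx = np.nonzero(below & above)[0]
    if len(idx) == 0:
        return None
    k = idx[0]
    frac = (level - trace[k]) / (trace[k + 1] - trace[k])
    return float(t_grid[k] + frac * (t_grid[k + 1] - t_grid[k]))
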