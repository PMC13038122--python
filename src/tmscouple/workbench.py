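"""Pipeline orchestration: configuration, manifests, fixtures, and the
end-to-end axonal -> dendritic -> surrogate workflow.

Every stage emits a :class:`RunManifest` (JSON) recording the configuration
hash, seeds, per-stage timings and all warnings (histogram overflow,
unreceived synaptic input), so runs are reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import defaults
from .analytic import AnalyticDendriticCurrent
from .axonal import (
    DelayKernel,
    CellDensity,
    average_kernels,
    build_histogram,
    detect_arrivals,
    population_kernel,
    resample_pchip,
    truncated_gaussian_density,
)
from .cable import CableConfig, ChannelSet, settle_steady_state, simulate
from .dendritic import (
    DendriticCurrent,
    SynapseFractions,
    average_current,
    run_single,
    sample_depths,
)
from .morphology import (
    CompartmentModel,
    Morphology,
    SyntheticMorphSpec,
    compartmentalize,
    generate_synthetic,
    read_swc,
    write_swc,
)
from .stimulus import (
    FieldParams,
    Waveform,
    make_biphasic_waveform,
    quasipotential,
    stimulus_timeseries,
)
from .surrogate import (
    BasisSpec,
    ParamBounds,
    PolynomialChaosSurrogate,
    nrmsd,
    sample_params,
)

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "cell_delay_kernel",
    "run_axonal_stage",
    "run_dendritic_stage",
    "run_surrogate_stage",
    "run_lookup_stage",
    "make_fixtures",
]


@dataclass
class PipelineConfig:
    """Hierarchical run configuration (YAML-serializable).

    Defaults reproduce the published circuit constants: count ratios
    5.04/0.40, a 2700 um column, 60 azimuthal rotations, 100 um / 0.1 ms
    axonal bins.
    """

    # morphology source
    swc_dir: str | None = None
    n_morphologies: int = 2
    morph_seed: int = 0
    n_axon_terminals: int = 20
    max_compartment_length: float = 20.0
    # field grid
    theta_list: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0, 180.0)
    intensity_list: tuple[float, ...] = (100.0, 200.0, 300.0)
    rel_gradient: float = 0.0
    n_phi: int = defaults.N_PHI_ROTATIONS
    waveform_frequency: float = 2.5
    waveform_damping_tau: float = 0.4
    # populations
    count_ratio_ex: float = defaults.COUNT_RATIO_EXCITATORY
    count_ratio_inh: float = defaults.COUNT_RATIO_INHIBITORY
    density_mean: float = -520.0
    density_sd: float = 150.0
    density_band: tuple[float, float] = defaults.L23_BAND_UM
    # synapses
    f_nmda: float = 0.5
    f_gabaa: float = 0.95
    f_ex: float = 0.5
    # cable configs
    axonal_dt: float = 0.025
    axonal_duration: float = 3.0
    dendritic_dt: float = 0.01
    dendritic_duration: float = 100.0
    n_depth_samples: int = defaults.N_DEPTH_SAMPLES
    # surrogate
    n_train: int = 4000
    n_test: int = 1000
    seed: int = 0
    output_dir: str = "tmscouple_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("theta_list", "intensity_list", "density_band"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record emitted by every pipeline stage."""

    stage: str
    config_hash: str
    seeds: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    tallies: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    outputs: list = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def _load_morphologies(config: PipelineConfig) -> list[Morphology]:
    if config.swc_dir is not None:
        paths = sorted(Path(config.swc_dir).glob("*.swc"))
        if not paths:
            raise FileNotFoundError(f"no SWC files under {config.swc_dir}")
        return [read_swc(p) for p in paths]
    return [
        generate_synthetic(
            SyntheticMorphSpec(
                n_axon_terminals=config.n_axon_terminals,
                rng_seed=config.morph_seed + i,
            )
        )
        for i in range(config.n_morphologies)
    ]


def cell_delay_kernel(
    model: CompartmentModel,
    theta: float,
    intensity: float,
    rel_gradient: float,
    waveform: Waveform,
    cable_config: CableConfig,
    n_phi: int = defaults.N_PHI_ROTATIONS,
    channels: ChannelSet | None = None,
    z_edges: np.ndarray | None = None,
    t_edges: np.ndarray | None = None,
) -> DelayKernel:
    """Azimuth-averaged axonal delay kernel for one cell and field point.

    The azimuthal average rotates the field rather than the cell (the two
    are equivalent for rotation about the somatodendritic axis), which lets
    the settled state be reused across all rotations.
    """
    channels = channels or ChannelSet()
    if z_edges is None:
        z_edges = np.arange(
            defaults.ZPRIME_RANGE_UM[0],
            defaults.ZPRIME_RANGE_UM[1] + 1,
            defaults.AXONAL_DZ_UM,
        )
    if t_edges is None:
        t_edges = np.arange(
            0.0, cable_config.duration + cable_config.dt / 2, defaults.AXONAL_DT_MS
        )
    settled = settle_steady_state(model, channels, cable_config)
    phis = np.arange(n_phi) * (360.0 / n_phi)
    kernels = []
    for phi in phis:
        fp = FieldParams(
            theta=theta, phi=phi, intensity=intensity, rel_gradient=rel_gradient
        )
        profile = quasipotential(model, fp)
        v_ext = stimulus_timeseries(profile, waveform, cable_config.t_grid)
        state = simulate(model, channels, cable_config, v_ext=v_ext, initial=settled)
        arrivals = detect_arrivals(state, model)
        kernels.append(build_histogram(arrivals, z_edges, t_edges))
    return average_kernels(kernels)


def run_axonal_stage(
    config: PipelineConfig, output_dir: str | Path | None = None
) -> tuple[dict, RunManifest]:
    """Average cell kernels and population kernels per (theta, |E|) point.

    Returns ``kernels[(theta, intensity)] = (cell_kernel, population_kernel)``
    and writes them as HDF5 alongside a manifest when an output directory is
    given.
    """
    t_start = time.time()
    out = Path(output_dir or config.output_dir)
    manifest = RunManifest(
        stage="axonal",
        config_hash=config.digest(),
        seeds={"morph_seed": config.morph_seed},
    )
    morphologies = _load_morphologies(config)
    models = [
        compartmentalize(m, config.max_compartment_length) for m in morphologies
    ]
    waveform = make_biphasic_waveform(
        frequency=config.waveform_frequency,
        damping_tau=config.waveform_damping_tau,
        dt=min(config.axonal_dt, 0.005),
        duration=config.axonal_duration,
    )
    cable_config = CableConfig(dt=config.axonal_dt, duration=config.axonal_duration)
    density = truncated_gaussian_density(
        config.density_mean, config.density_sd, config.density_band
    )
    kernels = {}
    n_runs = 0
    for theta in config.theta_list:
        for intensity in config.intensity_list:
            per_cell = [
                cell_delay_kernel(
                    model,
                    theta,
                    intensity,
                    config.rel_gradient,
                    waveform,
                    cable_config,
                    n_phi=config.n_phi,
                )
                for model in models
            ]
            n_runs += len(models) * config.n_phi
            cell_kernel = average_kernels(per_cell)
            pop_kernel = population_kernel(
                cell_kernel, density, config.count_ratio_ex
            )
            kernels[(theta, intensity)] = (cell_kernel, pop_kernel)
            if cell_kernel.overflow:
                manifest.warnings.append(
                    f"theta={theta} |E|={intensity}: {cell_kernel.overflow} "
                    "arrivals outside the histogram grid"
                )
    manifest.tallies["cable_runs"] = n_runs
    manifest.timings_s["axonal"] = round(time.time() - t_start, 3)
    if output_dir is not None or config.output_dir:
        out.mkdir(parents=True, exist_ok=True)
        for (theta, intensity), (cell_k, pop_k) in kernels.items():
            tag = f"theta{theta:g}_E{intensity:g}"
            cell_path = out / f"cell_kernel_{tag}.h5"
            pop_path = out / f"population_kernel_{tag}.h5"
            cell_k.to_hdf5(cell_path, theta=theta, intensity=intensity)
            pop_k.to_hdf5(pop_path, theta=theta, intensity=intensity)
            manifest.outputs += [str(cell_path), str(pop_path)]
        manifest.write(out / "manifest_axonal.json")
    return kernels, manifest


def run_dendritic_stage(
    config: PipelineConfig,
    kernel_ex: DelayKernel,
    kernel_inh: DelayKernel,
    output_dir: str | Path | None = None,
    post_models: list[CompartmentModel] | None = None,
) -> tuple[DendriticCurrent, RunManifest]:
    """Mean dendritic current across soma depths and morphologies."""
    t_start = time.time()
    manifest = RunManifest(stage="dendritic", config_hash=config.digest())
    if kernel_ex.domain != "cortical_z" or kernel_inh.domain != "cortical_z":
        raise ValueError("dendritic stage requires cortical-domain kernels")
    if post_models is None:
        post_models = [
            compartmentalize(
                generate_synthetic(
                    SyntheticMorphSpec(
                        n_axon_terminals=4,
                        n_dendrite_terminals=10,
                        rng_seed=config.morph_seed + 1000 + i,
                    )
                ),
                config.max_compartment_length,
            )
            for i in range(config.n_morphologies)
        ]
    density = truncated_gaussian_density(
        -1600.0, 300.0, (-2100.0, -1100.0)
    )  # postsynaptic (deep-layer) soma depths
    depths = sample_depths(density, config.n_depth_samples)
    fractions = SynapseFractions(
        f_nmda=config.f_nmda, f_gabaa=config.f_gabaa, f_ex=config.f_ex
    )
    cable_config = CableConfig(
        dt=config.dendritic_dt, duration=config.dendritic_duration
    )
    runs = []
    for j, model in enumerate(post_models):
        settled = baseline = None
        for depth in depths:
            cur = run_single(
                model,
                kernel_ex,
                kernel_inh,
                fractions,
                float(depth),
                cable_config,
                settled=settled,
                baseline=baseline,
            )
            runs.append((j, float(depth), cur))
            if cur.provenance.get("unreceived_input", 0) > 0:
                manifest.warnings.append(
                    f"morph {j} depth {depth:.0f}: unreceived input "
                    f"{cur.provenance['unreceived_input']:.3f} spikes"
                )
    mean_current = average_current(runs, density)
    manifest.tallies["single_runs"] = len(runs)
    manifest.timings_s["dendritic"] = round(time.time() - t_start, 3)
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "mean_dendritic_current.csv"
        mean_current.to_csv(path)
        manifest.outputs.append(str(path))
        manifest.write(out / "manifest_dendritic.json")
    return mean_current, manifest


def run_surrogate_stage(
    config: PipelineConfig,
    response_fn=None,
    output_dir: str | Path | None = None,
    basis_spec: BasisSpec | None = None,
) -> tuple[PolynomialChaosSurrogate, float, RunManifest]:
    """Fit the gPC surrogate to training responses and report held-out NRMSD.

    ``response_fn(X) -> (n, N_t)`` defaults to the packaged analytic
    dendritic-current generator; for production use pass a closure over
    precomputed simulation responses.
    """
    t_start = time.time()
    manifest = RunManifest(
        stage="surrogate", config_hash=config.digest(), seeds={"seed": config.seed}
    )
    bounds = ParamBounds()
    if response_fn is None:
        response_fn = AnalyticDendriticCurrent(bounds=bounds)
    x_train = sample_params(bounds, config.n_train, config.seed)
    x_test = sample_params(bounds, config.n_test, config.seed + 1)
    y_train = response_fn(x_train)
    y_test = response_fn(x_test)
    model = PolynomialChaosSurrogate(bounds=bounds, basis_spec=basis_spec)
    model.fit(x_train, y_train)
    err = nrmsd(y_test, model.predict(x_test))
    manifest.tallies.update(
        {
            "n_train": config.n_train,
            "n_test": config.n_test,
            "n_coefficients": len(model.multi_indices_),
            "rank": model.rank_,
            "nrmsd_percent": err,
        }
    )
    if model.rank_ < len(model.multi_indices_):
        manifest.warnings.append(
            f"rank-deficient fit: rank {model.rank_} < {len(model.multi_indices_)}"
        )
    manifest.timings_s["surrogate"] = round(time.time() - t_start, 3)
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        model.to_hdf5(out / "gpc_model.h5", nrmsd_percent=err)
        sens = model.sobol_indices()
        _write_sensitivity_csv(out, sens, model, config)
        manifest.outputs += [str(out / "gpc_model.h5")]
        manifest.write(out / "manifest_surrogate.json")
    return model, err, manifest


def _write_sensitivity_csv(out: Path, sens, model, config: PipelineConfig) -> None:
    names = sens.param_names
    rows = ["support,time_averaged_sobol"]
    for u, val in sorted(sens.sobol_time_averaged.items(), key=lambda kv: -kv[1]):
        label = "*".join(names[j] for j in u)
        rows.append(f"{label},{val:.6g}")
    (out / "sobol_time_averaged.csv").write_text("\n".join(rows) + "\n")
    deriv = model.derivative_sensitivity(n_mc=2000, seed=config.seed)
    header = "t_ms," + ",".join(names)
    body = np.column_stack([model.t_grid_, deriv.T])
    np.savetxt(out / "derivative_sensitivity.csv", body, delimiter=",",
               header=header, comments="")


def run_lookup_stage(
    config: PipelineConfig,
    kernels: dict,
    output_dir: str | Path | None = None,
    post_models: list[CompartmentModel] | None = None,
) -> dict:
    """Fixed-fraction lookup grid of mean dendritic current.

    Evaluates the dendritic stage over the (theta, |E|) grid with the three
    synapse fractions fixed at their bound midpoints.
    """
    mid = {
        name: 0.5 * (lo + hi)
        for name, (lo, hi) in defaults.PARAM_BOUNDS.items()
        if name.startswith("f_")
    }
    fixed = PipelineConfig(
        **{
            **asdict(config),
            "f_nmda": mid["f_nmda"],
            "f_gabaa": mid["f_gabaa"],
            "f_ex": mid["f_ex"],
        }
    )
    table = {}
    for (theta, intensity), (_, pop_kernel) in kernels.items():
        cur, _ = run_dendritic_stage(
            fixed, pop_kernel, pop_kernel, post_models=post_models
        )
        table[(theta, intensity)] = cur
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for (theta, intensity), cur in table.items():
            cur.to_csv(out / f"lookup_theta{theta:g}_E{intensity:g}.csv")
    return table


def make_fixtures(seed: int, output_dir: str | Path) -> dict:
    """Write a synthetic fixture bundle (SWC cells, density CSVs).

    Three presynaptic and two postsynaptic synthetic morphologies, plus
    truncated-Gaussian soma-density profiles for the superficial (L2/3 band,
    -270 to -783 um) and deep populations.  The smooth analytic dendritic-
    current generator is returned alongside for surrogate testing.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, list[str] | str] = {"presynaptic": [], "postsynaptic": []}
    for i in range(3):
        m = generate_synthetic(SyntheticMorphSpec(rng_seed=seed + i))
        p = out / f"presynaptic_{i}.swc"
        write_swc(m, p)
        paths["presynaptic"].append(str(p))
    for i in range(2):
        m = generate_synthetic(
            SyntheticMorphSpec(
                n_axon_terminals=4, n_dendrite_terminals=12, rng_seed=seed + 100 + i
            )
        )
        p = out / f"postsynaptic_{i}.swc"
        write_swc(m, p)
        paths["postsynaptic"].append(str(p))
    d_sup = truncated_gaussian_density(-520.0, 150.0, defaults.L23_BAND_UM)
    d_deep = truncated_gaussian_density(-1600.0, 300.0, (-2100.0, -1100.0))
    d_sup.to_csv(out / "density_superficial.csv")
    d_deep.to_csv(out / "density_deep.csv")
    paths["density_superficial"] = str(out / "density_superficial.csv")
    paths["density_deep"] = str(out / "density_deep.csv")
    paths["generator"] = "tmscouple.analytic.AnalyticDendriticCurrent"
    return paths
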