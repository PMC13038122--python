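"""Synaptic kernels, conductance assembly, somatic axial current (inward
positive), baseline subtraction, and depth/morphology averaging."""

import numpy as np
import pytest

from tmscouple import defaults
from tmscouple.axonal import CORTICAL, CellDensity, DelayKernel
from tmscouple.cable import CableConfig, CableState, ChannelParams, ChannelSet
from tmscouple.dendritic import (
    DendriticCurrent,
    KernelDrive,
    SynapseFractions,
    SynapseParams,
    assign_bins,
    average_current,
    compartment_conductances,
    double_exp_kernel,
    nmda_gate,
    partial_integral,
    run_single,
    sample_depths,
    soma_axial_current,
)
from tmscouple.morphology import (
    Morphology,
    Section,
    SectionKind,
    SyntheticMorphSpec,
    compartmentalize,
    generate_synthetic,
)


def cortical_kernel(values, dz=100.0, dt=0.1):
    values = np.asarray(values, float)
    nz, nt = values.shape
    assert nz == 27
    return DelayKernel(
        values=values,
        z_edges=-2700.0 + dz * np.arange(nz + 1),
        t_edges=dt * np.arange(nt + 1),
        domain=CORTICAL,
    )


@pytest.fixture(scope="module")
def post_model():
    cell = generate_synthetic(
        SyntheticMorphSpec(
            n_axon_terminals=3, n_dendrite_terminals=6, rng_seed=21
        )
    )
    return compartmentalize(cell, 30.0)


@pytest.fixture
def drive_kernels(post_model):
    """Kernels with mass overlapping the cell's dendrites at depth -1600 um."""
    vals = np.zeros((27, 20))
    vals[11:16, 3:6] = 0.02  # z in [-1600, -1100], t in [0.3, 0.6) ms
    return cortical_kernel(vals), cortical_kernel(0.5 * vals)


SOMA_DEPTH = -1600.0


class TestDoubleExpKernel:
    @pytest.mark.parametrize("receptor", ["AMPA", "NMDA", "GABAa", "GABAb"])
    def test_peak_equals_g_peak_at_analytic_tmax(self, receptor):
        params = SynapseParams()
        p = params[receptor]
        tmax = p.tau_rise * p.tau_fall / (p.tau_fall - p.tau_rise) * np.log(
            p.tau_fall / p.tau_rise
        )
        val = double_exp_kernel(receptor, params, np.array([tmax]))
        assert np.isclose(val[0], p.g_peak, rtol=1e-10)

    def test_ampa_tmax_closed_form(self):
        # 0.05 * 5.3 / 5.25 * ln(106) ~ 0.2354 ms
        tmax = 0.05 * 5.3 / (5.3 - 0.05) * np.log(5.3 / 0.05)
        assert np.isclose(tmax, 0.2354, atol=5e-4)
        t = np.arange(0.0, 5.0, 1e-4)
        k = double_exp_kernel("AMPA", SynapseParams(), t)
        assert np.isclose(t[np.argmax(k)], tmax, atol=2e-4)

    def test_zero_at_onset_positive_after(self):
        t = np.arange(0.0, 50.0, 0.01)
        for rec in ("AMPA", "NMDA", "GABAa", "GABAb"):
            k = double_exp_kernel(rec, SynapseParams(), t)
            assert k[0] == 0.0
            assert np.all(k[1:] > 0.0)

    def test_degenerate_time_constants_rejected(self):
        from tmscouple.dendritic import ReceptorParams

        with pytest.raises(ValueError):
            ReceptorParams(tau_rise=5.0, tau_fall=5.0, e_reversal=0.0, g_peak=0.1)


class TestNmdaGate:
    def test_printed_value_at_zero_mv(self):
        assert np.isclose(nmda_gate(0.0, mg=1.0), 1.0 / 1.28)
        assert np.isclose(nmda_gate(0.0, mg=1.0), 0.78125)

    def test_no_magnesium_no_block(self):
        v = np.linspace(-120.0, 60.0, 50)
        assert np.allclose(nmda_gate(v, mg=0.0), 1.0)

    def test_strictly_increasing_in_v(self):
        v = np.linspace(-120.0, 60.0, 200)
        g = nmda_gate(v, mg=1.0)
        assert np.all(np.diff(g) > 0)
        assert np.all((g > 0) & (g <= 1))


class TestPartialIntegral:
    def test_constant_density_rectangle(self):
        k = cortical_kernel(np.full((27, 5), 3.0))
        out = partial_integral(k, z_center=-1300.0, dz=50.0)
        assert np.allclose(out, 3.0 * 50.0)

    def test_delta_column_count_conserved_over_tiling(self):
        vals = np.zeros((27, 5))
        vals[13, 2] = 0.04  # mass = 0.04 * 100 um * 0.1 ms = 0.4 spikes
        k = cortical_kernel(vals)
        dt = k.dt
        centers = np.arange(-2700.0 + 25.0, 0.0, 50.0)
        total = sum(partial_integral(k, zc, 50.0).sum() * dt for zc in centers)
        assert np.isclose(total, k.total_count(), rtol=1e-9)

    def test_bins_tile_to_full_integral(self):
        rng = np.random.default_rng(0)
        k = cortical_kernel(rng.exponential(size=(27, 6)))
        centers = np.arange(-2700.0 + 25.0, 0.0, 50.0)
        tiled = sum(partial_integral(k, zc, 50.0) for zc in centers)
        full = k.values.T @ np.diff(k.z_edges)
        assert np.allclose(tiled, full, rtol=1e-9)

    def test_outside_range_is_zero(self):
        k = cortical_kernel(np.ones((27, 4)))
        assert np.allclose(partial_integral(k, z_center=500.0, dz=50.0), 0.0)


class TestCompartmentConductances:
    t_grid = np.arange(0.0, 30.0, 0.01)

    def test_pure_excitatory_silences_gaba(self):
        fr = SynapseFractions(f_ex=1.0)
        g = compartment_conductances(
            np.ones_like(self.t_grid), np.ones_like(self.t_grid), fr, 1.0,
            SynapseParams(), self.t_grid
        )
        assert np.all(g["GABAa"] == 0.0) and np.all(g["GABAb"] == 0.0)
        assert g["AMPA"].max() > 0

    def test_zero_nmda_fraction(self):
        fr = SynapseFractions(f_nmda=0.0, f_ex=0.5)
        g = compartment_conductances(
            np.ones_like(self.t_grid), np.zeros_like(self.t_grid), fr, 1.0,
            SynapseParams(), self.t_grid
        )
        assert np.all(g["NMDA"] == 0.0)

    def test_unit_impulse_recovers_receptor_kernel(self):
        """One spike as a discrete impulse reproduces K_AMPA exactly."""
        dt = self.t_grid[1] - self.t_grid[0]
        k_ex = np.zeros_like(self.t_grid)
        k_ex[0] = 1.0 / dt  # integrates to one spike
        fr = SynapseFractions(f_nmda=0.0, f_ex=1.0)
        g = compartment_conductances(
            k_ex, np.zeros_like(self.t_grid), fr, 1.0, SynapseParams(), self.t_grid
        )
        expected = double_exp_kernel("AMPA", SynapseParams(), self.t_grid)
        assert np.allclose(g["AMPA"], expected, rtol=1e-12)

    def test_nonnegative_for_valid_inputs(self):
        rng = np.random.default_rng(1)
        fr = SynapseFractions(f_nmda=0.3, f_gabaa=0.92, f_ex=0.4)
        g = compartment_conductances(
            rng.exponential(size=self.t_grid.shape),
            rng.exponential(size=self.t_grid.shape),
            fr, 0.37, SynapseParams(), self.t_grid
        )
        for rec in g:
            assert np.all(g[rec] >= 0.0)

    def test_negative_kernel_rejected(self):
        bad = -np.ones_like(self.t_grid)
        with pytest.raises(ValueError):
            compartment_conductances(
                bad, np.zeros_like(self.t_grid), SynapseFractions(), 1.0,
                SynapseParams(), self.t_grid
            )


class TestBinAssignment:
    def test_weights_sum_to_one_per_nonempty_bin(self, post_model):
        asg = assign_bins(post_model, SOMA_DEPTH)
        for b in np.unique(asg.bin_index[asg.bin_index >= 0]):
            members = asg.bin_index == b
            assert np.isclose(asg.weight[members].sum(), 1.0, atol=1e-9)

    def test_only_dendrites_assigned(self, post_model):
        asg = assign_bins(post_model, SOMA_DEPTH)
        dend = post_model.dendrite_mask()
        assert np.all(asg.bin_index[~dend] == -1)


class TestSomaAxialCurrent:
    def _two_compartment_model(self):
        # soma 10 um long; one dendrite of cross-section 1 um^2, so the
        # center-to-center path is 10 um
        d_dend = 2.0 / np.sqrt(np.pi)  # pi d^2/4 = 1 um^2
        soma = Section(
            id=0, parent_id=None, kind=SectionKind.SOMA,
            points=np.array([[0.0, 0.0, -5.0], [0.0, 0.0, 5.0]]),
            diameters=np.array([10.0, 10.0]),
        )
        dend = Section(
            id=1, parent_id=0, kind=SectionKind.APICAL_DENDRITE,
            points=np.array([[0.0, 0.0, 5.0], [0.0, 0.0, 15.0]]),
            diameters=np.array([d_dend, d_dend]),
        )
        m = Morphology(sections=[soma, dend], soma_center=np.zeros(3))
        return compartmentalize(m, 10.0, axial_resistivity=100.0)

    def _state(self, model, v_by_kind):
        v = np.array(
            [v_by_kind[c.kind.value] for c in model.compartments], dtype=float
        )
        return CableState(v=v[:, None], t_grid=np.array([0.0]), gates={})

    def test_uniform_potential_zero_current(self, post_model):
        state = CableState(
            v=np.full((len(post_model), 3), -65.0),
            t_grid=np.arange(3.0),
            gates={},
        )
        assert np.allclose(soma_axial_current(state, post_model), 0.0)

    def test_dimensional_analysis_oracle(self):
        """A=1 um^2, R=100 Ohm cm, L=10 um, dV=10 mV inward -> +1 nA."""
        model = self._two_compartment_model()
        state = self._state(model, {"soma": -70.0, "apical_dendrite": -60.0})
        i = soma_axial_current(state, model)
        assert np.isclose(i[0], 1.0, rtol=1e-9)

    def test_outward_gradient_gives_negative_current(self):
        model = self._two_compartment_model()
        state = self._state(model, {"soma": -60.0, "apical_dendrite": -70.0})
        assert soma_axial_current(state, model)[0] < 0


class TestRunSingle:
    cfg = CableConfig(dt=0.02, duration=30.0)

    def test_zero_kernels_exactly_zero_output(self, post_model):
        zero = cortical_kernel(np.zeros((27, 20)))
        cur = run_single(
            post_model, zero, zero, SynapseFractions(), SOMA_DEPTH, self.cfg
        )
        assert np.allclose(cur.i, 0.0, atol=1e-9)
        assert cur.baseline_subtracted

    def test_excitatory_only_net_inward_current(self, post_model, drive_kernels):
        k_ex, _ = drive_kernels
        zero = cortical_kernel(np.zeros((27, 20)))
        cur = run_single(
            post_model, k_ex, zero, SynapseFractions(f_ex=1.0), SOMA_DEPTH, self.cfg
        )
        assert np.trapezoid(cur.i, cur.t_grid) > 0.0

    def test_linearity_in_passive_magnesium_free_regime(self, post_model):
        """Small drive, passive dendrites, Mg=0: doubling the kernels doubles
        the output within 1%."""
        passive = ChannelParams(gna=0.0, gk=0.0)
        channels = ChannelSet(dendrite=passive)
        # drive small enough that synaptic shunting stays well below the
        # leak conductance (the linear regime of the conductance synapse)
        vals = np.zeros((27, 20))
        vals[11:16, 3:6] = 1e-5
        k1 = cortical_kernel(vals)
        k2 = cortical_kernel(2 * vals)
        fr = SynapseFractions(f_ex=0.7, mg=0.0)
        cur1 = run_single(post_model, k1, k1, fr, SOMA_DEPTH, self.cfg,
                          channels=channels)
        cur2 = run_single(post_model, k2, k2, fr, SOMA_DEPTH, self.cfg,
                          channels=channels)
        peak = np.max(np.abs(cur2.i))
        assert peak > 0
        assert np.max(np.abs(cur2.i - 2.0 * cur1.i)) / peak < 0.01

    def test_fast_transients_decay_within_100ms_window(self, post_model, drive_kernels):
        """AMPA-driven output decays below 1% of peak inside the 100 ms
        window.  (NMDA and GABAb fall constants, 150 and 260.9 ms, are
        longer than the window itself, so components carried by those
        receptors cannot decay that far by construction.)"""
        k_ex, _ = drive_kernels
        zero = cortical_kernel(np.zeros((27, 20)))
        cfg = CableConfig(dt=0.02, duration=100.0)
        cur = run_single(
            post_model, k_ex, zero,
            SynapseFractions(f_nmda=0.0, f_ex=1.0), SOMA_DEPTH, cfg,
        )
        peak = np.max(np.abs(cur.i))
        assert peak > 0
        tail = np.abs(cur.i[cur.t_grid > 95.0])
        assert np.all(tail < 0.01 * peak)


class TestAverageCurrent:
    def _density(self):
        d = np.zeros(27)
        d[10:18] = [1, 2, 4, 6, 6, 4, 2, 1]
        return CellDensity(d=d, z_edges=-2700.0 + 100.0 * np.arange(28)).normalize()

    def _current(self, amp, n=50):
        t = np.arange(n) * 0.1
        return DendriticCurrent(i=amp * np.exp(-t / 2.0), t_grid=t)

    def test_identical_runs_fixed_point(self):
        density = self._density()
        cur = self._current(1.0)
        avg = average_current(
            [(0, -1650.0, cur), (0, -1450.0, cur), (1, -1650.0, cur)], density
        )
        assert np.allclose(avg.i, cur.i)

    def test_two_depth_weighted_mean(self):
        density = self._density()
        z = density.z_centers
        d1, d2 = z[12], z[14]
        w1, w2 = density.d[12], density.d[14]
        c1, c2 = self._current(1.0), self._current(3.0)
        avg = average_current([(0, d1, c1), (0, d2, c2)], density)
        expected = (w1 * c1.i + w2 * c2.i) / (w1 + w2)
        assert np.allclose(avg.i, expected)

    def test_invariant_to_density_scale(self):
        density = self._density()
        scaled = CellDensity(
            d=10.0 * density.d, z_edges=density.z_edges, normalized=False
        )
        runs = [(0, density.z_centers[12], self._current(1.0)),
                (0, density.z_centers[14], self._current(2.0))]
        a = average_current(runs, density)
        b = average_current(runs, scaled)
        assert np.allclose(a.i, b.i)

    def test_sample_depths_span_support(self):
        density = self._density()
        depths = sample_depths(density, 25)
        assert len(depths) == 25
        support = density.z_centers[density.d > 0]
        assert depths.min() == support.min() and depths.max() == support.max()


class TestKernelDrive:
    def test_unreceived_input_tallied(self, post_model):
        """Kernel mass in bins with no dendritic area is tallied, not lost."""
        vals = np.zeros((27, 10))
        vals[2, 4] = 0.1  # far above the cell: no dendrites at -2450 um... (top)
        k = cortical_kernel(vals)
        drive = KernelDrive(
            post_model, k, cortical_kernel(np.zeros((27, 10))),
            SynapseFractions(), SOMA_DEPTH, np.arange(0.0, 2.0, 0.01),
        )
        assert drive.unreceived_count > 0
        assert np.isclose(
            drive.received_count + drive.unreceived_count,
            k.total_count(), rtol=0.05,
        )
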