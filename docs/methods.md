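# Methods

## Model overview

`tmscouple` couples a parameterized TMS-induced electric field to the mean
input current of a postsynaptic neural population in two stages: a
field-to-spike stage on presynaptic axons (the axonal delay kernel) and a
spike-to-current stage on postsynaptic dendrites (the synapto-dendritic
delay kernel).  Both stages run on quasi-one-dimensional compartmental
cable models; the coupling object between them is a 2D spike-density
kernel over depth and time.

Assumptions inherited from the modeling framework:

- Neurons are laterally interchangeable: only the vertical (cortical-depth)
  coordinate matters for the population average, and connectivity is
  homogeneous in the x–y plane.  Kernels are therefore 1D in space.
- Cells are azimuthally random, so every cell-level kernel is the average
  over 60 azimuthal field orientations (6° steps).
- Stimulation acts on a resting network: no background synaptic activity,
  and the postsynaptic cell is quenched (axosomatic gNa = 0) so that its
  somatic input current, not its spiking, is the output.
- Synapses are not placed discretely; synaptic input to a dendritic
  compartment is proportional to the spike density geometrically
  overlapping its 50 μm depth bin, area-weighted within the bin.

## Cable model

Membrane dynamics follow classic Hodgkin–Huxley Na/K/leak kinetics with
Q10 = 3 temperature scaling (base 6.3 °C, simulations at 37 °C).  Default
densities (S/cm²): soma gNa 0.12 / gK 0.036, axon 0.3 / 0.06, dendrite
0.012 / 0.01, leak 3·10⁻⁴ everywhere with E_leak = −70 mV; Ra = 100 Ω·cm,
Cm = 1 μF/cm².  The axon carries a higher sodium density (initial-segment
convention), which preserves terminal-initiated spiking and propagation at
37 °C.  These are deliberately generic channels: specialized
human-adjusted channel sets would shift absolute activation thresholds,
so thresholds are treated as model-specific and only the mechanism
(terminal polarization → initiation → backpropagation) is asserted in
tests.

The extracellular field enters as a quasipotential ψ = −∫E·dl accumulated
along the tree from the soma (midpoint rule per compartment step;
(V/m)·μm·10⁻³ = mV).  Only differences of ψ are physical; the solver
couples ψ exclusively through the axial term, so a global offset is
exactly inert (tested).  The field direction is global, set by (θ, φ)
against the somatodendritic axis; the relative gradient Δ|E| (%/mm) scales
only the magnitude, anchored at z′ = 0.  The biphasic pulse is a
peak-normalized damped sinusoid e^(−t/τ)·sin(2πft) with defaults
f = 2.5 kHz, τ = 0.4 ms (one dominant full cycle, Magstim-class
appearance); both parameters are configurable and recorded in run
manifests.

Numerics: steady-state settling uses backward Euler with 100 giant steps
of 10⁹ ms (gating pinned to its voltage-clamped steady state), accepted
only if max |dv/dt| < 10⁻⁹ mV/ms; transients use Crank–Nicolson with
Rush–Larsen gating updates and a sparse direct tree solve per step
(unconditionally stable).  Default steps: 0.025 ms (axonal stage), 0.01 ms
(dendritic stage, 100 ms window).  Divergence or potentials outside a
configurable sanity band (default −600…+300 mV) abort with a state
snapshot rather than returning NaNs.  The band is wider than a naive
physiological range on purpose: strong suprathreshold fields physically
drive passive terminal hyperpolarization beyond −150 mV, which is signal,
not failure.

## Axonal delay kernel

Arrivals are the first upward 0 mV crossing per axon terminal (linearly
interpolated between samples; repeated crossings ignored).  Histograms use
left-closed bins, Δz′ = 100 μm over z′ ∈ [−2000, 500] μm and Δt = 0.1 ms;
arrivals outside the grid are tallied, never silently dropped, so
histogram mass + overflow equals the arrival count exactly.  Azimuthal
averaging rotates the field rather than the cell — the two are equivalent
for rotations about the somatodendritic axis — which lets one settled
state serve all 60 rotations.

The population kernel is the superposition of the averaged cell kernel
over soma depths weighted by the normalized density d(z) (Σd = 1, which
preserves spike counts), evaluated per time column as a 'same'-mode
correlation along depth with crop start (N_r − 1)//2 of the full result.
Two conventions are fixed deliberately:

- The operation is implemented as `convolve(d, r)` with the centered crop.
  With both depth axes enumerated in ascending order this is the
  physically correct superposition k(z) = Σ_s d(z_s) r(z − z_s); the
  textbook cross-correlation form of the same formula corresponds to
  enumerating the cell kernel's depth axis in descending order.
- The centered 'same' crop maps the cell soma exactly onto its density
  depth only when the z′ grid is symmetric about 0; for asymmetric grids
  the documented crop index makes the z-index → depth mapping
  reproducible, which is what downstream consumers need.

Cell-count ratio scaling (5.04 excitatory, 0.40 inhibitory) converts the
per-presynaptic-cell kernel to per-postsynaptic-cell input.  Resampling
(display at 1 μm / 0.005 ms; dendritic stage at 50 μm) uses separable
pchip interpolation on bin centers, which cannot overshoot below zero.

## Synapto-dendritic stage

Receptor kernels are peak-normalized double exponentials with the shipped
constants (τ_rise/τ_fall ms, E_rev mV, g_peak μS): AMPA 0.05/5.3/0/0.1,
NMDA 15/150/0/0.03, GABAa 0.07/18.2/−80/0.5, GABAb 3.5/260.9/−93/0.5;
NMDA is gated by 1/(1 + 0.28·Mg·e^(−0.062 v)) with Mg = 1 mmol using the
instantaneous local potential each step.  The partial depth-integral of a
kernel over a 50 μm bin is computed exactly as the overlap-weighted sum of
the piecewise-constant bin densities — not by trapezoid on interpolated
bin centers, which would not conserve spike counts under bin tiling.  The
discrete receptor convolution carries the dt factor, so conductances are
in μS and a unit impulse (one spike) reproduces the receptor kernel
exactly.

The somatic output current sums (A_i/R_i)(V_i − V_soma)/L_i over
soma-adjacent dendritic compartments (cross-section area, axial
resistivity, center-to-center path length; μm²·mV/(Ω·cm·μm) → 10² nA),
inward positive.  The zero-input background current — nonzero because the
settled potential is not spatially uniform — is recomputed per morphology
by an identical zero-input simulation and subtracted, which makes
zero-kernel runs identically zero and avoids importing a background value
specific to any particular morphology set.  Kernel mass over bins without
dendritic membrane is reported as "unreceived input" in the run manifest.

Averaging follows ⟨I⟩ = (1/N_morph) Σ_j [Σ_k w_k I_jk / Σ_m w_m] with
w_k the soma density at 25 equidistant depth samples spanning its support.

A note on time support: with the shipped constants, NMDA (τ_fall 150 ms)
and GABAb (260.9 ms) outlive the 100 ms analysis window by construction,
so only the fast-receptor components decay below 1% of peak within it;
the corresponding test asserts the decay property for the AMPA-driven
output where it is attainable.

## Surrogate model

The gPC basis is the product of per-parameter orthonormal Legendre
polynomials (√(2k+1)·P_k on [−1, 1], each parameter affinely mapped from
its physical bounds), truncated anisotropically: univariate order ≤ 20
(≤ 6 for Δ|E|), at most 3 interacting parameters, interacting orders
summing to ≤ 8; over the six parameters θ ∈ [0, 180]°, Δ|E| ∈ [−20, 20]
%/mm, |E| ∈ [100, 400] V/m, f_NMDA ∈ [0.25, 0.75], f_GABAa ∈ [0.9, 1.0],
f_ex ∈ [0.2, 0.8] this yields 1642 basis functions.  Coefficients for all
time points (0–100 ms half-open at 0.2 ms → exactly 500 points) are
obtained at once as the minimal-norm least-squares solution — the
Moore–Penrose pseudoinverse action — with relative singular-value cutoff
10⁻¹².  No regularization or sparse selection is applied.

Sobol indices come directly from the coefficients (orthonormal basis:
variance = Σ c²_α over non-constant α, grouped by nonzero-pattern
support), normalized per time point and also reported time-averaged.
Global derivative sensitivities are signed Monte-Carlo averages of the
analytic basis derivatives over uniform ξ (default n = 10⁴,
seed-reproducible); signed rather than absolute averages are reported
because the sign carries the direction of influence.

## Synthetic data

Two synthetic stand-ins make the package self-contained:

- **Morphologies** (`generate_synthetic`): a single-cylinder soma, a
  vertical axonal trunk with one branch per terminal (terminal depths
  drawn from a truncated normal within z′ ∈ [−2000, 500] μm; the deepest
  branch extends the trunk tip so the terminal count is exact by
  construction), and a mirrored dendritic tree.  These emulate branched
  arbors with depth-distributed terminals — the feature the delay kernels
  measure — but not the tortuosity, diameter tapering, collateral
  structure or arbor statistics of reconstructed cells; kernel *shapes*
  obtained from them are illustrative, not biological.
- **Analytic dendritic-current generator** (`AnalyticDendriticCurrent`): a
  C∞, bounded closed-form I(t, ξ) used to exercise the surrogate at scale.
  It mimics the simulated phenomenology — a fast excitatory peak growing
  with |E| and f_ex, an intensity-dependent secondary bump, a slow
  NMDA-weighted tail, opposing GABA components — and every term couples at
  most three parameters, consistent with the observation that low-order
  effects dominate the variance.  Passing surrogate tests against it
  demonstrates the fitting and sensitivity machinery, not the fidelity of
  the cable simulations.

Soma-density profiles are truncated Gaussians confined to layer bands
(superficial band −270 to −783 μm; column depth 2700 μm), normalized to
Σd = 1.

## Problem sizes

The test suite and the acceptance script run at desk scale by choice:
synthetic cells with ~10–20 terminals discretized at 20 μm (a few hundred
compartments), a handful of azimuthal rotations where full symmetry makes
60 redundant, 2–3 ms axonal windows, and dendritic runs of 10–100 ms at
0.02–0.05 ms steps.  The surrogate stage runs at full published scale
(1642 coefficients, 4000 training / 1000 held-out draws, 500 time points)
because the analytic generator makes it cheap.

## Known limitations

- Generic HH channels: absolute field thresholds (here of order a few
  hundred V/m on the synthetic cells) are not comparable across channel
  models and are deliberately untested quantities.
- No myelination, ion accumulation, stochastic channels, or
  activity-dependent feedback from the postsynaptic cell; the mapping is
  feedforward.
- The correlation-based depth placement assumes cells at different depths
  within a layer experience the same field.
- En-passant boutons are not modeled; only terminal arrivals count.
- Monophasic and controllable-pulse waveforms are not provided (the
  biphasic default is configurable in frequency and damping).
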