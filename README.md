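# tmscouple

Coupling transcranial magnetic stimulation (TMS) induced electric fields to
neural state variables.

TMS depolarizes cortical neurons where the induced field aligns with their
axons, preferentially at axon terminals.  Models of cortical responses to
TMS (I-wave generation, motor evoked potentials) usually bypass this step
and inject arbitrary pulses into their circuits.  `tmscouple` computes the
missing link as a two-stage coupling model between a directly stimulated
presynaptic population and its postsynaptic targets:

1. **Axonal delay kernel** — compartmental Hodgkin–Huxley simulations of
   branched neurons under a parameterized field E(θ, φ, |E|, Δ|E|) with a
   normalized biphasic pulse.  Action potentials initiate at terminals and
   backpropagate through the arbor; each terminal's first 0 mV crossing is
   histogrammed over soma-relative depth z′ and time (Δz = 100 μm,
   Δt = 0.1 ms), averaged over 60 azimuthal rotations and over
   morphologies/subtypes, and lifted to a cortical-depth population kernel
   k(z, t) by 'same'-mode cross-correlation with the normalized soma-density
   profile d(z), scaled by the presynaptic:postsynaptic count ratio
   (5.04 excitatory, 0.40 inhibitory for the shipped L2/3 → L5 circuit).
2. **Synapto-dendritic delay kernel** — the population kernels drive
   AMPA/NMDA/GABAa/GABAb conductances on each dendritic compartment of a
   quenched (gNa = 0 on soma and axon) postsynaptic cell,

       g_AMPA = (A/A_bin)(1 − f_NMDA) f_ex · K_AMPA ⊛ K_z,ex    (etc.)

   where K_z is the 50 μm partial depth-integral of the kernel and K_SYN a
   peak-normalized double exponential; NMDA is gated by
   1/(1 + 0.28·Mg·exp(−0.062 v)).  The output is the baseline-subtracted
   axial current entering the soma, I = −Σ (A_i/R_i)(V_soma − V_i)/L_i
   (inward positive), averaged over 25 density-weighted soma depths and the
   morphology set.

A **generalized polynomial chaos (gPC) surrogate** expands the mean current
I(t, ξ) over six uniform parameters ξ = (θ, Δ|E|, |E|, f_NMDA, f_GABAa,
f_ex) in orthonormal Legendre polynomials with an anisotropic truncation
(univariate order ≤ 20, ≤ 6 for Δ|E|, ≤ 3 interacting parameters,
interaction orders summing to ≤ 8 — 1642 basis functions), fitted per time
point by Moore–Penrose pseudoinverse.  Sobol indices and global
derivative-based sensitivities follow directly from the coefficients.

## Worked example

Fit the full surrogate to the packaged smooth analytic dendritic-current
generator and inspect its sensitivities:

```python
from tmscouple import (
    AnalyticDendriticCurrent, ParamBounds, PolynomialChaosSurrogate,
    nrmsd, sample_params,
)

bounds = ParamBounds()
generator = AnalyticDendriticCurrent(bounds=bounds)
x_train = sample_params(bounds, 4000, seed=1)
x_test = sample_params(bounds, 1000, seed=2)

model = PolynomialChaosSurrogate(bounds=bounds)
model.fit(x_train, generator(x_train))
err = nrmsd(generator(x_test), model.predict(x_test))
print(f"basis functions: {len(model.multi_indices_)}")
print(f"held-out NRMSD: {err:.3f} %")

sens = model.sobol_indices()
for support, value in sens.top_supports(5):
    label = " x ".join(bounds.names[j] for j in support)
    print(f"  S[{label}] = {value:.3f}")
```

prints

```
basis functions: 1642
held-out NRMSD: 0.002 %
  S[f_ex] = 0.447
  S[intensity] = 0.321
  S[intensity x f_ex] = 0.105
  S[rel_gradient] = 0.037
  S[f_nmda] = 0.030
```

The 1642 basis functions are the anisotropic truncation over six
parameters; the held-out NRMSD is the time-averaged normalized RMS error of
the surrogate on 1000 unseen parameter draws; the time-averaged Sobol
indices say that the excitatory/inhibitory balance and the field intensity
(and their interaction) carry most of the output variance of this
generator, with the field gradient and NMDA balance playing minor roles.

The full simulation pipeline is exposed both as a library
(`run_axonal_stage`, `run_dendritic_stage`, `run_surrogate_stage`) and as a
CLI:

```bash
tmscouple fixtures --seed 1 --out fixtures/
tmscouple axonal --config config.yaml --out out/
tmscouple dendritic --ex-kernel out/population_kernel_theta30_E250.h5 \
    --inh-kernel out/population_kernel_theta30_E250.h5 --out out/
tmscouple surrogate --out out/
```

Every stage writes a JSON manifest with the configuration hash, seeds,
timings and warnings (histogram overflow, unreceived synaptic input).

## Scope

The package generates its own branched synthetic morphologies (SWC import
is supported for reconstructed cells) and uses classic Hodgkin–Huxley
channels with Q10 temperature scaling; absolute activation thresholds
therefore differ from models with specialized human-adjusted channel sets,
while the mechanism — terminal polarization, backpropagation, delay-kernel
statistics — is preserved.  Finite-element head-model field computation,
morphology repair, and spinal-circuit readouts are out of scope.
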