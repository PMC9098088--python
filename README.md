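# ndfmem

Simulation and analysis of **negative-derivative-feedback (NDF) working-memory
circuits** repaired online by unsupervised synaptic plasticity.

Persistent neural activity that stores an analog value — a firing-rate level,
or a location on a ring — requires finely tuned recurrent connectivity.  In
NDF circuits the tuning condition is *balance*: recurrent excitation and
inhibition of equal strength but different kinetics, with excitation slower,
so that their difference approximates −dr/dt and opposes drift.  A few
percent loss of excitatory-to-excitatory strength (as under NMDA-receptor
blockade) breaks the balance and the memory collapses within a trial.  This
package asks, and quantifies, how local unsupervised plasticity rules can
re-tune the balance from the activity itself, trial after trial.

It is aimed at computational neuroscientists studying continuous attractors,
the fine-tuning problem, and homeostatic/differential plasticity.

## Models

**Homogeneous population (rate-coded memory).**  The reduced model is

    τ dr/dt = −r + (W_exc − W_inh) r − w_der dr/dt + I(t),
    w_der = W_inh (τ_exc − τ_inh),

integrated by explicit Euler with the algebraic rearrangement
dr/dt = (−r + (W_exc−W_inh) r + I)/(τ + w_der).  A trial is stimulus
(50 time units, amplitude uniform on [0, 2c]), delay (300, input off), and an
inter-trial reset.  Four plasticity rules act on W_exc during the delay:

| rule | update |
|---|---|
| differential | dW/dt = −α_d (dr/dt) r |
| homeostatic | dW/dt = −α_h W (r − r0) |
| combined | W = g·U, dg/dt = −α_h (r−r0) g, dU/dt = −α_d (dr/dt) r |
| saturating differential | differential with dr/dt clipped to ±K (can stay on during the stimulus) |

A three-variable variant with explicit synaptic filters s_exc, s_inh
validates the one-variable reduction.

**Ring network (location-coded memory).**  N = 64 excitatory/inhibitory
columns with preferred features θ ∈ [−π, π), Gaussian circulant kernels
W_ij(θ,θ′) = J_ij exp(−d(θ−θ′)²/σ_ij²), rectified-linear transfer, four
synaptic-variable classes (τ_EE ≫ τ_EI, τ_IE, τ_II), and a Gaussian stimulus
with a low-pass-filtered time course.  Under per-mode balance
λ_EE(n)λ_II(n) = λ_EI(n)λ_IE(n) every cosine Fourier mode of the pattern
obeys scalar NDF dynamics and persists.  Structured perturbations (global,
postsynaptic/row-wise, presynaptic/column-wise scaling of W_EE) break the
balance; the same plasticity rules, applied to W_EE during the delay, repair
it.

**Analysis suite.**  Cosine Fourier modes; per-mode E-I balance from the
eigendecomposition of the (plastic) W_EE matched to Fourier modes; Poisson
population-vector decoding error ⟨1 − cos(θ0 − θ̃0)⟩; per-neuron spatial
selectivity F1 and the translation-invariance index std(F1)/mean(F1);
exponential decay-timescale fits; per-neuron E-I input ratios.

## Worked example

```python
import numpy as np
from ndfmem import (RateModelParams, TrialProtocol, PlasticityConfig,
                    run_session, trials_to_criterion)

# 10% loss of recurrent excitation: W_exc = 450 against W_inh = 500
params = RateModelParams(W_inh=500.0, W_exc0=450.0, c=500.0)
cfg = PlasticityConfig(rule="differential", alpha_d=0.01)
trace = run_session(params, TrialProtocol(), cfg, 500, np.random.default_rng(1))

print("trials to reach 0.99*W_inh:", trials_to_criterion(trace))
print("final W_exc/W_inh (mean of last 50 trials): %.4f" % trace.ratio[-50:].mean())
```

```
trials to reach 0.99*W_inh: 31
final W_exc/W_inh (mean of last 50 trials): 1.0020
```

Before learning, the 10% imbalance makes delay activity decay with an
effective time constant of ≈ 9.8 time units, so the memory is gone well
before the end of the delay.  Differential plasticity senses the decay
(dr/dt < 0) and potentiates W_exc each trial; after ~31 trials the ratio
crosses 0.99 and it settles at 1.002 — the exact fixed point W_exc = W_inh + τ
at which the recurrent drive also cancels the leak.

The same experiment from the shell:

```bash
ndfmem rate --plasticity differential --alpha-d 0.01 --strength 0.1 \
       --trials 500 --seed 1 --out runs/differential
ndfmem preset list          # shipped protocols (fig1, fig3, fig6, fig8, ...)
ndfmem preset run fig3 --seed 1 --out runs/homeostatic
```

Each run writes a per-trial `trace.csv` and a `metadata.json` sidecar with
the full parameter snapshot and seed; ring runs also store the final
connectivity (`connectivity.npz`), which `ndfmem analyze` can re-score.

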