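# Methods

## Models

### Homogeneous population

The reduced model treats one recurrently connected population as a single
linear rate variable,

    τ dr/dt = −r + (W_exc − W_inh) r − w_der dr/dt + I(t),

with τ = 1 (time is measured in intrinsic time constants),
w_der = W_inh·(τ_exc − τ_inh) and τ_exc − τ_inh = 1.  The derivative-feedback
term arises from balanced excitation and inhibition with different kinetics:
in the three-variable variant

    τ dr/dt = −r + W_exc s_exc − W_inh s_inh + I(t),
    τ_x ds_x/dt = −s_x + r    (x ∈ {exc, inh}),

the difference s_exc − s_inh ≈ −(τ_exc−τ_inh) dr/dt at the low frequencies
characteristic of persistent activity.  Only the difference of the synaptic
time constants is constrained; the full variant defaults to τ_exc = 2,
τ_inh = 1 and is used as a validation model (the reduction tracks it within
2% on the delay-period activity, and within ~1% on the trial protocol used
throughout).  The model is linear by assumption — no transfer nonlinearity —
and W_inh is never plastic.

Reference parameters: W_inh = 500, c = 500 (mean stimulus amplitude),
trial = 50 (stimulus) + 300 (delay) + 50 (inter-trial) time units.  The
stimulus amplitude is drawn once per trial from the continuous uniform
distribution on [0, 2c], which has the required mean c; activity is reset to
zero in the inter-trial interval.

### Plasticity rules and gating

Differential: dW/dt = −α_d (dr/dt) r, with dr/dt the same algebraically
rearranged instantaneous derivative the integrator uses (no finite
differencing of stored traces).  Homeostatic: dW/dt = −α_h W (r − r0),
multiplicative and sign-preserving.  Combined: W = g·U with g homeostatic
and U differential; to first order the materialized update equals the
additive sum of the two rules.  Saturating differential: the drive is
clipped to [−K, K]; below threshold it is the standard rule (the natural
continuous completion), above it the magnitude saturates at α_d·K·r.  The
saturating rule can stay on during the stimulus (always-on mode), because
the clip bounds the "unlearning" the stimulus transient would cause.

Gating is hard per epoch: off during stimulus and inter-trial interval, on
during the delay.  On the ring the delay gate is additionally multiplied by
1 − I_temp(t) so the decaying stimulus tail does not feed the rule; a flag
disables that factor.  No weight bounds are enforced by default (the
equations are followed literally); an optional nonnegativity clamp exists.
Plasticity updates are applied synchronously with the Euler state update,
using the derivative evaluated at the current step.

### Normalized delay-period dynamics

With w = W_exc/W_inh and r_n = r·W_inh/c (and 1/W_inh → 0), the delay
dynamics reduce to dr_n/dt = (w−1) r_n with

* differential: dw/dt = −α_eff (dr_n/dt) r_n, α_eff = α c²/W_inh³ — hence
  the scaling equivalences (α, k·W_inh) ↔ (α·k³, W_inh) and
  (α, k·c) ↔ (α·k², c), and the conservation of w + (α_eff/2) r_n² along any
  input-free trajectory (integrating to the closed-form final rate
  r_n(∞)² = r_n(0)² − 2W_inh³p/(αc²) when one trial carries w from 1−p to 1);
* homeostatic: dw/dt = −α′ w (r_n − r0′) with α′ = αc/W_inh,
  r0′ = W_inh r0/c, whose fixed point (r0′, 1) has purely imaginary Jacobian
  eigenvalues ± i√(α′r0′); in raw parameters the oscillation frequency is
  √(α·r0).

These normalized systems are integrated with `scipy.integrate.solve_ivp`
(RK45, rtol 1e−10, atol 1e−12): the conservation law then holds to ~1e−9
relative, which an O(dt) Euler scheme could not certify.  The production
trial simulator remains explicit Euler for transparency and speed.

### Ring network

N = 64 excitatory and inhibitory populations at preferred features
θ_k = −π + 2πk/N.  Kernels W_ij(θ,θ′) = J_ij exp(−d(θ−θ′)²/σ_ij²) are built
by evaluating the center row on the grid and circularly shifting it, so the
matrices are exactly circulant; stimulus profiles centered on grid points
are likewise rolled copies of one canonical profile, making on-grid
translation equivariance exact up to round-off in the (rotated) matrix-product
summation order.  The wrapped distance is min(|Δ|, 2π−|Δ|); the alternative
literal reading mod(|Δ|, π) — which would couple antipodes maximally — is
selectable via `distance_convention="mod_pi"` but is not the default, since
only the min convention yields the unimodal kernels the architecture
requires.

The ring integrals are discretized as Riemann sums: recurrent input =
Δθ·(W @ s) with Δθ = 2π/N, which reproduces the continuum integral the
kernel amplitudes were specified for.  The rectified-linear transfer wraps
the total E input (recurrent + external) and the recurrent I input.  Rates
therefore never go negative (each Euler step is a convex combination of the
current rate and a nonnegative drive).

Reference parameters (the standard table): τ_E = 20, τ_I = 10, τ_EE = 100,
τ_EI = 10, τ_IE = 25, τ_II = 10, τ_o = 100; J_EE = J_EI = 100,
J_IE = J_II = 200; σ_EE = σ_IE = 0.2π, σ_EI = σ_II = 0.1π; stimulus
J_o = 270, σ_o = 0.25π, h0 = 200; t_stim = 500, t_total = 3500.  With these
values the four kernels satisfy λ_EE(n)λ_II(n) = λ_EI(n)λ_IE(n) exactly in
every Fourier mode (the amplitude products are both 100·200 and the width
pairing matches), and in linear test mode (`transfer="linear"`) each cosine
mode of the simulated pattern follows the scalar two-population dynamics
built from the kernels' DFT coefficients to machine precision.

**Integration step.**  The per-mode linear system carries, besides the slow
memory eigenvalue (|Re λ| ≤ ~1e−5 unperturbed), a damped oscillation at
roughly 0.9 rad per time unit (eigenpair ≈ −0.12 ± 0.92i).  Forward Euler is
only stable for that pair when |1 + dt·λ| < 1, i.e. dt ≲ 0.28; dt = 0.5
amplifies it by ~4% per step and corrupts the late delay.  The default is
therefore **dt = 0.25**, validated by the convergence self-check at dt/2.
The analogous argument sets dt = 0.005 for the homogeneous three-variable
variant (its fast eigenpair is ≈ −1.25 ± 15.8i at W = 500) and dt = 0.1 for
the reduced model.

### Perturbations

Multiplicative scalings of W_EE only: global (every entry × (1−p)),
postsynaptic (row-wise) and presynaptic (column-wise) with the bell profile
1 − p·exp(−(d(θ, center)/σ_p)²).  σ_p has no reference value; the default is
0.25π (comparable to the stimulus width) and results that depend on it are
reported as sweeps.  The printed strength is the reduction p, so "10%
perturbation" multiplies by 0.9.

### Evaluation

The connectivity is frozen and the network is stimulated once at each of the
N preferred locations (continuous locations are supported but off by
default); the end-of-delay excitatory rates form the tuning matrix.
Decoding draws Poisson spike counts with means 0.2·rate (rates in Hz, a
200 ms window), decodes with the population vector
θ̃0 = arg Σ n_k e^{iθ_k}, and scores ⟨1 − cos(θ0 − θ̃0)⟩ over 20 repeats per
location.  A zero-resultant count vector is decoded as a uniformly random
angle, so an information-free network scores an expected error of one.
Spatial selectivity is the modulus of the first circular Fourier coefficient
of each neuron's tuning curve; translation invariance is std/mean of that
selectivity across neurons (population standard deviation, uniform weight
per neuron).  Per-mode balance after learning takes λ_EE(n) from the
eigendecomposition of the plastic W_EE, matching eigenvectors to Fourier
modes by largest projection onto span{cos nθ, sin nθ} (conjugate pairs
merged and reported by modulus, with the similarity score reported so
ambiguous matches are visible); the static kernels contribute their DFT
eigenvalues.  Decay-timescale fits are log-linear least squares on the mode
amplitude, excluding the first 100 time units of the delay as transient and
returning a capped sentinel (1e12) for non-decaying traces.

## Reproduced protocols and their outcomes

* Differential repair of a 10% homogeneous perturbation (α = 0.01):
  W_exc/W_inh returns to 1.002 — the leak-compensating fixed point
  W_exc = W_inh + τ — with the 0.99 criterion crossed after ~31 trials;
  trials-to-criterion grids over (α, W_inh) and (α, c) spanning 50%–200% of
  the reference values recover the scaling exponents −3 and +2.
* Homeostatic repair with matched r0 = 50 (α = 4×10⁻⁸): plateau at
  1.002 ± 0.001; a mismatched low r0 biases the plateau below 1 by exactly
  the amount that makes the delay-average rate equal r0; variability at the
  plateau grows with α (the √(α·r0) oscillation).
* Ring loss-of-information baseline: after a 10% global perturbation every
  low mode decays at −0.00129 per time unit (verified against the per-mode
  Jacobian), leaving ~2% of the end-of-stimulus pattern at the end of the
  delay.  With the reference stimulus amplitudes that residual still biases
  the decoder: the computed initial decoding error is ~0.73–0.80 rather
  than fully information-free (1.0).  The error reaches ~1 for p ≥ 0.2, or
  if rates were globally ~4× smaller.  This is a genuine property of the
  parameter set under this discretization and is reported as computed.
* Ring learning sessions: per-trial weight kicks in this implementation
  scale with the simulated activity level, and at the reference stimulus
  amplitudes a differential rate of α_d = 10⁻³ crosses balance within ~100
  trials, overshoots, and breaks translation invariance instead of settling.
  Scaled-down sessions therefore use α_d = 2×10⁻⁴ (inside the explored range
  10⁻⁵–0.1) on an N = 32 ring with ~300 trials.  There the qualitative
  pattern of interest holds: under a 30% presynaptic perturbation the
  combined rule ends with a decoding error of ~0.26 versus ~0.61 for
  homeostatic-only (which cannot undo column-wise asymmetry and lets the
  bump drift toward the perturbed site), and a slow rule shows the error
  increasing with perturbation strength.

## Test-suite problem sizes

The suite runs homogeneous sessions at full scale (they take seconds) and
ring sessions scaled down: N = 32 columns, ≤ 300 learning trials, evaluation
batteries at session start and end only, and shortened delays (t_total =
1500) for purely dynamical checks.  These sizes keep the complete suite
within a coffee break on one CPU while preserving the kernels' angular
geometry (widths are in radians, so halving N halves only the angular
resolution).

## What the simulations do and do not show

All dynamics are deterministic rate equations; stochasticity enters only
through per-trial stimulus draws and the post-hoc Poisson decoder.  Real
circuits add spiking noise, heterogeneous cell parameters, synapse-level
fluctuations and conduction delays, none of which are modeled; a unit here
is a population column, so "presynaptic perturbation" means a column-wise
change, not single-synapse damage.  Passing tests demonstrate the
self-repair logic of the balance condition under these idealizations — not
robustness to biological noise.  Known limitations: the absolute activity
scale (and with it the effective plasticity speed and the initial
post-perturbation decoding error) depends on the stimulus-amplitude
convention, as quantified above; differential repair of large perturbations
generically produces silent neurons and broken invariance; and homeostatic
repair requires r0 tuned to the delay-start statistics.
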