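"""Homogeneous rate-coded memory population with negative derivative feedback.

The reduced model collapses a recurrent E-I population into a single firing
rate r with dynamics

    tau * dr/dt = -r + (W_exc - W_inh) * r - w_der * dr/dt + I(t),

where ``w_der = W_inh * (tau_exc - tau_inh)`` is the strength of the negative
derivative feedback generated by balanced excitation and inhibition with
different kinetics.  Solved for dr/dt,

    dr/dt = (-r + (W_exc - W_inh) * r + I) / (tau + w_der),

which is the instantaneous derivative used both by the explicit-Euler
integrator and by the differential plasticity rule (no finite differencing of
stored traces).  The full three-variable variant keeps the synaptic filters
s_exc and s_inh explicitly and serves as a validation model.

A trial consists of stimulus presentation (input on, plasticity off), a delay
(input off, plasticity on) and an inter-trial interval in which the activity
is reset to zero.  Time is measured in units of the intrinsic time constant
tau = 1; the default protocol is 50/300/50 time units with the per-trial input
amplitude drawn uniformly on [0, 2c].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .plasticity import PlasticityConfig

__all__ = [
    "RateModelParams",
    "RateState",
    "TrialProtocol",
    "TrialRecord",
    "LearningTrace",
    "BalanceNotReachable",
    "rate_derivative",
    "step_reduced",
    "step_full",
    "run_trial",
    "run_session",
    "simulate_trial_reduced",
    "simulate_trial_full",
    "vector_field",
    "trials_to_criterion",
    "normalize_params",
    "NormalizedDifferentialSystem",
    "NormalizedHomeostaticSystem",
    "balanced_final_rate",
    "homeostatic_oscillation_frequency",
    "convergence_check",
]

#: Guard against runaway Euler integration; |r| beyond this aborts a phase.
OVERFLOW_GUARD = 1e12


class BalanceNotReachable(ValueError):
    """The balanced state cannot be reached within a single trial."""


@dataclass(frozen=True)
class RateModelParams:
    """Parameters of the homogeneous population.

    ``tau`` and ``tau_diff = tau_exc - tau_inh`` are unit time constants; the
    derivative-feedback strength is ``w_der = W_inh * tau_diff``.  ``c`` is
    the mean input amplitude during stimulation.  ``tau_exc``/``tau_inh`` are
    used only by the full three-variable variant; only their difference is
    constrained by the reduced model.
    """

    W_inh: float = 500.0
    W_exc0: float = 500.0
    tau: float = 1.0
    tau_diff: float = 1.0
    c: float = 500.0
    tau_exc: float = 2.0
    tau_inh: float = 1.0

    def __post_init__(self) -> None:
        if self.W_inh <= 0:
            raise ValueError("W_inh must be positive")
        if self.tau <= 0 or self.tau_diff <= 0:
            raise ValueError("tau and tau_diff must be positive")
        if not (self.tau_exc > self.tau_inh > 0):
            raise ValueError("the full variant requires tau_exc > tau_inh > 0")

    @property
    def w_der(self) -> float:
        """Derivative-feedback strength W_inh * (tau_exc - tau_inh)."""
        return self.W_inh * self.tau_diff


@dataclass
class RateState:
    """Dynamic state: firing rate, plastic excitatory weight and time.

    ``s_exc``/``s_inh`` are the filtered-rate synaptic variables of the full
    variant.  ``g``/``U`` hold the factorized weight of the combined rule
    (W_exc = g*U); they are initialized lazily when that rule is used.
    """

    r: float = 0.0
    W_exc: float = 500.0
    t: float = 0.0
    s_exc: float = 0.0
    s_inh: float = 0.0
    g: Optional[float] = None
    U: Optional[float] = None


@dataclass(frozen=True)
class TrialProtocol:
    """Trial timing and input statistics.

    ``input_range`` is the support of the uniform per-trial input amplitude;
    ``None`` resolves to [0, 2c] so the mean input strength equals ``c``.
    Plasticity is active in the delay epoch only (the integrator enforces the
    gating; ``always_on`` configurations override it).
    """

    t_stim: float = 50.0
    t_delay: float = 300.0
    t_iti: float = 50.0
    input_range: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if min(self.t_stim, self.t_delay, self.t_iti) <= 0:
            raise ValueError("all protocol durations must be positive")
        if self.input_range is not None and self.input_range[1] < self.input_range[0]:
            raise ValueError("input_range must be increasing")

    def resolve_input_range(self, params: RateModelParams) -> Tuple[float, float]:
        if self.input_range is not None:
            return self.input_range
        return (0.0, 2.0 * params.c)

    def draw_input(self, params: RateModelParams, rng: np.random.Generator) -> float:
        lo, hi = self.resolve_input_range(params)
        return float(rng.uniform(lo, hi))


@dataclass
class TrialRecord:
    trial: int
    amplitude: float
    r_end_stim: float
    r_end_delay: float
    W_exc: float


@dataclass
class LearningTrace:
    """Per-trial summary of a learning session of the homogeneous model."""

    trial: np.ndarray
    amplitude: np.ndarray
    r_end_stim: np.ndarray
    r_end_delay: np.ndarray
    W_exc: np.ndarray
    W_inh: float

    @property
    def ratio(self) -> np.ndarray:
        return self.W_exc / self.W_inh

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "trial": self.trial,
                "input_amplitude": self.amplitude,
                "r_end_stim": self.r_end_stim,
                "r_end_delay": self.r_end_delay,
                "W_exc": self.W_exc,
                "ratio": self.ratio,
            }
        )


def rate_derivative(state: RateState, params: RateModelParams, inp: float) -> float:
    """Instantaneous dr/dt of the reduced model.

    dr/dt = (-r + (W_exc - W_inh)*r + I) / (tau + w_der).
    """
    if not math.isfinite(inp):
        raise ValueError("input must be finite")
    denom = params.tau + params.w_der
    if denom <= 0:
        raise ValueError("tau + w_der must be positive")
    return (-state.r + (state.W_exc - params.W_inh) * state.r + inp) / denom


def step_reduced(state: RateState, params: RateModelParams, inp: float, dt: float,
                 cfg: Optional[PlasticityConfig] = None, gate: float = 0.0) -> RateState:
    """Advance the reduced (r, W_exc) system by one explicit-Euler step.

    The plasticity update (if any) uses the same instantaneous derivative as
    the rate update, evaluated at the pre-step state.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    drdt = rate_derivative(state, params, inp)
    W = state.W_exc
    g, U = state.g, state.U
    if cfg is not None and gate > 0.0 and cfg.rule != "none":
        r = state.r
        if cfg.rule == "differential":
            W = W - cfg.alpha_d * gate * dt * drdt * r
        elif cfg.rule == "saturating_differential":
            sensed = min(max(drdt, -cfg.K), cfg.K)
            W = W - cfg.alpha_d * gate * dt * sensed * r
        elif cfg.rule == "homeostatic":
            W = W * (1.0 - cfg.alpha_h * gate * dt * (r - cfg.r0))
        elif cfg.rule == "combined":
            if g is None:
                g, U = 1.0, W
            g = g * (1.0 - cfg.alpha_h * gate * dt * (r - cfg.r0))
            U = U - cfg.alpha_d * gate * dt * drdt * r
            W = g * U
        if cfg.clip_weights and W < 0.0:
            W = 0.0
    r_new = state.r + dt * drdt
    if not math.isfinite(r_new) or abs(r_new) > OVERFLOW_GUARD:
        raise RuntimeError(
            f"reduced-model integration unstable (|r| > {OVERFLOW_GUARD:g}) "
            f"with dt={dt}, W_exc={state.W_exc}, W_inh={params.W_inh}"
        )
    return RateState(r=r_new, W_exc=W, t=state.t + dt, s_exc=state.s_exc,
                     s_inh=state.s_inh, g=g, U=U)


def step_full(state: RateState, params: RateModelParams, inp: float, dt: float) -> RateState:
    """Advance the full (r, s_exc, s_inh) system by one explicit-Euler step.

    tau*dr/dt = -r + W_exc*s_exc - W_inh*s_inh + I;
    tau_x*ds_x/dt = -s_x + r for x in {exc, inh}.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not math.isfinite(inp):
        raise ValueError("input must be finite")
    r, se, si = state.r, state.s_exc, state.s_inh
    drdt = (-r + state.W_exc * se - params.W_inh * si + inp) / params.tau
    dse = (-se + r) / params.tau_exc
    dsi = (-si + r) / params.tau_inh
    r_new = r + dt * drdt
    if not math.isfinite(r_new) or abs(r_new) > OVERFLOW_GUARD:
        raise RuntimeError(
            f"full-model integration unstable with dt={dt}, "
            f"W_exc={state.W_exc}, W_inh={params.W_inh}"
        )
    return RateState(r=r_new, W_exc=state.W_exc, t=state.t + dt,
                     s_exc=se + dt * dse, s_inh=si + dt * dsi, g=state.g, U=state.U)


def _check_finite(r: float, W: float, dt: float, params: RateModelParams, phase: str) -> None:
    if not (math.isfinite(r) and math.isfinite(W)) or abs(r) > OVERFLOW_GUARD:
        raise RuntimeError(
            f"integration unstable during {phase} (r={r!r}) with dt={dt}, "
            f"W_inh={params.W_inh}, w_der={params.w_der}"
        )


def _integrate_phase(r: float, W: float, g, U, params: RateModelParams, inp: float,
                     dt: float, n_steps: int, cfg: Optional[PlasticityConfig],
                     gate: float, phase: str):
    """Tight Euler loop over one trial epoch of the reduced model.

    The rule dispatch happens once per phase so the per-step cost stays at a
    handful of float operations; sessions of thousands of trials depend on it.
    """
    W_inh = params.W_inh
    inv = 1.0 / (params.tau + params.w_der)
    rule = "none" if (cfg is None or gate <= 0.0) else cfg.rule
    if rule == "none":
        for _ in range(n_steps):
            drdt = (-r + (W - W_inh) * r + inp) * inv
            r += dt * drdt
    elif rule == "differential":
        a = cfg.alpha_d * gate * dt
        for _ in range(n_steps):
            drdt = (-r + (W - W_inh) * r + inp) * inv
            W -= a * drdt * r
            r += dt * drdt
    elif rule == "saturating_differential":
        a = cfg.alpha_d * gate * dt
        K = cfg.K
        for _ in range(n_steps):
            drdt = (-r + (W - W_inh) * r + inp) * inv
            sensed = -K if drdt < -K else (K if drdt > K else drdt)
            W -= a * sensed * r
            r += dt * drdt
    elif rule == "homeostatic":
        a = cfg.alpha_h * gate * dt
        r0 = cfg.r0
        for _ in range(n_steps):
            drdt = (-r + (W - W_inh) * r + inp) * inv
            W *= 1.0 - a * (r - r0)
            r += dt * drdt
    elif rule == "combined":
        if g is None:
            g, U = 1.0, W
        ah = cfg.alpha_h * gate * dt
        ad = cfg.alpha_d * gate * dt
        r0 = cfg.r0
        for _ in range(n_steps):
            W = g * U
            drdt = (-r + (W - W_inh) * r + inp) * inv
            g *= 1.0 - ah * (r - r0)
            U -= ad * drdt * r
            r += dt * drdt
        W = g * U
    else:  # pragma: no cover - PlasticityConfig already validates
        raise ValueError(f"unknown rule {rule!r}")
    if cfg is not None and cfg.clip_weights and W < 0.0:
        W = 0.0
    _check_finite(r, W, dt, params, phase)
    return r, W, g, U


def run_trial(state: RateState, params: RateModelParams, protocol: TrialProtocol,
              cfg: Optional[PlasticityConfig], rng: np.random.Generator,
              dt: float = 0.1, trial_index: int = 1) -> Tuple[RateState, TrialRecord]:
    """Run one trial: stimulus, delay, inter-trial reset.

    Draws the input amplitude, integrates the stimulus epoch with plasticity
    gated off (unless ``always_on``), the delay with input off and plasticity
    on, then resets the activity to zero for the inter-trial interval.
    """
    amplitude = protocol.draw_input(params, rng)
    n_stim = int(round(protocol.t_stim / dt))
    n_delay = int(round(protocol.t_delay / dt))
    r, W, g, U = state.r, state.W_exc, state.g, state.U

    stim_gate = 1.0 if (cfg is not None and cfg.always_on) else 0.0
    r, W, g, U = _integrate_phase(r, W, g, U, params, amplitude, dt, n_stim,
                                  cfg, stim_gate, "stimulus")
    r_end_stim = r
    r, W, g, U = _integrate_phase(r, W, g, U, params, 0.0, dt, n_delay,
                                  cfg, 1.0, "delay")
    r_end_delay = r
    # Inter-trial interval: activity is reset to zero, plasticity naturally off.
    new_state = RateState(r=0.0, W_exc=W, t=state.t + protocol.t_stim
                          + protocol.t_delay + protocol.t_iti, g=g, U=U)
    record = TrialRecord(trial=trial_index, amplitude=amplitude,
                         r_end_stim=r_end_stim, r_end_delay=r_end_delay, W_exc=W)
    return new_state, record


def run_session(params: RateModelParams, protocol: TrialProtocol,
                cfg: Optional[PlasticityConfig], n_trials: int,
                rng: np.random.Generator, dt: float = 0.1) -> LearningTrace:
    """Run ``n_trials`` successive trials, recording per-trial summaries."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    state = RateState(r=0.0, W_exc=params.W_exc0)
    amplitude = np.empty(n_trials)
    r_stim = np.empty(n_trials)
    r_delay = np.empty(n_trials)
    W_exc = np.empty(n_trials)
    for k in range(n_trials):
        state, rec = run_trial(state, params, protocol, cfg, rng, dt=dt,
                               trial_index=k + 1)
        amplitude[k] = rec.amplitude
        r_stim[k] = rec.r_end_stim
        r_delay[k] = rec.r_end_delay
        W_exc[k] = rec.W_exc
    return LearningTrace(trial=np.arange(1, n_trials + 1), amplitude=amplitude,
                         r_end_stim=r_stim, r_end_delay=r_delay, W_exc=W_exc,
                         W_inh=params.W_inh)


def simulate_trial_reduced(params: RateModelParams, W_exc: float, amplitude: float,
                           protocol: TrialProtocol, dt: float = 0.1,
                           r0: float = 0.0) -> Tuple[np.ndarray, np.ndarray]:
    """Trajectory (t, r) of one plasticity-free trial of the reduced model."""
    n_stim = int(round(protocol.t_stim / dt))
    n_delay = int(round(protocol.t_delay / dt))
    n = n_stim + n_delay
    t = np.arange(n + 1) * dt
    r = np.empty(n + 1)
    r[0] = r0
    state = RateState(r=r0, W_exc=W_exc)
    for k in range(n):
        inp = amplitude if k < n_stim else 0.0
        state = step_reduced(state, params, inp, dt)
        r[k + 1] = state.r
    return t, r


def simulate_trial_full(params: RateModelParams, W_exc: float, amplitude: float,
                        protocol: TrialProtocol, dt: float = 0.005,
                        ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Trajectory (t, r, s_exc, s_inh) of one trial of the full variant.

    The fast E-I loop of the three-variable system oscillates at roughly
    sqrt(W_inh*(1/tau_inh - 1/tau_exc)) per time unit (about 16 for the
    default parameters), so the explicit-Euler step must satisfy
    |1 + dt*lambda| < 1 for that eigenpair; dt = 0.005 does, with margin.
    """
    if dt > params.tau_inh / 10:
        raise ValueError("dt must resolve the fastest synaptic time constant "
                         f"(dt <= tau_inh/10 = {params.tau_inh / 10})")
    n_stim = int(round(protocol.t_stim / dt))
    n_delay = int(round(protocol.t_delay / dt))
    n = n_stim + n_delay
    t = np.arange(n + 1) * dt
    out = np.zeros((3, n + 1))
    state = RateState(r=0.0, W_exc=W_exc)
    for k in range(n):
        inp = amplitude if k < n_stim else 0.0
        state = step_full(state, params, inp, dt)
        out[0, k + 1] = state.r
        out[1, k + 1] = state.s_exc
        out[2, k + 1] = state.s_inh
    return t, out[0], out[1], out[2]


def vector_field(r_grid, Wexc_grid, params: RateModelParams, alpha: float = 0.01):
    """Phase-plane vector field (dr/dt, dW_exc/dt) with input off.

    Evaluates the coupled rate/differential-plasticity system on the grid of
    (r, W_exc) points; used for phase-plane portraits of the recovery.
    """
    r = np.asarray(r_grid, dtype=float)
    W = np.asarray(Wexc_grid, dtype=float)
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(W))):
        raise ValueError("grids must be finite")
    denom = params.tau + params.w_der
    drdt = (-r + (W - params.W_inh) * r) / denom
    dWdt = -alpha * drdt * r
    return drdt, dWdt


def trials_to_criterion(trace: LearningTrace, criterion: float = 0.99) -> int:
    """First trial (1-based) whose post-trial W_exc >= criterion * W_inh.

    Returns -1 if the criterion is never reached.
    """
    if not (0.0 < criterion <= 1.0):
        raise ValueError("criterion must be in (0, 1]")
    hit = trace.W_exc >= criterion * trace.W_inh
    if not hit.any():
        return -1
    return int(np.argmax(hit)) + 1


@dataclass(frozen=True)
class NormalizedDifferentialSystem:
    """Dimensionless delay-period dynamics under differential plasticity.

    With w = W_exc/W_inh and r_n = r / (c/W_inh) the system reduces to

        dr_n/dt = (w - 1) * r_n + I_hat(t),
        dw/dt   = -alpha_eff * (dr_n/dt) * r_n,

    with the single effective learning rate alpha_eff = alpha * c^2 / W_inh^3
    (time in units of tau_exc - tau_inh).  Along any input-free trajectory
    the quantity w + (alpha_eff/2) * r_n^2 is conserved.
    """

    alpha_eff: float

    def rhs(self, t, y, i_hat: float = 0.0):
        rn, w = y
        drn = (w - 1.0) * rn + i_hat
        return [drn, -self.alpha_eff * drn * rn]

    def conserved(self, rn, w):
        return np.asarray(w) + 0.5 * self.alpha_eff * np.asarray(rn) ** 2

    def simulate(self, rn0: float, w0: float, t_end: float, i_hat: float = 0.0,
                 n_eval: int = 400):
        t_eval = np.linspace(0.0, t_end, n_eval)
        sol = solve_ivp(self.rhs, (0.0, t_end), [rn0, w0], args=(i_hat,),
                        t_eval=t_eval, rtol=1e-10, atol=1e-12, method="RK45")
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"normalized-system integration failed: {sol.message}")
        return sol.t, sol.y[0], sol.y[1]


@dataclass(frozen=True)
class NormalizedHomeostaticSystem:
    """Dimensionless delay-period dynamics under homeostatic plasticity.

        dr_n/dt = (w - 1) * r_n + I_hat(t),
        dw/dt   = -alpha_prime * w * (r_n - r0_prime),

    with alpha_prime = alpha * c / W_inh and r0_prime = W_inh * r0 / c.  The
    input-free fixed point (r_n, w) = (r0_prime, 1) has purely imaginary
    Jacobian eigenvalues +-i*sqrt(alpha_prime * r0_prime), so the linearized
    motion is an oscillation at that angular frequency.
    """

    alpha_prime: float
    r0_prime: float

    def rhs(self, t, y, i_hat: float = 0.0):
        rn, w = y
        drn = (w - 1.0) * rn + i_hat
        return [drn, -self.alpha_prime * w * (rn - self.r0_prime)]

    def simulate(self, rn0: float, w0: float, t_end: float, i_hat: float = 0.0,
                 n_eval: int = 2000):
        t_eval = np.linspace(0.0, t_end, n_eval)
        sol = solve_ivp(self.rhs, (0.0, t_end), [rn0, w0], args=(i_hat,),
                        t_eval=t_eval, rtol=1e-10, atol=1e-12, method="RK45")
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"normalized-system integration failed: {sol.message}")
        return sol.t, sol.y[0], sol.y[1]


def normalize_params(params: RateModelParams, alpha: float, rule: str = "differential",
                     r0: Optional[float] = None):
    """Map raw parameters to the dimensionless delay-period system.

    Differential rule: returns :class:`NormalizedDifferentialSystem` with
    alpha_eff = alpha*c^2/W_inh^3, so (alpha, W_inh, c) and
    (alpha*k^3, k*W_inh, c) — or (alpha*k^2, c) and (alpha, k*c) — collapse
    onto identical systems.  Homeostatic rule: returns
    :class:`NormalizedHomeostaticSystem` with alpha' = alpha*c/W_inh and
    r0' = W_inh*r0/c.
    """
    if params.c <= 0:
        raise ValueError("c must be positive")
    if rule == "differential":
        return NormalizedDifferentialSystem(
            alpha_eff=alpha * params.c ** 2 / params.W_inh ** 3)
    if rule == "homeostatic":
        if r0 is None:
            raise ValueError("r0 is required for the homeostatic normalization")
        return NormalizedHomeostaticSystem(
            alpha_prime=alpha * params.c / params.W_inh,
            r0_prime=params.W_inh * r0 / params.c)
    raise ValueError(f"unknown rule {rule!r}")


def balanced_final_rate(r_n0: float, p: float, alpha: float, c: float,
                        W_inh: float) -> float:
    """Normalized rate once a single trial carries w from 1-p to balance.

    Integrating dw = -alpha_eff * r_n dr_n from w(0) = 1-p to w = 1 gives
    r_n(inf)^2 = r_n(0)^2 - 2*W_inh^3*p/(alpha*c^2); a negative radicand
    means the balanced state is not reachable within the trial.
    """
    radicand = r_n0 ** 2 - 2.0 * W_inh ** 3 * p / (alpha * c ** 2)
    if radicand < 0:
        raise BalanceNotReachable(
            "balance not reachable in one trial: initial activity too low for "
            f"perturbation p={p} at learning rate alpha={alpha}")
    return math.sqrt(radicand)


def homeostatic_oscillation_frequency(alpha: float, r0: float, c: float = 500.0,
                                      W_inh: float = 500.0) -> float:
    """Angular frequency of the homeostatic limit-cycle near balance.

    The normalized fixed point has Jacobian eigenvalues
    +-i*sqrt(alpha'*r0'); in raw parameters the primed factors cancel and the
    frequency is sqrt(alpha * r0) per time unit.
    """
    if min(alpha, r0, c, W_inh) <= 0:
        raise ValueError("all arguments must be positive")
    return math.sqrt(alpha * r0)


def convergence_check(params: RateModelParams, protocol: TrialProtocol,
                      amplitude: float, W_exc: float, dt: float = 0.1) -> float:
    """Max relative trajectory change when the Euler step is halved.

    Compares the dt and dt/2 trajectories of one plasticity-free trial on the
    shared time grid; the default step is accepted when this is below 0.5%.
    """
    t1, r1 = simulate_trial_reduced(params, W_exc, amplitude, protocol, dt=dt)
    _, r2 = simulate_trial_reduced(params, W_exc, amplitude, protocol, dt=dt / 2)
    scale = max(np.max(np.abs(r1)), 1e-12)
    return float(np.max(np.abs(r1 - r2[::2]) / scale))
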