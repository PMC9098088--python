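"""Ring network for location-coded persistent activity.

Columnar excitatory and inhibitory populations are laid out on a ring of N
preferred features theta_k = -pi + 2*pi*k/N.  Connectivity is Gaussian in
wrapped distance and translation-invariant (circulant), giving four kernels
W_EE, W_EI, W_IE, W_II.  Each projection has its own synaptic filter s_ij
relaxing toward the presynaptic rate with time constant tau_ij; the E-to-E
filter is the slowest, which together with per-mode balance of excitation and
inhibition produces negative derivative feedback in every Fourier mode:

    tau_E dr_E/dt = -r_E + q( dtheta * (W_EE s_EE - W_EI s_EI) + I_sp I_temp )
    tau_I dr_I/dt = -r_I + q( dtheta * (W_IE s_IE - W_II s_II) )
    tau_ij ds_ij/dt = -s_ij + r_j

with q the rectified-linear transfer function and the ring integrals
discretized as Riemann sums (matrix-vector product times dtheta = 2*pi/N).
A stimulus is a Gaussian spatial profile on a baseline, gated by a low-pass
filtered pulse in time.  Explicit Euler integrates the trial with a default
dt = 0.25: the fastest recurrent loop of the standard parameter set carries
a damped oscillation at about 0.9 rad per time unit, which forward Euler
amplifies for dt = 0.5 but resolves stably at 0.25 (the convergence
self-check at dt/2 confirms it).  Plasticity acts on W_EE during the delay,
gated by 1 - I_temp(t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from scipy.linalg import circulant

from . import analysis
from .plasticity import CombinedWeightState, PlasticityConfig

__all__ = [
    "RingParams",
    "ConnectivitySet",
    "RingState",
    "StimulusSpec",
    "RingTrialRecord",
    "RingLearningTrace",
    "wrapped_distance",
    "build_connectivity",
    "stimulus_spatial",
    "stimulus_temporal",
    "step_ring",
    "run_ring_trial",
    "compute_tuning",
    "run_learning_session",
]


def wrapped_distance(a, b, convention: str = "min"):
    """Circular distance between angles, in [0, pi].

    ``min`` (default): min(|a-b| mod 2pi, 2pi - |a-b| mod 2pi) — zero iff the
    angles coincide on the circle, maximal pi at antipodes.  ``mod_pi`` is
    the literal mod(|a-b|, pi) convention, exposed for comparison; it makes
    antipodal angles maximally coupled and is not the default because only
    the ``min`` convention yields unimodal connectivity kernels.
    """
    delta = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
    if convention == "min":
        delta = delta % (2.0 * np.pi)
        return np.minimum(delta, 2.0 * np.pi - delta)
    if convention == "mod_pi":
        return delta % np.pi
    raise ValueError(f"unknown distance convention {convention!r}")


@dataclass(frozen=True)
class RingParams:
    """Ring-network parameters (defaults: the standard parameter table).

    Time constants and durations share one unit; kernel widths are in
    radians.  ``distance_convention`` selects the wrapped-distance definition
    used to build kernels and stimuli.
    """

    N: int = 64
    tau_E: float = 20.0
    tau_I: float = 10.0
    tau_EE: float = 100.0
    tau_EI: float = 10.0
    tau_IE: float = 25.0
    tau_II: float = 10.0
    tau_o: float = 100.0
    J_EE: float = 100.0
    J_EI: float = 100.0
    J_IE: float = 200.0
    J_II: float = 200.0
    J_o: float = 270.0
    sigma_EE: float = 0.2 * np.pi
    sigma_EI: float = 0.1 * np.pi
    sigma_IE: float = 0.2 * np.pi
    sigma_II: float = 0.1 * np.pi
    sigma_o: float = 0.25 * np.pi
    h0: float = 200.0
    t_stim: float = 500.0
    t_total: float = 3500.0
    dt: float = 0.25
    distance_convention: str = "min"
    transfer: str = "relu"  # "linear" disables the rectifier (analysis mode)

    def __post_init__(self) -> None:
        if self.N < 4 or self.N % 2:
            raise ValueError("N must be even and >= 4")
        taus = (self.tau_E, self.tau_I, self.tau_EE, self.tau_EI, self.tau_IE,
                self.tau_II, self.tau_o)
        if min(taus) <= 0:
            raise ValueError("all time constants must be positive")
        if not (self.tau_EE > max(self.tau_EI, self.tau_IE, self.tau_II)):
            raise ValueError("tau_EE must exceed the other synaptic time constants "
                             "(slow recurrent excitation drives the derivative feedback)")
        for s in (self.sigma_EE, self.sigma_EI, self.sigma_IE, self.sigma_II, self.sigma_o):
            if not (0.0 < s < np.pi):
                raise ValueError("kernel widths must lie in (0, pi)")
        if not (0.0 < self.t_stim < self.t_total):
            raise ValueError("need 0 < t_stim < t_total")
        if self.transfer not in ("relu", "linear"):
            raise ValueError("transfer must be 'relu' or 'linear'")
        if self.dt <= 0 or self.dt > min(taus) / 10.0:
            raise ValueError(f"dt must be in (0, {min(taus) / 10.0}] to resolve the "
                             "fastest time constant")

    @property
    def theta_grid(self) -> np.ndarray:
        return -np.pi + 2.0 * np.pi * np.arange(self.N) / self.N

    @property
    def dtheta(self) -> float:
        return 2.0 * np.pi / self.N


def build_connectivity(J: float, sigma: float, N: int,
                       convention: str = "min") -> np.ndarray:
    """Circulant Gaussian kernel matrix W[i, j] = J*exp(-d(theta_i-theta_j)^2/sigma^2).

    The center row is evaluated on the preferred-feature grid and circularly
    shifted into the other rows, so the circulant structure (and hence exact
    translation equivariance of the dynamics) holds to the bit.
    """
    if J < 0:
        raise ValueError("J must be nonnegative")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    offsets = 2.0 * np.pi * np.arange(N) / N
    d = wrapped_distance(offsets, 0.0, convention)
    kernel = J * np.exp(-((d / sigma) ** 2))
    return circulant(kernel)


@dataclass
class ConnectivitySet:
    """The four ring kernels plus a pristine copy of W_EE for ratio metrics."""

    W_EE: np.ndarray
    W_EI: np.ndarray
    W_IE: np.ndarray
    W_II: np.ndarray
    W0_EE: np.ndarray

    @classmethod
    def from_params(cls, params: RingParams) -> "ConnectivitySet":
        conv = params.distance_convention
        W_EE = build_connectivity(params.J_EE, params.sigma_EE, params.N, conv)
        return cls(
            W_EE=W_EE,
            W_EI=build_connectivity(params.J_EI, params.sigma_EI, params.N, conv),
            W_IE=build_connectivity(params.J_IE, params.sigma_IE, params.N, conv),
            W_II=build_connectivity(params.J_II, params.sigma_II, params.N, conv),
            W0_EE=W_EE.copy(),
        )

    def copy(self) -> "ConnectivitySet":
        return ConnectivitySet(self.W_EE.copy(), self.W_EI.copy(),
                               self.W_IE.copy(), self.W_II.copy(), self.W0_EE.copy())


@dataclass
class RingState:
    """Rates and synaptic variables of the ring (all length-N vectors)."""

    r_E: np.ndarray
    r_I: np.ndarray
    s_EE: np.ndarray
    s_EI: np.ndarray
    s_IE: np.ndarray
    s_II: np.ndarray
    t: float = 0.0

    @classmethod
    def zeros(cls, N: int) -> "RingState":
        return cls(*(np.zeros(N) for _ in range(6)))


@dataclass(frozen=True)
class StimulusSpec:
    """Stimulus center on the ring; the profile comes from :class:`RingParams`."""

    theta0: float = 0.0

    def __post_init__(self) -> None:
        if not (-np.pi <= self.theta0 < np.pi):
            raise ValueError("theta0 must lie in [-pi, pi)")


def stimulus_spatial(theta0: float, params: RingParams) -> np.ndarray:
    """Spatial stimulus profile J_o*exp(-(d(theta-theta0)/sigma_o)^2) + h0.

    For a stimulus centered on a preferred feature the profile is the
    canonical center profile circularly shifted, making the response exactly
    translation-equivariant (bit for bit) on the grid.
    """
    grid = params.theta_grid
    k0 = int(np.argmin(np.abs(grid - theta0)))
    if abs(grid[k0] - theta0) < 1e-12:
        offsets = 2.0 * np.pi * np.arange(params.N) / params.N
        d = wrapped_distance(offsets, 0.0, params.distance_convention)
        base = params.J_o * np.exp(-((d / params.sigma_o) ** 2)) + params.h0
        return np.roll(base, k0)
    d = wrapped_distance(grid, theta0, params.distance_convention)
    return params.J_o * np.exp(-((d / params.sigma_o) ** 2)) + params.h0


def stimulus_temporal(t: float, params: RingParams) -> float:
    """Temporal stimulus gate: low-pass filtered pulse, continuous at t_stim.

    Rises as 1 - exp(-t/tau_o) during [0, t_stim), then decays exponentially
    from its offset value.
    """
    if t < 0 or t >= params.t_total:
        raise ValueError(f"t={t} outside [0, t_total={params.t_total})")
    peak = 1.0 - math.exp(-params.t_stim / params.tau_o)
    if t < params.t_stim:
        return 1.0 - math.exp(-t / params.tau_o)
    return peak * math.exp(-(t - params.t_stim) / params.tau_o)


def _temporal_profile(params: RingParams) -> np.ndarray:
    """I_temp sampled at every Euler step of a trial."""
    n_steps = int(round(params.t_total / params.dt))
    t = np.arange(n_steps) * params.dt
    peak = 1.0 - np.exp(-params.t_stim / params.tau_o)
    rise = 1.0 - np.exp(-t / params.tau_o)
    fall = peak * np.exp(-(t - params.t_stim) / params.tau_o)
    return np.where(t < params.t_stim, rise, fall)


def step_ring(state: RingState, conn: ConnectivitySet, stim_spatial: np.ndarray,
              i_temp: float, params: RingParams, dt: Optional[float] = None) -> RingState:
    """One explicit-Euler step of the ring dynamics (no plasticity).

    Recurrent drive is the Riemann sum dtheta * W @ s; the rectifier wraps
    the total input current (recurrent plus external for E, recurrent only
    for I); every synaptic variable relaxes toward its presynaptic rate.
    """
    dt = params.dt if dt is None else dt
    if dt > min(params.tau_E, params.tau_I, params.tau_EE, params.tau_EI,
                params.tau_IE, params.tau_II) / 10.0:
        raise ValueError("dt too large for the fastest time constant")
    dth = params.dtheta
    inp_E = dth * (conn.W_EE @ state.s_EE - conn.W_EI @ state.s_EI) + stim_spatial * i_temp
    inp_I = dth * (conn.W_IE @ state.s_IE - conn.W_II @ state.s_II)
    if params.transfer == "relu":
        inp_E = np.maximum(inp_E, 0.0)
        inp_I = np.maximum(inp_I, 0.0)
    dr_E = (inp_E - state.r_E) / params.tau_E
    dr_I = (inp_I - state.r_I) / params.tau_I
    new = RingState(
        r_E=state.r_E + dt * dr_E,
        r_I=state.r_I + dt * dr_I,
        s_EE=state.s_EE + dt * (state.r_E - state.s_EE) / params.tau_EE,
        s_EI=state.s_EI + dt * (state.r_I - state.s_EI) / params.tau_EI,
        s_IE=state.s_IE + dt * (state.r_E - state.s_IE) / params.tau_IE,
        s_II=state.s_II + dt * (state.r_I - state.s_II) / params.tau_II,
        t=state.t + dt,
    )
    if not np.all(np.isfinite(new.r_E)):
        raise RuntimeError(f"ring integration diverged at t={state.t} (dt={dt})")
    return new


@dataclass
class RingTrialRecord:
    theta0: float
    r_E_end_stim: np.ndarray
    r_E_end_delay: np.ndarray
    r_I_end_delay: np.ndarray
    mode_traces: Optional[np.ndarray] = None  # (n_modes, n_steps+1) if recorded


def run_ring_trial(conn: ConnectivitySet, theta0: float, params: RingParams,
                   cfg: Optional[PlasticityConfig] = None,
                   combined_state: Optional[CombinedWeightState] = None,
                   record_modes: int = 0) -> RingTrialRecord:
    """Integrate one trial from a zero state, applying plasticity to W_EE.

    Plasticity runs from t_stim onward (from t = 0 in always-on mode), gated
    by 1 - I_temp(t) when configured, and modifies ``conn.W_EE`` in place
    (through ``combined_state`` for the combined rule).  Snapshots of the
    rates are taken at the end of stimulation and at the end of the delay.
    ``record_modes`` > 0 additionally records that many cosine-mode
    amplitudes of r_E about theta0 at every step.
    """
    N = params.N
    dt = params.dt
    n_steps = int(round(params.t_total / dt))
    i_stim_end = int(round(params.t_stim / dt))
    I_sp = stimulus_spatial(theta0, params)
    it_arr = _temporal_profile(params)

    rule = "none" if cfg is None else cfg.rule
    if rule == "combined" and combined_state is None:
        raise ValueError("combined rule requires a CombinedWeightState")
    # plasticity gate per step
    if cfg is None or rule == "none":
        gate = np.zeros(n_steps)
    elif cfg.always_on:
        gate = np.ones(n_steps)
    else:
        gate = np.where(np.arange(n_steps) < i_stim_end, 0.0,
                        (1.0 - it_arr) if cfg.gate_with_stimulus else 1.0)

    theta = params.theta_grid
    dth = params.dtheta
    W_EE = conn.W_EE
    W_EI, W_IE, W_II = conn.W_EI, conn.W_IE, conn.W_II
    tau_E, tau_I = params.tau_E, params.tau_I
    k_EE, k_EI = dt / params.tau_EE, dt / params.tau_EI
    k_IE, k_II = dt / params.tau_IE, dt / params.tau_II

    r_E = np.zeros(N)
    r_I = np.zeros(N)
    s_EE = np.zeros(N)
    s_EI = np.zeros(N)
    s_IE = np.zeros(N)
    s_II = np.zeros(N)
    r_E_end_stim = np.zeros(N)

    modes = None
    if record_modes:
        modes = np.zeros((record_modes, n_steps + 1))
        cosines = np.stack([np.cos(n * (theta - theta0)) for n in range(record_modes)])

    rectify = params.transfer == "relu"
    for k in range(n_steps):
        inp_E = dth * (W_EE @ s_EE - W_EI @ s_EI) + I_sp * it_arr[k]
        inp_I = dth * (W_IE @ s_IE - W_II @ s_II)
        if rectify:
            np.maximum(inp_E, 0.0, out=inp_E)
            np.maximum(inp_I, 0.0, out=inp_I)
        dr_E = (inp_E - r_E) / tau_E
        dr_I = (inp_I - r_I) / tau_I

        g = gate[k]
        if g > 0.0:
            if rule == "differential":
                W_EE -= (cfg.alpha_d * g * dt) * np.multiply.outer(dr_E, r_E)
            elif rule == "saturating_differential":
                sensed = np.clip(dr_E, -cfg.K, cfg.K)
                W_EE -= (cfg.alpha_d * g * dt) * np.multiply.outer(sensed, r_E)
            elif rule == "homeostatic":
                W_EE *= (1.0 - cfg.alpha_h * g * dt * (r_E - cfg.r0))[:, None]
            elif rule == "combined":
                combined_state.g *= 1.0 - cfg.alpha_h * g * dt * (r_E - cfg.r0)
                combined_state.U -= (cfg.alpha_d * g * dt) * np.multiply.outer(dr_E, r_E)
                W_EE = combined_state.g[:, None] * combined_state.U
            if cfg.clip_weights:
                np.maximum(W_EE, 0.0, out=W_EE)

        s_EE += k_EE * (r_E - s_EE)
        s_IE += k_IE * (r_E - s_IE)
        s_EI += k_EI * (r_I - s_EI)
        s_II += k_II * (r_I - s_II)
        r_E += dt * dr_E
        r_I += dt * dr_I

        if modes is not None:
            modes[:, k + 1] = cosines @ r_E / N
        if k + 1 == i_stim_end:
            r_E_end_stim = r_E.copy()

    if not (np.all(np.isfinite(r_E)) and np.all(np.isfinite(W_EE))):
        raise RuntimeError(f"ring trial diverged (theta0={theta0}, dt={dt})")
    conn.W_EE = W_EE  # rebind for the combined rule's materialized product
    return RingTrialRecord(theta0=theta0, r_E_end_stim=r_E_end_stim,
                           r_E_end_delay=r_E, r_I_end_delay=r_I,
                           mode_traces=modes)


def compute_tuning(conn: ConnectivitySet, params: RingParams) -> analysis.TuningMatrix:
    """End-of-delay tuning matrix: one plasticity-free trial per preferred location."""
    theta = params.theta_grid
    rates = np.empty((params.N, params.N))
    for s, th0 in enumerate(theta):
        rec = run_ring_trial(conn, float(th0), params, cfg=None)
        rates[:, s] = rec.r_E_end_delay
    return analysis.TuningMatrix(rates=rates, theta_grid=theta, theta0_grid=theta.copy())


@dataclass
class RingLearningTrace:
    """Per-trial stimulus log plus periodic evaluation-battery records."""

    trial: np.ndarray
    theta0: np.ndarray
    peak_rate_end_delay: np.ndarray
    eval_trial: np.ndarray
    decoding_error: np.ndarray
    mean_F1: np.ndarray
    normalized_std_F1: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "trial": self.eval_trial,
            "decoding_error": self.decoding_error,
            "mean_F1": self.mean_F1,
            "normalized_std_F1": self.normalized_std_F1,
        })


def run_learning_session(conn: ConnectivitySet, params: RingParams,
                         cfg: PlasticityConfig, n_trials: int,
                         eval_stride: Optional[int], rng: np.random.Generator,
                         decode_scale: float = 0.2, n_repeats: int = 20,
                         continuous_theta0: bool = False) -> RingLearningTrace:
    """Learning session: random stimulus locations, periodic frozen evaluation.

    Each trial draws theta0 uniformly from the preferred-feature grid (or the
    continuous circle when requested) and applies the configured rule.  Every
    ``eval_stride`` trials — and before the first trial, and after the last —
    the connectivity is frozen and the evaluation battery (decoding error
    over all N locations with Poisson repeats, selectivity mean and
    normalized spread) is run.  Separate RNG streams drive stimulus-location
    draws and Poisson decoding, so changing the number of decode repeats does
    not perturb the learning trajectory.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng_theta, rng_decode = rng.spawn(2)
    combined_state = None
    if cfg.rule == "combined":
        combined_state = CombinedWeightState.from_weights(conn.W_EE)

    theta = params.theta_grid
    theta0s = np.empty(n_trials)
    peaks = np.empty(n_trials)
    eval_trials, errs, means, nstds = [], [], [], []

    def _evaluate(trial_idx: int) -> None:
        tuning = compute_tuning(conn, params)
        metrics = analysis.evaluate_network(tuning, rng_decode, scale=decode_scale,
                                            n_repeats=n_repeats)
        eval_trials.append(trial_idx)
        errs.append(metrics["decoding_error"])
        means.append(metrics["mean_F1"])
        nstds.append(metrics["normalized_std_F1"])

    _evaluate(0)
    for k in range(n_trials):
        if continuous_theta0:
            th0 = float(rng_theta.uniform(-np.pi, np.pi))
        else:
            th0 = float(theta[rng_theta.integers(params.N)])
        rec = run_ring_trial(conn, th0, params, cfg=cfg, combined_state=combined_state)
        theta0s[k] = th0
        peaks[k] = rec.r_E_end_delay.max()
        if (eval_stride is not None and (k + 1) % eval_stride == 0) or k + 1 == n_trials:
            _evaluate(k + 1)

    return RingLearningTrace(
        trial=np.arange(1, n_trials + 1), theta0=theta0s,
        peak_rate_end_delay=peaks, eval_trial=np.asarray(eval_trials),
        decoding_error=np.asarray(errs), mean_F1=np.asarray(means),
        normalized_std_F1=np.asarray(nstds),
    )
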